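"""Genomic data model, file readers/writers, and site-region classification.

Coordinates are 0-based half-open internally (BED convention).  GTF input,
which is 1-based closed, is converted on read and back on write.  All
interval arithmetic in the package goes through :class:`GenomicInterval`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ModificationSite",
    "DiffExprRecord",
    "ExpressionMatrix",
    "GtfParseError",
    "SiteTableError",
    "MOD_TYPES",
    "REGION_LABELS",
    "read_gtf",
    "write_gtf",
    "read_site_table",
    "write_site_table",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_mutations",
    "write_mutations",
    "classify_site_region",
]

MOD_TYPES = ("H3K4me1", "H3K4me3", "H3K27ac", "m6A")
HISTONE_MODS = ("H3K4me1", "H3K4me3", "H3K27ac")

#: region labels in precedence order (promoter bins > 3'UTR > CDS > exon > intron > distal)
REGION_LABELS = (
    "promoter_lt1kb",
    "promoter_1to2kb",
    "promoter_2to3kb",
    "utr3",
    "cds",
    "exon",
    "intron",
    "distal",
)

#: GENCODE long-non-coding biotypes collapsed to "lncRNA"
_LNCRNA_BIOTYPES = {
    "lncRNA",
    "lincRNA",
    "antisense",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
    "bidirectional_promoter_lncRNA",
    "macro_lncRNA",
    "processed_transcript",
}


class GtfParseError(ValueError):
    """Malformed GTF input; the message names the offending line."""


class SiteTableError(ValueError):
    """Malformed or invariant-violating modification-site table."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _merged_sorted(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with TSS, exon/CDS/3'UTR structure and biotype.

    ``tss`` is the transcription start site in 0-based coordinates:
    ``body.start`` on the + strand, ``body.end - 1`` on the - strand.
    """

    gene_id: str
    biotype: str  # protein_coding | lncRNA | other
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.biotype not in ("protein_coding", "lncRNA", "other"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        object.__setattr__(self, "exons", tuple(_merged_sorted(self.exons)))
        object.__setattr__(self, "cds", tuple(_merged_sorted(self.cds)))
        object.__setattr__(self, "utr3", tuple(_merged_sorted(self.utr3)))
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} / {b}")
        for name, ivs in (("cds", self.cds), ("utr3", self.utr3)):
            for iv in ivs:
                if not any(
                    ex.chrom == iv.chrom and ex.start <= iv.start and iv.end <= ex.end
                    for ex in self.exons
                ):
                    raise ValueError(
                        f"{self.gene_id}: {name} interval {iv} not contained in any exon"
                    )
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(f"{self.gene_id}: TSS outside gene body")

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand != "-" else self.body.end - 1

    def promoter_window(self, window: int = 3000) -> GenomicInterval:
        """The [tss - window, tss + window) promoter interval (clipped at 0)."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - window), self.tss + window, self.strand
        )


@dataclass(frozen=True)
class ModificationSite:
    """A differential histone site (DHMS) or m6A site (MMS).

    ``fold_change`` is signed: log2 fold-change for histone sites, enrichment
    direction for m6A sites.  ``p_value`` lies in (0, 1].
    """

    interval: GenomicInterval
    mod_type: str
    fold_change: float
    p_value: float
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"mod_type must be one of {MOD_TYPES} (got {self.mod_type!r})")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1] (got {self.p_value})")
        if not np.isfinite(self.fold_change):
            raise ValueError("fold_change must be finite")


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-gene differential-expression result on the log2 scale."""

    gene_id: str
    log2fc: float
    p_value: float
    p_adj: float

    def __post_init__(self) -> None:
        for name, p in (("p_value", self.p_value), ("p_adj", self.p_adj)):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must be in (0, 1] (got {p})")

    @property
    def passes(self) -> bool:
        """The |log2FC| > 1 and p < 0.05 differential-expression rule."""
        return abs(self.log2fc) > 1.0 and self.p_value < 0.05


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with per-sample metadata.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns.
    ``sample_meta`` is indexed by sample_id and may carry ``cohort``,
    ``os_time`` (days), ``os_event`` (0/1), ``ici_response``
    ("responder"/"non_responder") and any extra columns (e.g. planted
    cluster labels).  ``mutations`` maps sample_id to a frozenset of
    mutated gene_ids.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    mutations: dict[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples missing from sample_meta: {list(missing)[:5]}")
        self.sample_meta = self.sample_meta.loc[self.values.columns]
        if "os_time" in self.sample_meta:
            t = pd.to_numeric(self.sample_meta["os_time"], errors="coerce")
            if (t.dropna() <= 0).any():
                raise ValueError("os_time must be > 0 where present")
        if self.mutations is not None:
            self.mutations = {s: frozenset(g) for s, g in self.mutations.items()}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def cohorts(self) -> pd.Series:
        if "cohort" in self.sample_meta:
            return self.sample_meta["cohort"]
        return pd.Series("all", index=self.values.columns, name="cohort")

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        muts = None
        if self.mutations is not None:
            muts = {s: self.mutations[s] for s in ids if s in self.mutations}
        return ExpressionMatrix(
            self.values[ids].copy(), self.sample_meta.loc[ids].copy(), muts
        )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}: line {lineno}: invalid 1-based closed interval [{start}, {end}]"
                )


def _collapse_biotype(gene_type: str) -> str:
    if gene_type == "protein_coding":
        return "protein_coding"
    if gene_type in _LNCRNA_BIOTYPES:
        return "lncRNA"
    return "other"


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GENCODE-dialect GTF into :class:`GeneModel` records.

    Uses gene/exon/CDS/three_prime_UTR (or UTR) features; 1-based closed
    coordinates are converted to 0-based half-open.  Genes without exon
    records are skipped with a warning.  Malformed lines raise
    :class:`GtfParseError` naming the line number.
    """
    import pyranges

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    df = pyranges.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
    if df.empty:
        return []
    if "gene_id" not in df.columns:
        raise GtfParseError(f"{path}: no gene_id attribute found")
    genes: list[GeneModel] = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        feats = sub.set_index(sub["Feature"].astype(str), drop=False)
        gene_rows = sub[sub["Feature"] == "gene"]
        if gene_rows.empty:
            raise GtfParseError(f"{path}: gene {gene_id} has no 'gene' feature line")
        g = gene_rows.iloc[0]
        strand = str(g["Strand"]) if str(g["Strand"]) in ("+", "-") else "."
        chrom = str(g["Chromosome"])

        def _intervals(feature_names: tuple[str, ...]) -> tuple[GenomicInterval, ...]:
            rows = sub[sub["Feature"].isin(feature_names)]
            return tuple(
                GenomicInterval(chrom, int(r.Start), int(r.End), strand)
                for r in rows.itertuples()
            )

        exons = _intervals(("exon",))
        if not exons:
            warnings.warn(f"gene {gene_id} has no exons; skipped", stacklevel=2)
            continue
        gene_type = str(g["gene_type"]) if "gene_type" in sub.columns else "other"
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                biotype=_collapse_biotype(gene_type),
                body=GenomicInterval(chrom, int(g["Start"]), int(g["End"]), strand),
                exons=exons,
                cds=_intervals(("CDS",)),
                utr3=_intervals(("three_prime_UTR", "UTR")),
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.body.start, gm.gene_id))
    return genes


_GENCODE_BIOTYPE = {"protein_coding": "protein_coding", "lncRNA": "lncRNA", "other": "misc_RNA"}


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as a GENCODE-dialect GTF (1-based closed on disk)."""
    lines = []
    for gm in sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id)):
        attrs = f'gene_id "{gm.gene_id}"; gene_type "{_GENCODE_BIOTYPE[gm.biotype]}";'

        def _line(feature: str, iv: GenomicInterval) -> str:
            return "\t".join(
                [
                    iv.chrom,
                    "epicrosstalk",
                    feature,
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    attrs,
                ]
            )

        lines.append(_line("gene", gm.body))
        for ex in gm.exons:
            lines.append(_line("exon", ex))
        for c in gm.cds:
            lines.append(_line("CDS", c))
        for u in gm.utr3:
            lines.append(_line("three_prime_UTR", u))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site tables and matrices
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["chrom", "start", "end", "strand", "fold_change", "p_value"]


def read_site_table(
    path: str | Path, mod_type: str, cell_line: str = ""
) -> list[ModificationSite]:
    """Read a BED-like TSV of modification sites, sorted by (chrom, start).

    Required columns: chrom, start, end, strand, fold_change, p_value (header
    row required).  Rows violating the site invariants raise
    :class:`SiteTableError` naming the row index.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteTableError(f"{path}: missing required columns {missing}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            sites.append(
                ModificationSite(
                    interval=GenomicInterval(
                        str(row.chrom), int(row.start), int(row.end), str(row.strand)
                    ),
                    mod_type=mod_type,
                    fold_change=float(row.fold_change),
                    p_value=float(row.p_value),
                    cell_line=cell_line,
                )
            )
        except ValueError as exc:
            raise SiteTableError(f"{path}: row {i}: {exc}") from exc
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return sites


def write_site_table(sites: Iterable[ModificationSite], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "strand": s.interval.strand,
            "fold_change": s.fold_change,
            "p_value": s.p_value,
        }
        for s in sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    ]
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first column gene_id, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV keyed by sample_id."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_clinical(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_mutations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a sample_id<TAB>comma-separated-genes mutation table."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        genes = frozenset(g for g in str(row.mutated_genes).split(",") if g)
        out[str(row.sample_id)] = genes
    return out


def write_mutations(mutations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"sample_id": s, "mutated_genes": ",".join(sorted(g))}
        for s, g in sorted(mutations.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "mutated_genes"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Site-region classification
# ---------------------------------------------------------------------------


def _overlaps_any(site: GenomicInterval, intervals: Iterable[GenomicInterval]) -> bool:
    return any(
        iv.chrom == site.chrom and site.start < iv.end and iv.start < site.end
        for iv in intervals
    )


def classify_site_region(
    site: ModificationSite, gene: GeneModel, window: int = 3000
) -> str:
    """Classify a site relative to one gene.

    Precedence: promoter bins > 3'UTR > CDS > exon > intron > distal.  A site
    falls in a promoter bin when it overlaps [tss - window, tss + window);
    the bin (<1 kb, 1-2 kb, 2-3 kb) is chosen by the minimum absolute
    distance from any site base to the TSS.  Sites on another chromosome are
    distal.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    iv = site.interval
    if iv.chrom != gene.chrom:
        return "distal"
    tss = gene.tss
    if iv.start < tss + window and tss - window < iv.end:
        if iv.start <= tss < iv.end:
            dist = 0
        else:
            dist = min(abs(iv.start - tss), abs(iv.end - 1 - tss))
        third = window // 3
        if dist < third:
            return "promoter_lt1kb"
        if dist < 2 * third:
            return "promoter_1to2kb"
        return "promoter_2to3kb"
    if _overlaps_any(iv, gene.utr3):
        return "utr3"
    if _overlaps_any(iv, gene.cds):
        return "cds"
    if _overlaps_any(iv, gene.exons):
        return "exon"
    if iv.start < gene.body.end and gene.body.start < iv.end:
        return "intron"
    return "distal"


def site_region_distribution(
    sites: Iterable[ModificationSite],
    genes: Iterable[GeneModel],
    window: int = 3000,
) -> pd.Series:
    """Count sites per region label against the nearest-precedence gene.

    Each site takes the highest-precedence label it achieves against any
    gene, reproducing the binned site-distribution summary (doughnut-chart
    logic) per modification type.
    """
    genes = list(genes)
    order = {label: i for i, label in enumerate(REGION_LABELS)}
    counts = {label: 0 for label in REGION_LABELS}
    for site in sites:
        best = "distal"
        for gene in genes:
            label = classify_site_region(site, gene, window=window)
            if order[label] < order[best]:
                best = label
        counts[best] += 1
    return pd.Series(counts, name="n_sites")
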