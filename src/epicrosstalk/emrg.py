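"""Epigenetic-modification-related gene (EMRG) and lncRNA (EMRL) calling.

Two defining criteria, each existential over sites and cell lines:

1. A differential histone site (|fold-change| > 1, p < 0.05) lies in the
   gene's promoter (TSS +- 3 kb) and the gene is differentially expressed
   (|log2FC| > 1, p < 0.05) in the *same direction* within the *same* GC
   cell line.

2. An m6A site lies in the gene (transcribed region or promoter window) in
   at least one GC cell line, and the gene's expression is positively
   correlated (rho > 0.3) with at least one m6A writer/reader, or
   negatively correlated (rho < -0.3) with at least one m6A eraser
   (adjusted p < 0.05 by default).

EMRLs are the lncRNA members of the resulting catalog.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import DiffExprRecord, GeneModel, ModificationSite, HISTONE_MODS, MOD_TYPES
from .regulators import RegulatorSet, default_regulators
from .stats import CorrelationRecord

__all__ = [
    "EMRGEvidence",
    "EMRGCatalog",
    "emrg_criterion1",
    "emrg_criterion2",
    "build_catalog",
]


@dataclass(frozen=True)
class EMRGEvidence:
    """One piece of support for a gene's EMRG membership."""

    gene_id: str
    mod_type: str
    criterion: int  # 1 (histone/promoter/DEG) or 2 (m6A/CEG)
    site: ModificationSite
    cell_line: str
    deg_log2fc: float | None = None  # criterion 1: matched DEG direction
    regulator_id: str | None = None  # criterion 2: supporting regulator
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.criterion == 1 and self.mod_type not in HISTONE_MODS:
            raise ValueError("criterion 1 evidence requires a histone mod_type")
        if self.criterion == 2 and self.mod_type != "m6A":
            raise ValueError("criterion 2 evidence requires mod_type m6A")
        if self.criterion not in (1, 2):
            raise ValueError("criterion must be 1 or 2")


def _passing_sites(sites: Iterable[ModificationSite]) -> list[ModificationSite]:
    """The |fold-change| > 1, p < 0.05 site filter (idempotent on
    pre-filtered input)."""
    return [s for s in sites if abs(s.fold_change) > 1.0 and s.p_value < 0.05]


def _promoter_trees(
    genes: Sequence[GeneModel], window: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        w = g.promoter_window(window)
        trees[g.chrom][w.start : w.end] = g.gene_id
    return trees


def _gene_region_trees(
    genes: Sequence[GeneModel], window: int
) -> dict[str, IntervalTree]:
    """Transcribed region (exon union incl. 3'UTR) plus promoter window."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        w = g.promoter_window(window)
        trees[g.chrom][w.start : w.end] = g.gene_id
        for ex in g.exons:
            trees[g.chrom][ex.start : ex.end] = g.gene_id
    return trees


def emrg_criterion1(
    dhms: Mapping[str, Sequence[ModificationSite]],
    deg: Mapping[str, Sequence[DiffExprRecord]],
    genes: Sequence[GeneModel],
    window: int = 3000,
) -> list[EMRGEvidence]:
    """Criterion 1: direction-concordant promoter histone site + DEG, within
    one cell line.

    ``dhms`` and ``deg`` map cell line -> sites / DEG records.  Threshold
    filters are applied internally, so pre-filtered and raw inputs give the
    same result.
    """
    trees = _promoter_trees(genes, window)
    evidence = []
    for cell_line in sorted(set(dhms) & set(deg)):
        deg_by_gene = {r.gene_id: r for r in deg[cell_line] if r.passes}
        for site in _passing_sites(dhms[cell_line]):
            if site.mod_type not in HISTONE_MODS:
                continue
            iv = site.interval
            for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
                gene_id = hit.data
                rec = deg_by_gene.get(gene_id)
                if rec is None:
                    continue
                if (site.fold_change > 0) == (rec.log2fc > 0):
                    evidence.append(
                        EMRGEvidence(
                            gene_id=gene_id,
                            mod_type=site.mod_type,
                            criterion=1,
                            site=site,
                            cell_line=cell_line,
                            deg_log2fc=rec.log2fc,
                        )
                    )
    return evidence


def emrg_criterion2(
    mms: Mapping[str, Sequence[ModificationSite]],
    ceg: Sequence[CorrelationRecord],
    genes: Sequence[GeneModel],
    regulators: RegulatorSet | None = None,
    window: int = 3000,
    rho_threshold: float = 0.3,
    require_adjusted: bool = True,
) -> list[EMRGEvidence]:
    """Criterion 2: m6A site in the gene + signed correlation with an m6A
    regulator.

    Writers and readers are pooled for the positive branch (rho > threshold);
    erasers (ALKBH5, FTO) use the negative branch (rho < -threshold).  The
    correlation must reach adjusted p < 0.05 (``require_adjusted=False``
    relaxes to unadjusted p).
    """
    if regulators is None:
        regulators = default_regulators()
    wr = set(regulators.m6a_writers_readers)
    er = set(regulators.m6a_erasers)
    if not wr or not er:
        raise ValueError("regulator set must include m6A writers/readers and erasers")

    support: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for rec in ceg:
        p = rec.p_adj if require_adjusted else rec.p_value
        if p >= 0.05:
            continue
        if rec.regulator_id in wr and rec.rho > rho_threshold:
            support[rec.gene_id].append((rec.regulator_id, rec.rho))
        elif rec.regulator_id in er and rec.rho < -rho_threshold:
            support[rec.gene_id].append((rec.regulator_id, rec.rho))

    trees = _gene_region_trees(genes, window)
    evidence = []
    for cell_line in sorted(mms):
        for site in _passing_sites(mms[cell_line]):
            if site.mod_type != "m6A":
                continue
            iv = site.interval
            hit_genes = {
                h.data for h in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
            }
            for gene_id in sorted(hit_genes):
                for reg, rho in support.get(gene_id, ()):
                    evidence.append(
                        EMRGEvidence(
                            gene_id=gene_id,
                            mod_type="m6A",
                            criterion=2,
                            site=site,
                            cell_line=cell_line,
                            regulator_id=reg,
                            rho=rho,
                        )
                    )
    return evidence


@dataclass
class EMRGCatalog:
    """Per-gene union of EMRG evidence with biotype annotations."""

    entries: dict[str, list[EMRGEvidence]]
    biotypes: dict[str, str]

    def __post_init__(self) -> None:
        # order-insensitive, duplication-insensitive canonical form
        self.entries = {
            g: sorted(
                set(evs),
                key=lambda e: (
                    e.criterion,
                    e.mod_type,
                    e.cell_line,
                    e.site.interval,
                    e.regulator_id or "",
                ),
            )
            for g, evs in sorted(self.entries.items())
            if evs
        }

    def genes(self) -> list[str]:
        return list(self.entries)

    def mod_types(self, gene_id: str) -> set[str]:
        return {e.mod_type for e in self.entries.get(gene_id, [])}

    def emrls(self) -> list[str]:
        """The lncRNA members of the catalog."""
        return [g for g in self.entries if self.biotypes.get(g) == "lncRNA"]

    def per_mod_counts(self) -> pd.Series:
        counts = {m: 0 for m in MOD_TYPES}
        for g in self.entries:
            for m in self.mod_types(g):
                counts[m] += 1
        return pd.Series(counts, name="n_genes")

    def overlap_table(self) -> pd.Series:
        """Genes supported by exactly 1, 2, 3 or 4 modification types."""
        counts = {k: 0 for k in (1, 2, 3, 4)}
        for g in self.entries:
            counts[len(self.mod_types(g))] += 1
        return pd.Series(counts, name="n_genes").rename_axis("n_mod_types")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, evs in self.entries.items():
            rows.append(
                {
                    "gene_id": g,
                    "biotype": self.biotypes.get(g, "other"),
                    "mod_types": ",".join(sorted(self.mod_types(g))),
                    "n_mod_types": len(self.mod_types(g)),
                    "criteria": ",".join(sorted({str(e.criterion) for e in evs})),
                    "n_evidence": len(evs),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "biotype", "mod_types", "n_mod_types", "criteria", "n_evidence"],
        )


def build_catalog(
    evidence: Iterable[EMRGEvidence] | Iterable[Iterable[EMRGEvidence]],
    genes: Sequence[GeneModel],
) -> EMRGCatalog:
    """Union evidence lists into a catalog keyed by gene.

    Accepts a flat evidence iterable or several lists (e.g. criterion 1 and
    criterion 2 outputs).  Adding evidence can only grow the catalog;
    duplicate evidence rows are collapsed.
    """
    flat: list[EMRGEvidence] = []
    for item in evidence:
        if isinstance(item, EMRGEvidence):
            flat.append(item)
        else:
            flat.extend(item)
    entries: dict[str, list[EMRGEvidence]] = defaultdict(list)
    for ev in flat:
        entries[ev.gene_id].append(ev)
    biotypes = {g.gene_id: g.biotype for g in genes}
    return EMRGCatalog(dict(entries), biotypes)
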