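"""Synthetic cohort generator emulating the pipeline's real-world inputs.

Generates a toy gene annotation (protein-coding genes and lncRNAs on one
chromosome), differential histone / m6A site tables, a patient expression
matrix with four planted sample clusters (the last being the EMD-like
cluster with elevated "set1" and suppressed "set2" genes, high FTO and low
HDAC1), exponential survival times whose hazard increases with the planted
score, planted gene-regulator correlations, co-mutated regulator pairs, and
immunotherapy-response labels anti-correlated with the score.

Every generator is a deterministic function of (config, seed): two calls
with the same configuration produce identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    DiffExprRecord,
    ModificationSite,
    write_clinical,
    write_expression,
    write_gtf,
    write_mutations,
    write_site_table,
)
from .regulators import RegulatorSet, default_regulators

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "planted_design",
    "generate_annotation",
    "generate_sites",
    "generate_expression",
    "generate_clinical",
    "generate_mutations",
    "simulate_cohort",
    "write_fixture_dir",
]

_GENE_SPACING = 12_000  # >= 10 kb so +-3 kb promoter windows never collide
_MAX_BODY = 5_000
_FIRST_START = 5_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale gastric-cancer-like cohort: 300 genes
    (a quarter lncRNA), 120 patients in four equal clusters, a 2-unit log2
    shift on planted signature genes in the EMD-like cluster, unit log-hazard
    per standard deviation of the planted score, and strong (rho=0.8)
    planted gene-regulator correlations.
    """

    seed: int = 0
    n_genes: int = 300
    frac_lncrna: float = 0.25
    n_samples: int = 120
    n_clusters: int = 4
    set1_size: int = 40
    set2_size: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.5
    hazard_coef: float = 1.0
    corr_strength: float = 0.8
    n_corr_pairs: int = 4
    comut_pairs: tuple[tuple[str, str, float], ...] = ()
    n_background_sites: int = 100
    background_mutation_rate: float = 0.15
    baseline_median_days: float = 730.0
    censor_max_days: float = 1825.0
    response_slope: float = 1.5
    n_cohorts: int = 1

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 < self.frac_lncrna < 1.0):
            raise ValueError("frac_lncrna must be in (0, 1)")
        if not (0.0 <= self.corr_strength < 1.0):
            raise ValueError("corr_strength must be in [0, 1)")
        if self.set1_size + self.set2_size > self.n_genes:
            raise ValueError("set1_size + set2_size exceeds n_genes")
        if not np.isfinite(self.hazard_coef):
            raise ValueError("hazard_coef must be finite")
        if self.n_samples < self.n_clusters:
            raise ValueError("need at least one sample per cluster")


@dataclass
class PlantedDesign:
    """Deterministic gene-role assignment derived from (config, annotation).

    ``set1`` / ``set2`` are the planted up/down signature sets (protein-coding
    plus the up/down EMRL panels); ``marker_blocks[k]`` lists lncRNAs elevated
    only in non-EMD cluster k, which makes the non-EMD clusters mutually
    separable; ``corr_pairs`` are (target gene, regulator, sign) triples.
    """

    set1_pcg: list[str]
    set2_pcg: list[str]
    emrl_up: list[str]
    emrl_down: list[str]
    marker_blocks: list[list[str]]
    corr_pairs: list[tuple[str, str, int]]

    @property
    def set1(self) -> list[str]:
        return self.set1_pcg + self.emrl_up

    @property
    def set2(self) -> list[str]:
        return self.set2_pcg + self.emrl_down

    @property
    def emrl_panel(self) -> list[str]:
        out = self.emrl_up + self.emrl_down
        for block in self.marker_blocks:
            out += block
        return out


def _n_lncrna(cfg: SimulationConfig) -> int:
    return int(round(cfg.n_genes * cfg.frac_lncrna))


def generate_annotation(cfg: SimulationConfig) -> list[GeneModel]:
    """Tile genes on a toy chromosome with promoter-safe spacing.

    Genes are named G0001..; lncRNAs (no CDS/3'UTR) are chosen by the seeded
    RNG.  Adjacent genes are >= 12 kb apart so +-3 kb promoter windows are
    pairwise disjoint by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n_lnc = _n_lncrna(cfg)
    lnc_idx = set(rng.choice(cfg.n_genes, size=n_lnc, replace=False).tolist())
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        start = _FIRST_START + i * _GENE_SPACING
        length = int(rng.integers(2_000, _MAX_BODY + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{i + 1:04d}"
        body = GenomicInterval("chrS", start, start + length, strand)
        a = length // 5
        exon1 = GenomicInterval("chrS", start, start + a, strand)
        exon2 = GenomicInterval("chrS", start + 2 * a, start + 3 * a, strand)
        exon3 = GenomicInterval("chrS", start + 4 * a, start + length, strand)
        if i in lnc_idx:
            genes.append(
                GeneModel(gene_id, "lncRNA", body, exons=(exon1, exon2, exon3))
            )
        else:
            utr3 = exon3 if strand == "+" else exon1
            genes.append(
                GeneModel(
                    gene_id,
                    "protein_coding",
                    body,
                    exons=(exon1, exon2, exon3),
                    cds=(exon2,),
                    utr3=(utr3,),
                )
            )
    return genes


def planted_design(
    cfg: SimulationConfig, genes: Sequence[GeneModel], regulators: RegulatorSet | None = None
) -> PlantedDesign:
    """Assign planted roles to annotation genes, deterministically.

    Signature sets and marker blocks are drawn from the annotation in gene
    order (lncRNAs for the EMRL panels, protein-coding genes for the rest of
    the signature), so the same (config, annotation) always yields the same
    design.  Planted genes never include epigenetic regulators.
    """
    if regulators is None:
        regulators = default_regulators()
    lnc = [g.gene_id for g in genes if g.biotype == "lncRNA"]
    pcg = [g.gene_id for g in genes if g.biotype == "protein_coding"]
    n_marker_blocks = cfg.n_clusters - 1
    panel_up = min(8, max(2, len(lnc) // (n_marker_blocks + 3)))
    panel_down = panel_up
    block_size = min(4, max(1, (len(lnc) - panel_up - panel_down) // max(1, n_marker_blocks)))
    need_lnc = panel_up + panel_down + block_size * n_marker_blocks
    if len(lnc) < need_lnc:
        raise ValueError(
            f"annotation has {len(lnc)} lncRNAs; need >= {need_lnc} for the planted design"
        )
    emrl_up = lnc[:panel_up]
    emrl_down = lnc[panel_up : panel_up + panel_down]
    marker_blocks = []
    pos = panel_up + panel_down
    for _ in range(n_marker_blocks):
        marker_blocks.append(lnc[pos : pos + block_size])
        pos += block_size

    n1 = max(0, cfg.set1_size - panel_up)
    n2 = max(0, cfg.set2_size - panel_down)
    if len(pcg) < n1 + n2 + cfg.n_corr_pairs:
        raise ValueError("not enough protein-coding genes for the planted design")
    set1_pcg = pcg[:n1]
    set2_pcg = pcg[n1 : n1 + n2]
    corr_targets = pcg[n1 + n2 : n1 + n2 + cfg.n_corr_pairs]
    partner_pool = ["METTL3", "YTHDF1", "IGF2BP2", "FTO", "RBM15", "HNRNPC", "ALKBH5"]
    corr_pairs = []
    for i, t in enumerate(corr_targets):
        reg = partner_pool[i % len(partner_pool)]
        sign = -1 if regulators.regulators.get(reg) == "m6a_eraser" else 1
        corr_pairs.append((t, reg, sign))
    return PlantedDesign(set1_pcg, set2_pcg, emrl_up, emrl_down, marker_blocks, corr_pairs)


def generate_sites(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    planted: Mapping[str, tuple[str, int, bool]],
    cell_line: str = "SIM1",
    rng: np.random.Generator | None = None,
) -> list[ModificationSite]:
    """Place planted significant sites and sub-threshold background sites.

    ``planted`` maps gene_id -> (mod_type, sign, in_promoter).  A planted
    site overlaps the gene's promoter window when in_promoter, otherwise its
    3'UTR (falling back to the 3'-most exon) — the m6A convention.  Planted
    sites always satisfy |fold_change| > 1 and p < 0.05.  Background sites
    are placed in intergenic space with |fold_change| < 1.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    by_id = {g.gene_id: g for g in genes}
    sites: list[ModificationSite] = []
    for gene_id in sorted(planted):
        mod_type, sign, in_promoter = planted[gene_id]
        if gene_id not in by_id:
            raise ValueError(f"planted gene {gene_id} absent from annotation")
        gene = by_id[gene_id]
        if in_promoter:
            lo = max(0, gene.tss - 200)
            iv = GenomicInterval(gene.chrom, lo, gene.tss + 200, ".")
        else:
            host = gene.utr3[0] if gene.utr3 else gene.exons[-1]
            width = min(150, len(host))
            iv = GenomicInterval(host.chrom, host.start, host.start + width, ".")
        fc = float(sign) * rng.uniform(1.5, 3.0)
        sites.append(
            ModificationSite(iv, mod_type, fc, float(rng.uniform(1e-6, 0.01)), cell_line)
        )
    # background: intergenic, sub-threshold fold-changes
    n_gaps = len(genes) - 1
    for _ in range(cfg.n_background_sites):
        i = int(rng.integers(0, max(1, n_gaps)))
        gap_lo = genes[i].body.end + 3_200
        gap_hi = _FIRST_START + (i + 1) * _GENE_SPACING - 3_400
        pos = int(rng.integers(gap_lo, max(gap_lo + 1, gap_hi)))
        iv = GenomicInterval("chrS", pos, pos + 200, ".")
        fc = float(rng.uniform(-0.9, 0.9))
        sites.append(ModificationSite(iv, "H3K4me1", fc, float(rng.uniform(0.05, 1.0)), cell_line))
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return sites


def _cluster_assignment(cfg: SimulationConfig) -> np.ndarray:
    """Samples split evenly across clusters, round-robin; labels 1..K."""
    return np.arange(cfg.n_samples) % cfg.n_clusters + 1


#: log2 shifts applied to regulator genes in the EMD-like cluster (relative
#: to effect_size); mirrors the observed pattern: m6A erasers up, histone
#: deacetylases / demethylases down.
_REGULATOR_EMD_SHIFTS = {
    "FTO": 1.0,
    "ALKBH5": 0.5,
    "HDAC1": -1.0,
    "HDAC2": -0.5,
    "KDM1A": -0.5,
}


def generate_expression(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    regulators: RegulatorSet | None = None,
    design: PlantedDesign | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Genes x samples log2 expression with planted cluster structure.

    The last cluster (label ``n_clusters``) is the EMD-like cluster: planted
    set1 genes shifted by +effect_size, set2 genes by -effect_size, FTO up
    and HDAC1 down.  Each other cluster k is elevated on its own small
    lncRNA marker block so that all clusters are mutually separable.
    Planted gene-regulator pairs are constructed with correlation
    ``corr_strength``.  All 43 regulators are included as expression rows.
    """
    if regulators is None:
        regulators = default_regulators()
    if design is None:
        design = planted_design(cfg, genes, regulators)
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)

    gene_ids = [g.gene_id for g in genes] + regulators.all
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    clusters = _cluster_assignment(cfg)
    emd_label = cfg.n_clusters

    n_g, n_s = len(gene_ids), cfg.n_samples
    baseline = rng.normal(8.0, 1.0, size=n_g)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
    idx = {g: i for i, g in enumerate(gene_ids)}

    is_emd = clusters == emd_label
    for g in design.set1:
        values[idx[g], is_emd] += cfg.effect_size
    for g in design.set2:
        values[idx[g], is_emd] -= cfg.effect_size
    for k, block in enumerate(design.marker_blocks, start=1):
        in_k = clusters == k
        for g in block:
            values[idx[g], in_k] += cfg.effect_size
    for reg, scale in _REGULATOR_EMD_SHIFTS.items():
        if reg in idx:
            values[idx[reg], is_emd] += scale * cfg.effect_size

    # planted gene-regulator correlations: overwrite the target with a mix
    # of the (standardized) regulator profile and fresh noise
    c = cfg.corr_strength
    for target, reg, sign in design.corr_pairs:
        r = values[idx[reg]]
        z = (r - r.mean()) / (r.std() if r.std() > 0 else 1.0)
        eps = rng.normal(0.0, 1.0, size=n_s)
        values[idx[target]] = (
            baseline[idx[target]]
            + cfg.noise_sd * (sign * c * z + math.sqrt(1.0 - c * c) * eps)
        )

    meta = pd.DataFrame(
        {
            "cohort": [f"cohort{(i % cfg.n_cohorts) + 1}" for i in range(n_s)],
            "true_cluster": clusters,
            "is_emd_truth": is_emd.astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(vals, meta)


def planted_score(matrix: ExpressionMatrix, design: PlantedDesign) -> pd.Series:
    """Standardized (mean set1 - mean set2) expression: the planted risk score."""
    v = matrix.values
    s = v.loc[design.set1].mean(axis=0) - v.loc[design.set2].mean(axis=0)
    return (s - s.mean()) / s.std(ddof=0)


def generate_clinical(
    cfg: SimulationConfig,
    score: pd.Series,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with score-proportional hazard, plus ICI response.

    log-hazard = log(log 2 / median) + hazard_coef * standardized score;
    censoring is independent uniform on (31, censor_max_days]; event times
    of <= 30 days are resampled (the cohort exclusion rule).  Responder
    probability is a decreasing logistic function of the score.
    """
    if not np.isfinite(cfg.hazard_coef):
        raise ValueError("hazard_coef must be finite")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    z = np.asarray(score, dtype=float)
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    rate = (math.log(2.0) / cfg.baseline_median_days) * np.exp(cfg.hazard_coef * z)
    t = rng.exponential(1.0 / rate)
    for _ in range(1000):
        bad = t <= 30.0
        if not bad.any():
            break
        t[bad] = rng.exponential(1.0 / rate[bad])
    cens = rng.uniform(31.0, cfg.censor_max_days, size=len(z))
    os_time = np.minimum(t, cens)
    os_event = (t <= cens).astype(int)
    p_resp = 1.0 / (1.0 + np.exp(cfg.response_slope * z))
    resp = np.where(rng.random(len(z)) < p_resp, "responder", "non_responder")
    return pd.DataFrame(
        {"os_time": os_time, "os_event": os_event, "ici_response": resp},
        index=score.index if isinstance(score, pd.Series) else None,
    )


def _joint_mutation_probs(p: float, q: float, theta: float) -> tuple[float, float, float, float]:
    """(p11, p10, p01, p00) with margins p, q and odds ratio theta."""
    if theta == 1.0:
        p11 = p * q
    else:
        a = 1.0 + (p + q) * (theta - 1.0)
        p11 = (a - math.sqrt(a * a - 4.0 * theta * (theta - 1.0) * p * q)) / (
            2.0 * (theta - 1.0)
        )
    p10 = p - p11
    p01 = q - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = (p11, p10, p01, p00)
    if min(probs) < -1e-12:
        raise ValueError(f"infeasible odds ratio {theta} for margins ({p}, {q})")
    return tuple(max(0.0, x) for x in probs)  # type: ignore[return-value]


def generate_mutations(
    cfg: SimulationConfig,
    sample_ids: Sequence[str],
    gene_universe: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, frozenset[str]]:
    """Binary mutation sets: independent background plus planted co-mutated pairs.

    Genes default to the 43 regulators.  Genes in ``cfg.comut_pairs`` are
    drawn jointly with the configured odds ratio at the background marginal
    rate; all other genes mutate independently.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 4)
    if gene_universe is None:
        gene_universe = default_regulators().all
    n = len(sample_ids)
    p = cfg.background_mutation_rate
    paired = {g for a, b, _ in cfg.comut_pairs for g in (a, b)}
    mutated: dict[str, set[str]] = {s: set() for s in sample_ids}
    for g in gene_universe:
        if g in paired:
            continue
        hit = rng.random(n) < p
        for s, h in zip(sample_ids, hit):
            if h:
                mutated[s].add(g)
    for a, b, theta in cfg.comut_pairs:
        p11, p10, p01, p00 = _joint_mutation_probs(p, p, theta)
        draw = rng.choice(4, size=n, p=[p11, p10, p01, p00])
        for s, d in zip(sample_ids, draw):
            if d in (0, 1):
                mutated[s].add(a)
            if d in (0, 2):
                mutated[s].add(b)
    return {s: frozenset(g) for s, g in mutated.items()}


_HISTONE_CELL_LINES = ("SNU719", "NCC24", "YCC10")
_M6A_CELL_LINES = ("AGS", "BGC823", "SGC7901")


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the planted ground truth."""

    cfg: SimulationConfig
    genes: list[GeneModel]
    design: PlantedDesign
    sites: dict[str, dict[str, list[ModificationSite]]]  # mod_type -> cell_line -> sites
    cellline_deg: dict[str, list[DiffExprRecord]]
    expression: ExpressionMatrix
    truth: dict

    @property
    def emd_label(self) -> int:
        return self.cfg.n_clusters


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate the full coherent fixture: annotation, sites, cell-line DEG
    tables, expression with clusters, survival/response, and mutations.

    Planted EMRG structure: every panel lncRNA and planted signature gene
    receives a promoter histone site with a direction-matched cell-line DEG
    record (criterion-1 path); panel lncRNAs and correlation targets also
    receive a 3'UTR/exon m6A site (criterion-2 path, supported by the
    planted regulator correlations).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = generate_annotation(cfg)
    regulators = default_regulators()
    design = planted_design(cfg, genes, regulators)

    expression = generate_expression(cfg, genes, regulators, design)
    score = planted_score(expression, design)
    clinical = generate_clinical(cfg, score)
    meta = expression.sample_meta.join(clinical)
    mutations = generate_mutations(cfg, expression.sample_ids)
    expression = ExpressionMatrix(expression.values, meta, mutations)

    # planted histone sites (promoter) for signature genes and the EMRL panel
    histone_planted: dict[str, tuple[str, int, bool]] = {}
    histone_mods = ("H3K4me1", "H3K4me3", "H3K27ac")
    up_genes = design.set1
    down_genes = design.set2
    for i, g in enumerate(up_genes):
        histone_planted[g] = (histone_mods[i % 3], 1, True)
    for i, g in enumerate(down_genes):
        histone_planted[g] = (histone_mods[i % 3], -1, True)
    for block in design.marker_blocks:
        for i, g in enumerate(block):
            histone_planted[g] = (histone_mods[i % 3], 1, True)

    # planted m6A sites (3'UTR / exon) for the EMRL panel and corr targets
    m6a_planted = {g: ("m6A", 1, False) for g in design.emrl_up + design.emrl_down}
    for target, _reg, sign in design.corr_pairs:
        m6a_planted[target] = ("m6A", sign, False)

    sites: dict[str, dict[str, list[ModificationSite]]] = {m: {} for m in histone_mods}
    sites["m6A"] = {}
    site_rng = np.random.default_rng(cfg.seed + 10)
    for cl in _HISTONE_CELL_LINES:
        per_cl = generate_sites(cfg, genes, histone_planted, cell_line=cl, rng=site_rng)
        for m in histone_mods:
            sites[m][cl] = [s for s in per_cl if s.mod_type == m]
    for cl in _M6A_CELL_LINES:
        sites["m6A"][cl] = generate_sites(cfg, genes, m6a_planted, cell_line=cl, rng=site_rng)

    # cell-line DEG tables, direction-matched to the planted histone sites
    deg_rng = np.random.default_rng(cfg.seed + 11)
    cellline_deg: dict[str, list[DiffExprRecord]] = {}
    planted_dir = {g: s for g, (_m, s, _p) in histone_planted.items()}
    for cl in _HISTONE_CELL_LINES:
        recs = []
        for g in genes:
            if g.gene_id in planted_dir:
                lfc = planted_dir[g.gene_id] * deg_rng.uniform(1.5, 3.0)
                p = deg_rng.uniform(1e-6, 0.01)
            else:
                lfc = deg_rng.normal(0.0, 0.3)
                p = deg_rng.uniform(0.05, 1.0)
            recs.append(DiffExprRecord(g.gene_id, float(lfc), float(p), min(1.0, float(p) * 2)))
        cellline_deg[cl] = recs

    truth = {
        "seed": cfg.seed,
        "emd_cluster": cfg.n_clusters,
        "cluster_labels": {
            s: int(c) for s, c in zip(expression.sample_ids, meta["true_cluster"])
        },
        "set1": design.set1,
        "set2": design.set2,
        "emrl_panel": design.emrl_panel,
        "marker_blocks": design.marker_blocks,
        "corr_pairs": [list(p) for p in design.corr_pairs],
        "comut_pairs": [list(p) for p in cfg.comut_pairs],
        "planted_score": {s: float(v) for s, v in score.items()},
        "config": asdict(cfg),
    }
    return SimulatedCohort(cfg, genes, design, sites, cellline_deg, expression, truth)


def write_fixture_dir(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the full fixture as plain-text files plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(cohort.genes, outdir / "annotation.gtf")
    for mod_type, by_cl in cohort.sites.items():
        for cl, sites in by_cl.items():
            write_site_table(sites, outdir / f"sites_{mod_type}_{cl}.tsv")
    for cl, recs in cohort.cellline_deg.items():
        pd.DataFrame(
            [
                {"gene_id": r.gene_id, "log2fc": r.log2fc, "p_value": r.p_value, "p_adj": r.p_adj}
                for r in recs
            ]
        ).to_csv(outdir / f"deg_{cl}.tsv", sep="\t", index=False)
    write_expression(cohort.expression.values, outdir / "expression.tsv")
    write_clinical(cohort.expression.sample_meta, outdir / "clinical.tsv")
    write_mutations(cohort.expression.mutations or {}, outdir / "mutations.tsv")
    (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
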