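"""Signature selection, single-sample enrichment scoring, and the EMD score.

The EMD score for a patient is

    EMD score = log2( ssGSEA(set1) / ssGSEA(set2) )

where set1/set2 are the up/down signatures of the EMD subtype and the two
single-sample enrichment scores are min-max rescaled into (eps, 1] per
cohort before the ratio (raw enrichment scores can be negative, which would
make the log-ratio undefined).  The FTO/HDAC1 ratio is the log2-scale
expression difference of the m6A eraser FTO and the histone deacetylase
HDAC1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DiffExprRecord, ExpressionMatrix

__all__ = [
    "Signature",
    "select_signature",
    "ssgsea",
    "ssgsea_matrix",
    "emd_score",
    "fto_hdac1_ratio",
]


@dataclass(frozen=True)
class Signature:
    """Disjoint up (set1) and down (set2) gene sets with selection params."""

    set1: tuple[str, ...]
    set2: tuple[str, ...]
    selection_params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "set1", tuple(sorted(set(self.set1))))
        object.__setattr__(self, "set2", tuple(sorted(set(self.set2))))
        if not self.set1 or not self.set2:
            raise ValueError("set1 and set2 must both be non-empty")
        if set(self.set1) & set(self.set2):
            raise ValueError("set1 and set2 must be disjoint")


def _pearson_rows_vs_vector(values: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Pearson correlation of each row with a vector (zero-variance -> NaN)."""
    X = values.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    return pd.Series(r, index=values.index)


def _eigenprofile(values: pd.DataFrame) -> np.ndarray:
    """First principal component across samples of per-gene z-scored rows
    (module-eigengene surrogate), oriented to correlate positively with the
    mean member profile."""
    X = values.to_numpy(float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
    pc = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    return pc


def select_signature(
    matrix: ExpressionMatrix | pd.DataFrame,
    deg: Sequence[DiffExprRecord],
    emd_indicator: pd.Series,
    gs_threshold: float = 0.4,
    mm_threshold: float = 0.7,
) -> Signature:
    """Select set1/set2 from passing DEGs by trait and module correlation.

    Passing DEGs (|log2FC| > 1, p < 0.05) are partitioned by the sign of
    their correlation with the EMD indicator (gene significance, GS).  Each
    sign group gets a first-principal-component eigen-profile; module
    membership (MM) is each gene's correlation with it.  set1 keeps
    positive-GS genes with GS >= gs_threshold and MM >= mm_threshold; set2
    symmetrically keeps negative-GS genes with GS <= -gs_threshold and
    MM >= mm_threshold.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    passing = sorted({r.gene_id for r in deg if r.passes and r.gene_id in values.index})
    if not passing:
        raise ValueError("no passing DEGs to select from")
    y = emd_indicator.loc[values.columns].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("EMD indicator must contain both classes")
    gs = _pearson_rows_vs_vector(values.loc[passing], y).dropna()

    out_sets: dict[str, list[str]] = {}
    mm_all = {}
    for name, genes in (
        ("set1", [g for g in passing if gs.get(g, 0.0) > 0]),
        ("set2", [g for g in passing if gs.get(g, 0.0) < 0]),
    ):
        if not genes:
            raise ValueError(
                f"no {'up' if name == 'set1' else 'down'}-regulated passing DEGs; "
                "relax gs/mm thresholds or check the DEG input"
            )
        pc = _eigenprofile(values.loc[genes])
        mm = _pearson_rows_vs_vector(values.loc[genes], pc)
        mm_all.update(mm.to_dict())
        keep = [
            g
            for g in genes
            if abs(gs[g]) >= gs_threshold and mm[g] >= mm_threshold
        ]
        if not keep:
            raise ValueError(
                f"{name} empty at gs_threshold={gs_threshold}, mm_threshold={mm_threshold}; "
                "consider relaxing the thresholds"
            )
        out_sets[name] = keep
    return Signature(
        tuple(out_sets["set1"]),
        tuple(out_sets["set2"]),
        {
            "gs_threshold": gs_threshold,
            "mm_threshold": mm_threshold,
            "gs": {g: float(v) for g, v in gs.items()},
            "mm": {g: float(v) for g, v in mm_all.items()},
        },
    )


def ssgsea(
    expression: pd.Series,
    gene_set: Iterable[str],
    alpha: float = 0.25,
) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ranked by expression descending (ties broken by gene id).
    In-set step weights are |rank-normalized expression|^alpha, normalized
    to sum to one over the set; each out-of-set gene steps 1/(N - |S|).
    The score is the integrated running sum: the sum over the ranked list of
    (cumulative in-set weight - cumulative out-of-set weight).
    """
    genes = expression.index
    in_set = set(gene_set) & set(genes)
    n = len(genes)
    if not in_set or len(in_set) >= n:
        raise ValueError("gene_set must be a non-empty proper subset of measured genes")
    order = sorted(range(n), key=lambda i: (-float(expression.iloc[i]), genes[i]))
    is_in = np.array([genes[i] in in_set for i in order])
    rank_norm = (n - np.arange(n, dtype=float)) / n  # 1 for the top gene
    w = np.where(is_in, np.abs(rank_norm) ** alpha, 0.0)
    w_sum = w.sum()
    cum_in = np.cumsum(w / w_sum)
    cum_out = np.cumsum(np.where(is_in, 0.0, 1.0 / (n - len(in_set))))
    return float(np.sum(cum_in - cum_out))


def ssgsea_matrix(
    values: pd.DataFrame, gene_set: Iterable[str], alpha: float = 0.25
) -> pd.Series:
    """ssGSEA score of one gene set for every sample column."""
    gene_set = set(gene_set)
    return pd.Series(
        [ssgsea(values[c], gene_set, alpha=alpha) for c in values.columns],
        index=values.columns,
    )


def _minmax_unit(x: pd.Series, eps: float) -> pd.Series:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return pd.Series(1.0, index=x.index)
    return eps + (1.0 - eps) * (x - lo) / (hi - lo)


def emd_score(
    matrix: ExpressionMatrix,
    signature: Signature,
    alpha: float = 0.25,
    rescale: str = "per_cohort",
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per-sample score table: ssGSEA(set1), ssGSEA(set2), EMD score, group.

    Both enrichment-score vectors are min-max rescaled into (eps, 1]
    (per cohort by default, globally with ``rescale='global'``) before the
    log2 ratio.  ``score_group`` splits at the cohort median; samples at the
    median go to the low group.  Adds the FTO/HDAC1 ratio when both genes
    are present.
    """
    if rescale not in ("per_cohort", "global"):
        raise ValueError("rescale must be 'per_cohort' or 'global'")
    values = matrix.values
    s1 = ssgsea_matrix(values, signature.set1, alpha=alpha)
    s2 = ssgsea_matrix(values, signature.set2, alpha=alpha)
    cohorts = matrix.cohorts() if rescale == "per_cohort" else pd.Series(
        "all", index=values.columns
    )
    r1 = pd.Series(index=s1.index, dtype=float)
    r2 = pd.Series(index=s2.index, dtype=float)
    for _c, samples in cohorts.groupby(cohorts).groups.items():
        samples = list(samples)
        if len(samples) < 2:
            raise ValueError(
                f"cohort {_c!r} has a single sample; use rescale='global'"
            )
        r1[samples] = _minmax_unit(s1[samples], eps)
        r2[samples] = _minmax_unit(s2[samples], eps)
    score = np.log2(r1 / r2)
    group = pd.Series(index=score.index, dtype=object)
    for _c, samples in cohorts.groupby(cohorts).groups.items():
        samples = list(samples)
        med = float(score[samples].median())
        group[samples] = np.where(score[samples] > med, "high", "low")
    out = pd.DataFrame(
        {
            "ssgsea1": s1,
            "ssgsea2": s2,
            "emd_score": score,
            "score_group": group,
        }
    ).rename_axis("sample_id")
    if "FTO" in values.index and "HDAC1" in values.index:
        out["fto_hdac1_ratio"] = fto_hdac1_ratio(matrix)
    return out


def fto_hdac1_ratio(matrix: ExpressionMatrix, linear: bool = False) -> pd.Series:
    """Per-sample FTO/HDAC1 contrast.

    On the log2-scale matrix this is expr(FTO) - expr(HDAC1), i.e. the log2
    of the linear-scale ratio; ``linear=True`` returns 2**difference.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    for gene in ("FTO", "HDAC1"):
        if gene not in values.index:
            raise KeyError(f"gene {gene} missing from the expression matrix")
    diff = values.loc["FTO"].astype(float) - values.loc["HDAC1"].astype(float)
    diff.name = "fto_hdac1_ratio"
    return np.exp2(diff) if linear else diff
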