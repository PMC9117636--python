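"""Consensus k-means clustering of samples and EMD-subtype labeling.

Samples are clustered on z-scored expression of the screened
survival-associated EMRLs.  For each k in 2..maxK the sample set is
repeatedly subsampled, k-means (Euclidean) is run to convergence, and the
consensus matrix accumulates the co-clustering frequency of each sample
pair; final labels come from average-linkage hierarchical clustering of
1 - consensus.  k is chosen by minimum PAC (proportion of ambiguous
clustering) unless fixed by the caller (the study fixes k = 4).

The cluster with the worst Kaplan-Meier survival at the last common time
point is designated the epigenetic-modification-dysregulated (EMD) subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import ExpressionMatrix

__all__ = ["ConsensusResult", "EMDLabeling", "consensus_cluster", "label_emd_cluster"]

_PAC_WINDOW = (0.1, 0.9)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels and PAC, plus the chosen k."""

    sample_ids: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, pd.Series]
    pac: dict[int, float]
    chosen_k: int

    @property
    def chosen_labels(self) -> pd.Series:
        return self.labels[self.chosen_k]


def _kmeans_pp_init(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy spread-maximizing (k-means++) seeding."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _kmeans(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> np.ndarray:
    """Lloyd k-means with Euclidean distance; best inertia over restarts."""
    best_labels: np.ndarray | None = None
    best_inertia = np.inf
    for _ in range(n_restarts):
        centers = _kmeans_pp_init(X, k, rng)
        labels = np.zeros(len(X), dtype=int)
        for _it in range(max_iter):
            d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d.argmin(axis=1)
            if _it > 0 and (new_labels == labels).all():
                labels = new_labels
                break
            labels = new_labels
            for c in range(k):
                mask = labels == c
                if mask.any():
                    centers[c] = X[mask].mean(axis=0)
                else:  # re-seed an empty cluster at the farthest point
                    centers[c] = X[d.min(axis=1).argmax()]
        inertia = ((X - centers[labels]) ** 2).sum()
        if inertia < best_inertia:
            best_inertia = inertia
            best_labels = labels
    assert best_labels is not None
    return best_labels


def _zscore_features(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score, within cohort when cohort metadata is available."""
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
        cohorts = matrix.cohorts()
        out = values.copy().astype(float)
        for _c, samples in cohorts.groupby(cohorts).groups.items():
            sub = values[list(samples)].astype(float)
            sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
            out[list(samples)] = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        return out
    values = matrix.astype(float)
    sd = values.std(axis=1, ddof=0).replace(0.0, 1.0)
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


def consensus_cluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    max_k: int = 7,
    n_resamples: int = 1000,
    item_frac: float = 0.8,
    seed: int | None = None,
    fixed_k: int | None = None,
    n_restarts: int = 10,
    deterministic_init: bool = False,
) -> ConsensusResult:
    """Resampling-based consensus k-means over k = 2..max_k.

    ``fixed_k`` pins the reported clustering to one k (PAC is still computed
    for every k).  ``deterministic_init`` reuses one seeding stream per k so
    that with ``item_frac=1`` every resample yields identical labels (used
    to verify the consensus-matrix construction).  Samples are canonically
    ordered by id internally, so the result is invariant to input column
    order at the same seed.
    """
    features = _zscore_features(matrix)
    sample_ids = list(features.columns)
    order = np.argsort(sample_ids)
    canonical = [sample_ids[i] for i in order]
    X = features[canonical].to_numpy(float).T  # samples x genes
    n = len(canonical)
    if fixed_k is not None and not (2 <= fixed_k <= max_k):
        raise ValueError("fixed_k must lie in 2..max_k")
    if n < max_k * 3:
        raise ValueError(f"need >= {max_k * 3} samples for max_k={max_k}")
    m = max(2, int(round(item_frac * n)))
    rng = np.random.default_rng(seed)

    k_range = list(range(2, max_k + 1))
    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, pd.Series] = {}
    pac: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        km_rng = np.random.default_rng(rng.integers(2**31)) if deterministic_init else rng
        for _r in range(n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            if deterministic_init:
                km_rng = np.random.default_rng(k)  # same stream every resample
            lab = _kmeans(X[idx], k, km_rng, n_restarts=n_restarts)
            co_sample[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                mem = idx[lab == c]
                co_cluster[np.ix_(mem, mem)] += 1.0
        off = co_sample[iu]
        if (off == 0).any():
            raise RuntimeError(
                "some sample pairs were never co-sampled; increase n_resamples"
            )
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus[k] = cons
        dist = squareform(1.0 - cons, checks=False)
        lab_k = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
        labels[k] = pd.Series(lab_k, index=canonical, name=f"k{k}")
        vals = cons[iu]
        pac[k] = float(np.mean((vals > _PAC_WINDOW[0]) & (vals < _PAC_WINDOW[1])))

    chosen_k = fixed_k if fixed_k is not None else min(k_range, key=lambda k: (pac[k], k))
    # report in the caller's sample order
    labels = {k: lab.loc[sample_ids] for k, lab in labels.items()}
    inv = np.argsort(order)
    consensus = {k: c[np.ix_(inv, inv)] for k, c in consensus.items()}
    return ConsensusResult(sample_ids, k_range, consensus, labels, pac, chosen_k)


@dataclass
class EMDLabeling:
    """The cluster designated EMD, its reference, and per-cluster KM summary."""

    emd_cluster: int
    reference_cluster: int
    km_summary: pd.DataFrame  # per cluster: n, events, survival at t_common
    t_common: float


def label_emd_cluster(
    labels: pd.Series | "ConsensusResult",
    matrix: ExpressionMatrix,
    tie_break_genes: list[str] | None = None,
) -> EMDLabeling:
    """Designate the worst-survival cluster as the EMD subtype.

    Ranking uses the Kaplan-Meier survival probability at the last common
    time point (the smallest per-cluster maximum follow-up).  Ties are
    broken by the larger mean expression of ``tie_break_genes`` (the
    up-signature EMRLs) with a warning.
    """
    from lifelines import KaplanMeierFitter

    if isinstance(labels, ConsensusResult):
        labels = labels.chosen_labels
    meta = matrix.sample_meta
    if "os_time" not in meta or "os_event" not in meta:
        raise ValueError("sample_meta must carry os_time and os_event")
    labels = labels.loc[meta.index]
    t_common = float(
        min(meta.loc[labels == c, "os_time"].max() for c in sorted(labels.unique()))
    )
    rows = {}
    for c in sorted(labels.unique()):
        sub = meta[labels == c]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"])
        rows[int(c)] = {
            "n": len(sub),
            "events": int(sub["os_event"].sum()),
            "survival_at_t_common": float(kmf.predict(t_common)),
        }
    km = pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster")
    surv = km["survival_at_t_common"]
    worst = surv[np.isclose(surv, surv.min(), atol=1e-12)]
    if len(worst) > 1:
        warnings.warn(
            "tie in survival ranking; breaking by mean up-signature expression",
            stacklevel=2,
        )
        if tie_break_genes:
            means = {
                int(c): float(
                    matrix.values.loc[
                        [g for g in tie_break_genes if g in matrix.values.index],
                        labels.index[labels == c],
                    ]
                    .mean()
                    .mean()
                )
                for c in worst.index
            }
            emd = max(sorted(means), key=lambda c: means[c])
        else:
            emd = int(max(worst.index))
    else:
        emd = int(worst.index[0])
    reference = int(surv.idxmax())
    return EMDLabeling(emd, reference, km, t_common)
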