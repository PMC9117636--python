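"""Statistical primitives of the pipeline.

Differential expression (Welch test on log2 values with BH adjustment),
gene-regulator Spearman correlation (CEG screening), regulator-regulator
co-expression, pairwise co-mutation exact tests, and the univariate Cox
proportional-hazards screen with Breslow tie handling.

Thresholds follow the study rules: DEG |log2FC| > 1 & p < 0.05; CEG
|rho| > 0.3 & adjusted p < 0.05; co-mutation p < 0.05 (unadjusted);
survival screen p < 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import DiffExprRecord, ExpressionMatrix
from .regulators import RegulatorSet, default_regulators

__all__ = [
    "CorrelationRecord",
    "CoMutationRecord",
    "differential_expression",
    "correlate_with_regulators",
    "regulator_coexpression",
    "comutation_test",
    "cox_univariate",
    "cox_screen",
]

_P_FLOOR = 1e-300  # keep p-values inside (0, 1]


@dataclass(frozen=True)
class CorrelationRecord:
    """Spearman correlation of a gene with a regulator."""

    gene_id: str
    regulator_id: str
    rho: float
    p_value: float
    p_adj: float
    passes: bool  # |rho| > threshold and the relevant p-rule


@dataclass(frozen=True)
class CoMutationRecord:
    """Pairwise mutation co-occurrence / mutual-exclusivity test result."""

    gene_a: str
    gene_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_value: float
    direction: str  # co_occurrence | mutual_exclusivity
    degenerate: bool = False

    @property
    def passes(self) -> bool:
        """The co-mutation event rule: co-occurrence with p < 0.05."""
        return self.direction == "co_occurrence" and self.p_value < 0.05


def _as_values(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def differential_expression(
    matrix: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> list[DiffExprRecord]:
    """Per-gene Welch test between two sample groups on log2 values.

    log2FC = mean(group_a) - mean(group_b).  Genes with zero variance in
    both groups get p = 1 when the means are equal (no evidence either way)
    and a floor p otherwise.  BH adjustment is over all tested genes.  Each
    record's ``passes`` property applies the |log2FC| > 1, p < 0.05 rule.
    """
    values = _as_values(matrix)
    a_ids, b_ids = list(group_a), list(group_b)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs >= 3 samples")
    a = values[a_ids].to_numpy(float)
    b = values[b_ids].to_numpy(float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate & (np.abs(log2fc) < 1e-12)] = 1.0
    p[degenerate & (np.abs(log2fc) >= 1e-12)] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    p_adj = np.clip(p_adj, _P_FLOOR, 1.0)
    return [
        DiffExprRecord(g, float(fc), float(pv), float(pa))
        for g, fc, pv, pa in zip(values.index, log2fc, p, p_adj)
    ]


def _spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with the t-approximation p-value (two-sided)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        return rho, _P_FLOOR
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, max(_P_FLOOR, min(1.0, p))


def _pairwise_spearman(
    values: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> list[tuple[str, str, float, float]]:
    """Spearman rho/p for each (row_a, row_b) pair; constant rows dropped."""
    out = []
    rank_cache: dict[str, np.ndarray] = {}

    def _ranks(g: str) -> np.ndarray:
        if g not in rank_cache:
            rank_cache[g] = sps.rankdata(values.loc[g].to_numpy(float))
        return rank_cache[g]

    dropped: set[str] = set()
    for a, b in pairs:
        ra, rb = _ranks(a), _ranks(b)
        if ra.std() == 0 or rb.std() == 0:
            dropped.update(g for g, r in ((a, ra), (b, rb)) if r.std() == 0)
            continue
        n = len(ra)
        rho = float(np.corrcoef(ra, rb)[0, 1])
        rho = max(-1.0, min(1.0, rho))
        if abs(rho) >= 1.0:
            p = _P_FLOOR
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = max(_P_FLOOR, min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2)))
        out.append((a, b, rho, p))
    if dropped:
        warnings.warn(
            f"constant expression, pairs dropped for: {sorted(dropped)}", stacklevel=3
        )
    return out


def correlate_with_regulators(
    matrix: ExpressionMatrix | pd.DataFrame,
    targets: Iterable[str],
    regulators: RegulatorSet | None = None,
    rho_threshold: float = 0.3,
) -> list[CorrelationRecord]:
    """Spearman correlation of each target with each m6A regulator (CEG screen).

    BH adjustment is over all computed (target, regulator) pairs; a pair
    ``passes`` when |rho| > rho_threshold and adjusted p < 0.05.  A gene is
    a CEG when it passes against at least one m6A regulator.
    """
    if regulators is None:
        regulators = default_regulators()
    values = _as_values(matrix)
    if values.shape[1] < 10:
        raise ValueError("need >= 10 samples for correlation screening")
    regs = [r for r in regulators.m6a if r in values.index]
    if not regs:
        raise ValueError("no m6A regulators present in the matrix")
    targets = [t for t in targets if t in values.index]
    pairs = [(t, r) for t in targets for r in regs]
    raw = _pairwise_spearman(values, pairs)
    if not raw:
        return []
    p_adj = np.clip(multipletests([p for *_x, p in raw], method="fdr_bh")[1], _P_FLOOR, 1.0)
    return [
        CorrelationRecord(
            a, b, rho, p, float(pa), bool(abs(rho) > rho_threshold and pa < 0.05)
        )
        for (a, b, rho, p), pa in zip(raw, p_adj)
    ]


def ceg_genes(records: Iterable[CorrelationRecord]) -> set[str]:
    """Genes passing the CEG rule against at least one m6A regulator."""
    return {r.gene_id for r in records if r.passes}


def regulator_coexpression(
    matrix: ExpressionMatrix | pd.DataFrame,
    regulators: RegulatorSet | None = None,
    rho_threshold: float = 0.3,
) -> list[CorrelationRecord]:
    """Spearman co-expression over all unordered regulator pairs.

    A pair ``passes`` the co-expression-event rule at |rho| > threshold and
    unadjusted p < 0.05; BH-adjusted p-values are reported alongside.
    """
    if regulators is None:
        regulators = default_regulators()
    values = _as_values(matrix)
    regs = [r for r in regulators.all if r in values.index]
    pairs = [(a, b) for i, a in enumerate(regs) for b in regs[i + 1 :]]
    raw = _pairwise_spearman(values, pairs)
    if not raw:
        return []
    p_adj = np.clip(multipletests([p for *_x, p in raw], method="fdr_bh")[1], _P_FLOOR, 1.0)
    return [
        CorrelationRecord(
            a, b, rho, p, float(pa), bool(abs(rho) > rho_threshold and p < 0.05)
        )
        for (a, b, rho, p), pa in zip(raw, p_adj)
    ]


def comutation_test(
    mutations: Mapping[str, frozenset[str] | set[str]],
    genes: Sequence[str],
) -> list[CoMutationRecord]:
    """Fisher exact test of mutation co-occurrence for every gene pair.

    For each unordered pair, the 2x2 table of joint presence/absence across
    samples is tested with the two-sided exact conditional (hypergeometric)
    test.  Direction is co_occurrence when observed n11 exceeds its
    expectation under independence.  Genes mutated in no or all samples give
    degenerate records with p = 1.
    """
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    samples = sorted(mutations)
    if not samples:
        raise ValueError("need >= 1 sample")
    n = len(samples)
    has = {g: np.array([g in mutations[s] for s in samples]) for g in genes}
    out = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            xa, xb = has[a], has[b]
            n11 = int(np.sum(xa & xb))
            n10 = int(np.sum(xa & ~xb))
            n01 = int(np.sum(~xa & xb))
            n00 = n - n11 - n10 - n01
            degenerate = xa.all() or (~xa).all() or xb.all() or (~xb).all()
            if n10 * n01 > 0:
                odds = n11 * n00 / (n10 * n01)
            else:
                odds = math.inf if n11 * n00 > 0 else math.nan
            expected = (n11 + n10) * (n11 + n01) / n
            direction = "co_occurrence" if n11 > expected else "mutual_exclusivity"
            if degenerate:
                p = 1.0
            else:
                _, p = sps.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
            out.append(
                CoMutationRecord(
                    a, b, n11, n10, n01, n00, odds, float(p), direction, degenerate
                )
            )
    return out


def cox_univariate(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 50, tol: float = 1e-9
) -> tuple[float, float, float, bool]:
    """Univariate Cox PH fit maximizing the Breslow partial likelihood.

    Returns (coefficient, standard error, two-sided Wald p, converged).
    Newton-Raphson with step halving; ties handled by the Breslow
    approximation (each tied event sees the full risk-set sum).
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    x, time, event = x[order], time[order], event[order]
    n = len(x)
    if event.sum() == 0 or np.ptp(x) == 0:
        return 0.0, math.inf, 1.0, False

    def _derivs(beta: float) -> tuple[float, float, float]:
        # cumulative over descending time = risk set {j: t_j >= t_i}, but tied
        # times must share the full tied-block sum
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        # index of the last element of each tied block
        last_of_block = np.empty(n, dtype=int)
        idx = n - 1
        for i in range(n - 1, -1, -1):
            if i == n - 1 or time[i] != time[i + 1]:
                idx = i
            last_of_block[i] = idx
        # within a descending sort, ties appear consecutively; the risk set of
        # an event at t includes every tied j, i.e. cumsum up to block end
        blk = last_of_block
        ll = grad = hess = 0.0
        for i in np.flatnonzero(event):
            j = blk[i]
            ll += beta * x[i] - math.log(s0[j])
            mean = s1[j] / s0[j]
            grad += x[i] - mean
            hess += s2[j] / s0[j] - mean * mean
        return ll, grad, hess

    beta = 0.0
    ll, grad, hess = _derivs(beta)
    converged = False
    for _ in range(max_iter):
        if hess <= 0:
            break
        step = grad / hess
        # step halving if the likelihood does not improve
        new_beta = beta + step
        for _h in range(30):
            new_ll, new_grad, new_hess = _derivs(new_beta)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        if abs(new_beta - beta) < tol:
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            converged = True
            break
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    if hess <= 0 or not np.isfinite(beta):
        return float(beta), math.inf, 1.0, False
    se = 1.0 / math.sqrt(hess)
    p = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return float(beta), float(se), max(_P_FLOOR, min(1.0, float(p))), converged


def cox_screen(
    matrix: ExpressionMatrix,
    candidates: Iterable[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Univariate Cox screen of candidate genes against overall survival.

    Returns a DataFrame indexed by gene with columns coefficient, se,
    p_value, passes (Wald p < alpha), converged.  Candidates with constant
    expression are excluded with a warning.
    """
    meta = matrix.sample_meta
    if "os_time" not in meta or "os_event" not in meta:
        raise ValueError("sample_meta must carry os_time and os_event")
    ok = meta["os_time"].notna() & meta["os_event"].notna()
    if ok.sum() < 30:
        raise ValueError("need >= 30 samples with survival data")
    samples = meta.index[ok]
    time = meta.loc[samples, "os_time"].to_numpy(float)
    event = meta.loc[samples, "os_event"].to_numpy(float).astype(bool)
    rows = {}
    excluded = []
    for gene in candidates:
        if gene not in matrix.values.index:
            continue
        x = matrix.values.loc[gene, samples].to_numpy(float)
        if np.ptp(x) == 0:
            excluded.append(gene)
            continue
        coef, se, p, conv = cox_univariate(x, time, event)
        rows[gene] = {
            "coefficient": coef,
            "se": se,
            "p_value": p,
            "passes": bool(conv and p < alpha),
            "converged": conv,
        }
    if excluded:
        warnings.warn(f"constant candidates excluded from Cox screen: {excluded}", stacklevel=2)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
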