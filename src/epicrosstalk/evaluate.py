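"""Survival and immunotherapy-response read-outs.

Kaplan-Meier curves with the unweighted log-rank test, ROC/AUC for
recognizing the EMD subtype from the EMD score, and the lower-quartile
response-rate contrast used for ICI cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = ["KMResult", "ROCResult", "km_logrank", "score_auc", "response_contrast"]


@dataclass
class KMResult:
    """Per-group product-limit estimates plus the log-rank test."""

    tables: dict[object, pd.DataFrame]  # group -> (time, at_risk, events, survival)
    logrank_chi2: float
    logrank_p: float
    df: int


@dataclass
class ROCResult:
    """Empirical ROC curve and trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def km_logrank(times, events, groups) -> KMResult:
    """Kaplan-Meier estimate per group and the (groups-1)-df log-rank test.

    All event/censoring times must be positive; at least two groups are
    required.  A group with zero events is fine.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float).astype(int)
    groups = np.asarray(groups)
    if (times <= 0).any():
        raise ValueError("all times must be > 0")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    tables = {}
    for g in uniq:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        ev = kmf.event_table
        tables[g] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(float),
                "at_risk": ev["at_risk"].to_numpy(int),
                "events": ev["observed"].to_numpy(int),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
            }
        )
    res = multivariate_logrank_test(times, groups, events)
    return KMResult(
        tables,
        float(res.test_statistic),
        float(res.p_value),
        int(len(uniq) - 1),
    )


def score_auc(scores, labels) -> ROCResult:
    """Empirical ROC of a score against binary labels; AUC by trapezoid.

    Equivalent to the Mann-Whitney rank statistic U/(n1*n2) with midrank
    tie handling.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both label classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return ROCResult(thresholds, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def response_contrast(scores, responses, q: float = 0.25) -> dict:
    """Responder-rate contrast between low (<= Q1) and high score groups.

    The split point is the linear-interpolation (type-7) quantile of the
    scores; samples at the quantile go to the low group.  Significance is
    the two-sided Fisher exact test on the 2x2 response table.  Responses
    may be booleans or the strings 'responder'/'non_responder'.
    """
    scores = np.asarray(scores, float)
    resp = np.asarray(
        [
            r if isinstance(r, (bool, np.bool_, int, np.integer)) else r == "responder"
            for r in np.asarray(responses).ravel()
        ]
    ).astype(bool)
    if len(scores) < 4:
        raise ValueError("need >= 4 samples")
    cut = float(np.quantile(scores, q))
    low = scores <= cut
    high = ~low
    if not low.any() or not high.any():
        raise ValueError("empty group after quantile split")
    table = [
        [int(resp[low].sum()), int((~resp[low]).sum())],
        [int(resp[high].sum()), int((~resp[high]).sum())],
    ]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return {
        "rate_low": float(resp[low].mean()),
        "rate_high": float(resp[high].mean()),
        "n_low": int(low.sum()),
        "n_high": int(high.sum()),
        "fisher_p": float(p),
        "cut": cut,
    }
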