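"""Model/Results front end for EMD subtype discovery and scoring.

:class:`EMDSubtypeModel` is built from an expression matrix with survival
metadata plus a list of candidate modification-related lncRNAs (EMRLs);
``fit`` runs the full downstream pipeline — univariate Cox screen of the
candidates, consensus clustering of samples on the screened EMRLs,
worst-survival (EMD) cluster designation, differential expression against
the best-survival cluster, signature selection, and per-sample EMD scoring
— and returns an :class:`EMDResults` carrying labels, the signature, the
score table and survival/response diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ConsensusResult, EMDLabeling, consensus_cluster, label_emd_cluster
from .core import ExpressionMatrix
from .evaluate import KMResult, ROCResult, km_logrank, response_contrast, score_auc
from .scoring import Signature, emd_score, select_signature
from .stats import cox_screen, differential_expression

__all__ = ["EMDSubtypeModel", "EMDResults"]


class EMDSubtypeModel:
    """Subtype-discovery and scoring model over a gene x sample cohort.

    Parameters
    ----------
    expression
        Log2-scale expression with ``os_time``/``os_event`` in sample_meta.
    emrl_candidates
        Candidate EMRLs (e.g. the lncRNA members of an EMRG catalog) to be
        screened for survival association before clustering.
    k
        Number of sample clusters; ``None`` chooses k by minimum PAC.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        emrl_candidates: Sequence[str],
        k: int | None = 4,
        max_k: int = 7,
        screen_alpha: float = 0.01,
        n_resamples: int = 1000,
        item_frac: float = 0.8,
        gs_threshold: float = 0.4,
        mm_threshold: float = 0.7,
        ssgsea_alpha: float = 0.25,
    ) -> None:
        self.expression = expression
        self.emrl_candidates = [
            g for g in dict.fromkeys(emrl_candidates) if g in expression.values.index
        ]
        if not self.emrl_candidates:
            raise ValueError("no EMRL candidates present in the expression matrix")
        self.k = k
        self.max_k = max_k
        self.screen_alpha = screen_alpha
        self.n_resamples = n_resamples
        self.item_frac = item_frac
        self.gs_threshold = gs_threshold
        self.mm_threshold = mm_threshold
        self.ssgsea_alpha = ssgsea_alpha

    @classmethod
    def from_dataframes(
        cls,
        values: pd.DataFrame,
        clinical: pd.DataFrame,
        emrl_candidates: Sequence[str],
        mutations: dict | None = None,
        **kwargs,
    ) -> "EMDSubtypeModel":
        """Build from a raw matrix and clinical table keyed by sample_id."""
        matrix = ExpressionMatrix(values, clinical, mutations)
        return cls(matrix, emrl_candidates, **kwargs)

    def fit(self, seed: int | None = None) -> "EMDResults":
        """Run the screen -> cluster -> label -> signature -> score pipeline."""
        matrix = self.expression
        screen = cox_screen(matrix, self.emrl_candidates, alpha=self.screen_alpha)
        screened = list(screen.index[screen["passes"]])
        if len(screened) < 2:
            raise ValueError(
                f"only {len(screened)} candidates pass the survival screen at "
                f"alpha={self.screen_alpha}; cannot cluster"
            )
        emrl_matrix = ExpressionMatrix(
            matrix.values.loc[screened].copy(), matrix.sample_meta.copy()
        )
        consensus = consensus_cluster(
            emrl_matrix,
            max_k=self.max_k,
            n_resamples=self.n_resamples,
            item_frac=self.item_frac,
            seed=seed,
            fixed_k=self.k,
        )
        labels = consensus.chosen_labels
        labeling = label_emd_cluster(labels, matrix)
        emd_samples = list(labels.index[labels == labeling.emd_cluster])
        ref_samples = list(labels.index[labels == labeling.reference_cluster])
        deg = differential_expression(matrix, emd_samples, ref_samples)
        indicator = (labels == labeling.emd_cluster).astype(float)
        signature = select_signature(
            matrix,
            deg,
            indicator,
            gs_threshold=self.gs_threshold,
            mm_threshold=self.mm_threshold,
        )
        scores = emd_score(matrix, signature, alpha=self.ssgsea_alpha)
        return EMDResults(
            model=self,
            screen=screen,
            screened_emrls=screened,
            consensus=consensus,
            labels=labels,
            labeling=labeling,
            deg=deg,
            signature=signature,
            score_table=scores,
        )


@dataclass
class EMDResults:
    """Fitted subtype labels, signature, scores and diagnostics."""

    model: EMDSubtypeModel
    screen: pd.DataFrame
    screened_emrls: list[str]
    consensus: ConsensusResult
    labels: pd.Series
    labeling: EMDLabeling
    deg: list
    signature: Signature
    score_table: pd.DataFrame

    @property
    def emd_cluster(self) -> int:
        return self.labeling.emd_cluster

    @property
    def reference_cluster(self) -> int:
        return self.labeling.reference_cluster

    @property
    def is_emd(self) -> pd.Series:
        return (self.labels == self.emd_cluster).rename("is_emd")

    def subtype_auc(self) -> ROCResult:
        """How well the EMD score recognizes the EMD cluster."""
        return score_auc(
            self.score_table["emd_score"].to_numpy(),
            self.is_emd.loc[self.score_table.index].to_numpy(),
        )

    def km_by_score_group(self) -> KMResult:
        """Log-rank contrast of the cohort-median high/low score groups."""
        meta = self.model.expression.sample_meta
        ok = meta["os_time"].notna() & meta["os_event"].notna()
        idx = meta.index[ok]
        return km_logrank(
            meta.loc[idx, "os_time"],
            meta.loc[idx, "os_event"],
            self.score_table.loc[idx, "score_group"],
        )

    def km_by_cluster(self) -> KMResult:
        meta = self.model.expression.sample_meta
        ok = meta["os_time"].notna() & meta["os_event"].notna()
        idx = meta.index[ok]
        return km_logrank(
            meta.loc[idx, "os_time"], meta.loc[idx, "os_event"], self.labels.loc[idx]
        )

    def ici_response_contrast(self, q: float = 0.25) -> dict:
        """Responder-rate contrast below/above the EMD-score lower quartile."""
        meta = self.model.expression.sample_meta
        if "ici_response" not in meta:
            raise ValueError("sample_meta has no ici_response column")
        ok = meta["ici_response"].notna()
        idx = meta.index[ok]
        return response_contrast(
            self.score_table.loc[idx, "emd_score"].to_numpy(),
            meta.loc[idx, "ici_response"].to_numpy(),
            q=q,
        )

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = []
        lines.append("EMD subtype model")
        lines.append("=" * 60)
        n_pass = int(self.screen["passes"].sum())
        lines.append(
            f"Survival screen: {n_pass}/{len(self.screen)} candidate EMRLs "
            f"pass at p < {self.model.screen_alpha}"
        )
        lines.append(
            f"Consensus clustering: k = {self.consensus.chosen_k} "
            f"(PAC: {', '.join(f'k={k}: {v:.3f}' for k, v in self.consensus.pac.items())})"
        )
        sizes = self.labels.value_counts().sort_index()
        lines.append(
            "Cluster sizes: "
            + ", ".join(f"C{c}: {n}" for c, n in sizes.items())
        )
        lines.append(
            f"EMD cluster: C{self.emd_cluster} (worst survival); "
            f"reference: C{self.reference_cluster} (best survival)"
        )
        lines.append(self.labeling.km_summary.to_string())
        lines.append(
            f"Signature: |set1| = {len(self.signature.set1)}, "
            f"|set2| = {len(self.signature.set2)} "
            f"(GS >= {self.model.gs_threshold}, MM >= {self.model.mm_threshold})"
        )
        auc = self.subtype_auc().auc
        lines.append(f"EMD-score AUC for recognizing the EMD cluster: {auc:.3f}")
        try:
            km = self.km_by_score_group()
            lines.append(
                f"Median-split log-rank: chi2 = {km.logrank_chi2:.2f}, "
                f"p = {km.logrank_p:.3g}"
            )
        except ValueError:
            pass
        meta = self.model.expression.sample_meta
        if "ici_response" in meta and meta["ici_response"].notna().any():
            rc = self.ici_response_contrast()
            lines.append(
                f"ICI response (low vs high score, Q1 split): "
                f"{100 * rc['rate_low']:.0f}% vs {100 * rc['rate_high']:.0f}% "
                f"(Fisher p = {rc['fisher_p']:.3g})"
            )
        return "\n".join(lines)
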