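"""Tissue-specificity scoring.

Tau index over an N-tissue expression profile x:

    x_hat_i = x_i / max_j x_j
    tau     = sum_i (1 - x_hat_i) / (N - 1)

Tau is 0 for a perfectly uniform profile and 1 for expression confined to
a single tissue.  The Shannon-entropy alternative Hg = -sum p_i log2 p_i
(p_i = x_i / sum x) runs from 0 (one tissue) to log2 N (uniform); low
entropy means high specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DataError, ExpressionMatrix
from .characterize import compare_expression_distributions


@dataclass
class SpecificityConfig:
    min_fpkm_any_tissue: float = 1.0   # rows below this everywhere are discarded
    tau_threshold: float = 0.8         # strict: tau must exceed it
    expressed_threshold: float = 1.0   # FPKM at which a tissue counts as expressing

    def __post_init__(self) -> None:
        if min(self.min_fpkm_any_tissue, self.tau_threshold, self.expressed_threshold) < 0:
            raise DataError("specificity thresholds must be non-negative")


@dataclass
class SpecificityResult:
    transcript_id: str
    tau: float
    hg_entropy: float
    max_tissue: str | None
    is_tissue_specific: bool
    is_uniquely_expressed: bool


def _check_profile(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("profile must be a vector over >= 2 tissues")
    if (x < 0).any():
        raise DataError("profile has negative components")
    if x.max() == 0:
        raise DataError("all-zero profile: specificity undefined")
    return x


def tau(profile) -> float:
    """Tau tissue-specificity index in [0, 1]."""
    x = _check_profile(profile)
    x_hat = x / x.max()
    return float((1.0 - x_hat).sum() / (x.size - 1))


def hg_entropy(profile) -> float:
    """Shannon entropy of the normalized profile, in bits (0 .. log2 N)."""
    x = _check_profile(profile)
    p = x / x.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def call_specificity(
    expr: ExpressionMatrix, cfg: SpecificityConfig | None = None
) -> list[SpecificityResult]:
    """Score every row of a one-column-per-tissue matrix.

    Rows whose maximum FPKM is below ``min_fpkm_any_tissue`` are discarded
    (not scored).  A transcript is tissue-specific when tau strictly
    exceeds the threshold; its ``max_tissue`` is the argmax tissue, left
    unassigned on ties.  It is uniquely expressed when exactly one tissue
    reaches the expressed threshold.
    """
    cfg = cfg or SpecificityConfig()
    tissues = list(expr.values.columns)
    if len(tissues) < 2:
        raise DataError("specificity requires >= 2 tissues")
    results = []
    for tid, row in expr.values.iterrows():
        x = row.to_numpy(dtype=float)
        if x.max() < cfg.min_fpkm_any_tissue:
            continue
        t = tau(x)
        h = hg_entropy(x)
        top = x.max()
        winners = [tissues[i] for i in range(len(tissues)) if x[i] == top]
        max_tissue = winners[0] if len(winners) == 1 else None
        n_expressed = int((x >= cfg.expressed_threshold).sum())
        results.append(
            SpecificityResult(
                transcript_id=str(tid),
                tau=t,
                hg_entropy=h,
                max_tissue=max_tissue,
                is_tissue_specific=bool(t > cfg.tau_threshold),
                is_uniquely_expressed=n_expressed == 1,
            )
        )
    return results


def specificity_table(results: list[SpecificityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "tau": r.tau,
                "hg_entropy": r.hg_entropy,
                "max_tissue": r.max_tissue if r.max_tissue is not None else "",
                "is_tissue_specific": r.is_tissue_specific,
                "is_uniquely_expressed": r.is_uniquely_expressed,
            }
            for r in results
        ]
    )


def per_tissue_specific_counts(results: list[SpecificityResult]) -> dict[str, int]:
    """Count tissue-specific transcripts per argmax tissue (ties excluded)."""
    counts: dict[str, int] = {}
    for r in results:
        if r.is_tissue_specific and r.max_tissue is not None:
            counts[r.max_tissue] = counts.get(r.max_tissue, 0) + 1
    return counts


def specificity_distribution_compare(a, b) -> tuple[float, float]:
    """KS comparison of two tau distributions (e.g. lincRNA vs mRNA)."""
    return compare_expression_distributions(a, b)
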