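"""Gene-selection gates: overall expression level and replicate variability.

Two screens precede clustering and model fitting.  The expression gate ranks
genes by the median of their sample-channel (Cy3) intensities over all
arrays, bins them by the quartiles of that distribution (categories I-IV),
drops category I (below the first quartile) and rescues dropped genes that
show a pronounced peak.  The variability gate keeps genes whose replicate
coefficient of variation stays below 0.47 at eight or more time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSummary",
    "overall_expression_level",
    "quartile_categories",
    "select_highly_expressed",
    "select_low_cv",
]

CATEGORIES = ("I", "II", "III", "IV")


@dataclass
class ExpressionSummary:
    """Per-gene expression-gate verdicts plus the quartile thresholds used."""

    table: pd.DataFrame  # columns: overall_level, peak, category, highly_expressed, rescued_by_peak
    q1: float
    q2: float
    q3: float

    @property
    def kept_genes(self) -> list[str]:
        return list(self.table.index[self.table["highly_expressed"]])


def overall_expression_level(sample_signals: np.ndarray) -> float:
    """Median of all finite sample-channel intensities of one gene."""
    x = np.asarray(sample_signals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("need at least one finite sample-channel value")
    return float(np.median(x))


def quartile_categories(levels: pd.Series) -> tuple[float, float, float, pd.Series]:
    """Quartile thresholds of the overall levels and each gene's category I-IV.

    Category I: level < Q1; II: [Q1, Q2); III: [Q2, Q3); IV: >= Q3
    (linear-interpolation quantile convention).
    """
    if len(levels) < 4:
        raise ValueError("need >= 4 genes to form quartile categories")
    vals = levels.to_numpy(dtype=float)
    q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    cat = np.full(len(levels), "IV", dtype=object)
    cat[vals < q3] = "III"
    cat[vals < q2] = "II"
    cat[vals < q1] = "I"
    return float(q1), float(q2), float(q3), pd.Series(cat, index=levels.index)


def select_highly_expressed(
    sample_signal: pd.DataFrame, peak_min: float | None = None
) -> ExpressionSummary:
    """Apply the overall-expression gate with peak rescue.

    Genes in categories II-IV are kept.  A category-I gene is rescued iff its
    maximum sample-channel value reaches ``peak_min`` (default: the global
    median Q2 of the overall levels, a scale-free stand-in for a
    "significant peak").
    """
    levels = pd.Series(
        {g: overall_expression_level(sample_signal.loc[g].to_numpy()) for g in sample_signal.index},
        name="overall_level",
    )
    q1, q2, q3, cat = quartile_categories(levels)
    if peak_min is None:
        peak_min = q2
    peaks = sample_signal.max(axis=1, skipna=True)
    rescued = (cat == "I") & (peaks >= peak_min)
    kept = (cat != "I") | rescued
    table = pd.DataFrame(
        {
            "overall_level": levels,
            "peak": peaks,
            "category": cat,
            "highly_expressed": kept,
            "rescued_by_peak": rescued,
        }
    )
    return ExpressionSummary(table, q1, q2, q3)


def select_low_cv(
    cv: pd.DataFrame, cv_max: float = 0.47, min_points: int = 8
) -> list[str]:
    """Keep genes with replicate CV below ``cv_max`` at >= ``min_points`` time points.

    Time points where the CV is undefined (fewer than two retained
    replicates) do not count toward the quota.
    """
    ok = (cv < cv_max) & cv.notna()
    keep = ok.sum(axis=1) >= min_points
    return list(cv.index[keep])
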