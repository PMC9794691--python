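"""Small self-contained statistics used across the study's figures:
ellipsoid tumor volume, nuclear-localization percentage, and endpoint
comparison tests."""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

__all__ = [
    "tumor_volume",
    "percent_nuclear",
    "compare_localization",
    "endpoint_test",
]


def tumor_volume(width: float, length: float) -> float:
    """Ellipsoid tumor volume pi/6 * width^2 * length (mm^3).

    By convention the smaller caliper measurement is the width; unordered
    inputs are reordered accordingly.
    """
    if width <= 0 or length <= 0:
        raise ValueError("dimensions must be positive")
    w, l = sorted((float(width), float(length)))
    return math.pi / 6.0 * w * w * l


def percent_nuclear(nuclear, cytoplasmic) -> np.ndarray:
    """Per-cell percent nuclear signal: 100 * nuclear / (nuclear + cyto).

    Cells with zero total signal are dropped with a warning (NaN in the
    output marks them).
    """
    nuc = np.asarray(nuclear, dtype=float)
    cyt = np.asarray(cytoplasmic, dtype=float)
    if nuc.shape != cyt.shape:
        raise ValueError("signal arrays must align")
    if (nuc < 0).any() or (cyt < 0).any():
        raise ValueError("signals must be non-negative")
    total = nuc + cyt
    zero = total == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} cells with zero total signal",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, np.nan, 100.0 * nuc / total)
    return out


def compare_localization(percent_a, percent_b,
                         test: str = "rank_sum") -> dict[str, float]:
    """Two-group comparison of per-cell nuclear percentages.

    ``rank_sum`` (primary) is the unpaired two-sided Wilcoxon rank-sum
    (Mann-Whitney U); ``signed_rank`` is the paired Wilcoxon signed-rank
    variant for equal-length paired samples.
    """
    a = np.asarray(percent_a, dtype=float)
    b = np.asarray(percent_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if test == "rank_sum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "signed_rank":
        if len(a) != len(b):
            raise ValueError("signed-rank test needs paired, equal-length samples")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}


def endpoint_test(values_a, values_b) -> dict[str, float]:
    """Welch two-sided t-test on endpoint values (replicate AUCs or final
    tumor volumes)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "df": float(res.df), "mean_a": float(a.mean()),
            "mean_b": float(b.mean())}
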