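"""Group-wise differential expression with the signed fold-change convention.

Fold change between two groups is the ratio of arithmetic means of the linear
intensities.  A ratio above 1 is reported as-is; a ratio below 1 is reported as
the negative reciprocal, so fold changes live on (-inf, -1] ∪ [+1, +inf) and a
2-fold decrease reads -2.0 rather than 0.5.  Significance is a per-probe-set
two-group test on the log2 values (equal-variance t by default, one-way ANOVA
being algebraically identical for two groups, Welch optionally); a probe set is
called differentially expressed when p < alpha and the ratio is not exactly 1.
No multiple-testing correction is applied by default; an optional
Benjamini–Hochberg adjustment is available for exploratory use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

VALID_METHODS = ("ttest", "anova", "welch")

#: Significance threshold used throughout unless overridden.
DEFAULT_ALPHA = 0.05


def group_means(matrix: ExpressionMatrix, group: str) -> pd.Series:
    """Arithmetic mean of the linear intensities per probe set for one group.

    Raises ``KeyError`` naming the label if the group is absent.
    """
    return matrix.group_values(group).mean(axis=1)


def fold_change(mean_num: float, mean_den: float) -> float:
    """Signed fold change of two positive linear means.

    ratio > 1 -> ratio; ratio < 1 -> -1/ratio; ratio == 1 -> +1.0.
    Anti-symmetric for unequal means: fold_change(a, b) == -fold_change(b, a).
    """
    if mean_num <= 0 or mean_den <= 0:
        raise ValueError("group means must be strictly positive")
    ratio = mean_num / mean_den
    if ratio > 1:
        return float(ratio)
    if ratio < 1:
        return float(-1.0 / ratio)
    return 1.0


def _fold_change_vector(ratio: np.ndarray) -> np.ndarray:
    fc = np.where(ratio >= 1, ratio, -1.0 / ratio)
    return np.where(ratio == 1, 1.0, fc)


def _direction_vector(ratio: np.ndarray) -> np.ndarray:
    return np.select([ratio > 1, ratio < 1], ["up", "down"], default="none")


def _two_group_pvalues(
    log_a: np.ndarray, log_b: np.ndarray, method: str
) -> np.ndarray:
    """Vectorized per-row p-values for two groups of log2 values."""
    if method == "ttest":
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "welch":
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "anova":
        res = stats.f_oneway(log_a, log_b, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"method must be one of {VALID_METHODS}, got {method!r}")
    # Degenerate rows (zero variance in both groups) come back NaN: the test
    # statistic is 0/0.  Equal means -> no evidence of difference (p = 1);
    # unequal means with zero spread -> the statistic diverges (p = 0).
    nan = ~np.isfinite(p)
    if nan.any():
        equal = np.isclose(log_a[nan].mean(axis=1), log_b[nan].mean(axis=1))
        p[nan] = np.where(equal, 1.0, 0.0)
    return p


def significance(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    method: str = "ttest",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-probe-set p-values for group_a vs group_b on log2 values.

    Returns a DataFrame indexed by probe set with columns ``p_value`` and
    ``significant`` (p < alpha).  Both groups need at least two samples.
    """
    va = matrix.group_values(group_a)
    vb = matrix.group_values(group_b)
    if va.shape[1] < 2 or vb.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per group for testing; got "
            f"{group_a}={va.shape[1]}, {group_b}={vb.shape[1]}"
        )
    p = _two_group_pvalues(
        np.log2(va.to_numpy()), np.log2(vb.to_numpy()), method
    )
    return pd.DataFrame(
        {"p_value": p, "significant": p < alpha}, index=matrix.probe_set_ids
    )


def run_comparison(
    matrix: ExpressionMatrix,
    numerator_group: str,
    denominator_group: str,
    method: str = "ttest",
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = False,
) -> pd.DataFrame:
    """Full comparison table for one ordered group pair.

    One row per probe set with columns ``comparison``, ``mean_num``,
    ``mean_den``, ``ratio``, ``fold_change``, ``p_value``, ``direction``,
    ``significant``.  ``significant`` requires p < alpha AND a direction
    (ratio exactly 1 is never significant).  With ``adjust=True`` p-values are
    Benjamini–Hochberg adjusted before thresholding.
    """
    mean_num = group_means(matrix, numerator_group)
    mean_den = group_means(matrix, denominator_group)
    ratio = (mean_num / mean_den).to_numpy()
    sig = significance(matrix, numerator_group, denominator_group, method, alpha)
    p = sig["p_value"].to_numpy()
    if adjust:
        p = stats.false_discovery_control(p, method="bh")
    direction = _direction_vector(ratio)
    out = pd.DataFrame(
        {
            "comparison": f"{numerator_group}_vs_{denominator_group}",
            "mean_num": mean_num.to_numpy(),
            "mean_den": mean_den.to_numpy(),
            "ratio": ratio,
            "fold_change": _fold_change_vector(ratio),
            "p_value": p,
            "direction": direction,
            "significant": (p < alpha) & (direction != "none"),
        },
        index=matrix.probe_set_ids,
    )
    out.index.name = "probe_set_id"
    return out
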