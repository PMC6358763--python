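"""Western-blot densitometry: total-protein normalization and group comparison.

Band optical densities are divided by the total-protein (Coomassie) optical
density of the same lane, making lanes comparable across loading differences;
group contrasts are reported as percent change of the normalized means with a
two-tailed t-test (Welch by default, since nothing constrains the group
variances to be equal).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

BLOT_GROUPS = ("control_1g", "after_parabola_1", "after_parabola_15")


def normalize_od(band_od: float, total_protein_od: float) -> float:
    """Band OD divided by the lane's total-protein OD (scale-invariant)."""
    if total_protein_od <= 0:
        raise ValueError("total_protein_od must be strictly positive")
    if band_od < 0:
        raise ValueError("band_od must be non-negative")
    return band_od / total_protein_od


def read_lane_table(path: str | Path) -> pd.DataFrame:
    """Lane TSV with columns lane_id, group, band_od, total_protein_od."""
    df = pd.read_csv(path, sep="\t")
    required = {"lane_id", "group", "band_od", "total_protein_od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lane table missing columns {sorted(missing)}")
    return df


def compare_blot_groups(
    lanes: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> dict:
    """Percent change of normalized OD from group_a to group_b, with t-test.

    Returns ``{"relative_change_percent", "p_value", "significant", ...}``
    where the relative change is 100·(mean_b − mean_a)/mean_a on the
    normalized ODs.  Requires at least three lanes per group.
    """
    norm = lanes["band_od"] / lanes["total_protein_od"]
    a = norm[lanes["group"] == group_a].to_numpy(dtype=float)
    b = norm[lanes["group"] == group_b].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"need >= 3 lanes per group; got {group_a}={len(a)}, {group_b}={len(b)}"
        )
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if np.allclose(a.var(), 0) and np.allclose(b.var(), 0):
        p = 1.0 if np.isclose(mean_a, mean_b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "relative_change_percent": 100.0 * (mean_b - mean_a) / mean_a,
        "p_value": p,
        "significant": bool(p < alpha),
    }
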