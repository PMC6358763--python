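"""Gravisensitivity set logic.

A probe set is *hypergravity-sensitive* when it is significantly differentially
expressed in the baseline-hypergravity vs hardware-ground-control comparison.
The raw *microgravity-responsive* set (significant in µg vs baseline) is then
"controlled": because the microgravity phase always follows a hypergravity
phase, any probe set that was already regulated in the same direction in the
hypergravity control comparison may simply be carrying a delayed hypergravity
effect, and is excluded.  Probe sets significant in both comparisons are the
*double-sensitive* pool, partitioned by whether the two directions agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .designs import Comparison


@dataclass(frozen=True)
class CallSet:
    """Direction + significance calls of one comparison over a probe-set universe."""

    comparison: Comparison
    calls: pd.DataFrame  # index probe_set_id; columns: direction, significant

    def __post_init__(self) -> None:
        missing = {"direction", "significant"} - set(self.calls.columns)
        if missing:
            raise ValueError(f"CallSet calls missing columns {sorted(missing)}")
        bad = set(self.calls["direction"].unique()) - {"up", "down", "none"}
        if bad:
            raise ValueError(f"invalid directions {sorted(bad)}")
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate probe_set_id in CallSet")

    @classmethod
    def from_comparison_table(cls, comparison: Comparison, table: pd.DataFrame) -> "CallSet":
        return cls(comparison, table[["direction", "significant"]].copy())

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.calls.index)

    @property
    def significant_ids(self) -> frozenset[str]:
        return frozenset(self.calls.index[self.calls["significant"]])

    def direction_of(self, probe_set_id: str) -> str:
        return self.calls.at[probe_set_id, "direction"]

    def up_down_counts(self) -> dict[str, int]:
        sig = self.calls[self.calls["significant"]]
        up = int((sig["direction"] == "up").sum())
        down = int((sig["direction"] == "down").sum())
        return {"up": up, "down": down, "total": up + down}


@dataclass(frozen=True)
class SensitivityReport:
    """The five gravisensitivity sets of one campaign."""

    campaign_id: str
    hyper_sensitive: frozenset[str]
    micro_responsive: frozenset[str]
    micro_sensitive_controlled: frozenset[str]
    double_same: frozenset[str]
    double_opposite: frozenset[str]
    comparison_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.micro_sensitive_controlled != self.micro_responsive - self.double_same:
            raise ValueError("controlled set is not micro_responsive minus double_same")
        doubles = self.double_same | self.double_opposite
        if not doubles <= (self.micro_responsive & self.hyper_sensitive):
            raise ValueError("double-sensitive sets must lie in the intersection")
        if self.double_same & self.double_opposite:
            raise ValueError("double_same and double_opposite must be disjoint")


def hypergravity_sensitive(calls: CallSet, expected_comparison: Comparison | None = None) -> frozenset[str]:
    """Probe sets significant in the hypergravity control comparison (BL vs GC)."""
    if expected_comparison is not None and tuple(calls.comparison) != tuple(expected_comparison):
        raise ValueError(
            f"CallSet is for comparison {calls.comparison}, expected {expected_comparison}"
        )
    return calls.significant_ids


def microgravity_sensitive_controlled(
    mu_calls: CallSet, control_calls: CallSet
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Controlled microgravity-sensitive set and the double-sensitivity partition.

    Returns ``(controlled, double_same, double_opposite)`` where ``controlled``
    is the µg-vs-BL significant set minus probe sets significant in BOTH
    comparisons with the same direction.  A direction of ``none`` never
    matches any direction.
    """
    if mu_calls.universe != control_calls.universe:
        raise ValueError(
            "µg and control CallSets cover different probe-set universes "
            f"({len(mu_calls.universe)} vs {len(control_calls.universe)} ids)"
        )
    mu_sig = mu_calls.significant_ids
    ctrl_sig = control_calls.significant_ids
    both = mu_sig & ctrl_sig
    same, opposite = set(), set()
    for pid in both:
        d_mu = mu_calls.direction_of(pid)
        d_ct = control_calls.direction_of(pid)
        if d_mu == "none" or d_ct == "none":
            continue
        (same if d_mu == d_ct else opposite).add(pid)
    return frozenset(mu_sig - same), frozenset(same), frozenset(opposite)


def build_sensitivity_report(
    campaign_id: str,
    mu_calls: CallSet,
    control_calls: CallSet,
    other_calls: dict[str, CallSet] | None = None,
) -> SensitivityReport:
    """Assemble the full report from the µg and hypergravity-control CallSets.

    ``other_calls`` (comparisons computed but not feeding the set logic, such
    as 1 g IF vs GC) contribute up/down tallies only.
    """
    hyper = hypergravity_sensitive(control_calls)
    controlled, same, opposite = microgravity_sensitive_controlled(mu_calls, control_calls)
    counts = {}
    all_calls = {
        f"{mu_calls.comparison[0]}_vs_{mu_calls.comparison[1]}": mu_calls,
        f"{control_calls.comparison[0]}_vs_{control_calls.comparison[1]}": control_calls,
    }
    for name, cs in {**all_calls, **(other_calls or {})}.items():
        counts[name] = cs.up_down_counts()
    return SensitivityReport(
        campaign_id=campaign_id,
        hyper_sensitive=hyper,
        micro_responsive=mu_calls.significant_ids,
        micro_sensitive_controlled=controlled,
        double_same=same,
        double_opposite=opposite,
        comparison_counts=counts,
    )


def venn_counts(report: SensitivityReport) -> dict[str, int]:
    """Cardinalities of the five sets, as printed inside the Venn circles.

    The additive identity |micro_responsive| = |controlled| + |double_same|
    holds by construction.
    """
    return {
        "hyper_sensitive": len(report.hyper_sensitive),
        "micro_responsive": len(report.micro_responsive),
        "micro_sensitive_controlled": len(report.micro_sensitive_controlled),
        "double_same": len(report.double_same),
        "double_opposite": len(report.double_opposite),
    }


def report_to_dict(report: SensitivityReport) -> dict:
    """JSON-serializable summary: set cardinalities plus per-comparison tallies."""
    return {
        "campaign_id": report.campaign_id,
        "venn_counts": venn_counts(report),
        "comparison_counts": report.comparison_counts,
    }


def plot_venn(report: SensitivityReport, ax=None):
    """Two-circle Venn of the hypergravity-sensitive and µg-responsive sets.

    Drawn with plain matplotlib patches; region labels are the double-sensitive
    intersection and the exclusive remainders.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    n_hyper = len(report.hyper_sensitive)
    n_mu = len(report.micro_responsive)
    n_both = len(report.double_same | report.double_opposite)
    ax.add_patch(Circle((-0.6, 0), 1.0, alpha=0.4, color="tab:orange"))
    ax.add_patch(Circle((0.6, 0), 1.0, alpha=0.4, color="tab:blue"))
    ax.text(-1.0, 0, str(n_hyper - n_both), ha="center", va="center")
    ax.text(1.0, 0, str(n_mu - n_both), ha="center", va="center")
    ax.text(0, 0, str(n_both), ha="center", va="center")
    ax.text(-1.0, 1.15, "hypergravity-sensitive", ha="center")
    ax.text(1.0, -1.25, "µg-responsive", ha="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(report.campaign_id)
    return ax
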