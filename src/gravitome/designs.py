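"""Campaign designs: experimental groups, replicate counts and comparison graphs.

An altered-gravity campaign exposes suspended immune cells to a fixed sequence of
gravity phases — hypergravity during aircraft pull-up or rocket launch, then
microgravity — and lyses a dedicated sample group at the end of each phase.
Parabolic flights give ~20 s per phase at 1.8 g; suborbital ballistic rockets
give ~75 s of up to 13.5 g followed by ~300 s of microgravity.  Each campaign
additionally carries hardware ground controls and, where the hardware allows,
in-flight 1 g controls (on-board centrifuge) and standard cell-culture controls.

The four built-in designs reproduce the published campaign layouts: two
parabolic-flight campaigns (U937 myelomonocytic cells, Jurkat T cells) and two
TEXUS rocket missions, with their replicate counts and the comparison graph
evaluated between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Canonical group labels.
CC = "CC"  # 1 g cell-culture ground control
HW_1G_GC = "HW_1g_GC"  # hardware 1 g ground control
IF_1G = "IF_1g"  # 1 g in-flight control
BL_HYP_G = "BL_hyp_g"  # baseline sample lysed at end of the hypergravity phase
MU_G = "MU_G"  # sample lysed at end of the microgravity phase

GROUP_LABELS = (CC, HW_1G_GC, IF_1G, BL_HYP_G, MU_G)

Comparison = tuple[str, str]  # (numerator group, denominator group)


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: replicate count plus exposure metadata."""

    label: str
    n_replicates: int
    duration_s: float | None = None  # altered-gravity exposure, seconds
    g_level: float | None = None  # peak g during the phase

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.label!r}; expected one of {GROUP_LABELS}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class CampaignDesign:
    """Groups, replicate counts and the comparison graph of one campaign.

    ``control_comparison`` is the hypergravity control contrast (baseline
    hypergravity vs hardware ground control) used to "control" the
    microgravity-sensitive set; ``microgravity_comparison`` is µg vs baseline.
    Which contrast plays which role is campaign data, not code.
    """

    campaign_id: str
    platform_id: str
    cell_line: str
    groups: tuple[GroupSpec, ...]
    comparisons: tuple[Comparison, ...]
    control_comparison: Comparison
    microgravity_comparison: Comparison

    def __post_init__(self) -> None:
        declared = {g.label for g in self.groups}
        if len(declared) != len(self.groups):
            raise ValueError("duplicate group labels in design")
        for num, den in self.comparisons + (
            self.control_comparison,
            self.microgravity_comparison,
        ):
            if num not in declared or den not in declared:
                raise ValueError(
                    f"comparison ({num}, {den}) references undeclared group"
                )

    @property
    def replicate_counts(self) -> dict[str, int]:
        return {g.label: g.n_replicates for g in self.groups}

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"group {label!r} not in design {self.campaign_id!r}")


def _pfc_groups(gc: int, if_: int, bl: int, mug: int) -> tuple[GroupSpec, ...]:
    return (
        GroupSpec(HW_1G_GC, gc),
        GroupSpec(IF_1G, if_),
        GroupSpec(BL_HYP_G, bl, duration_s=20.0, g_level=1.8),
        GroupSpec(MU_G, mug, duration_s=20.0, g_level=0.0),
    )


# Comparison graphs follow the published direct comparisons per campaign.
_PFC_COMPARISONS: tuple[Comparison, ...] = (
    (IF_1G, HW_1G_GC),
    (BL_HYP_G, IF_1G),
    (MU_G, BL_HYP_G),
    (BL_HYP_G, HW_1G_GC),
)

PFC_19_U937 = CampaignDesign(
    campaign_id="19th_DLR_PFC",
    platform_id="nimblegen_hg18",
    cell_line="U937",
    groups=_pfc_groups(gc=6, if_=8, bl=6, mug=8),
    comparisons=_PFC_COMPARISONS,
    control_comparison=(BL_HYP_G, HW_1G_GC),
    microgravity_comparison=(MU_G, BL_HYP_G),
)

PFC_23_JURKAT = CampaignDesign(
    campaign_id="23rd_DLR_PFC",
    platform_id="hta_2_0",
    cell_line="Jurkat",
    groups=_pfc_groups(gc=6, if_=6, bl=6, mug=6),
    comparisons=_PFC_COMPARISONS,
    control_comparison=(BL_HYP_G, HW_1G_GC),
    microgravity_comparison=(MU_G, BL_HYP_G),
)

TEXUS_49_U937 = CampaignDesign(
    campaign_id="TEXUS-49",
    platform_id="nimblegen_hg18",
    cell_line="U937",
    groups=(
        GroupSpec(HW_1G_GC, 6),
        GroupSpec(BL_HYP_G, 5, duration_s=75.0, g_level=13.5),
        GroupSpec(MU_G, 7, duration_s=300.0, g_level=0.0),
    ),
    comparisons=(
        (MU_G, BL_HYP_G),
        (BL_HYP_G, HW_1G_GC),
        (MU_G, HW_1G_GC),
    ),
    control_comparison=(BL_HYP_G, HW_1G_GC),
    microgravity_comparison=(MU_G, BL_HYP_G),
)

TEXUS_51_JURKAT = CampaignDesign(
    campaign_id="TEXUS-51",
    platform_id="hta_2_0",
    cell_line="Jurkat",
    groups=(
        GroupSpec(CC, 7),
        GroupSpec(HW_1G_GC, 7),
        GroupSpec(IF_1G, 9),
        GroupSpec(BL_HYP_G, 7, duration_s=75.0, g_level=12.6),
        GroupSpec(MU_G, 9, duration_s=300.0, g_level=0.0),
    ),
    comparisons=(
        (IF_1G, HW_1G_GC),
        (BL_HYP_G, IF_1G),
        (MU_G, BL_HYP_G),
        (MU_G, IF_1G),
        (BL_HYP_G, HW_1G_GC),
        (HW_1G_GC, CC),
    ),
    control_comparison=(BL_HYP_G, HW_1G_GC),
    microgravity_comparison=(MU_G, BL_HYP_G),
)

BUILTIN_DESIGNS: dict[str, CampaignDesign] = {
    d.campaign_id: d
    for d in (PFC_19_U937, PFC_23_JURKAT, TEXUS_49_U937, TEXUS_51_JURKAT)
}


def get_design(campaign_id: str) -> CampaignDesign:
    """Look up a built-in campaign design by id."""
    try:
        return BUILTIN_DESIGNS[campaign_id]
    except KeyError:
        raise KeyError(
            f"unknown campaign {campaign_id!r}; "
            f"built-ins: {sorted(BUILTIN_DESIGNS)}"
        ) from None
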