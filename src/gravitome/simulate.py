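"""Synthetic data generation with planted ground truth.

Emulates the statistical structure the pipeline assumes: RMA-style normalized
intensities that are Gaussian on the log2 scale around a per-probe-set
baseline, with group-level shifts planted according to a temporal response
archetype (null, continuous up/down, adaptation, late response).  Replicate
counts come from the campaign designs; everything is a pure function of
(configuration, seed).

Noise model defaults: baselines uniform on [4, 12] log2 units, within-group
standard deviation 0.1 log2 units — small enough that a planted |FC| = 1.25
(the weakest headline effect the pipeline must resolve) is detected with
power > 0.9 at n = 6 per group, which the test suite verifies by simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import BL_HYP_G, CampaignDesign, HW_1G_GC, MU_G
from .expression import ExpressionMatrix
from .panel import GenePanelEntry, ProbeSetAnnotation

PLANTED_CLASSES = ("null", "continuous_up", "continuous_down", "adaptation", "late")


@dataclass(frozen=True)
class NoiseModel:
    """Log2-scale Gaussian noise around uniform baselines."""

    sigma_log2: float = 0.1
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log2 <= 0:
            raise ValueError("sigma_log2 must be positive")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ValueError("baseline_range must be increasing")


@dataclass(frozen=True)
class PlantedTruth:
    """Planted response class and per-(campaign, group) log2 effects.

    ``classes`` maps probe-set id -> planted class; ``effects`` maps
    campaign id -> DataFrame (probe sets × groups) of log2 shifts added on
    top of the baseline.  Groups without a column get zero effect.
    """

    classes: pd.Series
    effects: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.classes.unique()) - set(PLANTED_CLASSES)
        if bad:
            raise ValueError(f"unknown planted classes {sorted(bad)}")
        for campaign, eff in self.effects.items():
            if not eff.index.equals(self.classes.index):
                raise ValueError(
                    f"effects for {campaign!r} do not cover the probe-set universe"
                )

    @property
    def probe_set_ids(self) -> pd.Index:
        return self.classes.index

    def effect_matrix(self, campaign_id: str, groups: list[str]) -> pd.DataFrame:
        eff = self.effects.get(campaign_id)
        if eff is None:
            eff = pd.DataFrame(index=self.classes.index)
        return eff.reindex(columns=groups, fill_value=0.0).fillna(0.0)

    @classmethod
    def all_null(cls, probe_set_ids) -> "PlantedTruth":
        idx = pd.Index(probe_set_ids, name="probe_set_id")
        return cls(classes=pd.Series("null", index=idx))

    def to_frame(self) -> pd.DataFrame:
        """Truth table: probe_set_id, planted_class, per-(campaign, group) effects."""
        out = pd.DataFrame({"planted_class": self.classes})
        for campaign, eff in self.effects.items():
            for g in eff.columns:
                out[f"effect_log2.{campaign}.{g}"] = eff[g]
        out.index.name = "probe_set_id"
        return out


def _campaign_rng(seed: int, campaign_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(campaign_id.encode())])
    )


def generate_campaign(
    design: CampaignDesign,
    truth: PlantedTruth,
    noise: NoiseModel,
) -> ExpressionMatrix:
    """Simulate one campaign's expression matrix on the linear scale.

    Each sample value is ``2 ** (baseline + group effect + N(0, sigma))``,
    with replicate counts taken from the design.  Bit-identical under an
    identical (design, truth, noise) triple.
    """
    rng = _campaign_rng(noise.seed, design.campaign_id)
    probes = truth.probe_set_ids
    n_probes = len(probes)
    if n_probes == 0:
        raise ValueError("truth covers no probe sets")
    lo, hi = noise.baseline_range
    baseline = rng.uniform(lo, hi, size=n_probes)
    effects = truth.effect_matrix(
        design.campaign_id, [g.label for g in design.groups]
    )
    columns: dict[str, np.ndarray] = {}
    group_labels: dict[str, str] = {}
    for g in design.groups:
        eff = effects[g.label].to_numpy()
        for i in range(g.n_replicates):
            sample_id = f"{design.campaign_id}.{g.label}.{i + 1}"
            log2_values = baseline + eff + rng.normal(0.0, noise.sigma_log2, n_probes)
            columns[sample_id] = np.exp2(log2_values)
            group_labels[sample_id] = g.label
    values = pd.DataFrame(columns, index=probes)
    return ExpressionMatrix(values, group_labels, campaign_id=design.campaign_id)


def plant_timecourse_truth(
    n_probe_sets: int | None = None,
    short_design: CampaignDesign = None,
    long_design: CampaignDesign = None,
    condition: str = "hypergravity",
    effect_log2: float = 1.0,
    class_fractions: dict[str, float] | None = None,
    seed: int = 0,
    probe_set_ids=None,
) -> PlantedTruth:
    """Plant temporal response archetypes across a short/long campaign pair.

    For ``condition='hypergravity'`` effects act on the baseline-hypergravity
    group relative to the ground control (the BL-vs-GC comparison); the µg
    group inherits the BL effect so the microgravity contrast stays null.  For
    ``condition='microgravity'`` effects act on the µg group relative to BL.
    Classes: ``continuous_up``/``continuous_down`` shift both campaigns,
    ``adaptation`` shifts only the short campaign (random sign), ``late`` only
    the long campaign (random sign), ``null`` neither.  Default class mix is
    equal quarters over {null, continuous, adaptation, late}, with the
    continuous quarter split evenly between up and down.
    """
    if condition not in ("hypergravity", "microgravity"):
        raise ValueError("condition must be 'hypergravity' or 'microgravity'")
    if class_fractions is None:
        class_fractions = {
            "null": 0.25,
            "continuous_up": 0.125,
            "continuous_down": 0.125,
            "adaptation": 0.25,
            "late": 0.25,
        }
    if abs(sum(class_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if probe_set_ids is not None:
        idx = pd.Index(list(probe_set_ids), name="probe_set_id")
        if n_probe_sets is not None and n_probe_sets != len(idx):
            raise ValueError("n_probe_sets disagrees with probe_set_ids")
        n_probe_sets = len(idx)
    elif n_probe_sets is None:
        raise ValueError("pass n_probe_sets or probe_set_ids")
    else:
        idx = pd.Index(
            [f"PS{i:05d}" for i in range(1, n_probe_sets + 1)], name="probe_set_id"
        )
    labels = list(class_fractions)
    classes = pd.Series(
        rng.choice(labels, size=n_probe_sets, p=[class_fractions[l] for l in labels]),
        index=idx,
    )
    signs = rng.choice([-1.0, 1.0], size=n_probe_sets)

    short_eff = np.zeros(n_probe_sets)
    long_eff = np.zeros(n_probe_sets)
    is_up = (classes == "continuous_up").to_numpy()
    is_down = (classes == "continuous_down").to_numpy()
    is_adapt = (classes == "adaptation").to_numpy()
    is_late = (classes == "late").to_numpy()
    short_eff[is_up] = effect_log2
    long_eff[is_up] = effect_log2
    short_eff[is_down] = -effect_log2
    long_eff[is_down] = -effect_log2
    short_eff[is_adapt] = signs[is_adapt] * effect_log2
    long_eff[is_late] = signs[is_late] * effect_log2

    def _effects(design: CampaignDesign, eff: np.ndarray) -> pd.DataFrame:
        cols = {}
        if condition == "hypergravity":
            cols[BL_HYP_G] = eff
            if any(g.label == MU_G for g in design.groups):
                cols[MU_G] = eff  # µg phase follows hyp-g; its contrast stays null
        else:
            cols[MU_G] = eff  # relative to BL, which stays at baseline
        return pd.DataFrame(cols, index=idx)

    return PlantedTruth(
        classes=classes,
        effects={
            short_design.campaign_id: _effects(short_design, short_eff),
            long_design.campaign_id: _effects(long_design, long_eff),
        },
    )


def expected_category(planted_class: str) -> str:
    """Temporal category implied by a planted class (the recovery oracle)."""
    return {
        "null": "no_response",
        "continuous_up": "continuous",
        "continuous_down": "continuous",
        "adaptation": "adaptation",
        "late": "late_response",
    }[planted_class]


def generate_panel_annotation(
    n_genes: int,
    mean_probes_per_gene: float = 2.1,
    discordance_rate: float = 0.0,
    n_missing_genes: int = 0,
    n_offpanel_probes: int = 0,
    platform_id: str = "synthetic_platform",
    seed: int = 0,
) -> tuple[list[GenePanelEntry], list[ProbeSetAnnotation], frozenset[str]]:
    """Synthesize a gene panel plus platform annotation with known ground truth.

    Probe sets per gene follow a truncated geometric distribution (minimum 1,
    mean ``mean_probes_per_gene``), reproducing multi-probe-set gene coverage.
    A ``discordance_rate`` fraction of rows get an obsolete array-era
    annotation differing from the (always valid) current one, so selection
    under the current-annotation rule equals the full ground-truth set
    regardless of the rate.  ``n_missing_genes`` panel genes receive no
    annotation rows; ``n_offpanel_probes`` extra rows point at genes outside
    the panel.  Returns ``(panel, annotations, true_selection)``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= discordance_rate <= 1.0:
        raise ValueError("discordance_rate must be in [0, 1]")
    if n_missing_genes >= n_genes:
        raise ValueError("n_missing_genes must be < n_genes")
    rng = np.random.default_rng(seed)
    panel = [
        GenePanelEntry(gene_symbol=f"GENE{i:04d}", entrez_id=10_000 + i)
        for i in range(1, n_genes + 1)
    ]
    missing = set(
        rng.choice([e.gene_symbol for e in panel], size=n_missing_genes, replace=False)
    )
    annotations: list[ProbeSetAnnotation] = []
    counter = 0
    p_geom = min(1.0, 1.0 / mean_probes_per_gene)
    for entry in panel:
        if entry.gene_symbol in missing:
            continue
        n_probes = int(rng.geometric(p_geom))
        for _ in range(n_probes):
            counter += 1
            pid = f"SYN{counter:05d}"
            discordant = rng.random() < discordance_rate
            annotations.append(
                ProbeSetAnnotation(
                    probe_set_id=pid,
                    platform_id=platform_id,
                    array_symbol=f"OBSOLETE{counter:04d}" if discordant else entry.gene_symbol,
                    array_entrez=90_000 + counter if discordant else entry.entrez_id,
                    current_symbol=entry.gene_symbol,
                    current_entrez=entry.entrez_id,
                )
            )
    true_selection = frozenset(a.probe_set_id for a in annotations)
    for _ in range(n_offpanel_probes):
        counter += 1
        annotations.append(
            ProbeSetAnnotation(
                probe_set_id=f"SYN{counter:05d}",
                platform_id=platform_id,
                array_symbol=f"OFFPANEL{counter:04d}",
                array_entrez=50_000 + counter,
                current_symbol=f"OFFPANEL{counter:04d}",
                current_entrez=50_000 + counter,
            )
        )
    return panel, annotations, true_selection


def generate_densitometry(
    groups: list[tuple[str, int, float]],
    sigma: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Western-blot lane table with planted normalized-OD means.

    ``groups`` holds ``(label, n_lanes, true_mean)`` triples; each lane gets a
    total-protein OD drawn uniformly from [0.8, 1.2] and a band OD such that
    band/total ~ Normal(true_mean, sigma), redrawn if negative.  Needs >= 3
    lanes and a positive mean per group.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    lane = 0
    for label, n, true_mean in groups:
        if n < 3:
            raise ValueError(f"group {label!r} needs >= 3 lanes, got {n}")
        if true_mean <= 0:
            raise ValueError(f"group {label!r} has non-positive planted mean")
        for _ in range(n):
            lane += 1
            total = rng.uniform(0.8, 1.2)
            normalized = rng.normal(true_mean, sigma)
            while normalized < 0:
                normalized = rng.normal(true_mean, sigma)
            rows.append(
                {
                    "lane_id": f"lane{lane:03d}",
                    "group": label,
                    "band_od": normalized * total,
                    "total_protein_od": total,
                }
            )
    return pd.DataFrame(rows)
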