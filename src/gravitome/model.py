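"""Model/Results interface tying the pipeline stages together.

:class:`CampaignModel` is built from an expression matrix and a campaign
design; ``fit()`` runs every comparison in the design's comparison graph and
returns :class:`CampaignResults`, which carries the per-comparison tables, the
gravisensitivity report and a printable summary.  Two fitted campaigns at
different exposure durations combine into :class:`TimecourseResults` via
:func:`classify_timecourse`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import diffexpr, sets, timecourse
from .designs import CampaignDesign, Comparison
from .expression import ExpressionMatrix


def _comp_name(comparison: Comparison) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


class CampaignModel:
    """Differential-expression model of one altered-gravity campaign.

    Parameters
    ----------
    matrix
        Linear-scale expression matrix whose samples carry the design's group
        labels.
    design
        The campaign design (groups, replicate counts, comparison graph,
        control and microgravity contrasts).
    """

    def __init__(self, matrix: ExpressionMatrix, design: CampaignDesign) -> None:
        declared = {g.label for g in design.groups}
        present = set(matrix.sample_groups.unique())
        missing = declared - present
        if missing:
            raise ValueError(
                f"matrix for {design.campaign_id!r} lacks samples for groups "
                f"{sorted(missing)}"
            )
        self.matrix = matrix
        self.design = design

    @classmethod
    def from_tsv(
        cls,
        matrix_path: str | Path,
        sample_sheet_path: str | Path,
        design: CampaignDesign,
        scale: str = "linear",
    ) -> "CampaignModel":
        matrix = ExpressionMatrix.from_tsv(
            matrix_path, sample_sheet_path, campaign_id=design.campaign_id, scale=scale
        )
        return cls(matrix, design)

    def fit(
        self,
        method: str = "ttest",
        alpha: float = diffexpr.DEFAULT_ALPHA,
        adjust: bool = False,
    ) -> "CampaignResults":
        """Run every comparison in the design and assemble the results."""
        tables = {
            comp: diffexpr.run_comparison(
                self.matrix, comp[0], comp[1], method=method, alpha=alpha, adjust=adjust
            )
            for comp in self.design.comparisons
        }
        return CampaignResults(self, tables, method=method, alpha=alpha)


class CampaignResults:
    """Fitted comparisons, gravisensitivity sets and summaries of one campaign."""

    def __init__(
        self,
        model: CampaignModel,
        tables: dict[Comparison, pd.DataFrame],
        method: str,
        alpha: float,
    ) -> None:
        self.model = model
        self.design = model.design
        self.tables = tables
        self.method = method
        self.alpha = alpha

    def comparison_table(self, comparison: Comparison) -> pd.DataFrame:
        try:
            return self.tables[tuple(comparison)]
        except KeyError:
            raise KeyError(
                f"comparison {comparison} was not fitted; available: "
                f"{list(self.tables)}"
            ) from None

    def call_set(self, comparison: Comparison) -> sets.CallSet:
        return sets.CallSet.from_comparison_table(
            tuple(comparison), self.comparison_table(comparison)
        )

    @property
    def sensitivity(self) -> sets.SensitivityReport:
        """Hypergravity/microgravity sensitivity sets of this campaign."""
        others = {
            _comp_name(c): self.call_set(c)
            for c in self.tables
            if c not in (self.design.control_comparison, self.design.microgravity_comparison)
        }
        return sets.build_sensitivity_report(
            self.design.campaign_id,
            mu_calls=self.call_set(self.design.microgravity_comparison),
            control_calls=self.call_set(self.design.control_comparison),
            other_calls=others,
        )

    def counts_frame(self) -> pd.DataFrame:
        """Up/down/total significant probe sets per comparison (printable)."""
        rows = {
            _comp_name(c): self.call_set(c).up_down_counts() for c in self.tables
        }
        return pd.DataFrame(rows).T[["up", "down", "total"]]

    def summary(self) -> str:
        """Human-readable campaign summary."""
        rep = self.sensitivity
        venn = sets.venn_counts(rep)
        lines = [
            f"Campaign {self.design.campaign_id} "
            f"({self.design.cell_line}, platform {self.design.platform_id})",
            f"method={self.method}, alpha={self.alpha}, "
            f"{len(self.model.matrix.probe_set_ids)} probe sets",
            "",
            "Differentially expressed probe sets per comparison:",
            self.counts_frame().to_string(),
            "",
            "Gravisensitivity sets:",
            f"  hypergravity-sensitive            {venn['hyper_sensitive']}",
            f"  microgravity-responsive           {venn['micro_responsive']}",
            f"  microgravity-sensitive (controlled) {venn['micro_sensitive_controlled']}",
            f"  double-sensitive same direction   {venn['double_same']}",
            f"  double-sensitive opposite         {venn['double_opposite']}",
        ]
        return "\n".join(lines)

    def to_dir(self, out_dir: str | Path) -> None:
        """Write comparison TSVs and the sensitivity JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for comp, table in self.tables.items():
            table.to_csv(out / f"comparison_{_comp_name(comp)}.tsv", sep="\t")
        (out / "sensitivity.json").write_text(
            json.dumps(sets.report_to_dict(self.sensitivity), indent=2, sort_keys=True)
        )
        (out / "summary.txt").write_text(self.summary() + "\n")


class TimecourseResults:
    """Paired short/long-exposure classification and category shares."""

    def __init__(
        self,
        paired: pd.DataFrame,
        unmatched: dict[str, list[str]],
        short_id: str,
        long_id: str,
        condition: str,
    ) -> None:
        self.paired = paired
        self.unmatched = unmatched
        self.short_id = short_id
        self.long_id = long_id
        self.condition = condition

    def shares(self) -> timecourse.CategoryShares:
        return timecourse.category_shares(self.paired)

    def summary(self) -> str:
        shares = self.shares()
        lines = [
            f"Temporal classification ({self.condition}): "
            f"{self.short_id} (short) vs {self.long_id} (long), "
            f"{shares.total} units",
        ]
        for cat in timecourse.CATEGORIES:
            lines.append(
                f"  {cat:<14} {shares.counts[cat]:>5}  ({shares.percent[cat]:.1f}%)"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.paired.to_csv(path, sep="\t")


def classify_timecourse(
    short_results: CampaignResults,
    long_results: CampaignResults,
    condition: str = "hypergravity",
    key: str = "probe_set",
    per_gene: dict[str, list[str]] | None = None,
) -> TimecourseResults:
    """Classify temporal response across a short- and a long-exposure campaign.

    For ``condition='hypergravity'`` the relevant contrast in each campaign is
    the control comparison (baseline hypergravity vs ground control); for
    ``'microgravity'`` it is µg vs baseline.
    """
    if condition == "hypergravity":
        pick = lambda r: r.design.control_comparison  # noqa: E731
    elif condition == "microgravity":
        pick = lambda r: r.design.microgravity_comparison  # noqa: E731
    else:
        raise ValueError("condition must be 'hypergravity' or 'microgravity'")
    short_calls = short_results.comparison_table(pick(short_results))
    long_calls = long_results.comparison_table(pick(long_results))
    paired, unmatched = timecourse.pair_exposures(
        short_calls[["direction", "significant"]],
        long_calls[["direction", "significant"]],
        key=key,
        per_gene=per_gene,
    )
    return TimecourseResults(
        paired,
        unmatched,
        short_id=short_results.design.campaign_id,
        long_id=long_results.design.campaign_id,
        condition=condition,
    )
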