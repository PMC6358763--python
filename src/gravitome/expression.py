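"""Expression matrix container.

Holds RMA-style normalized intensities for probe sets × samples.  Values are
kept on the *linear* scale internally; matrices recorded on the log2 scale are
back-transformed on ingest (2**x), matching the convention that fold changes
are ratios of linear group means while significance testing happens on log2
values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ExpressionMatrix:
    """Normalized expression values with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe-set id, one column per sample.  Strictly
        positive when ``scale='linear'``.
    sample_groups
        Mapping (or Series) sample id -> group label covering every column.
    campaign_id
        Identifier of the campaign the samples belong to.
    scale
        ``'linear'`` (default) or ``'log2'``; log2 input is converted to
        linear immediately.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_groups: dict[str, str] | pd.Series,
        campaign_id: str,
        scale: str = "linear",
    ) -> None:
        if scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
        values = values.astype(float)
        if scale == "log2":
            values = np.exp2(values)
        if not np.all(np.isfinite(values.to_numpy())):
            raise ValueError("expression values must be finite")
        if (values.to_numpy() <= 0).any():
            raise ValueError("linear expression values must be strictly positive")
        groups = pd.Series(dict(sample_groups) if not isinstance(sample_groups, pd.Series) else sample_groups)
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe_set_id rows: {dup}")
        self.values = values
        self.sample_groups = groups.reindex(values.columns)
        self.campaign_id = campaign_id

    # -- introspection -----------------------------------------------------

    @property
    def probe_set_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        return sorted(self.sample_groups.unique())

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.sample_groups):
            raise KeyError(
                f"group {group!r} not present in campaign "
                f"{self.campaign_id!r}; available: {self.groups}"
            )
        return list(self.sample_groups.index[self.sample_groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        """Linear values for all samples of one group (probe sets × samples)."""
        return self.values[self.samples_in_group(group)]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(
        cls,
        matrix_path: str | Path,
        sample_sheet_path: str | Path,
        campaign_id: str | None = None,
        scale: str = "linear",
    ) -> "ExpressionMatrix":
        """Load from a matrix TSV (first column ``probe_set_id``) and a sample
        sheet TSV with columns ``sample_id``, ``campaign_id``, ``group``."""
        mat = pd.read_csv(matrix_path, sep="\t", index_col="probe_set_id")
        sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
        for col in ("sample_id", "campaign_id", "group"):
            if col not in sheet.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if campaign_id is None:
            campaigns = sheet["campaign_id"].unique()
            if len(campaigns) != 1:
                raise ValueError(
                    "sample sheet covers multiple campaigns; pass campaign_id"
                )
            campaign_id = campaigns[0]
        sheet = sheet[sheet["campaign_id"] == campaign_id]
        groups = sheet.set_index("sample_id")["group"]
        mat = mat[list(groups.index)]
        return cls(mat, groups, campaign_id=campaign_id, scale=scale)

    def to_tsv(self, matrix_path: str | Path, sample_sheet_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_set_id")
        sheet = pd.DataFrame(
            {
                "sample_id": self.sample_groups.index,
                "campaign_id": self.campaign_id,
                "group": self.sample_groups.to_numpy(),
            }
        )
        sheet.to_csv(sample_sheet_path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover
        n_p, n_s = self.values.shape
        return (
            f"<ExpressionMatrix {self.campaign_id}: {n_p} probe sets × "
            f"{n_s} samples, groups={self.groups}>"
        )
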