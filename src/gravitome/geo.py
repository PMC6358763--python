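"""Optional ingestion of GEO series-matrix files (real deposited data).

The deposited campaign data live in the Gene Expression Omnibus (Jurkat:
GSE94256, U937: GSE101309).  This hook parses an already-downloaded
series-matrix text file into an expression table; no network access is ever
performed and nothing in the tested pipeline depends on this module.
Series-matrix values are typically log2 scale, so pass ``scale='log2'`` when
building an :class:`~gravitome.expression.ExpressionMatrix` from them.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the matrix block of a GEO series-matrix file.

    Returns a DataFrame indexed by probe-set id with one column per GSM
    sample.  Handles plain-text and gzip files.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    lines: list[str] = []
    in_table = False
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table:
                lines.append(line)
    if not lines:
        raise ValueError(f"no series-matrix table block found in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t")
    df = df.rename(columns={df.columns[0]: "probe_set_id"})
    df["probe_set_id"] = df["probe_set_id"].astype(str).str.strip('"')
    return df.set_index("probe_set_id")
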