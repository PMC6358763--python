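"""Temporal response classification across short and long exposures.

Each campaign pair probes the same gravity condition at two durations — e.g.
20 s of 1.8 g on a parabolic flight versus 75 s of up to 13.5 g on a rocket
launch.  Per probe set, the pair of (direction, significant) calls at the two
exposures falls into exactly one of four categories:

* ``no_response``   — significant at neither exposure;
* ``continuous``    — significant at both, same direction;
* ``adaptation``    — an initial response that disappears or reverses at the
  longer exposure (short significant, long not significant or opposite);
* ``late_response`` — significant only at the longer exposure.

Category shares are reported as half-up one-decimal percentages (plus an
integer-rounded display variant).  Gene-level consensus across platforms calls
a gene stably regulated when every contributing dataset shows a significant,
same-signed response.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

CATEGORIES = ("no_response", "continuous", "adaptation", "late_response")

Call = tuple[str, bool]  # (direction in {up, down, none}, significant)


def classify_temporal(short_call: Call, long_call: Call) -> str:
    """Assign the four-way temporal category from the two exposure calls.

    Total over all direction × significance pairs; a ``none`` direction can
    only occur with ``significant=False`` in well-formed calls, but the
    function is defined for every input pair.
    """
    short_dir, short_sig = short_call
    long_dir, long_sig = long_call
    if not short_sig and not long_sig:
        return "no_response"
    if short_sig and long_sig and short_dir == long_dir:
        return "continuous"
    if short_sig:
        # long not significant, or significant in another direction
        return "adaptation"
    return "late_response"


def _percent(count: int, total: int, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(pct)


@dataclass(frozen=True)
class CategoryShares:
    """Counts and half-up one-decimal percentages per temporal category."""

    counts: dict[str, int]
    total: int
    percent: dict[str, float]
    percent_integer: dict[str, int]  # display variant, half-up to 0 decimals

    def as_dict(self) -> dict:
        return {
            cat: {
                "count": self.counts[cat],
                "percent": self.percent[cat],
                "percent_integer": self.percent_integer[cat],
            }
            for cat in CATEGORIES
        }


def category_shares(calls) -> CategoryShares:
    """Tally temporal categories and compute percentage shares.

    ``calls`` is an iterable of category strings, of (short_call, long_call)
    pairs, or a DataFrame with a ``category`` column.  Raises on empty input.
    """
    if isinstance(calls, pd.DataFrame):
        cats = list(calls["category"])
    else:
        cats = [
            c if isinstance(c, str) else classify_temporal(*c) for c in calls
        ]
    if not cats:
        raise ValueError("cannot compute category shares of an empty call list")
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    counts = {cat: cats.count(cat) for cat in CATEGORIES}
    total = len(cats)
    return CategoryShares(
        counts=counts,
        total=total,
        percent={c: _percent(n, total, 1) for c, n in counts.items()},
        percent_integer={c: int(_percent(n, total, 0)) for c, n in counts.items()},
    )


def shares_from_counts(counts: dict[str, int]) -> CategoryShares:
    """Category shares directly from per-category counts (e.g. published totals)."""
    return category_shares(
        [cat for cat, n in counts.items() for _ in range(n)]
    )


def pair_exposures(
    short_calls: pd.DataFrame,
    long_calls: pd.DataFrame,
    key: str = "probe_set",
    per_gene: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Pair short- and long-exposure call tables and classify each unit.

    Both inputs are indexed by probe-set id with columns ``direction`` and
    ``significant``.  With ``key='probe_set'`` units are the shared probe-set
    ids; with ``key='gene'`` each input is first collapsed through the
    ``per_gene`` mapping (gene -> probe-set ids) and units are genes, a probe
    set counting toward a gene's call only through unanimity (see
    :func:`gene_call`).  Returns the paired/classified table and a dict of
    unmatched unit ids per side; an empty intersection is an error.
    """
    if key == "gene":
        if per_gene is None:
            raise ValueError("key='gene' requires a per_gene mapping")
        short_calls = _collapse_to_genes(short_calls, per_gene)
        long_calls = _collapse_to_genes(long_calls, per_gene)
    elif key != "probe_set":
        raise ValueError("key must be 'probe_set' or 'gene'")
    shared = short_calls.index.intersection(long_calls.index)
    if len(shared) == 0:
        raise ValueError("no shared units between the short and long datasets")
    unmatched = {
        "short_only": sorted(short_calls.index.difference(long_calls.index)),
        "long_only": sorted(long_calls.index.difference(short_calls.index)),
    }
    s = short_calls.loc[shared]
    l = long_calls.loc[shared]
    paired = pd.DataFrame(
        {
            "short_direction": s["direction"],
            "short_significant": s["significant"].astype(bool),
            "long_direction": l["direction"],
            "long_significant": l["significant"].astype(bool),
        },
        index=shared,
    )
    paired["category"] = [
        classify_temporal(
            (row.short_direction, row.short_significant),
            (row.long_direction, row.long_significant),
        )
        for row in paired.itertuples()
    ]
    paired.index.name = "unit_id"
    return paired, unmatched


def gene_call(probe_calls: pd.DataFrame) -> tuple[str, bool]:
    """Collapse a gene's probe-set calls to a single (direction, significant).

    The gene counts as responsive only when at least one probe set is
    significant and ALL significant probe sets agree in direction (the
    conservative unanimity reading of a stable gene-level response).
    """
    sig = probe_calls[probe_calls["significant"]]
    if len(sig) == 0:
        return ("none", False)
    directions = set(sig["direction"])
    if len(directions) == 1 and "none" not in directions:
        return (directions.pop(), True)
    return ("none", False)


def _collapse_to_genes(
    calls: pd.DataFrame, per_gene: dict[str, list[str]]
) -> pd.DataFrame:
    rows = {}
    for gene, probes in per_gene.items():
        present = [p for p in probes if p in calls.index]
        if not present:
            continue
        d, s = gene_call(calls.loc[present])
        rows[gene] = {"direction": d, "significant": s}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=["direction", "significant"]
    )


@dataclass(frozen=True)
class GeneConsensus:
    """Cross-dataset consensus for one gene."""

    gene_symbol: str
    entrez_id: int
    fold_changes: dict[str, list[float]]  # dataset -> signed FCs of its probe sets
    consensus: str  # stable_up | stable_down | none


def interplatform_consensus(datasets: dict[str, pd.DataFrame]) -> list[GeneConsensus]:
    """Consensus regulation of each gene across >=2 independent datasets.

    Each dataset is a DataFrame with columns ``gene_symbol``, ``entrez_id``,
    ``fold_change``, ``significant`` (one row per probe set).  A gene is
    ``stable_up`` when, in EVERY dataset containing it, at least one of its
    probe sets is significant and all significant probe sets have positive
    fold change; ``stable_down`` analogously; anything else is ``none``.
    Genes are matched on (symbol, Entrez id).
    """
    if len(datasets) < 2:
        raise ValueError("interplatform consensus requires at least 2 datasets")
    keys: set[tuple[str, int]] = set()
    for df in datasets.values():
        keys |= {
            (str(r.gene_symbol), int(r.entrez_id)) for r in df.itertuples()
        }
    out = []
    for symbol, entrez in sorted(keys):
        per_dataset_sign: list[int] = []
        fcs: dict[str, list[float]] = {}
        covering = 0
        for name, df in datasets.items():
            sub = df[(df["gene_symbol"] == symbol) & (df["entrez_id"] == entrez)]
            if len(sub) == 0:
                continue
            covering += 1
            fcs[name] = [float(v) for v in sub["fold_change"]]
            sig = sub[sub["significant"]]
            signs = {1 if fc > 0 else -1 for fc in sig["fold_change"]}
            if len(sig) >= 1 and len(signs) == 1:
                per_dataset_sign.append(signs.pop())
            else:
                per_dataset_sign.append(0)
        if covering == len(datasets) and per_dataset_sign and all(
            s == 1 for s in per_dataset_sign
        ):
            consensus = "stable_up"
        elif covering == len(datasets) and per_dataset_sign and all(
            s == -1 for s in per_dataset_sign
        ):
            consensus = "stable_down"
        else:
            consensus = "none"
        out.append(GeneConsensus(symbol, entrez, fcs, consensus))
    return out
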