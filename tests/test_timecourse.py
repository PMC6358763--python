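"""Temporal response classification, category shares and gene consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravitome import published
from gravitome.timecourse import (
    CATEGORIES,
    category_shares,
    classify_temporal,
    gene_call,
    interplatform_consensus,
    pair_exposures,
    shares_from_counts,
)

DIRECTIONS = ("up", "down", "none")


def brute_force_category(short_dir, short_sig, long_dir, long_sig):
    """Independent enumeration of the classification rules."""
    if not short_sig and not long_sig:
        return "no_response"
    if short_sig and long_sig and short_dir == long_dir:
        return "continuous"
    if short_sig and (not long_sig or long_dir != short_dir):
        return "adaptation"
    return "late_response"


class TestClassifier:
    @pytest.mark.parametrize(
        "short, long, expected",
        [
            (("down", True), ("down", True), "continuous"),
            (("up", True), ("up", False), "adaptation"),
            (("up", True), ("down", True), "adaptation"),
            (("none", False), ("up", True), "late_response"),
            (("none", False), ("none", False), "no_response"),
            (("up", False), ("down", False), "no_response"),
        ],
    )
    def test_rule_examples(self, short, long, expected):
        assert classify_temporal(short, long) == expected

    def test_agrees_with_exhaustive_decision_table(self):
        """All 3x3x2x2 direction/significance combinations match the oracle."""
        for sd, ld, ss, ls in itertools.product(
            DIRECTIONS, DIRECTIONS, (False, True), (False, True)
        ):
            assert classify_temporal((sd, ss), (ld, ls)) == brute_force_category(
                sd, ss, ld, ls
            ), (sd, ss, ld, ls)


class TestCategoryShares:
    def test_published_jurkat_hypergravity_percentages(self):
        shares = shares_from_counts(
            {"no_response": 43, "continuous": 21, "adaptation": 49, "late_response": 71}
        )
        assert shares.total == 184
        assert shares.percent == {
            "no_response": 23.4,
            "continuous": 11.4,
            "adaptation": 26.6,
            "late_response": 38.6,
        }

    def test_published_u937_microgravity_percentages(self):
        shares = shares_from_counts(
            {"no_response": 319, "continuous": 1, "adaptation": 20, "late_response": 35}
        )
        assert shares.total == 375
        assert shares.percent == {
            "no_response": 85.1,
            "continuous": 0.3,
            "adaptation": 5.3,
            "late_response": 9.3,
        }

    def test_integer_display_rounding(self):
        # 165/184 = 89.67% -> one-decimal 89.7, integer display 90
        shares = shares_from_counts(
            {"no_response": 165, "continuous": 0, "adaptation": 10, "late_response": 9}
        )
        assert shares.percent["no_response"] == 89.7
        assert shares.percent_integer["no_response"] == 90

    def test_half_up_rounding_at_the_boundary(self):
        # 1/8 = 12.5% rounds up to 13 under half-up (banker's would give 12)
        shares = shares_from_counts(
            {"no_response": 1, "continuous": 7, "adaptation": 0, "late_response": 0}
        )
        assert shares.percent_integer["no_response"] == 13

    def test_single_call_is_100_percent(self):
        shares = category_shares(["adaptation"])
        assert shares.percent["adaptation"] == 100.0
        assert shares.counts["adaptation"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            category_shares([])

    @given(
        st.lists(st.sampled_from(CATEGORIES), min_size=1, max_size=300)
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, cats):
        shares = category_shares(cats)
        assert sum(shares.counts.values()) == shares.total == len(cats)
        # percents of a partition sum to ~100 (rounding slack < 0.2 per term)
        assert abs(sum(shares.percent.values()) - 100.0) <= 0.2 * len(CATEGORIES)


def _frame(calls):
    return pd.DataFrame(
        {"direction": [d for d, _ in calls.values()],
         "significant": [s for _, s in calls.values()]},
        index=pd.Index(calls.keys(), name="probe_set_id"),
    )


class TestPairing:
    def test_shared_universe_pairs_every_probe_set(self):
        n = 184
        short = _frame({f"P{i}": ("up", i % 3 == 0) for i in range(n)})
        long = _frame({f"P{i}": ("down", i % 5 == 0) for i in range(n)})
        paired, unmatched = pair_exposures(short, long)
        assert len(paired) == n
        assert unmatched == {"short_only": [], "long_only": []}
        assert set(paired["category"]).issubset(set(CATEGORIES))

    def test_unmatched_units_reported_not_dropped_silently(self):
        short = _frame({"A": ("up", True), "B": ("up", True)})
        long = _frame({"A": ("up", True), "C": ("down", True)})
        paired, unmatched = pair_exposures(short, long)
        assert list(paired.index) == ["A"]
        assert unmatched == {"short_only": ["B"], "long_only": ["C"]}

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no shared units"):
            pair_exposures(_frame({"A": ("up", True)}), _frame({"B": ("up", True)}))

    def test_gene_keyed_pairing_reports_missing_gene(self):
        per_gene = {"G1": ["P1", "P2"], "G2": ["P3"]}
        short = _frame({"P1": ("up", True), "P2": ("up", True), "P3": ("down", True)})
        long = _frame({"P1": ("up", True), "P2": ("up", False)})  # platform lacks G2
        paired, unmatched = pair_exposures(short, long, key="gene", per_gene=per_gene)
        assert list(paired.index) == ["G1"]
        assert unmatched["short_only"] == ["G2"]

    def test_gene_call_requires_unanimity_of_significant_probes(self):
        agree = _frame({"P1": ("up", True), "P2": ("up", True), "P3": ("down", False)})
        assert gene_call(agree) == ("up", True)
        conflict = _frame({"P1": ("up", True), "P2": ("down", True)})
        assert gene_call(conflict) == ("none", False)
        silent = _frame({"P1": ("up", False)})
        assert gene_call(silent) == ("none", False)


def _consensus_df(rows):
    return pd.DataFrame(
        rows, columns=["gene_symbol", "entrez_id", "fold_change", "significant"]
    )


class TestConsensus:
    def test_pdk1_style_gene_is_stable_up(self):
        """All-significant positive fold changes across both cell-line datasets."""
        jurkat = _consensus_df([("PDK1", 5163, 1.07, True), ("PDK1", 5163, 1.17, True)])
        u937 = _consensus_df(
            [("PDK1", 5163, 1.30, True), ("PDK1", 5163, 1.48, True),
             ("PDK1", 5163, 1.23, True), ("PDK1", 5163, 1.62, True)]
        )
        (res,) = interplatform_consensus({"jurkat": jurkat, "u937": u937})
        assert res.gene_symbol == "PDK1"
        assert res.consensus == "stable_up"

    def test_conflicting_directions_give_none(self):
        a = _consensus_df([("G", 1, 1.5, True)])
        b = _consensus_df([("G", 1, -1.5, True)])
        (res,) = interplatform_consensus({"a": a, "b": b})
        assert res.consensus == "none"

    def test_gene_absent_from_one_dataset_gives_none(self):
        a = _consensus_df([("G", 1, 1.5, True), ("H", 2, 1.2, True)])
        b = _consensus_df([("G", 1, 1.5, True)])
        by_gene = {c.gene_symbol: c for c in interplatform_consensus({"a": a, "b": b})}
        assert by_gene["G"].consensus == "stable_up"
        assert by_gene["H"].consensus == "none"

    def test_requires_two_datasets(self):
        with pytest.raises(ValueError, match="at least 2"):
            interplatform_consensus({"a": _consensus_df([("G", 1, 1.5, True)])})

    def test_planted_all_dataset_up_genes_recovered_exactly(self, rng):
        """Exactly the 3 planted always-up genes come out stable_up."""
        planted_up = {"UP1", "UP2", "UP3"}
        genes = sorted(planted_up | {f"N{i}" for i in range(20)})
        entrez = {g: i + 1 for i, g in enumerate(genes)}
        datasets = {}
        for ds in ("d1", "d2", "d3"):
            rows = []
            for g in genes:
                if g in planted_up:
                    rows.append((g, entrez[g], float(rng.uniform(1.1, 2.0)), True))
                else:
                    fc = float(rng.choice([-1, 1]) * rng.uniform(1.0, 2.0))
                    sig = bool(rng.random() < 0.4)
                    # avoid accidental all-up unanimity for null genes
                    rows.append((g, entrez[g], fc, sig and fc < 0))
            datasets[ds] = _consensus_df(rows)
        stable = {
            c.gene_symbol
            for c in interplatform_consensus(datasets)
            if c.consensus == "stable_up"
        }
        assert stable == planted_up


class TestPublishedContinuousTables:
    def test_jurkat_table_yields_21_continuous_probe_sets(self):
        table = published.jurkat_continuous_hypergravity()
        assert len(table) == 21
        cats = [
            classify_temporal(
                ("up" if r.fc_short > 0 else "down", True),
                ("up" if r.fc_long > 0 else "down", True),
            )
            for r in table.itertuples()
        ]
        assert cats == ["continuous"] * 21

    def test_u937_hypergravity_rows_all_continuous(self):
        table = published.u937_continuous_hypergravity()
        assert len(table) == 4
        assert table["gene_symbol"].nunique() == 3
        for r in table.itertuples():
            assert np.sign(r.fc_short) == np.sign(r.fc_long) == 1

    def test_u937_microgravity_single_row_continuous_down(self):
        (row,) = published.u937_continuous_microgravity().itertuples()
        assert row.gene_symbol == "IL1B"
        assert classify_temporal(("down", True), ("down", True)) == "continuous"
        assert row.fc_short == -1.65 and row.fc_long == -1.43
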