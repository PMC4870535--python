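"""COG cross-tabs, overlap regions and HOV rollups."""

import numpy as np
import pandas as pd
import pytest

from ticnet import (
    AnnotationMap,
    Comparison,
    classify_tiers,
    cog_crosstab,
    hov_rollup,
    overlap_counts,
)
from ticnet.diffstats import ComparisonResult
from ticnet.errors import ConfigError, ValidationError


def make_result(label, znet_by_protein):
    a, b = label.split("_vs_")
    frame = pd.DataFrame(
        {"znet": pd.Series(znet_by_protein)},
    )
    frame.index.name = "protein_id"
    return classify_tiers(ComparisonResult(frame, Comparison(a, b)))


def make_ann(cog_by_protein, **other):
    frame = pd.DataFrame({"cog": pd.Series(cog_by_protein, dtype=str)})
    for col, mapping in other.items():
        frame[col] = pd.Series(mapping, dtype=str)
    frame = frame.fillna("")
    frame.index.name = "protein_id"
    return AnnotationMap(frame)


class TestCogCrosstab:
    def test_counts_up_down_per_letter(self):
        res = make_result("A_vs_B", {"p1": 2.0, "p2": 1.7, "p3": -1.9})
        ann = make_ann({"p1": "C", "p2": "C", "p3": "C"})
        tab = cog_crosstab([res], ann)
        assert tab.loc["C", ("A_vs_B", "up")] == 2
        assert tab.loc["C", ("A_vs_B", "down")] == 1

    def test_unannotated_protein_lands_in_x(self):
        res = make_result("A_vs_B", {"p1": 2.0})
        ann = make_ann({"p1": ""})
        tab = cog_crosstab([res], ann)
        assert tab.loc["X", ("A_vs_B", "up")] == 1

    def test_multi_letter_counts_once_per_letter(self):
        res = make_result("A_vs_B", {"p1": 2.0})
        ann = make_ann({"p1": "C;E"})
        tab = cog_crosstab([res], ann)
        assert tab.loc["C", ("A_vs_B", "up")] == 1
        assert tab.loc["E", ("A_vs_B", "up")] == 1
        assert tab.loc["Total", ("A_vs_B", "up")] == 2

    def test_malformed_cog_letter_rejected(self):
        with pytest.raises(ValidationError, match="p1"):
            make_ann({"p1": "c1"})

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(8)
        proteins = [f"p{i}" for i in range(50)]
        znet = dict(zip(proteins, rng.normal(0, 1.5, 50)))
        letters = ["C", "E", "I", "O", ""]
        cogs = {p: rng.choice(letters) for p in proteins}
        res = make_result("A_vs_B", znet)
        tab = cog_crosstab([res], make_ann(cogs))
        # exhaustive nested-loop oracle
        for letter in set(tab.index) - {"Total"}:
            for direction, sign in (("up", 1), ("down", -1)):
                expected = sum(
                    1
                    for p in proteins
                    if abs(znet[p]) > 1.65
                    and np.sign(znet[p]) == sign
                    and (cogs[p] or "X") == letter
                )
                assert tab.loc[letter, ("A_vs_B", direction)] == expected

    def test_totals_match_significant_counts_single_letter(self):
        rng = np.random.default_rng(9)
        proteins = [f"p{i}" for i in range(80)]
        znet = dict(zip(proteins, rng.normal(0, 1.5, 80)))
        cogs = {p: rng.choice(["C", "E", "P"]) for p in proteins}
        res = make_result("A_vs_B", znet)
        tab = cog_crosstab([res], make_ann(cogs))
        n_sig_up = sum(1 for v in znet.values() if v > 1.65)
        n_sig_down = sum(1 for v in znet.values() if v < -1.65)
        assert tab.loc["Total", ("A_vs_B", "up")] == n_sig_up
        assert tab.loc["Total", ("A_vs_B", "down")] == n_sig_down

    def test_row_order_invariance(self):
        rng = np.random.default_rng(10)
        proteins = [f"p{i}" for i in range(30)]
        znet = dict(zip(proteins, rng.normal(0, 1.5, 30)))
        cogs = {p: rng.choice(["C", "E"]) for p in proteins}
        ann = make_ann(cogs)
        res1 = make_result("A_vs_B", znet)
        shuffled = dict(reversed(list(znet.items())))
        res2 = make_result("A_vs_B", shuffled)
        pd.testing.assert_frame_equal(
            cog_crosstab([res1], ann), cog_crosstab([res2], ann)
        )


def results_from_sets(sets, universe):
    """Three comparisons whose significant (up) sets are given."""
    labels = ["A_vs_B", "B_vs_C", "A_vs_C"]
    out = []
    for label, sig in zip(labels, sets):
        znet = {p: (2.0 if p in sig else 0.1) for p in universe}
        out.append(make_result(label, znet))
    return out


class TestOverlapCounts:
    def test_set_algebra_example(self):
        universe = ["A", "B", "C"]
        res = results_from_sets([{"A", "B"}, {"B", "C"}, {"C"}], universe)
        tab = overlap_counts(res)
        assert tab.loc["A_vs_B", "n"] == 1          # protein A only in set 1
        assert tab.loc["A_vs_B&B_vs_C", "n"] == 1   # protein B in sets 1&2
        assert tab.loc["B_vs_C&A_vs_C", "n"] == 1   # protein C in sets 2&3
        assert tab["n"].sum() == 3

    def test_identical_sets_fill_triple_region(self):
        universe = [f"p{i}" for i in range(10)]
        sig = set(universe[:6])
        res = results_from_sets([sig, sig, sig], universe)
        tab = overlap_counts(res)
        assert tab.loc["A_vs_B&B_vs_C&A_vs_C", "n"] == 6
        assert tab.drop("A_vs_B&B_vs_C&A_vs_C")["n"].eq(0).all()

    def test_matches_bitmask_oracle(self):
        rng = np.random.default_rng(11)
        universe = [f"p{i}" for i in range(60)]
        sets = [set(rng.choice(universe, 20, replace=False)) for _ in range(3)]
        res = results_from_sets(sets, universe)
        tab = overlap_counts(res)
        # brute-force membership-vector tally
        from collections import Counter

        masks = Counter()
        for p in set().union(*sets):
            masks[tuple(p in s for s in sets)] += 1
        labels = ["A_vs_B", "B_vs_C", "A_vs_C"]
        for mask, count in masks.items():
            region = "&".join(l for l, m in zip(labels, mask) if m)
            assert tab.loc[region, "n"] == count
        assert tab["n"].sum() == len(set().union(*sets))

    def test_direction_breakdown(self):
        universe = ["a", "b"]
        labels = ["A_vs_B", "B_vs_C", "A_vs_C"]
        res = [
            make_result(labels[0], {"a": 2.0, "b": -2.0}),
            make_result(labels[1], {"a": 0.0, "b": 0.0}),
            make_result(labels[2], {"a": 0.0, "b": 0.0}),
        ]
        tab = overlap_counts(res)
        assert tab.loc["A_vs_B", "A_vs_B_up"] == 1
        assert tab.loc["A_vs_B", "A_vs_B_down"] == 1

    def test_wrong_comparison_count_and_duplicates_rejected(self):
        universe = ["a"]
        res = results_from_sets([{"a"}, {"a"}, {"a"}], universe)
        with pytest.raises(ConfigError):
            overlap_counts(res[:2])
        res[1].comparison = res[0].comparison
        with pytest.raises(ConfigError):
            overlap_counts(res)


class TestHovRollup:
    def test_single_protein_single_category(self):
        res = make_result("A_vs_B", {"p1": 1.2})
        ann = make_ann({"p1": "C"})
        tab = hov_rollup(res, ann, "COG")
        assert tab.loc["C", "mean_znet"] == pytest.approx(1.2)
        assert tab.loc["C", "n_members"] == 1

    def test_multi_membership_appears_in_both_rows(self):
        res = make_result("A_vs_B", {"p1": 2.0})
        ann = make_ann({"p1": ""}, kegg={"p1": "M00001;M00002"})
        tab = hov_rollup(res, ann, "KEGG")
        assert set(tab.index) == {"M00001", "M00002"}
        assert (tab["n_up"] == 1).all()

    def test_grouped_means_match_recomputation(self):
        rng = np.random.default_rng(12)
        proteins = [f"p{i}" for i in range(20)]
        znet = dict(zip(proteins, rng.normal(0, 1.5, 20)))
        cogs = {p: rng.choice(["C", "E", "I"]) for p in proteins}
        tab = hov_rollup(make_result("A_vs_B", znet), make_ann(cogs), "COG")
        for letter in tab.index:
            members = [p for p in proteins if cogs[p] == letter]
            assert tab.loc[letter, "mean_znet"] == pytest.approx(
                np.mean([znet[p] for p in members])
            )
            assert tab.loc[letter, "n_members"] == len(members)

    def test_unknown_hov_rejected(self):
        res = make_result("A_vs_B", {"p1": 1.0})
        with pytest.raises(ConfigError, match="HOV"):
            hov_rollup(res, make_ann({"p1": "C"}), "PFAM")
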