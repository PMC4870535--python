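"""System/per-protein S/N statistics and Monte-Carlo FDR calibration."""

import numpy as np
import pandas as pd
import pytest

from ticnet import (
    Comparison,
    SyntheticConfig,
    apply_sn_filter,
    classify_tiers,
    compute_ratio_populations,
    generate_dataset,
    merge_znet,
    monte_carlo_fdr,
    protein_sn,
    system_sn,
)
from tests.test_diffstats import make_pops
from ticnet.errors import AlignmentError, DegeneratePopulationError


class TestSystemSn:
    def test_ratio_of_mean_sds(self):
        rng = np.random.default_rng(0)
        pops = make_pops(
            rng.normal(0, 5, 2000), rng.normal(0, 5, 2000),
            rng.normal(0, 1, 2000), rng.normal(0, 1, 2000),
        )
        assert system_sn(pops) == pytest.approx(5.0, rel=0.05)

    def test_identical_populations_give_one(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 2, 500)
        pops = make_pops(z, z[::-1], z, z[::-1])
        assert system_sn(pops) == pytest.approx(1.0)

    def test_matches_independent_sd_recomputation(self):
        cfg = SyntheticConfig(
            n_proteins=2000, de_fraction=0.2, effect_log2=2.0,
            rep_noise_sd=0.4, dropout_prob=0.0, seed=7,
        )
        table, _ = generate_dataset(cfg)
        comp = Comparison("condA", "condB")
        pops = compute_ratio_populations(table, comp)
        # independent recomputation straight from the generated table
        log2 = np.log2(table.values.to_numpy())
        a1, a2, b1, b2 = log2.T
        sd = lambda x: np.std(x, ddof=1)
        expected = ((sd(a1 - b1) + sd(a2 - b2)) / 2
                    / ((sd(a1 - a2) + sd(b1 - b2)) / 2))
        assert system_sn(pops) == pytest.approx(expected, abs=1e-12)

    def test_zero_intra_replicate_spread_raises(self):
        pops = make_pops([1.0, 2.0], [1.0, 2.0], [0.5, 0.5], [0.5, 0.5])
        with pytest.raises(DegeneratePopulationError):
            system_sn(pops)


class TestProteinSn:
    def test_vector_magnitude_ratio(self):
        # one protein at normalized (3,3)/(1,1) embedded in unit populations
        rng = np.random.default_rng(2)
        n = 20000
        z0, z1 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        r0, r1 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        pops = make_pops(z0, z1, r0, r1)
        scores = protein_sn(pops)
        from ticnet import normalized_populations

        norm = normalized_populations(pops)
        expected = np.hypot(norm["Z0n"], norm["Z1n"]) / np.hypot(
            norm["R0n"], norm["R1n"]
        )
        np.testing.assert_allclose(scores.values, expected)
        # direct arithmetic on chosen values
        i = scores.values.index[0]
        assert scores.values[i] == pytest.approx(
            np.hypot(norm.loc[i, "Z0n"], norm.loc[i, "Z1n"])
            / np.hypot(norm.loc[i, "R0n"], norm.loc[i, "R1n"])
        )

    def test_zero_cross_state_magnitude_gives_zero(self):
        rng = np.random.default_rng(3)
        n = 1000
        z0 = np.concatenate([[0.0], rng.normal(0, 1, n)])
        z1 = np.concatenate([[0.0], rng.normal(0, 1, n)])
        pops = make_pops(z0, z1,
                         rng.normal(0, 1, n + 1), rng.normal(0, 1, n + 1))
        # raw method applies no centering, so Z0=Z1=0 pins an exact zero
        scores = protein_sn(pops, method="raw")
        assert scores.values.iloc[0] == 0.0

    def test_zero_intra_magnitude_flagged_infinite(self):
        rng = np.random.default_rng(4)
        n = 500
        r0 = np.concatenate([[0.0], rng.normal(0, 1, n)])
        r1 = np.concatenate([[0.0], rng.normal(0, 1, n)])
        pops = make_pops(rng.normal(0, 1, n + 1), rng.normal(0, 1, n + 1),
                         r0, r1)
        scores = protein_sn(pops, method="raw")
        assert np.isinf(scores.values.iloc[0])
        assert scores.infinite.iloc[0]

    def test_raw_and_normalized_coincide_for_balanced_sds(self):
        rng = np.random.default_rng(5)
        n = 50000
        pops = make_pops(
            rng.normal(0, 3, n), rng.normal(0, 3, n),
            rng.normal(0, 1, n), rng.normal(0, 1, n),
        )
        a = protein_sn(pops, method="normalized").values
        b = protein_sn(pops, method="raw").values
        # populations have (near-)equal sds within Z and within R, so the
        # two definitions agree up to sampling error in the sd estimates
        assert np.median(np.abs(a - b) / b) < 0.02


@pytest.fixture(scope="module")
def null_pops():
    cfg = SyntheticConfig(
        n_proteins=4000, de_fraction=0.0, rep_noise_sd=0.4,
        dropout_prob=0.0, seed=17,
    )
    table, _ = generate_dataset(cfg)
    return compute_ratio_populations(table, Comparison("condA", "condB"))


class TestMonteCarloFdr:
    def test_pure_null_fdr_near_one(self, null_pops):
        curve = monte_carlo_fdr(null_pops, reps=200, seed=2)
        # wherever the observed data still has discoveries, essentially all
        # of them are false
        mask = ~np.isnan(curve.fdr) & (curve.cutoffs <= 2.0)
        assert np.nanmin(curve.fdr[mask]) > 0.8

    def test_curve_nonincreasing(self, null_pops):
        curve = monte_carlo_fdr(null_pops, reps=150, seed=3)
        vals = curve.fdr[~np.isnan(curve.fdr)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_no_discoveries_reported_missing_not_zero(self, null_pops):
        curve = monte_carlo_fdr(
            null_pops, grid=np.array([0.0, 2.8, 50.0]), reps=150, seed=4
        )
        assert np.isnan(curve.fdr_at(50.0))

    def test_deterministic_given_seed(self, null_pops):
        c1 = monte_carlo_fdr(null_pops, reps=120, seed=9)
        c2 = monte_carlo_fdr(null_pops, reps=120, seed=9)
        np.testing.assert_array_equal(c1.fdr, c2.fdr)

    def test_larger_effect_does_not_increase_fdr(self):
        comp = Comparison("condA", "condB")
        fdrs = []
        for effect in (1.0, 2.5):
            cfg = SyntheticConfig(
                n_proteins=3000, de_fraction=0.2, effect_log2=effect,
                rep_noise_sd=0.4, dropout_prob=0.0, seed=23,
            )
            table, _ = generate_dataset(cfg)
            pops = compute_ratio_populations(table, comp)
            fdrs.append(monte_carlo_fdr(pops, reps=150, seed=5).fdr_at(2.8))
        assert fdrs[1] <= fdrs[0] + 0.02


class TestSnFilter:
    def make_result(self, znet, sn_values):
        n = len(znet)
        frame = pd.DataFrame(
            {"znet": znet},
            index=pd.Index([f"P{i:03d}" for i in range(n)], name="protein_id"),
        )
        from ticnet.diffstats import ComparisonResult
        from ticnet.fdr import SnScores

        result = classify_tiers(ComparisonResult(frame, Comparison("a", "b")))
        scores = SnScores(system=5.0, values=pd.Series(sn_values,
                                                       index=frame.index))
        return result, scores

    def test_strict_boundary_and_counts(self):
        sn = [2.8, 2.81, 0.5, 3.5, np.inf, 1.0, 2.79, 4.0, 0.0, 2.9]
        result, scores = self.make_result(np.linspace(-2, 2, 10), sn)
        result = apply_sn_filter(result, scores)
        # brute-force oracle
        expected = [v > 2.8 for v in sn]
        assert list(result.frame["sn_reliable"]) == expected
        assert result.frame["sn_reliable"].sum() == 5
        assert not result.frame.loc["P000", "sn_reliable"]  # exactly 2.8

    def test_infinite_sn_passes_with_warning(self, caplog):
        result, scores = self.make_result([0.1, 0.2], [np.inf, 1.0])
        with caplog.at_level("WARNING"):
            result = apply_sn_filter(result, scores)
        assert result.frame["sn_reliable"].iloc[0]
        assert "infinite" in caplog.text

    def test_mismatched_proteins_raise(self):
        result, scores = self.make_result([0.1, 0.2], [1.0, 2.0])
        scores.values.index = pd.Index(["Q1", "Q2"])
        with pytest.raises(AlignmentError):
            apply_sn_filter(result, scores)

    def test_significance_and_reliability_carried_independently(self):
        result, scores = self.make_result([2.0, 0.1, -1.9], [1.0, 5.0, 3.0])
        result = apply_sn_filter(result, scores)
        f = result.frame
        assert f.loc["P000", "significant"] and not f.loc["P000", "sn_reliable"]
        assert not f.loc["P001", "significant"] and f.loc["P001", "sn_reliable"]
        assert f.loc["P002", "significant"] and f.loc["P002", "sn_reliable"]
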