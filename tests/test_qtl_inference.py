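"""Window statistics, ranking, bootstrap, PFP, and LD utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bayesgwa as bg
from bayesgwa.genotype_data import MISSING
from bayesgwa.qtl_inference import (
    QtlError,
    Region,
    WindowResult,
    score_windows,
)


class TestMakeWindows:
    def test_sliding_step_one_within_chromosomes(self):
        chroms = ["1"] * 7 + ["2"] * 6
        ws = bg.make_windows(chroms, size=5, step=1)
        spans = [(w.chromosome, w.start_idx, w.end_idx) for w in ws]
        assert spans == [
            ("1", 0, 5), ("1", 1, 6), ("1", 2, 7),
            ("2", 7, 12), ("2", 8, 13),
        ]

    def test_short_chromosome_single_window(self):
        ws = bg.make_windows(["1"] * 3, size=5)
        assert [(w.start_idx, w.end_idx) for w in ws] == [(0, 3)]

    def test_unmapped_block_windowed_separately(self):
        chroms = ["1"] * 5 + ["UNMAPPED"] * 5
        ws = bg.make_windows(chroms, size=5)
        assert len(ws) == 2
        assert ws[1].chromosome == "UNMAPPED"
        assert ws[1].span == (5, 10)

    def test_disjoint_windows_with_step(self):
        ws = bg.make_windows(["1"] * 10, size=5, step=5)
        assert [(w.start_idx, w.end_idx) for w in ws] == [(0, 5), (5, 10)]


class TestWindowModelFrequency:
    def test_never_included_window_zero(self):
        trace = np.zeros((100, 5), dtype=bool)
        assert bg.window_model_frequency(trace, (0, 5)) == 0.0

    def test_single_active_snp_passes_through(self):
        trace = np.zeros((100, 5), dtype=bool)
        trace[:30, 0] = True
        assert bg.window_model_frequency(trace, (0, 5)) == pytest.approx(0.3)

    def test_disjoint_inclusions_union(self):
        trace = np.zeros((100, 5), dtype=bool)
        trace[:20, 1] = True
        trace[50:80, 3] = True
        assert bg.window_model_frequency(trace, (0, 5)) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_union_bound_over_max_single_snp(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.random((60, 9)) < 0.2
        wf = bg.window_model_frequency(trace, (2, 7))
        assert wf >= trace[:, 2:7].mean(axis=0).max() - 1e-12


class TestBreedingValues:
    def test_zero_effects_zero_values(self):
        Z = np.ones((4, 6))
        assert (bg.breeding_values(Z, np.zeros(6)) == 0).all()

    def test_hand_multiplication(self):
        Z = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(
            bg.breeding_values(Z, np.array([0.5]), (0, 1)), [0.0, 0.5, 1.0]
        )

    def test_whole_genome_span_equals_gbv(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 3, (10, 8)).astype(float)
        u = rng.normal(size=8)
        np.testing.assert_array_equal(
            bg.breeding_values(Z, u, (0, 8)), bg.breeding_values(Z, u)
        )


class TestWindowVariance:
    def test_hand_variance(self):
        assert bg.window_variance(np.array([0.0, 0.5, 1.0])) == pytest.approx(0.25)

    def test_constant_zero(self):
        assert bg.window_variance(np.full(5, 1.3)) == 0.0

    def test_genome_window_proportion_one(self):
        rng = np.random.default_rng(2)
        gbv = rng.normal(size=20)
        assert bg.proportion_of_gbv(gbv, gbv) == pytest.approx(1.0)

    def test_zero_gbv_variance_rejected(self):
        with pytest.raises(QtlError, match="undefined"):
            bg.proportion_of_gbv(np.arange(3.0), np.zeros(3))

    def test_disjoint_windows_sum_to_gbv_without_ld(self):
        # independent SNPs: Var(GBV) ~ sum of disjoint window variances
        rng = np.random.default_rng(3)
        n, k = 2000, 40
        Z = rng.binomial(2, 0.5, (n, k)).astype(float)
        u = rng.normal(0, 0.3, k)
        gbv = bg.breeding_values(Z, u)
        total = sum(
            bg.window_variance(bg.breeding_values(Z, u, (s, s + 5)))
            for s in range(0, k, 5)
        )
        assert total == pytest.approx(bg.window_variance(gbv), rel=0.05)


class TestRankWindows:
    def test_overlapping_windows_merge(self):
        a = WindowResult(0, "1", 0, 5, variance=1.0)
        b = WindowResult(1, "1", 1, 6, variance=0.9)
        c = WindowResult(2, "2", 0, 5, variance=0.5)
        regions = bg.rank_windows([a, b, c])
        assert len(regions) == 2
        assert (regions[0].start_idx, regions[0].end_idx) == (0, 6)
        assert regions[0].best_window is a
        assert regions[1].chromosome == "2"

    def test_regions_sorted_by_best_variance(self):
        ws = [
            WindowResult(0, "1", 0, 5, variance=0.1),
            WindowResult(1, "2", 0, 5, variance=0.7),
        ]
        regions = bg.rank_windows(ws)
        assert regions[0].chromosome == "2"

    def test_unscored_windows_rejected(self):
        with pytest.raises(QtlError):
            bg.rank_windows([WindowResult(0, "1", 0, 5)])

    def test_top_region_covers_injected_qtl(self, small_fit):
        s = small_fit
        ws = score_windows(s["summary"], s["Z"], s["gm"].snps["chromosome"])
        regions = bg.rank_windows(ws)
        top = regions[0]
        strongest = s["truth"].qtl_indices[np.argmax(np.abs(s["truth"].effects))]
        covered = any(
            r.start_idx <= strongest < r.end_idx for r in regions[:3]
        )
        assert covered


class TestBootstrapSample:
    def _null_summary(self, summary, var_e=0.0):
        import copy

        s = copy.copy(summary)
        s.var_e_trace = np.full_like(summary.var_e_trace, var_e)
        return s

    def test_zero_residual_gives_fitted_mean(self, small_fit):
        s = self._null_summary(small_fit["summary"], 0.0)
        rng = np.random.default_rng(0)
        span = (0, 5)
        y1 = bg.bootstrap_sample(s, small_fit["X"], small_fit["Z"], span, rng)
        u = s.effect_mean.copy()
        u[0:5] = 0.0
        expected = small_fit["X"] @ s.b_mean + small_fit["Z"] @ u
        np.testing.assert_allclose(y1, expected, atol=1e-12)

    def test_excluded_window_shifts_mean_by_wbv(self, small_fit):
        s = self._null_summary(small_fit["summary"], 0.0)
        rng = np.random.default_rng(0)
        full = bg.bootstrap_sample(s, small_fit["X"], small_fit["Z"], (0, 0), rng)
        span = (10, 15)
        without = bg.bootstrap_sample(s, small_fit["X"], small_fit["Z"], span, rng)
        wbv = bg.breeding_values(small_fit["Z"], s.effect_mean, span)
        np.testing.assert_allclose(full - without, wbv, atol=1e-12)

    def test_replicate_variance_matches_sigma_e(self, small_fit):
        summary = small_fit["summary"]
        rng = np.random.default_rng(7)
        span = (0, 5)
        reps = np.array(
            [
                bg.bootstrap_sample(summary, small_fit["X"], small_fit["Z"], span, rng)
                for _ in range(200)
            ]
        )
        per_animal_var = reps.var(axis=0, ddof=1)
        assert per_animal_var.mean() == pytest.approx(summary.var_e_mean, rel=0.1)


class TestBootstrapPvalue:
    def test_one_exceedance_in_thousand(self):
        reps = np.linspace(0, 1, 1000)
        observed = reps[-2] + 1e-9  # exactly one replicate above
        assert bg.bootstrap_pvalue(observed, reps) == (0.001, 0.002)

    def test_zero_exceedances(self):
        assert bg.bootstrap_pvalue(2.0, np.linspace(0, 1, 1000)) == (0.0, 0.001)

    def test_observed_below_all(self):
        lo, hi = bg.bootstrap_pvalue(-1.0, np.linspace(0, 1, 1000))
        assert lo == pytest.approx(1.0 - 0.001) and hi == 1.0

    def test_ties_count_as_non_exceeding(self):
        assert bg.bootstrap_pvalue(0.5, np.full(10, 0.5)) == (0.0, 0.1)

    def test_empty_replicates_rejected(self):
        with pytest.raises(QtlError):
            bg.bootstrap_pvalue(1.0, np.array([]))


class TestBootstrapWindowTest:
    def test_null_window_not_significant(self, small_fit):
        # a window with no QTL should not produce an extreme p-value
        s = small_fit
        ws = score_windows(s["summary"], s["Z"], s["gm"].snps["chromosome"])
        qtl = set(s["truth"].qtl_indices.tolist())
        null_w = next(
            w for w in ws if not any(q in qtl for q in range(w.start_idx - 10, w.end_idx + 10))
        )
        rep_spec = bg.ModelSpec(seed=0, pi=0.99, chain_length=500, burn_in=100)
        res = bg.bootstrap_window_test(
            s["summary"], s["X"], s["Z"], null_w, n_replicates=20, seed=5, spec=rep_spec
        )
        assert res.p_interval[1] - res.p_interval[0] == pytest.approx(1 / 20)
        assert res.p_interval[0] > 0.05
        assert null_w.p_interval == res.p_interval


class TestPfp:
    def test_printed_working_values(self):
        assert bg.pfp(0.01, 0.5, 0.99) == pytest.approx(0.664, abs=5e-4)
        assert bg.pfp(0.001, 0.5, 0.99) == pytest.approx(0.165, abs=5e-4)

    def test_all_null_gives_certainty_of_false_positives(self):
        assert bg.pfp(0.03, 0.8, 1.0) == 1.0

    def test_monotonicity_grid(self):
        alphas = [0.001, 0.01, 0.05]
        powers = [0.2, 0.5, 0.9]
        pi0s = [0.5, 0.9, 0.99]
        for pw in powers:
            for p0 in pi0s:
                vals = [bg.pfp(a, pw, p0) for a in alphas]
                assert vals == sorted(vals)  # increasing in alpha
        for a in alphas:
            for p0 in pi0s:
                vals = [bg.pfp(a, pw, p0) for pw in powers]
                assert vals == sorted(vals, reverse=True)  # decreasing in power
        for a in alphas:
            for pw in powers:
                vals = [bg.pfp(a, pw, p0) for p0 in pi0s]
                assert vals == sorted(vals)  # increasing in pi0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(QtlError):
            bg.pfp(0.0, 0.5, 0.99)
        with pytest.raises(QtlError):
            bg.pfp(0.01, 0.5, 1.5)


class TestLdAndPlacement:
    def test_identical_columns_r2_one(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        assert bg.ld_r2(a, a.copy()) == pytest.approx(1.0)

    def test_complement_column_r2_one(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        assert bg.ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_missing_excluded(self):
        a = np.array([0, 1, 2, MISSING, 1])
        b = np.array([0, 1, 2, 0, MISSING])
        assert bg.ld_r2(a, b) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(QtlError, match="zero-variance"):
            bg.ld_r2(np.array([1, 1, 1]), np.array([0, 1, 2]))

    def test_perturbed_copy_placed_at_source(self):
        rng = np.random.default_rng(9)
        n, m = 200, 30
        mapped = rng.binomial(2, rng.uniform(0.2, 0.8, m), (n, m)).astype(np.int8)
        unmapped = mapped[:, 12].copy()
        swap = rng.random(n) < 0.05
        unmapped[swap] = rng.integers(0, 3, swap.sum())
        meta = pd.DataFrame(
            {
                "snp_id": [f"S{j}" for j in range(m)],
                "chromosome": "3",
                "position_bp": pd.array(range(100, 100 + m), dtype="Int64"),
                "gentrain_score": 0.9,
            }
        )
        hit = bg.place_unmapped(unmapped, mapped, meta)
        assert hit["snp_id"] == "S12"
        assert hit["r2"] > 0.7
        assert hit["position_bp"] == 112
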