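"""Procrustes ANOVA, directional asymmetry, FA scoring, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dentasym import (
    analyze_tooth_class,
    compare_groups,
    composite_and_standardize,
    directional_asymmetry,
    individual_fa_score,
    oneway_anova,
    procrustes_anova,
    simulate_landmarks,
)
from dentasym.errors import ComputationError, ValidationError
from dentasym.synthetic_data import ShapeSimParams


def _labels(i_n, r_n):
    ind = np.repeat([f"i{j}" for j in range(i_n)], 2 * r_n)
    side = np.tile(np.repeat(["L", "R"], r_n), i_n)
    rep = np.tile(np.arange(1, r_n + 1), 2 * i_n)
    return ind, side, rep


class TestProcrustesANOVA:
    def test_study_scale_degrees_of_freedom(self, rng):
        """154 individuals x 2 sides x 3 replicates gives the df ledger
        (153, 1, 153, 616, 923)."""
        i_n, r_n, k = 154, 3, 4
        ind, side, rep = _labels(i_n, r_n)
        table = procrustes_anova(rng.normal(size=(i_n * 2 * r_n, k)), ind, side, rep, n_perm=0)
        assert table.df == {
            "ind": 153, "side": 1, "ind_x_side": 153, "error": 616, "total": 923,
        }

    def test_ss_decomposition_matches_direct_total(self, rng):
        i_n, r_n, k = 12, 3, 6
        ind, side, rep = _labels(i_n, r_n)
        y = rng.normal(size=(i_n * 2 * r_n, k))
        table = procrustes_anova(y, ind, side, rep, n_perm=0)
        direct_total = ((y - y.mean(axis=0)) ** 2).sum()
        parts = sum(table.ss[e] for e in ("ind", "side", "ind_x_side", "error"))
        assert parts == pytest.approx(table.ss["total"], rel=1e-8)
        assert table.ss["total"] == pytest.approx(direct_total, rel=1e-10)
        r2_sum = sum(table.r2[e] for e in ("ind", "side", "ind_x_side", "error"))
        assert r2_sum == pytest.approx(1.0, abs=1e-12)

    def test_mixed_model_f_ratios_use_stated_denominators(self, rng):
        i_n, r_n, k = 10, 2, 3
        ind, side, rep = _labels(i_n, r_n)
        table = procrustes_anova(rng.normal(size=(i_n * 2 * r_n, k)), ind, side, rep, n_perm=0)
        assert table.f["ind_x_side"] == pytest.approx(
            table.ms["ind_x_side"] / table.ms["error"]
        )
        assert table.f["side"] == pytest.approx(table.ms["side"] / table.ms["ind_x_side"])
        assert table.f["ind"] == pytest.approx(table.ms["ind"] / table.ms["ind_x_side"])

    def test_zero_error_variance_flags_degenerate(self):
        # identical replicates, nonzero interaction: error MS is exactly 0
        i_n, r_n, k = 4, 2, 2
        ind, side, rep = _labels(i_n, r_n)
        rng = np.random.default_rng(3)
        cell = rng.normal(size=(i_n, 2, k))
        y = np.repeat(cell.reshape(i_n * 2, k), r_n, axis=0)
        table = procrustes_anova(y, ind, side, rep, n_perm=99, seed=0)
        assert table.degenerate
        assert np.isinf(table.f["ind_x_side"])

    def test_single_replicate_rejected(self, rng):
        ind, side, rep = _labels(5, 1)
        with pytest.raises(ValidationError):
            procrustes_anova(rng.normal(size=(10, 4)), ind, side, rep)

    def test_unbalanced_sides_rejected(self, rng):
        ind, side, rep = _labels(5, 2)
        side = side.copy()
        side[0] = "R"  # individual i0 now has 1 L and 3 R
        with pytest.raises(ValidationError):
            procrustes_anova(rng.normal(size=(20, 4)), ind, side, rep)

    def test_permutation_p_reproducible_for_fixed_seed(self, rng):
        i_n, r_n, k = 6, 2, 4
        ind, side, rep = _labels(i_n, r_n)
        y = rng.normal(size=(i_n * 2 * r_n, k))
        p1 = procrustes_anova(y, ind, side, rep, n_perm=199, seed=11).p
        p2 = procrustes_anova(y, ind, side, rep, n_perm=199, seed=11).p
        assert p1 == p2

    def test_f_increases_with_planted_fa_variance(self, um1_scheme):
        """F(FA) grows monotonically in sigma_fa^2 / sigma_err^2."""
        med = []
        for sigma_fa in (0.002, 0.006, 0.018):
            fs = []
            for s in range(8):
                params = ShapeSimParams(
                    scheme=um1_scheme, n_individuals=12, sigma_fa=sigma_fa,
                    seed=1000 + s,
                )
                cs, _ = simulate_landmarks(params)
                ana = analyze_tooth_class(cs, n_perm=0, n_cycles=1)
                fs.append(ana.anova.f["ind_x_side"])
            med.append(np.median(fs))
        assert med[0] < med[1] < med[2]


class TestDirectionalAsymmetry:
    def test_symmetric_sample_gives_zero_vector(self, rng):
        left = rng.normal(size=(20, 8))
        da = directional_asymmetry(left, left.copy())
        np.testing.assert_allclose(da.mean_diff, 0, atol=1e-15)

    def test_planted_offset_recovered_within_monte_carlo_error(self, rng):
        n, k = 200, 8
        delta = np.zeros(k)
        delta[2] = 0.05
        noise_sd = 0.02
        left = rng.normal(0, noise_sd, size=(n, k)) + delta / 2
        right = rng.normal(0, noise_sd, size=(n, k)) - delta / 2
        da = directional_asymmetry(left, right)
        se = noise_sd * np.sqrt(2.0 / n)
        assert np.all(np.abs(da.mean_diff - delta) < 4 * se)

    def test_equals_elementwise_average_oracle(self, rng):
        left = rng.normal(size=(9, 6))
        right = rng.normal(size=(9, 6))
        da = directional_asymmetry(left, right)
        oracle = np.array(
            [np.mean([left[i, j] - right[i, j] for i in range(9)]) for j in range(6)]
        )
        np.testing.assert_allclose(da.mean_diff, oracle, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            directional_asymmetry(np.empty((0, 4)), np.empty((0, 4)))


class TestFAScore:
    def test_identical_sides_and_zero_da_score_zero(self):
        l = np.arange(8.0)
        assert individual_fa_score(l, l, np.zeros(8)) == 0.0

    def test_three_four_five_closed_form(self):
        l = np.zeros(8)
        r = np.zeros(8)
        l[0], l[1] = 0.3, 0.4  # one landmark displaced by (0.3, 0.4)
        assert individual_fa_score(l, r, np.zeros(8)) == pytest.approx(0.5)

    def test_matches_flatten_and_norm_oracle(self, rng):
        l, r, d = rng.normal(size=(3, 10))
        oracle = np.sqrt(sum(((l[i] - r[i]) - d[i]) ** 2 for i in range(10)))
        assert individual_fa_score(l, r, d) == pytest.approx(oracle, rel=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            individual_fa_score(np.zeros(8), np.zeros(8), np.zeros(6))


class TestCompositeAndStandardize:
    def test_composite_is_mean_of_available_isomeres(self):
        df = pd.DataFrame(
            {"individual": ["a", "b"], "fa_um1": [0.02, 0.05], "fa_lm1": [0.04, np.nan]}
        )
        out, recs = composite_and_standardize(df)
        assert out.loc[0, "composite_fa"] == pytest.approx(0.03)
        assert out.loc[1, "composite_fa"] == pytest.approx(0.05)
        assert out["fa_z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["fa_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_identical_composites_rejected(self):
        df = pd.DataFrame({"individual": list("abc"), "fa_um1": [0.1, 0.1, 0.1]})
        with pytest.raises(ComputationError, match="variance"):
            composite_and_standardize(df)

    def test_zero_score_rejected_before_log(self):
        df = pd.DataFrame({"individual": list("ab"), "fa_um1": [0.0, 0.1]})
        with pytest.raises(ComputationError, match="log"):
            composite_and_standardize(df)

    def test_standardisation_preserves_ranks(self, rng):
        fa = np.exp(rng.normal(size=60))
        df = pd.DataFrame({"individual": [f"i{j}" for j in range(60)], "fa_um1": fa})
        out, _ = composite_and_standardize(df)
        rho = stats.spearmanr(out["fa_z"], np.log(out["composite_fa"])).statistic
        assert rho == pytest.approx(1.0)


class TestGroupComparisons:
    def test_identical_groups_are_indistinguishable(self):
        x = np.array([1.0, 2.0, 3.0])
        res = compare_groups(x, x.copy())
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_matches_brute_force_welch_formulas(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        res = compare_groups(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = 3, 4
        t = (x.mean() - y.mean()) / np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        assert res.t == pytest.approx(t)
        assert res.df == pytest.approx(df)
        sp_t, sp_p = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(sp_t)
        assert res.p == pytest.approx(sp_p)

    def test_recovers_planted_effect_size(self, rng):
        """Two cohorts separated by 0.68 SD (the immature-vs-mature FA
        contrast) yield a mean Cohen's d near 0.68 over replications."""
        ds = []
        for _ in range(200):
            x = rng.normal(0.68, 1.0, size=104)
            y = rng.normal(0.0, 1.0, size=112)
            ds.append(compare_groups(x, y).cohens_d)
        assert np.mean(ds) == pytest.approx(0.68, abs=0.03)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0], [2.0, 3.0])

    def test_oneway_anova_matches_scipy_f(self, rng):
        groups = [rng.normal(size=n) for n in (54, 33, 29, 100)]
        res = oneway_anova(groups)
        f, p = stats.f_oneway(*groups)
        assert res.f == pytest.approx(f) and res.p == pytest.approx(p)
        assert (res.df_between, res.df_within) == (3, 212)
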