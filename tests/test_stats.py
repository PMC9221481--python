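"""Test statistics and effect sizes, checked against enumeration and
sums-of-squares oracles."""

from itertools import product

import numpy as np
import pytest

from wavecoh.exceptions import ConfigError, DegenerateDataError
from wavecoh.pairing import ComparisonCell
from wavecoh.stats import (
    coefficient_of_variation, cohens_dz_from_t, compare_real_vs_random,
    compare_tasks, normality_gate, p_from_t, paired_t, rm_anova_gg,
    wilcoxon_signed_rank,
)


def values_with(mean, sd):
    """Two values realising an exact sample mean and SD."""
    return np.array([mean + sd / np.sqrt(2), mean - sd / np.sqrt(2)])


class TestCV:
    @pytest.mark.parametrize("mean,sd,expected", [
        (97.097, 4.895, 0.050),
        (20.556, 3.481, 0.169),
    ])
    def test_sd_over_mean(self, mean, sd, expected):
        assert coefficient_of_variation(values_with(mean, sd)) == pytest.approx(expected, abs=5e-4)

    def test_zero_spread_gives_zero(self):
        assert coefficient_of_variation(np.array([4.0, 4.0, 4.0])) == 0.0

    def test_zero_mean_undefined(self):
        assert coefficient_of_variation(np.array([-1.0, 1.0])) is None


class TestPairedT:
    def test_constructed_arithmetic(self):
        # differences mean 2, SD 2, n 4
        res = paired_t(np.array([-1.0, 3.0, 3.0, 3.0]), np.zeros(4))
        assert res.statistic == pytest.approx(2.0)
        assert res.effect_value == pytest.approx(1.0)
        assert res.df == 3

    def test_dz_identity_on_random_samples(self, rng):
        # dz = |t| / sqrt(n), both sides computed independently
        for _ in range(100):
            n = rng.integers(3, 20)
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            res = paired_t(a, b)
            assert res.effect_value == pytest.approx(cohens_dz_from_t(res.statistic, n))

    def test_sample_against_itself_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateDataError):
            paired_t(x, x)

    def test_p_invariant_under_sign_flip(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert paired_t(a, b).p == pytest.approx(paired_t(b, a).p)


class TestPFromT:
    def test_zero_statistic_gives_one(self):
        assert p_from_t(0.0, 10) == 1.0

    @pytest.mark.parametrize("t,df,expected", [
        (4.778, 8, 0.001),
        (3.636, 5, 0.015),
        (18.189, 2, 0.003),
    ])
    def test_reported_tail_probabilities(self, t, df, expected):
        assert p_from_t(t, df) == pytest.approx(expected, abs=5e-4)

    def test_df_below_one_rejected(self):
        with pytest.raises(ConfigError):
            p_from_t(1.0, 0)


def wilcoxon_exact_p_oracle(diff):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_obs = ranks[diff > 0].sum()
    n = len(diff)
    total = ranks.sum()
    w_all = np.array([np.sum(np.array(signs) * ranks)
                      for signs in product([0, 1], repeat=n)])
    p_le = np.mean(w_all <= w_obs)
    p_ge = np.mean(w_all >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_balanced_ranks_not_significant(self):
        res = wilcoxon_signed_rank(np.array([-1.0, 1, -2, 2, -3, 3]), np.zeros(6))
        assert res.p > 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        diff = rng.standard_normal(n) + 0.5
        res = wilcoxon_signed_rank(diff, np.zeros(n))
        assert res.p == pytest.approx(wilcoxon_exact_p_oracle(diff), abs=1e-12)

    def test_effect_size_is_z_over_sqrt_n(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        res = wilcoxon_signed_rank(a, b)
        assert res.effect_value == pytest.approx(abs(res.z) / np.sqrt(12))
        # the worked example: z = 2, n = 10 -> r ~ 0.632
        assert 2.0 / np.sqrt(10) == pytest.approx(0.632, abs=5e-4)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))


class TestNormalityGate:
    def test_gaussian_samples_routed_parametric(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(50)
            hits += normality_gate(x) == "parametric"
        assert hits >= 18

    def test_heavy_outlier_routed_nonparametric(self):
        x = np.r_[np.random.default_rng(0).normal(0, 0.1, 9), 50.0]
        assert normality_gate(x) == "nonparametric"

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateDataError):
            normality_gate(np.ones(10))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ConfigError):
            normality_gate(np.array([1.0, 2.0]))


def rm_ss_oracle(m):
    """From-scratch two-way (units x conditions) sums-of-squares split."""
    grand = m.mean()
    n, k = m.shape
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    eta_partial = ss_cond / (ss_cond + ss_err)
    return f, eta_partial


class TestRmAnova:
    def test_identical_conditions_give_null_result(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_gg(m)
        assert res.statistic == 0.0 and res.p == 1.0 and res.effect_value == 0.0

    def test_two_conditions_equal_squared_paired_t(self, rng):
        m = rng.standard_normal((8, 2))
        res = rm_anova_gg(m)
        t = paired_t(m[:, 0], m[:, 1]).statistic
        assert res.statistic == pytest.approx(t**2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sums_of_squares_oracle(self, seed):
        m = np.random.default_rng(seed).standard_normal((9, 3)) + [0.0, 0.4, 0.9]
        res = rm_anova_gg(m)
        f, eta = rm_ss_oracle(m)
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.effect_value == pytest.approx(eta, rel=1e-9)

    def test_missing_cells_rejected(self):
        m = np.random.default_rng(0).standard_normal((5, 3))
        m[2, 1] = np.nan
        with pytest.raises(DegenerateDataError):
            rm_anova_gg(m)

    def test_shape_requirements(self):
        with pytest.raises(ConfigError):
            rm_anova_gg(np.zeros((2, 3)))


class TestComparisonTables:
    @staticmethod
    def cells(offset):
        rng = np.random.default_rng(4)
        out = []
        for combo in ("inter-MMGs", "inter-EEGcen"):
            values = rng.normal(20.0, 3.0, 6) + offset
            out.append(ComparisonCell.from_values(combo, "Sum5PaD", values))
        return out

    def test_two_rows_per_combo_with_statistics(self):
        table = compare_real_vs_random(self.cells(30.0), self.cells(0.0))
        assert len(table) == 4
        assert set(table["mode"]) == {"AB_IMA", "rand"}
        assert (table["p"] < 0.05).all()

    def test_identical_cells_reported_degenerate(self):
        table = compare_real_vs_random(self.cells(0.0), self.cells(0.0))
        assert (table["test"] == "degenerate").all()

    def test_unmatched_combos_listed(self):
        with pytest.raises(ConfigError, match="inter-EEGcen"):
            compare_real_vs_random(self.cells(1.0), self.cells(1.0)[:1])

    def test_task_comparison_detects_offset(self, rng):
        import pandas as pd

        rows = []
        for unit in range(8):
            for partner in ("A", "B"):
                base = rng.normal(30, 2)
                rows.append(dict(region_combo="inter-MMGs", parameter="Sum5PaD",
                                 unit=f"u{unit}", partner=partner, task="HIMA",
                                 value=base + 10.0))
                rows.append(dict(region_combo="inter-MMGs", parameter="Sum5PaD",
                                 unit=f"u{unit}", partner=partner, task="PIMA",
                                 value=base + rng.normal(0, 0.5)))
        table = compare_tasks(pd.DataFrame(rows))
        assert len(table) == 1
        assert table["p"].item() < 0.01
        assert table["M_a"].item() > table["M_b"].item()
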