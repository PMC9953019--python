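"""Robust trimmed-mean statistics: estimators, tests, multiplicity."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import mstats

import pulsewss as pw
from pulsewss.robust import (johansen_statistic, trimmed_mean_squared_se,
                             yuen_contrast)
from pulsewss.synthetic import FactorialDesignSpec, make_factorial_table


class TestLocationScale:
    def test_trimmed_mean_drops_tail_fifths(self):
        assert pw.trimmed_mean(range(1, 11), 0.2) == 5.5

    def test_zero_trim_is_arithmetic_mean(self, rng):
        x = rng.normal(size=17)
        assert pw.trimmed_mean(x, 0.0) == pytest.approx(x.mean())
        assert pw.winsorized_variance(x, 0.0) == pytest.approx(
            x.var(ddof=1))

    def test_outlier_insensitivity(self):
        x = list(range(1, 10)) + [10 ** 6]
        assert pw.trimmed_mean(x, 0.2) == 5.5

    def test_agrees_with_scipy(self, rng):
        for _ in range(5):
            x = rng.normal(size=rng.integers(5, 40))
            assert pw.trimmed_mean(x, 0.2) == pytest.approx(
                stats.trim_mean(x, 0.2))

    def test_winsorized_variance_against_mstats_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=rng.integers(5, 40))
            w = mstats.winsorize(x, limits=(0.2, 0.2))
            assert pw.winsorized_variance(x, 0.2) == pytest.approx(
                np.asarray(w).var(ddof=1))

    def test_constant_vector_has_zero_winsorized_variance(self):
        assert pw.winsorized_variance(np.full(9, 3.3)) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            pw.trimmed_mean([], 0.2)
        with pytest.raises(ValueError):
            pw.trimmed_mean([1.0], 0.6)


class TestYuen:
    def test_matches_scipy_trimmed_welch(self, rng):
        for _ in range(5):
            x = rng.normal(size=19)
            y = rng.normal(loc=0.5, scale=2.0, size=23)
            est, sq_se, df, p = yuen_contrast(x, y, 0.2)
            ref = stats.ttest_ind(x, y, equal_var=False, trim=0.2)
            assert est / np.sqrt(sq_se) == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_identical_groups_give_zero_estimate(self):
        x = np.arange(10.0)
        est, _, _, p = yuen_contrast(x, x)
        assert est == 0.0
        assert p == pytest.approx(1.0)


class TestHochberg:
    def test_single_p_unchanged(self):
        assert pw.hochberg_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        # adj(k) = min over j >= k of (m - j + 1) p(j), capped at 1
        adj = pw.hochberg_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_equal_ps_stay_equal(self):
        adj = pw.hochberg_adjust([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_against_independent_step_up_oracle(self, rng):
        p = rng.uniform(size=9)
        adj = pw.hochberg_adjust(p)
        order = np.argsort(p)
        m = p.size
        oracle = np.empty(m)
        for rank_idx, i in enumerate(order):
            oracle[i] = min(
                min((m - j) * p[order[j]] for j in range(rank_idx, m)), 1.0)
        assert np.allclose(adj, oracle)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=6)
        assert np.all(pw.hochberg_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pw.hochberg_adjust([0.5, 1.5])


class TestEvidenceLabel:
    @pytest.mark.parametrize("p,label", [
        (0.001, "strong"), (0.0049, "strong"), (0.005, "weak"),
        (0.012, "weak"), (0.05, "weak"), (0.051, "none"), (0.5, "none"),
    ])
    def test_thresholds(self, p, label):
        assert pw.evidence_label(p) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pw.evidence_label(1.2)


def additive_table(seed, noise=1.0, n=7, outlier_rate=0.0):
    return make_factorial_table(FactorialDesignSpec(
        grand_mean=10.0,
        factor_a_effects=(2.0, 1.0, 0.0, -1.0, -2.0),
        factor_b_effects=(1.5, 0.0, -1.5),
        noise_scales=noise, n_per_cell=n, seed=seed,
        outlier_rate=outlier_rate))


class TestRobustAnova:
    def test_constant_cells_give_null_result(self):
        table = make_factorial_table(FactorialDesignSpec(seed=0))
        table["value"] = 3.0
        res = pw.robust_two_way_anova(table)
        # statistics vanish; scan p-values saturate at their 0.999 cap
        assert res.statistic_a == res.statistic_b == res.statistic_ab == 0.0
        assert res.p_a == res.p_b == res.p_ab == 0.999

    def test_planted_main_effects_detected_null_interaction_kept(self):
        res = pw.robust_two_way_anova(additive_table(seed=1, noise=0.5))
        assert res.p_a == 0.001
        assert res.p_b == 0.001
        assert res.p_ab > 0.05

    def test_zero_trim_matches_independent_welch_johansen_oracle(self, rng):
        table = additive_table(seed=2)
        res = pw.robust_two_way_anova(table, trim=0.0)
        # independent oracle: build the Johansen statistic for the row
        # factor from explicit per-cell means and variances
        cells, v, means = [], [], []
        for a in sorted(table.rheology.unique()):
            for b in sorted(table.inlet.unique()):
                x = table[(table.rheology == a)
                          & (table.inlet == b)].value.to_numpy()
                means.append(x.mean())
                v.append(x.var(ddof=1) / x.size)
                cells.append(x.size)
        ones_b = np.ones((1, 3))
        diff_a = np.eye(4, 5) - np.eye(4, 5, 1)
        cmat = np.kron(diff_a, ones_b)
        mu = np.array(means)
        V = np.diag(v)
        stat = mu @ cmat.T @ np.linalg.inv(cmat @ V @ cmat.T) @ cmat @ mu
        assert res.statistic_a == pytest.approx(stat, rel=1e-12)

    def test_unbalanced_design_rejected(self):
        table = additive_table(seed=3)
        with pytest.raises(ValueError, match="unbalanced"):
            pw.robust_two_way_anova(table.iloc[:-1])

    def test_tiny_cells_rejected_when_trimming(self):
        table = additive_table(seed=4, n=3)
        with pytest.raises(ValueError, match="too small"):
            pw.robust_two_way_anova(table)

    def test_effect_recovery_via_posthoc_contrasts(self):
        # planted inlet effects 1.5 / 0.0 / -1.5: the Parabolic - Plug
        # pooled contrast should recover 1.5 within simulation error
        ests = []
        for seed in range(8):
            table = additive_table(seed=seed, noise=0.5)
            c = pw.posthoc_main_effect_contrasts(table, "inlet")[0]
            assert (c.level1, c.level2) == ("Parabolic", "Plug")
            ests.append(c.estimate)
        assert np.mean(ests) == pytest.approx(1.5, abs=0.15)

    def test_contrast_cis_bracket_estimates(self):
        table = additive_table(seed=5)
        for c in pw.posthoc_main_effect_contrasts(table, "rheology"):
            assert c.ci_lower <= c.estimate <= c.ci_upper
            assert 0.0 <= c.p_adjusted <= 1.0

    def test_identical_levels_give_null_contrast(self):
        table = additive_table(seed=6)
        dup = table.copy()
        # overwrite all levels with the same values: no real differences
        base = table[table.inlet == "Plug"].value.to_numpy()
        for lv in ("Parabolic", "Womersley"):
            dup.loc[dup.inlet == lv, "value"] = base
        c = pw.posthoc_main_effect_contrasts(dup, "inlet")[0]
        assert c.estimate == 0.0
        assert c.p_adjusted == pytest.approx(1.0)

    def test_trimmed_contrasts_resist_gross_outliers(self):
        # replace one observation per cell by a 100x outlier: the pooled
        # trimmed contrast must move strictly less than the untrimmed one
        clean = additive_table(seed=7, noise=0.5)
        dirty = clean.copy()
        idx = dirty.groupby(["rheology", "inlet"]).head(1).index
        dirty.loc[idx, "value"] *= 100.0

        def contrast(table, trim):
            grp = table[table.inlet == "Parabolic"].value.to_numpy()
            grp2 = table[table.inlet == "Plug"].value.to_numpy()
            return pw.trimmed_mean(grp, trim) - pw.trimmed_mean(grp2, trim)

        shift_trimmed = abs(contrast(dirty, 0.2) - contrast(clean, 0.2))
        shift_raw = abs(contrast(dirty, 0.0) - contrast(clean, 0.0))
        assert shift_trimmed < shift_raw


class TestJohansenInternals:
    def test_statistic_matches_explicit_quadratic_form(self, rng):
        means = rng.normal(size=6)
        sq_se = rng.uniform(0.5, 2.0, size=6)
        h = np.full(6, 5)
        cmat = rng.normal(size=(3, 6))
        stat, A = johansen_statistic(cmat, means, sq_se, h)
        V = np.diag(sq_se)
        M = np.linalg.inv(cmat @ V @ cmat.T)
        assert stat == pytest.approx(
            means @ cmat.T @ M @ cmat @ means, rel=1e-12)
        R = V @ cmat.T @ M @ cmat
        assert A == pytest.approx(np.sum(np.diag(R) ** 2 / (h - 1)))

    def test_squared_se_reduces_to_classical_at_zero_trim(self, rng):
        x = rng.normal(size=12)
        assert trimmed_mean_squared_se(x, 0.0) == pytest.approx(
            x.var(ddof=1) / 12.0)
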