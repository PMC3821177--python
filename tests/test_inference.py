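"""Regression, permutation test, t-tests, ratios, observer agreement,
and the Model/Results pair."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pvstereo.aging import (
    PVAgingModel,
    aggregate_animal,
    density_ratio,
    dual_criterion,
    group_ttest,
    observer_agreement,
    pearson_regression,
    permutation_test,
)
from pvstereo.synthetic import CohortConfig, synthesize_animal_densities


def exact_permutation_p(x, y, tail="signed"):
    """Enumeration oracle: permutation p over all n! orderings."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = stats.pearsonr(x, y).statistic
    rs = np.array([
        stats.pearsonr(x, np.asarray(perm)).statistic
        for perm in itertools.permutations(y)
    ])
    if tail == "signed":
        return np.mean(rs >= r_obs - 1e-12)
    return np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)


class TestAggregateAnimal:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "subdivision",
                                           "density_per_mm3"])

    def test_unweighted_mean(self):
        df = self._df([("A1", "vMGN", 2000.0), ("A1", "vMGN", 3000.0)])
        out = aggregate_animal(df)
        assert out["density_per_mm3"].iloc[0] == 2500.0

    def test_mean_of_identical_values_is_idempotent(self):
        df = self._df([("A1", "vMGN", 1234.5)] * 5)
        assert aggregate_animal(df)["density_per_mm3"].iloc[0] == 1234.5

    def test_missing_subdivision_warns_and_emits_nan(self):
        df = self._df([("A1", "vMGN", 1.0), ("A1", "dMGN", 2.0),
                       ("A2", "vMGN", 3.0)])
        with pytest.warns(UserWarning, match="missing subdivisions"):
            out = aggregate_animal(df)
        gap = out[(out.animal_id == "A2") & (out.subdivision == "dMGN")]
        assert len(gap) == 1 and gap["density_per_mm3"].isna().all()


class TestPearsonRegression:
    def test_perfect_positive_linearity(self):
        ages = np.arange(3, 10, dtype=float)
        res = pearson_regression(ages, 2 * ages)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p_param < 1e-10

    def test_perfect_negative_linearity(self):
        ages = np.arange(3, 10, dtype=float)
        res = pearson_regression(ages, -ages + 10)
        assert res.r == pytest.approx(-1.0)

    def test_p_matches_t_transform_oracle(self, rng):
        """p_param must equal the two-sided p from
        t = r*sqrt((n-2)/(1-r^2)) with n-2 df, to 1e-6 and better."""
        for _ in range(20):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = pearson_regression(x, y)
            t = res.r * math.sqrt((n - 2) / (1 - res.r**2))
            p_oracle = 2 * stats.t.sf(abs(t), n - 2)
            assert res.p_param == pytest.approx(p_oracle, abs=1e-12)

    def test_r_083_at_n7_gives_p_above_criterion(self):
        """A dataset constructed with r = 0.83 at n = 7 yields the
        t-transform p of ~0.021 — above the 0.01 regression criterion."""
        x = np.arange(7, dtype=float)
        z = np.linspace(-1, 1, 7) ** 2  # any vector not collinear with x
        xs = (x - x.mean()) / x.std()
        zc = z - z.mean() - (z - z.mean()) @ xs / len(x) * xs
        zs = zc / zc.std()
        r = 0.83
        y = r * xs + math.sqrt(1 - r**2) * zs
        res = pearson_regression(x, y)
        assert res.r == pytest.approx(0.83, abs=1e-9)
        t = 0.83 * math.sqrt(5 / (1 - 0.83**2))
        assert res.p_param == pytest.approx(2 * stats.t.sf(t, 5), abs=1e-12)
        assert 0.01 < res.p_param < 0.03
        assert not res.passes_regression

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_regression([1, 2, 3], [5, 5, 5])
        with pytest.raises(ValueError, match="degenerate"):
            pearson_regression([4, 4, 4], [1, 2, 3])
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_regression([1, 2], [1, 2])


class TestPermutationTest:
    def test_exact_enumeration_small_n(self, rng):
        """Monte Carlo p agrees with the n! enumeration oracle within
        3 Monte Carlo standard errors for n = 3, 4, 5."""
        for n in (3, 4, 5):
            x = np.arange(n, dtype=float)
            y = rng.normal(size=n) + 0.8 * x
            p_exact = exact_permutation_p(x, y)
            n_iter = 4000
            p_mc = permutation_test(x, y, n_iter=n_iter, seed=rng)
            se = math.sqrt(p_exact * (1 - p_exact) / n_iter) or 1 / n_iter
            assert abs(p_mc - p_exact) <= 3 * se + 1e-12

    def test_monotone_three_points_is_one_sixth(self, rng):
        p_mc = permutation_test([1.0, 2.0, 3.0], [10.0, 20.0, 30.0],
                                n_iter=6000, seed=rng)
        se = math.sqrt((1 / 6) * (5 / 6) / 6000)
        assert abs(p_mc - 1 / 6) <= 3 * se

    def test_monotone_seven_points_is_extreme(self, rng):
        x = np.arange(7, dtype=float)
        p_mc = permutation_test(x, x**2 + 1, n_iter=1000, seed=rng)
        assert p_mc <= 0.002  # exact p = 1/5040

    def test_null_p_is_uniform_on_average(self):
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            ps.append(permutation_test(x, y, n_iter=400, seed=rng))
        assert 0.45 < np.mean(ps) < 0.55

    def test_signed_tail_makes_negative_r_non_extreme(self, rng):
        x = np.arange(5, dtype=float)
        y = -x + rng.normal(scale=0.01, size=5)
        assert permutation_test(x, y, n_iter=500, seed=1) > 0.95
        assert permutation_test(x, y, n_iter=500, seed=1,
                                tail="absolute") < 0.05

    def test_plus_one_correction_flag(self):
        p = permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                             n_iter=6, seed=0, plus_one=True)
        assert p * 7 == round(p * 7)  # denominator is n_iter + 1

    def test_seeded_reproducibility(self):
        x = np.arange(7, dtype=float)
        y = np.array([3.0, 1, 4, 1, 5, 9, 2])
        assert permutation_test(x, y, seed=5) == \
            permutation_test(x, y, seed=5)

    def test_parametric_and_permutation_nulls_agree_midrange(self, rng):
        """The t-transform p and a large-sample permutation p must agree
        within 0.02 at n = 7 for mid-range r (cross-check of nulls)."""
        x = np.arange(7, dtype=float)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.5, 6.0])
        res = pearson_regression(x, y)
        p_perm = permutation_test(x, y, n_iter=20000, seed=rng,
                                  tail="absolute")
        assert abs(res.p_param - p_perm) < 0.02


class TestDualCriterion:
    @pytest.mark.parametrize(
        "r,pp,pm,expected",
        [
            (0.83, 0.005, 0.01, True),    # the passing pattern
            (0.75, 0.027, 0.01, False),   # parametric p too large
            (0.95, 0.3, 0.3, False),      # conjunction fails
            (0.65, 0.001, 0.001, False),  # r below cutoff
            (0.71, 0.01, 0.05, True),     # boundary alphas inclusive
        ],
    )
    def test_conjunction(self, r, pp, pm, expected):
        assert dual_criterion(r, pp, pm) is expected

    @given(
        r=st.floats(-1, 1), pp=st.floats(0, 1), pm=st.floats(0, 1),
        d_r=st.floats(0, 0.3), d_pp=st.floats(0, 0.009),
        d_pm=st.floats(0, 0.049),
    )
    @settings(max_examples=200, deadline=None)
    def test_tightening_thresholds_never_creates_significance(
            self, r, pp, pm, d_r, d_pp, d_pm):
        loose = dual_criterion(r, pp, pm)
        tight = dual_criterion(r, pp, pm, r_cutoff=0.7 + d_r,
                               alpha_param=0.01 - d_pp,
                               alpha_mc=0.05 - d_pm)
        assert not (tight and not loose)


class TestGroupTtest:
    def test_identical_groups(self):
        res = group_ttest([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_hand_computed_pooled_t(self):
        """{1,2,3} vs {11,12,13}: pooled s^2 = 1, se = sqrt(2/3),
        t = -10/sqrt(2/3) = -12.247 on 4 df."""
        res = group_ttest([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        t_hand = -10.0 / math.sqrt(2.0 / 3.0)
        assert res.t_stat == pytest.approx(t_hand, abs=1e-9)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_hand), 4),
                                            abs=1e-12)
        assert res.significant

    def test_scale_invariance(self, rng):
        m = rng.normal(10, 2, size=4)
        a = rng.normal(12, 2, size=5)
        r1 = group_ttest(m, a)
        r2 = group_ttest(7.3 * m, 7.3 * a)
        assert r1.t_stat == pytest.approx(r2.t_stat, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_welch_flag_changes_df(self):
        m = [1.0, 2.0, 3.0]
        a = [10.0, 30.0, 50.0, 70.0]
        assert group_ttest(m, a).p_value != \
            group_ttest(m, a, welch=True).p_value

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_ttest([1.0], [2.0, 3.0])


class TestDensityRatio:
    def test_equal_means_give_unity(self):
        assert density_ratio([4.0, 6.0], [5.0, 5.0]) == 1.0

    def test_doubling(self):
        assert density_ratio([20.0], [10.0]) == 2.0

    def test_invariance_to_common_rescaling(self):
        a, m = [3.0, 5.0], [2.0, 4.0]
        assert density_ratio(a, m) == pytest.approx(
            density_ratio([x * 9 for x in a], [x * 9 for x in m]))

    def test_zero_middle_mean_rejected(self):
        with pytest.raises(ValueError, match="undefined|zero"):
            density_ratio([1.0], [0.0, 0.0])


class TestObserverAgreement:
    def test_identical_observers(self):
        a = np.arange(1, 26, dtype=float)
        agree, met, p = observer_agreement(a, a)
        assert (agree == 1.0).all()
        assert met
        assert p == 1.0

    def test_boundary_agreement_095_passes(self):
        agree, _, _ = observer_agreement([20.0], [19.0])
        assert agree[0] == pytest.approx(0.95)
        assert agree[0] >= 0.95

    def test_run_found_after_early_break(self):
        """19 perfect sections, one at 0.90, then 20 perfect: the
        criterion is met by the later window (sliding-window check)."""
        a = np.full(40, 20.0)
        b = a.copy()
        b[19] = 18.0  # agreement 0.9 at section 19
        agree, met, _ = observer_agreement(a, b)
        assert agree[19] == pytest.approx(0.9)
        assert met
        # truncating before the later window completes -> not met
        _, met_short, _ = observer_agreement(a[:38], b[:38])
        assert not met_short

    def test_both_zero_counts_as_full_agreement(self):
        agree, _, _ = observer_agreement([0.0], [0.0])
        assert agree[0] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            observer_agreement([1.0, 2.0], [1.0])


class TestModelResults:
    @pytest.fixture
    def fitted(self):
        cfg = CohortConfig(seed=7)
        est = synthesize_animal_densities(cfg)
        densities = est[["animal_id", "subdivision", "density_per_mm3"]]
        demo = est[["animal_id", "age_months", "sex", "thickness_um"]] \
            .drop_duplicates("animal_id")
        model = PVAgingModel(densities, demo)
        return model.fit(mc_iterations=500, seed=3)

    def test_all_regions_and_pooled_groups_present(self, fitted):
        subs = set(fitted.regressions["subdivision"])
        assert {"vMGN", "dMGN", "mMGN"} <= subs
        assert {f"LGN{i}" for i in range(1, 7)} <= subs
        assert {"LGN_magno", "LGN_parvo"} <= subs
        assert len(fitted.regressions) == 11
        assert len(fitted.group_comparisons) == 11
        assert len(fitted.ratios) == 11

    def test_significant_implies_r_above_cutoff(self, fitted):
        sig = fitted.regressions[fitted.regressions["significant"]]
        assert (sig["r"] > 0.7).all()
        assert (sig["p_param"] <= 0.01).all()
        assert (sig["p_mc"] <= 0.05).all()

    def test_fit_is_reproducible_and_order_independent(self):
        cfg = CohortConfig(seed=7)
        est = synthesize_animal_densities(cfg)
        densities = est[["animal_id", "subdivision", "density_per_mm3"]]
        demo = est[["animal_id", "age_months", "sex", "thickness_um"]] \
            .drop_duplicates("animal_id")
        r1 = PVAgingModel(densities, demo).fit(seed=3)
        shuffled = densities.sample(frac=1.0, random_state=1)
        r2 = PVAgingModel(shuffled, demo).fit(seed=3)
        pd.testing.assert_frame_equal(r1.regressions, r2.regressions)

    def test_orphan_animal_rejected(self):
        densities = pd.DataFrame({
            "animal_id": ["A1", "A2"], "subdivision": ["vMGN", "vMGN"],
            "density_per_mm3": [1.0, 2.0]})
        demo = pd.DataFrame({"animal_id": ["A1"], "age_months": [300]})
        with pytest.raises(ValueError, match="missing from the demographics"):
            PVAgingModel(densities, demo)

    def test_summary_mentions_criteria_and_regions(self, fitted):
        text = fitted.summary()
        assert "r > 0.7" in text
        assert "vMGN" in text and "LGN_parvo" in text

    def test_save_writes_tables_and_run_log(self, fitted, tmp_path):
        fitted.save(tmp_path)
        for name in ("regressions.tsv", "group_comparisons.tsv",
                     "ratios.tsv", "run_log.json"):
            assert (tmp_path / name).exists()
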