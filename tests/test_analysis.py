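import numpy as np
import pandas as pd
import pytest

from vchinrest import (
    compare_groups,
    fit_age_quadratic,
    icc_oneway_absolute,
    summarize,
    within_subject_sd,
)
from vchinrest.analysis import WithinSubjectSD


def icc1_oracle(x):
    """Brute-force one-way ANOVA ICC via explicit sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / x.size
    ssb = sum(k * (row.sum() / k - grand) ** 2 for row in x)
    ssw = sum((v - row.sum() / k) ** 2 for row in x for v in row)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC:
    def test_no_within_subject_variation_gives_one(self):
        x = np.array([[40.0] * 3, [50.0] * 3, [60.0] * 3])
        assert icc_oneway_absolute(x) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(400, 3))
        assert abs(icc_oneway_absolute(x)) < 0.1

    def test_hand_computed_4x3_table(self):
        x = [[50, 52, 51], [46, 44, 45], [60, 63, 60], [55, 54, 57]]
        # oracle: explicit sum-of-squares ANOVA by hand
        assert icc_oneway_absolute(x) == pytest.approx(0.961015948021264)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.normal(50, 10, size=(4, 3))
            assert icc_oneway_absolute(x) == pytest.approx(icc1_oracle(x), rel=1e-10)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(50, 10, size=(8, 3)) + rng.normal(0, 8, size=(8, 1))
        df = pd.DataFrame(x, columns=["s1", "s2", "s3"]).reset_index(names="subj")
        long = df.melt(id_vars="subj", var_name="session", value_name="d")
        ref = pingouin.intraclass_corr(data=long, targets="subj",
                                       raters="session", ratings="d")
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert icc_oneway_absolute(x) == pytest.approx(icc1, abs=1e-9)

    def test_degenerate_table_returns_none(self):
        assert icc_oneway_absolute(np.full((3, 3), 7.0)) is None

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway_absolute(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc_oneway_absolute(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestWithinSubjectSD:
    def test_constant_phases_give_zero(self):
        df = pd.DataFrame({"pre": [500.0], "mid": [500.0], "post": [500.0]})
        assert within_subject_sd(df).mean_sd_mm == 0.0

    def test_arithmetic_example(self):
        df = pd.DataFrame({"pre": [400.0], "mid": [500.0], "post": [600.0]})
        assert within_subject_sd(df).mean_sd_mm == pytest.approx(100.0)

    def test_missing_phase_excluded_and_counted(self):
        df = pd.DataFrame({"pre": [400.0, 450.0], "mid": [500.0, np.nan],
                           "post": [600.0, 460.0]})
        res = within_subject_sd(df)
        assert isinstance(res, WithinSubjectSD)
        assert res.n_used == 1 and res.n_excluded == 1
        assert res.mean_sd_mm == pytest.approx(100.0)

    def test_accepts_mappings(self):
        res = within_subject_sd([{"pre": 400.0, "mid": 500.0, "post": 600.0}])
        assert res.mean_sd_mm == pytest.approx(100.0)


class TestSummarize:
    def test_two_record_cell_means_and_ratio(self, record_factory):
        recs = [record_factory("a", ecc=4.0, crowding=1.0),
                record_factory("b", ecc=4.0, crowding=3.0)]
        s = summarize(recs)
        assert s.mean_crowding_by_ecc[4.0] == pytest.approx(2.0)
        assert s.bouma_ratio_by_ecc[4.0] == pytest.approx(0.5)
        assert 6.0 not in s.mean_crowding_by_ecc  # absent, not zero

    def test_order_invariance(self, record_factory):
        recs = [record_factory(f"s{i}", ecc=e, crowding=c, d=(d, d + 5, d - 5))
                for i, (e, c, d) in enumerate(
                    [(4.0, 1.5, 480.0), (6.0, 2.5, 520.0), (4.0, 2.0, 440.0)])]
        a, b = summarize(recs), summarize(recs[::-1])
        assert a.mean_crowding_by_ecc == b.mean_crowding_by_ecc
        assert a.within_subject_sd_mm == pytest.approx(b.within_subject_sd_mm)
        assert a.icc == pytest.approx(b.icc)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_dyslexia_cells_reported(self, record_factory):
        recs = [record_factory("a", crowding=1.8, dyslexia=True),
                record_factory("b", crowding=1.5, dyslexia=False),
                record_factory("c", crowding=1.7, dyslexia=False)]
        s = summarize(recs)
        assert s.mean_crowding_by_dyslexia_and_ecc[(True, 4.0)] == pytest.approx(1.8)
        assert s.mean_crowding_by_dyslexia_and_ecc[(False, 4.0)] == pytest.approx(1.6)


class TestCompareGroups:
    def u_oracle(self, a, b):
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    def test_identical_groups_null(self, record_factory):
        recs = ([record_factory(f"a{i}", ecc=4.0, crowding=c)
                 for i, c in enumerate([1.0, 2.0, 3.0])]
                + [record_factory(f"b{i}", ecc=6.0, crowding=c)
                   for i, c in enumerate([1.0, 2.0, 3.0])])
        cmp = compare_groups(recs, "eccentricity")
        assert cmp.mannwhitney_p > 0.9
        assert cmp.mannwhitney_u == self.u_oracle([1, 2, 3], [1, 2, 3])

    def test_shifted_groups_significant(self, record_factory):
        rng = np.random.default_rng(1)
        recs = ([record_factory(f"a{i}", ecc=4.0, crowding=float(c))
                 for i, c in enumerate(rng.normal(1.5, 0.1, 50))]
                + [record_factory(f"b{i}", ecc=6.0, crowding=float(c))
                   for i, c in enumerate(rng.normal(2.5, 0.1, 50))])
        cmp = compare_groups(recs, "eccentricity")
        assert cmp.mannwhitney_p < 0.001 and cmp.welch_p < 0.001
        assert cmp.welch_t < 0  # 4 deg group mean is smaller

    def test_u_statistic_matches_rank_enumeration(self, record_factory):
        a_vals, b_vals = [1.2, 3.4, 2.2], [2.0, 4.1, 3.9]
        recs = ([record_factory(f"a{i}", ecc=4.0, crowding=v)
                 for i, v in enumerate(a_vals)]
                + [record_factory(f"b{i}", ecc=6.0, crowding=v)
                   for i, v in enumerate(b_vals)])
        cmp = compare_groups(recs, "eccentricity")
        assert cmp.mannwhitney_u == self.u_oracle(a_vals, b_vals) == 2.0

    def test_dyslexia_factor_and_errors(self, record_factory):
        recs = [record_factory("a", dyslexia=True, crowding=2.0),
                record_factory("b", dyslexia=False, crowding=1.5)]
        with pytest.raises(ValueError):  # each group needs >= 2
            compare_groups(recs, "dyslexia")
        with pytest.raises(ValueError):
            compare_groups(recs, "gender")


class TestAgeQuadraticFit:
    def synthetic_df(self, rng, n=1000, age_coeff=0.004, ratio=0.38,
                     dys_effect=0.26, noise=0.1):
        ecc = rng.choice([4.0, 6.0], size=n)
        age = rng.uniform(7, 71, size=n)
        dys = rng.random(n) < 0.2
        crowding = (ratio * ecc + dys_effect * dys
                    + age_coeff * age ** 2 + rng.normal(0, noise, n))
        return pd.DataFrame({"crowding_effect_deg": crowding,
                             "eccentricity_deg": ecc, "dyslexia": dys,
                             "age": age})

    def test_null_age_coefficient_recovered(self):
        fit = fit_age_quadratic(
            self.synthetic_df(np.random.default_rng(0), age_coeff=0.0))
        assert abs(fit.params["age_sq"]) < 3 * fit.bse["age_sq"]

    def test_reference_coefficient_recovered(self):
        # generator-structured data with the reported 0.004 deg/yr^2 curvature
        fit = fit_age_quadratic(
            self.synthetic_df(np.random.default_rng(1), age_coeff=0.004))
        assert abs(fit.params["age_sq"] - 0.004) < 3 * fit.bse["age_sq"]
        assert fit.params["age_sq"] == pytest.approx(0.004, rel=0.05)

    def test_eccentricity_slope_and_dyslexia_recovered(self):
        fit = fit_age_quadratic(self.synthetic_df(np.random.default_rng(2)))
        assert abs(fit.params["eccentricity"] - 0.38) < 3 * fit.bse["eccentricity"]
        assert abs(fit.params["dyslexia"] - 0.26) < 3 * fit.bse["dyslexia"]

    def test_no_age_variation_rejected(self):
        df = self.synthetic_df(np.random.default_rng(3), n=50)
        df["age"] = 30.0
        with pytest.raises(ValueError):
            fit_age_quadratic(df)
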