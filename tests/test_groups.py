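import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import bioage as ba
from bioage.groups import _mannwhitney_cdf, _signedrank_cdf
from oracles import hl_two_sample_brute, hl_one_sample_brute


class TestHLTwoSample:
    def test_hand_example(self):
        res = ba.hl_shift_two_sample([1, 2, 3], [4, 5, 6])
        assert res["estimate"] == pytest.approx(-3.0)

    def test_identical_samples(self):
        res = ba.hl_shift_two_sample([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res["estimate"] == pytest.approx(0.0)

    @given(st.floats(-50, 50))
    def test_shift_equivariance(self, delta):
        x = np.array([0.3, 1.7, 2.2, 4.9, 5.1])
        y = np.array([1.1, 2.8, 3.0, 6.4])
        base = ba.hl_shift_two_sample(x, y)
        shifted = ba.hl_shift_two_sample(x + delta, y)
        assert shifted["estimate"] == pytest.approx(base["estimate"] + delta,
                                                    abs=1e-9)
        assert shifted["ci_low"] == pytest.approx(base["ci_low"] + delta,
                                                  abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 2.0, size=rng.integers(2, 15))
        y = rng.normal(0.0, 2.0, size=rng.integers(2, 15))
        res = ba.hl_shift_two_sample(x, y)
        assert res["estimate"] == pytest.approx(hl_two_sample_brute(x, y))
        assert res["ci_low"] <= res["estimate"] <= res["ci_high"]

    def test_matches_reference_distribution_free_intervals(self):
        """Frozen expectations from R's wilcox.test(conf.int=TRUE) for
        the same construction (exact, no ties)."""
        x = [1.1, 2.3, 3.5, 4.1, 5.9, 7.2]
        y = [2.0, 3.3, 4.8, 6.1, 7.7, 8.2, 9.5]
        res = ba.hl_shift_two_sample(x, y)
        assert res["estimate"] == pytest.approx(-2.1)
        assert res["ci_low"] == pytest.approx(-5.4)
        assert res["ci_high"] == pytest.approx(1.5)
        res99 = ba.hl_shift_two_sample(x, y, level=0.99)
        assert res99["ci_low"] == pytest.approx(-6.6)
        assert res99["ci_high"] == pytest.approx(2.6)
        a = [6.113, 0.306, 3.089, 3.899, 3.213, 1.682, 6.535, 1.716, 8.055,
             1.812, 5.915, 8.86, -2.167, 1.164, 1.6]
        b = [1.908, -0.853, -7.969, -7.321, 3.96, -0.92, -5.344, -0.516,
             3.644, 5.686, -1.291, -0.772, -5.289, 1.38, -1.92, 1.366,
             2.115, 3.105, -1.827, 1.515]
        res = ba.hl_shift_two_sample(a, b)
        assert res["estimate"] == pytest.approx(3.5315)
        assert res["ci_low"] == pytest.approx(1.181)
        assert res["ci_high"] == pytest.approx(6.687)

    def test_ci_level_monotonicity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2, 3, size=18)
        y = rng.normal(0, 3, size=22)
        r95 = ba.hl_shift_two_sample(x, y, level=0.95)
        r99 = ba.hl_shift_two_sample(x, y, level=0.99)
        assert r99["ci_low"] <= r95["ci_low"]
        assert r99["ci_high"] >= r95["ci_high"]

    def test_too_small_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            ba.hl_shift_two_sample([1.0], [2.0, 3.0])

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 1.0, size=80)
        y = rng.normal(0.0, 1.0, size=90)
        res = ba.hl_shift_two_sample(x, y)
        assert not res["exact"]
        assert res["ci_low"] < 1.0 < res["ci_high"]


class TestHLOneSample:
    def test_walsh_average_example(self):
        """{1, 2, 6}: Walsh averages {1, 1.5, 2, 3.5, 4, 6}, median 2.75."""
        res = ba.hl_one_sample([1.0, 2.0, 6.0])
        assert res["estimate"] == pytest.approx(2.75)

    def test_symmetric_sample_centred_at_zero(self):
        x = [-3.0, -1.0, 0.0, 1.0, 3.0]
        assert ba.hl_one_sample(x)["estimate"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0.5, 1.0, size=rng.integers(2, 20))
        res = ba.hl_one_sample(x)
        assert res["estimate"] == pytest.approx(hl_one_sample_brute(x))
        assert res["ci_low"] <= res["estimate"] <= res["ci_high"]

    def test_matches_reference_interval(self):
        z = [1.83, 0.50, 1.62, 2.48, 1.68, 1.88, 1.55, 3.06, 1.30, 0.90,
             0.75, 2.50]
        res = ba.hl_one_sample(z)
        assert res["estimate"] == pytest.approx(1.665)
        assert res["ci_low"] == pytest.approx(1.165)
        assert res["ci_high"] == pytest.approx(2.18)


class TestNullDistributions:
    def test_mannwhitney_cdf_against_scipy(self):
        """Exact U cdf agrees with scipy's exact Mann-Whitney p-values."""
        cdf = _mannwhitney_cdf(4, 5)
        x = [1, 2, 3, 9]
        y = [4, 5, 6, 7, 8]
        u = stats.mannwhitneyu(x, y, alternative="less", method="exact")
        # U for x: pairs (x_i < y_j) -> u statistic = 3 (only 9 beats some)
        assert u.pvalue == pytest.approx(cdf[int(u.statistic)])

    def test_signedrank_cdf_against_scipy(self):
        cdf = _signedrank_cdf(8)
        x = [-1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        w = stats.wilcoxon(x, alternative="less", method="exact")
        assert w.pvalue == pytest.approx(cdf[int(w.statistic)])

    def test_distribution_symmetry_and_mass(self):
        cdf = _mannwhitney_cdf(6, 9)
        assert cdf[-1] == pytest.approx(1.0)
        pmf = np.diff(np.concatenate([[0.0], cdf]))
        np.testing.assert_allclose(pmf, pmf[::-1], rtol=1e-10)


def _scored_frame(ad_by_group, ages=None, sex="F"):
    rows = []
    for label, ads in ad_by_group.items():
        for i, ad in enumerate(ads):
            age = 50.0 + (i % 20) if ages is None else ages[label][i]
            rows.append({"id": f"{label}{i}", "sex": sex, "age": age,
                         "subgroup": label, "hormone_use": 0,
                         "age_diff": ad})
    return pd.DataFrame(rows)


class TestSubgroupContrast:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        scored = _scored_frame({"DS": vals, "RASIG": vals})
        res = ba.subgroup_contrast(scored, scored["subgroup"] == "DS",
                                   scored["subgroup"] == "RASIG",
                                   age_match=False)
        assert res.hl_estimate == pytest.approx(0.0)
        assert res.t_p == pytest.approx(1.0)

    def test_shift_recovered_single_cohort(self):
        rng = np.random.default_rng(1)
        scored = _scored_frame({"DS": rng.normal(5.0, 2.0, size=40),
                                "RASIG": rng.normal(0.0, 2.0, size=300)})
        res = ba.subgroup_contrast(scored, scored["subgroup"] == "DS",
                                   scored["subgroup"] == "RASIG",
                                   age_match=False)
        assert res.hl_estimate == pytest.approx(5.0, abs=1.5)
        assert res.hl_ci_low < 5.0 < res.hl_ci_high
        assert res.t_p < 1e-6

    def test_age_matching_restricts_to_overlap(self):
        ads = {"DS": list(np.zeros(10)), "RASIG": list(np.zeros(50))}
        ages = {"DS": list(np.linspace(20, 60, 10)),
                "RASIG": list(np.linspace(35, 74, 50))}
        scored = _scored_frame(ads, ages=ages)
        res = ba.subgroup_contrast(scored, scored["subgroup"] == "DS",
                                   scored["subgroup"] == "RASIG",
                                   age_match=True)
        # DS subjects younger than 35 drop out of the comparison
        assert res.n_a == sum(a >= 35.0 for a in ages["DS"])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        scored = _scored_frame({"GO": rng.normal(size=25),
                                "SGO": rng.normal(size=25)})
        shuffled = scored.sample(frac=1.0, random_state=7).reset_index(drop=True)
        r1 = ba.subgroup_contrast(scored, scored["subgroup"] == "GO",
                                  scored["subgroup"] == "SGO", age_match=False)
        r2 = ba.subgroup_contrast(shuffled, shuffled["subgroup"] == "GO",
                                  shuffled["subgroup"] == "SGO",
                                  age_match=False)
        assert r1.hl_estimate == pytest.approx(r2.hl_estimate)
        assert r1.t_p == pytest.approx(r2.t_p)

    def test_empty_group_error(self):
        scored = _scored_frame({"RASIG": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="empty group"):
            ba.subgroup_contrast(scored, scored["subgroup"] == "DS",
                                 scored["subgroup"] == "RASIG")


class TestHormoneSplit:
    def _scored(self, n=120, shift=-2.0, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(35, 74, size=n)
        hu = (rng.random(n) < 0.4).astype(int)
        ad = rng.normal(0, 2.0, size=n)
        ad[(hu == 1) & (age > 50)] += shift
        return pd.DataFrame({"id": [f"S{i}" for i in range(n)],
                             "sex": "F", "age": age, "hormone_use": hu,
                             "subgroup": "RASIG", "age_diff": ad})

    def test_shift_above_cut_recovered_null_below(self):
        scored = self._scored(n=400, shift=-2.0, seed=3)
        res = ba.hormone_split_contrast(scored, age_cut=50.0)
        assert res["above"].hl_estimate == pytest.approx(-2.0, abs=1.0)
        assert res["above"].t_p < 0.01
        assert abs(res["below"].hl_estimate) < 1.0

    def test_empty_stratum_warns_not_fatal(self):
        scored = self._scored(n=40, seed=4)
        scored["hormone_use"] = 0
        res = ba.hormone_split_contrast(scored)
        assert res["below"] is None and res["above"] is None
        assert len(res["warnings"]) == 2

    def test_determinism(self):
        s = self._scored(n=200, seed=5)
        r1 = ba.hormone_split_contrast(s)
        r2 = ba.hormone_split_contrast(s)
        assert r1["above"].hl_estimate == r2["above"].hl_estimate


class TestDoseResponse:
    def test_exact_linear_exposure(self):
        packs = np.array([0.0, 100.0, 500.0, 1000.0, 2500.0])
        res = ba.dose_response(0.02 * packs, packs)
        assert res.slope == pytest.approx(0.02)
        assert res.r2 == pytest.approx(1.0)

    def test_permutation_null(self):
        """Permuting exposure kills the slope; p-values spread over (0,1)."""
        rng = np.random.default_rng(6)
        packs = rng.lognormal(6, 1, size=200)
        ad = 0.002 * packs + rng.normal(0, 2, size=200)
        slopes, ps = [], []
        for _ in range(50):
            perm = rng.permutation(packs)
            res = ba.dose_response(ad, perm)
            slopes.append(res.slope)
            ps.append(res.p)
        assert abs(np.mean(slopes)) < 5e-4
        assert 0.05 < np.mean(ps) < 0.95

    def test_constant_exposure_error(self):
        with pytest.raises(ValueError, match="constant"):
            ba.dose_response([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
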