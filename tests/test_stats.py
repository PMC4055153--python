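import numpy as np
import pandas as pd
import pytest
import scipy.stats

import alphavar as av
from alphavar.exceptions import InvalidArgumentError


def hemisphere_table(rng, n1=6, n2=6, shift=0.0, between_sd=1.0, within_sd=0.3):
    """Balanced two-hemisphere summary table with a planted group shift."""
    rows = []
    for group, n, delta in (("tinnitus", n1, -shift), ("control", n2, 0.0)):
        for i in range(n):
            mu = 5.0 + delta + between_sd * rng.standard_normal()
            for hemi in ("left", "right"):
                rows.append(
                    {
                        "subject_id": f"{group[:3]}{i}",
                        "group": group,
                        "hemisphere": hemi,
                        "band": "low_alpha",
                        "mean_power": mu + within_sd * rng.standard_normal(),
                        "cv": mu + within_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_degrees_of_freedom_21_21(self):
        rng = np.random.default_rng(0)
        df = hemisphere_table(rng, 21, 21, shift=1.0)
        res = av.mixed_anova(df, "mean_power", "low_alpha")
        assert (res.df_num, res.df_den) == (1, 40)

    @pytest.mark.parametrize("n", [3, 10, 21])
    def test_denominator_df_rule(self, n):
        rng = np.random.default_rng(n)
        df = hemisphere_table(rng, n, n)
        res = av.mixed_anova(df, "cv", "low_alpha")
        assert res.df_den == 2 * n - 2

    def test_balanced_equals_subject_mean_anova(self):
        rng = np.random.default_rng(3)
        df = hemisphere_table(rng, 8, 8, shift=1.2)
        res = av.mixed_anova(df, "mean_power", "low_alpha")
        means = df.groupby(["subject_id", "group"], as_index=False)[
            "mean_power"
        ].mean()
        g1 = means[means.group == "tinnitus"]["mean_power"]
        g2 = means[means.group == "control"]["mean_power"]
        f_oneway = scipy.stats.f_oneway(g1, g2)
        assert np.isclose(res.F, f_oneway.statistic, atol=1e-6, rtol=1e-6)
        assert np.isclose(res.p, f_oneway.pvalue, atol=1e-6, rtol=1e-4)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(100):
            df = hemisphere_table(rng, 6, 6, shift=0.0)
            ps.append(av.mixed_anova(df, "cv", "low_alpha").p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unbalanced_hemispheres_rejected(self):
        rng = np.random.default_rng(1)
        df = hemisphere_table(rng, 4, 4).iloc[:-1]
        with pytest.raises(InvalidArgumentError):
            av.mixed_anova(df, "cv", "low_alpha")

    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        df = hemisphere_table(rng, 4, 4)
        df = df[df.group == "control"]
        with pytest.raises(InvalidArgumentError):
            av.mixed_anova(df, "cv", "low_alpha")


class TestDurationModel:
    def test_noiseless_exact_recovery(self):
        d = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        cv = 1.0 / d + 2.0
        res = av.fit_duration_model(cv, d)
        assert res.a == pytest.approx(2.0, abs=1e-8)
        assert res.b == pytest.approx(1.0, abs=1e-8)

    def test_flat_data_reduces_to_mean(self):
        rng = np.random.default_rng(0)
        d = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        cv = 2.5 + 0.1 * rng.standard_normal(5)
        res = av.fit_duration_model(cv, d, fix_b=0.0)
        assert res.a == pytest.approx(cv.mean())
        assert res.b_fixed

    def test_fixed_b_literal_model(self):
        d = np.array([1.0, 2.0, 4.0])
        cv = 1.0 / d + 3.0
        res = av.fit_duration_model(cv, d, fix_b=1.0)
        assert res.a == pytest.approx(3.0)
        assert res.b == 1.0

    def test_degenerate_durations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            av.fit_duration_model(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))


class TestMedianSplitWelch:
    @staticmethod
    def welch_oracle(x, y):
        """Explicit Welch-Satterthwaite formulas."""
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * scipy.stats.t.sf(abs(t), df)
        return t, df, p

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        d = np.array([1, 1.5, 2, 2.5, 4, 5, 6, 8.0])
        cv = rng.uniform(1, 4, size=8)
        res = av.median_split_welch(cv, d)
        short = cv[d <= np.median(d)]
        long = cv[d > np.median(d)]
        t, df, p = self.welch_oracle(short, long)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_direction_short_greater(self):
        d = np.array([1.0, 2.0, 5.0, 6.0])
        cv = np.array([3.0, 3.01, 2.0, 1.99])
        res = av.median_split_welch(cv, d)
        assert res.t > 0
        assert res.mean_short > res.mean_long

    def test_at_median_goes_to_short_group(self):
        d = np.array([1.0, 3.0, 3.0, 8.0, 9.0])
        res = av.median_split_welch(np.arange(5.0) + 1, d)
        assert res.split_point == 3.0
        assert res.n_short == 3 and res.n_long == 2

    def test_identical_durations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            av.median_split_welch(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestCovariateCheck:
    def test_perfect_association(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = av.covariate_check(x, x, "distress")
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_matches_closed_form_pearson(self):
        cv = np.array([2.1, 3.0, 1.2, 4.4, 2.8])
        age = np.array([30.0, 45.0, 28.0, 60.0, 50.0])
        res = av.covariate_check(cv, age, "age")
        num = ((cv - cv.mean()) * (age - age.mean())).sum()
        den = np.sqrt(((cv - cv.mean()) ** 2).sum() * ((age - age.mean()) ** 2).sum())
        assert res.r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            av.covariate_check(np.ones(4), np.arange(4.0), "age")
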