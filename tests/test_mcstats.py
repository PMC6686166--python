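"""Agreement statistics against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stvquant import (PairedMeasurements, agreement_regression, bland_altman,
                      icc_3_1, loa_from_summary)


def pairs_from(diffs, base=1000.0):
    d = np.asarray(diffs, dtype=float)
    b = np.full_like(d, base)
    return PairedMeasurements(a=b + d, b=b)


class TestBlandAltman:
    def test_identical_pairs_are_fully_concordant(self):
        p = PairedMeasurements(a=np.array([1.0, 2, 3]), b=np.array([1.0, 2, 3]))
        r = bland_altman(p)
        assert r.mean_diff == 0 and r.sd_diff == 0
        assert r.loa95 == (0.0, 0.0)

    def test_unit_sd_closed_form(self):
        r = bland_altman(pairs_from([-1.0, 0.0, 1.0]))
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa95 == pytest.approx((-1.96, 1.96))

    def test_matches_first_principles_recomputation(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(5000, 30000, 20)
        b = a + rng.normal(0, 800, 20)
        r = bland_altman(PairedMeasurements(a=a, b=b))
        d = a - b
        mean = d.sum() / d.size
        sd = np.sqrt(((d - mean) ** 2).sum() / (d.size - 1))
        t = stats.t.ppf(0.975, d.size - 1)
        assert r.mean_diff == pytest.approx(mean, abs=1e-12)
        assert r.sd_diff == pytest.approx(sd, abs=1e-12)
        assert r.ci95_mean[0] == pytest.approx(mean - t * sd / np.sqrt(20), abs=1e-12)
        assert r.loa95[1] == pytest.approx(mean + 1.96 * sd, abs=1e-12)

    def test_log_transform_requires_positive(self):
        p = PairedMeasurements(a=np.array([1.0, -2.0]), b=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            bland_altman(p, log_transform=True)

    def test_log_transform_analyses_log_differences(self):
        a = np.array([100.0, 200.0, 400.0])
        r = bland_altman(PairedMeasurements(a=2 * a, b=a), log_transform=True)
        assert r.mean_diff == pytest.approx(np.log(2))
        assert r.sd_diff == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), n=st.integers(2, 40))
    def test_antisymmetry_under_method_swap(self, seed, n):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(1, 100, n), rng.uniform(1, 100, n)
        r_ab = bland_altman(PairedMeasurements(a=a, b=b))
        r_ba = bland_altman(PairedMeasurements(a=b, b=a))
        assert r_ab.mean_diff == pytest.approx(-r_ba.mean_diff, abs=1e-9)
        assert r_ab.loa95[0] == pytest.approx(-r_ba.loa95[1], abs=1e-9)
        assert r_ab.loa95[1] == pytest.approx(-r_ba.loa95[0], abs=1e-9)


class TestLoaFromSummary:
    def test_zero_width_ci_degenerates_to_mean(self):
        lo, hi = loa_from_summary(5.0, 5.0 - 1e-12, 5.0 + 1e-12, 10)
        assert lo == pytest.approx(5.0, abs=1e-9)
        assert hi == pytest.approx(5.0, abs=1e-9)

    def test_inconsistent_interval_rejected(self):
        with pytest.raises(ValueError):
            loa_from_summary(0.0, 1.0, 2.0, 10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), n=st.integers(3, 50))
    def test_round_trip_with_bland_altman(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.uniform(1000, 30000, n)
        b = a + rng.normal(100, 700, n)
        r = bland_altman(PairedMeasurements(a=a, b=b))
        lo, hi = loa_from_summary(r.mean_diff, *r.ci95_mean, n)
        assert lo == pytest.approx(r.loa95[0], abs=1e-10 * max(1, abs(r.loa95[0])))
        assert hi == pytest.approx(r.loa95[1], abs=1e-10 * max(1, abs(r.loa95[1])))


class TestIcc31:
    def test_exact_copy_gives_unity(self):
        x = np.random.default_rng(0).uniform(0, 10, 12)
        icc, _ = icc_3_1(np.column_stack([x, x]))
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_ignored_by_consistency_form(self):
        x = np.random.default_rng(1).uniform(0, 10, 12)
        icc, _ = icc_3_1(np.column_stack([x, x + 1234.5]))
        assert icc == pytest.approx(1.0, abs=1e-9)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, (12, 2))
        icc, _ = icc_3_1(x)
        # independent decomposition via explicit two-way ANOVA sums of squares
        n, k = x.shape
        grand = x.mean()
        bms = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        jms = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        ems = (((x - grand) ** 2).sum()
               - bms * (n - 1) - jms * (k - 1)) / ((n - 1) * (k - 1))
        expected = (bms - ems) / (bms + (k - 1) * ems)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, (10, 3))
        n, k = x.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="score")
        row = ref[ref["Type"] == "ICC(C,1)"]  # consistency, single rater
        icc, ci = icc_3_1(x)
        assert icc == pytest.approx(float(row["ICC"].iloc[0]), abs=1e-8)
        ref_ci = row["CI95"].iloc[0]  # pingouin rounds its CI to 2 decimals
        assert ci[0] == pytest.approx(float(ref_ci[0]), abs=0.01)
        assert ci[1] == pytest.approx(float(ref_ci[1]), abs=0.01)

    def test_bounded_and_offset_invariant_property(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.uniform(0, 50, (8, 3))
            icc, _ = icc_3_1(x)
            k = x.shape[1]
            assert -1 / (k - 1) - 1e-9 <= icc <= 1 + 1e-9
            shifted = x.copy()
            shifted[:, 0] += 42.0
            assert icc_3_1(shifted)[0] == pytest.approx(icc, abs=1e-9)

    def test_missing_cells_rejected(self):
        x = np.random.default_rng(5).uniform(0, 1, (5, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_3_1(x)


class TestAgreementRegression:
    def test_identity_relation(self):
        a = np.array([1.0, 2, 3, 4])
        r = agreement_regression(PairedMeasurements(a=a, b=a))
        assert (r.slope, r.intercept, r.r_squared) == \
            pytest.approx((1.0, 0.0, 1.0))

    def test_exact_affine_relation(self):
        a = np.array([1.0, 2, 3, 4, 5])
        r = agreement_regression(PairedMeasurements(a=a, b=2 * a + 3))
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(3.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 100, 30)
        b = 0.9 * a + rng.normal(0, 5, 30)
        r = agreement_regression(PairedMeasurements(a=a, b=b))
        X = np.column_stack([a, np.ones_like(a)])
        beta = np.linalg.solve(X.T @ X, X.T @ b)
        resid = b - X @ beta
        r2 = 1 - (resid ** 2).sum() / ((b - b.mean()) ** 2).sum()
        assert r.slope == pytest.approx(beta[0], abs=1e-12)
        assert r.intercept == pytest.approx(beta[1], abs=1e-10)
        assert r.r_squared == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        p = PairedMeasurements(a=np.array([2.0, 2, 2]), b=np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            agreement_regression(p)
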