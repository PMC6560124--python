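"""ICC(1,1), correlations, and cohort summarization."""

import numpy as np
import pandas as pd
import pytest

from sulcmorph import (
    classify_icc,
    icc_1_1,
    partial_correlation,
    pearson_r,
    summarize_cohort,
)
from sulcmorph.registry import SUPPORTED_SULCI

# hand-computed one-way ANOVA oracle for the 3 subjects x 2 sessions fixture
# {(1,2),(4,5),(9,8)}: row means 1.5, 4.5, 8.5; grand mean 4.8333...;
# SSB = 2*sum((row-grand)^2) = 49.3333..., MSB = 24.6667; SSW = 1.5, MSW = 0.5
FIXTURE_3X2 = np.array([[1.0, 2.0], [4.0, 5.0], [9.0, 8.0]])
FIXTURE_MSB = 2 * ((FIXTURE_3X2.mean(axis=1) - FIXTURE_3X2.mean()) ** 2).sum() / 2
FIXTURE_MSW = ((FIXTURE_3X2 - FIXTURE_3X2.mean(axis=1, keepdims=True)) ** 2).sum() / 3
FIXTURE_ICC = (FIXTURE_MSB - FIXTURE_MSW) / (FIXTURE_MSB + FIXTURE_MSW)


class TestICC:
    def test_duplicated_sessions_is_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        res = icc_1_1(np.column_stack([x, x]))
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_hand_computed_fixture(self):
        res = icc_1_1(FIXTURE_3X2)
        assert res.icc == pytest.approx(FIXTURE_ICC, abs=1e-12)
        assert res.ms_between == pytest.approx(FIXTURE_MSB, abs=1e-12)
        assert res.ms_within == pytest.approx(FIXTURE_MSW, abs=1e-12)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(17)
        data = rng.normal(0, 2, (12, 1)) + rng.normal(0, 1, (12, 3))
        res = icc_1_1(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "session": np.tile(np.arange(3), 12),
                "y": data.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="session", ratings="y")
        row = ref[ref["Type"] == "ICC(1,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        lo, hi = row["CI95"]
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_zero_variance_undefined(self):
        res = icc_1_1(np.full((4, 2), 3.0))
        assert res.undefined
        assert np.isnan(res.icc)

    def test_invariances(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 2, (10, 1)) + rng.normal(0, 1, (10, 2))
        base = icc_1_1(data).icc
        perm = rng.permutation(10)
        assert icc_1_1(data[perm]).icc == pytest.approx(base, abs=1e-12)
        assert icc_1_1(data + 7.5).icc == pytest.approx(base, abs=1e-9)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(23)
        data = rng.normal(0, 2, (15, 1)) + rng.normal(0, 1, (15, 2))
        res = icc_1_1(data)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_listwise_missing_rows_dropped(self):
        data = FIXTURE_3X2.tolist() + [[np.nan, 4.0]]
        res = icc_1_1(pd.DataFrame(data))
        assert res.n_subjects == 3
        assert res.icc == pytest.approx(FIXTURE_ICC, abs=1e-12)

    @pytest.mark.parametrize(
        "value,band",
        [(0.9, "excellent"), (0.75, "excellent"), (0.65, "good"), (0.5, "fair"),
         (0.2, "poor"), (float("nan"), "undefined")],
    )
    def test_classification_bands(self, value, band):
        assert classify_icc(value) == band

    def test_variance_ratio_expectation(self):
        # between:within = 9:1 -> population ICC = 0.9
        rng = np.random.default_rng(5)
        iccs = [
            icc_1_1(rng.normal(0, 3, (30, 1)) + rng.normal(0, 1, (30, 2))).icc
            for _ in range(50)
        ]
        assert np.mean(iccs) == pytest.approx(0.9, abs=0.05)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_simulation_within_fisher_band(self):
        rng = np.random.default_rng(99)
        n, rho = 500, 0.5
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        res = pearson_r(x, y)
        z = np.arctanh(res.r) - np.arctanh(rho)
        assert abs(z) < 2.576 / np.sqrt(n - 3)

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([2, 4, 6, 8, 1])
        res = pearson_r(x, y)
        assert res.n == 4 and res.r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        res = pearson_r(np.ones(5), np.arange(5.0))
        assert res.flag == "zero-variance" and np.isnan(res.r)


class TestPartialCorrelation:
    def test_orthogonal_controls_equal_raw(self):
        # controls exactly orthogonal to x and y (and centered)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        # project the controls off span{1, x, y} so they are exactly
        # orthogonal to everything the correlation sees
        basis, _ = np.linalg.qr(np.column_stack([np.ones(8), x, y]))

        def orthogonalize(z):
            return z - basis @ (basis.T @ z)

        z1 = orthogonalize(np.array([1.0, 2.0, -1.0, 3.0, 0.0, -2.0, 1.0, -4.0]))
        z2 = orthogonalize(np.array([0.0, 1.0, 4.0, -1.0, 2.0, 0.0, -3.0, 1.0]))
        raw = pearson_r(x, y)
        part = partial_correlation(x, y, [z1, z2])
        assert part.r == pytest.approx(raw.r, abs=1e-9)

    def test_control_fully_explains(self):
        rng = np.random.default_rng(4)
        z1 = rng.standard_normal(20)
        z2 = rng.standard_normal(20)
        x = rng.standard_normal(20)
        y = z1.copy()
        res = partial_correlation(x, y, [z1, z2])
        assert res.r == pytest.approx(0.0, abs=1e-7) or np.isnan(res.r)

    def test_matches_pingouin_oracle(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((8, 4)), columns=list("xyab"))
        res = partial_correlation(df.x, df.y, [df.a, df.b])
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_controls_flagged(self):
        x = np.arange(10.0)
        y = np.arange(10.0)[::-1].copy()
        z = np.arange(10.0)
        res = partial_correlation(x, y, [z, 2 * z])
        assert res.flag == "collinear-controls"

    def test_no_controls_degenerates_to_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 30))
        assert partial_correlation(x, y).r == pearson_r(x, y).r


def _long_table(n_subjects, fail_subjects=(), sulcus="S_central", hemis=("lh", "rh")):
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n_subjects):
        subj = f"sub{i:02d}"
        for h in hemis:
            for s in SUPPORTED_SULCI:
                for metric, base in (("width", 3.0), ("depth", 10.0)):
                    failed = (
                        i in fail_subjects and s == sulcus and h == "lh"
                        and metric == "width"
                    )
                    rows.append(
                        {
                            "subject": subj,
                            "hemi": h,
                            "sulcus": s,
                            "metric": metric,
                            "value": np.nan if failed else base + rng.normal(0, 0.1),
                            "status": "discontinuous-region" if failed else "ok",
                        }
                    )
    return pd.DataFrame(rows)


class TestSummarizeCohort:
    def test_threshold_flags_failing_sulcus(self):
        wide, qc = summarize_cohort(_long_table(20, fail_subjects=(0, 1, 2)))
        assert qc["flagged_sulci"] == ["lh_S_central"]

    def test_no_failures_no_flags(self):
        wide, qc = summarize_cohort(_long_table(10))
        assert qc["flagged_sulci"] == []

    def test_mean_is_arithmetic_mean_of_16(self):
        wide, _ = summarize_cohort(_long_table(3))
        cols = [f"{h}_{s}_width" for h in ("lh", "rh") for s in SUPPORTED_SULCI]
        assert len(cols) == 16
        expected = wide[cols].mean(axis=1)
        pd.testing.assert_series_equal(
            wide["mean_width"], expected, check_names=False
        )

    def test_mean_requires_all_by_default(self):
        wide, _ = summarize_cohort(_long_table(20, fail_subjects=(0,)))
        assert np.isnan(wide.loc["sub00", "mean_width"])
        assert not np.isnan(wide.loc["sub01", "mean_width"])
        # opt-in mean over available measures
        wide2, _ = summarize_cohort(
            _long_table(20, fail_subjects=(0,)), mean_requires_all=False
        )
        assert not np.isnan(wide2.loc["sub00", "mean_width"])
        assert wide2.loc["sub00", "n_width_available"] == 15

    def test_failed_measures_are_nan_not_zero(self):
        wide, _ = summarize_cohort(_long_table(20, fail_subjects=(0,)))
        assert np.isnan(wide.loc["sub00", "lh_S_central_width"])
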