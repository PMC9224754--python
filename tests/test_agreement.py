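import numpy as np
import pandas as pd
import pytest

from gaitpipe.agreement import (
    PairedSample,
    bland_altman,
    compare_instruments,
    icc,
    mean_difference,
    rate_icc,
)
from gaitpipe.config import SimulationConfig
from gaitpipe.report import analyze_session
from gaitpipe.spatiotemporal import summarize_subject
from gaitpipe.synthetic import generate_cohort, generate_session


def sample(psw, mlmc, name="x", units="u"):
    return PairedSample(name, units, np.asarray(psw, float),
                        np.asarray(mlmc, float))


def anova_oracle(data):
    """Brute-force two-way ANOVA mean squares by explicit sum-of-squares."""
    n, k = data.shape
    grand = data.sum() / (n * k)
    ssr = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum((data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_oracle(data, form):
    n, k = data.shape
    msr, msc, mse = anova_oracle(data)
    if form == "3,1":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestMeanDifference:
    def test_identical_columns(self):
        md, sd, pct = mean_difference(sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert (md, sd, pct) == (0.0, 0.0, 0.0)

    def test_sign_convention_psw_minus_mlmc(self):
        md, _, pct = mean_difference(sample([0.12, 0.13], [0.13, 0.15]))
        assert md == pytest.approx(-0.015)
        assert md < 0  # walkway reads lower than motion capture
        assert pct == pytest.approx(100 * 0.015 / 0.125)

    def test_constant_offset(self):
        md, sd, _ = mean_difference(sample([1.3, 2.3, 3.3], [1.0, 2.0, 3.0]))
        assert md == pytest.approx(0.3)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_zero_psw_mean_percent_error_undefined(self):
        with pytest.warns(UserWarning, match="percent error"):
            _, _, pct = mean_difference(sample([-1.0, 1.0], [0.5, 0.5]))
        assert np.isnan(pct)


class TestBlandAltman:
    def test_identical_columns_all_zero(self):
        res = bland_altman(sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.mean_diff == res.loa_lower == res.loa_upper == 0.0

    def test_closed_form(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = bland_altman(sample(a, b))
        d = a - b
        assert res.mean_diff == pytest.approx(d.mean())
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1),
                                              abs=1e-9)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1),
                                              abs=1e-9)
        assert res.loa_lower <= res.mean_diff <= res.loa_upper

    def test_antisymmetry_under_column_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        fwd = bland_altman(sample(a, b))
        rev = bland_altman(sample(b, a))
        assert rev.mean_diff == -fwd.mean_diff
        assert rev.loa_lower == -fwd.loa_upper
        assert rev.loa_upper == -fwd.loa_lower


class TestICC:
    def test_identical_columns_unity(self):
        s = sample([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert icc(s, "2,1").estimate == pytest.approx(1.0)
        assert icc(s, "3,1").estimate == pytest.approx(1.0)

    def test_offset_consistency_vs_agreement(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = sample(base, base + 0.8)
        assert icc(s, "3,1").estimate == pytest.approx(1.0)
        assert icc(s, "2,1").estimate < 1.0

    def test_offset_invariance_of_consistency(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert icc(sample(a, b), "3,1").estimate == pytest.approx(
            icc(sample(a, b + 5.0), "3,1").estimate, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            data = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            s = sample(data[:, 0], data[:, 1])
            for form in ("2,1", "3,1"):
                assert abs(icc(s, form).estimate
                           - icc_oracle(data, form)) < 1e-10

    def test_consistency_geq_agreement_when_msc_geq_mse(self):
        # larger rater variance can only shrink the agreement denominator's
        # complement, so consistency dominates agreement whenever the
        # estimate is non-negative (MSR >= MSE) and MSC >= MSE
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(3, 10))
            data = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            s = sample(data[:, 0], data[:, 1])
            r21, r31 = icc(s, "2,1"), icc(s, "3,1")
            if r21.msc >= r21.mse and r21.msr >= r21.mse:
                assert r31.estimate >= r21.estimate - 1e-12
                checked += 1
        assert checked > 20

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(5, 15))
            data = rng.normal(size=(n, 2)) + 2 * rng.normal(size=(n, 1))
            s = sample(data[:, 0], data[:, 1])
            df = pd.DataFrame({
                "subj": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "y": data.reshape(-1),
            })
            ref = pg.intraclass_corr(df, "subj", "rater", "y").set_index("Type")
            mine21, mine31 = icc(s, "2,1"), icc(s, "3,1")
            assert mine21.estimate == pytest.approx(
                ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
            assert mine31.estimate == pytest.approx(
                ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
            # pingouin reports CIs rounded to 2 decimals
            np.testing.assert_allclose(
                [mine21.ci_lower, mine21.ci_upper],
                np.asarray(ref.loc["ICC(A,1)", "CI95"], float), atol=6e-3)
            np.testing.assert_allclose(
                [mine31.ci_lower, mine31.ci_upper],
                np.asarray(ref.loc["ICC(C,1)", "CI95"], float), atol=6e-3)

    def test_degenerate_zero_variance_flagged(self):
        s = sample([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        res = icc(s, "3,1")
        assert res.degenerate

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        for form in ("2,1", "3,1"):
            r = icc(sample(data[:, 0], data[:, 1]), form)
            assert r.ci_lower <= r.estimate <= r.ci_upper


class TestRating:
    @pytest.mark.parametrize("value,expected", [
        (0.997, "excellent"),
        (0.874, "good"),
        (0.45, "poor"),
        (0.5, "moderate"),
        (0.75, "good"),
        (0.9, "excellent"),
        (0.0, "poor"),
        (1.0, "excellent"),
        (-0.2, "poor"),
    ])
    def test_thresholds(self, value, expected):
        assert rate_icc(value) == expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            rate_icc(1.1)


def cohort_summaries(n, base, seed, latency=0.0):
    cfg = base.replace(contact_latency=latency)
    mls, psws = [], []
    for i, c in enumerate(generate_cohort(n, cfg, seed=seed)):
        ses = generate_session(c)
        a = analyze_session(ses.mlmc, ses.psw)
        mls.append(summarize_subject(a.mlmc_rows, f"s{i}", "SS", "MLMC"))
        psws.append(summarize_subject(a.psw_rows, f"s{i}", "SS", "PSW"))
    return psws, mls


@pytest.fixture(scope="module")
def zero_latency_results():
    psws, mls = cohort_summaries(8, SimulationConfig(n_passes=4), seed=21)
    return compare_instruments(psws, mls).to_frame().set_index("parameter")


class TestCompareInstruments:
    def test_zero_latency_mean_diffs_within_coarse_sample(self,
                                                          zero_latency_results):
        temporal = ["step_time", "stride_time", "stance_time", "swing_time",
                    "single_support_time", "double_support_1",
                    "double_support_2"]
        assert (zero_latency_results.loc[temporal, "mean_diff"].abs()
                <= 1.0 / 60.0).all()

    def test_zero_latency_headline_iccs_excellent(self, zero_latency_results):
        headline = ["cadence", "speed", "step_length", "stride_length",
                    "stride_width", "step_time", "stride_time"]
        assert (zero_latency_results.loc[headline, "icc21"] > 0.99).all()
        assert (zero_latency_results["icc31"] > 0.95).all()

    def test_latency_produces_stance_swing_sign_pattern(self):
        psws, mls = cohort_summaries(8, SimulationConfig(n_passes=4), seed=22,
                                     latency=0.02)
        df = compare_instruments(psws, mls).to_frame().set_index("parameter")
        assert df.loc["stance_time", "mean_diff"] < 0
        assert df.loc["swing_time", "mean_diff"] > 0
        assert abs(df.loc["stance_time", "mean_diff"]
                   + df.loc["swing_time", "mean_diff"]) < 5e-3
        assert abs(df.loc["stride_time", "mean_diff"]) < 5e-3
        # stride time excludes toe off, so its agreement stays excellent
        assert df.loc["stride_time", "icc31"] > 0.99

    def test_unmatched_subjects_error(self):
        psws, mls = cohort_summaries(3, SimulationConfig(n_passes=2), seed=23)
        with pytest.raises(ValueError, match="unmatched"):
            compare_instruments(psws[:2], mls)

    def test_single_subject_pairing_error(self):
        psws, mls = cohort_summaries(2, SimulationConfig(n_passes=2), seed=24)
        with pytest.raises(ValueError, match="at least 2"):
            compare_instruments(psws[:1], mls[:1])

    def test_summary_renders(self, zero_latency_results):
        psws, mls = cohort_summaries(2, SimulationConfig(n_passes=2), seed=25)
        text = compare_instruments(psws, mls).summary()
        assert "cadence" in text and "PSW" in text
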