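"""Association models: OR/HR estimation, diagnostics, agreement."""

import numpy as np
import pandas as pd
import pytest

from kneedxa import (
    SynthSpec,
    cohen_kappa,
    fit_coxph,
    fit_logistic,
    schoenfeld_check,
    sex_interaction,
    synth_cohort,
)
from kneedxa.association import ModelError


def _two_by_two(n_ec=10, n_en=20, n_uc=20, n_un=10) -> pd.DataFrame:
    rows = (
        [(1, 1)] * n_ec + [(1, 0)] * n_en + [(0, 1)] * n_uc + [(0, 0)] * n_un
    )
    return pd.DataFrame(rows, columns=["exposed", "case"])


class TestLogistic:
    def test_crude_or_equals_cross_product_ratio(self):
        res = fit_logistic(_two_by_two(), "case", "exposed")
        (r,) = res
        assert r.measure == "OR"
        assert r.estimate == pytest.approx(0.25, rel=1e-6)  # 10*10 / (20*20)
        assert r.ci_low < 0.25 < r.ci_high

    def test_uncorrelated_covariate_barely_moves_estimate(self, rng):
        n = 20000
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + np.log(2) * x)))).astype(int)
        z = rng.normal(size=n)  # independent of exposure and outcome
        df = pd.DataFrame({"exposed": x, "case": y, "z": z})
        crude = fit_logistic(df, "case", "exposed")[0]
        adjusted = fit_logistic(df, "case", "exposed", adjust=("z",))[0]
        assert np.log(adjusted.estimate) == pytest.approx(
            np.log(crude.estimate), abs=0.02
        )

    def test_separation_is_flagged_not_silent(self):
        df = pd.DataFrame({"exposed": [0] * 20 + [1] * 20,
                           "case": [0] * 20 + [1] * 20})
        (r,) = fit_logistic(df, "case", "exposed")
        assert r.flag is not None

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"exposed": [0, 1, 0, 1], "case": [0, 1, 2, 1]})
        with pytest.raises(ModelError):
            fit_logistic(df, "case", "exposed")


def _surv_frame(rng, n, log_hr, rate0=0.1, horizon=8.0):
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (rate0 * np.exp(log_hr * x)))
    return pd.DataFrame(
        {"exposed": x, "time": np.minimum(t, horizon), "event": (t <= horizon).astype(int)}
    )


class TestCox:
    def test_null_hazard_ratio_near_one(self, rng):
        df = _surv_frame(rng, 4000, log_hr=0.0)
        (r,) = fit_coxph(df, "time", "event", "exposed")
        assert r.ci_low < 1.0 < r.ci_high

    def test_known_hazard_ratio_recovered(self, rng):
        df = _surv_frame(rng, 20000, log_hr=np.log(3.0))
        (r,) = fit_coxph(df, "time", "event", "exposed")
        assert r.estimate == pytest.approx(3.0, rel=0.10)

    def test_time_rescaling_leaves_hr_unchanged(self, rng):
        df = _surv_frame(rng, 3000, log_hr=np.log(2.0))
        (r1,) = fit_coxph(df, "time", "event", "exposed")
        df2 = df.assign(time=df.time * 365.25)
        (r2,) = fit_coxph(df2, "time", "event", "exposed")
        assert r2.estimate == pytest.approx(r1.estimate, rel=1e-6)

    def test_zero_event_level_dropped_and_flagged(self, rng):
        df = _surv_frame(rng, 1000, log_hr=0.0)
        df["grade"] = rng.integers(0, 2, 1000)
        df.loc[df.index[:50], "grade"] = 2
        df.loc[df.grade == 2, "event"] = 0  # no events at level 2
        res = fit_coxph(df, "time", "event", "grade")
        by_level = {r.level: r for r in res}
        assert by_level["2"].flag is not None
        assert np.isfinite(by_level["1"].estimate)

    def test_non_positive_times_rejected(self):
        df = pd.DataFrame({"exposed": [0, 1], "time": [0.0, 1.0], "event": [1, 1]})
        with pytest.raises(ModelError):
            fit_coxph(df, "time", "event", "exposed")


class TestSchoenfeld:
    def test_single_covariate_yields_single_p(self, rng):
        df = _surv_frame(rng, 2000, log_hr=np.log(2.0))
        _, cph, X = fit_coxph(df, "time", "event", "exposed", return_fitter=True)
        p = schoenfeld_check(cph, X)
        assert list(p) == ["exposed_1"]
        assert 0.0 <= p["exposed_1"] <= 1.0

    def test_proportional_hazards_not_rejected_under_null(self, rng):
        # under proportional hazards the test should rarely fire
        rejections = 0
        for _ in range(20):
            df = _surv_frame(rng, 1500, log_hr=np.log(2.0))
            _, cph, X = fit_coxph(df, "time", "event", "exposed", return_fitter=True)
            rejections += schoenfeld_check(cph, X)["exposed_1"] < 0.01
        assert rejections <= 2

    def test_time_varying_effect_detected(self, rng):
        # hazard ratio that switches sign at t=1 violates proportionality
        n = 5000
        x = rng.integers(0, 2, n)
        t1 = rng.exponential(1.0 / (0.5 * np.exp(np.log(4.0) * x)))
        t = np.where(
            t1 <= 1.0, t1, 1.0 + rng.exponential(1.0 / (0.5 * np.exp(-np.log(4.0) * x)))
        )
        df = pd.DataFrame({"exposed": x, "time": t, "event": np.ones(n, int)})
        _, cph, X = fit_coxph(df, "time", "event", "exposed", return_fitter=True)
        assert schoenfeld_check(cph, X)["exposed_1"] < 0.01


class TestSexInteraction:
    def test_single_sex_data_rejected(self):
        df = pd.DataFrame(
            {"sex": ["female"] * 10, "exposed": [0, 1] * 5, "case": [0, 1] * 5}
        )
        with pytest.raises(ModelError):
            sex_interaction(df, "case", "exposed")

    def test_differential_effect_detected(self, rng):
        # effects differing by log 2 between sexes at n=20000
        n = 20000
        female = rng.random(n) < 0.5
        x = rng.integers(0, 2, n)
        beta = np.where(female, np.log(1.5), np.log(3.0))
        p = 1 / (1 + np.exp(-(-1.5 + beta * x)))
        df = pd.DataFrame(
            {
                "sex": np.where(female, "female", "male"),
                "exposed": x,
                "case": (rng.random(n) < p).astype(int),
            }
        )
        pint = sex_interaction(df, "case", "exposed")
        assert pint["1"] < 0.05

    def test_equal_effects_yield_non_small_p_typically(self):
        df = synth_cohort(SynthSpec(n_subjects=20000), seed=31)
        pint = sex_interaction(df, "pain", "rkoa_grade_collapsed")
        assert all(0.0 <= v <= 1.0 for v in pint.values())


class TestCohenKappa:
    def test_identical_sequences(self):
        assert cohen_kappa([1, 2, 3, 1], [1, 2, 3, 1]) == 1.0

    def test_independent_labels_near_zero(self, rng):
        a = rng.integers(0, 3, 10000)
        b = rng.integers(0, 3, 10000)
        assert abs(cohen_kappa(a.tolist(), b.tolist())) < 0.05

    def test_hand_computed_two_by_two_table(self):
        # 45/100 agree on each category, 5+5 disagree: po=0.9, pe=0.5, k=0.8
        a = [0] * 50 + [1] * 50
        b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
        po = sum(x == y for x, y in zip(a, b)) / 100
        pe = 0.5 * 0.5 + 0.5 * 0.5
        assert cohen_kappa(a, b) == pytest.approx((po - pe) / (1 - pe))
        assert cohen_kappa(a, b) == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohen_kappa([1, 2], [1, 2, 3])
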