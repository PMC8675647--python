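"""Psychometric threshold estimation and model-free behavioral analyses."""

import numpy as np
import pandas as pd
import pytest

from subjopt.task import TaskSpec, ValueParams
from subjopt.behavior import (
    fit_psychometric,
    fit_empirical_thresholds,
    threshold_interval,
    rt_difficulty_profile,
    split_half_thresholds,
    lagged_choice_regression,
    DegenerateFitError,
)
from subjopt.models import subjective_thresholds
from subjopt.synth import simulate_agent_dataset
from subjopt.rivals import simulate_regret


def _bernoulli_trials(theta, s, n, rng):
    v = rng.integers(0, 151, size=n)
    acc = rng.random(n) < (1 - 0.5 * (1 + np.array([np.math.erf((theta - x) / (s * np.sqrt(2))) for x in v])))
    return v, acc


class TestPsychometricFit:
    def test_recovers_known_threshold(self):
        rng = np.random.default_rng(0)
        from scipy.stats import norm

        v = rng.integers(0, 151, size=200)
        acc = rng.random(200) < norm.cdf((v - 80.0) / 10.0)
        fit = fit_psychometric(v, acc, 1)
        assert fit.threshold == pytest.approx(80.0, abs=3.0)
        assert fit.variability == pytest.approx(10.0, abs=4.0)

    def test_separated_data_step_limit(self):
        v = np.arange(0, 151)
        acc = v > 90
        fit = fit_psychometric(v, acc, 1)
        assert fit.threshold == pytest.approx(90.5, abs=0.6)
        assert fit.variability == pytest.approx(0.5, abs=0.1)  # floor

    def test_invariant_to_duplicating_trials(self):
        rng = np.random.default_rng(3)
        from scipy.stats import norm

        v = rng.integers(0, 151, size=150)
        acc = rng.random(150) < norm.cdf((v - 75.0) / 12.0)
        f1 = fit_psychometric(v, acc, 1)
        f2 = fit_psychometric(np.tile(v, 2), np.tile(acc, 2), 1)
        assert f2.threshold == pytest.approx(f1.threshold, abs=1e-3)
        assert f2.variability == pytest.approx(f1.variability, abs=1e-3)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        from scipy.stats import norm

        v = rng.integers(0, 131, size=200).astype(float)
        acc = rng.random(200) < norm.cdf((v - 70.0) / 10.0)
        f1 = fit_psychometric(v, acc, 1)
        f2 = fit_psychometric(v + 20.0, acc, 1)
        assert f2.threshold == pytest.approx(f1.threshold + 20.0, abs=0.2)

    def test_single_category_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_psychometric(np.arange(20), np.ones(20, bool), 1)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            fit_psychometric(np.arange(5), np.array([0, 1, 0, 1, 0], bool), 1)


class TestEmpiricalThresholds:
    def test_recovers_generating_schedule(self, small_dataset, fig2_params):
        fits = fit_empirical_thresholds(small_dataset)
        sched = subjective_thresholds(TaskSpec(K=5), fig2_params)
        assert len(fits) == 4
        for f in fits:
            se = 2 * f.variability / np.sqrt(f.n)
            assert f.threshold == pytest.approx(
                sched[f.opportunity], abs=max(5.0, 3 * se)
            )

    def test_concave_on_subjective_data(self):
        """Second differences of empirical thresholds trend negative on
        subjective-model synthetic cohorts."""
        d2s = []
        for seed in range(6):
            df = simulate_agent_dataset(
                ValueParams(r=110.51, rho=0.62, s=10.0), "subjective",
                TaskSpec(K=5, n_rounds=200), np.random.default_rng(seed),
            )
            fits = {f.opportunity: f.threshold for f in fit_empirical_thresholds(df)}
            th = np.array([fits[i] for i in sorted(fits)])
            d2s.append(np.diff(np.diff(th)).mean())
        assert np.mean(d2s) < 0


class TestThresholdInterval:
    def test_contains_point_estimate(self, small_dataset):
        g = small_dataset[
            (small_dataset["opportunity"] == 2) & (~small_dataset["forced"])
        ]
        fit = fit_psychometric(g["value"], g["choice"] == "accept", 2)
        lo, hi = threshold_interval(g["value"], g["choice"] == "accept")
        assert lo <= fit.threshold <= hi

    def test_coverage_near_nominal(self):
        """95% HDI covers the true threshold about 95% of the time."""
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            v = rng.integers(0, 151, size=150)
            acc = rng.random(150) < norm.cdf((v - 75.0) / 12.0)
            lo, hi = threshold_interval(v, acc)
            hits += lo <= 75.0 <= hi
        assert hits / n_rep >= 0.85

    def test_width_shrinks_with_n(self):
        from scipy.stats import norm

        rng = np.random.default_rng(8)
        widths = []
        for n in (100, 400):
            v = rng.integers(0, 151, size=n)
            acc = rng.random(n) < norm.cdf((v - 75.0) / 12.0)
            lo, hi = threshold_interval(v, acc)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestRTProfile:
    def test_peak_at_zero_difficulty(self, small_dataset, fig2_params):
        sched = subjective_thresholds(TaskSpec(K=5), fig2_params)
        th = {i: sched[i] for i in range(1, 5)}
        prof = rt_difficulty_profile(small_dataset, th)
        best = prof.loc[prof["mean_rt"].idxmax(), "bin_center"]
        assert abs(best) <= 15.0

    def test_empty_bins_are_nan(self, small_dataset, fig2_params):
        sched = subjective_thresholds(TaskSpec(K=5), fig2_params)
        th = {i: sched[i] for i in range(1, 5)}
        prof = rt_difficulty_profile(small_dataset, th, min_per_bin=10**6)
        assert prof["mean_rt"].isna().all()
        assert (prof["mean_rt"].fillna(-1) != 0).all()

    def test_missing_rt_rejected(self, small_dataset):
        df = small_dataset.copy()
        df["rt_ms"] = np.nan
        with pytest.raises(ValueError):
            rt_difficulty_profile(df, {1: 100.0})


class TestSplitHalf:
    def test_stationary_agent_centered_at_zero(self):
        diffs = []
        for seed in range(8):
            df = simulate_agent_dataset(
                ValueParams(r=105.0, rho=0.7, s=10.0), "subjective",
                TaskSpec(K=5, n_rounds=200), np.random.default_rng(seed + 50),
            )
            res = split_half_thresholds(df)
            diffs.extend(res["difference"].values())
        assert abs(np.mean(diffs)) < 3.0

    def test_drifting_agent_detected(self):
        """An agent whose threshold rises 20 units mid-session shows a
        clearly positive second-minus-first difference."""
        rng = np.random.default_rng(9)
        spec = TaskSpec(K=5, n_rounds=100)
        lo = simulate_agent_dataset({"c": 75.0, "s": 10.0}, "constant", spec, rng)
        hi = simulate_agent_dataset({"c": 95.0, "s": 10.0}, "constant", spec, rng)
        hi = hi.assign(round=hi["round"] + 100)
        df = pd.concat([lo, hi], ignore_index=True)
        res = split_half_thresholds(df)
        assert np.mean(list(res["difference"].values())) > 10.0

    def test_odd_round_count_first_half_larger(self):
        rng = np.random.default_rng(10)
        df = simulate_agent_dataset(
            {"c": 80.0, "s": 12.0}, "constant", TaskSpec(K=5, n_rounds=101), rng
        )
        res = split_half_thresholds(df)
        n1 = res["first"][0].n + 0  # fits exist; halves split 51/50 rounds
        assert df[df["round"] <= 51]["round"].nunique() == 51
        assert df[df["round"] > 51]["round"].nunique() == 50

    def test_too_few_rounds_rejected(self):
        rng = np.random.default_rng(11)
        df = simulate_agent_dataset(
            {"c": 80.0, "s": 12.0}, "constant", TaskSpec(K=5, n_rounds=20), rng
        )
        with pytest.raises(ValueError):
            split_half_thresholds(df)


class TestLaggedRegression:
    def test_memoryless_agent_lag_near_zero(self):
        zs = []
        for seed in range(5):
            df = simulate_agent_dataset(
                ValueParams(r=75.0, rho=1.0, s=10.0), "subjective",
                TaskSpec(K=5, n_rounds=200), np.random.default_rng(seed + 70),
            )
            res = lagged_choice_regression(df)
            for i, d in res.items():
                for name, c in d["coef"].items():
                    if name.startswith("lag"):
                        zs.append(c / d["se"][name])
        zs = np.array(zs)
        assert np.mean(np.abs(zs) < 2) >= 0.85

    def test_current_value_coefficient_positive(self, small_dataset):
        res = lagged_choice_regression(small_dataset)
        assert res  # at least one opportunity fitted
        for d in res.values():
            assert d["coef"]["current"] > 0

    def test_regret_agent_earlier_lags_weigh_more(self):
        """Regret data: negative lag effects, with earlier opportunities
        weighted at least as strongly as the most recent one."""
        res = simulate_regret(TaskSpec(K=5), n_rounds=8000, n_reps=1, seed=21)[0]
        reg = lagged_choice_regression(res.data)
        d = reg[4]  # fourth opportunity: lags 1..3 available
        lags = {k: v for k, v in d["coef"].items() if k.startswith("lag")}
        assert all(v < 0 for v in lags.values())
        # lag3 (earliest, opportunity 1) at least as negative as lag1
        assert d["coef"]["lag3"] <= d["coef"]["lag1"] + 1e-6
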