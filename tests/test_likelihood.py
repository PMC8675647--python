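"""Choice likelihood, AIC/LRT comparison, and cross-context prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import log_ndtr
from scipy.stats import norm

from subjopt.task import TaskSpec, ValueParams
from subjopt.models import optimal_thresholds, subjective_thresholds, expected_round_payoff
from subjopt.likelihood import (
    accept_probability,
    dataset_loglik,
    fit_subjects_ml,
    aic,
    compare_models,
    likelihood_ratio_test,
    predict_context_thresholds,
    FitResult,
)
from subjopt.synth import simulate_agent_dataset


class TestAcceptProbability:
    def test_half_at_threshold(self):
        assert accept_probability(80.0, 80.0, 12.0) == pytest.approx(0.5)

    def test_complement_sums_to_one(self):
        p = accept_probability(93.0, 80.0, 12.0)
        q = accept_probability(80.0 + (80.0 - 93.0), 80.0, 12.0)  # mirror
        assert p + q == pytest.approx(1.0)

    def test_one_sd_above(self):
        assert accept_probability(92.0, 80.0, 12.0) == pytest.approx(
            norm.cdf(1.0), abs=1e-12
        )

    def test_nonpositive_s_rejected(self):
        with pytest.raises(ValueError):
            accept_probability(80, 80, 0.0)


class TestDatasetLoglik:
    def test_empty_dataset_gives_zero(self):
        df = pd.DataFrame(
            columns=["subject_id", "K", "round", "opportunity", "value",
                     "choice", "rt_ms", "forced"]
        )
        assert dataset_loglik(df, "optimal", {"s": 10.0}) == 0.0

    def test_single_accept_at_threshold(self):
        df = pd.DataFrame(
            [{"subject_id": "a", "K": 5, "round": 1, "opportunity": 1,
              "value": 110, "choice": "accept", "rt_ms": np.nan,
              "forced": False}]
        )
        # optimal theta[1] = 110 at K = 5
        assert dataset_loglik(df, "optimal", {"s": 8.0}) == pytest.approx(
            np.log(0.5)
        )

    def test_matches_row_by_row_oracle(self, small_dataset, fig2_params):
        """Vectorized likelihood equals a naive per-row summation."""
        df = small_dataset.head(120)
        params = {"r": 110.51, "rho": 0.62, "s": 10.0}
        got = dataset_loglik(df, "subjective", params)
        theta = subjective_thresholds(TaskSpec(K=5), fig2_params).theta
        expect = 0.0
        for _, row in df.iterrows():
            if row["forced"]:
                continue
            z = (row["value"] - theta[row["opportunity"] - 1]) / 10.0
            expect += log_ndtr(z) if row["choice"] == "accept" else log_ndtr(-z)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_invariant_to_row_order(self, small_dataset):
        params = {"r": 110.51, "rho": 0.62, "s": 10.0}
        a = dataset_loglik(small_dataset, "subjective", params)
        shuffled = small_dataset.sample(frac=1.0, random_state=0)
        b = dataset_loglik(shuffled, "subjective", params)
        assert a == pytest.approx(b, abs=1e-10)

    def test_unforced_row_at_k_rejected(self):
        df = pd.DataFrame(
            [{"subject_id": "a", "K": 5, "round": 1, "opportunity": 5,
              "value": 10, "choice": "reject", "rt_ms": np.nan,
              "forced": False}]
        )
        with pytest.raises(ValueError):
            dataset_loglik(df, "optimal", {"s": 10.0})


class TestModelComparison:
    def test_aic_arithmetic(self):
        assert aic(-100.0, 3) == 206.0

    def test_identical_fits_give_zero_delta(self):
        f = FitResult("constant", ["a", "b"], {}, {"a": -50.0, "b": -60.0}, 2)
        res = compare_models(f, f, n_boot=200, rng=1)
        assert res["mean"] == 0.0
        assert res["ci95"] == (0.0, 0.0)

    def test_subject_mismatch_rejected(self):
        fa = FitResult("constant", ["a"], {}, {"a": -50.0}, 2)
        fb = FitResult("linear", ["b"], {}, {"b": -50.0}, 3)
        with pytest.raises(ValueError):
            compare_models(fa, fb)

    def test_lrt_basics(self):
        fn = FitResult("constant", ["a"], {}, {"a": -100.0}, 2)
        ff = FitResult("linear", ["a"], {}, {"a": -100.0}, 3)
        res = likelihood_ratio_test(fn, ff)
        assert res["statistic"] == 0.0
        assert res["df"] == 1
        assert res["p"] == pytest.approx(1.0)

    def test_non_nested_pair_rejected(self):
        fa = FitResult("linear", ["a"], {}, {"a": -100.0}, 3)
        fb = FitResult("subjective", ["a"], {}, {"a": -100.0}, 3)
        with pytest.raises(ValueError):
            likelihood_ratio_test(fa, fb)

    def test_ml_fit_recovers_constant_agent(self):
        rng = np.random.default_rng(5)
        spec = TaskSpec(K=5, n_rounds=200)
        df = simulate_agent_dataset({"c": 85.0, "s": 10.0}, "constant", spec, rng)
        fit = fit_subjects_ml(df, "constant")
        p = fit.params["s01"]
        assert p["c"] == pytest.approx(85.0, abs=4.0)
        assert p["s"] == pytest.approx(10.0, abs=3.0)
        assert fit.k == 2

    def test_useless_extra_parameter_costs_about_two_aic(self):
        """Fitting the cost-augmented model on no-cost data pays ~2 AIC."""
        rng = np.random.default_rng(11)
        spec = TaskSpec(K=5, n_rounds=200)
        deltas = []
        for seed in range(4):
            df = simulate_agent_dataset(
                ValueParams(r=100.0, rho=0.8, s=10.0), "subjective", spec,
                np.random.default_rng(seed), subject_id=f"s{seed}",
            )
            f_small = fit_subjects_ml(df, "subjective")
            f_big = fit_subjects_ml(df, "subjective_cost")
            subj = f"s{seed}"
            deltas.append(f_big.aic[subj] - f_small.aic[subj])
        # extra parameter buys < 1 loglik on average: Delta-AIC near +2
        assert 0.0 <= np.mean(deltas) <= 4.0


class TestGeneratingModelWins:
    @pytest.mark.parametrize("gen_tag,gen_params", [
        ("constant", {"c": 85.0, "s": 10.0}),
        ("subjective", ValueParams(r=110.51, rho=0.62, s=10.0)),
    ])
    def test_aic_prefers_generating_model(self, gen_tag, gen_params):
        """AIC ranks the generating model best (or tied) among rivals on
        cohorts it generated."""
        spec = TaskSpec(K=5, n_rounds=200)
        wins = 0
        n_cohorts = 3
        for seed in range(n_cohorts):
            frames = [
                simulate_agent_dataset(gen_params, gen_tag, spec,
                                       np.random.default_rng(100 * seed + j),
                                       subject_id=f"s{j}")
                for j in range(3)
            ]
            df = pd.concat(frames, ignore_index=True)
            mean_aic = {}
            for tag in ("constant", "linear", "subjective"):
                f = fit_subjects_ml(df, tag)
                mean_aic[tag] = np.mean(list(f.aic.values()))
            best = min(mean_aic, key=mean_aic.get)
            # the generating model wins outright or within the AIC penalty
            # of one extra parameter of the winner
            wins += (best == gen_tag) or (
                mean_aic[gen_tag] <= mean_aic[best] + 2.0
            )
        assert wins >= n_cohorts - 1


class TestContextPrediction:
    def test_same_context_zero_shift(self):
        params = [{"r": 110.51, "rho": 0.62}]
        res = predict_context_thresholds(params, 5, 5, n_draws=50, rng=0)
        assert res["shift"] == 0.0
        model_th = subjective_thresholds(
            TaskSpec(K=5), ValueParams(r=110.51, rho=0.62, s=10.0)
        )[4]
        assert res["prediction"] == pytest.approx(model_th)

    def test_scarce_context_prediction_is_lower(self):
        params = [{"r": 110.51, "rho": 0.62}]
        res = predict_context_thresholds(params, 5, 2, n_draws=100, rng=0)
        th_k5_4th = subjective_thresholds(
            TaskSpec(K=5), ValueParams(r=110.51, rho=0.62, s=10.0)
        )[4]
        assert res["shift"] < 0
        assert res["prediction"] < th_k5_4th

    def test_point_inside_own_interval(self):
        rng = np.random.default_rng(2)
        params = [
            {"r": float(r), "rho": float(t)}
            for r, t in zip(rng.uniform(80, 130, 15), rng.uniform(0.3, 1.2, 15))
        ]
        res = predict_context_thresholds(params, 5, 10, n_draws=500, rng=3)
        lo, hi = res["ci95"]
        assert lo <= res["prediction"] <= hi

    def test_shift_equals_payoff_difference(self):
        res = predict_context_thresholds(
            [{"r": 100.0, "rho": 0.8}], 5, 2, n_draws=10, rng=0
        )
        e2 = expected_round_payoff(optimal_thresholds(TaskSpec(K=2)), TaskSpec(K=2))
        e5 = expected_round_payoff(optimal_thresholds(TaskSpec(K=5)), TaskSpec(K=5))
        assert res["shift"] == pytest.approx(e2 - e5)
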