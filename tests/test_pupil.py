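"""Pupillometry preprocessing, epoching, and cluster statistics."""

import numpy as np
import pandas as pd
import pytest

from subjopt.task import TaskSpec, ValueParams
from subjopt.models import optimal_thresholds
from subjopt.synth import EffectSpec, simulate_agent_dataset, generate_pupil_session
from subjopt.pupil import (
    PupilSession,
    preprocess_pupil,
    epoch_pupil,
    cluster_permutation_test,
    peak_difficulty_regression,
    sensitivity_pupil_profile,
    local_regression,
    read_pupil,
    write_pupil,
)


def _session(seed=0, n_rounds=40, effects=None, rho=1.0):
    rng = np.random.default_rng(seed)
    df = simulate_agent_dataset(
        ValueParams(r=100, rho=0.8, s=10), "subjective",
        TaskSpec(K=5, n_rounds=n_rounds), rng,
    )
    eff = effects or EffectSpec(accept_amp=0.3, blink_rate=8, noise_sd=0.3)
    return df, generate_pupil_session(df, eff, np.random.default_rng(seed + 1000),
                                      rho=rho)


class TestPreprocess:
    def test_constant_input_near_zero_after_bandpass(self):
        n = 200_000
        t = np.arange(n) * 2.0
        ev = pd.DataFrame({"time_ms": [1000.0], "event": ["stimulus"],
                           "event_id": [0]})
        sess = PupilSession(fs=500, time_ms=t, left=np.full(n, 5.0),
                            right=np.full(n, 5.0), blinks=[], saccades=[],
                            events=ev)
        out = preprocess_pupil(sess)
        # z-scoring a flat residual is numerically guarded, not amplified
        assert np.all(np.isfinite(out.pupil))
        assert not out.excluded

    def test_blink_bridge_and_mask_padding(self):
        n = 50_000
        t = np.arange(n) * 2.0
        sig = np.sin(2 * np.pi * 0.5 * np.arange(n) / 500.0)
        left = sig.copy()
        left[10_000:10_100] = -4.0  # 200 ms artifact at 20 s
        ev = pd.DataFrame({"time_ms": [1000.0], "event": ["stimulus"],
                           "event_id": [0]})
        sess = PupilSession(fs=500, time_ms=t, left=left, right=sig.copy(),
                            blinks=[(20_000.0, 20_200.0)], saccades=[],
                            events=ev)
        out = preprocess_pupil(sess)
        # mask covers blink plus 150 ms padding each side
        lo = np.searchsorted(t, 20_000.0 - 150.0)
        hi = np.searchsorted(t, 20_200.0 + 150.0)
        assert out.interp_mask[lo:hi].all()
        assert not out.interp_mask[: lo - 5].any()
        # the -4 artifact is gone from the cleaned trace
        assert out.pupil[lo:hi].min() > -3.0

    def test_exclusion_verdict_over_half_masked(self):
        n = 20_000
        t = np.arange(n) * 2.0
        ev = pd.DataFrame({"time_ms": [1000.0], "event": ["stimulus"],
                           "event_id": [0]})
        rng = np.random.default_rng(0)
        sess = PupilSession(fs=500, time_ms=t,
                            left=rng.normal(size=n), right=rng.normal(size=n),
                            blinks=[(0.0, 25_000.0)], saccades=[], events=ev)
        out = preprocess_pupil(sess)
        assert out.interp_fraction > 0.5
        assert out.excluded

    def test_mask_idempotent(self):
        _, sess = _session(1)
        a = preprocess_pupil(sess)
        resess = PupilSession(fs=sess.fs, time_ms=sess.time_ms, left=a.pupil,
                              right=a.pupil, blinks=sess.blinks,
                              saccades=sess.saccades, events=sess.events)
        b = preprocess_pupil(resess)
        assert np.array_equal(a.interp_mask, b.interp_mask)

    def test_wrong_sampling_rate_rejected(self):
        ev = pd.DataFrame({"time_ms": [1.0], "event": ["stimulus"],
                           "event_id": [0]})
        sess = PupilSession(fs=250, time_ms=np.arange(100.0),
                            left=np.zeros(100), right=np.zeros(100),
                            blinks=[], saccades=[], events=ev)
        with pytest.raises(ValueError):
            preprocess_pupil(sess)


class TestEpoching:
    def test_epoch_geometry_and_baseline(self):
        df, sess = _session(2)
        clean = preprocess_pupil(sess)
        ep = epoch_pupil(clean, sess.events, sess.trial_meta)
        assert ep.data.shape == (len(df), 851)
        assert ep.times_ms[0] == -200.0 and ep.times_ms[-1] == 1500.0
        base = (ep.times_ms >= -20.0) & (ep.times_ms <= 20.0)
        inc = ep.included
        assert np.allclose(np.nanmean(ep.data[inc][:, base], axis=1), 0.0,
                           atol=1e-9)

    def test_bookkeeping_counts(self):
        df, sess = _session(3)
        clean = preprocess_pupil(sess)
        ep = epoch_pupil(clean, sess.events, sess.trial_meta)
        assert len(ep.meta) == len(df)
        assert ep.included.sum() == len(df) - ep.meta["excluded"].sum()


class TestClusterTest:
    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(0)
        D = np.zeros((8, 100))
        D += rng.normal(0, 1e-12, D.shape)  # numerically non-constant
        res = cluster_permutation_test(D + rng.normal(0, 1.0, D.shape) * 0.0
                                       + rng.normal(0, 1, (8, 1)) * 0.0
                                       + rng.normal(0, 1, (8, 100)),
                                       n_perm=200, seed=1)
        # white noise: any cluster found should not be significant
        assert all(c["p"] > 0.05 for c in res.clusters) or not res.clusters

    def test_constant_curves_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.ones((6, 50)), n_perm=100)

    def test_injected_effect_detected_with_correct_extent(self):
        rng = np.random.default_rng(2)
        D = rng.normal(0, 1.0, (10, 200))
        D[:, 80:140] += 1.5
        res = cluster_permutation_test(D, n_perm=500, seed=3)
        sig = res.significant
        assert sig
        best = max(sig, key=lambda c: abs(c["mass"]))
        assert best["start"] <= 95 and best["stop"] >= 110  # overlaps injection

    def test_bit_reproducible(self):
        rng = np.random.default_rng(4)
        D = rng.normal(0, 1, (8, 120))
        a = cluster_permutation_test(D, n_perm=300, seed=9)
        b = cluster_permutation_test(D, n_perm=300, seed=9)
        assert a.clusters == b.clusters

    def test_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.random.default_rng(0).normal(size=(3, 50)))


def _epoch_cohort(n_subj, effects, seed0=100, n_rounds=30, rho_by_subj=None):
    sets, thresholds = {}, {}
    opt = optimal_thresholds(TaskSpec(K=5))
    for k in range(n_subj):
        rho = rho_by_subj[k] if rho_by_subj is not None else 1.0
        rng = np.random.default_rng(seed0 + k)
        df = simulate_agent_dataset(
            ValueParams(r=100, rho=0.8, s=10), "subjective",
            TaskSpec(K=5, n_rounds=n_rounds), rng,
        )
        sess = generate_pupil_session(df, effects,
                                      np.random.default_rng(seed0 + 500 + k),
                                      rho=rho)
        clean = preprocess_pupil(sess)
        ep = epoch_pupil(clean, sess.events, sess.trial_meta)
        subj = f"p{k:02d}"
        sets[subj] = ep
        thresholds[subj] = {i: opt[i] for i in range(1, 5)}
    return sets, thresholds


class TestDifficultyRegression:
    def test_negative_slope_recovered(self):
        eff = EffectSpec(difficulty_slope=0.02, accept_amp=0.1,
                         blink_rate=5, noise_sd=0.25)
        sets, th = _epoch_cohort(8, eff, seed0=200, n_rounds=40)
        res = peak_difficulty_regression(sets, th)
        assert res["group_slope"] < 0
        assert res["p"] < 0.05

    def test_flat_generator_slope_near_zero(self):
        eff = EffectSpec(difficulty_slope=0.0, accept_amp=0.0,
                         blink_rate=5, noise_sd=0.25)
        sets, th = _epoch_cohort(8, eff, seed0=300, n_rounds=40)
        res = peak_difficulty_regression(sets, th)
        assert abs(res["group_slope"]) < 0.01 or res["p"] > 0.05

    def test_at_1500ms_same_sign_as_peak(self):
        eff = EffectSpec(difficulty_slope=0.02, accept_amp=0.1,
                         blink_rate=5, noise_sd=0.25)
        sets, th = _epoch_cohort(8, eff, seed0=200, n_rounds=40)
        res_peak = peak_difficulty_regression(sets, th, use_peak=True)
        res_late = peak_difficulty_regression(sets, th, use_peak=False)
        assert np.sign(res_peak["group_slope"]) == np.sign(res_late["group_slope"])

    def test_window_rule_excludes_out_of_range(self):
        eff = EffectSpec(blink_rate=5, noise_sd=0.25)
        sets, th = _epoch_cohort(5, eff, seed0=400, n_rounds=25)
        res = peak_difficulty_regression(sets, th)
        # every used epoch respects the signed-difficulty windows
        for _, row in res["per_subject"].iterrows():
            assert row["n"] >= 5


class TestSensitivityProfile:
    def test_coupling_detected(self):
        rhos = np.linspace(0.2, 1.8, 10)
        eff = EffectSpec(coupling=0.5, blink_rate=5, noise_sd=0.2)
        sets, th = _epoch_cohort(10, eff, seed0=500, n_rounds=30,
                                 rho_by_subj=rhos)
        sens = {f"p{k:02d}": rhos[k] for k in range(10)}
        res = sensitivity_pupil_profile(sets, th, sens, n_perm=300, seed=1)
        assert res["clusters"].significant
        # high-sensitivity group dilates more overall
        valid = ~np.isnan(res["high_group"]) & ~np.isnan(res["low_group"])
        assert np.nanmean(res["high_group"][valid] - res["low_group"][valid]) > 0

    def test_too_few_subjects_refused(self):
        with pytest.raises(ValueError):
            sensitivity_pupil_profile({f"p{k}": None for k in range(5)}, {}, {})

    def test_local_regression_fits_smooth_function(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-90, 60, 600)
        y = 0.001 * x ** 2 + 0.02 * x + rng.normal(0, 0.05, 600)
        grid = np.arange(-80.0, 51.0, 10.0)
        fit = local_regression(x, y, grid, bandwidth=30.0)
        truth = 0.001 * grid ** 2 + 0.02 * grid
        assert np.nanmax(np.abs(fit - truth)) < 0.08


class TestSessionIO:
    def test_tsv_roundtrip(self, tmp_path):
        _, sess = _session(7, n_rounds=10)
        path = tmp_path / "session.tsv"
        write_pupil(sess, path)
        back = read_pupil(path)
        assert np.allclose(back.left, sess.left)
        assert np.allclose(back.right, sess.right)
        assert len(back.events) == len(sess.events)
        assert len(back.blinks) == len(sess.blinks)
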