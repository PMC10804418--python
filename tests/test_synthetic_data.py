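import numpy as np
import pandas as pd
import pytest

from vmdcm import dcm_core as dcm
from vmdcm import synthetic_data as gen
from vmdcm.behavior import compute_rmse


class TestTaskSchedule:
    def test_three_sessions_block_counts(self):
        scheds = gen.generate_task_schedule(3, seed=0)
        conds = [c for s in scheds for c in s.conditions]
        assert len(conds) == 18
        assert conds.count("TT") == 9 and conds.count("TTNF") == 9
        for s in scheds:
            assert s.conditions.count("TT") == 3
            assert all(d == 21.0 for _, _, d in s.blocks)

    def test_session_span_and_gaps(self):
        (s,) = gen.generate_task_schedule(1, seed=5)
        onsets = [o for _, o, _ in s.blocks]
        span = onsets[-1] + 21.0 - onsets[0]
        assert span == pytest.approx(6 * 21 + 5 * 15)
        gaps = np.diff(onsets)
        assert np.allclose(gaps, 21 + 15)
        # schedule conservation: 126 task seconds, split equally by condition
        per_cond = {c: sum(d for cc, _, d in s.blocks if cc == c)
                    for c in ("TT", "TTNF")}
        assert per_cond["TT"] == per_cond["TTNF"] == 63.0

    def test_order_varies_with_seed(self):
        orders = {tuple(gen.generate_task_schedule(1, seed=s)[0].conditions)
                  for s in range(10)}
        assert len(orders) >= 2

    def test_rejects_bad_session_count(self):
        with pytest.raises(ValueError):
            gen.generate_task_schedule(0, seed=0)

    def test_input_functions_are_boxcars(self):
        (s,) = gen.generate_task_schedule(1, seed=1)
        t, U = s.input_functions()
        assert set(np.unique(U)) <= {0.0, 1.0}
        # never both conditions at once; 21 s of each block per box-car
        assert (U.sum(axis=1) <= 1).all()
        dt = s.microtime_dt
        for col, cond in ((0, "TTNF"), (1, "TT")):
            # block edges are quantized to the microtime grid (one bin each)
            assert U[:, col].sum() * dt == pytest.approx(63.0, abs=3 * dt)


class TestTargetTrace:
    def test_block_sample_count_and_bounds(self, two_block_schedule):
        tr = gen.generate_target_trace(two_block_schedule, jitter_max_px=0,
                                       seed=0)
        in_block = tr.condition != "rest"
        assert in_block.sum() == 2 * 630            # 21 s x 30 Hz per block
        assert tr.target_px.min() >= 200 and tr.target_px.max() <= 600

    def test_zero_jitter_steps_are_exactly_25(self, two_block_schedule):
        tr = gen.generate_target_trace(two_block_schedule, jitter_max_px=0,
                                       seed=3)
        steps = np.abs(np.diff(tr.target_px))
        moving = steps > 0
        inner = (tr.target_px[1:] > 200) & (tr.target_px[1:] < 600)
        assert np.allclose(steps[moving & inner], 25.0)

    def test_jitter_bounded(self, two_block_schedule):
        tr = gen.generate_target_trace(two_block_schedule, seed=4)
        steps = np.abs(np.diff(tr.target_px))
        inner = (tr.target_px[1:] > 200) & (tr.target_px[1:] < 600)
        moving = (steps > 0) & inner
        assert steps[moving].min() >= 25.0 - 1e-9
        assert steps[moving].max() <= 27.0 + 1e-9

    def test_reverses_at_bounds(self, two_block_schedule):
        tr = gen.generate_target_trace(two_block_schedule, seed=0)
        d = np.sign(np.diff(tr.target_px))
        reversals = np.sum((d[:-1] > 0) & (d[1:] < 0))
        assert reversals >= 1

    def test_rejects_bad_fs(self, two_block_schedule):
        with pytest.raises(ValueError):
            gen.generate_target_trace(two_block_schedule, fs=0, seed=0)


class TestFeedbackTrace:
    def test_noiseless_feedback_equals_target(self, two_block_schedule):
        tgt = gen.generate_target_trace(two_block_schedule, seed=0)
        fb = gen.generate_feedback_trace(tgt, "TT", seed=0)
        assert np.array_equal(fb.feedback_px, tgt.target_px)

    def test_rmse_converges_to_noise_sd(self):
        # law of large numbers on a single long block
        sch = gen.TaskSchedule(session_index=0,
                               blocks=[("TT", 0.0, 100000 / 30.0)],
                               rest_s=0.0, lead_in_s=0.0)
        tgt = gen.generate_target_trace(sch, seed=1)
        fb = gen.generate_feedback_trace(tgt, "TT", noise_sd_px=50.0, seed=1)
        mask = tgt.condition == "TT"
        rmse = compute_rmse(tgt.target_px[mask], fb.feedback_px[mask])
        assert rmse == pytest.approx(50.0, rel=0.02)

    def test_tt_beats_ttnf_across_replicates(self, two_block_schedule):
        wins = 0
        for s in range(50):
            traces = gen.generate_subject_behavior(
                [two_block_schedule], rmse_tt=81.5, rmse_ttnf=120.8,
                seed=1000 + s)
            tr = traces[0]
            r = {}
            for cond in ("TT", "TTNF"):
                m = tr.condition == cond
                r[cond] = compute_rmse(tr.target_px[m], tr.feedback_px[m])
            wins += r["TT"] < r["TTNF"]
        assert wins >= 48

    def test_rejects_negative_noise(self, two_block_schedule):
        tgt = gen.generate_target_trace(two_block_schedule, seed=0)
        with pytest.raises(ValueError):
            gen.generate_feedback_trace(tgt, "TT", noise_sd_px=-1.0, seed=0)


class TestSubjectParams:
    def test_degenerate_cohort_equals_group_mean(self):
        truth = gen.make_ground_truth(n_subjects=3, seed=0,
                                      between_subject_sd=0.0,
                                      covariate_effects={})
        p = gen.sample_subject_params(truth, 1)
        assert np.array_equal(p.to_vector(), truth.group_mean.to_vector())

    def test_covariate_effect_shifts_target_connection(self):
        truth = gen.make_ground_truth(n_subjects=3, seed=0,
                                      between_subject_sd=0.0)
        z = truth.covariates["improved_rmse_z"].to_numpy()
        i = int(np.argmax(z))
        p = gen.sample_subject_params(truth, i)
        expected = truth.group_mean["b222"] + 0.577 * z[i]
        assert p["b222"] == pytest.approx(expected, abs=1e-12)

    def test_rejects_base_condition_effects(self):
        with pytest.raises(KeyError):
            gen.make_ground_truth(n_subjects=3, seed=0,
                                  covariate_effects={"b111": {"mean_mdf": 1.0}})

    def test_between_subject_sd_recovered(self):
        # a stable, boundary-distant group mean so truncation is negligible
        gm = dcm.ConnectivityParams.zeros()
        truth = gen.make_ground_truth(n_subjects=4000, seed=7,
                                      between_subject_sd=0.05,
                                      covariate_effects={}, group_mean=gm)
        draws = np.array([gen.sample_subject_params(truth, i)["a21"]
                          for i in range(truth.n_subjects)])
        assert np.std(draws) == pytest.approx(0.05, rel=0.03)


class TestBoldSimulation:
    def test_quiescent_network_is_flat(self, schedules_one):
        p = dcm.ConnectivityParams.zeros()       # self-decay only (log mode)
        ts = gen.simulate_subject_bold(p, schedules_one, obs_noise_sd=0.0,
                                       seed=0)
        assert np.allclose(ts.y, 0.0, atol=1e-12)

    def test_seeded_simulation_is_bit_identical(self, schedules_one,
                                                group_mean_params):
        a = gen.simulate_subject_bold(group_mean_params, schedules_one,
                                      obs_noise_sd=0.5, seed=9)
        b = gen.simulate_subject_bold(group_mean_params, schedules_one,
                                      obs_noise_sd=0.5, seed=9)
        assert np.array_equal(a.y, b.y)

    def test_roundtrip_through_tsv(self, tmp_path, schedules_one,
                                   group_mean_params):
        ts = gen.simulate_subject_bold(group_mean_params, schedules_one,
                                       obs_noise_sd=0.3, seed=2)
        ts.write(tmp_path / "sub00")
        back = dcm.RoiTimeSeriesSet.read(tmp_path / "sub00")
        assert np.allclose(back.y, ts.y, atol=1e-8)
        assert back.scans_per_session == ts.scans_per_session
        assert np.array_equal(back.inputs[0], ts.inputs[0])


class TestSyntheticEmg:
    def test_dominant_hum_peaks_at_60hz(self, two_block_schedule):
        rec = gen.generate_synthetic_emg(two_block_schedule,
                                         line_hum_amp=50.0, seed=0)
        x = rec.data[:, 0]
        freqs = np.fft.rfftfreq(len(x), 1 / rec.fs)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert peak == pytest.approx(60.0, abs=0.2)

    def test_null_condition_is_exchangeable(self, two_block_schedule):
        """With zero spectral shift/gain, TT and TTNF MDFs are statistically
        indistinguishable in at least 90% of seeded runs."""
        from scipy import stats
        from vmdcm.emg import compute_mdf
        nonsig = 0
        n_runs = 60
        for s in range(n_runs):
            rec = gen.generate_synthetic_emg(
                two_block_schedule, condition_mdf_shift=0.0,
                condition_amp_gain=1.0, line_hum_amp=0.0, seed=3000 + s)
            mdfs = {}
            for cond in ("TT", "TTNF"):
                idx = np.flatnonzero(rec.condition == cond)
                chunks = np.array_split(rec.data[idx, 0], 10)
                mdfs[cond] = [compute_mdf(c, rec.fs) for c in chunks]
            p = stats.ttest_ind(mdfs["TT"], mdfs["TTNF"]).pvalue
            nonsig += p > 0.05
        assert nonsig >= 0.9 * n_runs

    def test_positive_shift_raises_tt_mdf(self, two_block_schedule):
        from vmdcm.emg import compute_mdf
        hits = 0
        n_runs = 40
        for s in range(n_runs):
            rec = gen.generate_synthetic_emg(
                two_block_schedule, condition_mdf_shift=8.0,
                condition_amp_gain=1.3, line_hum_amp=0.0, seed=5000 + s)
            out = {}
            for cond in ("TT", "TTNF"):
                idx = np.flatnonzero(rec.condition == cond)
                out[cond] = (compute_mdf(rec.data[idx, 0], rec.fs),
                             np.sqrt(np.mean(rec.data[idx, 0] ** 2)))
            hits += (out["TT"][0] > out["TTNF"][0]
                     and out["TT"][1] > out["TTNF"][1])
        assert hits >= 0.95 * n_runs

    def test_emg_roundtrip(self, tmp_path, two_block_schedule):
        rec = gen.generate_synthetic_emg(two_block_schedule, seed=1)
        rec.write(tmp_path / "emg0")
        back = gen.EmgRecording.read(tmp_path / "emg0")
        assert np.allclose(back.data, rec.data, atol=1e-4)
        assert list(back.condition) == list(rec.condition)


def test_dt_refinement_changes_prediction_below_tenth_percent(
        schedules_one, group_mean_params):
    sch = schedules_one[0]
    hemo = dcm.HemodynamicParams()
    nscan = [int(sch.duration_s // dcm.TR_S)]
    preds = {}
    for div in (16, 32):
        dt = dcm.TR_S / div
        U = sch.input_functions(dt)[1]
        preds[div] = dcm.predict_bold(group_mean_params, hemo, [U], nscan,
                                      microtime_dt=dt)
    diff = np.sqrt(np.mean((preds[16] - preds[32]) ** 2))
    scale = np.sqrt(np.mean(preds[32] ** 2))
    assert diff / scale < 1e-3


def test_ground_truth_roundtrip(tmp_path):
    truth = gen.make_ground_truth(n_subjects=5, seed=3)
    truth.to_json(tmp_path / "gt.json")
    back = gen.GroundTruthGroup.from_json(tmp_path / "gt.json")
    assert np.allclose(back.group_mean.to_vector(),
                       truth.group_mean.to_vector())
    pd.testing.assert_frame_equal(back.covariates, truth.covariates)
    assert back.covariate_effects == truth.covariate_effects
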