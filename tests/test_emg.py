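import numpy as np
import pandas as pd
import pytest

from vmdcm import emg as emg_mod
from vmdcm import synthetic_data as gen

FS = 2000.0


def _as_recording(x: np.ndarray, condition=None) -> gen.EmgRecording:
    data = np.tile(np.asarray(x, dtype=float)[:, None], (1, 8))
    cond = condition if condition is not None else np.full(len(x), "TT",
                                                           dtype=object)
    return gen.EmgRecording(data=data, fs=FS, condition=cond)


class TestPreprocess:
    def test_notch_attenuates_60hz(self):
        t = np.arange(int(FS * 4)) / FS
        rec = _as_recording(np.sin(2 * np.pi * 60 * t))
        out = emg_mod.preprocess_emg(rec).data[:, 0]
        atten = 20 * np.log10(np.sqrt(np.mean(out[2000:-2000] ** 2))
                              / np.sqrt(0.5))
        assert atten <= -20

    def test_passband_preserves_100hz(self):
        t = np.arange(int(FS * 4)) / FS
        rec = _as_recording(np.sin(2 * np.pi * 100 * t))
        out = emg_mod.preprocess_emg(rec).data[:, 0]
        db = 20 * np.log10(np.sqrt(np.mean(out[2000:-2000] ** 2))
                           / np.sqrt(0.5))
        assert abs(db) <= 1.0

    def test_dc_removed(self):
        rec = _as_recording(np.ones(8000))
        out = emg_mod.preprocess_emg(rec).data[:, 0]
        assert np.max(np.abs(out[2000:-2000])) < 1e-6

    def test_rejects_wrong_rate(self):
        with pytest.raises(ValueError):
            gen.EmgRecording(data=np.zeros((100, 8)), fs=1000.0,
                             condition=np.full(100, "TT", dtype=object))


class TestSegmentation:
    @staticmethod
    def _behavior_from_target(target, fs=30.0, condition="TT"):
        n = len(target)
        return gen.BehaviorTrace(
            time_s=np.arange(n) / fs, target_px=np.asarray(target, float),
            feedback_px=np.asarray(target, float),
            condition=np.full(n, condition, dtype=object), fs=fs)

    def test_triangle_wave_counts_cycles(self):
        cycle = np.concatenate([np.linspace(200, 600, 16, endpoint=False),
                                np.linspace(600, 200, 16, endpoint=False)])
        target = np.tile(cycle, 10)
        beh = self._behavior_from_target(target)
        n_emg = int(len(target) / 30.0 * FS)
        rec = _as_recording(np.random.default_rng(0).normal(0, 1, n_emg))
        bounds = emg_mod.segment_repetitions(rec, beh)
        assert len(bounds) == 10

    def test_monotone_target_has_no_repetitions(self):
        beh = self._behavior_from_target(np.linspace(200, 600, 300))
        rec = _as_recording(np.zeros(20000))
        assert emg_mod.segment_repetitions(rec, beh) == []

    def test_matches_bruteforce_extremum_scan(self, schedules_one):
        tgt = gen.generate_target_trace(schedules_one[0], seed=2)
        rec = gen.generate_synthetic_emg(schedules_one[0], seed=2)
        bounds = emg_mod.segment_repetitions(rec, tgt)
        # brute force: enumerate sample-wise direction reversals down->up
        troughs = []
        last_dir = 0.0
        x = tgt.target_px
        for i in range(1, len(x)):
            d = np.sign(x[i] - x[i - 1])
            if d != 0:
                if last_dir < 0 and d > 0:
                    troughs.append(i - 1)
                last_dir = d
        expected = 0
        for t0, t1 in zip(troughs[:-1], troughs[1:]):
            conds = set(tgt.condition[t0:t1])
            expected += len(conds) == 1 and "rest" not in conds
        assert len(bounds) == expected > 0


class TestSpectralFeatures:
    def test_single_tone_mdf(self):
        t = np.arange(1024) / FS
        seg = np.sin(2 * np.pi * 80 * t)
        # 80 Hz falls between bins of the 1024-point grid; nearest bin wins
        assert emg_mod.compute_mdf(seg, FS) == pytest.approx(80.0, abs=1.0)

    def test_equal_tone_tie_breaks_low(self):
        # two equal-power tones placed on exact bin centres of the
        # 2048-point spectrum: the tie resolves to the lower bin
        t = np.arange(2048) / FS
        seg = (np.sin(2 * np.pi * 50.78125 * t)
               + np.sin(2 * np.pi * 150.390625 * t))
        assert emg_mod.compute_mdf(seg, FS) == pytest.approx(50.78125,
                                                             abs=1e-9)

    def test_matches_bruteforce_cumsum(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(64, 1000))
            seg = rng.normal(0, 1, n)
            m = 1 << (n - 1).bit_length()
            power = np.abs(np.fft.rfft(seg, m)) ** 2
            total = power.sum()
            acc = 0.0
            for j, pj in enumerate(power):    # smallest bin >= half power
                acc += pj
                if acc >= 0.5 * total:
                    break
            expected = np.fft.rfftfreq(m)[j] * FS
            assert emg_mod.compute_mdf(seg, FS) == expected

    def test_mdf_amplitude_invariance(self):
        rng = np.random.default_rng(3)
        seg = rng.normal(0, 1, 500)
        assert emg_mod.compute_mdf(seg, FS) == emg_mod.compute_mdf(10 * seg, FS)

    def test_rejects_short_or_silent_segments(self):
        with pytest.raises(ValueError):
            emg_mod.compute_mdf(np.ones(32), FS)
        with pytest.raises(ValueError):
            emg_mod.compute_mdf(np.zeros(128), FS)

    def test_amplitude_closed_forms(self):
        t = np.arange(int(FS)) / FS
        a = 3.7
        assert emg_mod.compute_amplitude(a * np.sin(2 * np.pi * 50 * t)) \
            == pytest.approx(a / np.sqrt(2), rel=5e-3)
        assert emg_mod.compute_amplitude(np.full(100, -2.5)) == 2.5
        rng = np.random.default_rng(0)
        assert emg_mod.compute_amplitude(rng.normal(0, 1.5, 100000)) \
            == pytest.approx(1.5, rel=0.02)
        with pytest.raises(ValueError):
            emg_mod.compute_amplitude(np.array([]))


class TestNormalization:
    def test_ttnf_mean_is_exactly_one(self, emg_cohort):
        norm = emg_mod.normalize_by_ttnf(emg_cohort)
        ttnf = norm[norm["condition"] == "TTNF"]
        means = ttnf.groupby(["subject", "muscle"])[
            ["norm_mdf", "norm_amplitude"]].mean()
        assert np.allclose(means.to_numpy(), 1.0, atol=1e-12)

    def test_scale_invariance(self, emg_cohort):
        scaled = emg_cohort.copy()
        scaled.loc[scaled["subject"] == 0, ["mdf", "amplitude"]] *= 10
        a = emg_mod.normalize_by_ttnf(emg_cohort)
        b = emg_mod.normalize_by_ttnf(scaled)
        assert np.allclose(a["norm_amplitude"], b["norm_amplitude"])

    def test_all_equal_repetitions_normalize_to_one(self):
        df = pd.DataFrame({
            "subject": 0, "muscle": "FCR",
            "condition": ["TTNF", "TTNF", "TT"],
            "repetition": [0, 1, 2], "mdf": 75.0, "amplitude": 1.1})
        norm = emg_mod.normalize_by_ttnf(df)
        assert np.allclose(norm["norm_mdf"], 1.0)

    def test_missing_ttnf_rejected(self):
        df = pd.DataFrame({"subject": 0, "muscle": "FCR",
                           "condition": ["TT"], "repetition": [0],
                           "mdf": [75.0], "amplitude": [1.0]})
        with pytest.raises(ValueError):
            emg_mod.normalize_by_ttnf(df)


def _null_features(rng, n_subjects=12, reps=1):
    rows = []
    for s in range(n_subjects):
        for m in gen.MUSCLES:
            for cond in ("TTNF", "TT"):
                for t in range(reps):
                    rows.append({"subject": s, "muscle": m, "condition": cond,
                                 "repetition": t,
                                 "norm_mdf": rng.normal(1, 0.05),
                                 "norm_amplitude": rng.normal(1, 0.05)})
    return pd.DataFrame(rows)


class TestConditionContrast:
    def test_identical_distributions_give_t_zero(self):
        df = _null_features(np.random.default_rng(0))
        df["norm_mdf"] = 1.0
        res = emg_mod.condition_contrast(df, "norm_mdf")
        assert np.allclose(res.per_muscle["t"], 0.0)
        assert np.allclose(res.per_muscle["p"], 1.0)

    def test_results_are_uncorrected(self):
        df = _null_features(np.random.default_rng(1))
        assert emg_mod.condition_contrast(df).corrected is False

    def test_generator_shift_detected(self, schedules_one):
        """Positive spectral shift and gain recovered as positive TT-TTNF
        contrasts through the full pipeline, per-muscle and on the mean."""
        frames = []
        for i in range(4):
            rec = gen.generate_subject_emg(schedules_one, mdf_ratio=1.05,
                                           amp_ratio=1.3, seed=77,
                                           subject_index=i)[0]
            tgt = gen.generate_target_trace(schedules_one[0],
                                            seed=77 + 7919 * i)
            clean = emg_mod.preprocess_emg(rec)
            bounds = emg_mod.segment_repetitions(clean, tgt)
            frames.append(emg_mod.repetition_features(clean, bounds,
                                                      subject=i))
        norm = emg_mod.normalize_by_ttnf(pd.concat(frames, ignore_index=True))
        res = emg_mod.condition_contrast(norm, "norm_mdf")
        assert float(res.mean_across["t"].iloc[0]) > 0
        res_a = emg_mod.condition_contrast(norm, "norm_amplitude")
        assert float(res_a.mean_across["t"].iloc[0]) > 0

    def test_type_one_error_calibrated(self):
        """Per-muscle null rejection rate at alpha=0.05 within [0.04, 0.06]."""
        rng = np.random.default_rng(9)
        n_rep = 2000
        rej = 0
        for _ in range(n_rep):
            df = _null_features(rng, n_subjects=10)
            res = emg_mod.condition_contrast(df, "norm_mdf")
            rej += float(res.per_muscle["p"].iloc[0]) < 0.05
        assert 0.04 <= rej / n_rep <= 0.06

    def test_too_few_subjects_rejected(self):
        df = _null_features(np.random.default_rng(2), n_subjects=1)
        with pytest.raises(ValueError):
            emg_mod.condition_contrast(df)


def test_filter_segment_commute_on_interior(self=None):
    """Filtering then segmenting matches segmenting then filtering away from
    the segment edges."""
    sch = gen.TaskSchedule(session_index=0,
                           blocks=[("TT", 5.0, 21.0)], lead_in_s=5.0)
    rec = gen.generate_synthetic_emg(sch, seed=8)
    tgt = gen.generate_target_trace(sch, seed=8)
    filtered = emg_mod.preprocess_emg(rec)
    bounds = emg_mod.segment_repetitions(filtered, tgt)
    i0, i1, _ = bounds[len(bounds) // 2]
    a = filtered.data[i0:i1, 0]
    pad = 2000
    j0, j1 = max(i0 - pad, 0), min(i1 + pad, rec.data.shape[0])
    chunk = gen.EmgRecording(data=rec.data[j0:j1], fs=rec.fs,
                             condition=rec.condition[j0:j1])
    b = emg_mod.preprocess_emg(chunk).data[i0 - j0:i1 - j0, 0]
    assert np.allclose(a, b, atol=5e-3 * np.std(a))


def test_mean_mdf_covariate_zscored(emg_cohort):
    norm = emg_mod.normalize_by_ttnf(emg_cohort)
    cov = emg_mod.mean_mdf_covariate(norm)
    assert len(cov) == 2
    assert abs(cov["mean_mdf_z"].mean()) < 1e-10
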