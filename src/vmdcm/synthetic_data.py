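"""Synthetic cohort generator with known ground truth.

Emulates the structure of the visuomotor experiment end to end so that every
downstream stage (tracking RMSE, EMG median frequency, DCM inversion, group
PEB, LOOCV) can be exercised without any recorded data:

* block design — three sessions, each holding three feedback (TT) and three
  no-feedback (TTNF) tracking blocks of 21 s in seeded random order,
  separated by 15 s rests;
* target kinematics — a reciprocating vertical sweep bounded to [200, 600]
  px, one 25 px step per 30 Hz sample plus half-normal jitter clipped to
  [0, 2] px, direction reversing at the bounds;
* tracking feedback — lagged target plus white tracking noise, with an
  additional per-block random-walk drift in the no-feedback condition
  (open-loop error accumulation), calibrated per subject so that group-mean
  RMSE is about 81.5 px (TT) and 120.8 px (TTNF);
* BOLD — the bilinear three-region model integrated through the
  balloon–Windkessel cascade at the scanner's 1.91 s repetition time, with
  subject-level connectivity tied to behavioral/EMG covariates;
* EMG — eight channels of band-limited (20–150 Hz) Gaussian noise at
  2 kHz whose spectral centroid and RMS rise during feedback blocks, plus
  mains interference at 60/120/180/240 Hz.

Randomness: a single master seed fans out into independent per-stream,
per-subject generators via ``default_rng([master, stream_code, index])``;
stream codes are listed in :data:`STREAMS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dcm_core import (PARAM_NAMES, TR_S, TE_S, ConnectivityParams,
                       HemodynamicParams, RoiTimeSeriesSet, _index_of,
                       predict_bold)

MUSCLES = ("FCR", "ECRL", "BR", "BCM", "TCM", "ADS", "PD", "SFT")
EMG_FS = 2000.0
BEHAVIOR_FS = 30.0
BLOCK_S = 21.0
REST_S = 15.0
BLOCKS_PER_CONDITION = 3

#: stream codes of the seed fan-out scheme
STREAMS = {"schedule": 1, "target": 2, "feedback": 3, "params": 4,
           "bold": 5, "emg": 6, "covariates": 7, "posterior": 8}

#: group-mean effective connectivity of the synthetic cohort (Hz; self
#: entries are log-scalings of the -0.5 Hz baseline).  Entries absent from
#: the mapping are zero.
GROUP_MEAN_CONNECTIVITY = {
    "a11": -0.885, "a22": 0.267, "a33": -0.148,
    "a21": 0.697, "a31": 0.732, "a12": -0.070,
    "a32": -0.509, "a13": 0.277, "a23": 0.217,
    "b112": 1.180, "b122": -0.451, "b222": 1.798,
    "b322": -0.606, "b232": -0.399,
    "c21": 0.083, "c22": 0.409, "c32": 0.379,
}

#: per-unit-covariate effects injected on specific connections, so that
#: group-level covariate recovery is falsifiable: improved tracking couples
#: to the two motor-bound modulations, muscle activation to the cerebellar
#: self-modulation.
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "b222": {"improved_rmse": 0.577},
    "b232": {"improved_rmse": 0.189},
    "b112": {"mean_mdf": 0.960},
}

#: behavioral calibration targets (pixels)
RMSE_TT_MEAN, RMSE_TT_SD = 81.5, 14.4
RMSE_IMPROVEMENT_MEAN, RMSE_IMPROVEMENT_SD = 120.8 - 81.5, 25.0
#: feedback-condition MDF ratio calibration (dimensionless)
MDF_RATIO_MEAN, MDF_RATIO_SD = 1.014, 0.044
AMP_RATIO_MEAN = 1.068

#: observation noise of the synthetic BOLD (percent signal change).  The
#: group-mean dynamics produce a signal of sd ~2.6 in these units, so the
#: default puts subject-level fits around 90 % explained variance — a
#: validation regime in which parameter recovery is informative about the
#: estimator rather than about measurement noise.  Real ROI recordings are
#: far noisier (explained variance near 36 % corresponds to ~3.5 here) and
#: can be emulated by raising this value in the config.
DEFAULT_OBS_NOISE_SD = 0.5

DEFAULT_BETWEEN_SUBJECT_SD = 0.0625  # Hz; prior variance / 16 convention


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), STREAMS[stream], int(index)])


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

@dataclass
class TaskSchedule:
    """Block timing of one session; houses the condition box-cars u1/u2."""

    session_index: int
    blocks: list[tuple[str, float, float]]   # (condition, onset_s, duration_s)
    rest_s: float = REST_S
    microtime_dt: float = TR_S / 16
    lead_in_s: float = REST_S

    def __post_init__(self) -> None:
        onsets = [b[1] for b in self.blocks]
        if any(o2 <= o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")

    @property
    def duration_s(self) -> float:
        """Total session length including lead-in and trailing rest."""
        last = self.blocks[-1]
        return last[1] + last[2] + self.rest_s

    @property
    def conditions(self) -> list[str]:
        return [b[0] for b in self.blocks]

    def input_functions(self, dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(t, U) box-cars on the microtime grid; u1 = TTNF, u2 = TT.

        Block edges are quantized to the schedule's native microtime grid, so
        requesting a finer ``dt`` (an integer refinement) refines the
        integration grid without moving the stimulus edges.
        """
        dt = dt or self.microtime_dt
        n = int(round(self.duration_s / dt))
        t = np.arange(n) * dt
        U = np.zeros((n, 2))
        base = self.microtime_dt
        for cond, onset, dur in self.blocks:
            col = 0 if cond == "TTNF" else 1
            o = round(onset / base) * base
            e = round((onset + dur) / base) * base
            U[(t >= o - 1e-9) & (t < e - 1e-9), col] = 1.0
        return t, U

    def condition_at(self, t: np.ndarray) -> np.ndarray:
        out = np.full(len(t), "rest", dtype=object)
        for cond, onset, dur in self.blocks:
            out[(t >= onset) & (t < onset + dur)] = cond
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"session": self.session_index, "block": i, "condition": c,
             "onset_s": o, "duration_s": d}
            for i, (c, o, d) in enumerate(self.blocks)])


def generate_task_schedule(n_sessions: int, seed: int,
                           block_s: float = BLOCK_S, rest_s: float = REST_S,
                           lead_in_s: float = REST_S,
                           microtime_dt: float = TR_S / 16) -> list[TaskSchedule]:
    """Seeded random block orders: 3 TTNF + 3 TT blocks of 21 s per session."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = _rng(seed, "schedule")
    schedules = []
    for s in range(n_sessions):
        conds = ["TTNF"] * BLOCKS_PER_CONDITION + ["TT"] * BLOCKS_PER_CONDITION
        order = rng.permutation(len(conds))
        blocks = []
        t = lead_in_s
        for i in order:
            blocks.append((conds[i], t, block_s))
            t += block_s + rest_s
        schedules.append(TaskSchedule(session_index=s, blocks=blocks,
                                      rest_s=rest_s, microtime_dt=microtime_dt,
                                      lead_in_s=lead_in_s))
    return schedules


def write_schedules(schedules: Sequence[TaskSchedule], path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat([s.to_frame() for s in schedules]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# behavior traces
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTrace:
    """Target/feedback pixel traces sampled at 30 Hz with condition labels."""

    time_s: np.ndarray
    target_px: np.ndarray
    feedback_px: np.ndarray
    condition: np.ndarray
    fs: float = BEHAVIOR_FS
    session_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "session": self.session_index, "time_s": self.time_s,
            "target_px": self.target_px, "feedback_px": self.feedback_px,
            "condition": self.condition})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float = BEHAVIOR_FS) -> "BehaviorTrace":
        return cls(time_s=df["time_s"].to_numpy(float),
                   target_px=df["target_px"].to_numpy(float),
                   feedback_px=df["feedback_px"].to_numpy(float),
                   condition=df["condition"].to_numpy(object), fs=fs,
                   session_index=int(df["session"].iloc[0]) if "session" in df else 0)


def generate_target_trace(schedule: TaskSchedule, step_px: float = 25.0,
                          jitter_max_px: float = 2.0, lo: float = 200.0,
                          hi: float = 600.0, fs: float = BEHAVIOR_FS,
                          seed: int = 0) -> BehaviorTrace:
    """Reciprocating target sweep: one step per sample during blocks.

    Jitter is half-normal (scale ``jitter_max_px / 2``) clipped to
    ``[0, jitter_max_px]`` and added to the step magnitude; the position is
    clamped to ``[lo, hi]`` with direction reversal at the bounds.  The target
    holds its position during rests.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if step_px <= 0:
        raise ValueError("step_px must be positive")
    rng = _rng(seed, "target", schedule.session_index)
    n = int(round(schedule.duration_s * fs))
    t = np.arange(n) / fs
    cond = schedule.condition_at(t)
    pos = np.empty(n)
    p, direction = lo, 1.0
    for i in range(n):
        if cond[i] != "rest":
            jitter = abs(rng.normal(0.0, jitter_max_px / 2)) if jitter_max_px > 0 else 0.0
            step = step_px + min(jitter, jitter_max_px)
            p = p + direction * step
            if p >= hi:
                p, direction = hi, -1.0
            elif p <= lo:
                p, direction = lo, 1.0
        pos[i] = p
    return BehaviorTrace(time_s=t, target_px=pos, feedback_px=pos.copy(),
                         condition=cond, fs=fs,
                         session_index=schedule.session_index)


def generate_feedback_trace(target: BehaviorTrace, condition: str,
                            lag_s: float = 0.0, noise_sd_px: float = 0.0,
                            drift_sd_px: float = 0.0, seed: int = 0) -> BehaviorTrace:
    """Simulated controller trace for blocks of one condition.

    ``feedback = lagged target + white tracking noise``, plus a per-block
    random walk when ``drift_sd_px > 0`` (open-loop drift of the unseen
    cursor in the no-feedback task).  Samples of other conditions are left
    unchanged.
    """
    if noise_sd_px < 0 or drift_sd_px < 0 or lag_s < 0:
        raise ValueError("noise/drift scales and lag must be non-negative")
    rng = _rng(seed, "feedback", target.session_index)
    lag = int(round(lag_s * target.fs))
    fb = target.feedback_px.copy()
    lagged = np.concatenate([np.full(lag, target.target_px[0]),
                             target.target_px[:len(fb) - lag]]) if lag else target.target_px
    mask = target.condition == condition
    # per contiguous block so the drift resets at each block onset
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        m = i1 - i0
        noise = rng.normal(0.0, noise_sd_px, m) if noise_sd_px > 0 else 0.0
        drift = (np.cumsum(rng.normal(0.0, drift_sd_px, m))
                 if drift_sd_px > 0 else 0.0)
        fb[i0:i1] = lagged[i0:i1] + noise + drift
    return BehaviorTrace(time_s=target.time_s, target_px=target.target_px,
                         feedback_px=fb, condition=target.condition,
                         fs=target.fs, session_index=target.session_index)


def generate_subject_behavior(schedules: Sequence[TaskSchedule],
                              rmse_tt: float, rmse_ttnf: float, seed: int,
                              subject_index: int = 0) -> list[BehaviorTrace]:
    """Per-session behavior traces calibrated to subject RMSE targets.

    The feedback condition uses pure white tracking noise with
    ``sd = rmse_tt``; the no-feedback condition splits its error budget
    evenly between white noise and a per-block random walk, which reproduces
    the target RMSE in expectation.
    """
    if not rmse_tt < rmse_ttnf:
        raise ValueError("TT error scale must be below the TTNF error scale")
    traces = []
    n_block = int(round(BLOCK_S * BEHAVIOR_FS))
    for sch in schedules:
        tgt = generate_target_trace(sch, seed=seed + 7919 * subject_index)
        tr = generate_feedback_trace(tgt, "TT", noise_sd_px=rmse_tt,
                                     seed=seed + 7919 * subject_index)
        tr = generate_feedback_trace(tr, "TTNF",
                                     noise_sd_px=rmse_ttnf / np.sqrt(2),
                                     drift_sd_px=rmse_ttnf / np.sqrt(n_block + 1),
                                     seed=seed + 7919 * subject_index + 1)
        traces.append(tr)
    return traces


def write_behavior(traces: Sequence[BehaviorTrace], path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat([tr.to_frame() for tr in traces]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_behavior(path: Path) -> list[BehaviorTrace]:
    df = pd.read_csv(path, sep="\t")
    return [BehaviorTrace.from_frame(g) for _, g in df.groupby("session", sort=True)]


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

@dataclass
class EmgRecording:
    """8-channel surface EMG at 2 kHz with per-sample condition labels."""

    data: np.ndarray             # (n, 8) arbitrary voltage units
    fs: float = EMG_FS
    condition: np.ndarray = field(default_factory=lambda: np.array([]))
    channels: tuple = MUSCLES
    session_index: int = 0
    rep_bounds: list[tuple[int, int, str]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise ValueError("data must be (n_samples, n_channels)")
        if len(self.channels) != 8 or any(c not in MUSCLES for c in self.channels):
            raise ValueError(f"channels must be the 8 muscles {MUSCLES}")
        if self.fs != EMG_FS:
            raise ValueError(f"fs must be {EMG_FS:g} Hz")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) / self.fs

    def write(self, prefix: Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.data, columns=list(self.channels)).to_csv(
            prefix.with_suffix(".tsv"), sep="\t", index=False,
            float_format="%.6g")
        prefix.with_suffix(".json").write_text(json.dumps(
            {"fs": self.fs, "channels": list(self.channels),
             "session": self.session_index}, indent=1, sort_keys=True))
        edges = np.flatnonzero(np.concatenate(
            [[True], self.condition[1:] != self.condition[:-1]]))
        ev = pd.DataFrame({
            "onset_s": edges / self.fs,
            "condition": self.condition[edges],
        })
        ev.to_csv(prefix.parent / (prefix.name + "_events.tsv"), sep="\t",
                  index=False, float_format="%.10g")

    @classmethod
    def read(cls, prefix: Path) -> "EmgRecording":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t").to_numpy(float)
        ev = pd.read_csv(prefix.parent / (prefix.name + "_events.tsv"), sep="\t")
        cond = np.full(len(data), "rest", dtype=object)
        onsets = (ev["onset_s"] * meta["fs"]).round().astype(int).tolist() + [len(data)]
        for (i0, i1), c in zip(zip(onsets[:-1], onsets[1:]), ev["condition"]):
            cond[i0:i1] = c
        return cls(data=data, fs=meta["fs"], condition=cond,
                   channels=tuple(meta["channels"]),
                   session_index=meta.get("session", 0))


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, center: float,
                  width: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian noise with a Gaussian spectral envelope, unit RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    env = np.exp(-0.5 * ((freqs - center) / width) ** 2)
    env[(freqs < band[0]) | (freqs > band[1])] = 0.0
    spec = env * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def generate_synthetic_emg(schedule: TaskSchedule,
                           condition_mdf_shift: float = 1.1,
                           condition_amp_gain: float = AMP_RATIO_MEAN,
                           line_hum_amp: float = 0.5,
                           seed: int = 0, fs: float = EMG_FS,
                           center_hz: float = 80.0, width_hz: float = 30.0,
                           band: tuple[float, float] = (20.0, 150.0),
                           rest_amp: float = 0.3) -> EmgRecording:
    """One session of synthetic 8-channel EMG.

    Each contiguous condition segment is stationary band-limited Gaussian
    noise; feedback (TT) segments have their spectral envelope shifted up by
    ``condition_mdf_shift`` Hz and their RMS scaled by ``condition_amp_gain``.
    Mains interference is added at 60/120/180/240 Hz with amplitude
    ``line_hum_amp`` (per harmonic, relative to the unit task RMS).
    """
    if not (np.isfinite(condition_mdf_shift) and np.isfinite(condition_amp_gain)):
        raise ValueError("shift and gain must be finite")
    if fs != EMG_FS:
        raise ValueError(f"fs must be {EMG_FS:g} Hz")
    rng = _rng(seed, "emg", schedule.session_index)
    n = int(round(schedule.duration_s * fs))
    t = np.arange(n) / fs
    cond = schedule.condition_at(t)
    data = np.zeros((n, len(MUSCLES)))
    edges = np.flatnonzero(np.concatenate([[True], cond[1:] != cond[:-1]]))
    bounds = list(edges) + [n]
    for ch in range(len(MUSCLES)):
        x = np.empty(n)
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            c = cond[i0]
            center = center_hz + (condition_mdf_shift if c == "TT" else 0.0)
            amp = {"TT": condition_amp_gain, "TTNF": 1.0}.get(c, rest_amp)
            x[i0:i1] = amp * _shaped_noise(rng, i1 - i0, fs, center, width_hz, band)
        for f0 in (60.0, 120.0, 180.0, 240.0):
            x += line_hum_amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        data[:, ch] = x
    return EmgRecording(data=data, fs=fs, condition=cond,
                        session_index=schedule.session_index)


def generate_subject_emg(schedules: Sequence[TaskSchedule], mdf_ratio: float,
                         amp_ratio: float, seed: int, subject_index: int = 0,
                         center_hz: float = 80.0, **kw) -> list[EmgRecording]:
    """Per-session recordings whose TT/TTNF median-frequency ratio is
    approximately ``mdf_ratio`` (shift = center * (ratio - 1))."""
    shift = center_hz * (mdf_ratio - 1.0)
    return [generate_synthetic_emg(s, condition_mdf_shift=shift,
                                   condition_amp_gain=amp_ratio,
                                   seed=seed + 104729 * subject_index,
                                   center_hz=center_hz, **kw)
            for s in schedules]


# ---------------------------------------------------------------------------
# group ground truth and BOLD
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthGroup:
    """Ground-truth group model: mean connectivity, dispersion, covariates."""

    group_mean: ConnectivityParams
    between_subject_sd: float | Mapping[str, float]
    covariate_effects: dict[str, dict[str, float]]
    covariates: pd.DataFrame       # raw and z-scored columns per subject
    n_subjects: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for name, eff in self.covariate_effects.items():
            _index_of(name)  # raises for unknown / base-condition parameters
            for cov in eff:
                if f"{cov}_z" not in self.covariates.columns:
                    raise ValueError(f"covariate {cov!r} missing from table")

    def sd_of(self, name: str) -> float:
        if isinstance(self.between_subject_sd, Mapping):
            return float(self.between_subject_sd.get(name, 0.0))
        return float(self.between_subject_sd)

    def subject_mean(self, subject_index: int) -> ConnectivityParams:
        """Group mean plus covariate effects (no random deviate)."""
        p = ConnectivityParams.from_dict(self.group_mean.to_dict(),
                                         self_mode=self.group_mean.self_mode)
        row = self.covariates.iloc[subject_index]
        for name, eff in self.covariate_effects.items():
            for cov, beta in eff.items():
                p[name] = p[name] + beta * float(row[f"{cov}_z"])
        return p

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps({
            "group_mean": self.group_mean.to_dict(),
            "self_mode": self.group_mean.self_mode,
            "between_subject_sd": (dict(self.between_subject_sd)
                                   if isinstance(self.between_subject_sd, Mapping)
                                   else self.between_subject_sd),
            "covariate_effects": self.covariate_effects,
            "covariates": self.covariates.to_dict(orient="list"),
            "covariate_columns": list(self.covariates.columns),
            "n_subjects": self.n_subjects,
            "seed": self.seed,
        }, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path) -> "GroundTruthGroup":
        d = json.loads(Path(path).read_text())
        return cls(group_mean=ConnectivityParams.from_dict(
                       d["group_mean"], self_mode=d["self_mode"]),
                   between_subject_sd=d["between_subject_sd"],
                   covariate_effects=d["covariate_effects"],
                   covariates=pd.DataFrame(d["covariates"])[
                       d.get("covariate_columns",
                             sorted(d["covariates"]))],
                   n_subjects=d["n_subjects"], seed=d["seed"])


def _zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    sd = np.std(x, ddof=ddof)
    if sd == 0:
        raise ValueError("zero-variance covariate cannot be z-scored")
    return (x - np.mean(x)) / sd


def make_ground_truth(n_subjects: int = 14, seed: int = 0,
                      between_subject_sd: float | Mapping[str, float] = DEFAULT_BETWEEN_SUBJECT_SD,
                      covariate_effects: dict | None = None,
                      group_mean: ConnectivityParams | None = None) -> GroundTruthGroup:
    """Draw a synthetic cohort: covariates (raw + z-scored) and group model."""
    rng = _rng(seed, "covariates")
    improvement = RMSE_IMPROVEMENT_MEAN + RMSE_IMPROVEMENT_SD * rng.standard_normal(n_subjects)
    improvement = np.maximum(improvement, 5.0)
    rmse_tt = np.maximum(RMSE_TT_MEAN + RMSE_TT_SD * rng.standard_normal(n_subjects), 20.0)
    mean_mdf = MDF_RATIO_MEAN + MDF_RATIO_SD * rng.standard_normal(n_subjects)
    cov = pd.DataFrame({
        "subject": np.arange(n_subjects),
        "rmse_tt": rmse_tt,
        "rmse_ttnf": rmse_tt + improvement,
        "improved_rmse": improvement,
        "mean_mdf": mean_mdf,
        "improved_rmse_z": _zscore(improvement),
        "mean_mdf_z": _zscore(mean_mdf),
    })
    gm = group_mean or ConnectivityParams.from_dict(GROUP_MEAN_CONNECTIVITY)
    effects = (DEFAULT_COVARIATE_EFFECTS if covariate_effects is None
               else covariate_effects)
    return GroundTruthGroup(group_mean=gm,
                            between_subject_sd=between_subject_sd,
                            covariate_effects=effects, covariates=cov,
                            n_subjects=n_subjects, seed=seed)


def _is_stable(p: ConnectivityParams, margin: float = 0.02,
               max_rate: float = 20.0, max_gain: float = 3.0) -> bool:
    """Plausibility screen for a subject's dynamics in both condition regimes.

    Requires strictly negative leading eigenvalues (no runaway activity),
    no mode faster than ``max_rate`` Hz (regions do not relax on sub-50 ms
    timescales, and such rates would also defeat any fixed-step integrator),
    and a steady-state neuronal response to a sustained unit input below
    ``max_gain`` (near-singular regimes amplify inputs unphysically).
    """
    for u2 in (0.0, 1.0):
        M = p.effective_matrix(u2)
        eig = np.linalg.eigvals(M).real
        if eig.max() >= -margin or np.abs(eig).max() > max_rate:
            return False
        x_ss = np.linalg.solve(M, -p.C[:, int(u2)])
        if np.abs(x_ss).max() > max_gain:
            return False
        # sustained deactivation beyond -gamma (= -0.32) has no
        # positive-flow equilibrium in the balloon model; keep a margin
        if x_ss.min() < -0.25:
            return False
    return True


def sample_subject_params(truth: GroundTruthGroup,
                          subject_index: int) -> ConnectivityParams:
    """Subject connectivity = group mean + covariate effects + Gaussian deviate.

    The between-subject distribution is truncated to the model's stability
    region: deviates are redrawn (deterministically, from the subject's own
    stream) until both condition regimes are dynamically stable, since an
    exponentially diverging brain is outside the model class the cohort is
    meant to emulate.
    """
    if not 0 <= subject_index < truth.n_subjects:
        raise IndexError("subject_index out of range")
    base = truth.subject_mean(subject_index)
    gm = truth.group_mean
    rng = _rng(truth.seed, "params", subject_index)
    sds = np.array([truth.sd_of(name) for name in PARAM_NAMES])
    if not sds.any() and _is_stable(base):
        return base
    deviation = {n: base[n] - gm[n] for n in PARAM_NAMES}
    # graded attenuation toward the (stable) group mean: if a subject's
    # covariate-shifted dynamics leave the stable region, the whole
    # deviation (covariate effect + random part) is scaled down until the
    # subject is admissible
    for shrink in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0):
        for _ in range(200):
            p = ConnectivityParams.from_dict(gm.to_dict(),
                                             self_mode=gm.self_mode)
            for name, sd in zip(PARAM_NAMES, sds):
                dev = deviation[name] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                p[name] = p[name] + shrink * dev
            if _is_stable(p):
                return p
    raise RuntimeError("group mean itself is outside the stable region")


def simulate_subject_bold(params: ConnectivityParams,
                          schedules: Sequence[TaskSchedule],
                          tr_s: float = TR_S, te_s: float = TE_S,
                          obs_noise_sd: float = DEFAULT_OBS_NOISE_SD,
                          seed: int = 0, subject_index: int = 0,
                          hemo: HemodynamicParams | None = None,
                          method: str = "rk4") -> RoiTimeSeriesSet:
    """Integrate the generative model and sample noisy ROI series at TR."""
    if obs_noise_sd < 0:
        raise ValueError("obs_noise_sd must be >= 0")
    hemo = hemo or HemodynamicParams(te=te_s)
    dt = schedules[0].microtime_dt
    inputs = [s.input_functions()[1] for s in schedules]
    nscans = [int(np.floor(s.duration_s / tr_s)) for s in schedules]
    y = predict_bold(params, hemo, inputs, nscans, tr_s=tr_s, microtime_dt=dt,
                     method=method)
    if obs_noise_sd > 0:
        rng = _rng(seed, "bold", subject_index)
        y = y + rng.normal(0.0, obs_noise_sd, y.shape)
    return RoiTimeSeriesSet(y=y, tr_s=tr_s, te_s=te_s, microtime_dt=dt,
                            inputs=inputs, scans_per_session=nscans)


def simulate_subject_posteriors(truth: GroundTruthGroup,
                                estimation_noise_sd: float = 0.1,
                                seed: int | None = None,
                                names: Sequence[str] = PARAM_NAMES
                                ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Subject-level parameter estimates with calibrated uncertainty.

    Emulates the output of subject-level inversion at the group stage:
    for each subject the 'posterior' mean is the true subject parameter
    vector plus Gaussian estimation noise of sd ``estimation_noise_sd``, and
    the posterior covariance is the matching diagonal.  This is the unit the
    group-level stages (PEB, BMR/BMA, LOOCV) consume, and makes large
    group-level Monte-Carlo suites affordable.
    """
    seed = truth.seed if seed is None else seed
    means, covs = [], []
    for i in range(truth.n_subjects):
        theta = sample_subject_params(truth, i).to_vector(names)
        rng = _rng(seed, "posterior", i)
        means.append(theta + rng.normal(0.0, estimation_noise_sd, len(theta)))
        covs.append(np.eye(len(theta)) * estimation_noise_sd ** 2)
    return means, covs
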