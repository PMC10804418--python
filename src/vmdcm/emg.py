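"""Surface-EMG preprocessing and spectral features.

Pipeline: zero-phase notch filters at the 60/120/180/240 Hz mains harmonics
followed by a zero-phase 8–200 Hz band-pass; segmentation into repetitions
(one repetition = one full reciprocating target cycle, trough to trough);
per-repetition features — median frequency (MDF) and RMS amplitude.

The MDF of a segment is the frequency bin that splits the periodogram's
power in half,

    sum_{j<=MDF} P_j = sum_{j>=MDF} P_j = (1/2) sum_j P_j,

with the spectrum computed on ``M`` = next power of two of the segment
length, and ties resolved to the *smallest* bin whose cumulative power
reaches half the total (no interpolation).

Because absolute EMG scale is subject- and electrode-dependent, features are
normalized per subject x muscle by the mean over that subject's no-feedback
(TTNF) repetitions:

    normMDF_sk(t) = MDF_sk(t) / mean_t'{ MDF_sk(t') : t' in TTNF },

which forces the TTNF-condition average of the normalized feature to exactly
1 for every subject x muscle; both conditions are divided by the same TTNF
mean, so feedback-condition values are interpretable as ratios to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synthetic_data import EMG_FS, MUSCLES, BehaviorTrace, EmgRecording

NOTCH_FREQS = (60.0, 120.0, 180.0, 240.0)
NOTCH_Q = 30.0
BANDPASS_HZ = (8.0, 200.0)
BANDPASS_ORDER = 4


def preprocess_emg(rec: EmgRecording) -> EmgRecording:
    """Notch out mains harmonics, then band-pass 8–200 Hz (both zero-phase)."""
    if rec.fs != EMG_FS:
        raise ValueError(f"expected fs = {EMG_FS:g} Hz, got {rec.fs:g}")
    x = rec.data.copy()
    for f0 in NOTCH_FREQS:
        b, a = signal.iirnotch(f0, NOTCH_Q, fs=rec.fs)
        x = signal.filtfilt(b, a, x, axis=0)
    sos = signal.butter(BANDPASS_ORDER, BANDPASS_HZ, btype="bandpass",
                        fs=rec.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)
    out = replace(rec, data=x)
    out.condition = rec.condition
    out.rep_bounds = rec.rep_bounds
    return out


def find_target_troughs(target_px: np.ndarray) -> np.ndarray:
    """Indices where the target direction turns from downward to upward."""
    d = np.sign(np.diff(target_px))
    # carry the last nonzero direction through flat (rest) stretches
    last = 0.0
    dirs = np.empty_like(d)
    for i, v in enumerate(d):
        if v != 0:
            last = v
        dirs[i] = last
    troughs = []
    nonzero = np.flatnonzero(d)
    if len(nonzero) and d[nonzero[0]] > 0:
        # the trace starts (possibly after a flat stretch) by rising from a
        # minimum: that minimum opens the first repetition
        troughs.append(int(nonzero[0]))
    for i in range(1, len(dirs)):
        if dirs[i - 1] < 0 and dirs[i] > 0:
            troughs.append(i)
    if len(dirs) and dirs[-1] < 0 and d[-1] < 0:
        # the trace ends on a fall: its final sample closes the last cycle
        troughs.append(len(target_px) - 1)
    return np.asarray(troughs, dtype=int)


def segment_repetitions(rec: EmgRecording,
                        behavior: BehaviorTrace) -> list[tuple[int, int, str]]:
    """Repetition boundaries (EMG sample indices) from the target trace.

    One repetition spans two successive troughs of the target (a full
    up–down cycle); repetitions crossing a condition change or a rest are
    discarded.  Returns ``[]`` with no error if the trace holds less than one
    full cycle.
    """
    if behavior.time_s[-1] < rec.time_s[-1] - 1.0 / behavior.fs:
        raise ValueError("behavior trace does not cover the EMG time span")
    troughs = find_target_troughs(behavior.target_px)
    bounds: list[tuple[int, int, str]] = []
    ratio = rec.fs / behavior.fs
    for t0, t1 in zip(troughs[:-1], troughs[1:]):
        conds = set(behavior.condition[t0:t1])
        if len(conds) != 1 or "rest" in conds:
            continue
        i0, i1 = int(round(t0 * ratio)), int(round(t1 * ratio))
        if i1 <= rec.data.shape[0]:
            bounds.append((i0, i1, behavior.condition[t0]))
    rec.rep_bounds = bounds
    return bounds


def power_spectrum(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-taper periodogram zero-padded to the next power of two.

    Returns (frequency bins, power); frequencies assume unit sampling rate —
    callers scale by ``fs``.
    """
    n = len(segment)
    m = 1 << (n - 1).bit_length()
    spec = np.fft.rfft(segment, m)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(m)
    return freqs, power


def compute_mdf(segment: np.ndarray, fs: float = EMG_FS) -> float:
    """Median frequency of a segment's periodogram (Hz)."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) < 64:
        raise ValueError("segment too short for a spectral estimate (< 64)")
    if not np.any(segment):
        raise ValueError("all-zero segment has undefined median frequency")
    freqs, power = power_spectrum(segment)
    total = power.sum()
    j = int(np.searchsorted(np.cumsum(power), 0.5 * total))
    return float(freqs[j] * fs)


def compute_amplitude(segment: np.ndarray) -> float:
    """Root-mean-square amplitude of a segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sqrt(np.mean(segment ** 2)))


def repetition_features(rec: EmgRecording,
                        bounds: Sequence[tuple[int, int, str]] | None = None,
                        subject: object = 0) -> pd.DataFrame:
    """Per-repetition MDF and RMS amplitude for all 8 muscles."""
    bounds = bounds if bounds is not None else rec.rep_bounds
    if not bounds:
        return pd.DataFrame(columns=["subject", "muscle", "condition",
                                     "repetition", "mdf", "amplitude"])
    rows = []
    for t, (i0, i1, cond) in enumerate(bounds):
        for k, muscle in enumerate(rec.channels):
            seg = rec.data[i0:i1, k]
            rows.append({"subject": subject, "muscle": muscle,
                         "condition": cond, "repetition": t,
                         "mdf": compute_mdf(seg, rec.fs),
                         "amplitude": compute_amplitude(seg)})
    return pd.DataFrame(rows)


def normalize_by_ttnf(features: pd.DataFrame) -> pd.DataFrame:
    """Divide every repetition's features by the subject x muscle TTNF mean."""
    if features.empty:
        raise ValueError("no repetition features to normalize")
    out = features.copy()
    for col in ("mdf", "amplitude"):
        base = (features[features["condition"] == "TTNF"]
                .groupby(["subject", "muscle"])[col].mean())
        if base.empty or (base == 0).any() or base.isna().any():
            raise ValueError(f"missing or zero TTNF baseline for {col}")
        key = pd.MultiIndex.from_frame(out[["subject", "muscle"]])
        denom = base.reindex(key).to_numpy()
        if np.isnan(denom).any():
            raise ValueError("subject x muscle without TTNF repetitions")
        out[f"norm_{col}"] = out[col].to_numpy() / denom
    return out


def subject_level_means(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized feature per subject x muscle x condition."""
    return (normalized.groupby(["subject", "muscle", "condition"], sort=True)
            [["norm_mdf", "norm_amplitude"]].mean().reset_index())


def condition_summary(normalized: pd.DataFrame) -> pd.DataFrame:
    """Group mean/sd of normalized features per muscle and condition
    (plus a Mean column across the 8 muscles), repetition-and-subject
    averaged — the layout of the normalized feature tables."""
    subj = subject_level_means(normalized)
    per_subject_mean = (subj.groupby(["subject", "condition"], sort=True)
                        [["norm_mdf", "norm_amplitude"]].mean().reset_index())
    per_subject_mean["muscle"] = "Mean"
    full = pd.concat([subj, per_subject_mean], ignore_index=True)
    agg = (full.groupby(["muscle", "condition"], sort=False)
           [["norm_mdf", "norm_amplitude"]].agg(["mean", "std"]))
    agg.columns = ["_".join(c) for c in agg.columns]
    order = list(MUSCLES) + ["Mean"]
    return (agg.reset_index()
            .assign(_o=lambda d: d["muscle"].map(order.index))
            .sort_values(["_o", "condition"]).drop(columns="_o")
            .reset_index(drop=True))


@dataclass
class ContrastResult:
    per_muscle: pd.DataFrame   # muscle, t, p, mean_ttnf, mean_tt
    mean_across: pd.DataFrame  # same for the across-muscle mean feature
    feature: str
    paired: bool
    corrected: bool = False    # no multiplicity correction applied


def condition_contrast(normalized: pd.DataFrame, feature: str = "norm_mdf",
                       paired: bool = False) -> ContrastResult:
    """TT vs TTNF t-tests on subject-level means, per muscle and averaged.

    The unit of analysis is the subject-level mean over repetitions.  Tests
    are two-sample by default (paired optional) and reported uncorrected.
    """
    subj = subject_level_means(normalized)
    wide = subj.pivot_table(index=["subject", "muscle"], columns="condition",
                            values=feature).reset_index()
    for cond in ("TTNF", "TT"):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond} missing")
    rows = []
    for muscle, grp in wide.groupby("muscle", sort=False):
        rows.append({"muscle": muscle,
                     **_ttest(grp["TT"], grp["TTNF"], paired)})
    per_muscle = pd.DataFrame(rows)
    order = [m for m in MUSCLES if m in set(per_muscle["muscle"])]
    per_muscle = per_muscle.set_index("muscle").loc[order].reset_index()
    mean_wide = wide.groupby("subject")[["TTNF", "TT"]].mean()
    mean_across = pd.DataFrame(
        [{"muscle": "Mean", **_ttest(mean_wide["TT"], mean_wide["TTNF"], paired)}])
    return ContrastResult(per_muscle=per_muscle, mean_across=mean_across,
                          feature=feature, paired=paired)


def _ttest(tt: pd.Series, ttnf: pd.Series, paired: bool) -> dict:
    tt = tt.dropna()
    ttnf = ttnf.dropna()
    if len(tt) < 2 or len(ttnf) < 2:
        raise ValueError("each condition needs >= 2 subjects")
    if paired:
        res = stats.ttest_rel(tt, ttnf)
    else:
        res = stats.ttest_ind(tt, ttnf)
    if np.var(np.concatenate([tt.to_numpy(), ttnf.to_numpy()])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = float(res.statistic), float(res.pvalue)
    return {"t": t, "p": p, "mean_tt": float(tt.mean()),
            "mean_ttnf": float(ttnf.mean())}


def mean_mdf_covariate(normalized: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-subject mean normalized MDF over the 8 muscles during TT, z-scored."""
    subj = subject_level_means(normalized)
    tt = subj[subj["condition"] == "TT"]
    per_subject = tt.groupby("subject")["norm_mdf"].mean().rename("mean_mdf")
    x = per_subject.to_numpy()
    sd = np.std(x, ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance in mean MDF; cannot normalize")
    out = per_subject.reset_index()
    out["mean_mdf_z"] = (x - x.mean()) / sd
    return out
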