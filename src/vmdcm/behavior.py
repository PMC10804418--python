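"""Tracking-performance analysis.

The performance measure is the root mean square error between the target
trajectory ``z_t`` and the cursor (feedback) trajectory ``y_t`` over a block,

    RMSE = sqrt( (1/T) * sum_t (z_t - y_t)^2 )   [pixels],

computed per block and averaged over each subject's blocks of a condition.
The per-subject *improvement* is RMSE(TTNF) - RMSE(TT) — larger means the
subject gained more from visual feedback — and its mean-centered, z-scored
version is the covariate fed to the group-level model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import BehaviorTrace

CONDITIONS = ("TTNF", "TT")


def compute_rmse(target: np.ndarray, feedback: np.ndarray) -> float:
    """Root mean square error between two equal-length pixel series."""
    z = np.asarray(target, dtype=float)
    y = np.asarray(feedback, dtype=float)
    if z.shape != y.shape:
        raise ValueError("target and feedback must have equal length")
    if z.size == 0:
        raise ValueError("empty trace")
    return float(np.sqrt(np.mean((z - y) ** 2)))


def block_rmse(trace: BehaviorTrace) -> pd.DataFrame:
    """RMSE per contiguous task block of one session."""
    cond = trace.condition
    edges = np.flatnonzero(np.concatenate([[True], cond[1:] != cond[:-1]]))
    bounds = list(edges) + [len(cond)]
    rows = []
    block = 0
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        c = cond[i0]
        if c == "rest":
            continue
        rows.append({"session": trace.session_index, "block": block,
                     "condition": c,
                     "rmse": compute_rmse(trace.target_px[i0:i1],
                                          trace.feedback_px[i0:i1])})
        block += 1
    return pd.DataFrame(rows, columns=["session", "block", "condition", "rmse"])


@dataclass
class RmseSummary:
    """Per-subject condition RMSEs and the normalized improvement covariate."""

    table: pd.DataFrame   # subject, rmse_ttnf, rmse_tt, improvement, improvement_z
    ddof: int = 1

    def covariates(self) -> pd.DataFrame:
        return self.table[["subject", "improvement", "improvement_z"]].rename(
            columns={"improvement": "improved_rmse",
                     "improvement_z": "improved_rmse_z"})


def summarize_group(traces_per_subject: Mapping[object, Iterable[BehaviorTrace]],
                    ddof: int = 1) -> RmseSummary:
    """Pool each subject's block RMSEs and build the improvement covariate.

    Per-subject, per-condition RMSE is the mean over that subject's blocks of
    the condition (robust to unequal block counts); improvement is
    ``RMSE(TTNF) - RMSE(TT)``; normalization is mean-centering followed by
    division by the sample sd (``ddof`` configurable).
    """
    if len(traces_per_subject) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for subject, traces in traces_per_subject.items():
        blocks = pd.concat([block_rmse(tr) for tr in traces])
        per_cond = blocks.groupby("condition")["rmse"].mean()
        missing = [c for c in CONDITIONS if c not in per_cond.index]
        if missing:
            raise ValueError(f"subject {subject!r} lacks condition(s) {missing}")
        rows.append({"subject": subject,
                     "rmse_ttnf": per_cond["TTNF"], "rmse_tt": per_cond["TT"],
                     "improvement": per_cond["TTNF"] - per_cond["TT"]})
    table = pd.DataFrame(rows)
    sd = table["improvement"].std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance in improvement; cannot normalize")
    table["improvement_z"] = (table["improvement"]
                              - table["improvement"].mean()) / sd
    return RmseSummary(table=table, ddof=ddof)


@dataclass
class PairedTestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_condition_test(summary: RmseSummary) -> PairedTestResult:
    """Paired two-sided t-test of per-subject TTNF vs TT RMSE."""
    a = summary.table["rmse_ttnf"].to_numpy(float)
    b = summary.table["rmse_tt"].to_numpy(float)
    return paired_t(a, b)


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 paired values")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return PairedTestResult(t=0.0, p=1.0, n=len(a))
        return PairedTestResult(t=float("nan"), p=float("nan"), n=len(a),
                                degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), p=float(res.pvalue), n=len(a))
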