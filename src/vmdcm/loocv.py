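"""Leave-one-out predictive validity of the group model.

For each left-out subject a PEB model (group mean + one covariate) is fitted
to the remaining subjects using only the designated connections' parameters.
The left-out subject's covariate is then predicted from their own parameter
estimate through the posterior predictive density

    p(x | m_loo) ∝ N(x; 0, 1) * N(m_loo; mu_m + mu_c x,
                                   Sigma_b + S_loo + V_mm + x V_mc + x^2 V_cc)

which marginalizes the group-effect uncertainty (V__ are the blocks of the
group posterior covariance mapped through the design).  The density is
evaluated on a fixed grid, so the whole report is a deterministic function
of the dataset and configuration.  The report carries, per subject, the
predictive expectation, the central 90% credible interval and whether the
actual (z-scored) covariate falls inside it, plus the Pearson correlation
between predictions and actuals.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peb import build_design, fit_peb

GRID = np.linspace(-6.0, 6.0, 601)
CI_LEVEL = 0.90


def _grid_loglik(m_loo: np.ndarray, mu_m: np.ndarray, mu_c: np.ndarray,
                 Sb: np.ndarray, V_mm: np.ndarray, V_mc: np.ndarray,
                 V_cc: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """log N(m_loo; mu_m + mu_c x, Sb + V_mm + x(V_mc+V_mc') + x^2 V_cc)
    evaluated for every x on the grid (small k, vectorized)."""
    k = len(m_loo)
    out = np.empty(len(grid))
    sym = V_mc + V_mc.T
    base = Sb + V_mm
    for gi, xg in enumerate(grid):
        cov = base + xg * sym + xg ** 2 * V_cc
        diff = m_loo - (mu_m + mu_c * xg)
        try:
            c = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            out[gi] = -np.inf
            continue
        z = np.linalg.solve(c, diff)
        out[gi] = (-0.5 * z @ z - np.sum(np.log(np.diag(c)))
                   - 0.5 * k * np.log(2 * np.pi))
    return out


@dataclass
class LoocvReport:
    table: pd.DataFrame       # subject, actual, predicted, lo90, hi90, inside
    r: float
    p: float
    connections: list[str]
    covariate: str

    def write(self, prefix: Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False,
                          float_format="%.10g")
        cov = interval_coverage(self)
        prefix.with_suffix(".json").write_text(json.dumps({
            "r": self.r, "p": self.p, "coverage": cov,
            "connections": self.connections, "covariate": self.covariate,
        }, indent=1, sort_keys=True))


def loo_predict(subject_means: Sequence[np.ndarray],
                subject_covs: Sequence[np.ndarray],
                covariates: pd.DataFrame,
                connection_ids: Sequence[str],
                covariate_name: str,
                param_names: Sequence[str],
                prior_var: np.ndarray | None = None) -> LoocvReport:
    """Leave-one-out prediction of a covariate from designated connections."""
    n = len(subject_means)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    for c in connection_ids:
        if c not in param_names:
            raise ValueError(f"connection {c!r} not in the model")
    x_raw = covariates[covariate_name].to_numpy(dtype=float)
    if np.std(x_raw) == 0:
        raise ValueError("covariate is constant across subjects")
    x = (x_raw - x_raw.mean()) / np.std(x_raw, ddof=1)
    idx = [list(param_names).index(c) for c in connection_ids]
    k = len(idx)
    means_k = [np.asarray(m)[idx] for m in subject_means]
    covs_k = [np.asarray(S)[np.ix_(idx, idx)] for S in subject_covs]
    pv = None
    if prior_var is not None:
        pv = np.asarray(prior_var, dtype=float)[idx]
    rows = []
    for loo in range(n):
        keep = [i for i in range(n) if i != loo]
        x_train = x[keep]
        if np.std(x_train) == 0:
            raise ValueError("covariate constant across training subjects")
        # the fold's design re-standardizes the covariate, so the
        # predictive density lives on the training scale; remember the
        # affine map back to the full-sample z-scale
        m_t = float(np.mean(x_train))
        s_t = float(np.std(x_train, ddof=1))
        design = build_design(pd.DataFrame({covariate_name: x_train}))
        peb = fit_peb([means_k[i] for i in keep], [covs_k[i] for i in keep],
                      design, param_names=list(connection_ids), prior_var=pv)
        mu = peb.beta_mean
        V = peb.beta_cov
        mu_m, mu_c = mu[:k], mu[k:]
        V_mm, V_cc = V[:k, :k], V[k:, k:]
        V_mc = V[:k, k:]
        Sb = np.diag(peb.sigma_b) + covs_k[loo]
        m_loo = means_k[loo]
        logp = (_grid_loglik(m_loo, mu_m, mu_c, Sb, V_mm, V_mc, V_cc, GRID)
                + stats.norm.logpdf(GRID))
        w = np.exp(logp - logp.max())
        w /= np.trapezoid(w, GRID)
        if not np.isfinite(w).all() or w.sum() == 0:
            rows.append({"subject": loo, "actual": x[loo],
                         "predicted": np.nan, "lo90": np.nan,
                         "hi90": np.nan, "inside": False, "degenerate": True})
            continue
        pred = float(np.trapezoid(w * GRID, GRID)) * s_t + m_t
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (w[1:] + w[:-1]) * np.diff(GRID))])
        cdf /= cdf[-1]
        a = (1 - CI_LEVEL) / 2
        lo = float(np.interp(a, cdf, GRID)) * s_t + m_t
        hi = float(np.interp(1 - a, cdf, GRID)) * s_t + m_t
        rows.append({"subject": loo, "actual": float(x[loo]),
                     "predicted": pred, "lo90": lo, "hi90": hi,
                     "inside": bool(lo <= x[loo] <= hi), "degenerate": False})
    table = pd.DataFrame(rows)
    ok = ~table["degenerate"]
    if ok.sum() >= 3 and np.std(table.loc[ok, "predicted"]) > 0:
        r, p = stats.pearsonr(table.loc[ok, "predicted"],
                              table.loc[ok, "actual"])
    else:
        r, p = float("nan"), float("nan")
    return LoocvReport(table=table, r=float(r), p=float(p),
                       connections=list(connection_ids),
                       covariate=covariate_name)


def interval_coverage(report: LoocvReport) -> dict:
    """Fraction of subjects whose actual value lies inside their interval.

    Degenerate records (empty predictive density) are flagged and excluded
    from the fraction.
    """
    if report.table.empty:
        raise ValueError("empty report")
    ok = report.table[~report.table["degenerate"]]
    n_inside = int(ok["inside"].sum())
    return {"n_inside": n_inside, "n_valid": len(ok),
            "n_excluded": int(report.table["degenerate"].sum()),
            "fraction": n_inside / len(ok) if len(ok) else float("nan")}
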