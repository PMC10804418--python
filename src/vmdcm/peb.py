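"""Group-level parametric empirical Bayes over subject posteriors.

The hierarchical model treats each subject's posterior parameter estimate
``m_i`` (with covariance ``S_i``) as a noisy observation of that subject's
true parameter vector, which in turn follows a group-level GLM:

    theta_i = (x_i^T kron I_k) beta + eps_i,    eps_i ~ N(0, Sigma_b),

where ``x_i`` is the subject's row of the design matrix (ones column for the
group mean, plus mean-centered z-scored covariates), ``beta`` stacks one
k-vector of group effects per design column, and the between-subject
covariance is ``Sigma_b = exp(-gamma) * V`` with ``V`` proportional to the
subject-level prior variances.  The precision scale ``gamma`` is set by
empirical Bayes (maximizing the marginal likelihood); ``beta`` then has an
exact Gaussian posterior.

Model pruning uses Bayesian model reduction: for Gaussian priors and
posteriors the evidence and posterior of any model whose prior shrinks
selected effects to a numerical point mass at zero follow in closed form
from the full model, so a greedy search can switch off group effects that do
not contribute to the evidence and a Bayesian model average over the
surviving reduced models yields per-effect posterior probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .dcm_core import PARAM_NAMES, _index_of, default_priors

REDUCED_PRIOR_VAR = 1e-8   # "switched off" = numerical point mass at zero
PP_PRUNE_THRESHOLD = 0.5
MAX_SEARCH_ITER = 64
BMA_ENUM_MAX = 8           # exhaustively average over up to 2^8 final models


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(covariates: pd.DataFrame,
                 columns: Sequence[str] | None = None,
                 ddof: int = 1) -> pd.DataFrame:
    """Ones column plus mean-centered, z-scored covariate columns.

    Already-standardized input columns pass through unchanged
    (standardization is idempotent).  Zero-variance or collinear covariates
    are rejected.
    """
    cols = list(columns) if columns is not None else [
        c for c in covariates.columns if c != "subject"]
    X = pd.DataFrame({"mean": np.ones(len(covariates))},
                     index=covariates.index)
    for c in cols:
        x = covariates[c].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"covariate {c!r} has missing values")
        sd = np.std(x, ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {c!r} has zero variance")
        X[c] = (x - x.mean()) / sd
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# Bayesian model reduction (Gaussian identity)
# ---------------------------------------------------------------------------

def reduce_gaussian(mu: np.ndarray, Sigma: np.ndarray,
                    mu0: np.ndarray, Sigma0: np.ndarray,
                    mu0_r: np.ndarray, Sigma0_r: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """Evidence change and posterior of a reduced-prior model, analytically.

    Given full prior N(mu0, Sigma0), full posterior N(mu, Sigma) and a
    reduced prior N(mu0_r, Sigma0_r), returns ``(dF, mu_r, Sigma_r)`` where
    dF = log evidence(reduced) - log evidence(full).
    """
    P = _inv_psd(Sigma)
    P0 = _inv_psd(Sigma0)
    P0r = _inv_psd(Sigma0_r)
    Pr = P + P0r - P0
    Sigma_r = _inv_psd(Pr)
    h = P @ mu + P0r @ mu0_r - P0 @ mu0
    mu_r = Sigma_r @ h
    dF = 0.5 * (_logdet(P) + _logdet(P0r) - _logdet(P0) - _logdet(Pr))
    dF += 0.5 * (h @ mu_r - mu @ P @ mu - mu0_r @ P0r @ mu0_r
                 + mu0 @ P0 @ mu0)
    return float(dF), mu_r, 0.5 * (Sigma_r + Sigma_r.T)


def _inv_psd(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.T)
    try:
        c = linalg.cho_factor(M)
        return linalg.cho_solve(c, np.eye(M.shape[0]))
    except linalg.LinAlgError as exc:
        raise ValueError("matrix is not positive definite") from exc


def _logdet(M: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(0.5 * (M + M.T))
    if sign <= 0:
        raise ValueError("matrix is not positive definite")
    return float(val)


# ---------------------------------------------------------------------------
# PEB fit
# ---------------------------------------------------------------------------

@dataclass
class PebModel:
    """Group posterior over design-column x parameter effects."""

    param_names: list[str]
    design: pd.DataFrame
    beta_mean: np.ndarray          # (c*k,) ordered column-major by design col
    beta_cov: np.ndarray
    beta_prior_mean: np.ndarray
    beta_prior_cov: np.ndarray
    gamma: float
    free_energy: float
    sigma_b: np.ndarray            # between-subject variances (k,)
    evidence_ledger: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def columns(self) -> list[str]:
        return list(self.design.columns)

    def effect_index(self, param: str, column: str) -> int:
        return self.columns.index(column) * self.n_params \
            + self.param_names.index(param)

    def effect_labels(self) -> list[tuple[str, str]]:
        return [(p, c) for c in self.columns for p in self.param_names]


def fit_peb(subject_means: Sequence[np.ndarray],
            subject_covs: Sequence[np.ndarray],
            design: pd.DataFrame,
            param_names: Sequence[str] = PARAM_NAMES,
            prior_var: np.ndarray | None = None,
            gamma_bounds: tuple[float, float] = (-5.0, 5.0)) -> PebModel:
    """Empirical-Bayes fit of the group GLM over subject posteriors."""
    n = len(subject_means)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if len(subject_covs) != n or len(design) != n:
        raise ValueError("subjects, covariances and design rows must align")
    k = len(param_names)
    for m, S in zip(subject_means, subject_covs):
        if len(m) != k or S.shape != (k, k):
            raise ValueError("parameter spaces differ across subjects")
    X = design.to_numpy(dtype=float)
    c = X.shape[1]
    if prior_var is None:
        _, _, prior_var = default_priors(list(param_names))
    prior_var = np.asarray(prior_var, dtype=float)
    # prior over group effects: same per-parameter variances for every column
    D = np.diag(np.tile(prior_var, c))
    mu_beta0 = np.zeros(c * k)
    # between-subject covariance structure: prior variance / 16 (the usual
    # convention that random effects are an order of magnitude tighter than
    # the prior), rescaled by the empirical-Bayes precision exp(gamma)
    V = np.diag(prior_var) / 16.0

    ms = [np.asarray(m, dtype=float) for m in subject_means]
    Ss = [np.asarray(S, dtype=float) for S in subject_covs]
    Ik = np.eye(k)
    Zs = [np.kron(X[i], Ik) for i in range(n)]   # (k, c*k)

    def _posterior(gamma: float):
        Sigma_b = np.exp(-gamma) * V
        P = _inv_psd(D)
        h = P @ mu_beta0
        ll_data = 0.0
        for i in range(n):
            Wi_inv = _inv_psd(Sigma_b + Ss[i])
            P += Zs[i].T @ Wi_inv @ Zs[i]
            h += Zs[i].T @ Wi_inv @ ms[i]
            ll_data += -0.5 * (_logdet(Sigma_b + Ss[i])
                               + ms[i] @ Wi_inv @ ms[i]
                               + k * np.log(2 * np.pi))
        Sigma_beta = _inv_psd(P)
        mu_beta = Sigma_beta @ h
        # marginal likelihood of the stacked estimates + weak N(0,1) on gamma
        F = ll_data - 0.5 * (_logdet(D) + _logdet(P)) \
            + 0.5 * (h @ mu_beta - mu_beta0 @ _inv_psd(D) @ mu_beta0) \
            - 0.5 * gamma ** 2
        return F, mu_beta, Sigma_beta

    res = optimize.minimize_scalar(lambda g: -_posterior(g)[0],
                                   bounds=gamma_bounds, method="bounded",
                                   options={"xatol": 1e-3})
    gamma = float(res.x)
    F, mu_beta, Sigma_beta = _posterior(gamma)
    return PebModel(param_names=list(param_names), design=design.copy(),
                    beta_mean=mu_beta, beta_cov=Sigma_beta,
                    beta_prior_mean=mu_beta0, beta_prior_cov=D,
                    gamma=gamma, free_energy=float(F),
                    sigma_b=np.exp(-gamma) * prior_var / 16.0)


# ---------------------------------------------------------------------------
# greedy search + BMA
# ---------------------------------------------------------------------------

def default_candidates(peb: PebModel) -> list[tuple[str, str]]:
    """Effects the search may prune.

    Mean column: every modulation (B) and driving-input (C) entry plus the
    between-region (off-diagonal) A entries; self-connections are always
    retained.  Covariate columns: every effect is a candidate.
    """
    cands = []
    for col in peb.columns:
        for p in peb.param_names:
            mat, j, kk = _index_of(p)
            if col == "mean" and mat == "A" and j == kk:
                continue
            cands.append((p, col))
    return cands


def _reduced_prior(peb: PebModel, off: Sequence[tuple[str, str]]):
    Sigma0_r = peb.beta_prior_cov.copy()
    mu0_r = peb.beta_prior_mean.copy()
    for p, colname in off:
        i = peb.effect_index(p, colname)
        Sigma0_r[i, i] = REDUCED_PRIOR_VAR
        mu0_r[i] = 0.0
    return mu0_r, Sigma0_r


def model_evidence(peb: PebModel, off: Sequence[tuple[str, str]]
                   ) -> tuple[float, np.ndarray, np.ndarray]:
    """dF (vs the full model) and reduced posterior with effects in ``off``
    switched off."""
    mu0_r, Sigma0_r = _reduced_prior(peb, off)
    return reduce_gaussian(peb.beta_mean, peb.beta_cov, peb.beta_prior_mean,
                           peb.beta_prior_cov, mu0_r, Sigma0_r)


@dataclass
class SearchResult:
    surviving: list[tuple[str, str]]
    pruned: list[tuple[str, str]]
    candidates: list[tuple[str, str]]
    ledger: pd.DataFrame          # iteration, effect, dF, action
    n_iterations: int


def greedy_search(peb: PebModel,
                  candidates: Sequence[tuple[str, str]] | None = None,
                  max_iter: int = MAX_SEARCH_ITER,
                  evidence_threshold: float = 3.0) -> SearchResult:
    """Iteratively switch off group effects that do not contribute evidence.

    Each iteration evaluates, for every still-active candidate, the evidence
    change of additionally switching that single effect off; all candidates
    whose removal does not cost at least ``evidence_threshold`` nats (the
    conventional "positive evidence" margin — with dozens of candidate
    effects, ~3-sigma flukes carrying a nat or two of apparent evidence are
    expected under the null) are discarded together, and the search stops
    when an iteration discards nothing.
    """
    candidates = list(candidates) if candidates is not None else default_candidates(peb)
    active = list(candidates)
    off: list[tuple[str, str]] = []
    rows = []
    it = 0
    base_dF, _, _ = model_evidence(peb, off) if off else (0.0, None, None)
    for it in range(1, max_iter + 1):
        if not active:
            break
        drops = []
        for cand in active:
            dF, _, _ = model_evidence(peb, off + [cand])
            rel = dF - base_dF
            prune = rel >= -evidence_threshold
            rows.append({"iteration": it, "param": cand[0], "column": cand[1],
                         "dF": rel,
                         "action": "prune" if prune else "keep"})
            if prune:
                drops.append(cand)
        if not drops:
            break
        off.extend(drops)
        active = [c for c in active if c not in drops]
        base_dF, _, _ = model_evidence(peb, off)
    ledger = pd.DataFrame(rows, columns=["iteration", "param", "column",
                                         "dF", "action"])
    peb.evidence_ledger.append(ledger)
    return SearchResult(surviving=active, pruned=off,
                        candidates=candidates, ledger=ledger,
                        n_iterations=it)


@dataclass
class BmaResult:
    """Evidence-weighted average over the surviving reduced models."""

    table: pd.DataFrame     # param, column, mean, pp, pruned
    model_ledger: pd.DataFrame
    weights: np.ndarray

    def lookup(self, param: str, column: str) -> tuple[float, float]:
        row = self.table[(self.table["param"] == param)
                         & (self.table["column"] == column)]
        return float(row["mean"].iloc[0]), float(row["pp"].iloc[0])


def bma(peb: PebModel, search: SearchResult) -> BmaResult:
    """Average over the final iteration's model space.

    With at most :data:`BMA_ENUM_MAX` surviving prunable effects, all their
    on/off combinations (with the greedily pruned effects held off) are
    scored by Bayesian model reduction; posterior model probabilities are the
    softmax of the evidences, the per-effect posterior probability is the
    summed weight of models containing the effect, and posterior means are
    the weighted averages of the reduced posteriors.
    """
    surv = search.surviving
    if len(surv) <= BMA_ENUM_MAX:
        subsets = [[surv[i] for i in range(len(surv)) if not (mask >> i) & 1]
                   for mask in range(2 ** len(surv))]
    else:  # fall back to the greedy endpoint plus single-effect removals
        subsets = [[]] + [[c] for c in surv]
    evidences, posts, rows = [], [], []
    for extra_off in subsets:
        off = search.pruned + list(extra_off)
        dF, mu_r, Sigma_r = model_evidence(peb, off)
        evidences.append(dF)
        posts.append(mu_r)
        rows.append({"off": [f"{p}:{c}" for p, c in off], "dF": dF})
    evid = np.array(evidences)
    w = np.exp(evid - evid.max())
    w /= w.sum()
    mean = sum(wi * mi for wi, mi in zip(w, posts))
    labels = peb.effect_labels()
    pp = np.ones(len(labels))
    for idx, (p, colname) in enumerate(labels):
        if (p, colname) in search.pruned:
            pp[idx] = 0.0
        elif (p, colname) in surv:
            on_w = sum(wi for wi, extra in zip(w, subsets)
                       if (p, colname) not in extra)
            pp[idx] = on_w
    table = pd.DataFrame({
        "param": [p for p, _ in labels],
        "column": [c for _, c in labels],
        "mean": [mean[peb.effect_index(p, c)] for p, c in labels],
        "pp": pp,
    })
    table["pruned"] = table["pp"] < PP_PRUNE_THRESHOLD
    ledger = pd.DataFrame(rows)
    ledger["weight"] = w
    return BmaResult(table=table, model_ledger=ledger, weights=w)
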