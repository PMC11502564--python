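"""Point estimation of log-relative hazards and the baseline hazard.

Two estimation routes are provided for NCC data:

* **conditional** -- the stratified partial likelihood over matched sets
  (case + m controls), identical in form for both designs; equivalent to
  conditional logistic regression.
* **IPW** -- the pseudo-partial likelihood over the pooled sample, with
  risk-set sums replaced by inverse-inclusion-probability weighted sums
  S^(r)(t; beta) = sum_{j in s} w_j exp(beta'Z_j) Z_j^{(x) r} over sampled
  subjects at risk at t.  With the full cohort and unit weights this is
  exactly the Cox partial likelihood, which is how the full-cohort fits in
  the simulation study are computed.

Baseline-hazard estimation mirrors the two routes: the Langholz-Borgan
weighted Breslow estimator inflates each matched set by |R(t)| / |R~(t)| to
represent the full risk set, while the IPW Breslow estimator divides the
event count by S^(0)(t; beta_hat).

All optimizers are Newton-Raphson with step-halving; the likelihoods are
concave in beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .inclusion import InclusionWeights
from .sampling import NCCSample

__all__ = [
    "FitResult",
    "BaselineHazard",
    "fit_cox",
    "fit_ipw",
    "fit_conditional",
    "fit_conditional_strata",
    "breslow_lb",
    "breslow_ipw",
    "cumulative_hazard",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 50
_MAX_HALVINGS = 20
_DIVERGENCE_NORM = 50.0


@dataclass
class FitResult:
    """Converged (pseudo-)partial-likelihood fit."""

    beta: np.ndarray
    loglik: float
    score: np.ndarray
    score_norm: float
    iterations: int
    converged: bool
    information: np.ndarray
    method: str
    # per-case-time weighted sums at beta-hat (pooled fits only)
    case_times: np.ndarray | None = None
    S0: np.ndarray | None = field(default=None, repr=False)
    S1: np.ndarray | None = field(default=None, repr=False)
    S2: np.ndarray | None = field(default=None, repr=False)

    @property
    def cov(self) -> np.ndarray:
        """Inverse observed information (model-based covariance)."""
        return np.linalg.inv(self.information)


@dataclass
class BaselineHazard:
    """Step-function cumulative baseline hazard: increments at case times."""

    times: np.ndarray
    increments: np.ndarray

    def cumulative(self, tau0: float = 0.0, tau1: float = np.inf) -> float:
        """Lambda_0(tau0, tau1]: sum of increments with tau0 < t_k <= tau1."""
        if not tau0 < tau1:
            raise ValueError("tau0 must be < tau1")
        mask = (self.times > tau0) & (self.times <= tau1)
        return float(self.increments[mask].sum())


# ---------------------------------------------------------------------------
# Risk-set sums over (entry, exit] windows via sorted prefix structures
# ---------------------------------------------------------------------------


class _RiskSums:
    """S^(r)(t_k) = sum over subjects with entry < t_k <= exit of x_j * Z_j^r.

    Subjects at risk at t are those with exit >= t minus those with
    entry >= t (entry >= t implies exit > t), so each sum is a difference of
    two sorted suffix sums; O((n + D) log n) per evaluation.
    """

    def __init__(self, entry, exit_, times) -> None:
        self.n = entry.shape[0]
        self.order_exit = np.argsort(exit_, kind="stable")
        self.order_entry = np.argsort(entry, kind="stable")
        self.idx_exit = np.searchsorted(exit_[self.order_exit], times, side="left")
        self.idx_entry = np.searchsorted(entry[self.order_entry], times, side="left")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """x: (n,) or (n, q); returns sums at the prepared times, shape (D,[q])."""
        out_exit = self._suffix(x, self.order_exit, self.idx_exit)
        out_entry = self._suffix(x, self.order_entry, self.idx_entry)
        return out_exit - out_entry

    @staticmethod
    def _suffix(x, order, idx):
        xs = x[order]
        rev = np.cumsum(xs[::-1], axis=0)[::-1]
        pad_shape = (1,) + xs.shape[1:]
        suff = np.concatenate([rev, np.zeros(pad_shape)], axis=0)
        return suff[idx]


def _pack_sym(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columns of the symmetric outer products Z_j Z_j', packed upper-triangular."""
    p = Z.shape[1]
    iu, ju = np.triu_indices(p)
    return Z[:, iu] * Z[:, ju], iu, ju


def _unpack_sym(packed: np.ndarray, iu, ju, p: int) -> np.ndarray:
    out = np.zeros(packed.shape[:-1] + (p, p))
    out[..., iu, ju] = packed
    out[..., ju, iu] = packed
    return out


def _fit_weighted(
    entry, exit_, delta, Z, w, init=None, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER
) -> FitResult:
    """Newton-Raphson root of the weighted pseudo-score (Horvitz-Thompson Cox)."""
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    delta = np.asarray(delta)
    Z = np.atleast_2d(np.asarray(Z, float))
    w = np.asarray(w, float)
    if np.any(np.isnan(Z)):
        raise ValueError("missing covariates in the estimation sample")
    if np.any(w <= 0):
        raise ValueError("non-positive sampling weight")
    n, p = Z.shape

    case_rows = np.flatnonzero(delta == 1)
    case_rows = case_rows[np.argsort(exit_[case_rows], kind="stable")]
    times = exit_[case_rows]
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("tied case times")
    sums = _RiskSums(entry, exit_, times)
    Zsym, iu, ju = _pack_sym(Z)
    Zcase = Z[case_rows]

    beta = np.zeros(p) if init is None else np.asarray(init, float).copy()

    def evaluate(b):
        eta = Z @ b
        x0 = w * np.exp(eta)
        S0 = sums(x0)
        if np.any(S0 <= 0):
            raise ValueError("empty pooled risk set at a case time")
        S1 = sums(x0[:, None] * Z)
        ll = float(np.sum(eta[case_rows]) - np.sum(np.log(S0)))
        return eta, x0, S0, S1, ll

    eta, x0, S0, S1, ll = evaluate(beta)
    score = np.zeros(p)
    info = np.eye(p)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        Zbar = S1 / S0[:, None]
        score = (Zcase - Zbar).sum(axis=0)
        S2 = _unpack_sym(sums(x0[:, None] * Zsym), iu, ju, p)
        info = (S2 / S0[:, None, None] - Zbar[:, :, None] * Zbar[:, None, :]).sum(axis=0)
        score_norm = float(np.max(np.abs(score)))
        if score_norm < tol:
            converged = True
            break
        step = np.linalg.solve(info, score)
        for _ in range(_MAX_HALVINGS + 1):
            cand = beta + step
            if np.max(np.abs(cand)) > _DIVERGENCE_NORM:
                step = step / 2.0
                continue
            cand_eval = evaluate(cand)
            if cand_eval[-1] >= ll - 1e-12 * max(abs(ll), 1.0):
                break
            step = step / 2.0
        else:
            raise ValueError(
                "step-halving failed to increase the log-likelihood (separation?)"
            )
        beta = beta + step
        eta, x0, S0, S1, ll = cand_eval
    if not converged and float(np.max(np.abs(score))) >= tol:
        raise ValueError(f"no convergence in {max_iter} Newton iterations")
    S2 = _unpack_sym(sums(x0[:, None] * Zsym), iu, ju, p)
    return FitResult(
        beta=beta,
        loglik=ll,
        score=score,
        score_norm=float(np.max(np.abs(score))),
        iterations=it,
        converged=True,
        information=info,
        method="ipw",
        case_times=times,
        S0=S0,
        S1=S1,
        S2=S2,
    )


def fit_cox(
    cohort: Cohort, init=None, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER
) -> FitResult:
    """Full-cohort Cox partial-likelihood fit (unit weights, all subjects)."""
    if cohort.covariates is None:
        raise ValueError("cohort carries no covariates")
    if np.any(np.isnan(cohort.covariates)):
        raise ValueError("full-cohort fit requires complete covariates")
    res = _fit_weighted(
        cohort.entry, cohort.exit, cohort.event, cohort.covariates,
        np.ones(cohort.n), init, tol, max_iter,
    )
    res.method = "cox"
    return res


def fit_ipw(
    cohort: Cohort,
    sample: NCCSample,
    weights: InclusionWeights,
    init=None,
    tol=DEFAULT_TOL,
    max_iter=DEFAULT_MAX_ITER,
) -> FitResult:
    """IPW pseudo-partial-likelihood fit on the pooled NCC sample."""
    subj = weights.subject_ids
    idx = cohort.index_of(subj)
    Z = cohort.covariates_of(subj)
    return _fit_weighted(
        cohort.entry[idx], cohort.exit[idx], cohort.event[idx], Z,
        weights.weights, init, tol, max_iter,
    )


# ---------------------------------------------------------------------------
# Conditional (stratified) partial likelihood
# ---------------------------------------------------------------------------


def fit_conditional_strata(
    strata: list, init=None, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER
) -> FitResult:
    """Maximize the stratified partial likelihood.

    ``strata`` is a list of 2D arrays, one per matched set, with the case's
    covariate row first.  Identical code path for both designs.
    """
    strata = [np.atleast_2d(np.asarray(s, float)) for s in strata]
    if not strata:
        raise ValueError("no strata")
    if any(s.shape[0] < 2 for s in strata):
        raise ValueError("every matched set needs the case and at least one control")
    if any(np.any(np.isnan(s)) for s in strata):
        raise ValueError("missing covariates in a matched set")
    p = strata[0].shape[1]
    Z = np.concatenate(strata, axis=0)
    sizes = np.array([s.shape[0] for s in strata])
    labels = np.repeat(np.arange(len(strata)), sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    case_rows = starts  # case first in each stratum
    K = len(strata)
    Zsym, iu, ju = _pack_sym(Z)

    def seg_sum(x):
        if x.ndim == 1:
            return np.bincount(labels, weights=x, minlength=K)
        return np.stack(
            [np.bincount(labels, weights=x[:, j], minlength=K) for j in range(x.shape[1])],
            axis=1,
        )

    beta = np.zeros(p) if init is None else np.asarray(init, float).copy()

    def evaluate(b):
        eta = Z @ b
        shift = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - shift[labels])
        S0 = seg_sum(ex)
        ll = float(np.sum(eta[case_rows] - shift - np.log(S0)))
        return eta, ex, S0, ll

    eta, ex, S0, ll = evaluate(beta)
    score = np.zeros(p)
    info = np.eye(p)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        S1 = seg_sum(ex[:, None] * Z)
        Zbar = S1 / S0[:, None]
        score = (Z[case_rows] - Zbar).sum(axis=0)
        S2 = _unpack_sym(seg_sum(ex[:, None] * Zsym), iu, ju, p)
        info = (S2 / S0[:, None, None] - Zbar[:, :, None] * Zbar[:, None, :]).sum(axis=0)
        score_norm = float(np.max(np.abs(score)))
        if score_norm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            # non-identifiable direction: score is (numerically) zero along it
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        for _ in range(_MAX_HALVINGS + 1):
            cand = beta + step
            if np.max(np.abs(cand)) > _DIVERGENCE_NORM:
                step = step / 2.0
                continue
            cand_eval = evaluate(cand)
            if cand_eval[-1] >= ll - 1e-12 * max(abs(ll), 1.0):
                break
            step = step / 2.0
        else:
            raise ValueError(
                "step-halving failed to increase the log-likelihood (separation?)"
            )
        beta = beta + step
        eta, ex, S0, ll = cand_eval
    if not converged and float(np.max(np.abs(score))) >= tol:
        raise ValueError(f"no convergence in {max_iter} Newton iterations")
    return FitResult(
        beta=beta,
        loglik=ll,
        score=score,
        score_norm=float(np.max(np.abs(score))),
        iterations=it,
        converged=True,
        information=info,
        method="conditional",
    )


def fit_conditional(
    cohort: Cohort, sample: NCCSample, init=None, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER
) -> FitResult:
    """Conditional fit on the matched sets of an NCC sample."""
    strata = []
    for k in range(sample.n_case_times):
        members = sample.matched_set(k)
        if len(members) < 2:
            continue  # empty pool at this case time: stratum carries no information
        strata.append(cohort.covariates_of(members))
    return fit_conditional_strata(strata, init=init, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Breslow-type baseline-hazard estimators
# ---------------------------------------------------------------------------


def breslow_lb(cohort: Cohort, sample: NCCSample, beta) -> BaselineHazard:
    """Langholz-Borgan weighted Breslow estimator from matched sets.

    Each matched set is inflated by |R(t_k)| / |R~(t_k)| so the sampled risk
    set stands in for the full-cohort risk set; only the cohort's follow-up
    skeleton (not its covariates) is needed outside the sample.
    """
    beta = np.asarray(beta, float)
    D = sample.n_case_times
    increments = np.zeros(D)
    for k in range(D):
        members = sample.matched_set(k)
        Zm = cohort.covariates_of(members)
        n_full = cohort.risk_set_size(sample.case_times[k])
        ratio = n_full / len(members)
        denom = ratio * float(np.exp(Zm @ beta).sum())
        increments[k] = 1.0 / denom
    return BaselineHazard(times=np.asarray(sample.case_times).copy(), increments=increments)


def breslow_ipw(fit: FitResult) -> BaselineHazard:
    """IPW weighted Breslow estimator: events / S^(0)(t_k; beta_hat).

    Solves the weighted estimating equation for dLambda_0(t) exactly at each
    case time.  Takes the converged pooled fit (full-cohort or IPW), whose
    stored S^(0) are the weighted at-risk sums.
    """
    if fit.S0 is None:
        raise ValueError("fit carries no risk sums; use a pooled fit")
    return BaselineHazard(times=fit.case_times.copy(), increments=1.0 / fit.S0)


def cumulative_hazard(hazard: BaselineHazard, tau0: float = 0.0, tau1: float = np.inf) -> float:
    """Sum of baseline-hazard increments over (tau0, tau1]."""
    return hazard.cumulative(tau0, tau1)
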