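"""Influence-function variance estimation for IPW NCC estimators.

The estimator's sampling error is linearized as a sum of per-subject
influence functions.  Writing S^(r)(t) for the weighted at-risk sums at the
converged fit, dLambda(t) = 1 / S^(0)(t) for the IPW Breslow increments and
Zbar(t) = S^(1)(t) / S^(0)(t), each sampled subject contributes

    IF_i(score)  = sum_t {Z_i - Zbar(t)} dM_i(t),
    dM_i(t)      = dN_i(t) - exp(eta_i) Y_i(t) dLambda(t),
    IF_i(beta)   = I^{-1} IF_i(score),          I = observed pseudo-information,
    IF_i(dL(t))  = dM_i(t) / S^(0)(t) - dLambda(t) Zbar(t)' IF_i(beta).

These are the *complete-data* per-subject influences (no sampling weight
inside): the weighted sum over the sample, sum_{i in s} w_i IF_i(score),
is exactly the estimating equation and vanishes at convergence.  The
sampling weight enters the variance once, as the Horvitz-Thompson
estimation factor.

The variance of the sum of influences splits into a superpopulation term
(complete-data cohort variance, Horvitz-Thompson weighted) and a design term
driven by the covariances sigma_ij of the sampling indicators:

    N/(N-1) sum_{i in s} w_i IF_i IF_i' + sum_{i,j in s} w_ij w_i w_j IF_i IF_j' sigma_ij.

Cases are included with certainty and contribute nothing to the design term;
pairs never co-at-risk have sigma_ij = 0.  The conditional (partial
likelihood) estimator instead uses the inverse observed information of the
stratified likelihood, with a Taylor-series variance for its
Langholz-Borgan baseline hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort
from .estimators import BaselineHazard, FitResult, breslow_lb
from .inclusion import InclusionWeights
from .sampling import NCCSample

__all__ = [
    "InfluenceSet",
    "VarianceEstimate",
    "influence_functions",
    "interval_hazard_if",
    "variance_estimate",
    "wald_ci",
    "lb_hazard_variance",
]


@dataclass
class InfluenceSet:
    """Per-subject influence functions of the IPW fit.

    ``if_beta`` has one row per sampled subject.  Influences of baseline-
    hazard increments are produced on demand (:meth:`if_dLambda`,
    :func:`interval_hazard_if`) from the stored per-time sums.
    """

    subject_ids: np.ndarray
    delta: np.ndarray
    weights: np.ndarray
    if_beta: np.ndarray
    psi11: np.ndarray
    case_times: np.ndarray = field(repr=False)
    S0: np.ndarray = field(repr=False)
    S1: np.ndarray = field(repr=False)
    dLambda: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    # per-subject index range [lo, hi) of case times within (entry, exit]
    _lo: np.ndarray = field(repr=False)
    _hi: np.ndarray = field(repr=False)
    _case_time_pos: np.ndarray = field(repr=False)  # position of own case time, -1 if none

    @property
    def n(self) -> int:
        return self.subject_ids.shape[0]

    def martingale_residuals(self) -> np.ndarray:
        """dM_i(t_k) = dN_i(t_k) - exp(eta_i) Y_i(t_k) dLambda(t_k), shape (n, D)."""
        D = self.case_times.size
        dM = np.zeros((self.n, D))
        for i in range(self.n):
            dM[i, self._lo[i]: self._hi[i]] = (
                -np.exp(self.eta[i]) * self.dLambda[self._lo[i]: self._hi[i]]
            )
            if self._case_time_pos[i] >= 0:
                dM[i, self._case_time_pos[i]] += 1.0
        return dM

    def if_dLambda(self, k: int) -> np.ndarray:
        """Per-subject influence of the increment at the k-th case time."""
        Zbar = self.S1[k] / self.S0[k]
        at_risk = (self._lo <= k) & (k < self._hi)
        own = self._case_time_pos == k
        comp = np.exp(self.eta) * at_risk * self.dLambda[k]
        return (own.astype(float) - comp) / self.S0[k] - self.dLambda[k] * (
            self.if_beta @ Zbar
        )


def influence_functions(
    cohort: Cohort, fit: FitResult, weights: InclusionWeights
) -> InfluenceSet:
    """Influence functions of the pooled (IPW or full-cohort) fit.

    For the full-cohort fit pass unit weights; the result is the classical
    Cox influence (inverse information times score residual).
    """
    if fit.S0 is None:
        raise ValueError("fit carries no per-time sums; use a pooled fit")
    subj = weights.subject_ids
    idx = cohort.index_of(subj)
    entry = cohort.entry[idx]
    exit_ = cohort.exit[idx]
    delta = cohort.event[idx].astype(int)
    Z = cohort.covariates_of(subj)
    w = weights.weights
    times = fit.case_times
    S0, S1 = fit.S0, fit.S1
    dL = 1.0 / S0
    Zbar = S1 / S0[:, None]
    eta = Z @ fit.beta

    lo = np.searchsorted(times, entry, side="right")
    hi = np.searchsorted(times, exit_, side="right")
    pos = np.full(subj.shape[0], -1, dtype=np.intp)
    is_case = delta == 1
    pos[is_case] = np.searchsorted(times, exit_[is_case])

    # compensator: e^{eta_i} [Z_i A_i - B_i], A = sum Y dL, B = sum Y Zbar dL
    cumA = np.concatenate([[0.0], np.cumsum(dL)])
    cumB = np.concatenate([np.zeros((1, Z.shape[1])), np.cumsum(Zbar * dL[:, None], axis=0)])
    A = cumA[hi] - cumA[lo]
    B = cumB[hi] - cumB[lo]
    comp = np.exp(eta)[:, None] * (Z * A[:, None] - B)
    score_if = -comp
    score_if[is_case] += Z[is_case] - Zbar[pos[is_case]]

    info = fit.information
    if_beta = np.linalg.solve(info, score_if.T).T
    return InfluenceSet(
        subject_ids=subj,
        delta=delta,
        weights=w,
        if_beta=if_beta,
        psi11=-info,
        case_times=times,
        S0=S0,
        S1=S1,
        dLambda=dL,
        eta=eta,
        Z=Z,
        _lo=lo,
        _hi=hi,
        _case_time_pos=pos,
    )


def interval_hazard_if(
    influences: InfluenceSet, tau0: float = 0.0, tau1: float = np.inf
) -> np.ndarray:
    """Per-subject influence of the cumulative baseline hazard over (tau0, tau1]."""
    if not tau0 < tau1:
        raise ValueError("tau0 must be < tau1")
    times = influences.case_times
    k0 = int(np.searchsorted(times, tau0, side="right"))
    k1 = int(np.searchsorted(times, tau1, side="right"))
    n = influences.n
    if k1 <= k0:
        return np.zeros(n)
    dL, S0 = influences.dLambda, influences.S0
    Zbar = influences.S1 / S0[:, None]

    # event part: dN_i(t_i) / S0(t_i) for own case time inside the window
    out = np.zeros(n)
    pos = influences._case_time_pos
    inside = (pos >= k0) & (pos < k1)
    out[inside] = 1.0 / S0[pos[inside]]

    # compensator part over case times in the window intersected with (entry, exit]
    cum = np.concatenate([[0.0], np.cumsum(dL / S0)])
    lo = np.maximum(influences._lo, k0)
    hi = np.minimum(influences._hi, k1)
    span = np.maximum(hi - lo, 0)
    seg = np.where(span > 0, cum[np.maximum(hi, lo)] - cum[lo], 0.0)
    out -= np.exp(influences.eta) * seg

    # propagated beta uncertainty
    g = (Zbar[k0:k1] * dL[k0:k1, None]).sum(axis=0)
    out -= influences.if_beta @ g
    return out


@dataclass
class VarianceEstimate:
    """Two-component covariance: superpopulation + sampling-design terms."""

    cov: np.ndarray
    component_super: np.ndarray
    component_design: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(np.atleast_2d(self.cov)))


def variance_estimate(influences, weights: InclusionWeights, N: int) -> VarianceEstimate:
    """Evaluate the two-term variance for any stack of influence functions.

    ``influences`` is either an :class:`InfluenceSet` (its ``if_beta`` is
    used) or an ``(n, q)`` array aligned with ``weights.subject_ids``.
    """
    IF = influences.if_beta if isinstance(influences, InfluenceSet) else np.asarray(influences)
    if IF.ndim == 1:
        IF = IF[:, None]
    w = weights.weights
    if IF.shape[0] != w.shape[0]:
        raise ValueError("influence rows do not match the sampled subjects")
    super_term = (N / (N - 1)) * (IF * w[:, None]).T @ IF
    nc, M = weights.pairwise_design_matrix()
    IF_nc = IF[nc]
    design_term = IF_nc.T @ (M @ IF_nc)
    design_term = 0.5 * (design_term + design_term.T)
    return VarianceEstimate(
        cov=super_term + design_term,
        component_super=super_term,
        component_design=design_term,
    )


def wald_ci(theta_hat: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """theta_hat +/- z_{(1+level)/2} * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return theta_hat - z * se, theta_hat + z * se


def lb_hazard_variance(
    cohort: Cohort,
    sample: NCCSample,
    fit: FitResult,
    tau0: float = 0.0,
    tau1: float = np.inf,
) -> float:
    """Taylor-series variance of the Langholz-Borgan cumulative hazard.

    Increment variances are dLambda_k^2 (one event against the inflated risk
    sum) and the beta uncertainty is propagated through the gradient
    -sum_k dLambda_k Zbar_k with the conditional fit's covariance.
    """
    beta = fit.beta
    cov = fit.cov
    var = 0.0
    grad = np.zeros_like(beta)
    for k in range(sample.n_case_times):
        t_k = sample.case_times[k]
        if not (tau0 < t_k <= tau1):
            continue
        members = sample.matched_set(k)
        Zm = cohort.covariates_of(members)
        ratio = cohort.risk_set_size(t_k) / len(members)
        ex = np.exp(Zm @ beta)
        S0 = ratio * float(ex.sum())
        Zbar = (ratio * (ex[:, None] * Zm).sum(axis=0)) / S0
        dL = 1.0 / S0
        var += dL**2
        grad -= dL * Zbar
    return float(var + grad @ cov @ grad)
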