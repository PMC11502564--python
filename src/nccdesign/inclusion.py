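"""Inclusion probabilities and sampling weights for NCC designs.

For a non-case i, the probability of ever being sampled as a control is the
complement of never being picked at any case time where i is at risk,

    pi_i = 1 - prod_{k: i at risk at t_k} (1 - m_k / r_k),

with r_k the realized sampling-pool size (r_k for the standard design, r_k*
for the modified design) and m_k the realized number of controls drawn at t_k
(m except at shortfall times).  The joint inclusion probability of two
non-cases i != j is

    pi_ij = pi_i + pi_j - 1 + prod_k f_k,

where f_k = 1 - 2 m_k/r_k + m_k (m_k - 1) / {r_k (r_k - 1)} when both are at
risk at t_k, f_k = 1 - m_k/r_k when exactly one is, and f_k = 1 otherwise.
The product is the probability that i and j are never *both* sampled at the
same time; the formula reduces to pi_i * pi_j when i and j share no at-risk
case time.  Cases have inclusion probability 1 by convention and contribute
no design covariance.

An exhaustive enumeration of the sampling distribution is provided as an
independent oracle on small cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .cohort import Cohort
from .sampling import NCCSample

__all__ = [
    "InclusionWeights",
    "DesignDistribution",
    "at_risk_matrix",
    "inclusion_probabilities",
    "joint_inclusion",
    "sampling_weights",
    "compute_weights",
    "full_cohort_weights",
    "pairwise_design_weights",
    "enumerate_design",
]

_LOG_CLAMP = -1e6  # stands in for log(0) in the vectorized pair products


def at_risk_matrix(cohort: Cohort, subject_ids, case_times) -> np.ndarray:
    """Boolean (D, n) matrix: subject j at risk at case time t_k."""
    idx = cohort.index_of(subject_ids)
    entry = cohort.entry[idx]
    exit_ = cohort.exit[idx]
    t = np.asarray(case_times)[:, None]
    return (entry[None, :] < t) & (t <= exit_[None, :])


def inclusion_probabilities(at_risk, pool_sizes, m, design: str = "modified") -> np.ndarray:
    """First-order inclusion probabilities from the at-risk matrix.

    Parameters
    ----------
    at_risk : bool (D, n) matrix over the subjects of interest (non-cases).
    pool_sizes : realized pool size r_k per case time.
    m : scalar, or per-time realized draw counts m_k.
    """
    at_risk = np.asarray(at_risk, dtype=bool)
    r = np.asarray(pool_sizes, dtype=float)
    m_k = np.broadcast_to(np.asarray(m, dtype=float), r.shape)
    if np.any((m_k > r) & (r > 0)):
        raise ValueError("m exceeds a realized pool size without a recorded shortfall")
    frac = np.zeros_like(r)
    np.divide(m_k, r, out=frac, where=r > 0)
    factors = np.where(at_risk, (1.0 - frac)[:, None], 1.0)
    return 1.0 - factors.prod(axis=0)


def joint_inclusion(at_risk_i, at_risk_j, pool_sizes, m) -> float:
    """Exact pairwise joint inclusion probability for two non-cases.

    ``at_risk_i``/``at_risk_j`` are boolean vectors over case times.  Handles
    degenerate pools (r_k <= m: everyone taken) exactly.
    """
    ai = np.asarray(at_risk_i, dtype=bool)
    aj = np.asarray(at_risk_j, dtype=bool)
    r = np.asarray(pool_sizes, dtype=float)
    m_k = np.broadcast_to(np.asarray(m, dtype=float), r.shape)
    pi_i = 1.0 - np.prod([1.0 - m_k[k] / r[k] for k in np.flatnonzero(ai)] or [1.0])
    pi_j = 1.0 - np.prod([1.0 - m_k[k] / r[k] for k in np.flatnonzero(aj)] or [1.0])
    q = 1.0
    for k in range(r.size):
        if ai[k] and aj[k]:
            if r[k] < 2:
                raise ValueError(f"degenerate pool of size {r[k]} with two subjects at risk")
            q *= 1.0 - 2.0 * m_k[k] / r[k] + m_k[k] * (m_k[k] - 1.0) / (r[k] * (r[k] - 1.0))
        elif ai[k] or aj[k]:
            q *= 1.0 - m_k[k] / r[k]
    return pi_i + pi_j - 1.0 + q


def sampling_weights(pi: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """w_i = delta_i + (1 - delta_i) / pi_i; cases get weight 1."""
    pi = np.asarray(pi, dtype=float)
    delta = np.asarray(delta)
    noncase = delta == 0
    if np.any(noncase & (pi <= 0.0)):
        raise ValueError("zero inclusion probability for a sampled non-case")
    w = np.ones_like(pi)
    w[noncase] = 1.0 / pi[noncase]
    return w


@dataclass
class InclusionWeights:
    """Per-subject inclusion probabilities and IPW weights for a pooled sample.

    ``pi`` is 1 for cases (deterministic inclusion).  Pairwise quantities are
    exposed through :meth:`joint`, :meth:`sigma` and
    :meth:`pairwise_design_matrix`; only non-case pairs that share at least
    one at-risk case time deviate from independence.
    """

    subject_ids: np.ndarray
    delta: np.ndarray
    pi: np.ndarray
    weights: np.ndarray
    at_risk: np.ndarray = field(repr=False)  # (D, n) over subject_ids
    pool_sizes: np.ndarray = field(repr=False)
    m_k: np.ndarray = field(repr=False)
    design: str = "modified"

    def _pos(self, sid) -> int:
        hits = np.flatnonzero(self.subject_ids == sid)
        if hits.size != 1:
            raise KeyError(sid)
        return int(hits[0])

    @property
    def deterministic(self) -> bool:
        """True when every subject is included with certainty (full cohort)."""
        return self.pool_sizes.size == 0

    def joint(self, i, j) -> float:
        """pi_ij for subjects with ids i, j (pi_i for i == j)."""
        a, b = self._pos(i), self._pos(j)
        if a == b:
            return float(self.pi[a])
        if self.deterministic or (self.delta[a] == 1 and self.delta[b] == 1):
            return float(self.pi[a] * self.pi[b])
        if self.delta[a] == 1:
            return float(self.pi[b])
        if self.delta[b] == 1:
            return float(self.pi[a])
        return joint_inclusion(self.at_risk[:, a], self.at_risk[:, b], self.pool_sizes, self.m_k)

    def sigma(self, i, j) -> float:
        """Design covariance of the sampling indicators V_i, V_j."""
        a, b = self._pos(i), self._pos(j)
        if self.delta[a] == 1 or self.delta[b] == 1:
            return 0.0
        if a == b:
            return float(self.pi[a] * (1.0 - self.pi[a]))
        return self.joint(i, j) - float(self.pi[a] * self.pi[b])

    def pair_weight(self, i, j) -> float:
        """w_ij = 1/pi_i if i == j else 1/pi_ij."""
        return 1.0 / self.joint(i, j)

    def pairwise_design_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized M with M_ab = w_ij * w_i * w_j * sigma_ij over non-cases.

        Returns ``(noncase_positions, M)`` where M is symmetric of size
        ``(n_nc, n_nc)``; see :func:`pairwise_design_weights`.
        """
        nc = np.flatnonzero(self.delta == 0)
        if self.deterministic:
            return nc, np.zeros((nc.size, nc.size))
        M = pairwise_design_weights(
            self.at_risk[:, nc], self.pool_sizes, self.m_k, self.pi[nc]
        )
        return nc, M


def compute_weights(cohort: Cohort, sample: NCCSample) -> InclusionWeights:
    """Inclusion probabilities and weights for the pooled sample of ``sample``.

    Pool sizes are the realized r_k (standard) or r_k* (modified) recorded in
    the sample; realized draw counts m_k account for shortfall times.
    """
    if sample.pool_sizes is None:
        raise ValueError("sample lacks pool sizes; run sampling.attach_pools first")
    subj = sample.subjects
    idx = cohort.index_of(subj)
    delta = cohort.event[idx].astype(int)
    ar = at_risk_matrix(cohort, subj, sample.case_times)
    m_k = sample.m_k
    pi = inclusion_probabilities(ar, sample.pool_sizes, m_k, sample.design)
    pi = np.where(delta == 1, 1.0, pi)
    weights = sampling_weights(pi, delta)
    return InclusionWeights(
        subject_ids=subj,
        delta=delta,
        pi=pi,
        weights=weights,
        at_risk=ar,
        pool_sizes=np.asarray(sample.pool_sizes),
        m_k=m_k,
        design=sample.design,
    )


def full_cohort_weights(cohort: Cohort) -> InclusionWeights:
    """Unit weights for the full cohort (pi = 1, no design covariance)."""
    n = cohort.n
    return InclusionWeights(
        subject_ids=cohort.ids,
        delta=cohort.event.astype(int),
        pi=np.ones(n),
        weights=np.ones(n),
        at_risk=np.zeros((0, n), dtype=bool),
        pool_sizes=np.zeros(0),
        m_k=np.zeros(0),
        design="full",
    )


def pairwise_design_weights(at_risk_nc, pool_sizes, m_k, pi_nc) -> np.ndarray:
    """Dense symmetric matrix M_ab = w_ij w_i w_j sigma_ij over sampled non-cases.

    Uses M_ij = w_i w_j (1 - pi_i pi_j / pi_ij) for i != j and
    M_ii = w_i^2 (1 - pi_i), algebraically identical to the definition.  The
    per-pair product over shared at-risk times is evaluated in log space with
    two symmetric matrix products; exact zeros (pools fully taken) are clamped
    to a log value whose exponential underflows to 0.
    """
    A = np.asarray(at_risk_nc, dtype=bool)  # (D, n)
    r = np.asarray(pool_sizes, dtype=float)
    m = np.broadcast_to(np.asarray(m_k, dtype=float), r.shape)
    pi = np.asarray(pi_nc, dtype=float)
    D, n = A.shape
    if n == 0:
        return np.zeros((0, 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(r > 0, 1.0 - m / r, 1.0)
        g = np.where(
            r > 1,
            1.0 - 2.0 * m / np.maximum(r, 1.0)
            + m * (m - 1.0) / np.maximum(r * (r - 1.0), 1.0),
            0.0,
        )
        log_h = np.where(h > 0, np.log(np.maximum(h, 1e-300)), _LOG_CLAMP)
        log_g = np.where(g > 0, np.log(np.maximum(g, 1e-300)), _LOG_CLAMP)

    # Each subject's at-risk case times form one contiguous run [lo, hi) in the
    # sorted schedule (interval censoring), so every per-pair product over
    # shared/exclusive at-risk times is a prefix-sum difference:
    #   log Q_ij = (cumG - 2 cumH)[overlap] + u_i + u_j,
    # with overlap = [max(lo_i, lo_j), min(hi_i, hi_j)).
    hi = D - np.argmax(A[::-1], axis=0)      # one past last at-risk index
    lo = np.argmax(A, axis=0)
    none = ~A.any(axis=0)
    hi[none] = 0
    lo[none] = 0
    if np.any(A.sum(axis=0) != (hi - lo)):
        raise ValueError("non-contiguous at-risk pattern")
    cumH = np.concatenate([[0.0], np.cumsum(log_h)])
    cumGH = np.concatenate([[0.0], np.cumsum(log_g - 2.0 * log_h)])
    u = cumH[hi] - cumH[lo]
    mn = np.minimum.outer(hi, hi)
    mx = np.maximum.outer(lo, lo)
    np.minimum(mx, mn, out=mx)  # clamp empty overlaps
    logQ = (cumGH[mn] - cumGH[mx]) + u[:, None] + u[None, :]
    Q = np.exp(logQ)
    pi_ij = pi[:, None] + pi[None, :] - 1.0 + Q
    w = 1.0 / pi
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pi[:, None] * pi[None, :] / pi_ij
    M = w[:, None] * w[None, :] * (1.0 - ratio)
    np.fill_diagonal(M, w**2 * (1.0 - pi))
    if not np.all(np.isfinite(M)):
        raise ValueError("joint inclusion probability vanished for an observed pair")
    return M


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (small cohorts only)
# ---------------------------------------------------------------------------


@dataclass
class DesignDistribution:
    """The full sampling distribution of a design on a small cohort.

    ``samples[o]`` is the tuple of per-time control tuples of outcome o and
    ``probabilities[o]`` its exact path probability (product over case times
    of 1 / C(pool size, draws)).  Marginal and pairwise control-inclusion
    probabilities are accumulated exactly.
    """

    design: str
    m: int
    case_ids: np.ndarray
    samples: list
    probabilities: np.ndarray
    at_risk_matrix: np.ndarray
    subject_ids: np.ndarray
    pi: dict
    joint: dict

    @property
    def n_outcomes(self) -> int:
        return len(self.samples)

    def total_probability(self) -> float:
        return float(self.probabilities.sum())

    def expected_ht_sum(self, subject_id, pi_value: float) -> float:
        """E(V_i / pi_i) under the enumerated distribution."""
        total = 0.0
        for sample, p in zip(self.samples, self.probabilities):
            v = any(subject_id in controls for controls in sample)
            total += p * (v / pi_value)
        return total


def enumerate_design(
    cohort: Cohort, m: int, design: str = "modified", budget: int = 1_000_000
) -> DesignDistribution:
    """Enumerate every sampling outcome of the design with exact probabilities.

    Walks the case schedule depth-first; for the modified design the pool at
    t_k depends on the controls chosen along the path.  The number of
    outcomes is capped by ``budget``.
    """
    schedule = cohort.event_schedule()
    D = len(schedule)
    case_ids = [cid for _, cid in schedule]
    # upper bound on |Omega| using standard-design pools (largest pools)
    bound = 1
    for t_k, cid in schedule:
        pool = sorted(set(cohort.risk_set(t_k).members) - {cid}, key=str)
        bound *= max(comb(len(pool), min(m, len(pool))), 1)
        if bound > budget:
            raise ValueError(f"enumeration budget exceeded (> {budget} outcomes)")

    samples: list = []
    probs: list = []
    pi: dict = {}
    joint: dict = {}

    def walk(k: int, chosen: tuple, q: frozenset, p: float) -> None:
        if k == D:
            samples.append(chosen)
            probs.append(p)
            ever = frozenset().union(*chosen) if chosen else frozenset()
            for i in ever:
                pi[i] = pi.get(i, 0.0) + p
            for i, j in itertools.combinations(sorted(ever, key=str), 2):
                joint[(i, j)] = joint.get((i, j), 0.0) + p
            return
        t_k, cid = schedule[k]
        pool = sorted(set(cohort.risk_set(t_k).members) - {cid} - set(q), key=str)
        take = min(m, len(pool))
        n_choices = comb(len(pool), take) if take else 1
        for combo in itertools.combinations(pool, take) if take else [()]:
            q_next = q | set(combo) if design == "modified" else q
            walk(k + 1, chosen + (combo,), q_next, p / n_choices)

    walk(0, (), frozenset(), 1.0)
    subj = cohort.ids
    ar = at_risk_matrix(cohort, subj, [t for t, _ in schedule]) if D else np.zeros((0, cohort.n), bool)
    return DesignDistribution(
        design=design,
        m=m,
        case_ids=np.asarray(case_ids),
        samples=samples,
        probabilities=np.asarray(probs),
        at_risk_matrix=ar,
        subject_ids=subj,
        pi=pi,
        joint=joint,
    )
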