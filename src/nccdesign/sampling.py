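"""Control sampling for nested case-control designs.

Two schemes are implemented:

* **standard** -- at every case time, m controls are drawn uniformly without
  replacement (within that time) from the at-risk non-cases; draws at
  different case times are independent, so a subject can serve as a control
  repeatedly.
* **modified** -- controls are drawn without replacement *across* case times:
  once sampled, a subject is excluded from every later sampling pool.  A
  sampled control can still become a case later (case incidence is not under
  the sampler's control), so matched sets are pairwise disjoint as control
  sets but a control id may reappear as a case.

A *coupled* sampler draws both designs on the same cohort with shared
randomness such that the standard sample is a subset of the modified sample,
which makes paired design comparisons sharper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort

__all__ = ["NCCSample", "sample_standard", "sample_modified", "sample_coupled", "attach_pools"]


@dataclass
class NCCSample:
    """A realized NCC sample: matched sets, pools and sampling history.

    ``pool_sizes[k]`` is the realized sampling-pool size at the k-th case time
    (r_k for the standard design, r_k* for the modified design) and drives the
    inclusion probabilities.  ``history[k]`` is the set Q_k of controls sampled
    strictly before t_k (empty for the standard design).  ``shortfall[k]``
    flags case times where the pool held fewer than m candidates and the whole
    pool was taken.
    """

    design: str
    m: int
    case_times: np.ndarray
    case_ids: np.ndarray
    matched_controls: list
    pool_sizes: np.ndarray | None
    history: list | None
    shortfall: np.ndarray
    pools: list | None = None

    @property
    def n_case_times(self) -> int:
        return len(self.case_times)

    @property
    def m_k(self) -> np.ndarray:
        """Realized number of controls drawn at each case time."""
        return np.array([len(c) for c in self.matched_controls])

    @property
    def control_ids(self) -> np.ndarray:
        """Distinct subjects ever sampled as controls."""
        nonempty = [np.asarray(c) for c in self.matched_controls if len(c)]
        if not nonempty:
            return np.asarray(self.case_ids)[:0]
        return np.unique(np.concatenate(nonempty))

    @property
    def subjects(self) -> np.ndarray:
        """The pooled sample s: all cases and all sampled controls, de-duplicated."""
        return np.unique(np.concatenate([np.asarray(self.case_ids), self.control_ids]))

    def matched_set(self, k: int) -> np.ndarray:
        """R-tilde(t_k): the case at t_k plus its sampled controls."""
        return np.concatenate([[self.case_ids[k]], np.asarray(self.matched_controls[k])])

    def sampled_flags(self, cohort: Cohort) -> np.ndarray:
        """V_i (or V_i*): per cohort subject, 1 if ever sampled as a control."""
        flags = np.zeros(cohort.n, dtype=bool)
        if self.control_ids.size:
            flags[cohort.index_of(self.control_ids)] = True
        return flags


def _case_positions(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    order = np.flatnonzero(cohort.event == 1)
    order = order[np.argsort(cohort.exit[order], kind="stable")]
    times = cohort.exit[order]
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("tied case times; resolve ties before sampling")
    return order, times


def _draw(rng: np.random.Generator, pool: np.ndarray, m: int) -> np.ndarray:
    """Uniform without-replacement draw of min(m, |pool|) from an ordered pool."""
    if pool.size <= m:
        return pool.copy()
    # permutation-based draw on the ascending-sorted pool: platform-stable
    return pool[rng.permutation(pool.size)[:m]]


def sample_standard(
    cohort: Cohort, m: int, seed=None, rng: np.random.Generator | None = None
) -> NCCSample:
    """Draw the standard (with replacement across times) NCC sample."""
    return _sample(cohort, m, "standard", seed, rng)


def sample_modified(
    cohort: Cohort, m: int, seed=None, rng: np.random.Generator | None = None
) -> NCCSample:
    """Draw the modified (without replacement across times) NCC sample."""
    return _sample(cohort, m, "modified", seed, rng)


def _sample(cohort, m, design, seed, rng) -> NCCSample:
    if m < 1:
        raise ValueError("m must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    case_pos, case_times = _case_positions(cohort)
    D = case_times.size
    sampled = np.zeros(cohort.n, dtype=bool)  # ever-sampled flags (modified)
    matched, history, psizes, short = [], [], np.zeros(D, dtype=np.intp), np.zeros(D, dtype=bool)
    prior: list = []
    for k in range(D):
        t_k = case_times[k]
        mask = cohort.at_risk_mask(t_k)
        mask[case_pos[k]] = False
        if design == "modified":
            mask &= ~sampled
        pool = np.sort(np.flatnonzero(mask))
        psizes[k] = pool.size
        take = _draw(rng, pool, m)
        short[k] = take.size < m
        history.append(cohort.ids[np.sort(np.array(prior, dtype=np.intp))] if prior else np.array([]))
        if design == "modified":
            sampled[take] = True
            prior.extend(take.tolist())
        matched.append(cohort.ids[np.sort(take)])
    return NCCSample(
        design=design,
        m=m,
        case_times=case_times,
        case_ids=cohort.ids[case_pos],
        matched_controls=matched,
        pool_sizes=psizes,
        history=history if design == "modified" else [np.array([])] * D,
        shortfall=short,
    )


def sample_coupled(
    cohort: Cohort, m: int, seed=None, rng: np.random.Generator | None = None
) -> tuple[NCCSample, NCCSample]:
    """Draw both designs with shared randomness so s_std is a subset of s_mod.

    At each case time, m distinct controls are first drawn from the standard
    pool (these form the standard matched set).  Draws already present in the
    modified design's control history are dropped and replaced by fresh draws
    from the modified pool excluding the retained draws; retained + fresh form
    the modified matched set.  By induction every standard control belongs to
    the modified history, hence s_std is contained in s_mod.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    case_pos, case_times = _case_positions(cohort)
    D = case_times.size
    in_history = np.zeros(cohort.n, dtype=bool)
    std_matched, mod_matched = [], []
    std_sizes = np.zeros(D, dtype=np.intp)
    mod_sizes = np.zeros(D, dtype=np.intp)
    std_short = np.zeros(D, dtype=bool)
    mod_short = np.zeros(D, dtype=bool)
    mod_history: list = []
    prior: list = []
    for k in range(D):
        t_k = case_times[k]
        at_risk = cohort.at_risk_mask(t_k)
        at_risk[case_pos[k]] = False
        std_pool = np.sort(np.flatnonzero(at_risk))
        std_sizes[k] = std_pool.size
        std_take = _draw(rng, std_pool, m)
        std_short[k] = std_take.size < m
        std_matched.append(cohort.ids[np.sort(std_take)])

        retained = std_take[~in_history[std_take]]
        n_fresh = std_take.size - retained.size
        mod_mask = at_risk & ~in_history
        mod_sizes[k] = int(mod_mask.sum())
        mod_take = retained
        if n_fresh > 0:
            mod_mask2 = mod_mask.copy()
            mod_mask2[retained] = False
            fresh_pool = np.sort(np.flatnonzero(mod_mask2))
            fresh = _draw(rng, fresh_pool, n_fresh)
            mod_take = np.concatenate([retained, fresh])
        mod_short[k] = mod_take.size < m
        mod_history.append(
            cohort.ids[np.sort(np.array(prior, dtype=np.intp))] if prior else np.array([])
        )
        in_history[mod_take] = True
        prior.extend(mod_take.tolist())
        mod_matched.append(cohort.ids[np.sort(mod_take)])
    case_ids = cohort.ids[case_pos]
    std = NCCSample(
        design="standard", m=m, case_times=case_times, case_ids=case_ids,
        matched_controls=std_matched, pool_sizes=std_sizes,
        history=[np.array([])] * D, shortfall=std_short,
    )
    mod = NCCSample(
        design="modified", m=m, case_times=case_times, case_ids=case_ids,
        matched_controls=mod_matched, pool_sizes=mod_sizes,
        history=mod_history, shortfall=mod_short,
    )
    return std, mod


def attach_pools(cohort: Cohort, sample: NCCSample) -> NCCSample:
    """Reconstruct realized pool sizes and history for a sample read from file.

    The pool at t_k is the full-cohort risk set minus the case (and, for the
    modified design, minus the controls sampled before t_k); both are
    recoverable from the cohort skeleton plus the matched sets.
    """
    D = sample.n_case_times
    psizes = np.zeros(D, dtype=np.intp)
    history = []
    prior: list = []
    for k in range(D):
        t_k = sample.case_times[k]
        mask = cohort.at_risk_mask(t_k)
        mask[cohort.index_of([sample.case_ids[k]])] = False
        hist_ids = np.array(sorted(prior, key=str)) if prior else np.array([])
        if sample.design == "modified" and prior:
            mask[cohort.index_of(hist_ids)] = False
        history.append(hist_ids)
        psizes[k] = int(mask.sum())
        if sample.design == "modified":
            prior.extend(np.asarray(sample.matched_controls[k]).tolist())
    sample.pool_sizes = psizes
    sample.history = history if sample.design == "modified" else [np.array([])] * D
    return sample
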