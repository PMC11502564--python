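"""Shared fixtures: small worked-example cohorts and simulated data."""

import numpy as np
import pytest

from nccdesign import Cohort, NCCSample, attach_pools


@pytest.fixture
def toy_cohort() -> Cohort:
    """Ten subjects, three cases (ids 1, 4, 6) at times 1, 2, 3.

    Exits are arranged so the standard sampling pools are {2..10} at t1,
    {5..10} at t2 and {7..10} at t3 (ids sorted by exit time).
    """
    ids = list(range(1, 11))
    exits = [1.0, 1.2, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]
    event = [1, 0, 0, 1, 0, 1, 0, 0, 0, 0]
    Z = np.random.default_rng(7).normal(size=(10, 2))
    return Cohort(ids, [0.0] * 10, exits, event, covariates=Z)


@pytest.fixture
def toy_modified_realization(toy_cohort) -> NCCSample:
    """One realized modified-design history on the toy cohort (m = 2).

    Controls {3, 8} at t1, {6, 9} at t2 (subject 6 later becomes the case at
    t3) and {7, 10} at t3, leaving realized pool sizes r* = (9, 5, 2).
    """
    sample = NCCSample(
        design="modified",
        m=2,
        case_times=np.array([1.0, 2.0, 3.0]),
        case_ids=np.array([1, 4, 6]),
        matched_controls=[np.array([3, 8]), np.array([6, 9]), np.array([7, 10])],
        pool_sizes=None,
        history=None,
        shortfall=np.array([False, False, False]),
    )
    return attach_pools(toy_cohort, sample)


@pytest.fixture
def truncated_cohort() -> Cohort:
    """Small cohort with delayed entry arranged so modified-design pool sizes
    are the same along every sampling path (no control can become a case and
    no sampled control leaves the risk set before the last case time)."""
    #   cases enter just before their own case time; non-cases span everything
    ids = list(range(1, 11))
    entry = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.9, 2.9]
    exits = [1.0, 9.0, 9.5, 10.0, 10.5, 11.0, 11.5, 12.0, 2.0, 3.0]
    event = [1, 0, 0, 0, 0, 0, 0, 0, 1, 1]
    Z = np.random.default_rng(11).normal(size=(10, 1))
    return Cohort(ids, entry, exits, event, covariates=Z)
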