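"""Cohort simulator: Cox model with constant baseline hazard.

The generative model is the study-condition model used throughout the test
battery: two standard-normal risk factors with correlation ``rho``, survival
times from a proportional-hazards model with constant baseline rate
``lambda0`` (default ``-log(0.95)/10``, i.e. 5% cumulative incidence at the
study end t=10 for a referent subject), independent exponential dropout
calibrated so a fraction ``p_c`` is censored by the administrative end of
study ``tau_end``, and administrative censoring at ``tau_end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort

__all__ = ["SimConfig", "SimulatedCohort", "generate_cohort", "survival_time"]

DEFAULT_LAMBDA0 = -np.log(0.95) / 10.0


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Attributes
    ----------
    n : cohort size.
    beta : true log-relative hazards (length 2 by default).
    lambda0 : constant baseline hazard rate per unit time.
    rho : correlation of the two standard-normal covariates.
    p_c : probability of dropout (non-administrative censoring) by ``tau_end``;
        the dropout rate is ``alpha = -log(1 - p_c) / tau_end`` so that
        ``P(C <= tau_end) = p_c`` exactly.
    tau_end : administrative end of study.
    seed : RNG seed (any value accepted by ``numpy.random.default_rng``).
    """

    n: int = 5000
    beta: tuple[float, ...] = (0.5, 0.9)
    lambda0: float = DEFAULT_LAMBDA0
    rho: float = 0.25
    p_c: float = 0.2
    tau_end: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")
        if not (0.0 <= self.p_c < 1.0):
            raise ValueError("p_c must lie in [0, 1)")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if not self.tau_end > 0:
            raise ValueError("tau_end must be positive")
        self.beta = tuple(float(b) for b in self.beta)

    @property
    def censoring_rate(self) -> float:
        """Exponential dropout rate alpha with P(C <= tau_end) = p_c."""
        return -np.log1p(-self.p_c) / self.tau_end


@dataclass
class SimulatedCohort:
    """A generated cohort plus the latent times the observer never sees."""

    cohort: Cohort
    latent_T: np.ndarray
    latent_C: np.ndarray
    config: SimConfig = field(repr=False, default=None)


def survival_time(u, z, beta, lambda0: float = DEFAULT_LAMBDA0):
    """Invert the Cox model's survival function at uniform draw ``u``.

    With constant baseline hazard, ``T = -log(u) / (lambda0 * exp(beta'z))``;
    strictly decreasing in ``u``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly in (0, 1)")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    eta = z @ np.asarray(beta, dtype=float)
    t = -np.log(u) / (lambda0 * np.exp(eta))
    return t if t.size > 1 else float(t.reshape(-1)[0])


def generate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Draw one cohort; reproducible given ``config.seed`` (or an explicit rng)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    Z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    eta = Z @ np.asarray(config.beta)
    u = rng.uniform(size=n)
    T = -np.log(u) / (config.lambda0 * np.exp(eta))
    if config.p_c > 0.0:
        C = rng.exponential(scale=1.0 / config.censoring_rate, size=n)
    else:
        C = np.full(n, np.inf)
    exit_ = np.minimum(np.minimum(T, C), config.tau_end)
    event = (T <= np.minimum(C, config.tau_end)).astype(int)
    cohort = Cohort(
        ids=np.arange(1, n + 1),
        entry=np.zeros(n),
        exit=exit_,
        event=event,
        covariates=Z,
    )
    return SimulatedCohort(cohort=cohort, latent_T=T, latent_C=C, config=config)
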