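"""Seeded Monte-Carlo validation of the two frequentist guarantees.

Two experiments, both over many simulated studies:

1. *Long-run error rate.*  With every null true, the fraction of studies
   with p < alpha converges to alpha — the Neyman-Pearson "we shall not be
   too often wrong" guarantee.

2. *Frequentist meaning of the calibrated bound.*  Studies are a mixture:
   with probability pi0 the null holds (p uniform on (0,1)); otherwise an
   alternative generates p from a stochastically smaller distribution.
   Among studies whose p lands in a narrow window around p0, the fraction of
   true nulls is the conditional false-positive proportion.  The calibrated
   bound says this fraction is at least alpha(p0) for every
   decreasing-density alternative, with equality at the least-favorable
   Beta(xi*, 1) alternative, xi* = -1/ln(p0).

Two alternative families are provided:

- ``BetaAlternative(xi)``: p-density xi * p**(xi-1), drawn by inverse
  transform u**(1/xi).  xi = 1 is the uniform null itself.
- ``ShiftedMeanAlternative(delta)``: the z-test alternative with
  standardized mean shift delta; z ~ N(delta, 1), p = 2*(1 - Phi(|z|)).

Every run is driven by an explicit ``numpy.random.default_rng(seed)``; the
seed is echoed into the outcome so any record can be re-run exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .calibration import least_favorable_xi

__all__ = [
    "BetaAlternative",
    "ShiftedMeanAlternative",
    "Alternative",
    "SimConfig",
    "SimOutcome",
    "least_favorable_alternative",
    "draw_pvalue",
    "null_rejection_rate",
    "conditional_null_proportion",
    "analytic_conditional",
]


@dataclass(frozen=True)
class BetaAlternative:
    """Beta(xi, 1) p-value distribution: density xi * p**(xi-1) on (0, 1)."""

    xi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.xi <= 1.0):
            raise ValueError(f"xi must lie in (0, 1]; got {self.xi!r}")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        # inverse transform: P(p <= x) = x**xi  =>  p = u**(1/xi)
        return rng.random(size) ** (1.0 / self.xi)

    def cdf(self, x: float) -> float:
        return float(np.clip(x, 0.0, 1.0)) ** self.xi

    def label(self) -> str:
        return f"beta_xi({self.xi:g})"


@dataclass(frozen=True)
class ShiftedMeanAlternative:
    """Two-sided z-test p-values under a standardized mean shift delta."""

    delta: float

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        z = self.delta + rng.standard_normal(size)
        return 2.0 * stats.norm.sf(np.abs(z))

    def cdf(self, x: float) -> float:
        """P(p <= x) = P(|Z| > c) with c the two-sided critical value of x."""
        if x <= 0.0:
            return 0.0
        if x >= 1.0:
            return 1.0
        c = stats.norm.isf(x / 2.0)
        return float(stats.norm.cdf(self.delta - c) + stats.norm.cdf(-self.delta - c))

    def label(self) -> str:
        return f"shifted_mean({self.delta:g})"


Alternative = Union[BetaAlternative, ShiftedMeanAlternative]


def least_favorable_alternative(p0: float) -> BetaAlternative:
    """The Beta alternative attaining the calibrated bound at p0."""
    return BetaAlternative(xi=least_favorable_xi(p0).xi)


@dataclass(frozen=True)
class SimConfig:
    """A seeded simulation scenario.

    Attributes
    ----------
    pi0 : float
        Probability a simulated study is a true null, in (0, 1]; pi0 = 1
        gives a pure-null run for rejection-rate checks.
    n_experiments : int
        Number of simulated studies.
    seed : int
        RNG seed; recorded in every outcome.
    alternative : Alternative, optional
        p-value distribution for non-null studies (required when pi0 < 1).
    p_window : (float, float), optional
        Conditioning window [lo, hi] in (0, 1) for conditional-proportion
        runs.
    alpha : float, optional
        Rejection threshold for rejection-rate runs.
    """

    pi0: float
    n_experiments: int
    seed: int
    alternative: Optional[Alternative] = None
    p_window: Optional[tuple[float, float]] = None
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pi0 <= 1.0):
            raise ValueError(f"pi0 must lie in (0, 1]; got {self.pi0!r}")
        if self.n_experiments < 1:
            raise ValueError(
                f"n_experiments must be >= 1; got {self.n_experiments!r}"
            )
        if self.pi0 < 1.0 and self.alternative is None:
            raise ValueError("an alternative is required when pi0 < 1")
        if self.p_window is not None:
            lo, hi = self.p_window
            if not (0.0 < lo < hi < 1.0):
                raise ValueError(
                    f"p_window must satisfy 0 < lo < hi < 1; got {self.p_window!r}"
                )


@dataclass(frozen=True)
class SimOutcome:
    """Tallies from one simulation run, with its seed and config echoed."""

    config: SimConfig
    n_null: int
    n_alt: int
    n_window_null: int = 0
    n_window_alt: int = 0
    conditional_null_prop: Optional[float] = None
    mc_se: Optional[float] = None
    null_rejection_rate: Optional[float] = None
    rejection_mc_se: Optional[float] = None

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def n_window(self) -> int:
        return self.n_window_null + self.n_window_alt

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "seed": cfg.seed,
            "pi0": cfg.pi0,
            "n_experiments": cfg.n_experiments,
            "alternative": cfg.alternative.label() if cfg.alternative else None,
            "p_window": list(cfg.p_window) if cfg.p_window else None,
            "alpha": cfg.alpha,
            "n_null": self.n_null,
            "n_alt": self.n_alt,
            "n_window_null": self.n_window_null,
            "n_window_alt": self.n_window_alt,
            "conditional_null_prop": self.conditional_null_prop,
            "mc_se": self.mc_se,
            "null_rejection_rate": self.null_rejection_rate,
            "rejection_mc_se": self.rejection_mc_se,
        }


def draw_pvalue(
    is_null: bool,
    alternative: Optional[Alternative],
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw p-values for ``size`` studies, null-uniform or from ``alternative``."""
    if is_null:
        return rng.random(size)
    if alternative is None:
        raise ValueError("alternative must be given for non-null draws")
    return alternative.draw(rng, size)


def _binomial_se(q: float, m: int) -> float:
    return math.sqrt(q * (1.0 - q) / m) if m > 0 else float("nan")


def null_rejection_rate(config: SimConfig) -> SimOutcome:
    """Long-run type I error rate of a pure-null run: fraction with p < alpha."""
    if config.pi0 != 1.0:
        raise ValueError("null_rejection_rate requires pi0 = 1 (all nulls true)")
    if config.alpha is None:
        raise ValueError("config.alpha must be set for a rejection-rate run")
    rng = np.random.default_rng(config.seed)
    p = draw_pvalue(True, None, rng, config.n_experiments)
    rate = float(np.mean(p < config.alpha))
    return SimOutcome(
        config=config,
        n_null=config.n_experiments,
        n_alt=0,
        null_rejection_rate=rate,
        rejection_mc_se=_binomial_se(rate, config.n_experiments),
    )


def conditional_null_proportion(config: SimConfig) -> SimOutcome:
    """Fraction of true nulls among studies whose p lands in the window.

    Simulates the pi0 / (1 - pi0) mixture, conditions on p in ``p_window``,
    and reports the conditional null proportion with its binomial Monte-Carlo
    standard error.  An empty window (no study landed) is reported as an
    undefined proportion (None) with the counts, never silently as zero.
    """
    if config.p_window is None:
        raise ValueError("config.p_window must be set for a conditional run")
    rng = np.random.default_rng(config.seed)
    n = config.n_experiments
    is_null = rng.random(n) < config.pi0
    n_null = int(is_null.sum())
    n_alt = n - n_null

    p = np.empty(n)
    p[is_null] = draw_pvalue(True, None, rng, n_null)
    if n_alt:
        p[~is_null] = draw_pvalue(False, config.alternative, rng, n_alt)

    lo, hi = config.p_window
    in_window = (p >= lo) & (p <= hi)
    m_null = int((in_window & is_null).sum())
    m_alt = int((in_window & ~is_null).sum())
    m = m_null + m_alt

    prop = m_null / m if m > 0 else None
    se = _binomial_se(prop, m) if m > 0 else None
    outcome = SimOutcome(
        config=config,
        n_null=n_null,
        n_alt=n_alt,
        n_window_null=m_null,
        n_window_alt=m_alt,
        conditional_null_prop=prop,
        mc_se=se,
    )
    if config.alpha is not None:
        null_p = p[is_null]
        rate = float(np.mean(null_p < config.alpha)) if n_null else None
        outcome = SimOutcome(
            config=config,
            n_null=n_null,
            n_alt=n_alt,
            n_window_null=m_null,
            n_window_alt=m_alt,
            conditional_null_prop=prop,
            mc_se=se,
            null_rejection_rate=rate,
            rejection_mc_se=_binomial_se(rate, n_null) if n_null else None,
        )
    return outcome


def analytic_conditional(
    pi0: float, window: tuple[float, float], alternative: Alternative
) -> float:
    """Exact P(null | p in window) for the mixture, no simulation.

    The null contributes mass pi0 * (hi - lo) (uniform p); the alternative
    contributes (1 - pi0) * (F1(hi) - F1(lo)) with F1 its p-value CDF.
    In the point-window limit at p0 with the least-favorable alternative this
    recovers the calibrated bound alpha(p0) exactly.
    """
    if not (0.0 < pi0 < 1.0):
        raise ValueError(f"pi0 must lie strictly in (0, 1); got {pi0!r}")
    lo, hi = window
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"window must satisfy 0 < lo < hi < 1; got {window!r}")
    null_mass = pi0 * (hi - lo)
    alt_mass = (1.0 - pi0) * (alternative.cdf(hi) - alternative.cdf(lo))
    return null_mass / (null_mass + alt_mass)
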