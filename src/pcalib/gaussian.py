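"""Known-variance normal-mean testing: the machinery behind both paradigms.

One sampling model underlies everything here: n observations from a
population with mean mu and known variance sigma2, so by the CLT the sample
mean Xbar ~ N(mu, sigma2/n) and Z = (Xbar - mu0)/sqrt(sigma2/n) is standard
normal under the null H0: mu = mu0.

Fisher significance testing computes the observed z and grades the evidence
by the two-sided p-value P(|Z| > |z|).  Neyman-Pearson hypothesis testing
fixes the type I error alpha in advance, rejects iff |z| exceeds the
critical value z_{1-alpha/2}, and buys a long-run guarantee: over repeated
experiments with a true null, the rejection rate is alpha.  Power, type II
error and sample-size requirements are all evaluated exactly under a point
alternative mu = mu1.

Conventions: two-sided throughout (one-sided variants behind an explicit
``sided`` flag, never default); variance is always passed as ``sigma2``,
never as a bare second normal parameter, to dodge the N(mean, sd) vs
N(mean, var) ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "MeanTestSpec",
    "SignificanceResult",
    "NPDesign",
    "sampling_sd",
    "z_statistic",
    "p_two_sided",
    "p_value",
    "significance_test",
    "tail_probability",
    "critical_value",
    "np_decide",
    "np_design",
    "power",
    "required_n",
    "required_n_continuous",
]

_SIDES = ("two", "greater", "less")


@dataclass(frozen=True)
class MeanTestSpec:
    """A known-variance normal-mean testing problem.

    Attributes
    ----------
    mu0 : float
        Null mean (in the measurement's units, e.g. hours).
    sigma2 : float
        Known population variance (units squared); must be positive.
    n : int
        Sample size, at least 1.
    """

    mu0: float
    sigma2: float
    n: int

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive; got {self.sigma2!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1; got {self.n!r}")


@dataclass(frozen=True)
class SignificanceResult:
    """Observed sample mean with its z statistic and p-value."""

    xbar: float
    z: float
    p: float
    sided: str = "two"


@dataclass(frozen=True)
class NPDesign:
    """A Neyman-Pearson design: pre-set alpha, critical value, power at mu1."""

    alpha: float
    critical_z: float
    mu1: float
    power: float
    beta: float


def sampling_sd(spec: MeanTestSpec) -> float:
    """Standard error of the sample mean, sqrt(sigma2/n)."""
    return math.sqrt(spec.sigma2 / spec.n)


def z_statistic(spec: MeanTestSpec, xbar: float) -> float:
    """Signed standardized statistic (xbar - mu0) / sqrt(sigma2/n)."""
    return (xbar - spec.mu0) / sampling_sd(spec)


def p_two_sided(z: float) -> float:
    """Two-sided p-value 2*(1 - Phi(|z|)) for a standard-normal statistic."""
    z = float(z)
    if not math.isfinite(z):
        raise ValueError(f"z must be finite; got {z!r}")
    return 2.0 * stats.norm.sf(abs(z))


def p_value(z: float, sided: str = "two") -> float:
    """p-value for a standard-normal statistic; ``sided`` in {two, greater, less}."""
    z = float(z)
    if not math.isfinite(z):
        raise ValueError(f"z must be finite; got {z!r}")
    if sided == "two":
        return p_two_sided(z)
    if sided == "greater":
        return float(stats.norm.sf(z))
    if sided == "less":
        return float(stats.norm.cdf(z))
    raise ValueError(f"sided must be one of {_SIDES}; got {sided!r}")


def significance_test(
    spec: MeanTestSpec, xbar: float, sided: str = "two"
) -> SignificanceResult:
    """Fisher significance test: z statistic and its p-value for an observed mean."""
    z = z_statistic(spec, xbar)
    return SignificanceResult(xbar=xbar, z=z, p=p_value(z, sided), sided=sided)


def tail_probability(spec: MeanTestSpec, low: float, high: float) -> float:
    """P(Xbar <= low) + P(Xbar >= high) under the null sampling distribution.

    The null sampling distribution is N(mu0, sigma2/n).  For an interval
    symmetric about mu0 this equals the two-sided p-value of its endpoint.
    """
    if not low < high:
        raise ValueError(f"need low < high; got low={low!r}, high={high!r}")
    sd = sampling_sd(spec)
    return float(
        stats.norm.cdf(low, loc=spec.mu0, scale=sd)
        + stats.norm.sf(high, loc=spec.mu0, scale=sd)
    )


def critical_value(alpha: float) -> float:
    """Two-sided critical value: the upper (1 - alpha/2) standard-normal quantile.

    alpha = 1 degenerately gives 0 (always reject off the null point).
    """
    alpha = float(alpha)
    if not (0.0 < alpha <= 1.0) or math.isnan(alpha):
        raise ValueError(f"alpha must lie in (0, 1]; got {alpha!r}")
    return float(stats.norm.isf(alpha / 2.0))


def np_decide(spec: MeanTestSpec, xbar: float, alpha: float) -> str:
    """Neyman-Pearson decision: 'reject' iff |z| > critical value, else 'accept'.

    Equality with the critical value accepts (the rejection region is the
    strict inequality |z| > z_crit).
    """
    z = z_statistic(spec, xbar)
    return "reject" if abs(z) > critical_value(alpha) else "accept"


def power(spec: MeanTestSpec, mu1: float, alpha: float) -> float:
    """Exact power of the two-sided test at the point alternative mu = mu1.

    With delta = (mu1 - mu0)/sqrt(sigma2/n) and c the critical value,
    power = Phi(delta - c) + Phi(-delta - c).  At mu1 = mu0 this is alpha.
    """
    delta = (mu1 - spec.mu0) / sampling_sd(spec)
    c = critical_value(alpha)
    return float(stats.norm.cdf(delta - c) + stats.norm.cdf(-delta - c))


def np_design(
    spec: MeanTestSpec, mu1: float, alpha: float
) -> NPDesign:
    """Assemble the full Neyman-Pearson design for a point alternative."""
    pw = power(spec, mu1, alpha)
    return NPDesign(
        alpha=alpha,
        critical_z=critical_value(alpha),
        mu1=mu1,
        power=pw,
        beta=1.0 - pw,
    )


def required_n_continuous(
    effect: float, sigma2: float, alpha: float, target_power: float
) -> float:
    """Closed-form (continuous-n) sample size for the two-sided test.

    ``n = sigma2 * (z_{1-alpha/2} + z_{power})**2 / effect**2``.  Ignores the
    far tail, so it slightly underestimates; used as the initializer for the
    exact integer search and for continuous-n ratios between alpha levels.
    """
    effect = float(effect)
    if effect == 0.0:
        raise ValueError("effect must be nonzero (no finite n detects a null effect)")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha!r}")
    if not (0.0 < target_power < 1.0):
        raise ValueError(f"target_power must lie in (0, 1); got {target_power!r}")
    za = stats.norm.isf(alpha / 2.0)
    zb = stats.norm.ppf(target_power)
    return float(sigma2 * (za + zb) ** 2 / effect**2)


def required_n(
    effect: float, sigma2: float, alpha: float, target_power: float
) -> int:
    """Smallest integer n whose exact two-sided power reaches ``target_power``.

    Starts from the closed-form approximation and walks to the true integer
    minimum by exact power evaluation (power is increasing in n for a fixed
    nonzero effect).
    """
    n0 = required_n_continuous(effect, sigma2, alpha, target_power)
    n = max(1, math.floor(n0) - 2)

    def pw(n_: int) -> float:
        spec = MeanTestSpec(mu0=0.0, sigma2=sigma2, n=n_)
        return power(spec, effect, alpha)

    while pw(n) < target_power:
        n += 1
    while n > 1 and pw(n - 1) >= target_power:
        n -= 1
    return n
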