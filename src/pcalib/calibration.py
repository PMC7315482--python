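"""Calibration of p-values into lower bounds on the posterior null probability.

A p-value is routinely misread as "the probability the null hypothesis is
true".  It is not — but it can be *calibrated* into a defensible lower bound
on that probability.  Over the class of alternatives whose p-value density is
decreasing on (0, 1) (the Beta(xi, 1) family, 0 < xi <= 1), the Bayes factor
in favour of H0 given an observed p is bounded below by

    B(p) = -e * p * ln(p),        valid for p < 1/e,

and with prior odds ``omega = prior_null / (1 - prior_null)`` the posterior
probability of the null is bounded below by

    alpha(p) = (1 + [omega * B(p)]**-1)**-1,

which at equal prior odds (omega = 1) is the familiar calibrated p-value
{1 + [-e p ln p]**-1}**-1.  The bound is attained by the least-favorable
member of the family, xi* = -1/ln(p): the alternative under which the
observed p discredits H0 as strongly as any decreasing-density alternative
can.

For p >= 1/e the expression -e p ln p exceeds 1 and no longer bounds a Bayes
factor from below; such p-values carry no evidence against H0 and the bound
is clamped to B = 1 (posterior = prior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

__all__ = [
    "CalibrationResult",
    "LeastFavorableAlternative",
    "INFORMATIVE_THRESHOLD",
    "min_bayes_factor",
    "calibrate",
    "least_favorable_xi",
    "bf_beta_alternative",
    "calibration_table",
]

#: p-values at or above 1/e carry no evidence against the null under the
#: decreasing-density bound; the minimum Bayes factor is clamped to 1 there.
INFORMATIVE_THRESHOLD = 1.0 / math.e

# Below this the log evaluation is too close to the subnormal range to trust;
# refuse rather than silently return a bound of 0.
_P_UNDERFLOW = 1e-300


@dataclass(frozen=True)
class CalibrationResult:
    """A p-value together with its minimum Bayes factor and calibrated bound.

    Attributes
    ----------
    p : float
        The observed p-value, in (0, 1).
    bf_bound : float
        Minimum Bayes factor in favour of H0 over decreasing-density
        alternatives; in (0, 1) for p < 1/e, exactly 1 otherwise.
    alpha_lower : float
        Lower bound on P(H0 | evidence) at the given prior.
    prior_null : float
        Prior probability of the null (default 1/2, equal prior odds).
    informative : bool
        True iff p < 1/e, i.e. the bound is non-trivial.
    """

    p: float
    bf_bound: float
    alpha_lower: float
    prior_null: float
    informative: bool


@dataclass(frozen=True)
class LeastFavorableAlternative:
    """The Beta(xi, 1) alternative attaining the minimum Bayes factor at p0.

    Its p-value density is ``xi * p**(xi - 1)`` on (0, 1); ``xi = -1/ln(p0)``.
    """

    xi: float
    p0: float


def _check_p(p: float, name: str = "p") -> float:
    p = float(p)
    if not (0.0 < p < 1.0) or math.isnan(p):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {name}={p!r}")
    if p < _P_UNDERFLOW:
        raise ValueError(
            f"{name}={p!r} is below {_P_UNDERFLOW:g}; the bound cannot be "
            "evaluated reliably that deep in the tail"
        )
    return p


def min_bayes_factor(p: float) -> float:
    """Minimum Bayes factor ``-e * p * ln(p)`` in favour of the null.

    Parameters
    ----------
    p : float
        Observed p-value, strictly in (0, 1).

    Returns
    -------
    float
        The bound, in (0, 1) for p < 1/e; exactly 1.0 for p >= 1/e, where
        the expression stops being a lower bound and the honest statement
        is "no evidence either way".

    Examples
    --------
    >>> round(min_bayes_factor(0.05), 4)
    0.4072
    """
    p = _check_p(p)
    if p >= INFORMATIVE_THRESHOLD:
        return 1.0
    return -math.e * p * math.log(p)


def calibrate(p: float, prior_null: float = 0.5) -> CalibrationResult:
    """Calibrate a p-value into a lower bound on P(H0 | evidence).

    Applies the minimum Bayes factor to the prior odds:
    ``alpha_lower = omega*B / (1 + omega*B)`` with
    ``omega = prior_null / (1 - prior_null)``.  At the default equal prior
    odds this is exactly ``{1 + [-e p ln p]**-1}**-1``.

    Parameters
    ----------
    p : float
        Observed p-value in (0, 1).
    prior_null : float, optional
        Prior probability of the null, in (0, 1).  Default 1/2.

    Returns
    -------
    CalibrationResult

    Examples
    --------
    >>> round(calibrate(0.05).alpha_lower, 3)
    0.289
    """
    p = _check_p(p)
    prior_null = float(prior_null)
    if not (0.0 < prior_null < 1.0) or math.isnan(prior_null):
        raise ValueError(
            f"prior_null must lie strictly in (0, 1); got {prior_null!r}"
        )
    bf = min_bayes_factor(p)
    omega = prior_null / (1.0 - prior_null)
    posterior_odds = omega * bf
    alpha_lower = posterior_odds / (1.0 + posterior_odds)
    return CalibrationResult(
        p=p,
        bf_bound=bf,
        alpha_lower=alpha_lower,
        prior_null=prior_null,
        informative=p < INFORMATIVE_THRESHOLD,
    )


def least_favorable_xi(p0: float) -> LeastFavorableAlternative:
    """The Beta(xi, 1) shape minimizing the Bayes factor at ``p0``.

    ``xi = -1/ln(p0)``, interior to (0, 1) only for p0 < 1/e.

    Raises
    ------
    ValueError
        If p0 >= 1/e (no interior minimizer: the uniform xi=1 endpoint
        already gives Bayes factor 1) or p0 outside (0, 1).
    """
    p0 = _check_p(p0, "p0")
    if p0 >= INFORMATIVE_THRESHOLD:
        raise ValueError(
            f"p0={p0!r} >= 1/e: the Bayes factor has no interior minimizer "
            "there (the bound is trivially 1)"
        )
    return LeastFavorableAlternative(xi=-1.0 / math.log(p0), p0=p0)


def bf_beta_alternative(p: float, xi: float) -> float:
    """Bayes factor for H0 against a specific Beta(xi, 1) alternative.

    The null p-density is uniform, the alternative density is
    ``xi * p**(xi-1)``, so the factor is ``1 / (xi * p**(xi-1))``.

    Parameters
    ----------
    p : float
        Observed p-value in (0, 1).
    xi : float
        Beta shape in (0, 1]; xi = 1 recovers the null (factor 1).
    """
    p = _check_p(p)
    xi = float(xi)
    if not (0.0 < xi <= 1.0) or math.isnan(xi):
        raise ValueError(f"xi must lie in (0, 1]; got {xi!r}")
    return 1.0 / (xi * p ** (xi - 1.0))


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def calibration_table(
    ps: Iterable[float], prior_null: float = 0.5, decimals: int = 3
) -> list[tuple[float, float]]:
    """Tabulate (p, calibrated lower bound) rows at equal prior odds.

    The bound column is rounded half-up to ``decimals`` places for
    presentation; use :func:`calibrate` for full precision.  Input order is
    preserved; a domain error in any element is re-raised naming its index.
    """
    rows: list[tuple[float, float]] = []
    for i, p in enumerate(ps):
        try:
            res = calibrate(p, prior_null=prior_null)
        except ValueError as exc:
            raise ValueError(f"element {i}: {exc}") from exc
        rows.append((res.p, round_half_up(res.alpha_lower, decimals)))
    return rows


#: The eight p-values whose calibrated bounds the package prints as its
#: self-check grid (the commonly reported significance levels).
REFERENCE_PS: Sequence[float] = (0.20, 0.15, 0.10, 0.05, 0.02, 0.01, 0.005, 0.001)
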