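# Methods

## The calibration

Under the null hypothesis a (continuous, exact) p-value is uniform on
(0, 1). An alternative hypothesis makes small p-values more likely; the
package models this with the Beta(ξ, 1) family, whose p-value density is
ξp^(ξ−1) with shape ξ ∈ (0, 1] — a decreasing power law, with ξ = 1
recovering the uniform null. The Bayes factor in favour of H₀ at an
observed p against a specific member is the density ratio

    BF(p; ξ) = 1 / (ξ p^(ξ−1)).

Minimizing over ξ gives the least-favorable shape ξ\* = −1/ln p (interior to
(0, 1) exactly when p < 1/e) and the minimum Bayes factor

    B(p) = −e · p · ln p.

With prior odds ω = π₀/(1−π₀) the posterior null probability against any
member of the family is therefore bounded below by

    α(p) = ω·B(p) / (1 + ω·B(p)),

the *calibrated p-value* at equal prior odds (ω = 1). The library exposes
`prior_null` with default 1/2 so that the default behaviour is the
equal-odds formula; the generalisation is the standard Bayesian odds
update and costs nothing.

**The p ≥ 1/e regime.** −e·p·ln p rises to 1 at p = 1/e and is not a
meaningful "minimum" beyond it (the minimizing ξ hits the boundary ξ = 1,
i.e. the alternative collapses onto the null). The package clamps the
factor to 1 there and flags the result as uninformative: a Bayes factor of
1 leaves the posterior equal to the prior, which is the honest statement
for a large p-value.

**Numerical edges.** Inputs are validated to lie strictly in (0, 1);
p-values below 1e−300 are rejected with a range error rather than allowed
to underflow the log evaluation into a silent 0. Printed tables use
round-half-up to 3 decimals (`decimal.Decimal`, not banker's rounding), the
convention of published tables; machine-readable output always carries full
precision.

**A transcription note.** The widely reproduced reference grid of
calibrated bounds prints 0.465 at p = 0.20, while the formula gives
0.46668 → 0.467. The package computes the formula; the reproduction test
covers the other seven grid values exactly and documents this cell as a
quirk of the printed source rather than of the mathematics.

## The known-variance z-test machinery

All worked examples live in one sampling model: n observations with
population mean μ and known variance σ², so the sample mean is
(approximately, by the CLT) N(μ, σ²/n) and Z = (X̄−μ₀)/√(σ²/n) is standard
normal under H₀: μ = μ₀. The reference scenario is μ₀ = 24 h, σ² = 200,
n = 50, giving a standard error of exactly 2.

- *Significance testing (Fisher)*: report z and the two-sided p-value
  2(1−Φ(|z|)) as a graded measure of evidence. Two-sided is the default
  everywhere; one-sided variants sit behind an explicit `sided` flag
  because the reference numbers (0.3173, 0.0455, 1.96) are all two-sided
  even though "lasts longer" is a one-sided question.
- *Hypothesis testing (Neyman–Pearson)*: fix α in advance, reject iff
  |z| > z₍₁₋α/₂₎. A tie (|z| exactly at the critical value) accepts: the
  rejection region is the strict inequality. The procedure's guarantee is a
  long-run frequency: among repeated experiments with a true null, the
  rejection rate is α.
- *Power and sample size*: power at a point alternative μ₁ is evaluated
  exactly as Φ(δ−c) + Φ(−δ−c) with δ = (μ₁−μ₀)/√(σ²/n); at μ₁ = μ₀ this is
  α. `required_n` initialises at the closed form
  n ≈ σ²(z₍₁₋α/₂₎+z₍power₎)²/effect² — which ignores the far tail and can be
  off by one — and then walks to the true integer minimum by exact power
  evaluation, so `power(n) ≥ target` and `power(n−1) < target` always hold.
  The "70% larger sample at α = 0.005" figure is the continuous-n ratio
  (z₍₀.₉₉₇₅₎+z₍₀.₈₎)²/(z₍₀.₉₇₅₎+z₍₀.₈₎)² = 1.696, which is scale-free in the
  effect and variance.

σ² is treated as known throughout; there is no t-distribution fallback.
Distribution parameters are always passed as a variance (`sigma2`), never
as a bare second argument, to avoid the N(mean, sd) vs N(mean, var)
ambiguity.

## The Monte-Carlo validator

The simulator emulates a literature of independent experiments. Each
experiment is a true null with probability π₀ (its p-value uniform) or an
alternative with probability 1−π₀, drawn from one of two families:

- `beta_xi(ξ)`: p = u^(1/ξ) by inverse transform — the calibration's own
  class;
- `shifted_mean(δ)`: p = 2(1−Φ(|δ+Z|)), Z standard normal — the z-test
  under a standardized mean shift δ, mirroring the hypothesis-testing
  alternative.

Two quantities are tallied:

1. the pure-null rejection rate (fraction of p < α at π₀ = 1), which
   estimates α — the Neyman–Pearson guarantee;
2. the conditional null proportion: the fraction of true nulls among
   experiments whose p lands in a window [lo, hi] around a target p₀
   (default p₀ ± 10%), with its binomial standard error √(q(1−q)/m).

Every run takes an explicit integer seed into `numpy.random.default_rng`
with a fixed draw order, so identical configurations reproduce bit for bit,
and the seed is echoed into every output record. Default run sizes are
2×10⁶ experiments for conditional-proportion runs and 10⁶ for
rejection-rate runs (a few seconds on one CPU); stochastic tests assert
within 3 Monte-Carlo standard errors and are sized so the conditioning
window holds ≥ 10⁴ experiments.

**Deterministic oracle.** Each simulated conditional proportion is checked
against the exact mixture probability

    P(null | p ∈ [lo, hi]) = π₀(hi−lo) / [π₀(hi−lo) + (1−π₀)(F₁(hi)−F₁(lo))],

where F₁ is the alternative's p-value CDF: x^ξ for `beta_xi`, and
Φ(δ−c)+Φ(−δ−c) with c = Φ⁻¹(1−x/2) for `shifted_mean` (a closed form; the
test suite additionally cross-checks it by quadrature of the p-density
cosh(δc)·e^(−δ²/2)).

**Window averaging.** The calibration α(p₀) is a point statement; the
simulator necessarily conditions on a window. Averaging the alternative's
density over [0.045, 0.055] instead of evaluating it at 0.05 shifts the
least-favorable conditional from 0.28935 to 0.28897 — an O(window-width)
effect that the test tolerances (3 MC SE, ≈ 0.007) absorb comfortably.

**What the bound does and does not claim.** Within the Beta(ξ, 1) family
the conditional null proportion near p₀ is minimized at ξ\* and never falls
below α(p₀): this is verified both analytically (a sweep over ξ with
equality only at ξ\*) and by simulation. The bound is a statement about
that family, not about every conceivable alternative. In particular, the
two-sided mean-shift family has p-density cosh(δc(p))·e^(−δ²/2) — also
decreasing in p, but not a power law — and a shift tuned near the observed
effect (δ ≈ z₀, e.g. δ = 2 for p₀ = 0.05) concentrates more density at p₀
(3.41 versus the Beta-class maximum 1/B(0.05) = 2.46), pushing the
conditional null fraction down to 0.226. Shifts away from the observed
effect (δ ∈ {0.5, 1, 3, 4}) stay above the bound. The validator therefore
asserts the ≥ α(p₀) property over the Beta sweep, and asserts
simulation–oracle agreement (not the bound) for mean-shift alternatives.
Readers using the calibrated value in practice should understand it as a
carefully chosen reference bound — tight within its class, and indicative
rather than universal outside it; the minimum over *all* alternatives at a
fixed z is lower still (e^(−z²/2) for a point alternative at the observed
effect).

## What the generator emulates, and what it does not

The mixture world is idealised: p-values are exact and continuous (no
discreteness, no composite-null conservatism), experiments are independent,
π₀ is known, and alternatives come from two tractable families. Passing
tests therefore demonstrate the internal correctness of the calibration and
of the testing machinery — not that real literatures have π₀ = 1/2 or
Beta-shaped alternatives. No empirical estimate of π₀ exists in scope; 1/2
is the equal-odds reference, and sensitivity to it is exposed through the
`pi0`/`prior_null` parameters rather than asserted.

## Design choices

- Calibration, test machinery and simulation are deliberately kept as
  plain functions over small frozen dataclasses; nothing is fitted, so no
  estimator/results split is warranted.
- scipy supplies all normal CDF/quantile evaluations; numpy's `default_rng`
  supplies randomness; pandas handles the CSV surface. The calibration
  formulas, the exact-power sample-size search and the mixture oracle are
  implemented here.
- CLI exit codes: 0 success, 2 usage/domain error, 3 I/O error. Every
  invocation emits one self-describing run record (command, parameters,
  seed, version, results) so any output can be regenerated from itself.

## Known limitations

- Known-variance z-tests only: no t-tests, two-sample designs, confidence
  intervals or multiple-testing adjustments.
- The calibration addresses a single p-value in isolation; it says nothing
  about optional stopping, p-hacking or model misspecification.
- The bound class is Beta(ξ, 1); see above for how non-power-law
  alternatives can undercut it.
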