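# Methods

## The model

`popimpact` estimates the population impact of a clinical intervention as the
product of two quantities estimated from pragmatic randomised trials:

    impact = RRR × uptake,    RRR = 1 − RR.

The interpretation is conditional on the population of encounters where the
outcome (e.g. an antibiotic prescription) would occur absent the
intervention. Each such encounter falls into exactly one of three strata:

| stratum            | fraction          | meaning                                  |
|--------------------|-------------------|------------------------------------------|
| averted            | uptake × (1 − RR) | intervention used, outcome averted        |
| uptake_no_effect   | uptake × RR       | intervention used, outcome still occurs   |
| no_uptake          | 1 − uptake        | intervention never adopted                |

The strata sum to one by construction; the package asserts this to 1e−12.

The key assumptions, inherited from the estimation strategy:

1. **Trial effectiveness transfers.** The intention-to-treat RR from
   pragmatic trials approximates the effect among clinicians who adopt the
   intervention in routine care.
2. **Trial recruitment proxies uptake.** The fraction of invited clinicians
   who participate in a pragmatic trial of the intervention approximates its
   real-world adoption. Research burden biases this down; trial support and
   post-evidence promotion bias it up. The package computes the estimate; it
   cannot adjudicate the proxy.
3. **Independence.** Effectiveness and uptake are estimated from disjoint
   data (outcome tables vs recruitment logs), so uncertainty is propagated
   under independence.

## Effectiveness: random-effects meta-analysis of relative risks

Per trial, log RR = ln[(a/n₁)/(c/n₂)] with variance 1/a − 1/n₁ + 1/c − 1/n₂.
A zero event count in either arm adds a continuity correction (default 0.5,
the RevMan convention) to all four cells of that trial's 2×2 table.

Pooling uses the DerSimonian–Laird moment estimator:
Q = Σwᵢ(yᵢ − ŷ_FE)² with fixed-effect weights wᵢ = 1/vᵢ;
τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)); random-effects weights
wᵢ* = 1/(vᵢ + τ²); Wald CI on the log scale; I² = max(0, (Q − (k−1))/Q).
DL with a Wald CI matches the random-effects default of the meta-analysis
software in which the source pooled RRs were produced; REML is available via
`tau2_estimator="reml"` for sensitivity analysis but is not the default.
A single study is passed through unchanged (τ² = 0, flagged `single_study`).

Noteworthy edge: for k = 2 the DL estimate satisfies v + τ̂² = (y₁−y₂)²/2, so
rescaling both sampling variances leaves the random-effects CI unchanged
whenever τ̂² > 0 — variance scaling only widens the CI in the homogeneous
(τ̂² = 0) regime.

## Uptake: recruitment cascades and the effective denominator

A cascade is an ordered list of (participated, approached) counts from
outermost (practice) to innermost (clinician) level. Uptake is the product
of the level proportions. The *effective denominator* re-expresses that
product over a single clinician-scale denominator: the innermost approached
count times Π(approachedᵢ/participatedᵢ) over the outer levels — e.g.
92 × (61/22) = 255.09, reported rounded to 255 while the unrounded value is
used in all arithmetic, so proportion ≡ numerator/denominator exactly. The
scaling is undefined when an outer level has zero participating units; such
cascades raise an error and are unusable for uptake estimation.

Single-trial CIs come from `statsmodels.stats.proportion.proportion_confint`:
Clopper–Pearson (default, exact), Wilson, or Wald. The exact interval is
deliberately conservative (coverage ≥ nominal, verified exhaustively in the
tests for n ≤ 30). Wald is retained because at least one published interval
in the case study (12–19% for 53/345) reproduces only under Wald rounding;
the report layer footnotes the method used. Lower bounds are floored at 0 and
upper bounds capped at 1 on the proportion scale.

### Pooling several trials

With J ≥ 2 population-based trials reduced to (xⱼ, nⱼ), the model is a
binomial GLMM with one observation per trial:

    xⱼ ~ Binomial(nⱼ, pⱼ),   logit(pⱼ) = β₀ + uⱼ,   uⱼ ~ N(0, σ²).

The marginal likelihood is maximised directly in (β₀, σ). Each trial's
integral over uⱼ uses **adaptive** Gauss–Hermite quadrature (default 21
nodes): the integrand is recentred at its conditional mode (found by Newton
iteration) and rescaled by the curvature there. This matters — with
thousands of clinicians per trial the integrand is orders of magnitude
narrower than the N(0,1) prior, and fixed-node quadrature can place every
node off the peak and maximise a wrong surface (observed during development:
a 61-node non-adaptive grid search returned a spurious optimum with σ
inflated ~3×). Binomial normalising constants are dropped from the kernel,
which also lets nⱼ be the unrounded effective denominator.

Numerical choices: Nelder-Mead restarted from three fixed starting points
(the pooled logit with σ ∈ {0.1, 0.5}, and a shifted start at σ = 1);
σ entered unsigned (the likelihood is even in σ) and reflected; because the
profile likelihood is quadratically flat in σ at 0, the fit is snapped to the
σ = 0 boundary whenever the σ = 0 profile attains an equal likelihood within
1e−6, and flagged `boundary`. Non-convergence raises an error carrying the
optimiser trace; nothing is reported from a failed fit.

The reported proportion is the population-averaged (marginal) mean
E[expit(β₀ + σZ)], computed by quadrature — not expit(β₀), the
median-clinician value; the published summary is a *mean uptake rate*, and
the conditional value is recoverable from the returned fit. The CI is the
Wald interval for β₀ pushed through the same marginalisation with σ held at
its estimate, floored at 0 (the flooring is inherited from the published
table's convention; on this CI scale it is rarely active). The standard
error comes from the finite-difference observed information in (β₀, σ); at
the σ = 0 boundary it falls back to the binomial information Σnp(1−p).

## Impact uncertainty

No closed-form CI exists for the product, so the interval is Monte-Carlo:
log RR ~ Normal with SE recovered from the RR CI, uptake on the logit scale
~ Normal with SE recovered from its CI by the delta method (one-sided
recovery when a bound sits at 0 or 1), independent draws, percentile
interval, lower bound floored at 0, deterministic given a seed. 10⁵ draws
(the default) give bounds stable to ~3 decimals across seeds. Degenerate
(zero-width) inputs return a point-mass interval with a warning. A negative
RRR (harmful intervention) is propagated unchanged with a prominent warning
rather than clipped.

Ranking is by impact descending, ties broken by higher uptake, then
lexicographic id — so a tie is resolved toward the intervention reaching more
clinicians.

## Synthetic data

The generator emulates exactly what the estimators assume: trial-level true
log RRs drawn Normal(μ, τ²) with binomial arm outcomes (treated risk clipped
at 1 with a warning rather than resampled, keeping the generator total), and
participation at each cascade level drawn binomially with a trial-level
Normal random effect on the log-odds. One seed drives a spawned, per-trial
independent stream, so outputs are reproducible and insensitive to trial
order.

Defaults mirror the antibiotic-prescribing setting the method was developed
on: μ = ln 0.36 and τ = 0.3 (a strongly effective intervention with the
substantial between-trial heterogeneity seen there), control-arm risk 0.6
(mid-range of the published control event rates, 0.49–0.93), arm sizes
100–500, participation log-odds β₀ = logit(0.19) at each level (the observed
single-trial uptake operating point) with σ = 0.5, 20–60 practices
approached and 1–5 clinicians per participating practice. With two cascade
levels the implied single-clinician uptake is ≈ 0.19² ≈ 3.6%; setting
`clinicians_per_practice_range=None` gives single-level (clinician-only)
recruitment at ≈ 19%.

What passing on synthetic data shows — and does not. Recovery tests confirm
the estimators are consistent and approximately unbiased *under the assumed
model*: correct binomial sampling, Gaussian random effects, no selection.
Real recruitment data violate these in known ways (non-random invitation,
clustering below the practice level, reporting gaps), so passing recovery
says nothing about the uptake-proxy assumption itself.

Problem sizes used in the shipped tests and acceptance script — 200 trials
of 500/arm for meta-analysis recovery, 50 trials of 300 clinicians for GLMM
recovery, 20 seeds of a 12-trial pipeline for end-to-end recovery, 10⁵
Monte-Carlo draws — are desk-scale by design; each run completes in seconds
to a couple of minutes on one CPU.

## The case-study inputs and a known inconsistency

The worked example (in `popimpact.example_antibiotics`) takes the published
pooled RRs as *inputs* rather than re-pooling: the per-study 2×2 tables live
in the four underlying systematic reviews and are not reproduced in the
summary tables the package encodes. The meta-analysis engine is therefore
validated on hand-computed and synthetic data, not on those four RRs; the
published per-intervention RRR heterogeneity ranges (42–74%, 42–79%) are
likewise not reproducible from the shipped inputs.

The pooled shared-decision-making uptake is published as 281/3389 across
three trials, but the per-trial recruitment counts reported alongside
(45/345; 101/2036; and a two-level cascade of 4/24 family-medicine groups
then 33/42 physicians, which the effective-denominator rule reduces to
33/252) do not sum to those totals. The package ships both versions; the
pooling reproduction uses the subtraction-based reconstruction of the third
trial (135/1008, labelled synthetic), which restores the published totals.
The discrepancy is documented here, not resolved. On the reconstruction the
GLMM gives a marginal mean of ≈ 10.4% (β₀ = −2.25, σ = 0.49) against the
published 9.5% (0–20%) — the published fit came from different software with
an unstated summary scale, and its floored-at-zero lower bound suggests a
proportion-scale Wald interval rather than the marginalised-logit interval
used here.

## Limitations

- Uptake is clinician-level only; no trial in the case study reported
  patient-level eligibility, so patient uptake is out of scope.
- The impact CI assumes independence and log/logit-normality recovered from
  printed CIs; asymmetric or correlated uncertainty is not modelled.
- Absolute impact (events averted per population) needs baseline event rates
  the recruitment data do not carry.
- One-observation-per-cluster GLMMs are inherently fragile for very few
  trials: with J = 3 the σ CI is essentially uninformative, and the reported
  interval conditions on σ̂.
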