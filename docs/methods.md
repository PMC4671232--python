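# Methods

This note records the model structure, the parameter conventions and the
design decisions behind `hgscreen`, in the spirit of a model write-up a
maintainer can audit.

## Cohort and comparators

The unit of analysis is a *planned live birth* to a mother aged 20–49.
Two comparators are evaluated: standard care (no screening) and a
screening program in which every woman planning a pregnancy receives a
blood-mercury test and, if her level exceeds the intervention threshold,
dietary advice substituting low-Hg/high-PUFA fish for high-Hg species.
The base-case intervention threshold equals the maternal adverse-effect
threshold of 3.4 μg/L; 4.7 and 8 μg/L are scenario thresholds. Costs take
a societal perspective (health care + education) and outcomes are
lifetime discounted QALYs.

## Exposure stage

Maternal blood Hg in each age group is lognormal. The geometric mean is
the lognormal median, so log μ = ln GM exactly; log σ is identified from
upper percentile anchors via ln q_p − ln GM = z_p·σ. For the 20–39 group
one anchor is available (P75 = 1.6 μg/L, giving σ = 1.313); for the
40–59 group two are (P75 = 1.7, P90 = 2.9), combined by least squares
through the origin (σ = 1.006). Using both anchors rather than one is a
modelling choice — the source surveys do not dictate a combination rule —
and is the main lever by which fitted tail masses (and hence counts of
women above 3.4 μg/L) could shift by a few percent.

Exposure categories are defined on the cord-blood scale
(≤5.8, 5.8–7.3, 7.3–10.2, 10.2–13.0, >13.0 μg/L) and mapped to maternal
blood by dividing the cut points by the cord/maternal ratio. The
deterministic analysis uses the mean ratio 1.7 but keeps the *exact*
divided bounds (3.412, 4.294, 6.0, 7.647) rather than their rounded
presentation, because the probabilistic analysis varies the ratio
continuously and the bounds must be functions of it.

The intervention multiplies a treated woman's blood Hg by (1 − e).
Scaling a lognormal preserves lognormality, so the mass a treated
category contributes to each destination category is an exact difference
of normal CDFs; no numerical integration is needed and mass conservation
is structural. An individual-level Monte Carlo oracle (10⁶ simulated
women) confirms the closed form in the test suite.

## Cognition stage

Each above-threshold category k carries an IQ loss
m_k · β · 15 with multipliers m = (0.125, 0.5, 1, 1.25) and β = 0.094 SD
per exposure doubling. The multipliers already encode the blended
linear/logarithmic dose–response; no separate curve is fitted. The
probability of shifting a child into MMR is the exact normal-interval
probability Φ(−2 + loss/15) − Φ(−2); the expected MMR probability per
birth is the category-mass-weighted sum, averaged over age bands using
live-birth weights (band shares renormalized over the modelled 20–49
bands, which carry 97% of births).

## Life-course stage

Alive/dead Markov chain with annual cycles: S(0) = 1,
S(t+1) = S(t)(1 − q(t)). Rewards accrue at the start of each cycle and
are discounted with factor Π(1+r_y)⁻¹; no half-cycle correction is
applied and the child's life begins at the decision time (cycle 0).
QALYs are Σ S(t)·max(u(t) − d·1_MMR, 0)·DF(t) with MMR disutility
d = 0.38 (scenarios 0.56, 0.76). Education costs apply the SEPPA tiers
$931.29 / $715.34 / $472.92 over ages 4–8 / 9–13 / 14–17 (junior
kindergarten through grade 3, grades 4–8, grades 9–12; the tier-to-grade
grouping in the narrative source conflicts with its own table, and the
narrative grouping is adopted). Survival weighting of school ages changes
the education present value by well under 1%.

Screening costs per planned live birth are
(lab test + orphan-share·visit + P(Hg > 3.4)·visit) / 0.9: every screened
pregnancy pays the $23.27 test; the 8% of patients without a family
doctor pay a $33.70 visit to be screened; women above the adverse-effect
threshold pay a visit for the dietary advice; and division by 0.9 (the
probability a planned pregnancy yields a live birth) converts per
screened pregnancy to per planned live birth. The advice visit is tied to
the *adverse-effect* threshold rather than the strategy's intervention
threshold: this costing convention keeps screening-arm costs nearly
constant across intervention thresholds (the behaviour the comparative
cost structure exhibits) and is interpretable as all flagged women
receiving counselling even when only the highest exposures trigger the
formal intervention. At the base threshold the two conventions coincide.

## Probabilistic sensitivity analysis

Nine parameters are uncertain, mutually independent:

| parameter | distribution | rationale |
|---|---|---|
| log μ, each group | Normal(ln GM, SE) | SE back-solved from the GM's 95% CI on the log scale |
| log σ, each group | trunc-Normal(σ̂, SE), σ > 0 | SE propagated from the anchor-percentile CIs through the LS weights |
| cord/maternal ratio | Lognormal, CI (1.0, 3.4) matched symmetrically in logs | positive support, right-skewed printed CI |
| effect β | Gamma(101, 0.000926) | stated uncertainty (mean 0.0935, SE 0.0093) |
| P(success) | Beta(6, 1) | 6 of 7 trial successes |
| effectiveness e | Beta(11.6, 9.2) | mean 0.556, SE 0.11 |
| MMR disutility | trunc-Normal(0.38, 0.021) on [0, 1] | no family stated; positive, bounded utility decrement |

A master seed drives a `numpy` SeedSequence; all marginals are drawn in a
fixed order so runs are bit-reproducible. Every replication is evaluated
with the same vectorized closed-form kernel as the deterministic
analysis, so 5,000 replications take well under a second.

The headline "average ICUR" is the ratio of expected increments
E[ΔC]/E[ΔE]. The per-replication ratio ΔC/ΔE is heavy-tailed (its mean is
dominated by replications with tiny QALY gains), so averaging ratios is
avoided; the 90% interval is still reported from the 5th/95th empirical
percentiles of the per-replication ratios, as is conventional.

## Value of information

EVPI(λ) = E[max_s NB_s(θ)] − max_s E[NB_s(θ)] from the PSA sample.
EVPPI uses the quadrature scheme: the parameter of interest is fixed at
20 equal-probability quantile nodes of its marginal; an inner Monte Carlo
expectation (default 1,000 replications, common random numbers across
nodes) gives conditional mean net benefits; EVPPI is the node-average of
the conditional maxima minus the maximum of the overall means. Small
negative estimates (inner-loop noise) are clipped to zero, matching the
convention of reporting exact zeros for non-influential parameters.
Node and inner-replication counts are package defaults — the quadrature
literature fixes no canonical choice — and are CLI-adjustable.

## Synthetic external inputs

Two inputs the model needs are not part of the printed parameterization:
a period life table and age-specific utility norms. The package generates
stand-ins:

- **Life table**: Gompertz–Makeham q(a) = A + B·e^{ga} with A = 2×10⁻⁴,
  B = 1.5×10⁻⁵, g = 0.10 and an infant bump q(0) = 0.005, closed at age
  110. Curtate life expectancy Σ S(t) ≈ 82 years, emulating a
  contemporary Ontario period table.
- **Utility norms**: u(a) = 0.93 − 0.23·(a/110)^1.5, declining smoothly
  from 0.93 in childhood to 0.70 at the terminal age. All values exceed
  0.38, so the MMR utility never truncates at zero in the base case.

These reproduce the *regime* of real inputs (discounted lifetime QALYs at
5% land in [17, 20]) but not their fine structure: no accident hump in
young-adult mortality, no sex stratification, no plateau in mid-life
utilities. Results that lean on the life table (incremental QALYs, ICURs)
therefore carry a wider tolerance than pure cost accounting, and passing
tests on synthetic inputs demonstrate correct model mechanics, not
calibration to any jurisdiction. Real tables dropped in as
`age,qx` / `age,utility` CSV files are used verbatim.

## Numerical and edge-case conventions

- All category and tail probabilities use `scipy.special.ndtr`; masses sum
  to 1 within 10⁻¹² and intervention conserves mass within 10⁻⁹.
- A median-only percentile anchor (no spread information) yields a
  degenerate fit flag rather than σ = 0.
- `icur` raises on zero QALY difference and flags dominance instead of
  returning a misleading ratio.
- Effectiveness is restricted to [0, 1); the e → 1 limit moves all
  treated mass below the first category boundary.
- Life tables must be closed (q at the terminal age = 1); tables implying
  q > 1 before the terminal age are rejected, not clipped.
- Reported currency is rounded to cents, ICURs to whole dollars and QALYs
  to 4 decimals in CLI outputs; library functions return full precision.

## Problem sizes

Deterministic analyses evaluate a 111-age cohort and run in milliseconds.
The default PSA uses 5,000 replications; the test suite and the
acceptance checks use 1,000-replication PSAs (repeated across five seeds
to quantify Monte Carlo error) and reduced EVPPI settings (8 nodes × 400
inner replications), which reproduce the full-size estimates well inside
their Monte Carlo noise.

## Known limitations

- Cardiovascular effects of mercury, lost lifetime earnings, caregiver
  QALY losses and non-education MMR costs are outside scope.
- The intervention evidence derives from a seven-subject trial arm; the
  Beta distributions propagate, but cannot repair, that fragility.
- Survey design effects (clustering, weights) behind the blood-Hg
  summaries are not modelled; the lognormal fit uses printed summary
  statistics only.
- Children already below IQ 70 before exposure receive no additional
  disutility; only the shift across the MMR boundary is counted.
- All children enter the Markov chain at the decision time regardless of
  maternal age; no gestation lag or maternal-age offset is applied to
  discounting.
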