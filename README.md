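# hgscreen

Cost–utility model of a **periconceptional blood-mercury screening
program** for women planning a pregnancy.

Prenatal methylmercury from maternal fish consumption causes small
cognitive deficits. At the population scale these deficits shift the
entire IQ distribution, pushing children whose IQ would have been just
above 70 into mild mental retardation (MMR, IQ 50–70), with lifelong
quality-of-life losses and remedial-education costs. `hgscreen` evaluates
whether screening women who plan to become pregnant — a single blood test,
followed by dietary fish-substitution advice when blood Hg exceeds a
threshold — is good value for money compared with standard care. It is
aimed at health economists and environmental-health analysts who want a
tested, scriptable implementation of this class of decision model.

## The model

A combined decision tree / Markov cohort model per planned live birth:

- **Exposure.** Maternal blood Hg in each age group (20–39, 40–49) is
  lognormal, fitted to survey geometric means and upper percentiles:
  log μ = ln GM, log σ from the anchor quantiles (least squares when two
  are printed). Cord-blood category cut points (5.8, 7.3, 10.2, 13.0 μg/L)
  divided by the cord/maternal ratio (1.7) define five maternal exposure
  categories.
- **Dose–response.** A doubling of prenatal exposure costs
  β = 0.094 SD of IQ (1.41 points); the four above-threshold categories
  scale this by (0.125, 0.5, 1, 1.25). The probability a child is shifted
  into MMR is Φ((70 + loss − 100)/15) − Φ((70 − 100)/15) under the
  population IQ normal.
- **Intervention.** Dietary advice succeeds with probability
  p ~ Beta(6, 1) (mean 6/7) and multiplies blood Hg by (1 − e) with
  e ~ Beta(11.6, 9.2) (mean 0.556); a scaled lognormal is again lognormal,
  so re-categorization is closed-form.
- **Life course.** An annual alive/dead Markov chain with period
  life-table transitions accumulates discounted QALYs (age-specific
  utility norms, MMR disutility 0.38) and SEPPA remedial-education costs
  over school ages 4–17, at a 5% base discount rate.
- **Decision metrics.** ICUR = ΔC/ΔE, INB(λ) = λ·ΔE − ΔC; probabilistic
  sensitivity analysis over nine uncertain parameters; CEAC, EVPI and
  quadrature EVPPI.

The external life table and utility norms are generated synthetically
(Gompertz–Makeham mortality, life expectancy ≈ 81; utilities declining
0.93 → 0.70) and can be replaced by real two-column CSV files without code
changes. See `docs/methods.md` for assumptions and design choices.

## Worked example

```bash
hgscreen base-case --out results
```

writes `results/base_case.csv`:

```
strategy,cost,qaly,incr_cost,incr_qaly,icur
reference,2.56,18.5197,,,
screening@3.4,33.68,18.5217,31.12,0.001993,15612
screening@4.7,33.92,18.5214,31.36,0.001706,18383
screening@8,34.78,18.5203,32.21,0.000677,47605
```

Reading the base row pair: with no screening, the expected discounted
remedial-education cost is $2.56 per planned live birth and expected
lifetime QALYs are 18.5197. Screening at the 3.4 μg/L threshold costs
$33.68 ($31.12 incremental) and gains 0.001993 QALYs per birth — tiny on
average, but concentrated in the few prevented MMR cases — for an
incremental cost–utility ratio of about $15,600 per QALY, well under a
$50,000/QALY willingness to pay. Raising the intervention threshold saves
nothing and forgoes most of the benefit, so the 3.4 μg/L program dominates.

The same library surface drives:

```bash
hgscreen scenarios --out results            # discounting/disutility/threshold scenarios
hgscreen psa --seed 1 --out results         # PSA, CEAC and EVPI curves
hgscreen voi --seed 1 --out results         # EVPI + nine EVPPIs by willingness to pay
hgscreen synth --out results                # write the synthetic life table/utility norms
```

`hgscreen voi` reports, for example, that at $20,000/QALY the parameter
whose uncertainty is most worth resolving is the spread of the blood-Hg
distribution of women 20–39 (EVPPI ≈ $2.1 per planned live birth), and
that essentially no parameter uncertainty matters at $50,000/QALY.

As a library:

```python
from hgscreen import (default_parameters, synth_life_table,
                      synth_utility_norms, evaluate_strategy, icur, Strategy)

ps, lt, un = default_parameters(), synth_life_table(), synth_utility_norms()
ref = evaluate_strategy(ps, Strategy.reference(), lt, un)
scr = evaluate_strategy(ps, Strategy.screening(3.4), lt, un)
print(icur(ref, scr).value)   # ≈ 15612 CAD per QALY
```

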