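# osicea

Cost-effectiveness analysis of **3 years of adjuvant osimertinib vs placebo
in resected EGFR-mutant stage IB–IIIA NSCLC**, built as a reusable,
fully tested Python package. It covers the whole published-analysis workflow:

1. **Pseudo-digitized data** — simulate right-censored survival samples from
   six parametric families and turn them into "digitized" Kaplan–Meier
   coordinates plus numbers-at-risk tables (`osicea.synthetic_data`), so the
   pipeline is testable end to end with known ground truth.
2. **IPD reconstruction** — invert digitized KM curves and risk tables back
   into individual patient-level data, Guyot-style (`osicea.ipd_reconstruction`).
3. **Parametric survival fitting** — censored maximum likelihood for
   exponential, Weibull, gamma, log-normal, log-logistic and generalized
   gamma; AIC/BIC model selection; a martingale/Schoenfeld-residual
   proportional-hazards diagnostic (`osicea.parametric_survival`).
4. **Markov cohort model** — four states (NED, PD CNS−, PD CNS+, Death), two
   arms, monthly cycles over a 10-year horizon, with tunnel sub-states for
   time-since-progression, tiered costs and utilities, discounted at 3%/yr
   (costs) and 5%/yr (QALYs) (`osicea.markov_cohort`).
5. **CEA and sensitivity analyses** — ICER vs a $195,000/QALY threshold,
   deterministic sweeps of the assumed overall-survival benefit and of drug
   price discounts, and a 1000-draw probabilistic sensitivity analysis on the
   cost-effectiveness plane (`osicea.cea_sensitivity`).

## The model

Disease-free survival in each arm is described by log-normal fits to the
CNS-positive-event and CNS-negative-event curves,
S(t) = 1 − Φ((ln t − μ)/σ) with t in years. Each DFS event is split into
recurrence vs death using the observed event composition (33/39, 4/6,
118/120, 31/31). Post-progression survival follows a Gamma(α = 1.86,
β = 0.56 yr⁻¹) fit to pooled first/second-line osimertinib reference data
(mean 1/0.56 · 1.86 ≈ 3.3 years), with the assumed overall-survival benefit
of osimertinib entering as a hazard ratio (0.95 in the base case) on the
PD→death transition. Background mortality (63-year-old US male, 0.012/yr)
acts on every alive state.

Per cycle of length Δ, state occupancies advance through competing-risk
transition probabilities of the form 1 − S(t+Δ)/S(t); costs and QALYs accrue
half-cycle corrected, with one-time costs (progression work-up, CNS+ burden,
end-of-life, adverse events, EGFR testing) attached to state-entry masses.
The headline result is the incremental cost-effectiveness ratio
ICER = ΔC/ΔE of osimertinib vs placebo.

## Worked example

```python
import osicea

cfg = osicea.load_config()            # packaged base-case inputs
placebo, osi, res = cfg.cea_model().evaluate()
print(f"{placebo.arm}: total ${placebo.cost_total:,.0f}, {placebo.qalys:.3f} QALYs")
print(f"{osi.arm}: total ${osi.cost_total:,.0f}, {osi.qalys:.3f} QALYs")
print(f"ICER ${res.icer:,.0f}/QALY -> {res.verdict}")
```

prints

```
placebo: total $290,734, 4.301 QALYs
osimertinib: total $773,375, 5.273 QALYs
ICER $496,380/QALY -> not_cost_effective
```

Per model entrant, the placebo cohort accrues 4.301 discounted QALYs and
$290,734 (almost entirely post-progression: osimertinib re-treatment,
CNS-disease burden and end-of-life care), while the osimertinib cohort
accrues 5.273 QALYs and $773,375 (dominated by the 3-year adjuvant drug
cost). Buying the extra 0.97 QALYs costs $496,380 each — far above the
$195,000/QALY willingness-to-pay threshold (3× US GDP per capita), so the
strategy is not cost-effective at list price under the base-case 5% OS
benefit. See `docs/methods.md` for the calibration choices behind these
numbers and a discussion of how they relate to previously reported values.

The same analyses are available from the command line:

```bash
osicea run-base                 # base case, traces + results.json
osicea sweep-os                 # ICER vs assumed OS benefit (0-45%)
osicea sweep-discount           # ICER vs drug price discount
osicea psa --n 1000 --seed 1    # probabilistic sensitivity analysis
osicea fit ipd.csv              # six-family fit + AIC/BIC table
osicea reconstruct curve.csv risk.csv   # digitized KM -> patient-level data
```

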