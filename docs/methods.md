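# Methods

## Model structure

The decision problem compares two strategies for resected EGFR-mutant stage
IB–IIIA NSCLC: 3 years of adjuvant osimertinib vs placebo. A cohort Markov
model with four aggregated health states — NED (no evidence of disease),
PD CNS-negative, PD CNS-positive, Death — is propagated in monthly cycles
(Δ = 1/12 year) over a 10-year horizon, starting 100% NED. All times are in
years; all costs in inflation-adjusted US dollars as published.

### NED dynamics and the two DFS curves

The disease-free survival evidence enters as **two log-normal models per
arm**, fitted (in the original trial analysis) to the CNS-positive-event and
CNS-negative-event curves:

| arm | stratum | μ | σ | median e^μ |
|---|---|---|---|---|
| placebo | CNS+ events | 1.94 | 1.22 | 7.0 y |
| placebo | CNS− events | 1.11 | 1.44 | 3.0 y |
| osimertinib | CNS+ events | 2.66 | 0.91 | 14.3 y |
| osimertinib | CNS− events | 2.19 | 1.13 | 8.9 y |

Because each curve describes an event *subset*, two readings of the joint
NED exit process are defensible, and the package implements both
(`ModelInputs.ned_structure`):

- **partitioned** (default): the NED cohort is split at model start into a
  CNS-positive-event stratum and a CNS-negative-event stratum, weighted by
  the observed event composition (39/159 placebo, 6/37 osimertinib); each
  stratum exits through its own fitted curve. Aggregate NED survival is the
  event-share-weighted mixture of the two curves.
- **competing**: a single NED pool faces both processes as independent
  latent competing risks; aggregate NED survival is the product of the two
  curves. `build_transition_matrix` exposes this reading as an explicit 4×4
  one-cycle matrix.

The default was **frozen by a one-time calibration** against the published
base-case outcomes: the partitioned reading reproduces the published
per-arm QALYs (5.108 / 4.169) and the QALY difference (0.9389) to about 3%,
while the competing reading misses the placebo QALYs by ~15% (its product
survival empties NED far faster). The competing reading, conversely, comes
closer to the published placebo cost components. No single reading
reproduces both — see *Known limitations*. The calibration was run once and
the default not revisited per target.

Each DFS event splits into recurrence (→ the matching PD state) vs death
using recurrence fractions computed exactly from the published event counts
(33/39 = 85%, 4/6 = 67%, 118/120 = 98%, 31/31 = 100%). Background
non-disease mortality, a configurable annual probability with default
0.012/yr (63-year-old US male), acts on every alive state. Within a cycle,
simultaneous exit causes are combined as constant hazards: the joint stay
probability is the product of the per-cause stay probabilities, and the exit
mass is allocated proportionally to the cause hazards −log(1−p).

### Post-progression survival and tunnel states

PD→death follows a gamma fit to pooled reference-arm overall survival of
osimertinib-treated metastatic disease, parameterized as **shape α = 1.86,
rate β = 0.56 yr⁻¹** (mean α/β ≈ 3.32 years). The rate-vs-scale ambiguity
was resolved by the documented calibration: the scale reading (mean ≈ 1.04
years) roughly halves post-progression costs and is clinically incoherent
for this population, so the rate reading is frozen in the packaged config.

PD death probabilities are conditioned on **time since progression** via
cycle-indexed tunnel sub-states (the trace aggregates them back to the four
reported states). The assumed overall-survival benefit of osimertinib is a
hazard ratio on this transition: conditional survival is raised to the power
HR, with HR = 1 − risk reduction (base case 0.95, i.e. a 5% benefit).

### Costs, utilities, adverse events

Accruals per cycle use half-cycle-corrected occupancy (average of the
cycle-boundary occupancies); one-time costs attach to entry masses at the
cycle midpoint. Costs discount at 3%/yr, QALYs at 5%/yr, both as
(1+r)^(−t).

- NED: tiered follow-up ($1,078.76/yr years 1–3, $539.38 years 4–5, $296.69
  after), plus adjuvant drug $222,196/yr while t < 3 years (osimertinib arm).
- PD entry (both arms are re-treated): one-time diagnosis work-up $7,202.88,
  probability-weighted adverse-event costs, and, for CNS+ entrants, the
  one-time lifetime CNS+ burden $43,598.83. The placebo arm pays the EGFR
  test ($324.58) here; the osimertinib arm pays it at model start.
- PD occupancy: health-care $1,186.76/yr, MRIs $1,482.56/yr (CNS+ only),
  re-treatment drug $222,196/yr while time-in-PD < 2 years (tunnel-tracked).
- Death entry: end-of-life care $78,571.06.
- Adverse events (grade ≥ 3) are expected one-time cost and disutility
  decrements: the pre-progression profile at adjuvant treatment start
  (osimertinib arm), the post-progression profile at PD entry, the CNS+
  profile (disutilities only; costs folded into the CNS+ one-time figure) at
  CNS+ PD entry.
- Utilities: NED 0.830 (placebo) / 0.812 (osimertinib), PD CNS− 0.71,
  PD CNS+ 0.55; Death 0.

Drug price discounts (`drug_discount_fraction`) scale both the adjuvant and
the re-treatment osimertinib cost.

## Survival stack

`fit_parametric` maximizes the right-censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t) with a deterministic multi-start
L-BFGS-B on log-transformed positive parameters (ftol 1e-8). Families and
conventions are fixed in `osicea._families`; the generalized gamma uses the
log-time (location μ, scale σ, shape q) parameterization — the classic trap
family, mapped to `scipy.stats.gengamma` in exactly one place. AIC/BIC
selection is a stable ascending AIC sort with the BIC winner flagged
separately; disagreement is reported, never silently resolved. The
proportional-hazards diagnostic fits a two-group Cox model and applies the
scaled-Schoenfeld-residual score test for a time trend (rank transform) at
α = 0.05; lifelines provides the KM estimator, the Cox fit and the residual
test, and its parametric fitters serve as independent cross-checks in the
test suite (the package's own MLE is the implementation under test).

`reconstruct_ipd` inverts a digitized curve plus numbers-at-risk table
interval by interval: events are placed at drop times via the product-limit
relation d = n·(1 − S/S_prev), censorings are spread uniformly over each
inter-risk-time interval, and the censoring count is iterated until the
implied number at risk matches the table. Integer counts use
half-away-from-zero rounding with a carried remainder so totals are
conserved; residual ±1 mismatches (inevitable with integer counts) are
carried forward with a warning, while gross inconsistencies — more digitized
exits than the table permits, beyond max(2, 5% of the interval cohort) —
raise a reconciliation error naming the interval. A published total event
count, when supplied, is honored by rebalancing the final interval. With
annual risk tables (the granularity trials print) the KM round-trip error is
below 0.006 across all six families at n = 300; the acceptance property
requires ≤ 0.02.

## Synthetic data

`simulate_ipd` draws event times from any of the six families and censors
them by an independent exponential drop-out process plus an administrative
cutoff — the standard generative stand-in, since trial censoring mechanisms
are never published. `make_digitized_curve` evaluates the KM estimator on a
coordinate grid and counts subjects at risk at scheduled times, emulating
what figure digitization yields. What this does **not** emulate: digitization
coordinate noise, informative censoring, delayed entry, and reporting
artifacts of real figures; passing round-trip tests therefore demonstrate
correctness of the reconstruction algorithm, not robustness to sloppy
digitization.

## Sensitivity analyses

Deterministic sweeps re-run the full model over the OS risk reduction
(0–45% in 0.05 steps, matching the resolution at which the published
crossing is bracketed) and over drug discounts {10%, 25%, 50%}; both reduce
exactly to the base case at their null points (same code path). The PSA
re-runs the model n = 1000 times (seeded, bit-reproducible) with inputs
resampled per parameter: moment-matched Beta for probabilities, utilities
and disutility magnitudes (relative SE 20%), Gamma for costs (20%), Normal
for log-time locations and log-Normal for positive scale/shape survival
parameters (10%). Parameters at a domain boundary (a recurrence fraction of
exactly 1, the placebo HR of 1) are held fixed; invalid draws are rejected
and resampled with a logged count; draws with ΔE ≤ 0 stay in the
cost-effectiveness plane but are excluded from summary ICERs.

## Numerical choices

- Monthly cycles: halving the cycle length moves discounted totals by well
  under 1% (tested), so discretization error is below reporting precision.
- Occupancy conservation is asserted to 1e-10 every cycle; Death occupancy
  must be non-decreasing.
- Transition probabilities are clipped to [0, 1 − 1e-15] before the hazard
  transform; an exhausted survival function (S(t) = 0) pins the conditional
  event probability to 1 with a logged warning.
- Time-zero one-time items (EGFR test, pre-progression AE burden) are
  charged undiscounted at cycle 0.

## Known limitations

- **The published cost decomposition is internally inconsistent**: the
  reported pre-PD + post-PD components sum to neither arm's reported total
  (placebo 2,388 + 379,047 = 381,435 vs 502,937; osimertinib
  505,775 + 255,638 = 761,413 vs 800,697), while the reported totals are
  consistent with the reported ΔC and ICER. No combination of the printed
  inputs we could construct produces the residuals. Consequently the package
  reproduces the published QALYs, ΔE and the osimertinib total cost within a
  few percent under the frozen defaults, but not the cost components, ΔC or
  the ICER; `tests/test_acceptance.py` prints the achieved deviation for
  every target and fails honestly where the 10% band cannot be met.
- Under the stated mechanism (HR on PD→death only), the ICER is weakly
  sensitive to the assumed OS benefit — the osimertinib arm has few, late
  PD entrants — so the published threshold crossing at a 25–30% risk
  reduction is not reproducible from the printed inputs; the sweep is
  monotone decreasing as required but crosses no threshold within 0–45%.
- Treatment lines beyond osimertinib re-treatment at first recurrence are
  out of scope (as in the original analysis), as are stage-stratified
  sub-models and microsimulation.
- Whether the original analysis conditioned PD survival on time since
  progression or since model start is unstated; time-since-progression
  (tunnel states) is implemented as the clinically coherent reading.
- Background mortality is a single annual probability, not an age-updated
  life table; it is a config input and a PSA parameter.
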