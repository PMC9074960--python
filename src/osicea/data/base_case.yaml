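# Base-case inputs: 3 years of adjuvant osimertinib vs placebo after resection
# of EGFR-mutant stage IB-IIIA NSCLC. Every value is a published model input
# (Medicare reimbursement schedules, ADAURA/FLAURA/AURA3 trial data and
# published utility literature); costs are inflation-adjusted US dollars.
# Times are in years.

mode: parameters          # "parameters": survival models given below;
                          # "reconstruction": fit them from digitized curves
seed: 20220314
output_dir: results
log_level: INFO

model:
  horizon_years: 10.0
  cycle_length_years: 0.08333333333333333   # monthly cycles
  discount_costs_annual: 0.03
  discount_qalys_annual: 0.05
  threshold_per_qaly: 195000.0              # 3x US GDP per capita
  drug_discount_fraction: 0.0
  # NED dynamics reading for the two stratum-specific DFS curves:
  # "partitioned" = event-share-weighted strata (calibrated default),
  # "competing"  = latent competing risks (product of the curves).
  ned_structure: partitioned
  half_cycle_correction: true
  background_mortality_annual: 0.012        # US male, age 63 (WHO life tables)

  costs:
    egfr_test_onetime: 324.58          # one-time; at start (osi) or at PD (placebo)
    drug_annual: 222196.0              # osimertinib per year
    adjuvant_drug_years: 3.0           # adjuvant treatment window
    ned_annual_y1_3: 1078.76           # NED follow-up, model years 1-3
    ned_annual_y4_5: 539.38            # NED follow-up, years 4-5
    ned_annual_after: 296.69           # NED follow-up, after year 5
    pd_diagnosis_onetime: 7202.88      # work-up at progression
    pd_drug_years: 2.0                 # osimertinib re-treatment window at PD
    pd_annual: 1186.76                 # PD health-care, annual
    cns_pos_onetime: 43598.83          # lifetime CNS+ treatment/AE, one-time
    cns_pos_mri_annual: 1482.56        # surveillance MRIs in CNS+ PD
    end_of_life_onetime: 78571.06      # palliative / end-of-life

  utilities:
    ned_placebo: 0.830
    ned_osimertinib: 0.812
    pd_cns_neg: 0.71
    pd_cns_pos: 0.55

  # grade >= 3 adverse events: probability, disutility, cost per event.
  # phase "ned" applies once at adjuvant treatment start (osimertinib arm),
  # "pd" once at PD entry (both arms are re-treated with osimertinib),
  # "cns" once at CNS+ PD entry (costs folded into cns_pos_onetime).
  adverse_events:
    - {name: diarrhea,                phase: ned, probability: 0.023, disutility: -0.32, cost: 159.68}
    - {name: rash_stomatitis,         phase: ned, probability: 0.018, disutility: -0.15, cost: 169.97}
    - {name: decreased_appetite,      phase: ned, probability: 0.005, disutility: -0.39, cost: 38.25}
    - {name: pneumonia_sepsis,        phase: ned, probability: 0.015, disutility: -0.50, cost: 42928.16}
    - {name: diarrhea,                phase: pd,  probability: 0.025, disutility: -0.32, cost: 159.68}
    - {name: rash_itching_dry_skin,   phase: pd,  probability: 0.018, disutility: -0.15, cost: 169.97}
    - {name: decreased_appetite,      phase: pd,  probability: 0.011, disutility: -0.39, cost: 38.25}
    - {name: pneumonia_sepsis,        phase: pd,  probability: 0.047, disutility: -0.50, cost: 42928.16}
    - {name: pneumonitis_respiratory, phase: pd,  probability: 0.05,  disutility: -0.40, cost: 16584.44}
    - {name: neurocognitive_defects,  phase: cns, probability: 0.10,  disutility: -0.35, cost: 0.0}
    - {name: radionecrosis,           phase: cns, probability: 0.01,  disutility: -0.50, cost: 0.0}

arms:
  placebo:
    # log-normal DFS fits (log-time location mu, scale sigma), selected by
    # AIC/BIC on data reconstructed from the digitized ADAURA curves
    dfs_cns_pos: {family: lognormal, params: {mu: 1.94, sigma: 1.22}}
    dfs_cns_neg: {family: lognormal, params: {mu: 1.11, sigma: 1.44}}
    # DFS event composition at the ADAURA interim analysis
    dfs_events_cns_pos: {recurrence: 33, total: 39}
    dfs_events_cns_neg: {recurrence: 118, total: 120}
    # gamma (shape, rate/year) fit to pooled AURA3 + FLAURA reference-arm OS
    pd_death: {family: gamma, params: {shape: 1.86, rate: 0.56}}
    os_hazard_ratio: 1.0
  osimertinib:
    dfs_cns_pos: {family: lognormal, params: {mu: 2.66, sigma: 0.91}}
    dfs_cns_neg: {family: lognormal, params: {mu: 2.19, sigma: 1.13}}
    dfs_events_cns_pos: {recurrence: 4, total: 6}
    dfs_events_cns_neg: {recurrence: 31, total: 31}
    pd_death: {family: gamma, params: {shape: 1.86, rate: 0.56}}
    os_hazard_ratio: 0.95              # assumed 5% OS benefit (base case)

# reconstruction-mode inputs: per arm/stratum CSV paths (curve: time,survival;
# risk: time,n_at_risk); ignored in "parameters" mode.
reconstruction: {}

sensitivity:
  os_benefit_grid: {start: 0.0, stop: 0.45, step: 0.05}
  drug_discounts: [0.10, 0.25, 0.50]
  psa:
    n: 1000
    rel_se_probabilities: 0.20
    rel_se_costs: 0.20
    rel_se_survival: 0.10
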