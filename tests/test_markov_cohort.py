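"""Four-state cohort engine: transitions, occupancy, costs, QALYs."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import special

from osicea.markov_cohort import (
    ArmSpec,
    Costs,
    ModelInputs,
    Utilities,
    accumulate_costs,
    accumulate_qalys,
    build_transition_matrix,
    evaluate_arm,
    recurrence_fraction,
    run_cohort,
)
from osicea.parametric_survival import ParametricFit

LN = lambda mu, sigma: ParametricFit("lognormal", {"mu": mu, "sigma": sigma})
EXP = lambda rate: ParametricFit("exponential", {"rate": rate})
GAMMA = ParametricFit("gamma", {"shape": 1.86, "rate": 0.56})
#: effectively event-free process (median e^50 years)
NEVER = LN(50.0, 1.0)


def make_arm(**kw):
    base = dict(
        arm="placebo",
        dfs_cns_pos=LN(1.94, 1.22),
        dfs_cns_neg=LN(1.11, 1.44),
        recurrence_fraction_cns_pos=33 / 39,
        recurrence_fraction_cns_neg=118 / 120,
        pd_death_fit=GAMMA,
        os_hazard_ratio=1.0,
        background_mortality_annual=0.012,
        ned_partition_cns_pos=39 / 159,
    )
    base.update(kw)
    return ArmSpec(**base)


def test_recurrence_fractions_match_printed_percentages():
    assert round(100 * recurrence_fraction(33, 39)) == 85
    assert round(100 * recurrence_fraction(4, 6)) == 67
    assert round(100 * recurrence_fraction(118, 120)) == 98
    assert round(100 * recurrence_fraction(31, 31)) == 100
    with pytest.raises(ValueError):
        recurrence_fraction(5, 0)


def test_degenerate_arm_gives_identity_matrix():
    arm = make_arm(dfs_cns_pos=NEVER, dfs_cns_neg=NEVER,
                   pd_death_fit=NEVER, background_mortality_annual=0.0)
    m = build_transition_matrix(arm, cycle_index=0, delta=1 / 12)
    np.testing.assert_allclose(m, np.eye(4), atol=1e-12)


def test_null_effect_symmetry_between_arms():
    plc = make_arm()
    osi = make_arm(arm="osimertinib", os_hazard_ratio=1.0)
    m_p = build_transition_matrix(plc, 5, 1 / 12)
    m_o = build_transition_matrix(osi, 5, 1 / 12)
    np.testing.assert_allclose(m_p[1:], m_o[1:], atol=1e-15)


def test_ned_row_against_brute_force_competing_risk_oracle():
    """Cycle-0 NED row, monthly cycles, placebo DFS models and event splits,
    recomputed from scratch via the normal CDF and hazard allocation."""
    arm = make_arm()
    delta = 1.0 / 12.0
    m = build_transition_matrix(arm, 0, delta)

    s = lambda mu, sg, x: special.ndtr((mu - np.log(x)) / sg) if x > 0 else 1.0
    p_pos = 1.0 - s(1.94, 1.22, delta) / 1.0
    p_neg = 1.0 - s(1.11, 1.44, delta) / 1.0
    q_bg = 1.0 - (1.0 - 0.012) ** delta
    h = -np.log([1 - p_pos, 1 - p_neg, 1 - q_bg])
    stay = np.exp(-h.sum())
    share = h / h.sum()
    exit_total = 1.0 - stay
    f_pos, f_neg = 33 / 39, 118 / 120
    expected = [
        stay,
        exit_total * share[1] * f_neg,
        exit_total * share[0] * f_pos,
        exit_total * (share[0] * (1 - f_pos) + share[1] * (1 - f_neg) + share[2]),
    ]
    np.testing.assert_allclose(m[0], expected, atol=1e-12)
    assert m[0].sum() == pytest.approx(1.0, abs=1e-12)


def test_matrix_rows_always_stochastic():
    arm = make_arm(os_hazard_ratio=0.55)
    for cycle in (0, 1, 17, 80, 119):
        m = build_transition_matrix(arm, cycle, 1 / 12)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()


def default_inputs(**kw):
    base = dict(horizon_years=10.0, cycle_length_years=1 / 12)
    base.update(kw)
    return ModelInputs(**base)


def test_zero_hazards_keep_cohort_in_ned():
    arm = make_arm(dfs_cns_pos=NEVER, dfs_cns_neg=NEVER,
                   pd_death_fit=NEVER, background_mortality_annual=0.0)
    trace = run_cohort(arm, default_inputs())
    np.testing.assert_allclose(trace.occupancy[:, 0], 1.0, atol=1e-12)


def test_occupancy_matches_transition_matrix_powers():
    """With memoryless (exponential) processes the tunnel bookkeeping must
    reduce to plain matrix powers of the one-cycle matrix."""
    arm = make_arm(dfs_cns_pos=EXP(0.3), dfs_cns_neg=EXP(0.5),
                   pd_death_fit=EXP(0.4))
    inputs = default_inputs(ned_structure="competing", horizon_years=2.0)
    trace = run_cohort(arm, inputs)
    m = build_transition_matrix(arm, 0, inputs.cycle_length_years)
    v = np.array([1.0, 0.0, 0.0, 0.0])
    for i in range(inputs.n_cycles):
        np.testing.assert_allclose(trace.occupancy[i], v, atol=1e-10)
        v = v @ m
    np.testing.assert_allclose(trace.occupancy[-1], v, atol=1e-10)


@pytest.mark.parametrize("structure", ["partitioned", "competing"])
def test_occupancy_conservation_and_death_monotone(structure, base_config):
    inputs = replace(base_config.model, ned_structure=structure)
    for arm in (base_config.placebo, base_config.osimertinib):
        trace = run_cohort(arm, inputs)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert (np.diff(trace.occupancy[:, 3]) >= -1e-12).all()


def test_greater_os_benefit_means_less_death(base_config):
    inputs = base_config.model
    osi = base_config.osimertinib
    d_base = run_cohort(osi, inputs).occupancy[-1, 3]
    d_better = run_cohort(replace(osi, os_hazard_ratio=0.7), inputs).occupancy[-1, 3]
    d_placebo = run_cohort(base_config.placebo, inputs).occupancy[-1, 3]
    assert d_better < d_base < d_placebo


def test_null_equivalence_of_identical_arms():
    """Same survival models, same splits, drug/AE/test costs zeroed and equal
    utilities: the two arms are indistinguishable."""
    plc = make_arm()
    osi = make_arm(arm="osimertinib")
    inputs = default_inputs(
        costs=Costs(egfr_test_onetime=0.0, drug_annual=0.0),
        utilities=Utilities(ned_placebo=0.83, ned_osimertinib=0.83),
        adverse_events=(),
    )
    a = evaluate_arm(plc, inputs)
    b = evaluate_arm(osi, inputs)
    np.testing.assert_allclose(a.trace.occupancy, b.trace.occupancy, atol=1e-14)
    assert a.cost_total == pytest.approx(b.cost_total, abs=1e-9)
    assert a.qalys == pytest.approx(b.qalys, abs=1e-12)


def test_removing_discounting_increases_costs_and_qalys(base_config):
    inputs = base_config.model
    undiscounted = replace(inputs, discount_costs_annual=0.0, discount_qalys_annual=0.0)
    for arm in (base_config.placebo, base_config.osimertinib):
        disc = evaluate_arm(arm, inputs)
        undisc = evaluate_arm(arm, undiscounted)
        assert undisc.cost_total > disc.cost_total
        assert undisc.qalys > disc.qalys


def test_halving_cycle_length_changes_totals_below_one_percent(base_config):
    monthly = base_config.model
    half = replace(monthly, cycle_length_years=1 / 24)
    for arm in (base_config.placebo, base_config.osimertinib):
        a = evaluate_arm(arm, monthly)
        b = evaluate_arm(arm, half)
        assert abs(b.cost_total / a.cost_total - 1) < 0.01
        assert abs(b.qalys / a.qalys - 1) < 0.01


def test_one_undiscounted_ned_year_yields_ned_utility():
    arm = make_arm(dfs_cns_pos=NEVER, dfs_cns_neg=NEVER,
                   pd_death_fit=NEVER, background_mortality_annual=0.0)
    inputs = default_inputs(horizon_years=1.0, discount_qalys_annual=0.0)
    trace = run_cohort(arm, inputs)
    qalys = accumulate_qalys(trace, inputs, arm)
    assert qalys == pytest.approx(0.83, abs=1e-12)


def test_zero_utilities_and_costs_give_zero_totals():
    arm = make_arm()
    inputs = default_inputs(
        costs=Costs(**{f.name: 0.0 for f in Costs.__dataclass_fields__.values()
                       if f.name not in ("adjuvant_drug_years", "pd_drug_years")},
                    adjuvant_drug_years=3.0, pd_drug_years=2.0),
        utilities=Utilities(0.0, 0.0, 0.0, 0.0),
        adverse_events=(),
    )
    out = evaluate_arm(arm, inputs)
    assert out.cost_total == 0.0
    assert out.qalys == 0.0


def test_ned_only_costs_match_discounted_annuity_oracle():
    """A cohort that never leaves NED accrues exactly the tiered follow-up
    annuity; recomputed here from first principles."""
    arm = make_arm(dfs_cns_pos=NEVER, dfs_cns_neg=NEVER,
                   pd_death_fit=NEVER, background_mortality_annual=0.0)
    inputs = default_inputs()
    trace = run_cohort(arm, inputs)
    pre, post, total = accumulate_costs(trace, inputs, arm)
    delta = inputs.cycle_length_years
    expected = 0.0
    for i in range(inputs.n_cycles):
        tmid = (i + 0.5) * delta
        rate = 1078.76 if tmid < 3 else (539.38 if tmid < 5 else 296.69)
        expected += rate * delta * 1.03 ** (-tmid)
    assert post == 0.0
    assert pre == pytest.approx(expected, rel=1e-12)


def test_trace_frame_has_expected_columns(base_outputs):
    ref, _, _ = base_outputs
    df = ref.trace.to_frame()
    for col in ("cycle", "time_years", "occ_NED", "occ_Death",
                "disc_cost_prePD", "disc_cost_postPD", "disc_qaly"):
        assert col in df.columns
    assert len(df) == 120
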