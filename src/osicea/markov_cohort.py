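"""Four-state, two-arm, time-inhomogeneous Markov cohort model.

States: NED (no evidence of disease after resection), PD_CNSneg and PD_CNSpos
(progressive disease without/with CNS involvement) and Death (absorbing). The
cohort starts 100% NED and is propagated in discrete cycles (default one
month) over a 10-year horizon.

Transitions out of NED are driven by parametric disease-free-survival models
fitted separately to CNS-positive-event and CNS-negative-event curves of each
trial arm. Each DFS event is split into recurrence (entering the matching PD
state) versus death using the observed event composition (e.g. 33/39 of
CNS-positive placebo DFS events were recurrences). Background non-disease
mortality acts on every alive state. PD occupants face a post-progression
death process (gamma fit to pooled metastatic EGFR-TKI survival), conditioned
on time since progression via internal tunnel sub-states; an overall-survival
hazard ratio (< 1 in the osimertinib arm) scales that hazard.

Because the trial reports the two DFS processes as curves for event subsets,
two readings of the NED dynamics are supported:

``partitioned`` (default)
    NED is split at model start into a CNS-positive-event stratum and a
    CNS-negative-event stratum (weights = observed event composition); each
    stratum exits via its own DFS model. The aggregate NED survival is the
    event-share-weighted mixture of the two fitted curves.
``competing``
    A single NED pool faces both DFS processes simultaneously as latent
    competing risks (aggregate NED survival = product of the two curves).

The default was frozen by calibrating both readings against the published
base-case outcomes (see docs/methods.md).

Costs accrue per Medicare-derived schedules (adjuvant drug up to 3 years,
re-treatment at PD up to 2 years, tiered NED follow-up, one-time progression /
CNS / end-of-life costs, expected adverse-event costs at treatment start and
PD entry) discounted at 3%/year; QALYs weight state occupancy by published
utilities, subtract expected adverse-event disutilities, and discount at
5%/year. Half-cycle correction applies to occupancy accruals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .parametric_survival import ParametricFit

STATES = ("NED", "PD_CNSneg", "PD_CNSpos", "Death")
_OCC_TOL = 1e-10


class ModelError(RuntimeError):
    """A transition probability or occupancy left its valid domain."""


@dataclass(frozen=True)
class AdverseEvent:
    """One grade >= 3 adverse-event row: probability, disutility (<= 0), cost.

    ``phase`` is the trigger point: ``ned`` rows apply once at adjuvant
    treatment initiation (osimertinib arm), ``pd`` rows once at PD entry (both
    arms are re-treated), ``cns`` rows once at CNS-positive PD entry (their
    costs are folded into the one-time CNS+ cost, so cost is 0 here).
    """

    name: str
    phase: Literal["ned", "pd", "cns"]
    probability: float
    disutility: float
    cost: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"AE {self.name}: probability outside [0, 1]")
        if self.disutility > 0.0:
            raise ValueError(f"AE {self.name}: disutility must be <= 0")
        if self.cost < 0.0:
            raise ValueError(f"AE {self.name}: cost must be >= 0")


@dataclass(frozen=True)
class Costs:
    """Cost schedule in inflation-adjusted US dollars (as published)."""

    egfr_test_onetime: float = 324.58
    drug_annual: float = 222_196.0
    adjuvant_drug_years: float = 3.0
    ned_annual_y1_3: float = 1_078.76
    ned_annual_y4_5: float = 539.38
    ned_annual_after: float = 296.69
    pd_diagnosis_onetime: float = 7_202.88
    pd_drug_years: float = 2.0
    pd_annual: float = 1_186.76
    cns_pos_onetime: float = 43_598.83
    cns_pos_mri_annual: float = 1_482.56
    end_of_life_onetime: float = 78_571.06


@dataclass(frozen=True)
class Utilities:
    ned_placebo: float = 0.830
    ned_osimertinib: float = 0.812
    pd_cns_neg: float = 0.71
    pd_cns_pos: float = 0.55

    def __post_init__(self):
        for name in ("ned_placebo", "ned_osimertinib", "pd_cns_neg", "pd_cns_pos"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility {name} outside [0, 1]: {v}")


def default_adverse_events() -> tuple[AdverseEvent, ...]:
    """Published grade >= 3 AE inputs (ADAURA for pre-, FLAURA for post-progression)."""
    return (
        AdverseEvent("diarrhea", "ned", 0.023, -0.32, 159.68),
        AdverseEvent("rash_stomatitis", "ned", 0.018, -0.15, 169.97),
        AdverseEvent("decreased_appetite", "ned", 0.005, -0.39, 38.25),
        AdverseEvent("pneumonia_sepsis", "ned", 0.015, -0.50, 42_928.16),
        AdverseEvent("diarrhea", "pd", 0.025, -0.32, 159.68),
        AdverseEvent("rash_itching_dry_skin", "pd", 0.018, -0.15, 169.97),
        AdverseEvent("decreased_appetite", "pd", 0.011, -0.39, 38.25),
        AdverseEvent("pneumonia_sepsis", "pd", 0.047, -0.50, 42_928.16),
        AdverseEvent("pneumonitis_respiratory", "pd", 0.05, -0.40, 16_584.44),
        AdverseEvent("neurocognitive_defects", "cns", 0.10, -0.35, 0.0),
        AdverseEvent("radionecrosis", "cns", 0.01, -0.50, 0.0),
    )


@dataclass
class ModelInputs:
    """Economic parameter set shared by both arms."""

    costs: Costs = field(default_factory=Costs)
    utilities: Utilities = field(default_factory=Utilities)
    adverse_events: tuple[AdverseEvent, ...] = field(
        default_factory=default_adverse_events
    )
    discount_costs_annual: float = 0.03
    discount_qalys_annual: float = 0.05
    horizon_years: float = 10.0
    cycle_length_years: float = 1.0 / 12.0
    drug_discount_fraction: float = 0.0
    ned_structure: Literal["partitioned", "competing"] = "partitioned"
    half_cycle_correction: bool = True

    def __post_init__(self):
        if not 0.0 <= self.discount_costs_annual < 1.0:
            raise ValueError("discount_costs_annual outside [0, 1)")
        if not 0.0 <= self.discount_qalys_annual < 1.0:
            raise ValueError("discount_qalys_annual outside [0, 1)")
        if self.horizon_years <= 0 or self.cycle_length_years <= 0:
            raise ValueError("horizon and cycle length must be > 0")
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be an integer multiple of cycle length")
        if not 0.0 <= self.drug_discount_fraction <= 1.0:
            raise ValueError("drug_discount_fraction outside [0, 1]")
        if self.ned_structure not in ("partitioned", "competing"):
            raise ValueError(f"unknown ned_structure {self.ned_structure!r}")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))

    def ae_cost(self, phase: str) -> float:
        return sum(a.probability * a.cost for a in self.adverse_events if a.phase == phase)

    def ae_disutility(self, phase: str) -> float:
        """Expected one-time QALY decrement (positive number) for a phase."""
        return -sum(
            a.probability * a.disutility for a in self.adverse_events if a.phase == phase
        )


@dataclass
class ArmSpec:
    """Arm-specific survival models, event composition and OS effect."""

    arm: Literal["placebo", "osimertinib"]
    dfs_cns_pos: ParametricFit
    dfs_cns_neg: ParametricFit
    recurrence_fraction_cns_pos: float
    recurrence_fraction_cns_neg: float
    pd_death_fit: ParametricFit
    os_hazard_ratio: float = 1.0
    background_mortality_annual: float = 0.012
    #: share of the NED cohort on the CNS-positive-event pathway (partitioned
    #: structure only); the observed event composition of the arm.
    ned_partition_cns_pos: float | None = None

    def __post_init__(self):
        for name in ("recurrence_fraction_cns_pos", "recurrence_fraction_cns_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.os_hazard_ratio <= 0:
            raise ValueError("os_hazard_ratio must be > 0")
        if not 0.0 <= self.background_mortality_annual < 1.0:
            raise ValueError("background_mortality_annual outside [0, 1)")
        if self.ned_partition_cns_pos is not None and not (
            0.0 <= self.ned_partition_cns_pos <= 1.0
        ):
            raise ValueError("ned_partition_cns_pos outside [0, 1]")


def recurrence_fraction(n_recurrence: int, n_events: int) -> float:
    """Fraction of DFS events that were recurrences (exact integer arithmetic)."""
    if n_events <= 0 or n_recurrence < 0 or n_recurrence > n_events:
        raise ValueError("need 0 <= n_recurrence <= n_events with n_events > 0")
    return n_recurrence / n_events


def _conditional_event_probs(fit: ParametricFit, grid: np.ndarray) -> np.ndarray:
    """1 - S(t_{i+1})/S(t_i) on a grid; pinned to 1 once S vanishes."""
    s = fit.dist.sf(grid)
    p = np.ones(len(grid) - 1)
    ok = s[:-1] > 0.0
    p[ok] = 1.0 - s[1:][ok] / s[:-1][ok]
    return np.clip(p, 0.0, 1.0)


def _hazard_allocate(p_causes: np.ndarray) -> tuple[float, np.ndarray]:
    """Combine per-cause cycle probabilities as competing risks.

    Returns (stay probability, per-cause exit probabilities). Causes act as
    independent constant hazards within the cycle; the joint exit mass is
    allocated proportionally to the cause hazards.
    """
    p = np.clip(np.asarray(p_causes, dtype=float), 0.0, 1.0 - 1e-15)
    h = -np.log1p(-p)
    total = h.sum()
    if total <= 0.0:
        return 1.0, np.zeros_like(p)
    stay = float(np.exp(-total))
    return stay, (1.0 - stay) * h / total


def build_transition_matrix(
    arm: ArmSpec,
    cycle_index: int,
    delta: float,
    pd_time_in_state: float | None = None,
) -> np.ndarray:
    """One-cycle stochastic matrix over (NED, PD_CNSneg, PD_CNSpos, Death).

    The NED row combines both DFS processes and background mortality as
    competing risks (the ``competing`` reading; the cohort engine additionally
    supports the partitioned reading via internal NED strata). PD rows use the
    post-progression death model at ``pd_time_in_state`` (defaults to
    ``cycle_index * delta``) with the arm's OS hazard ratio.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    t = cycle_index * delta
    u = t if pd_time_in_state is None else pd_time_in_state
    grid_t = np.array([t, t + delta])
    p_pos = _conditional_event_probs(arm.dfs_cns_pos, grid_t)[0]
    p_neg = _conditional_event_probs(arm.dfs_cns_neg, grid_t)[0]
    q_bg = 1.0 - (1.0 - arm.background_mortality_annual) ** delta

    stay, exits = _hazard_allocate([p_pos, p_neg, q_bg])
    e_pos, e_neg, e_bg = exits
    f_pos, f_neg = arm.recurrence_fraction_cns_pos, arm.recurrence_fraction_cns_neg

    s_pd = arm.pd_death_fit.dist.sf(np.array([u, u + delta]))
    if s_pd[0] <= 0.0:
        p_pd = 1.0
    else:
        p_pd = 1.0 - (s_pd[1] / s_pd[0]) ** arm.os_hazard_ratio
    p_pd_death = 1.0 - (1.0 - np.clip(p_pd, 0.0, 1.0)) * (1.0 - q_bg)

    m = np.zeros((4, 4))
    m[0] = [stay, e_neg * f_neg, e_pos * f_pos, e_bg + e_pos * (1 - f_pos) + e_neg * (1 - f_neg)]
    m[1] = [0.0, 1.0 - p_pd_death, 0.0, p_pd_death]
    m[2] = [0.0, 0.0, 1.0 - p_pd_death, p_pd_death]
    m[3] = [0.0, 0.0, 0.0, 1.0]
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        bad = np.argwhere((m < -1e-12) | (m > 1 + 1e-12))[0]
        raise ModelError(f"transition probability outside [0,1] at cell {tuple(bad)}")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ModelError("transition matrix rows do not sum to 1")
    return m


@dataclass
class CohortTrace:
    """Per-cycle bookkeeping of one arm's cohort run.

    ``occupancy`` holds the four aggregated state proportions at every cycle
    boundary; ``avg_occupancy`` the per-cycle accrual weights (half-cycle
    corrected when enabled). Entrant masses feed the one-time costs and
    disutilities; ``pd_drug_avg`` is the PD occupancy still inside the 2-year
    re-treatment window.
    """

    arm: str
    delta: float
    times: np.ndarray  # cycle-start times, length n_cycles
    occupancy: np.ndarray  # (n_cycles + 1, 4) at cycle boundaries
    avg_occupancy: np.ndarray  # (n_cycles, 4)
    pd_drug_avg: np.ndarray  # (n_cycles,)
    entrants_pd_pos: np.ndarray
    entrants_pd_neg: np.ndarray
    entrants_death: np.ndarray
    # filled by accumulate_costs / accumulate_qalys
    disc_cost_pre: np.ndarray | None = None
    disc_cost_post: np.ndarray | None = None
    undisc_cost_pre: np.ndarray | None = None
    undisc_cost_post: np.ndarray | None = None
    disc_qaly: np.ndarray | None = None

    def __post_init__(self):
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _OCC_TOL):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise ModelError(f"occupancy does not sum to 1 at cycle {i}: {sums[i]!r}")
        death = self.occupancy[:, 3]
        if np.any(np.diff(death) < -_OCC_TOL):
            raise ModelError("Death occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.times)
        df = pd.DataFrame(
            {
                "cycle": np.arange(n),
                "time_years": self.times,
                **{
                    f"occ_{s}": self.occupancy[:-1, i] for i, s in enumerate(STATES)
                },
            }
        )
        for col, arr in (
            ("disc_cost_prePD", self.disc_cost_pre),
            ("disc_cost_postPD", self.disc_cost_post),
            ("disc_qaly", self.disc_qaly),
        ):
            if arr is not None:
                df[col] = arr
        return df


def run_cohort(arm: ArmSpec, inputs: ModelInputs) -> CohortTrace:
    """Propagate a unit cohort through the model horizon. Deterministic."""
    delta = inputs.cycle_length_years
    n = inputs.n_cycles
    grid = np.arange(n + 1) * delta

    p_pos = _conditional_event_probs(arm.dfs_cns_pos, grid)
    p_neg = _conditional_event_probs(arm.dfs_cns_neg, grid)
    q_bg = 1.0 - (1.0 - arm.background_mortality_annual) ** delta

    # PD -> death conditional on time since progression (tunnel index k),
    # hazard scaled by the arm's OS hazard ratio.
    s_pd = arm.pd_death_fit.dist.sf(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_pd[:-1] > 0.0, s_pd[1:] / np.maximum(s_pd[:-1], 1e-300), 0.0)
    p_pd = 1.0 - np.clip(ratio, 0.0, 1.0) ** arm.os_hazard_ratio
    stay_pd = (1.0 - np.clip(p_pd, 0.0, 1.0)) * (1.0 - q_bg)
    # tunnel index runs 0..n; occupants at the last tunnel keep its hazard
    stay_ext = np.append(stay_pd, stay_pd[-1])

    partitioned = inputs.ned_structure == "partitioned"
    if partitioned:
        w_pos = arm.ned_partition_cns_pos
        if w_pos is None:
            raise ModelError(
                "partitioned NED structure requires ned_partition_cns_pos"
            )
        ned = np.array([w_pos, 1.0 - w_pos])  # [CNS+ stratum, CNS- stratum]
    else:
        ned = np.array([1.0])

    pd_pos = np.zeros(n + 1)  # tunnel occupancy by completed cycles in state
    pd_neg = np.zeros(n + 1)
    dead = 0.0

    drug_window = grid < inputs.costs.pd_drug_years  # tunnels (0..n) on PD drug

    occupancy = np.zeros((n + 1, 4))
    avg_occ = np.zeros((n, 4))
    pd_drug_avg = np.zeros(n)
    ent_pos = np.zeros(n)
    ent_neg = np.zeros(n)
    ent_death = np.zeros(n)

    def snapshot():
        return np.array([ned.sum(), pd_neg.sum(), pd_pos.sum(), dead])

    occupancy[0] = snapshot()
    f_pos, f_neg = arm.recurrence_fraction_cns_pos, arm.recurrence_fraction_cns_neg

    for i in range(n):
        start = occupancy[i]
        w_start = pd_pos[drug_window].sum() + pd_neg[drug_window].sum()

        # --- NED exits
        new_pd_pos = new_pd_neg = ned_death = 0.0
        if partitioned:
            stay_p, exits_p = _hazard_allocate([p_pos[i], q_bg])
            stay_n, exits_n = _hazard_allocate([p_neg[i], q_bg])
            ev_pos = ned[0] * exits_p[0]
            ev_neg = ned[1] * exits_n[0]
            ned_death = ned[0] * exits_p[1] + ned[1] * exits_n[1]
            ned = np.array([ned[0] * stay_p, ned[1] * stay_n])
        else:
            stay, exits = _hazard_allocate([p_pos[i], p_neg[i], q_bg])
            ev_pos = ned[0] * exits[0]
            ev_neg = ned[0] * exits[1]
            ned_death = ned[0] * exits[2]
            ned = np.array([ned[0] * stay])
        new_pd_pos = ev_pos * f_pos
        new_pd_neg = ev_neg * f_neg
        ned_death += ev_pos * (1.0 - f_pos) + ev_neg * (1.0 - f_neg)

        # --- PD exits and tunnel shift
        pd_deaths = float(pd_pos.dot(1.0 - stay_ext)) + float(pd_neg.dot(1.0 - stay_ext))
        nxt_pos = np.zeros(n + 1)
        nxt_neg = np.zeros(n + 1)
        nxt_pos[1:] = pd_pos[:-1] * stay_ext[:-1]
        nxt_neg[1:] = pd_neg[:-1] * stay_ext[:-1]
        # occupants already at the last tunnel stay there (horizon end anyway)
        nxt_pos[-1] += pd_pos[-1] * stay_ext[-1]
        nxt_neg[-1] += pd_neg[-1] * stay_ext[-1]
        nxt_pos[0] = new_pd_pos
        nxt_neg[0] = new_pd_neg
        pd_pos, pd_neg = nxt_pos, nxt_neg
        dead += ned_death + pd_deaths

        occupancy[i + 1] = snapshot()
        end = occupancy[i + 1]
        if inputs.half_cycle_correction:
            avg_occ[i] = 0.5 * (start + end)
            w_end = pd_pos[drug_window].sum() + pd_neg[drug_window].sum()
            pd_drug_avg[i] = 0.5 * (w_start + w_end)
        else:
            avg_occ[i] = start
            pd_drug_avg[i] = w_start
        ent_pos[i] = new_pd_pos
        ent_neg[i] = new_pd_neg
        ent_death[i] = ned_death + pd_deaths

    return CohortTrace(
        arm=arm.arm,
        delta=delta,
        times=grid[:-1],
        occupancy=occupancy,
        avg_occupancy=avg_occ,
        pd_drug_avg=pd_drug_avg,
        entrants_pd_pos=ent_pos,
        entrants_pd_neg=ent_neg,
        entrants_death=ent_death,
    )


def accumulate_costs(
    trace: CohortTrace, inputs: ModelInputs, arm: ArmSpec
) -> tuple[float, float, float]:
    """Discounted (pre-PD, post-PD, total) costs per model entrant."""
    if abs(trace.delta - inputs.cycle_length_years) > 1e-12:
        raise ModelError("trace cycle length does not match inputs")
    c = inputs.costs
    delta = trace.delta
    tmid = trace.times + delta / 2.0
    disc = (1.0 + inputs.discount_costs_annual) ** (-tmid)
    is_osi = arm.arm == "osimertinib"
    drug_price = c.drug_annual * (1.0 - inputs.drug_discount_fraction)

    ned_occ = trace.avg_occupancy[:, 0]
    pd_neg_occ = trace.avg_occupancy[:, 1]
    pd_pos_occ = trace.avg_occupancy[:, 2]
    pd_occ = pd_neg_occ + pd_pos_occ
    entrants_pd = trace.entrants_pd_pos + trace.entrants_pd_neg

    # tiered NED follow-up costs by model year
    ned_rate = np.where(
        tmid < 3.0, c.ned_annual_y1_3, np.where(tmid < 5.0, c.ned_annual_y4_5, c.ned_annual_after)
    )
    pre = ned_occ * ned_rate * delta
    if is_osi:
        pre = pre + ned_occ * drug_price * delta * (tmid < c.adjuvant_drug_years)

    post = (
        entrants_pd * (c.pd_diagnosis_onetime + inputs.ae_cost("pd"))
        + trace.entrants_pd_pos * c.cns_pos_onetime
        + pd_occ * c.pd_annual * delta
        + pd_pos_occ * c.cns_pos_mri_annual * delta
        + trace.pd_drug_avg * drug_price * delta
        + trace.entrants_death * c.end_of_life_onetime
    )
    if not is_osi:
        post = post + entrants_pd * c.egfr_test_onetime

    disc_pre = pre * disc
    disc_post = post * disc
    undisc_pre = pre.copy()
    undisc_post = post.copy()
    if is_osi:
        # model-start one-time costs (t = 0, undiscounted by construction)
        start_cost = c.egfr_test_onetime + inputs.ae_cost("ned")
        disc_pre[0] += start_cost
        undisc_pre[0] += start_cost

    trace.disc_cost_pre = disc_pre
    trace.disc_cost_post = disc_post
    trace.undisc_cost_pre = undisc_pre
    trace.undisc_cost_post = undisc_post
    pre_total = float(disc_pre.sum())
    post_total = float(disc_post.sum())
    return pre_total, post_total, pre_total + post_total


def accumulate_qalys(trace: CohortTrace, inputs: ModelInputs, arm: ArmSpec) -> float:
    """Discounted QALYs per model entrant."""
    if abs(trace.delta - inputs.cycle_length_years) > 1e-12:
        raise ModelError("trace cycle length does not match inputs")
    u = inputs.utilities
    delta = trace.delta
    tmid = trace.times + delta / 2.0
    disc = (1.0 + inputs.discount_qalys_annual) ** (-tmid)
    u_ned = u.ned_osimertinib if arm.arm == "osimertinib" else u.ned_placebo

    per_cycle = (
        trace.avg_occupancy[:, 0] * u_ned
        + trace.avg_occupancy[:, 1] * u.pd_cns_neg
        + trace.avg_occupancy[:, 2] * u.pd_cns_pos
    ) * delta
    entrants_pd = trace.entrants_pd_pos + trace.entrants_pd_neg
    decrement = (
        entrants_pd * inputs.ae_disutility("pd")
        + trace.entrants_pd_pos * inputs.ae_disutility("cns")
    )
    qaly = (per_cycle - decrement) * disc
    if arm.arm == "osimertinib":
        qaly[0] -= inputs.ae_disutility("ned")  # one-time at treatment start, t = 0
    trace.disc_qaly = qaly
    return float(qaly.sum())


@dataclass
class ArmOutputs:
    """Evaluated endpoints of one arm."""

    arm: str
    cost_pre_pd: float
    cost_post_pd: float
    cost_total: float
    qalys: float
    trace: CohortTrace


def evaluate_arm(arm: ArmSpec, inputs: ModelInputs) -> ArmOutputs:
    trace = run_cohort(arm, inputs)
    pre, post, total = accumulate_costs(trace, inputs, arm)
    qalys = accumulate_qalys(trace, inputs, arm)
    return ArmOutputs(
        arm=arm.arm,
        cost_pre_pd=pre,
        cost_post_pd=post,
        cost_total=total,
        qalys=qalys,
        trace=trace,
    )
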