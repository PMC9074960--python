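"""Incremental cost-effectiveness results and sensitivity analyses.

The base case compares 3 years of adjuvant osimertinib with placebo:
ICER = (C_osi - C_placebo) / (E_osi - E_placebo), judged against a
willingness-to-pay threshold of $195,000 per QALY (3x US GDP per capita).

Deterministic sweeps re-run the model over (a) the assumed overall-survival
benefit of osimertinib, expressed as a risk reduction r with PD->death hazard
ratio 1 - r, on a 0-45% grid, and (b) annual drug-price discounts applied to
both the adjuvant and the re-treatment osimertinib cost. The probabilistic
sensitivity analysis re-runs the model 1000 times with inputs resampled from
per-parameter distributions (Beta for probabilities and utilities, Gamma for
costs, Normal for log-time locations, log-Normal for positive scale/shape
survival parameters) and reports the (delta cost, delta QALY) cloud of the
cost-effectiveness plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markov_cohort import (
    AdverseEvent,
    ArmOutputs,
    ArmSpec,
    Costs,
    ModelInputs,
    Utilities,
    evaluate_arm,
)
from .parametric_survival import ParametricFit

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 195_000.0


@dataclass
class CEAResult:
    """Incremental comparison of comparator vs reference strategy."""

    cost_ref: float
    cost_cmp: float
    qaly_ref: float
    qaly_cmp: float
    threshold: float = DEFAULT_THRESHOLD
    label_ref: str = "placebo"
    label_cmp: str = "osimertinib"

    @property
    def delta_cost(self) -> float:
        return self.cost_cmp - self.cost_ref

    @property
    def delta_qaly(self) -> float:
        return self.qaly_cmp - self.qaly_ref

    @property
    def icer(self) -> float:
        """Dollars per QALY gained; NaN when the QALY difference is zero."""
        if self.delta_qaly == 0.0:
            return float("nan")
        return self.delta_cost / self.delta_qaly

    @property
    def verdict(self) -> str:
        dc, de = self.delta_cost, self.delta_qaly
        if dc < 0 and de > 0:
            return "dominant"
        if dc > 0 and de < 0:
            return "dominated"
        if de == 0.0:
            return "not_cost_effective" if dc > 0 else "cost_effective"
        if de > 0:  # north-east quadrant: pay at most the threshold per QALY
            return "cost_effective" if self.icer <= self.threshold else "not_cost_effective"
        # south-west quadrant: savings per QALY forgone must exceed the threshold
        return "cost_effective" if self.icer >= self.threshold else "not_cost_effective"

    def to_dict(self) -> dict:
        return {
            "reference": self.label_ref,
            "comparator": self.label_cmp,
            "cost_ref": self.cost_ref,
            "cost_cmp": self.cost_cmp,
            "qaly_ref": self.qaly_ref,
            "qaly_cmp": self.qaly_cmp,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "threshold": self.threshold,
            "verdict": self.verdict,
        }


def compute_icer(
    ref: ArmOutputs, cmp: ArmOutputs, threshold: float = DEFAULT_THRESHOLD
) -> CEAResult:
    """CEAResult from two evaluated arms (reference first)."""
    return CEAResult(
        cost_ref=ref.cost_total,
        cost_cmp=cmp.cost_total,
        qaly_ref=ref.qalys,
        qaly_cmp=cmp.qalys,
        threshold=threshold,
        label_ref=ref.arm,
        label_cmp=cmp.arm,
    )


@dataclass
class CEAModel:
    """Two-arm model: reference (placebo) vs comparator (osimertinib)."""

    placebo: ArmSpec
    osimertinib: ArmSpec
    inputs: ModelInputs
    threshold: float = DEFAULT_THRESHOLD

    def evaluate(self) -> tuple[ArmOutputs, ArmOutputs, CEAResult]:
        ref = evaluate_arm(self.placebo, self.inputs)
        cmp = evaluate_arm(self.osimertinib, self.inputs)
        return ref, cmp, compute_icer(ref, cmp, self.threshold)

    def result(self) -> CEAResult:
        return self.evaluate()[2]


def os_benefit_sweep(
    model: CEAModel, reductions: Sequence[float] | None = None
) -> pd.DataFrame:
    """ICER as a function of the assumed OS risk reduction for osimertinib.

    ``reductions`` default to 0 to 0.45 in steps of 0.05. Returns a table with
    columns (risk_reduction, hazard_ratio, icer, cost_effective); the smallest
    grid reduction reaching the threshold is available from the table.
    """
    if reductions is None:
        reductions = np.round(np.arange(0.0, 0.4501, 0.05), 10)
    rows = []
    for r in reductions:
        if not 0.0 <= r <= 0.45:
            raise ValueError(f"risk reduction outside [0, 0.45]: {r}")
        m = replace(model, osimertinib=replace(model.osimertinib, os_hazard_ratio=1.0 - r))
        res = m.result()
        rows.append(
            {
                "risk_reduction": float(r),
                "hazard_ratio": 1.0 - float(r),
                "icer": res.icer,
                "cost_effective": res.verdict == "cost_effective",
            }
        )
    return pd.DataFrame(rows)


def threshold_crossing(sweep: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD):
    """(below, above) bracketing risk reductions where the ICER crosses the
    threshold; ``below`` is the smallest grid reduction with ICER <= threshold."""
    hit = sweep[sweep["icer"] <= threshold]
    if hit.empty:
        return None
    first = hit["risk_reduction"].iloc[0]
    prev = sweep[sweep["risk_reduction"] < first]
    return (float(prev["risk_reduction"].iloc[-1]) if not prev.empty else None, float(first))


def drug_discount_sweep(
    model: CEAModel, discounts: Sequence[float] = (0.10, 0.25, 0.50)
) -> pd.DataFrame:
    """ICER under annual osimertinib price discounts (adjuvant and at PD)."""
    rows = []
    for d in discounts:
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"drug discount outside [0, 1]: {d}")
        m = replace(model, inputs=replace(model.inputs, drug_discount_fraction=float(d)))
        res = m.result()
        rows.append({"drug_discount": float(d), "icer": res.icer})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSADistributions:
    """Relative standard errors of the PSA parameter distributions.

    Probabilities and utilities get moment-matched Beta distributions, costs
    Gamma, log-time location parameters Normal, positive scale/shape survival
    parameters log-Normal. Parameters at a domain boundary (e.g. a recurrence
    fraction of exactly 1) are held fixed.
    """

    rel_se_probabilities: float = 0.20
    rel_se_costs: float = 0.20
    rel_se_survival: float = 0.10


@dataclass
class PSAResult:
    draws: pd.DataFrame  # columns: draw, delta_cost, delta_qaly, icer
    n: int
    seed: int
    n_rejected: int
    base: CEAResult

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    def summary(self) -> dict:
        d = self.draws
        valid = d[d["delta_qaly"] > 0]
        return {
            "n": self.n,
            "seed": self.seed,
            "n_rejected": self.n_rejected,
            "mean_delta_cost": float(d["delta_cost"].mean()),
            "mean_delta_qaly": float(d["delta_qaly"].mean()),
            "icer_of_means": float(d["delta_cost"].mean() / d["delta_qaly"].mean()),
            "prob_cost_effective": float(
                (
                    (d["delta_qaly"] > 0)
                    & (d["delta_cost"] <= self.base.threshold * d["delta_qaly"])
                ).mean()
            ),
            "n_undefined_icer": int((d["delta_qaly"] <= 0).sum()),
            "share_summarized": float(len(valid) / max(len(d), 1)),
        }


def _beta_draw(rng, mean, rel_se):
    """Moment-matched Beta(mean, sd = rel_se * mean); fixed at boundaries."""
    if mean <= 0.0 or mean >= 1.0 or rel_se <= 0.0:
        return mean
    sd = min(rel_se * mean, 0.95 * np.sqrt(mean * (1 - mean)))
    var = sd**2
    common = mean * (1 - mean) / var - 1.0
    a, b = mean * common, (1 - mean) * common
    return float(rng.beta(a, b))


def _gamma_draw(rng, mean, rel_se):
    if mean <= 0.0 or rel_se <= 0.0:
        return mean
    shape = 1.0 / rel_se**2
    return float(rng.gamma(shape, mean / shape))


def _lognorm_draw(rng, value, rel_se):
    if value <= 0.0 or rel_se <= 0.0:
        return value
    return float(value * np.exp(rng.normal(0.0, rel_se)))


def _normal_draw(rng, value, rel_se):
    if rel_se <= 0.0:
        return value
    scale = rel_se * max(abs(value), 1e-6)
    return float(rng.normal(value, scale))


def _sample_fit(rng, fit: ParametricFit, rel_se: float) -> ParametricFit:
    from ._families import POSITIVE_PARAMS

    pos = POSITIVE_PARAMS[fit.family]
    params = {}
    for name, value in fit.params.items():
        if name in pos:
            params[name] = _lognorm_draw(rng, value, rel_se)
        else:
            params[name] = _normal_draw(rng, value, rel_se)
    return ParametricFit(family=fit.family, params=params)


def _sample_arm(rng, arm: ArmSpec, d: PSADistributions) -> ArmSpec:
    return replace(
        arm,
        dfs_cns_pos=_sample_fit(rng, arm.dfs_cns_pos, d.rel_se_survival),
        dfs_cns_neg=_sample_fit(rng, arm.dfs_cns_neg, d.rel_se_survival),
        pd_death_fit=_sample_fit(rng, arm.pd_death_fit, d.rel_se_survival),
        recurrence_fraction_cns_pos=_beta_draw(
            rng, arm.recurrence_fraction_cns_pos, d.rel_se_probabilities
        ),
        recurrence_fraction_cns_neg=_beta_draw(
            rng, arm.recurrence_fraction_cns_neg, d.rel_se_probabilities
        ),
        background_mortality_annual=_beta_draw(
            rng, arm.background_mortality_annual, d.rel_se_probabilities
        ),
        os_hazard_ratio=(
            _lognorm_draw(rng, arm.os_hazard_ratio, d.rel_se_survival)
            if arm.os_hazard_ratio != 1.0
            else 1.0
        ),
    )


def _sample_inputs(rng, inputs: ModelInputs, d: PSADistributions) -> ModelInputs:
    c = inputs.costs
    costs = Costs(
        egfr_test_onetime=_gamma_draw(rng, c.egfr_test_onetime, d.rel_se_costs),
        drug_annual=_gamma_draw(rng, c.drug_annual, d.rel_se_costs),
        adjuvant_drug_years=c.adjuvant_drug_years,
        ned_annual_y1_3=_gamma_draw(rng, c.ned_annual_y1_3, d.rel_se_costs),
        ned_annual_y4_5=_gamma_draw(rng, c.ned_annual_y4_5, d.rel_se_costs),
        ned_annual_after=_gamma_draw(rng, c.ned_annual_after, d.rel_se_costs),
        pd_diagnosis_onetime=_gamma_draw(rng, c.pd_diagnosis_onetime, d.rel_se_costs),
        pd_drug_years=c.pd_drug_years,
        pd_annual=_gamma_draw(rng, c.pd_annual, d.rel_se_costs),
        cns_pos_onetime=_gamma_draw(rng, c.cns_pos_onetime, d.rel_se_costs),
        cns_pos_mri_annual=_gamma_draw(rng, c.cns_pos_mri_annual, d.rel_se_costs),
        end_of_life_onetime=_gamma_draw(rng, c.end_of_life_onetime, d.rel_se_costs),
    )
    u = inputs.utilities
    utilities = Utilities(
        ned_placebo=_beta_draw(rng, u.ned_placebo, d.rel_se_probabilities),
        ned_osimertinib=_beta_draw(rng, u.ned_osimertinib, d.rel_se_probabilities),
        pd_cns_neg=_beta_draw(rng, u.pd_cns_neg, d.rel_se_probabilities),
        pd_cns_pos=_beta_draw(rng, u.pd_cns_pos, d.rel_se_probabilities),
    )
    aes = tuple(
        AdverseEvent(
            name=a.name,
            phase=a.phase,
            probability=_beta_draw(rng, a.probability, d.rel_se_probabilities),
            disutility=-_beta_draw(rng, -a.disutility, d.rel_se_probabilities),
            cost=_gamma_draw(rng, a.cost, d.rel_se_costs) if a.cost > 0 else 0.0,
        )
        for a in inputs.adverse_events
    )
    return replace(inputs, costs=costs, utilities=utilities, adverse_events=aes)


def run_psa(
    model: CEAModel,
    distributions: PSADistributions | None = None,
    n: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Re-run the model ``n`` times with resampled inputs. Reproducible by seed.

    Draws producing invalid inputs are rejected and resampled (counted in
    ``n_rejected``); draws with a non-positive QALY difference are retained in
    the cloud and excluded from summary ICERs.
    """
    if distributions is None:
        distributions = PSADistributions()
    rng = np.random.default_rng(seed)
    base = model.result()
    rows = []
    rejected = 0
    for i in range(n):
        for _attempt in range(100):
            try:
                m = CEAModel(
                    placebo=_sample_arm(rng, model.placebo, distributions),
                    osimertinib=_sample_arm(rng, model.osimertinib, distributions),
                    inputs=_sample_inputs(rng, model.inputs, distributions),
                    threshold=model.threshold,
                )
                res = m.result()
                break
            except (ValueError, RuntimeError):
                rejected += 1
        else:  # pragma: no cover - would need a pathological spec
            raise RuntimeError(f"PSA draw {i}: no valid parameter sample in 100 tries")
        rows.append(
            {
                "draw": i,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
            }
        )
    if rejected:
        logger.info("PSA rejected and resampled %d invalid draws", rejected)
    return PSAResult(
        draws=pd.DataFrame(rows), n=n, seed=seed, n_rejected=rejected, base=base
    )
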