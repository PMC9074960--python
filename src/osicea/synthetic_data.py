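"""Synthetic right-censored survival samples and pseudo-digitized KM curves.

The downstream pipeline (curve -> individual patient data -> parametric fit)
normally starts from survival curves digitized out of published trial figures.
This module generates the same artifacts from known ground truth — a chosen
parametric family, an independent exponential censoring process and an
administrative cutoff — so the reconstruction and fitting stages can be tested
end to end without any external data.

Times are in years throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._families import FAMILIES, make_dist, validate_params


@dataclass(frozen=True)
class SimulationSpec:
    """Generating recipe for one right-censored sample.

    ``censor_rate`` is the rate (per year) of an exponential drop-out process
    acting independently of the event process; ``admin_censor_time`` is a hard
    administrative cutoff (everyone still at risk is censored there).
    """

    family: str
    params: dict
    n: int
    censor_rate: float = 0.0
    admin_censor_time: float = 25.0
    seed: int = 0

    def __post_init__(self):
        validate_params(self.family, self.params)
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.censor_rate < 0:
            raise ValueError(f"censor_rate must be >= 0, got {self.censor_rate}")
        if not self.admin_censor_time > 0:
            raise ValueError(
                f"admin_censor_time must be > 0, got {self.admin_censor_time}"
            )


@dataclass
class IPDataset:
    """Individual patient-level right-censored records.

    ``times`` are observation times (> 0, years); ``events`` is True where the
    terminal event was observed and False where the record is right-censored.
    """

    times: np.ndarray
    events: np.ndarray
    arm_label: str = ""
    stratum_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise ValueError("times and events must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("IPDataset must contain at least one record")
        if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("all times must be finite and > 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events.astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm_label: str = "", stratum_label: str = "") -> "IPDataset":
        df = pd.read_csv(path)
        if not {"time", "event"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'time' and 'event'")
        return cls(
            times=df["time"].to_numpy(float),
            events=df["event"].to_numpy(int).astype(bool),
            arm_label=arm_label,
            stratum_label=stratum_label,
        )


def simulate_ipd(spec: SimulationSpec) -> IPDataset:
    """Draw ``spec.n`` right-censored records from the generating family.

    Each record observes min(event time, drop-out time, administrative cutoff);
    the event flag is set iff the event time is the smallest. Deterministic
    under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    dist = make_dist(spec.family, spec.params)
    event_t = dist.rvs(size=spec.n, random_state=rng)
    if spec.censor_rate > 0:
        censor_t = rng.exponential(1.0 / spec.censor_rate, size=spec.n)
    else:
        censor_t = np.full(spec.n, np.inf)
    censor_t = np.minimum(censor_t, spec.admin_censor_time)
    observed = np.minimum(event_t, censor_t)
    events = event_t <= censor_t
    # guard against pathological zero draws (possible only in degenerate corners)
    observed = np.maximum(observed, np.finfo(float).tiny)
    return IPDataset(
        times=observed,
        events=events,
        arm_label=f"simulated:{spec.family}",
        stratum_label="",
    )


def make_digitized_curve(
    ipd: IPDataset,
    grid: Sequence[float],
    risk_times: Sequence[float],
):
    """Emulate digitization: KM coordinates on ``grid`` plus a numbers-at-risk
    table at ``risk_times``.

    Returns ``(DigitizedCurve, RiskTable)``; the risk table also carries the
    total event count, mirroring what trial publications report alongside
    their figures.
    """
    from .ipd_reconstruction import DigitizedCurve, RiskTable  # avoid cycle

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must contain at least one time")
    if np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be strictly increasing and start at >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    surv = kmf.survival_function_at_times(grid).to_numpy(float)

    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array([(ipd.times >= t).sum() for t in risk_times], dtype=int)
    curve = DigitizedCurve(times=grid, survival=surv)
    risk = RiskTable(times=risk_times, n_at_risk=n_at_risk, total_events=ipd.n_events)
    return curve, risk


# round-trip convenience used by tests and the CLI
def simulate_digitized(
    spec: SimulationSpec,
    grid: Sequence[float],
    risk_times: Sequence[float],
):
    """simulate_ipd + make_digitized_curve in one call; returns (ipd, curve, risk)."""
    ipd = simulate_ipd(spec)
    curve, risk = make_digitized_curve(ipd, grid, risk_times)
    return ipd, curve, risk
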