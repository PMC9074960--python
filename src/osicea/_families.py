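"""Parametric time-to-event families and their package-wide conventions.

Every duration in this package is measured in YEARS. Parameterizations are
fixed here once and used identically for simulation, fitting and model
evaluation:

``exponential``
    ``rate`` — events per year; mean = 1/rate.
``weibull``
    ``shape`` (k), ``scale`` (years); S(t) = exp(-(t/scale)^shape).
``gamma``
    ``shape`` (alpha), ``rate`` (beta, per year); mean = shape/rate.
    The RATE convention is deliberate: with (1.86, 0.56) it implies a mean
    post-progression survival of about 3.3 years, the clinically coherent
    reading for EGFR-TKI-treated metastatic disease (the scale reading would
    give about 1.0 year).
``lognormal``
    ``mu``, ``sigma`` — location/scale of log(time in years); median = e^mu.
``loglogistic``
    ``shape``, ``scale`` (years); S(t) = 1/(1 + (t/scale)^shape).
``gengamma``
    ``mu``, ``sigma``, ``q`` — the log-time (location, scale, shape)
    parameterization (Prentice): log T = mu + sigma * w with
    w = log(q^2 * G) / q and G ~ Gamma(1/q^2). q -> 0 recovers the
    log-normal, q = 1 the Weibull, q = sigma the gamma. This is the classic
    trap family: other conventions exist, so the mapping to
    ``scipy.stats.gengamma`` is done in exactly one place (here).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "lognormal",
    "loglogistic",
    "gengamma",
)

#: ordered parameter names per family
PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("shape", "scale"),
    "gengamma": ("mu", "sigma", "q"),
}

#: which parameters must be strictly positive (others are unconstrained reals,
#: except gengamma q which must only be non-zero)
POSITIVE_PARAMS = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "lognormal": ("sigma",),
    "loglogistic": ("shape", "scale"),
    "gengamma": ("sigma",),
}

_Q_FLOOR = 1e-6  # |q| below this is numerically indistinguishable from log-normal


class FamilyError(ValueError):
    """Invalid family name or parameter outside its domain."""


def validate_params(family: str, params: dict) -> dict:
    """Validate and normalize a parameter dict; returns a plain float dict.

    Raises :class:`FamilyError` naming the offending parameter.
    """
    if family not in FAMILIES:
        raise FamilyError(f"unknown family {family!r}; expected one of {FAMILIES}")
    names = PARAM_NAMES[family]
    extra = set(params) - set(names)
    if extra:
        raise FamilyError(f"{family}: unexpected parameter(s) {sorted(extra)}")
    missing = set(names) - set(params)
    if missing:
        raise FamilyError(f"{family}: missing parameter(s) {sorted(missing)}")
    out = {}
    for name in names:
        value = float(params[name])
        if not np.isfinite(value):
            raise FamilyError(f"{family}: parameter {name!r} is not finite ({value})")
        if name in POSITIVE_PARAMS[family] and value <= 0:
            raise FamilyError(f"{family}: parameter {name!r} must be > 0, got {value}")
        out[name] = value
    if family == "gengamma" and abs(out["q"]) < _Q_FLOOR:
        raise FamilyError(
            f"gengamma: parameter 'q' must be non-zero (|q| >= {_Q_FLOOR}); "
            "use the lognormal family for the q -> 0 limit"
        )
    return out


def make_dist(family: str, params: dict):
    """Frozen scipy.stats distribution for the given family/parameters."""
    p = validate_params(family, params)
    if family == "exponential":
        return stats.expon(scale=1.0 / p["rate"])
    if family == "weibull":
        return stats.weibull_min(c=p["shape"], scale=p["scale"])
    if family == "gamma":
        return stats.gamma(a=p["shape"], scale=1.0 / p["rate"])
    if family == "lognormal":
        return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
    if family == "loglogistic":
        return stats.fisk(c=p["shape"], scale=p["scale"])
    # gengamma: T = exp(mu + (sigma/q) * log(q^2 * G)), G ~ Gamma(q^-2)
    # maps to scipy's X = scale * G^(1/c) with a = q^-2, c = q/sigma,
    # scale = exp(mu) * (q^2)^(sigma/q); valid for q of either sign.
    mu, sigma, q = p["mu"], p["sigma"], p["q"]
    a = q**-2
    c = q / sigma
    scale = np.exp(mu) * (q * q) ** (sigma / q)
    return stats.gengamma(a=a, c=c, scale=scale)
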