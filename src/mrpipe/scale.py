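"""Interpretation-scale transforms for MR coefficients.

MR estimates with a binary exposure analysed by logistic-regression GWAS
are in outcome units per unit increase in the log odds of the exposure —
a 2.72-fold (e-fold) multiplicative increase in the odds.  For rare
conditions the odds approximate the probability, so multiplying the
coefficient by ln(2) re-expresses it per *doubling* of liability; a
further multiplication by the outcome's SD (for educational attainment,
one SD = 4.2 years of schooling) converts SD units to years, months or
days.  For binary outcomes, log-odds coefficients and their SEs map to
odds ratios with log-symmetric confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from mrpipe.errors import ConfigurationError

LN2 = math.log(2.0)

_UNIT_FACTOR = {"years": 1.0, "months": 12.0, "days": 365.0}


@dataclass(frozen=True)
class ScaleSpec:
    """How to map a raw MR coefficient to reporting units.

    ``outcome_sd_years`` is required when converting an SD-unit outcome to
    time units; a year is taken as 365 days and 12 months.
    """

    exposure_type: str = "binary_liability"   # or "continuous_sd"
    outcome_type: str = "continuous_sd"       # or "binary_liability"
    outcome_sd_years: Optional[float] = None
    time_unit: str = "years"

    def __post_init__(self) -> None:
        for t in (self.exposure_type, self.outcome_type):
            if t not in ("binary_liability", "continuous_sd"):
                raise ConfigurationError(f"unknown trait type {t!r}")
        if self.time_unit not in _UNIT_FACTOR:
            raise ConfigurationError(f"unknown time unit {self.time_unit!r}")
        if self.outcome_sd_years is not None and self.outcome_sd_years <= 0:
            raise ConfigurationError("outcome_sd_years must be positive")


def doubling_effect(beta_sd_per_logodds: float, spec: ScaleSpec) -> float:
    """Outcome change, in ``spec.time_unit``, per doubling of exposure liability.

    beta * ln(2) * outcome_sd_years * unit factor (12 for months, 365 for
    days).  ``beta`` must be in outcome-SD units per unit log-odds of the
    exposure.  Linear and sign-preserving in beta; the unrounded value is
    returned (use :func:`round_report` for presentation).
    """
    if spec.exposure_type != "binary_liability":
        raise ConfigurationError("doubling_effect requires a binary-liability exposure")
    if spec.outcome_sd_years is None:
        raise ConfigurationError("outcome_sd_years is required to convert SD units to time")
    return beta_sd_per_logodds * LN2 * spec.outcome_sd_years * _UNIT_FACTOR[spec.time_unit]


def invert_doubling_effect(value: float, spec: ScaleSpec) -> float:
    """Inverse of :func:`doubling_effect` (round-trips to ~1e-12 before rounding)."""
    if spec.outcome_sd_years is None:
        raise ConfigurationError("outcome_sd_years is required")
    return value / (LN2 * spec.outcome_sd_years * _UNIT_FACTOR[spec.time_unit])


def or_ci_from_log_scale(or_point: float, se_log: float,
                         level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for an odds ratio whose SE is on the log-odds scale.

    exp(ln(OR) +/- z * se_log); geometrically symmetric about the point
    estimate (low * high = OR^2 in exact arithmetic).
    """
    if or_point <= 0 or se_log <= 0:
        raise ConfigurationError("or_point and se_log must be positive")
    if not (0.0 < level < 1.0):
        raise ConfigurationError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_or = math.log(or_point)
    return math.exp(log_or - z * se_log), math.exp(log_or + z * se_log)


def unit_logodds_fold(beta_logodds: float) -> float:
    """Fold change in odds per unit log-odds coefficient: exp(beta).

    A unit increase corresponds to a 2.72-fold multiplicative increase in
    the odds; ln(2) corresponds to a doubling.
    """
    return math.exp(beta_logodds)


def round_report(value: float, kind: str) -> float:
    """Presentation rounding: 1 dp for months, integer for days, 2 dp for ORs.

    Full precision is always retained internally; this is applied only at
    report-writing time.
    """
    if kind == "months":
        return round(value, 1)
    if kind == "days":
        return float(round(value))
    if kind in ("or", "odds_ratio"):
        return round(value, 2)
    if kind == "years":
        return round(value, 2)
    raise ConfigurationError(f"unknown rounding kind {kind!r}")
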