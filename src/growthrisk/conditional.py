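"""Conditional weight gain and the composite obesity-risk outcome.

A raw change in weight z-score penalises small babies and rewards large ones
through regression to the mean.  Conditional gain removes this: regress the
follow-up z-score on the baseline z-score in a fitting sample and express
each infant's follow-up value as a standardized residual,

    gain = (z_t - (a + b * z_0)) / residual_sd.

By construction the gains have mean 0, SD 1 and zero correlation with the
baseline z in the fitting sample, so "gain" measures growth relative to
peers who started at the same size.

The composite outcome used for risk-equation development flags an infant
whose 2-year BMI exceeds a reference centile (default the 91st) AND whose
conditional weight gain from birth to 2 years exceeds one centile band on
UK nine-centile growth charts (adjacent major centile lines are 2/3 of an
SD apart, so the default band width is 0.67 SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError, DomainError
from .reference import centile_to_z


@dataclass(frozen=True)
class ConditionalModel:
    """Conditioning regression of follow-up weight z on baseline weight z."""

    intercept: float
    slope: float
    residual_sd: float
    n_fit: int
    baseline_age_days: int = 0
    followup_age_days: int = 730

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise DegenerateModelError(
                f"residual_sd must be positive, got {self.residual_sd}")
        if self.n_fit < 3:
            raise DomainError(f"n_fit must be >= 3, got {self.n_fit}")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "residual_sd": self.residual_sd,
            "n_fit": self.n_fit,
            "baseline_age_days": self.baseline_age_days,
            "followup_age_days": self.followup_age_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalModel":
        return cls(**d)


@dataclass(frozen=True)
class OutcomeRule:
    """Composite outcome: high 2-year BMI and rapid conditional 0-2y gain.

    ``strict`` chooses the comparator for the gain condition (``>`` when
    True, ``>=`` when False); the BMI condition is always strict.
    """

    bmi_centile_cutoff: float = 91.0
    band_width_sd: float = 0.67
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.bmi_centile_cutoff < 100.0:
            raise DomainError(
                f"bmi_centile_cutoff must be in (0, 100), got {self.bmi_centile_cutoff}")
        if self.band_width_sd <= 0:
            raise DomainError(f"band_width_sd must be positive, got {self.band_width_sd}")

    @property
    def bmi_z_cutoff(self) -> float:
        return centile_to_z(self.bmi_centile_cutoff)

    def to_dict(self) -> dict:
        return {
            "bmi_centile_cutoff": self.bmi_centile_cutoff,
            "band_width_sd": self.band_width_sd,
            "strict": self.strict,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeRule":
        return cls(**d)


def fit_conditional_model(
    z0,
    zt,
    baseline_age_days: int = 0,
    followup_age_days: int = 730,
) -> ConditionalModel:
    """OLS of follow-up z on baseline z; residual SD uses the n-2 denominator.

    Raises :class:`DegenerateModelError` when the baseline has no variance or
    the fit is exact (zero residual variance), since a conditional gain is
    undefined in either case.
    """
    z0 = np.asarray(z0, dtype=float)
    zt = np.asarray(zt, dtype=float)
    if z0.shape != zt.shape or z0.ndim != 1:
        raise DomainError(
            f"z0 and zt must be 1-d arrays of equal length, got {z0.shape} and {zt.shape}")
    n = len(z0)
    if n < 3:
        raise DomainError(f"need at least 3 pairs to fit, got {n}")
    if not (np.all(np.isfinite(z0)) and np.all(np.isfinite(zt))):
        raise DomainError("z0 and zt must be finite")
    sxx = float(np.sum((z0 - z0.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateModelError("baseline z-scores have zero variance")
    sxy = float(np.sum((z0 - z0.mean()) * (zt - zt.mean())))
    slope = sxy / sxx
    intercept = float(zt.mean() - slope * z0.mean())
    resid = zt - (intercept + slope * z0)
    rss = float(np.sum(resid**2))
    residual_sd = np.sqrt(rss / (n - 2))
    if residual_sd == 0.0:
        raise DegenerateModelError(
            "exact linear relationship between z0 and zt; conditional gain undefined")
    return ConditionalModel(
        intercept=intercept, slope=slope, residual_sd=residual_sd, n_fit=n,
        baseline_age_days=baseline_age_days, followup_age_days=followup_age_days)


def conditional_gain_z(z0, zt, model: ConditionalModel):
    """Standardized residual of ``zt`` given ``z0`` under the fitted model.

    Accepts scalars or arrays.  With standardized inputs and intercept 0,
    slope r and residual SD sqrt(1 - r^2) this reduces to the textbook
    (zt - r*z0) / sqrt(1 - r^2).
    """
    z0 = np.asarray(z0, dtype=float)
    zt = np.asarray(zt, dtype=float)
    out = (zt - (model.intercept + model.slope * z0)) / model.residual_sd
    return float(out) if out.ndim == 0 else out


def outcome_flag(bmi_z_2y: float, cg_0_2y: float, rule: OutcomeRule = OutcomeRule()) -> bool:
    """Composite obesity-risk flag from 2-year BMI z and conditional 0-2y gain."""
    if not (np.isfinite(bmi_z_2y) and np.isfinite(cg_0_2y)):
        raise DomainError("bmi_z_2y and cg_0_2y must be finite")
    bmi_high = bmi_z_2y > rule.bmi_z_cutoff
    gain_high = cg_0_2y > rule.band_width_sd if rule.strict else cg_0_2y >= rule.band_width_sd
    return bool(bmi_high and gain_high)
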