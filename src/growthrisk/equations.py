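"""The published infant obesity-risk equations and the scoring pipeline.

Six logistic equations estimate the probability that an infant will show
the composite obesity-risk outcome at age two years.  Two equations exist
for each of three assessment windows (6 +/- 1.5, 9 +/- 1.5 and 12 +/- 1.5
months): a base variant using sex, birthweight z-score and conditional
weight-gain z-score, and a variant adding maternal BMI.  The risk score is

    p = logistic(alpha + b_f * 1[female] + b_bw * bw_z + b_gain * gain_z
                 [+ b_mbmi * maternal_bmi])

and is mapped to a three-tier band using thresholds fixed at the 10%, 20%
and 30% points of the development-sample score distribution: scores in the
top decile are "high" risk, decile-to-quintile "medium", the rest "low".
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .conditional import ConditionalModel, conditional_gain_z
from .errors import AgeRangeError, DomainError
from .reference import (
    DAYS_PER_MONTH,
    ReferenceSet,
    normalize_sex,
    parse_length,
    parse_weight,
)

EQUATION_IDS = ("eq1", "eq2", "eq3")
VARIANTS = ("base", "with_maternal_bmi")

#: half-open assessment windows in months; the last is closed at 13.5
WINDOWS_MONTHS = {"eq1": (4.5, 7.5), "eq2": (7.5, 10.5), "eq3": (10.5, 13.5)}


@dataclass(frozen=True)
class Thresholds:
    """Score-distribution cut-offs: t10 (top decile) > t20 > t30."""

    t10: float
    t20: float
    t30: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t30 < self.t20 < self.t10 < 1.0):
            raise DomainError(
                f"thresholds must satisfy 0 < t30 < t20 < t10 < 1, "
                f"got {self.t30}, {self.t20}, {self.t10}")

    def to_dict(self) -> dict:
        return {"t10": self.t10, "t20": self.t20, "t30": self.t30}


@dataclass(frozen=True)
class EquationSpec:
    """One risk equation: coefficients, assessment window and band thresholds."""

    id: str
    variant: str
    alpha: float
    beta_female: float
    beta_bw_z: float
    beta_gain_z: float
    thresholds: Thresholds
    beta_maternal_bmi: float | None = None

    def __post_init__(self) -> None:
        if self.id not in EQUATION_IDS:
            raise DomainError(f"unknown equation id {self.id!r}")
        if self.variant not in VARIANTS:
            raise DomainError(f"unknown variant {self.variant!r}")
        if self.variant == "with_maternal_bmi" and self.beta_maternal_bmi is None:
            raise DomainError(f"{self.id}/{self.variant}: beta_maternal_bmi required")
        if self.variant == "base" and self.beta_maternal_bmi is not None:
            raise DomainError(f"{self.id}/base: beta_maternal_bmi must be absent")

    @property
    def window_months(self) -> tuple[float, float]:
        return WINDOWS_MONTHS[self.id]

    def linear_predictor(self, female, bw_z, gain_z, maternal_bmi=None):
        lp = (self.alpha
              + self.beta_female * np.asarray(female, dtype=float)
              + self.beta_bw_z * np.asarray(bw_z, dtype=float)
              + self.beta_gain_z * np.asarray(gain_z, dtype=float))
        if self.variant == "with_maternal_bmi":
            if maternal_bmi is None:
                raise DomainError(
                    f"{self.id}/{self.variant} requires maternal_bmi")
            lp = lp + self.beta_maternal_bmi * np.asarray(maternal_bmi, dtype=float)
        return lp

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "variant": self.variant,
            "alpha": self.alpha,
            "beta_female": self.beta_female,
            "beta_bw_z": self.beta_bw_z,
            "beta_gain_z": self.beta_gain_z,
            "thresholds": self.thresholds.to_dict(),
        }
        if self.beta_maternal_bmi is not None:
            d["beta_maternal_bmi"] = self.beta_maternal_bmi
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EquationSpec":
        d = dict(d)
        d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)


# Published coefficients (base: sex + birthweight z + gain z; the second set
# adds maternal BMI) and the matching 10/20/30% score-distribution thresholds.
_PUBLISHED = (
    EquationSpec("eq1", "base", alpha=-3.718, beta_female=0.488,
                 beta_bw_z=0.599, beta_gain_z=1.501,
                 thresholds=Thresholds(t10=0.2072, t20=0.1155, t30=0.0731)),
    EquationSpec("eq2", "base", alpha=-3.542, beta_female=0.288,
                 beta_bw_z=0.551, beta_gain_z=1.508,
                 thresholds=Thresholds(t10=0.2082, t20=0.1104, t30=0.0662)),
    EquationSpec("eq3", "base", alpha=-3.937, beta_female=0.234,
                 beta_bw_z=0.824, beta_gain_z=2.174,
                 thresholds=Thresholds(t10=0.2391, t20=0.1065, t30=0.0609)),
    EquationSpec("eq1", "with_maternal_bmi", alpha=-4.920, beta_female=0.493,
                 beta_bw_z=0.577, beta_gain_z=1.494, beta_maternal_bmi=0.044,
                 thresholds=Thresholds(t10=0.2183, t20=0.1156, t30=0.0696)),
    EquationSpec("eq2", "with_maternal_bmi", alpha=-4.745, beta_female=0.255,
                 beta_bw_z=0.505, beta_gain_z=1.501, beta_maternal_bmi=0.046,
                 thresholds=Thresholds(t10=0.2042, t20=0.1076, t30=0.0646)),
    EquationSpec("eq3", "with_maternal_bmi", alpha=-4.625, beta_female=0.230,
                 beta_bw_z=0.798, beta_gain_z=2.149, beta_maternal_bmi=0.026,
                 thresholds=Thresholds(t10=0.2404, t20=0.1051, t30=0.0612)),
)


def published_equations() -> tuple[EquationSpec, ...]:
    """The six published equations (three windows x two variants)."""
    return _PUBLISHED


def get_equation(equation_id: str, variant: str = "base") -> EquationSpec:
    for spec in _PUBLISHED:
        if spec.id == equation_id and spec.variant == variant:
            return spec
    raise DomainError(f"no published equation {equation_id!r} variant {variant!r}")


def select_equation(age_days: float) -> str:
    """Map assessment age to an equation id by its half-open month window."""
    months = age_days / DAYS_PER_MONTH
    if 4.5 <= months < 7.5:
        return "eq1"
    if 7.5 <= months < 10.5:
        return "eq2"
    if 10.5 <= months <= 13.5:
        return "eq3"
    raise AgeRangeError(
        f"assessment age {months:.2f} months ({age_days:g} d) outside the "
        f"supported 4.5-13.5 month range")


def predict_probability(sex, bw_z, gain_z, spec: EquationSpec, maternal_bmi=None):
    """Risk probability from one equation; scalar in, scalar out (arrays ok)."""
    female = _female_indicator(sex)
    for name, v in (("bw_z", bw_z), ("gain_z", gain_z)):
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise DomainError(f"{name} must be finite")
    lp = spec.linear_predictor(female, bw_z, gain_z, maternal_bmi)
    p = 1.0 / (1.0 + np.exp(-lp))
    return float(p) if np.ndim(p) == 0 else p


def _female_indicator(sex):
    if isinstance(sex, str):
        return 1.0 if normalize_sex(sex) == "female" else 0.0
    return np.asarray(sex, dtype=float)


def classify(probability: float, spec: EquationSpec) -> str:
    """Three-tier band: high above t10, medium between t20 and t10, else low."""
    if not 0.0 < probability < 1.0:
        raise DomainError(f"probability must be in (0, 1), got {probability}")
    if probability >= spec.thresholds.t10:
        return "high"
    if probability >= spec.thresholds.t20:
        return "medium"
    return "low"


@dataclass(frozen=True)
class RiskAssessment:
    """Full scoring output for one infant."""

    equation_id: str
    variant: str
    probability: float
    band: str
    bw_z: float
    current_weight_z: float
    gain_z: float
    maternal_bmi_used: bool
    maternal_bmi: float | None = None

    def to_dict(self) -> dict:
        return {
            "equation_id": self.equation_id,
            "variant": self.variant,
            "probability": self.probability,
            "band": self.band,
            "bw_z": self.bw_z,
            "current_weight_z": self.current_weight_z,
            "gain_z": self.gain_z,
            "maternal_bmi_used": self.maternal_bmi_used,
            "maternal_bmi": self.maternal_bmi,
        }


def assess(
    sex: str,
    dob: dt.date,
    assessment_date: dt.date,
    birth_weight,
    current_weight,
    refs: ReferenceSet,
    conditional_model: ConditionalModel,
    maternal_height=None,
    maternal_weight=None,
) -> RiskAssessment:
    """Score one infant end to end, replicating the App's input contract.

    Weights accept kg or lb ('3.2kg', '7lb', bare numbers mean kg); maternal
    height accepts cm, inches or feet+inches.  Maternal BMI is used only when
    both maternal height and weight are supplied, switching to the
    with-maternal-BMI equation variant.  Birthweight is z-scored at age 0,
    the current weight at the assessment age, and the conditional gain is
    computed under the supplied conditioning model.
    """
    if assessment_date <= dob:
        raise DomainError(
            f"assessment date {assessment_date} must fall after birth {dob}")
    sex = normalize_sex(sex)
    age_days = (assessment_date - dob).days
    eq_id = select_equation(age_days)

    bw_kg = parse_weight(birth_weight)
    cur_kg = parse_weight(current_weight)
    weight_ref = refs.get_curve("weight", sex)
    bw_z = weight_ref.zscore(bw_kg, 0)
    cur_z = weight_ref.zscore(cur_kg, age_days)
    gain_z = conditional_gain_z(bw_z, cur_z, conditional_model)

    maternal_bmi = None
    if maternal_height is not None and maternal_weight is not None:
        h_m = parse_length(maternal_height) / 100.0
        w_kg = parse_weight(maternal_weight)
        maternal_bmi = w_kg / h_m**2
    use_maternal = maternal_bmi is not None
    spec = get_equation(eq_id, "with_maternal_bmi" if use_maternal else "base")
    p = predict_probability(sex, bw_z, gain_z, spec, maternal_bmi)
    return RiskAssessment(
        equation_id=eq_id,
        variant=spec.variant,
        probability=p,
        band=classify(p, spec),
        bw_z=bw_z,
        current_weight_z=cur_z,
        gain_z=gain_z,
        maternal_bmi_used=use_maternal,
        maternal_bmi=maternal_bmi,
    )
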