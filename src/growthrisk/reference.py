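"""LMS growth references and age/sex-adjusted z-scores.

Infant anthropometry (weight, length, BMI) is expressed in SD units relative
to an age- and sex-specific reference distribution summarised by three
curves: the Box-Cox power ``L`` (skewness), the median ``M`` and the
coefficient of variation ``S``.  For a measured value ``x`` at a given age

    z = ((x / M)**L - 1) / (L * S)        (L != 0)
    z = ln(x / M) / S                     (L -> 0 limit)

and the inverse maps a z-score back to measurement units.  ``L``, ``M`` and
``S`` are interpolated linearly in age (days) between tabulated knots.

National references such as UK90 are licensed tables and are not
redistributed here; :func:`synthetic_reference` builds a smooth synthetic
stand-in covering 0-30 months with realistic magnitudes, sufficient for
exercising and testing every downstream computation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AgeRangeError, DomainError, ReferenceTableError, UnitError

#: One month, in days, for every age-window computation in the package.
DAYS_PER_MONTH = 30.4375

MEASUREMENTS = ("weight", "length", "bmi")
SEXES = ("male", "female")

_SEX_ALIASES = {
    "male": "male", "m": "male", "boy": "male",
    "female": "female", "f": "female", "girl": "female",
}

#: below this |L| the Box-Cox transform switches to its logarithmic limit
_L_EPS = 1e-7

LB_TO_KG = 0.45359237
IN_TO_CM = 2.54


def normalize_sex(sex: str) -> str:
    """Map common sex spellings (``m``/``f``/``boy``/``girl``...) to canonical form."""
    try:
        return _SEX_ALIASES[str(sex).strip().lower()]
    except KeyError:
        raise DomainError(f"unknown sex {sex!r}; expected one of male/female/m/f")


def lms_transform(x: float, L: float, M: float, S: float) -> float:
    """Box-Cox z-score of a raw value against one (L, M, S) triple."""
    if x <= 0:
        raise DomainError(f"measurement value must be positive, got {x}")
    if M <= 0 or S <= 0:
        raise DomainError(f"M and S must be positive, got M={M}, S={S}")
    if abs(L) < _L_EPS:
        return math.log(x / M) / S
    # expm1 form is numerically stable through small |L|
    return math.expm1(L * math.log(x / M)) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Raw measurement value whose z-score is ``z`` under one (L, M, S) triple."""
    if M <= 0 or S <= 0:
        raise DomainError(f"M and S must be positive, got M={M}, S={S}")
    if abs(L) < _L_EPS:
        return M * math.exp(S * z)
    if 1.0 + L * S * z <= 0:
        raise DomainError(f"z={z} is outside the support of the Box-Cox transform")
    return M * math.exp(math.log1p(L * S * z) / L)


def z_to_centile(z: float) -> float:
    """Standard-normal CDF, on the 0-100 centile scale."""
    return float(norm.cdf(z) * 100.0)


def centile_to_z(centile: float) -> float:
    """Inverse of :func:`z_to_centile`; ``centile`` must lie strictly in (0, 100)."""
    if not 0.0 < centile < 100.0:
        raise DomainError(f"centile must be in (0, 100), got {centile}")
    return float(norm.ppf(centile / 100.0))


@dataclass(frozen=True)
class LMSReference:
    """One measurement/sex reference: L, M, S tabulated on an age grid (days)."""

    measurement: str
    sex: str
    age_days: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        for name in ("age_days", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.measurement not in MEASUREMENTS:
            raise ReferenceTableError(
                f"unknown measurement {self.measurement!r}; expected one of {MEASUREMENTS}")
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        n = len(self.age_days)
        if not (len(self.L) == len(self.M) == len(self.S) == n) or n < 2:
            raise ReferenceTableError(
                f"{self.measurement}/{self.sex}: need >= 2 knots with matching L/M/S lengths")
        diffs = np.diff(self.age_days)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ReferenceTableError(
                f"{self.measurement}/{self.sex}: ages must be strictly increasing; "
                f"violation at rows {i} -> {i + 1} "
                f"(ages {self.age_days[i]:g}, {self.age_days[i + 1]:g})")
        bad = np.flatnonzero((self.M <= 0) | (self.S <= 0))
        if bad.size:
            i = int(bad[0])
            raise ReferenceTableError(
                f"{self.measurement}/{self.sex}: non-positive M or S at row {i} "
                f"(age {self.age_days[i]:g}, M={self.M[i]:g}, S={self.S[i]:g})")

    @property
    def span(self) -> tuple[float, float]:
        """(min, max) age in days covered by the grid."""
        return float(self.age_days[0]), float(self.age_days[-1])

    def lms_at(self, age_days: float) -> tuple[float, float, float]:
        """L, M, S linearly interpolated at an age inside the grid span."""
        lo, hi = self.span
        if not lo <= age_days <= hi:
            raise AgeRangeError(
                f"age {age_days:g} d outside {self.measurement}/{self.sex} "
                f"reference span [{lo:g}, {hi:g}] d")
        return (
            float(np.interp(age_days, self.age_days, self.L)),
            float(np.interp(age_days, self.age_days, self.M)),
            float(np.interp(age_days, self.age_days, self.S)),
        )

    def zscore(self, value: float, age_days: float) -> float:
        """Z-score of a raw value at an age, interpolating L/M/S."""
        return lms_transform(value, *self.lms_at(age_days))

    def value_for_z(self, z: float, age_days: float) -> float:
        """Raw value whose z-score at ``age_days`` equals ``z`` (inverse of zscore)."""
        return lms_inverse(z, *self.lms_at(age_days))

    def centile(self, value: float, age_days: float) -> float:
        return z_to_centile(self.zscore(value, age_days))


@dataclass(frozen=True)
class Measurement:
    """One infant's raw anthropometry at a single visit."""

    subject_id: str
    sex: str
    age_days: int
    weight_kg: float | None = None
    length_cm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        if self.age_days < 0:
            raise DomainError(f"age_days must be non-negative, got {self.age_days}")
        if self.weight_kg is None and self.length_cm is None:
            raise DomainError("at least one of weight_kg/length_cm must be present")
        for name in ("weight_kg", "length_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")

    @property
    def bmi(self) -> float | None:
        """kg/m^2, when both weight and length are available."""
        if self.weight_kg is None or self.length_cm is None:
            return None
        return self.weight_kg / (self.length_cm / 100.0) ** 2


@dataclass(frozen=True)
class AnthropometryZ:
    """Z-scores computed from one Measurement; fields are None when unavailable."""

    weight_z: float | None = None
    length_z: float | None = None
    bmi_z: float | None = None


class ReferenceSet(Mapping):
    """Immutable collection of LMSReference curves keyed by (measurement, sex)."""

    def __init__(self, references: Iterable[LMSReference]):
        self._refs: dict[tuple[str, str], LMSReference] = {}
        for ref in references:
            key = (ref.measurement, ref.sex)
            if key in self._refs:
                raise ReferenceTableError(f"duplicate reference for {key}")
            self._refs[key] = ref

    def __getitem__(self, key):
        return self._refs[key]

    def __iter__(self):
        return iter(self._refs)

    def __len__(self):
        return len(self._refs)

    def get_curve(self, measurement: str, sex: str) -> LMSReference:
        key = (measurement, normalize_sex(sex))
        try:
            return self._refs[key]
        except KeyError:
            raise ReferenceTableError(
                f"reference table has no {key[0]} curve for sex {key[1]!r}")

    def zscore(self, measurement: str, sex: str, value: float, age_days: float) -> float:
        return self.get_curve(measurement, sex).zscore(value, age_days)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (meas, sex), ref in sorted(self._refs.items()):
            for a, L, M, S in zip(ref.age_days, ref.L, ref.M, ref.S):
                rows.append((meas, sex, int(a), L, M, S))
        return pd.DataFrame(rows, columns=["measurement", "sex", "age_days", "L", "M", "S"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


_REQUIRED_COLUMNS = ["measurement", "sex", "age_days", "L", "M", "S"]


def load_reference(path) -> ReferenceSet:
    """Read an LMS table CSV (columns measurement,sex,age_days,L,M,S).

    Rows are grouped into one :class:`LMSReference` per (measurement, sex);
    all grid invariants are enforced, naming the offending row on failure.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceTableError(f"LMS table {path} is missing columns {missing}")
    refs = []
    for (meas, sex), grp in df.groupby(["measurement", "sex"], sort=True):
        grp = grp.sort_values("age_days", kind="stable")
        ages = grp["age_days"].to_numpy(dtype=float)
        if np.any(np.diff(ages) == 0):
            i = int(np.argmax(np.diff(ages) == 0))
            raise ReferenceTableError(
                f"{meas}/{sex}: duplicated age_days {ages[i]:g} in {path}")
        refs.append(LMSReference(
            measurement=str(meas), sex=str(sex), age_days=ages,
            L=grp["L"].to_numpy(), M=grp["M"].to_numpy(), S=grp["S"].to_numpy()))
    return ReferenceSet(refs)


def measurement_to_z(m: Measurement, refs: ReferenceSet) -> AnthropometryZ:
    """Z-score whichever of weight/length/BMI a measurement provides.

    BMI (weight / length^2 in kg/m^2) is computed and scored only when both
    components are present.
    """
    weight_z = length_z = bmi_z = None
    if m.weight_kg is not None:
        weight_z = refs.zscore("weight", m.sex, m.weight_kg, m.age_days)
    if m.length_cm is not None:
        length_z = refs.zscore("length", m.sex, m.length_cm, m.age_days)
    if m.bmi is not None:
        bmi_z = refs.zscore("bmi", m.sex, m.bmi, m.age_days)
    return AnthropometryZ(weight_z=weight_z, length_z=length_z, bmi_z=bmi_z)


# ---------------------------------------------------------------------------
# synthetic reference fixture


def _weight_curves(t: np.ndarray, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # median weight (kg): fast saturating gain plus a slow linear component
    scale = 1.0 if sex == "male" else 0.94
    M = scale * (3.5 + 5.8 * (1.0 - np.exp(-t / 6.0)) + 0.16 * t)
    L = -0.2 - 0.1 * t / 30.0
    S = 0.13 - 0.02 * t / 30.0
    return L, M, S


def _length_curves(t: np.ndarray, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    scale = 1.0 if sex == "male" else 0.985
    M = scale * (50.0 + 26.0 * (1.0 - np.exp(-t / 7.0)) + 0.35 * t)
    L = np.ones_like(t)  # length is close to Gaussian
    S = np.full_like(t, 0.035)
    return L, M, S


def _bmi_curves(t: np.ndarray, M_weight: np.ndarray, M_length: np.ndarray):
    # the BMI median is derived from the weight/length medians so that a
    # median infant (weight z = length z = 0) sits exactly on the BMI median
    M = M_weight / (M_length / 100.0) ** 2
    L = -1.3 + 0.3 * t / 30.0
    # S matches the ln-BMI spread induced by on-reference weight and length
    S = 0.075 + 0.015 * t / 30.0
    return L, M, S


def synthetic_reference(seed: int = 0, max_age_months: int = 30) -> ReferenceSet:
    """Build a synthetic LMS reference set covering 0 to ``max_age_months``.

    Smooth parametric L/M/S curves with infant-plausible magnitudes, sampled
    at monthly knots, for weight, length and BMI in both sexes; the BMI
    median is derived from the weight and length medians so the three
    references are mutually consistent.  A seeded sub-percent smooth
    perturbation of the median curves makes distinct seeds produce distinct
    (but equally valid) references; it never breaks monotonicity or
    positivity.  This is a test fixture standing in for a licensed national
    reference, not a clinical standard.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0, max_age_months + 1, dtype=float)
    age_days = np.round(t * DAYS_PER_MONTH)
    refs = []
    for sex in SEXES:
        curves = {"weight": _weight_curves(t, sex), "length": _length_curves(t, sex)}
        wobbled = {}
        for meas in ("weight", "length"):
            L, M, S = curves[meas]
            wobble = rng.uniform(-1.0, 1.0) * 0.003
            M = M * (1.0 + wobble * np.sin(np.pi * t / max_age_months))
            wobbled[meas] = M
            refs.append(LMSReference(
                measurement=meas, sex=sex, age_days=age_days, L=L, M=M, S=S))
        L, M, S = _bmi_curves(t, wobbled["weight"], wobbled["length"])
        refs.append(LMSReference(
            measurement="bmi", sex=sex, age_days=age_days, L=L, M=M, S=S))
    return ReferenceSet(refs)


# ---------------------------------------------------------------------------
# unit parsing (App-style free-form input)

_WEIGHT_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(kg|lb|lbs)?\s*$", re.IGNORECASE)
_LENGTH_RE = re.compile(
    r"^\s*(?:([0-9]*\.?[0-9]+)\s*(cm|in)|([0-9]+)\s*(?:ft|')\s*([0-9]*\.?[0-9]+)?\s*(?:in|\")?)\s*$",
    re.IGNORECASE,
)


def parse_weight(value) -> float:
    """Weight in kg from a number (assumed kg) or a string like '7.9kg' / '17.4lb'."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _WEIGHT_RE.match(str(value))
    if not m:
        raise UnitError(f"cannot parse weight {value!r}; expected e.g. '3.2kg' or '7lb'")
    x = float(m.group(1))
    unit = (m.group(2) or "kg").lower()
    return x * LB_TO_KG if unit in ("lb", "lbs") else x


def parse_length(value) -> float:
    """Length/height in cm from a number (assumed cm) or '165cm' / '65in' / "5ft6in"."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _LENGTH_RE.match(str(value))
    if not m:
        raise UnitError(
            f"cannot parse length {value!r}; expected e.g. '70cm', '27.5in' or '5ft6in'")
    if m.group(1) is not None:
        x = float(m.group(1))
        return x * IN_TO_CM if m.group(2).lower() == "in" else x
    feet = float(m.group(3))
    inches = float(m.group(4)) if m.group(4) else 0.0
    return (feet * 12.0 + inches) * IN_TO_CM
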