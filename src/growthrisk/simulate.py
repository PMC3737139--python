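"""Seeded synthetic cohorts with the structure of the development/validation samples.

Two generating modes:

* **model mode** draws covariates independently — sex, birthweight z,
  conditional gain z (standard normal by construction of conditioning),
  maternal BMI (truncated normal), ethnicity, education, smoking,
  gestational diabetes, preterm birth — and draws the outcome from the
  logistic model whose coefficients are configured (the published equations
  by default).  Outcome prevalence is emergent, not forced.

* **growth mode** simulates raw weight/length measurements at birth, one
  assessment visit and ~24 months through a latent correlated z-process
  mapped to measurement units via the LMS reference, then recomputes the
  whole cohort table (z-scores, conditional models, composite outcome)
  from those raw measurements with the same pipeline a real cohort would
  use.

Defaults are calibrated to the published development-sample summary
(birthweight z mean -0.56 SD 1.2, maternal BMI 25.9 SD 5.6, about half
South Asian, outcome prevalence emerging near 8%); presets cover each
equation sample and the external (ALSPAC-like, almost entirely White,
leaner mothers) sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .conditional import ConditionalModel, OutcomeRule, conditional_gain_z, fit_conditional_model, outcome_flag
from .develop import EDUCATION_LEVELS, CohortRecord
from .equations import EquationSpec, WINDOWS_MONTHS, get_equation
from .errors import DomainError
from .reference import DAYS_PER_MONTH, Measurement, ReferenceSet


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort draw."""

    n: int
    seed: int
    mode: str = "model"
    equation: EquationSpec = field(default_factory=lambda: get_equation("eq3", "base"))
    p_female: float = 0.49
    bw_z_mean: float = -0.56
    bw_z_sd: float = 1.2
    gain_z_mean: float = 0.0
    gain_z_sd: float = 1.0
    maternal_bmi_mean: float = 25.9
    maternal_bmi_sd: float = 5.6
    maternal_bmi_bounds: tuple[float, float] = (13.0, 60.0)
    p_south_asian: float = 0.52
    p_smoked: float = 0.13
    p_gdm: float = 0.074
    p_preterm: float = 0.046
    education_probs: tuple[float, ...] = (0.186, 0.303, 0.168, 0.285, 0.058)
    outcome_rule: OutcomeRule = field(default_factory=OutcomeRule)
    # growth-mode only: correlation of latent weight z between birth and 24 m,
    # and between weight and length z at 24 m
    latent_corr_birth_24m: float = 0.5
    weight_length_corr: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"invalid config field n: must be >= 1, got {self.n}")
        if self.mode not in ("model", "growth"):
            raise DomainError(f"invalid config field mode: {self.mode!r}")
        for name in ("p_female", "p_south_asian", "p_smoked", "p_gdm", "p_preterm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"invalid config field {name}: must be in [0, 1], got {v}")
        for name in ("bw_z_sd", "gain_z_sd", "maternal_bmi_sd"):
            v = getattr(self, name)
            if v <= 0:
                raise DomainError(f"invalid config field {name}: must be positive, got {v}")
        if len(self.education_probs) != len(EDUCATION_LEVELS):
            raise DomainError(
                f"invalid config field education_probs: need {len(EDUCATION_LEVELS)} values")
        if not np.isclose(sum(self.education_probs), 1.0, atol=1e-6):
            raise DomainError("invalid config field education_probs: must sum to 1")
        for name in ("latent_corr_birth_24m", "weight_length_corr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise DomainError(f"invalid config field {name}: must be in [0, 1), got {v}")


def _truncated_normal(rng, mean, sd, bounds, size):
    lo, hi = bounds
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # redraw the tails; truncation loses < 2% of draws here
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_covariates(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n
    probs = np.asarray(config.education_probs, dtype=float)
    probs = probs / probs.sum()
    return pd.DataFrame({
        "subject_id": [f"s{i:06d}" for i in range(n)],
        "sex": np.where(rng.random(n) < config.p_female, "female", "male"),
        "ethnicity": np.where(
            rng.random(n) < config.p_south_asian, "south_asian", "white_british"),
        "maternal_bmi": _truncated_normal(
            rng, config.maternal_bmi_mean, config.maternal_bmi_sd,
            config.maternal_bmi_bounds, n),
        "education": rng.choice(EDUCATION_LEVELS, size=n, p=probs),
        "smoked": (rng.random(n) < config.p_smoked).astype(int),
        "gdm": (rng.random(n) < config.p_gdm).astype(int),
        "preterm": (rng.random(n) < config.p_preterm).astype(int),
    })


def simulate_model_mode(config: SimulationConfig) -> pd.DataFrame:
    """Cohort drawn from the configured logistic data-generating process.

    Conditional gain is standard-normal and independent of birthweight z by
    construction (it is the standardized residual on birthweight z); the
    2-year BMI z-score is a correlated companion of the gain (r = 0.5),
    carried for table completeness but not used to generate the outcome.
    Returns a cohort DataFrame; deterministic under ``config.seed``.
    """
    if config.mode != "model":
        raise DomainError(f"config.mode must be 'model', got {config.mode!r}")
    rng = np.random.default_rng(config.seed)
    frame = _draw_covariates(config, rng)
    n = config.n
    frame["bw_z"] = rng.normal(config.bw_z_mean, config.bw_z_sd, n)
    frame["gain_z"] = rng.normal(config.gain_z_mean, config.gain_z_sd, n)
    frame["bmi_z_2y"] = (-0.03 + 1.1 * (0.5 * (frame["gain_z"] - config.gain_z_mean)
                                        / config.gain_z_sd
                                        + np.sqrt(0.75) * rng.normal(size=n)))
    spec = config.equation
    female = (frame["sex"] == "female").to_numpy(dtype=float)
    mbmi = (frame["maternal_bmi"].to_numpy()
            if spec.variant == "with_maternal_bmi" else None)
    lp = spec.linear_predictor(
        female, frame["bw_z"].to_numpy(), frame["gain_z"].to_numpy(), mbmi)
    p = 1.0 / (1.0 + np.exp(-lp))
    frame["outcome"] = (rng.random(n) < p).astype(int)
    cols = ["subject_id", "sex", "ethnicity", "bw_z", "gain_z", "bmi_z_2y",
            "maternal_bmi", "education", "smoked", "gdm", "preterm", "outcome"]
    return frame[cols]


# ---------------------------------------------------------------------------
# growth mode: raw measurements through the full pipeline


@dataclass
class GrowthSimulation:
    """Raw measurements plus the cohort table recomputed from them."""

    measurements: list
    covariates: pd.DataFrame
    cohort: pd.DataFrame
    conditional_assess: ConditionalModel
    conditional_2y: ConditionalModel


def _latent_weight_z(config: SimulationConfig, rng, n: int) -> np.ndarray:
    """Latent weight z at (birth, assessment, 24 m) with AR-like correlation.

    The birth-to-24-month correlation equals ``latent_corr_birth_24m``; the
    assessment visit sits between them with corr sqrt(c) to each end, the
    unique choice consistent with a first-order autoregressive process.
    """
    c = config.latent_corr_birth_24m
    rc = np.sqrt(c)
    R = np.array([[1.0, rc, c], [rc, 1.0, rc], [c, rc, 1.0]])
    u = rng.standard_normal((n, 3)) @ np.linalg.cholesky(R).T
    z = np.empty_like(u)
    z[:, 0] = config.bw_z_mean + config.bw_z_sd * u[:, 0]
    z[:, 1] = u[:, 1]   # later visits: nominally on-reference, mean 0 SD 1
    z[:, 2] = u[:, 2]
    return z


def simulate_growth_mode(config: SimulationConfig, refs: ReferenceSet) -> GrowthSimulation:
    """Emit raw weights/lengths and rebuild the cohort from them.

    Weights at three visits come from a latent correlated z-process pushed
    through the inverse LMS transform; 24-month length is correlated with
    24-month weight so BMI is realistic.  The returned cohort table is the
    output of :func:`build_cohort_from_measurements` on the emitted raw
    data — the outcome satisfies the composite rule exactly, and z-scoring
    the raw values recovers the latent z-process to numerical precision.
    """
    if config.mode != "growth":
        raise DomainError(f"config.mode must be 'growth', got {config.mode!r}")
    rng = np.random.default_rng(config.seed)
    cov = _draw_covariates(config, rng)
    n = config.n
    lo_m, hi_m = WINDOWS_MONTHS[config.equation.id]
    assess_age = np.round(rng.uniform(
        lo_m * DAYS_PER_MONTH, hi_m * DAYS_PER_MONTH, size=n)).astype(int)
    age_2y = rng.integers(730 - 61, 730 + 62, size=n)

    z = _latent_weight_z(config, rng, n)
    wl = config.weight_length_corr
    length_z_2y = wl * z[:, 2] + np.sqrt(1 - wl**2) * rng.standard_normal(n)

    measurements = []
    for i in range(n):
        sid, sex = cov.at[i, "subject_id"], cov.at[i, "sex"]
        wref = refs.get_curve("weight", sex)
        lref = refs.get_curve("length", sex)
        measurements.append(Measurement(
            subject_id=sid, sex=sex, age_days=0,
            weight_kg=wref.value_for_z(z[i, 0], 0)))
        measurements.append(Measurement(
            subject_id=sid, sex=sex, age_days=int(assess_age[i]),
            weight_kg=wref.value_for_z(z[i, 1], int(assess_age[i]))))
        measurements.append(Measurement(
            subject_id=sid, sex=sex, age_days=int(age_2y[i]),
            weight_kg=wref.value_for_z(z[i, 2], int(age_2y[i])),
            length_cm=lref.value_for_z(length_z_2y[i], int(age_2y[i]))))
    cohort, cond_a, cond_2y = build_cohort_from_measurements(
        measurements, cov, refs, config.outcome_rule)
    return GrowthSimulation(
        measurements=measurements, covariates=cov, cohort=cohort,
        conditional_assess=cond_a, conditional_2y=cond_2y)


def build_cohort_from_measurements(
    measurements: Sequence[Measurement],
    covariates: pd.DataFrame,
    refs: ReferenceSet,
    rule: OutcomeRule = OutcomeRule(),
) -> tuple[pd.DataFrame, ConditionalModel, ConditionalModel]:
    """Full raw-data pipeline: z-score, condition, flag the composite outcome.

    Each subject needs a birth weight (age 0), one assessment-window weight
    (4.5-13.5 months) and a ~2-year (+/- 2 months) visit with weight and
    length; when several measurements fall in a window the nearest to the
    window centre is used.  Conditional models (birth -> assessment and
    birth -> 2 years) are fitted within the cohort itself.
    """
    lo_a = 4.5 * DAYS_PER_MONTH
    hi_a = 13.5 * DAYS_PER_MONTH
    by_subject: dict[str, dict] = {}
    for m in measurements:
        slot = None
        if m.age_days == 0:
            slot = "birth"
        elif lo_a <= m.age_days <= hi_a:
            slot = "assess"
        elif abs(m.age_days - 730) <= 61:
            slot = "2y"
        if slot is None:
            continue
        entry = by_subject.setdefault(m.subject_id, {})
        centre = {"birth": 0, "assess": 9 * DAYS_PER_MONTH, "2y": 730}[slot]
        if slot not in entry or abs(m.age_days - centre) < abs(entry[slot].age_days - centre):
            entry[slot] = m

    rows = []
    for sid, entry in by_subject.items():
        if not all(k in entry for k in ("birth", "assess", "2y")):
            continue
        if entry["2y"].length_cm is None:
            continue
        sex = entry["birth"].sex
        wref = refs.get_curve("weight", sex)
        bmi_ref = refs.get_curve("bmi", sex)
        rows.append({
            "subject_id": sid,
            "bw_z": wref.zscore(entry["birth"].weight_kg, 0),
            "z_assess": wref.zscore(entry["assess"].weight_kg, entry["assess"].age_days),
            "z_2y": wref.zscore(entry["2y"].weight_kg, entry["2y"].age_days),
            "bmi_z_2y": bmi_ref.zscore(entry["2y"].bmi, entry["2y"].age_days),
        })
    ztab = pd.DataFrame(rows)
    if len(ztab) < 3:
        raise DomainError("need at least 3 complete subjects to build a cohort")
    cond_assess = fit_conditional_model(
        ztab["bw_z"], ztab["z_assess"], baseline_age_days=0,
        followup_age_days=int(9 * DAYS_PER_MONTH))
    cond_2y = fit_conditional_model(
        ztab["bw_z"], ztab["z_2y"], baseline_age_days=0, followup_age_days=730)
    ztab["gain_z"] = conditional_gain_z(ztab["bw_z"], ztab["z_assess"], cond_assess)
    cg_2y = conditional_gain_z(ztab["bw_z"], ztab["z_2y"], cond_2y)
    ztab["outcome"] = [
        int(outcome_flag(b, g, rule)) for b, g in zip(ztab["bmi_z_2y"], cg_2y)]
    cohort = covariates.merge(ztab, on="subject_id", how="inner")
    cols = ["subject_id", "sex", "ethnicity", "bw_z", "gain_z", "bmi_z_2y",
            "maternal_bmi", "education", "smoked", "gdm", "preterm", "outcome"]
    return cohort[cols], cond_assess, cond_2y


# ---------------------------------------------------------------------------
# presets


# Development-sample summaries per equation window (sex split, birthweight z,
# maternal BMI, ethnicity and binary covariate rates as published).
_BIB = {
    "eq1": dict(p_female=0.474, bw_z_mean=-0.56, p_south_asian=0.519,
                maternal_bmi_mean=25.9, maternal_bmi_sd=5.6,
                p_smoked=0.133, p_gdm=0.074, p_preterm=0.046,
                education_probs=(0.186, 0.303, 0.168, 0.285, 0.058)),
    "eq2": dict(p_female=0.486, bw_z_mean=-0.54, p_south_asian=0.572,
                maternal_bmi_mean=26.0, maternal_bmi_sd=5.6,
                p_smoked=0.132, p_gdm=0.074, p_preterm=0.049,
                education_probs=(0.216, 0.309, 0.153, 0.266, 0.056)),
    "eq3": dict(p_female=0.497, bw_z_mean=-0.58, p_south_asian=0.547,
                maternal_bmi_mean=25.8, maternal_bmi_sd=5.5,
                p_smoked=0.133, p_gdm=0.079, p_preterm=0.045,
                education_probs=(0.194, 0.304, 0.170, 0.267, 0.065)),
}


def bib_preset(equation_id: str = "eq3", n: int = 100_000, seed: int = 0,
               variant: str = "base", **overrides) -> SimulationConfig:
    """Development-cohort-like config for one equation window."""
    if equation_id not in _BIB:
        raise DomainError(f"unknown equation id {equation_id!r}")
    kw = dict(_BIB[equation_id])
    kw.update(overrides)
    return SimulationConfig(
        n=n, seed=seed, equation=get_equation(equation_id, variant), **kw)


def external_preset(equation_id: str = "eq3", n: int = 100_000, seed: int = 0,
                    **overrides) -> SimulationConfig:
    """External-validation-like config: almost entirely White, leaner mothers."""
    kw = dict(
        p_female=0.458, bw_z_mean=-0.055, bw_z_sd=1.04,
        gain_z_sd=0.94, maternal_bmi_mean=23.4, maternal_bmi_sd=4.0,
        p_south_asian=0.017, p_smoked=0.168, p_gdm=0.002, p_preterm=0.040,
        education_probs=(0.105, 0.367, 0.272, 0.150, 0.106))
    kw.update(overrides)
    return SimulationConfig(n=n, seed=seed, equation=get_equation(equation_id, "base"), **kw)


PRESETS = {
    "bib-eq1": lambda n, seed: bib_preset("eq1", n, seed),
    "bib-eq2": lambda n, seed: bib_preset("eq2", n, seed),
    "bib-eq3": lambda n, seed: bib_preset("eq3", n, seed),
    "alspac": lambda n, seed: external_preset("eq3", n, seed),
}
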