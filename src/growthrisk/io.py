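"""Cohort CSV round-tripping and model-configuration files.

A model configuration bundles everything the scoring engine needs —
equation coefficients and thresholds, the conditioning-regression
constants, the outcome rule — so updated equations ship as config rather
than code.  JSON is the native format; YAML is accepted on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .conditional import ConditionalModel, OutcomeRule
from .develop import CohortRecord, cohort_to_frame, frame_to_records
from .equations import EquationSpec, published_equations
from .errors import CohortFormatError, ConfigError

COHORT_COLUMNS = [
    "subject_id", "sex", "ethnicity", "bw_z", "gain_z", "bmi_z_2y",
    "maternal_bmi", "education", "smoked", "gdm", "preterm", "outcome",
]

SCHEMA_VERSION = 1


def read_cohort(path) -> list[CohortRecord]:
    """Read a cohort CSV; row-addressed errors on unknown columns or bad values."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if df.empty and list(df.columns) == []:
        raise CohortFormatError(f"{path}: empty file without header")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise CohortFormatError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")
    return frame_to_records(df)


def write_cohort(records: Iterable[CohortRecord] | pd.DataFrame, path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.12g")


@dataclass
class ModelConfig:
    """Scoring configuration: equations, conditioning constants, outcome rule."""

    equations: Sequence[EquationSpec]
    conditional_model: ConditionalModel
    outcome_rule: OutcomeRule = field(default_factory=OutcomeRule)
    reference_path: str | None = None
    schema_version: int = SCHEMA_VERSION

    def get_equation(self, equation_id: str, variant: str = "base") -> EquationSpec:
        for spec in self.equations:
            if spec.id == equation_id and spec.variant == variant:
                return spec
        raise ConfigError(f"config has no equation {equation_id!r} variant {variant!r}")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "equations": [e.to_dict() for e in self.equations],
            "conditional_model": self.conditional_model.to_dict(),
            "outcome_rule": self.outcome_rule.to_dict(),
            "reference_path": self.reference_path,
        }


def default_model_config(reference_path: str | None = None) -> ModelConfig:
    """The shipped configuration: the six published equations.

    The conditioning regression the published tool used is not public; the
    default assumes on-reference tracking with birth-to-assessment weight-z
    correlation 0.65 (intercept 0, slope 0.65, residual SD sqrt(1-0.65^2)),
    a mid-range value for infant weight tracking.  Replace it with a model
    fitted to local data (``growthrisk develop`` writes one) when available.
    """
    r = 0.65
    return ModelConfig(
        equations=published_equations(),
        conditional_model=ConditionalModel(
            intercept=0.0, slope=r, residual_sd=float((1 - r**2) ** 0.5),
            n_fit=1000, baseline_age_days=0, followup_age_days=274),
        reference_path=reference_path,
    )


def save_model_config(config: ModelConfig, path) -> None:
    path = Path(path)
    payload = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def load_model_config(path) -> ModelConfig:
    """Load a JSON or YAML model configuration, validating the schema."""
    path = Path(path)
    text = path.read_text()
    try:
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse ({exc})") from exc
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    problems = []
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        problems.append(f"schema_version: expected {SCHEMA_VERSION}, got {version!r}")
    for key in ("equations", "conditional_model"):
        if key not in payload:
            problems.append(f"{key}: missing")
    if problems:
        raise ConfigError(f"{path}: schema violations: " + "; ".join(problems))
    equations = []
    for i, d in enumerate(payload["equations"]):
        try:
            equations.append(EquationSpec.from_dict(d))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: equations[{i}]: {exc}") from exc
    try:
        cond = ConditionalModel.from_dict(payload["conditional_model"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: conditional_model: {exc}") from exc
    rule = OutcomeRule.from_dict(payload.get("outcome_rule", OutcomeRule().to_dict()))
    ref_path = payload.get("reference_path")
    if ref_path is not None and not Path(ref_path).exists():
        raise ConfigError(f"{path}: reference_path {ref_path!r} does not resolve")
    return ModelConfig(
        equations=equations, conditional_model=cond, outcome_rule=rule,
        reference_path=ref_path, schema_version=version)
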