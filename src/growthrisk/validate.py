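"""Discrimination, threshold diagnostics, and internal/external validation.

AUC is the Mann-Whitney estimator (ties count one half), identical to
exhaustive counting over all case-control pairs, with a DeLong confidence
interval.  Threshold diagnostics reproduce the published table shape:
sensitivity, specificity, PPV and NPV at score cut-offs placing 10%, 20%
and 30% of the population in the test-positive group, each rate with a
Clopper-Pearson exact interval.

Internal validation follows the bootstrap scheme of the original study:
resample the cohort with replacement, re-run the full stepwise development
on each resample, summarise which terms survive, refit the surviving terms
on the original sample and report that model's AUC on the original sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm, rankdata

from .develop import (
    CANDIDATE_TERMS,
    DevelopmentResult,
    LogisticFit,
    build_design,
    cohort_to_frame,
    develop_equation,
    fit_logistic,
)
from .equations import EquationSpec, predict_probability
from .errors import (
    CohortFormatError,
    ConvergenceError,
    DomainError,
    SeparationError,
)

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class AucResult:
    """Area under the ROC curve with a DeLong 95% confidence interval."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_cases": self.n_cases, "n_controls": self.n_controls}


def auc(scores, labels) -> AucResult:
    """Mann-Whitney AUC of ``scores`` against boolean ``labels`` (True = case).

    Equals the proportion of case-control pairs in which the case scores
    higher, with ties counting one half; the variance is DeLong's, from the
    empirical placement values of cases and controls.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be 1-d arrays of equal length")
    cases, ctrls = scores[labels], scores[~labels]
    m, n = len(cases), len(ctrls)
    if m == 0 or n == 0:
        raise DomainError("both classes must be present to compute an AUC")
    all_ranks = rankdata(np.concatenate([cases, ctrls]))
    case_ranks, ctrl_ranks = all_ranks[:m], all_ranks[m:]
    estimate = (case_ranks.sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong placement values
    v10 = (case_ranks - rankdata(cases)) / n
    v01 = 1.0 - (ctrl_ranks - rankdata(ctrls)) / m
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    return AucResult(
        auc=float(estimate), se=se,
        ci_low=max(0.0, float(estimate - _Z975 * se)),
        ci_high=min(1.0, float(estimate + _Z975 * se)),
        n_cases=m, n_controls=n)


# ---------------------------------------------------------------------------
# threshold diagnostics


@dataclass(frozen=True)
class RateCI:
    """A rate in percent with its exact (Clopper-Pearson) 95% CI."""

    value: float
    ci_low: float
    ci_high: float


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> RateCI:
    if n == 0:
        return RateCI(float("nan"), 0.0, 100.0)
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return RateCI(100.0 * k / n, 100.0 * lo, 100.0 * hi)


@dataclass(frozen=True)
class DiagnosticsRow:
    """Test performance at one population cut-off proportion."""

    proportion: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: RateCI
    specificity: RateCI
    ppv: RateCI
    npv: RateCI

    def to_dict(self) -> dict:
        d = {"proportion": self.proportion, "threshold": self.threshold,
             "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            r: RateCI = getattr(self, name)
            d[name] = r.value
            d[f"{name}_ci_low"] = r.ci_low
            d[f"{name}_ci_high"] = r.ci_high
        return d


def top_fraction_threshold(scores, proportion: float) -> float:
    """Score threshold placing about ``proportion`` of the sample at or above it.

    The threshold is the ceil(q*n)-th largest score; test-positive means
    score >= threshold, so ties at the threshold are admitted (the positive
    fraction can exceed ``proportion`` only through ties).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if not 0.0 < proportion < 1.0:
        raise DomainError(f"proportion must be in (0, 1), got {proportion}")
    k = max(1, math.ceil(proportion * n))
    return float(np.sort(scores)[n - k])


def diagnostics_at_cutoffs(
    scores,
    labels,
    proportions: Sequence[float] = (0.3, 0.2, 0.1),
) -> list[DiagnosticsRow]:
    """Sensitivity/specificity/PPV/NPV at population cut-off proportions."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise DomainError("both classes must be present")
    rows = []
    for q in proportions:
        thr = top_fraction_threshold(scores, q)
        pos = scores >= thr
        tp = int(np.sum(pos & labels))
        fp = int(np.sum(pos & ~labels))
        fn = int(np.sum(~pos & labels))
        tn = int(np.sum(~pos & ~labels))
        rows.append(DiagnosticsRow(
            proportion=q, threshold=thr, tp=tp, fp=fp, fn=fn, tn=tn,
            sensitivity=_clopper_pearson(tp, tp + fn),
            specificity=_clopper_pearson(tn, tn + fp),
            ppv=_clopper_pearson(tp, tp + fp),
            npv=_clopper_pearson(tn, tn + fn)))
    return rows


def diagnostics_frame(rows: Sequence[DiagnosticsRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


# ---------------------------------------------------------------------------
# bootstrap internal validation


@dataclass
class BootstrapResult:
    """Bootstrap internal validation of stepwise equation development."""

    B: int
    n_skipped: int
    coef_samples: pd.DataFrame          # reps x design columns (0 when dropped)
    retention: dict                     # term -> fraction of reps retained
    summary_terms: list[str]
    final_fit: LogisticFit
    auc_on_original: AucResult
    development: DevelopmentResult

    def coefficient_summary(self) -> pd.DataFrame:
        q = self.coef_samples.quantile([0.025, 0.5, 0.975]).T
        q.columns = ["p2.5", "median", "p97.5"]
        q["mean"] = self.coef_samples.mean()
        return q


def bootstrap_validate(
    cohort,
    candidates: Sequence[str] = CANDIDATE_TERMS,
    interactions: Sequence[str] = (),
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    forced: Sequence[str] = ("female",),
    rule: str = "percentile",
) -> BootstrapResult:
    """Resample-with-replacement validation of the stepwise development.

    Each of ``B`` resamples (drawn at the original n) re-runs the full
    backward stepwise selection.  A term enters the summary ("final
    bootstrap") model either when its bootstrap 95% percentile interval
    excludes zero (``rule='percentile'``; coefficients count as zero in
    reps where the term was dropped) or when it is retained in at least
    half of the reps (``rule='retention'``).  Multi-column blocks and
    forced terms always use the retention rule.  The summary model is then
    refit on the original sample and its AUC on the original sample is
    reported.  Resamples where the fit degenerates (separation, constant
    columns) are skipped and counted.
    """
    if B < 1:
        raise DomainError(f"B must be >= 1, got {B}")
    if rule not in ("percentile", "retention"):
        raise DomainError(f"unknown summary rule {rule!r}")
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    n = len(frame)
    rng = np.random.default_rng(seed)

    development = develop_equation(frame, candidates, interactions, alpha, forced)
    all_terms = list(dict.fromkeys(list(candidates) + list(interactions)))
    _, full_colmap = build_design(frame, all_terms)
    all_columns = [c for t in all_terms for c in full_colmap[t]]

    coef_rows, retained_rows = [], []
    n_skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resample = frame.iloc[idx].reset_index(drop=True)
        try:
            res = develop_equation(resample, candidates, interactions, alpha, forced)
        except (SeparationError, ConvergenceError, DomainError):
            n_skipped += 1
            continue
        coefs = {c: 0.0 for c in all_columns}
        retained = {t: False for t in all_terms}
        for t in res.terms:
            retained[t] = True
            for c in res.colmap[t]:
                coefs[c] = float(res.fit.params[c])
        coef_rows.append(coefs)
        retained_rows.append(retained)
    if not coef_rows:
        raise ConvergenceError("every bootstrap resample failed to fit")
    coef_samples = pd.DataFrame(coef_rows, columns=all_columns)
    retention_df = pd.DataFrame(retained_rows, columns=all_terms)
    retention = {t: float(retention_df[t].mean()) for t in all_terms}

    summary_terms = []
    for t in all_terms:
        if t in forced:
            summary_terms.append(t)
            continue
        cols = full_colmap[t]
        if rule == "percentile" and len(cols) == 1:
            lo, hi = coef_samples[cols[0]].quantile([0.025, 0.975])
            keep = not (lo <= 0.0 <= hi)
        else:
            keep = retention[t] >= 0.5
        if keep:
            summary_terms.append(t)

    design, _ = build_design(frame, summary_terms)
    final_fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), design)
    scores = final_fit.predict(design)
    auc_orig = auc(scores, frame["outcome"].to_numpy(dtype=bool))
    return BootstrapResult(
        B=B, n_skipped=n_skipped, coef_samples=coef_samples,
        retention=retention, summary_terms=summary_terms,
        final_fit=final_fit, auc_on_original=auc_orig, development=development)


# ---------------------------------------------------------------------------
# external validation


def score_cohort(spec: EquationSpec, cohort) -> np.ndarray:
    """Probability score for each cohort record under a frozen equation."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    required = ["sex", "bw_z", "gain_z"]
    if spec.variant == "with_maternal_bmi":
        required.append("maternal_bmi")
    missing = [c for c in required + ["outcome"] if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"cohort is missing required column(s) {missing}")
    female = (frame["sex"] == "female").to_numpy(dtype=float)
    mbmi = (frame["maternal_bmi"].to_numpy(dtype=float)
            if spec.variant == "with_maternal_bmi" else None)
    return predict_probability(
        female, frame["bw_z"].to_numpy(dtype=float),
        frame["gain_z"].to_numpy(dtype=float), spec, mbmi)


def external_validate(spec: EquationSpec, cohort) -> AucResult:
    """Apply a frozen equation to an external cohort and report its AUC."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    scores = score_cohort(spec, frame)
    return auc(scores, frame["outcome"].to_numpy(dtype=bool))
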