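"""Cohort records and risk-equation development.

Re-derives risk equations from a cohort table: maximum-likelihood logistic
fitting (Newton-Raphson, via statsmodels behind this surface) and backward
stepwise elimination on Wald p-values, with the interaction screen used in
the original development (sex x birthweight, sex x gain, ethnicity x
birthweight, ethnicity x gain).

Term semantics
--------------
Candidate predictors are *terms*; most map to a single design column, but
the five-level maternal-education factor enters as a block of four dummies
tested jointly (a Wald chi-square on the block) and removed or retained as
a whole.  A main effect is only eligible for removal once no retained
interaction contains it, so interactions are always eliminated first.
Ties in p-values are broken by removing the term declared later, which
makes the procedure deterministic for a given candidate order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import CohortFormatError, ConvergenceError, DomainError, SeparationError

ETHNICITIES = ("white_british", "south_asian")
EDUCATION_LEVELS = ("lt5_gcse", "gcse_5plus", "a_level", "degree", "other")

#: terms available as stepwise candidates, in canonical declaration order
CANDIDATE_TERMS = (
    "female", "bw_z", "gain_z", "maternal_bmi",
    "south_asian", "education", "smoked", "gdm", "preterm",
)

#: the interaction pairs screened during development
STANDARD_INTERACTIONS = (
    "female:bw_z", "female:gain_z", "south_asian:bw_z", "south_asian:gain_z",
)


@dataclass(frozen=True)
class CohortRecord:
    """One infant in a development/validation cohort (complete-case)."""

    subject_id: str
    sex: str
    ethnicity: str
    bw_z: float
    gain_z: float
    bmi_z_2y: float
    maternal_bmi: float
    education: str
    smoked: bool
    gdm: bool
    preterm: bool
    outcome: bool

    def __post_init__(self) -> None:
        from .reference import normalize_sex

        object.__setattr__(self, "sex", normalize_sex(self.sex))
        if self.ethnicity not in ETHNICITIES:
            raise CohortFormatError(
                f"subject {self.subject_id}: unknown ethnicity {self.ethnicity!r}")
        if self.education not in EDUCATION_LEVELS:
            raise CohortFormatError(
                f"subject {self.subject_id}: unknown education {self.education!r}")
        for name in ("bw_z", "gain_z", "bmi_z_2y", "maternal_bmi"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise CohortFormatError(
                    f"subject {self.subject_id}: {name} must be finite, got {v}")


def cohort_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Tabulate records; booleans become 0/1 integers."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "sex": r.sex, "ethnicity": r.ethnicity,
            "bw_z": r.bw_z, "gain_z": r.gain_z, "bmi_z_2y": r.bmi_z_2y,
            "maternal_bmi": r.maternal_bmi, "education": r.education,
            "smoked": int(r.smoked), "gdm": int(r.gdm),
            "preterm": int(r.preterm), "outcome": int(r.outcome),
        })
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[CohortRecord]:
    records = []
    for i, row in df.iterrows():
        try:
            records.append(CohortRecord(
                subject_id=str(row["subject_id"]), sex=str(row["sex"]),
                ethnicity=str(row["ethnicity"]), bw_z=float(row["bw_z"]),
                gain_z=float(row["gain_z"]), bmi_z_2y=float(row["bmi_z_2y"]),
                maternal_bmi=float(row["maternal_bmi"]),
                education=str(row["education"]), smoked=bool(int(row["smoked"])),
                gdm=bool(int(row["gdm"])), preterm=bool(int(row["preterm"])),
                outcome=bool(int(row["outcome"]))))
        except (ValueError, CohortFormatError) as exc:
            raise CohortFormatError(f"row {i}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# design matrix construction


def term_columns(frame: pd.DataFrame, term: str) -> pd.DataFrame:
    """Design columns for one term (an education block yields four dummies)."""
    if ":" in term:
        left, right = term.split(":", 1)
        lcols, rcols = term_columns(frame, left), term_columns(frame, right)
        if lcols.shape[1] != 1 or rcols.shape[1] != 1:
            raise DomainError(f"interaction {term!r} requires single-column terms")
        return pd.DataFrame({term: lcols.iloc[:, 0] * rcols.iloc[:, 0]})
    if term == "female":
        return pd.DataFrame({"female": (frame["sex"] == "female").astype(float)})
    if term == "south_asian":
        return pd.DataFrame(
            {"south_asian": (frame["ethnicity"] == "south_asian").astype(float)})
    if term == "education":
        # dummies against the lowest-attainment reference level
        cols = {}
        for lvl in EDUCATION_LEVELS[1:]:
            cols[f"education[{lvl}]"] = (frame["education"] == lvl).astype(float)
        return pd.DataFrame(cols)
    if term in ("bw_z", "gain_z", "maternal_bmi"):
        return frame[[term]].astype(float)
    if term in ("smoked", "gdm", "preterm"):
        return frame[[term]].astype(float)
    if term in frame.columns:  # ad-hoc numeric covariates (e.g. noise screens)
        return frame[[term]].astype(float)
    raise DomainError(f"unknown candidate term {term!r}")


def build_design(frame: pd.DataFrame, terms: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Concatenate term columns; returns (design, term -> column-name map)."""
    pieces, colmap = [], {}
    for term in terms:
        cols = term_columns(frame, term)
        pieces.append(cols)
        colmap[term] = list(cols.columns)
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=frame.index)
    return design, colmap


# ---------------------------------------------------------------------------
# maximum-likelihood logistic fitting


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, covariance, likelihood."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n: int
    n_iter: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        """Per-coefficient Wald p-values (chi-square, 1 df)."""
        z2 = (self.params / self.bse) ** 2
        return pd.Series(chi2.sf(z2, df=1), index=self.params.index)

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(design, has_constant="add")
        X = X[self.params.index]
        lp = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))

    def wald_block_p(self, columns: Sequence[str]) -> float:
        """Joint Wald test that a block of coefficients is zero."""
        b = self.params[list(columns)].to_numpy()
        V = self.cov.loc[list(columns), list(columns)].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        return float(chi2.sf(stat, df=len(columns)))


def fit_logistic(outcome, design: pd.DataFrame, maxiter: int = 100) -> LogisticFit:
    """Newton-Raphson ML logistic regression of a binary outcome on a design.

    An intercept is added internally; the design must not already contain a
    constant column.  Non-convergence raises :class:`ConvergenceError` and
    complete (or numerically complete) separation raises
    :class:`SeparationError` rather than returning divergent estimates.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    if design.shape[1] and np.any(design.nunique() <= 1):
        const_cols = list(design.columns[design.nunique() <= 1])
        raise DomainError(f"design contains constant column(s) {const_cols}; "
                          "the intercept is added internally")
    X = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) <= X.shape[1]:
        raise DomainError(f"need n > number of terms, got n={len(y)}, k={X.shape[1]}")
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is re-checked below
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"separation or singular information: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"Newton-Raphson did not converge in {maxiter} iterations")
    phat = res.predict()
    eps = 1e-8
    cases, ctrls = y == 1, y == 0
    if np.all(phat[cases] > 1 - eps) and np.all(phat[ctrls] < eps):
        raise SeparationError("complete separation: fitted probabilities saturate")
    if np.any(np.abs(res.params) > 1e3):
        raise SeparationError("quasi-separation: divergent coefficient estimates")
    return LogisticFit(
        params=res.params, cov=pd.DataFrame(
            res.cov_params(), index=res.params.index, columns=res.params.index),
        llf=float(res.llf), n=len(y),
        n_iter=int(res.mle_retvals.get("iterations", 0)))


# ---------------------------------------------------------------------------
# backward stepwise selection


@dataclass
class DevelopmentResult:
    """Outcome of backward stepwise development on one cohort."""

    fit: LogisticFit
    terms: list[str]
    colmap: dict
    term_pvalues: dict
    removed: list[tuple[str, float]]      # (term, p at removal), in order
    dropped_collinear: list[str]
    n: int
    auc: "object" = None                  # AucResult, filled by develop_equation

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    def or_table(self) -> pd.DataFrame:
        return development_ors(self)


def _removable(term: str, current: Sequence[str], forced: Sequence[str]) -> bool:
    if term in forced:
        return False
    if ":" in term:
        return True
    # a main effect is frozen while any retained interaction contains it
    for other in current:
        if ":" in other and term in other.split(":"):
            return False
    return True


def backward_stepwise(
    cohort,
    candidates: Sequence[str] = CANDIDATE_TERMS,
    interactions: Sequence[str] = (),
    alpha: float = 0.05,
    forced: Sequence[str] = (),
) -> DevelopmentResult:
    """Backward elimination on Wald p-values until every retained term has p < alpha.

    ``cohort`` is a DataFrame (see :func:`cohort_to_frame`) or an iterable of
    :class:`CohortRecord`.  ``forced`` terms are never removed regardless of
    significance (the published scoring equations force sex).  Collinear
    terms adding no rank to the design are dropped up front, later-declared
    first.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    for inter in interactions:
        for part in inter.split(":"):
            if part not in candidates:
                raise DomainError(
                    f"interaction {inter!r} requires main effect {part!r} in candidates")
    terms = list(dict.fromkeys(list(candidates) + list(interactions)))

    # collinearity pruning: keep a term only if its columns add rank
    dropped_collinear: list[str] = []
    kept: list[str] = []
    n = len(frame)
    basis = np.ones((n, 1))
    for term in terms:
        cols = term_columns(frame, term).to_numpy()
        trial = np.hstack([basis, cols])
        if np.linalg.matrix_rank(trial) == basis.shape[1] + cols.shape[1]:
            kept.append(term)
            basis = trial
        else:
            dropped_collinear.append(term)
    terms = kept

    y = frame["outcome"].to_numpy(dtype=float)
    removed: list[tuple[str, float]] = []
    while True:
        design, colmap = build_design(frame, terms)
        fit = fit_logistic(y, design)
        pvals = {t: fit.wald_block_p(colmap[t]) for t in terms}
        eligible = [t for t in terms if _removable(t, terms, forced)]
        worst, worst_p = None, -1.0
        for t in eligible:  # ties: later-declared term wins removal
            if pvals[t] >= worst_p:
                worst, worst_p = t, pvals[t]
        if worst is None or worst_p < alpha:
            return DevelopmentResult(
                fit=fit, terms=terms, colmap=colmap, term_pvalues=pvals,
                removed=removed, dropped_collinear=dropped_collinear, n=len(frame))
        terms = [t for t in terms if t != worst]
        removed.append((worst, worst_p))


def development_ors(result: DevelopmentResult, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios exp(b) with Wald confidence intervals exp(b +/- z*SE)."""
    from scipy.stats import norm

    zcrit = float(norm.ppf(0.5 + level / 2.0))
    fit = result.fit
    rows = []
    for col in fit.params.index:
        if col == "const":
            continue
        b, se = float(fit.params[col]), float(fit.bse[col])
        rows.append({
            "term": col, "coef": b, "se": se, "or": np.exp(b),
            "ci_low": np.exp(b - zcrit * se), "ci_high": np.exp(b + zcrit * se),
            "p": float(fit.pvalues[col]),
        })
    return pd.DataFrame(rows)


def develop_equation(
    cohort,
    candidates: Sequence[str] = CANDIDATE_TERMS,
    interactions: Sequence[str] = (),
    alpha: float = 0.05,
    forced: Sequence[str] = ("female",),
) -> DevelopmentResult:
    """Backward stepwise development plus in-sample discrimination (AUC)."""
    from .validate import auc as _auc

    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    result = backward_stepwise(frame, candidates, interactions, alpha, forced)
    design, _ = build_design(frame, result.terms)
    scores = result.fit.predict(design)
    result.auc = _auc(scores, frame["outcome"].to_numpy(dtype=bool))
    return result
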