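"""Logistic ML fitting and backward stepwise development."""

import math

import numpy as np
import pandas as pd
import pytest

import growthrisk as gr
from growthrisk.develop import build_design, fit_logistic, term_columns
from growthrisk.errors import CohortFormatError, DomainError, SeparationError


def _frame(x, y):
    return pd.DataFrame({"x": np.asarray(x, dtype=float)}), np.asarray(y, dtype=float)


class TestFitLogistic:
    def test_balanced_crossed_design_gives_zero(self):
        # x and y fully crossed and balanced: no association
        x = [0, 0, 1, 1] * 10
        y = [0, 1, 0, 1] * 10
        design, yy = _frame(x, y)
        fit = fit_logistic(yy, design)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_closed_form(self):
        # exposed: 10 cases / 90 controls; unexposed: 5 / 95
        x = [1] * 100 + [0] * 100
        y = [1] * 10 + [0] * 90 + [1] * 5 + [0] * 95
        design, yy = _frame(x, y)
        fit = fit_logistic(yy, design)
        assert fit.params["x"] == pytest.approx(math.log(10 * 95 / (90 * 5)), abs=1e-6)
        assert fit.params["x"] == pytest.approx(0.7472, abs=1e-4)

    def test_separation_raises(self):
        x = [0] * 20 + [1] * 20
        design, yy = _frame(x, x)
        with pytest.raises(SeparationError):
            fit_logistic(yy, design)

    def test_constant_column_rejected(self):
        design = pd.DataFrame({"c": np.ones(40)})
        with pytest.raises(DomainError):
            fit_logistic(np.tile([0, 1], 20), design)

    def test_agrees_with_grid_likelihood_maximum(self):
        # brute-force maximization of the 1-covariate log-likelihood over a
        # fine (intercept, slope) grid
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.random(400) < p).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))

        def llf(a, b):
            lp = a + b * x
            return float(np.sum(y * lp - np.log1p(np.exp(lp))))

        grid = np.arange(-2.0, 2.0001, 0.001)
        best_a = max(grid, key=lambda a: llf(a, fit.params["x"]))
        best_b = max(grid, key=lambda b: llf(fit.params["const"], b))
        assert fit.params["const"] == pytest.approx(best_a, abs=1e-3)
        assert fit.params["x"] == pytest.approx(best_b, abs=1e-3)

    def test_deviance_never_increases_with_added_term(self, eq3_cohort):
        # nesting property of maximum likelihood
        frame = eq3_cohort.iloc[:4000]
        y = frame["outcome"].to_numpy(float)
        d1, _ = build_design(frame, ["bw_z"])
        d2, _ = build_design(frame, ["bw_z", "gain_z"])
        assert fit_logistic(y, d2).llf >= fit_logistic(y, d1).llf - 1e-9

    def test_parameter_recovery_at_scale(self, eq3_cohort):
        spec = gr.get_equation("eq3")
        design, _ = build_design(eq3_cohort, ["female", "bw_z", "gain_z"])
        fit = fit_logistic(eq3_cohort["outcome"].to_numpy(float), design)
        truth = {"const": spec.alpha, "female": spec.beta_female,
                 "bw_z": spec.beta_bw_z, "gain_z": spec.beta_gain_z}
        for col, true_val in truth.items():
            assert abs(fit.params[col] - true_val) < 3 * fit.bse[col]


class TestBackwardStepwise:
    def test_noise_dropped_signal_retained(self, eq3_cohort):
        frame = eq3_cohort.copy()
        rng = np.random.default_rng(7)
        frame["noise"] = rng.standard_normal(len(frame))
        res = gr.backward_stepwise(
            frame, candidates=("female", "bw_z", "gain_z", "noise"), forced=("female",))
        assert "noise" not in res.terms
        assert {"bw_z", "gain_z"} <= set(res.terms)

    def test_null_covariates_mostly_removed(self):
        # alpha=0.05 retains a pure-noise covariate in ~5% of runs
        kept = 0
        runs = 30
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            frame = pd.DataFrame({
                "x1": rng.standard_normal(2000),
                "x2": rng.standard_normal(2000),
                "outcome": (rng.random(2000) < 0.1).astype(int),
            })
            res = gr.backward_stepwise(frame, candidates=("x1", "x2"))
            kept += len(res.terms)
        # 60 term-retention trials at a 5% rate: P(>=13 kept) < 1e-5
        assert kept <= 12

    def test_duplicate_covariate_dropped_by_tie_rule(self, eq3_cohort):
        frame = eq3_cohort.iloc[:5000].copy()
        frame["gain_copy"] = frame["gain_z"]
        res = gr.backward_stepwise(
            frame, candidates=("female", "bw_z", "gain_z", "gain_copy"))
        assert res.dropped_collinear == ["gain_copy"]
        assert "gain_z" in res.terms

    def test_interaction_removed_before_main_effect(self, eq3_cohort):
        frame = eq3_cohort.iloc[:8000]
        res = gr.backward_stepwise(
            frame,
            candidates=("female", "bw_z", "gain_z", "south_asian"),
            interactions=("female:bw_z", "south_asian:gain_z"))
        # the data were generated without interactions; both must be gone,
        # and each must have been removed while its main effects were present
        assert all(":" not in t for t in res.terms)
        removed_order = [t for t, _ in res.removed]
        for inter in ("female:bw_z", "south_asian:gain_z"):
            if inter in removed_order:
                for part in inter.split(":"):
                    if part in removed_order:
                        assert removed_order.index(inter) < removed_order.index(part)

    def test_forced_term_survives(self, eq3_cohort):
        frame = eq3_cohort.iloc[:2000]
        res = gr.backward_stepwise(
            frame, candidates=("female", "bw_z", "gain_z"), forced=("female",))
        assert "female" in res.terms

    def test_education_enters_as_block(self, eq3_cohort):
        cols = term_columns(eq3_cohort, "education")
        assert cols.shape[1] == 4


class TestDevelopmentORs:
    def test_null_effect_is_unity(self, eq3_cohort):
        res = gr.develop_equation(
            eq3_cohort.iloc[:5000], candidates=("female", "bw_z", "gain_z"))
        table = gr.development_ors(res)
        assert np.allclose(table["or"], np.exp(table["coef"]))

    def test_ci_arithmetic(self):
        # exp(b +/- 1.959964*se) for b=-1.347, se=0.665 brackets (0.07, 0.96)
        lo = math.exp(-1.347 - 1.959964 * 0.665)
        hi = math.exp(-1.347 + 1.959964 * 0.665)
        assert lo == pytest.approx(0.0706, abs=1e-3)
        assert hi == pytest.approx(0.9570, abs=1e-3)

    def test_recovers_generating_or(self, eq3_cohort):
        res = gr.develop_equation(
            eq3_cohort, candidates=("female", "bw_z", "gain_z"))
        table = gr.development_ors(res).set_index("term")
        # generating birthweight OR is exp(0.824) ~ 2.28
        assert table.loc["bw_z", "ci_low"] < math.exp(0.824) < table.loc["bw_z", "ci_high"]


class TestCohortRecords:
    def test_frame_round_trip(self, eq3_cohort):
        records = gr.frame_to_records(eq3_cohort.iloc[:50])
        back = gr.cohort_to_frame(records)
        pd.testing.assert_frame_equal(
            back, eq3_cohort.iloc[:50].reset_index(drop=True), check_dtype=False)

    def test_bad_value_names_row(self, eq3_cohort):
        frame = eq3_cohort.iloc[:5].copy().reset_index(drop=True)
        frame.loc[3, "sex"] = "banana"
        with pytest.raises(CohortFormatError, match="row 3"):
            gr.frame_to_records(frame)
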