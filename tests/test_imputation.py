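"""Chained-equations engine: design construction, PMM/logistic steps,
support preservation, convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mifs import (ImputationSpec, build_design, estimate_factor_scores,
                  run_chained_equations, rhat)
from mifs.imputation import logistic_step, pmm_step



class TestBuildDesign:
    def test_predictor_pool_count_by_enumeration(self, masked_30x100,
                                                 scores_30x100):
        """p=6, r=2, s=2, 2 scores, lag-1 only: each y target's pool is
        (8-1) other analysis variables + 2 scores + 10 lags + (8-1)
        indicators + 2 auxiliaries = 28."""
        spec = ImputationSpec()
        design, predictors, targets = build_design(masked_30x100,
                                                   scores_30x100, spec)
        assert set(targets) == {f"y{j}" for j in range(1, 7)} | {"x1", "x2"}
        for t in targets:
            assert len(predictors[t]) == 7 + 2 + 10 + 7 + 2
            assert t not in predictors[t]
            assert f"R_{t}" not in predictors[t]

    def test_no_other_manifest_option(self, masked_30x100, scores_30x100):
        spec = ImputationSpec(include_other_manifest=False)
        _, predictors, _ = build_design(masked_30x100, scores_30x100, spec)
        others = {f"y{j}" for j in range(1, 7)}
        assert not (set(predictors["y1"]) & (others - {"y1"}))
        # covariates still predict y, and y still predicts covariates
        assert "x1" in predictors["y1"] and "y1" in predictors["x2"]

    def test_first_occasion_lag_cells_are_missing(self, masked_30x100,
                                                  scores_30x100):
        design, _, _ = build_design(masked_30x100, scores_30x100,
                                    ImputationSpec())
        first = design.groupby("id").head(1)
        assert first["L1_y1"].isna().all()
        assert first["L1_fs1"].isna().all()

    def test_leads_included_on_request(self, masked_30x100, scores_30x100):
        design, predictors, _ = build_design(
            masked_30x100, scores_30x100, ImputationSpec(include_leads=True))
        assert "F1_y3" in design.columns
        assert "F1_y3" in predictors["y1"]
        last = design.groupby("id").tail(1)
        assert last["F1_y3"].isna().all()

    def test_scores_required_when_requested(self, masked_30x100):
        with pytest.raises(ValueError, match="factor scores"):
            build_design(masked_30x100, None, ImputationSpec())


class TestPMM:
    def test_imputed_values_come_from_observed_support(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(size=n)
        miss = rng.random(n) < 0.4
        out = pmm_step(np.where(miss, np.nan, y), x[:, None], miss, 5, rng)
        observed = set(y[~miss])
        assert set(out) <= observed

    def test_exact_match_with_single_donor_noiseless(self):
        """k=1 on noiseless y = 2x, observed at x = 1..10 plus one missing
        case at x = 5: the imputation is the observed y at x = 5, i.e. 10."""
        x = np.append(np.arange(1.0, 11.0), 5.0)
        target = np.append(2 * np.arange(1.0, 11.0), np.nan)
        miss = np.isnan(target)
        rng = np.random.default_rng(1)
        out = pmm_step(target, x[:, None], miss, 1, rng)
        assert out[0] == 10.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_support_preservation_property(self, seed):
        """Imputations never exceed the observed min/max, any seed."""
        rng = np.random.default_rng(seed)
        n = 120
        x = rng.normal(size=(n, 2))
        y = x @ np.array([1.5, -0.5]) + 0.3 * rng.normal(size=n)
        miss = rng.random(n) < 0.4
        if miss.sum() == 0 or (~miss).sum() < 10:
            return
        out = pmm_step(np.where(miss, np.nan, y), x, miss, 5, rng)
        assert out.min() >= y[~miss].min() and out.max() <= y[~miss].max()

    def test_mcar_imputation_nearly_unbiased(self):
        """With strong predictors and MCAR holes, the mean of imputed values
        tracks the mean of the masked true values (200 seeded runs)."""
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            y = 1.0 + 2.0 * x + 0.2 * rng.normal(size=n)
            miss = rng.random(n) < 0.4
            out = pmm_step(np.where(miss, np.nan, y), x[:, None], miss, 5, rng)
            errors.append(out.mean() - y[miss].mean())
        se = np.std(errors, ddof=1) / np.sqrt(len(errors))
        assert abs(np.mean(errors)) < 3 * se + 0.01

    def test_donor_count_reduced_with_warning(self):
        rng = np.random.default_rng(2)
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        x = np.arange(5.0)[:, None]
        miss = np.isnan(y)
        with pytest.warns(UserWarning, match="donors"):
            pmm_step(y, x, miss, 5, rng)


class TestLogistic:
    def test_single_class_imputes_that_class(self):
        rng = np.random.default_rng(0)
        y = np.array([1.0, 1.0, 1.0, np.nan, np.nan])
        with pytest.warns(UserWarning, match="single observed class"):
            out = logistic_step(y, np.zeros((5, 1)), np.isnan(y), rng)
        assert (out == 1.0).all()

    def test_null_coefficients_match_base_rate(self):
        rng = np.random.default_rng(1)
        n = 6000
        y = (rng.random(n) < 0.35).astype(float)
        miss = rng.random(n) < 0.5
        x = rng.normal(size=(n, 1))  # unrelated predictor
        out = logistic_step(np.where(miss, np.nan, y), x, miss, rng)
        rate = out.mean()
        assert abs(rate - 0.35) < 4 * np.sqrt(0.35 * 0.65 / miss.sum())

    def test_strong_predictor_sign_rule(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        y = (x + 0.1 * rng.normal(size=n) > 0).astype(float)
        miss = rng.random(n) < 0.3
        out = logistic_step(np.where(miss, np.nan, y), x[:, None], miss, rng)
        agree = (out == (x[miss] > 0)).mean()
        assert agree >= 0.95


class TestEngine:
    def test_identity_on_complete_panel(self, panel_30x100):
        panel, _ = panel_30x100
        spec = ImputationSpec(m=3, n_iter=2, include_factor_scores=False,
                              seed=0)
        imp = run_chained_equations(panel, None, spec)
        assert imp.m == 3
        assert imp.traces.empty
        for ds in imp.datasets:
            assert ds.frame.equals(panel.frame)

    def test_observed_cells_identical_across_copies(self, masked_30x100,
                                                    scores_30x100):
        spec = ImputationSpec(m=3, n_iter=3, seed=1)
        imp = run_chained_equations(masked_30x100, scores_30x100, spec)
        for c in masked_30x100.y_cols + masked_30x100.x_cols:
            obs = ~masked_30x100.frame[c].isna()
            ref = masked_30x100.frame.loc[obs, c]
            for ds in imp.datasets:
                assert (ds.frame.loc[obs, c] == ref).all()
                assert not ds.frame[c].isna().any()

    def test_binary_covariate_imputed_as_binary(self, masked_30x100,
                                                scores_30x100):
        spec = ImputationSpec(m=2, n_iter=2, seed=2)
        imp = run_chained_equations(masked_30x100, scores_30x100, spec)
        for ds in imp.datasets:
            assert set(np.unique(ds.frame["x1"])) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, masked_30x100, scores_30x100):
        spec = ImputationSpec(m=2, n_iter=2, seed=3)
        a = run_chained_equations(masked_30x100, scores_30x100, spec)
        b = run_chained_equations(masked_30x100, scores_30x100, spec)
        for da, db in zip(a.datasets, b.datasets):
            assert da.frame.equals(db.frame)


class TestRhat:
    @staticmethod
    def _traces_from_values(values):
        """values: dict chain -> (n_iter, n_cells) array."""
        rows = []
        for chain, arr in values.items():
            for it in range(arr.shape[0]):
                v = arr[it]
                rows.append((chain, it + 1, "y1", v.mean(), v.std(ddof=1),
                             len(v)))
        return pd.DataFrame(rows, columns=["chain", "iteration", "variable",
                                           "mean", "sd", "n"])

    def test_identical_chains_report_one(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(10, 20))
        traces = self._traces_from_values({1: arr, 2: arr, 3: arr})
        assert rhat(traces)["y1"] == 1.0

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(1)
        traces = self._traces_from_values({
            1: rng.normal(0, 1, size=(10, 20)),
            2: rng.normal(100, 1, size=(10, 20)),
        })
        assert rhat(traces)["y1"] > 10

    def test_matches_textbook_formula_on_fixture(self):
        """Value-level potential scale reduction recomputed directly from the
        raw draws on a 3-chain x 10-iteration fixture, to 1e-10."""
        rng = np.random.default_rng(2)
        values = {c: rng.normal(c * 0.5, 1 + 0.1 * c, size=(10, 15))
                  for c in (1, 2, 3)}
        traces = self._traces_from_values(values)
        got = rhat(traces)["y1"]
        # direct recomputation: draws = retained (second-half) values
        chains = [values[c][5:].ravel() for c in (1, 2, 3)]
        n = len(chains[0])
        W = np.mean([v.var(ddof=1) for v in chains])
        B = n * np.var([v.mean() for v in chains], ddof=1)
        expect = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert abs(got - max(1.0, expect)) < 1e-10

    def test_needs_two_chains(self):
        traces = self._traces_from_values(
            {1: np.random.default_rng(3).normal(size=(4, 5))})
        with pytest.raises(ValueError, match="2 chains"):
            rhat(traces)
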