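"""Missingness mechanisms, calibration and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from mifs import (MissingnessSpec, apply_composite_dependent,
                  apply_factor_dependent, apply_item_dependent,
                  apply_mar_location, calibrate_phi0, factor_dependent_spec,
                  item_dependent_spec, missingness_summary, mz_rsquared,
                  simulate_panel)
from mifs.panel import PanelData

from conftest import panel_from_arrays


def _uniform_z(rng, n):
    return rng.uniform(-3, 3, size=(n, 2))


@pytest.fixture(scope="module")
def big_panel(low_preset):
    return simulate_panel(low_preset, 60, 50, seed=314)


class TestItemDependent:
    def test_constant_probability_rate(self):
        rng = np.random.default_rng(0)
        n = 3000
        panel = panel_from_arrays(rng.normal(size=(n, 1)), z=_uniform_z(rng, n))
        spec = MissingnessSpec("item_dependent",
                               phi0={"y1": float(logit(0.3))}, phi1=0.0,
                               phi2=0.0, phi3={"y1": 0.0},
                               driver={"y1": "self"})
        masked = apply_item_dependent(panel, spec, seed=1)
        rate = masked.frame["y1"].isna().mean()
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(rate - 0.3) < 3 * se

    def test_calibrated_preset_rates_near_30pct(self, big_panel,
                                                calibrated_fd_spec,
                                                low_preset):
        panel, _ = big_panel
        spec = calibrate_phi0(panel, item_dependent_spec())
        fresh, _ = simulate_panel(low_preset, 60, 50, seed=999)
        masked = apply_item_dependent(fresh, spec, seed=5)
        rates = masked.mask.mean()
        assert (np.abs(rates - 0.30) < 0.03).all()

    def test_items_masked_independently_given_drivers(self, big_panel):
        """Empirical P(y1..y3 all missing at an occasion) matches the mean of
        the per-row products of conditional probabilities (independence given
        the drivers), within Monte Carlo error."""
        from mifs.missingness import _probabilities
        panel, _ = big_panel
        spec = calibrate_phi0(panel, item_dependent_spec())
        masked = apply_item_dependent(panel, spec, seed=2)
        m = masked.frame[["y1", "y2", "y3"]].isna()
        joint = m.all(axis=1).mean()
        prod = np.ones(panel.n_rows)
        for t in ("y1", "y2", "y3"):
            prod *= _probabilities(t, spec, panel, None)
        expect = prod.mean()
        se = np.sqrt(expect * (1 - expect) / panel.n_rows)
        assert abs(joint - expect) < 4 * se

    def test_input_panel_untouched(self, big_panel):
        panel, _ = big_panel
        before = panel.frame.copy()
        spec = calibrate_phi0(panel, item_dependent_spec())
        masked = apply_item_dependent(panel, spec, seed=3)
        assert panel.frame.equals(before)
        # observed cells carry the original values bit-for-bit
        for c in masked.y_cols:
            obs = ~masked.frame[c].isna()
            assert (masked.frame.loc[obs, c] == before.loc[obs, c]).all()


class TestFactorDependent:
    def test_all_or_none_per_indicator_block(self, masked_30x100):
        m = masked_30x100.frame[["y1", "y2", "y3"]].isna().sum(axis=1)
        assert set(m.unique()) <= {0, 3}
        m2 = masked_30x100.frame[["y4", "y5", "y6"]].isna().sum(axis=1)
        assert set(m2.unique()) <= {0, 3}

    def test_rates_near_target(self, masked_30x100):
        rates = masked_30x100.mask.mean()
        assert (np.abs(rates - 0.30) < 0.05).all()

    def test_positive_phi3_masks_high_factor_values(self, panel_30x100,
                                                    masked_30x100):
        panel, latent = panel_30x100
        miss = masked_30x100.frame["y4"].isna().to_numpy()
        eta2 = latent.values[:, 1]
        assert eta2[miss].mean() > eta2[~miss].mean()
        # and negative phi3 for factor 1 masks low values
        miss1 = masked_30x100.frame["y1"].isna().to_numpy()
        eta1 = latent.values[:, 0]
        assert eta1[miss1].mean() < eta1[~miss1].mean()

    def test_zero_phi3_reduces_to_mar(self, big_panel):
        panel, latent = big_panel
        spec = factor_dependent_spec()
        spec.phi3 = {k: 0.0 for k in spec.phi3}
        spec = calibrate_phi0(panel, spec, latent=latent)
        masked = apply_factor_dependent(panel, latent, spec, seed=4)
        miss = masked.frame["y1"].isna().to_numpy()
        eta1 = latent.values[:, 0]
        pooled_sd = eta1.std()
        se = pooled_sd * np.sqrt(1 / miss.sum() + 1 / (~miss).sum())
        assert abs(eta1[miss].mean() - eta1[~miss].mean()) < 3 * se


class TestMarLocation:
    def test_simultaneous_blocks_and_indicators(self, big_panel):
        panel, _ = big_panel
        masked, ind = apply_mar_location(panel, "simultaneous", 0.25, seed=6)
        m = masked.frame[["y1", "y2", "y3"]].isna().sum(axis=1)
        assert set(m.unique()) <= {0, 3}
        assert list(ind.columns) == ["R_eta1", "R_eta2"]
        assert (ind["R_eta1"].to_numpy() ==
                masked.frame["y1"].isna().to_numpy()).all()

    def test_rate_zero_leaves_panel_unchanged(self, big_panel):
        panel, _ = big_panel
        masked, _ = apply_mar_location(panel, "scattered", 0.0, seed=7)
        assert masked.frame.equals(panel.frame)

    def test_indicators_independent_of_data(self, big_panel):
        panel, _ = big_panel
        _, ind = apply_mar_location(panel, "scattered", 0.3, seed=8)
        n = panel.n_rows
        for c in ["y1", "y4"]:
            r = np.corrcoef(ind[f"R_{c}"], panel.frame[c])[0, 1]
            assert abs(r) < 3 / np.sqrt(n)


class TestCompositeDependent:
    def test_composite_is_row_mean(self):
        rng = np.random.default_rng(1)
        y = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 6.0], [-1.0, 1.0, 0.0]])
        panel = panel_from_arrays(y, z=_uniform_z(rng, 3))
        from mifs.missingness import _driver_values
        spec = MissingnessSpec("composite_dependent",
                               phi3={"y1": 0.5}, driver={"y1": "composite"})
        comp = _driver_values("y1", spec, panel, None)
        assert np.allclose(comp, [2.0, 2.0, 0.0])
        # all-equal columns: composite equals any column
        panel2 = panel_from_arrays(np.tile([[1.5]], (3, 3)),
                                   z=_uniform_z(rng, 3))
        assert np.allclose(_driver_values("y1", spec, panel2, None), 1.5)

    def test_calibrated_rate(self):
        rng = np.random.default_rng(2)
        n = 4000
        y = rng.normal(size=(n, 3)) + rng.normal(size=(n, 1))
        panel = panel_from_arrays(y, z=_uniform_z(rng, n))
        spec = MissingnessSpec(
            "composite_dependent",
            phi3={f"y{j}": 0.6 for j in (1, 2, 3)},
            driver={f"y{j}": "composite" for j in (1, 2, 3)})
        spec = calibrate_phi0(panel, spec, target_rate=0.3)
        masked = apply_composite_dependent(panel, spec, seed=9)
        assert abs(masked.mask.mean().mean() - 0.30) < 0.03

    def test_wrong_column_count_rejected(self, big_panel):
        panel, _ = big_panel  # six manifest columns
        spec = MissingnessSpec("composite_dependent", phi3={"y1": 0.5},
                               driver={"y1": "composite"})
        with pytest.raises(ValueError, match="3 manifest"):
            apply_composite_dependent(panel, spec, seed=0)


class TestCalibration:
    def test_zero_slopes_analytic(self):
        rng = np.random.default_rng(3)
        panel = panel_from_arrays(rng.normal(size=(500, 1)),
                                  z=_uniform_z(rng, 500))
        spec = MissingnessSpec("item_dependent", phi1=0.0, phi2=0.0,
                               phi3={"y1": 0.0}, driver={"y1": "self"})
        out = calibrate_phi0(panel, spec, target_rate=0.3)
        assert np.isclose(out.phi0["y1"], logit(0.3), atol=1e-5)

    def test_sign_symmetry_of_driver(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(4000, 1))
        y = np.concatenate([y, -y])  # exactly symmetric driver
        z = np.concatenate([_uniform_z(rng, 4000)] * 2)
        panel = panel_from_arrays(y, ids=np.ones(8000, dtype=int), z=z)
        pos = MissingnessSpec("item_dependent", phi1=0.6, phi2=0.6,
                              phi3={"y1": 0.6}, driver={"y1": "self"})
        neg = MissingnessSpec("item_dependent", phi1=0.6, phi2=0.6,
                              phi3={"y1": -0.6}, driver={"y1": "self"})
        c1 = calibrate_phi0(panel, pos, target_rate=0.3)
        c2 = calibrate_phi0(panel, neg, target_rate=0.3)
        assert np.isclose(c1.phi0["y1"], c2.phi0["y1"], atol=1e-6)

    def test_out_of_sample_rate_within_tolerance(self, calibrated_fd_spec,
                                                 low_preset):
        fresh, latent = simulate_panel(low_preset, 100, 100, seed=5150)
        masked = apply_factor_dependent(fresh, latent, calibrated_fd_spec,
                                        seed=10)
        rates = masked.mask.mean()
        assert (np.abs(rates - 0.30) < 0.02).all()

    def test_monotone_in_phi0(self):
        rng = np.random.default_rng(5)
        panel = panel_from_arrays(rng.normal(size=(2000, 1)),
                                  z=_uniform_z(rng, 2000))
        spec = MissingnessSpec("item_dependent", phi3={"y1": 0.5},
                               driver={"y1": "self"})
        rates = []
        for phi0 in (-2.0, -1.0, 0.0, 1.0):
            spec.phi0 = {"y1": phi0}
            masked = apply_item_dependent(panel, spec, seed=11)
            rates.append(masked.frame["y1"].isna().mean())
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_unreachable_rate_reports_range(self):
        # a huge negative driver effect caps the achievable rate near zero
        rng = np.random.default_rng(6)
        y = rng.normal(5.0, 0.1, size=(100, 1))
        panel = panel_from_arrays(y, z=_uniform_z(rng, 100))
        spec = MissingnessSpec("item_dependent", phi3={"y1": -50.0},
                               driver={"y1": "self"})
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_phi0(panel, spec, target_rate=0.9)


class TestMzRsquared:
    def test_null_predictor_zero(self):
        with pytest.warns(UserWarning):
            out = mz_rsquared({"a": np.zeros(100),
                               "b": np.random.default_rng(0).normal(size=100)})
        assert out.loc["a", "share"] == 0.0 and out.loc["a", "single"] == 0.0

    def test_uniform_driver_closed_form(self):
        """phi = 0.6, x ~ U(-3,3): Var(phi x) = 0.36 * 3 = 1.08 and the
        single-predictor value is 1.08 / (1.08 + pi^2/3) ~ 0.247."""
        x = np.random.default_rng(1).uniform(-3, 3, size=400_000)
        out = mz_rsquared({"t": 0.6 * x})
        expect = 1.08 / (1.08 + np.pi ** 2 / 3)
        assert abs(out.loc["t", "single"] - expect) < 0.005
        assert abs(expect - 0.2467) < 1e-3

    def test_monotone_in_coefficient(self):
        x = np.random.default_rng(2).normal(size=10_000)
        lo = mz_rsquared({"t": 0.6 * x}).loc["t", "single"]
        hi = mz_rsquared({"t": 1.2 * x}).loc["t", "single"]
        assert hi > lo


class TestSummary:
    def test_complete_panel_all_zero(self, big_panel):
        panel, _ = big_panel
        rep = missingness_summary(panel)
        assert (rep.rates == 0).all()

    def test_fully_masked_column(self, big_panel):
        panel, _ = big_panel
        f = panel.frame.copy()
        f["y1"] = np.nan
        rep = missingness_summary(PanelData(f, validate=False))
        assert rep.rates["y1"] == 1.0

    def test_rates_match_independent_recount(self, masked_30x100):
        rep = missingness_summary(masked_30x100)
        for c in masked_30x100.y_cols + masked_30x100.x_cols:
            assert rep.rates[c] == masked_30x100.frame[c].isna().to_numpy().mean()
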