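"""Shared fixtures: model presets, small simulated panels, masked panels.

Everything is generated programmatically with fixed seeds; expensive objects
are session-scoped.
"""

import numpy as np
import pandas as pd
import pytest

from mifs import (
    ImputationSpec, ModelParams, FreeParam, PanelData,
    factor_dependent_spec, calibrate_phi0, apply_factor_dependent,
    pfa_preset, pfa_template, simulate_panel,
)


@pytest.fixture(scope="session")
def low_preset():
    return pfa_preset("low")


@pytest.fixture(scope="session")
def low_template():
    return pfa_template("low", covariates=True)


@pytest.fixture(scope="session")
def low_template_nocov():
    return pfa_template("low", covariates=False)


@pytest.fixture(scope="session")
def panel_30x100(low_preset):
    """One full-size complete panel plus true latent paths."""
    return simulate_panel(low_preset, 30, 100, seed=1)


@pytest.fixture(scope="session")
def small_panel(low_preset):
    """A small complete panel (10 persons x 40 times) for fast fits."""
    return simulate_panel(low_preset, 10, 40, seed=42)


@pytest.fixture(scope="session")
def calibrated_fd_spec(low_preset):
    """Factor-dependent missingness spec calibrated on a reference panel."""
    ref_panel, ref_latent = simulate_panel(low_preset, 100, 100, seed=90210)
    return calibrate_phi0(ref_panel, factor_dependent_spec(), latent=ref_latent)


@pytest.fixture(scope="session")
def masked_30x100(panel_30x100, calibrated_fd_spec):
    panel, latent = panel_30x100
    return apply_factor_dependent(panel, latent, calibrated_fd_spec, seed=77)


@pytest.fixture(scope="session")
def scores_30x100(masked_30x100, low_template_nocov):
    from mifs import estimate_factor_scores
    scores, _ = estimate_factor_scores(masked_30x100, low_template_nocov,
                                       gtol=1e-5)
    return scores


def scalar_ar1(phi=0.5, q_var=2.0, eps_var=1.0, lam=1.0, tau=0.0,
               init_mean=0.0, init_var=None, free=()):
    """Scalar AR(1)-plus-noise model helper used by several test modules."""
    if init_var is None:
        init_var = q_var / (1.0 - phi ** 2)
    return ModelParams(
        transition=[[phi]],
        process_noise_cov=[[q_var]],
        loadings=[[lam]],
        meas_noise_cov=[[eps_var]],
        meas_intercept=[tau],
        init_mean=[init_mean],
        init_cov=[[init_var]],
        free_map=list(free),
    )


def panel_from_arrays(y, ids=None, x=None, z=None):
    """Build a PanelData from a (rows, p) array (single or multi person)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[0]
    data = {"id": np.ones(n, dtype=int) if ids is None else ids}
    counts = pd.Series(data["id"]).groupby(data["id"], sort=False).cumcount()
    data["time"] = counts.to_numpy() + 1
    for j in range(y.shape[1]):
        data[f"y{j + 1}"] = y[:, j]
    if x is not None:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        for j in range(x.shape[1]):
            data[f"x{j + 1}"] = x[:, j]
    if z is not None:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        for j in range(z.shape[1]):
            data[f"z{j + 1}"] = z[:, j]
    return PanelData(pd.DataFrame(data))
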