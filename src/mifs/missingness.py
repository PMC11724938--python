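"""NMAR / MAR missingness generators for complete panels.

Two nonignorable mechanisms are provided.  *Item-dependent* missingness draws
an independent Bernoulli per cell with

    logit P(R_v = 1) = phi0_v + phi1 z1 + phi2 z2 + phi3_v * v

where v is the (complete) value of the target variable itself.
*Factor-dependent* missingness replaces the self-driver for the indicators of
factor k by the true latent state eta_k and makes ONE draw per (person,
occasion, factor), so all indicators of a factor go missing together;
covariates are still masked by the item-dependent rule.  Intercepts phi0 are
calibrated per target so the expected missingness rate hits a target
(30% in the study conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .panel import LatentPaths, PanelData

__all__ = [
    "MissingnessSpec", "MissingnessReport",
    "item_dependent_spec", "factor_dependent_spec",
    "apply_item_dependent", "apply_factor_dependent", "apply_mar_location",
    "apply_composite_dependent", "calibrate_phi0", "mz_rsquared",
    "missingness_summary",
]

_MECHANISMS = ("item_dependent", "factor_dependent", "mar_scattered",
               "mar_simultaneous", "composite_dependent")


@dataclass
class MissingnessSpec:
    """Logistic missing-data generation model.

    ``phi0``/``phi3``/``driver`` are per-target maps; ``driver`` values are
    'self', a factor name ('eta1', 'eta2', ...), or 'composite'.
    """

    mechanism: str
    phi0: dict[str, float] = field(default_factory=dict)
    phi1: float = 0.6
    phi2: float = 0.6
    phi3: dict[str, float] = field(default_factory=dict)
    driver: dict[str, str] = field(default_factory=dict)
    target_rate: float = 0.30

    def __post_init__(self):
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target_rate must be in (0, 1)")
        if self.mechanism in ("item_dependent", "factor_dependent"):
            missing = [t for t in self.phi3 if t not in self.driver]
            if missing:
                raise ValueError(f"targets without a driver: {missing}")

    @property
    def targets(self) -> list[str]:
        return list(self.phi3)


def item_dependent_spec(p: int = 6, r: int = 2,
                        target_rate: float = 0.30) -> MissingnessSpec:
    """Study preset: phi3 = -0.6 for y1-y3, +0.6 for y4-y6, -0.8 for covariates."""
    phi3 = {}
    driver = {}
    for j in range(p):
        name = f"y{j + 1}"
        phi3[name] = -0.6 if j < p // 2 else 0.6
        driver[name] = "self"
    for j in range(r):
        name = f"x{j + 1}"
        phi3[name] = -0.8
        driver[name] = "self"
    return MissingnessSpec("item_dependent", phi3=phi3, driver=driver,
                           target_rate=target_rate)


def factor_dependent_spec(p: int = 6, r: int = 2,
                          target_rate: float = 0.30) -> MissingnessSpec:
    """Study preset: indicators driven by their factor (phi3 = -0.6 for eta1,
    +0.6 for eta2); covariates masked by the item-dependent rule."""
    phi3 = {}
    driver = {}
    for j in range(p):
        name = f"y{j + 1}"
        phi3[name] = -0.6 if j < p // 2 else 0.6
        driver[name] = "eta1" if j < p // 2 else "eta2"
    for j in range(r):
        name = f"x{j + 1}"
        phi3[name] = -0.8
        driver[name] = "self"
    return MissingnessSpec("factor_dependent", phi3=phi3, driver=driver,
                           target_rate=target_rate)


# ---------------------------------------------------------------------------
# driver extraction and probabilities
# ---------------------------------------------------------------------------

def _driver_values(target: str, spec: MissingnessSpec, panel: PanelData,
                   latent: LatentPaths | None):
    d = spec.driver.get(target, "self")
    if d == "self":
        vals = panel.frame[target].to_numpy()
        if np.isnan(vals).any():
            raise ValueError(f"target {target} must be complete before masking")
        return vals
    if d == "composite":
        vals = panel.frame[panel.y_cols].to_numpy()
        if np.isnan(vals).any():
            raise ValueError("manifest variables must be complete before masking")
        return vals.mean(axis=1)
    if d.startswith("eta"):
        if latent is None:
            raise ValueError(f"target {target} is driven by {d} but no latent "
                             "paths were supplied")
        k = int(d[3:])
        if not 1 <= k <= latent.q:
            raise ValueError(f"driver {d!r} references unknown factor")
        return latent.values[:, k - 1]
    raise ValueError(f"unknown driver {d!r} for target {target}")


def _probabilities(target: str, spec: MissingnessSpec, panel: PanelData,
                   latent: LatentPaths | None):
    if panel.s < 2:
        raise ValueError("panel must carry the auxiliary variables z1, z2")
    z = panel.z
    lin = (spec.phi0.get(target, 0.0) + spec.phi1 * z[:, 0] + spec.phi2 * z[:, 1]
           + spec.phi3[target] * _driver_values(target, spec, panel, latent))
    return expit(lin)


def _mask_cells(panel: PanelData, masks: dict[str, np.ndarray]) -> PanelData:
    out = panel.copy()
    for col, m in masks.items():
        out.frame.loc[m, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# mechanisms
# ---------------------------------------------------------------------------

def apply_item_dependent(panel: PanelData, spec: MissingnessSpec,
                         seed: int) -> PanelData:
    """Independent Bernoulli per cell, probability driven by the cell's value.

    The input panel is untouched; a masked copy is returned.  Draws use one
    stream ordered by (person, time, target) for reproducibility.
    """
    rng = np.random.default_rng(seed)
    targets = spec.targets
    u = rng.random((panel.n_rows, len(targets)))
    masks = {}
    for j, t in enumerate(targets):
        pr = _probabilities(t, spec, panel, None)
        masks[t] = u[:, j] < pr
    return _mask_cells(panel, masks)


def apply_factor_dependent(panel: PanelData, latent: LatentPaths,
                           spec: MissingnessSpec, seed: int) -> PanelData:
    """One Bernoulli draw per (person, occasion, factor): all indicators of a
    factor are missing together.  Covariates are masked by the item rule."""
    if latent.kind != "true":
        raise ValueError("factor-dependent masking needs the true latent paths")
    if len(latent.states) != panel.n_rows:
        raise ValueError("latent paths not aligned with panel")
    rng = np.random.default_rng(seed)
    y_targets = [t for t in spec.targets if t.startswith("y")]
    x_targets = [t for t in spec.targets if t.startswith("x")]
    factors = []  # preserve first-appearance order of factor drivers
    for t in y_targets:
        d = spec.driver[t]
        if not d.startswith("eta"):
            raise ValueError(f"indicator {t} must be driven by a factor, got {d!r}")
        if d not in factors:
            factors.append(d)
    u = rng.random((panel.n_rows, len(factors) + len(x_targets)))
    masks = {}
    for t in y_targets:
        j = factors.index(spec.driver[t])
        pr = _probabilities(t, spec, panel, latent)
        masks[t] = u[:, j] < pr
    for j, t in enumerate(x_targets):
        pr = _probabilities(t, spec, panel, None)
        masks[t] = u[:, len(factors) + j] < pr
    return _mask_cells(panel, masks)


def apply_mar_location(panel: PanelData, mode: str, rate: float, seed: int):
    """MAR masking at random locations, independent of all data.

    mode='scattered' draws one indicator per manifest variable;
    mode='simultaneous' draws one indicator per factor block (first half /
    second half of the indicators).  Returns (masked panel, DataFrame of the
    fully observed location-indicator columns, named R_<target> or R_eta<k>).
    """
    if mode not in ("scattered", "simultaneous"):
        raise ValueError("mode must be 'scattered' or 'simultaneous'")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    masks = {}
    indicators = {}
    if mode == "scattered":
        for c in panel.y_cols:
            m = rng.random(panel.n_rows) < rate
            masks[c] = m
            indicators[f"R_{c}"] = m.astype(float)
    else:
        half = panel.p // 2
        blocks = {"eta1": panel.y_cols[:half], "eta2": panel.y_cols[half:]}
        for name, cols in blocks.items():
            m = rng.random(panel.n_rows) < rate
            indicators[f"R_{name}"] = m.astype(float)
            for c in cols:
                masks[c] = m
    ind = pd.DataFrame(indicators, index=panel.frame.index)
    return _mask_cells(panel, masks), ind


def apply_composite_dependent(trivar_panel: PanelData, spec: MissingnessSpec,
                              seed: int) -> PanelData:
    """Missingness driven by the per-occasion composite (row mean) of the
    manifest variables; used for the misspecified factor-structure scenario."""
    if trivar_panel.p != 3:
        raise ValueError(f"composite mechanism expects 3 manifest columns, "
                         f"got {trivar_panel.p}")
    rng = np.random.default_rng(seed)
    targets = [t for t in spec.targets if t.startswith("y")]
    u = rng.random((trivar_panel.n_rows, len(targets)))
    masks = {}
    for j, t in enumerate(targets):
        pr = _probabilities(t, spec, trivar_panel, None)
        masks[t] = u[:, j] < pr
    return _mask_cells(trivar_panel, masks)


# ---------------------------------------------------------------------------
# calibration and diagnostics
# ---------------------------------------------------------------------------

def calibrate_phi0(panel: PanelData, spec: MissingnessSpec,
                   target_rate: float | None = None,
                   latent: LatentPaths | None = None,
                   tol: float = 1e-3) -> MissingnessSpec:
    """Solve phi0 per target so the mean missingness probability over the
    reference panel equals the target rate (monotone root-finding).

    The reference panel should be a large dedicated simulation so phi0 does
    not adapt to one replication's noise.
    """
    rate = spec.target_rate if target_rate is None else target_rate
    if not 0.0 < rate < 1.0:
        raise ValueError("target rate must be in (0, 1)")
    if panel.s < 2:
        raise ValueError("reference panel must carry z1, z2")
    z = panel.z
    phi0 = {}
    for t in spec.targets:
        v = _driver_values(t, spec, panel, latent)
        base = spec.phi1 * z[:, 0] + spec.phi2 * z[:, 1] + spec.phi3[t] * v

        def gap(c):
            return expit(c + base).mean() - rate

        lo, hi = -30.0, 30.0
        glo, ghi = gap(lo), gap(hi)
        if glo > 0 or ghi < 0:
            raise ValueError(
                f"target rate {rate} unreachable for {t}: achievable range "
                f"({glo + rate:.4f}, {ghi + rate:.4f})")
        phi0[t] = float(optimize.brentq(gap, lo, hi, xtol=1e-6))
        if abs(gap(phi0[t])) > tol:
            raise RuntimeError(f"calibration for {t} did not reach tolerance")
    return replace(spec, phi0=phi0, target_rate=rate)


def mz_rsquared(linear_predictor_terms: dict[str, np.ndarray]) -> pd.DataFrame:
    """McKelvey-Zavoina pseudo-R² contributions of logistic predictor terms.

    For each named term (an array of phi*x contributions to the linear
    predictor) two variants are reported: ``share`` = Var(term) /
    (Var(full predictor) + pi^2/3), and ``single`` = Var(term) /
    (Var(term) + pi^2/3), i.e. the term as sole predictor.
    """
    import warnings

    terms = {k: np.asarray(v, dtype=float) for k, v in linear_predictor_terms.items()}
    total = np.sum(list(terms.values()), axis=0)
    vtot = total.var()
    resid = np.pi ** 2 / 3.0
    rows = {}
    for name, v in terms.items():
        vv = v.var()
        if vv == 0.0:
            warnings.warn(f"term {name!r} has zero variance; R^2 = 0")
        rows[name] = {
            "share": vv / (vtot + resid),
            "single": vv / (vv + resid),
        }
    return pd.DataFrame(rows).T


@dataclass
class MissingnessReport:
    rates: pd.Series                 # per-variable empirical missing proportion
    simultaneous: pd.Series          # count of occasions by number of missing y
    mechanism: str | None = None


def missingness_summary(panel: PanelData,
                        mechanism: str | None = None) -> MissingnessReport:
    mask = panel.mask
    rates = mask.mean()
    n_missing_y = mask[panel.y_cols].sum(axis=1)
    simultaneous = n_missing_y.value_counts().sort_index()
    return MissingnessReport(rates=rates, simultaneous=simultaneous,
                             mechanism=mechanism)
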