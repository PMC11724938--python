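"""Monte Carlo evaluation harness.

Runs H replications of {simulate -> mask -> handle -> fit -> pool} per
condition (autocorrelation level x missingness mechanism) and computes the
performance measures: bias, relative bias, mean estimated SE, Monte Carlo SE,
RMSE, dSEfull (mean SE minus the complete-data benchmark SE), power (CI
excludes 0) and coverage (CI contains the truth), the last two in percent.
All methods within a replication consume the same masked panel (paired
design); the missingness intercepts are calibrated once per condition on a
large dedicated reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputation import ImputationSpec
from .missingness import (MissingnessSpec, apply_factor_dependent,
                          apply_item_dependent, calibrate_phi0,
                          factor_dependent_spec, item_dependent_spec)
from .model import fit_ml, simulate_panel
from .panel import PanelData
from .params import ModelParams, pfa_preset, pfa_template, pfa_true_values
from .pipelines import run_ld, run_mi_fs, run_mi_mv, run_pmi_mv, tidy_single

__all__ = ["StudyConfig", "PerfSummary", "run_replication",
           "performance_measures", "run_condition", "typeI_rates",
           "PARAMETER_GROUPS"]

#: reporting groups used for aggregate summaries
PARAMETER_GROUPS = {
    "d_ar": ["a1", "a2"],
    "d_cr": ["b1", "b2"],
    "d_x1": ["c1", "c2"],
    "d_x2": ["d1", "d2"],
    "d_var": ["szeta_11", "szeta_22"],
    "d_cov": ["szeta_21"],
    "m_int": [f"mu_{j}" for j in range(1, 7)],
    "m_var": [f"seps_{j}" for j in range(1, 7)],
    "m_load": [f"lambda_{j}" for j in range(1, 5)],
}

_METHODS = ("LD", "MI-MV", "PMI-MV", "MI-FS")


@dataclass
class StudyConfig:
    """One cell of the simulation design plus execution settings."""

    autocorr: str = "low"                      # 'low' (0.5) or 'high' (0.7)
    mechanism: str = "factor_dependent"        # or 'item_dependent'
    methods: tuple[str, ...] = _METHODS
    H: int = 50
    n_persons: int = 30
    n_times: int = 100
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    master_seed: int = 1000
    null_effects: bool = False
    fit_complete_benchmark: bool = True
    calibration_size: tuple[int, int] = (200, 200)
    calibration_seed: int = 86420
    fit_options: dict = field(default_factory=dict)
    #: per-method overrides merged over fit_options, e.g. {"PMI-MV":
    #: {"compute_se": False}} when only point estimates are summarised
    method_fit_options: dict = field(default_factory=dict)
    #: use the LD estimates of the same masked panel as the optimizer start
    #: for the per-imputation fits (initialisation only; cuts runtime)
    warm_start_from_ld: bool = True

    def __post_init__(self):
        if self.H < 1:
            raise ValueError("H must be >= 1")
        if self.autocorr not in ("low", "high"):
            raise ValueError("autocorr must be 'low' or 'high'")
        if self.mechanism not in ("item_dependent", "factor_dependent"):
            raise ValueError("mechanism must be item_ or factor_dependent")
        bad = [m for m in self.methods if m not in _METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}")

    # generating model / templates -------------------------------------
    def generating_params(self) -> ModelParams:
        return pfa_preset(self.autocorr, self.null_effects)

    def analysis_template(self) -> ModelParams:
        return pfa_template(self.autocorr, covariates=True,
                            null_effects=self.null_effects)

    def scoring_template(self) -> ModelParams:
        return pfa_template(self.autocorr, covariates=False,
                            null_effects=self.null_effects)

    def truth(self) -> dict[str, float]:
        return pfa_true_values(self.autocorr, self.null_effects)

    def replication_seed(self, h: int) -> int:
        return self.master_seed + h


def calibrate_condition(config: StudyConfig) -> MissingnessSpec:
    """Calibrate phi0 on a dedicated large reference panel (fixed seed)."""
    gen = config.generating_params()
    n, T = config.calibration_size
    panel, latent = simulate_panel(gen, n, T, seed=config.calibration_seed)
    if config.mechanism == "item_dependent":
        spec = item_dependent_spec(p=gen.p, r=gen.r)
        return calibrate_phi0(panel, spec)
    spec = factor_dependent_spec(p=gen.p, r=gen.r)
    return calibrate_phi0(panel, spec, latent=latent)


def _apply_mechanism(config: StudyConfig, mspec: MissingnessSpec,
                     panel: PanelData, latent, seed: int) -> PanelData:
    if config.mechanism == "item_dependent":
        return apply_item_dependent(panel, mspec, seed)
    return apply_factor_dependent(panel, latent, mspec, seed)


def run_replication(config: StudyConfig, h: int,
                    mspec: MissingnessSpec | None = None) -> pd.DataFrame:
    """One replication: returns tidy rows (method incl. 'complete', parameter,
    estimate, se, ci bounds, converged) for every requested method.

    Deterministic given (config, h): the replication seed is master_seed + h.
    """
    if mspec is None:
        mspec = calibrate_condition(config)
    seed = config.replication_seed(h)
    gen = config.generating_params()
    template = config.analysis_template()
    panel, latent = simulate_panel(gen, config.n_persons, config.n_times,
                                   seed=seed)
    rows = []

    def add(tidy: pd.DataFrame, converged: bool):
        t = tidy.copy()
        t["rep"] = h
        t["converged"] = converged
        rows.append(t)

    def opts(method):
        return {**config.fit_options,
                **config.method_fit_options.get(method, {})}

    if config.fit_complete_benchmark:
        bench = fit_ml(panel, template, **opts("complete"))
        add(tidy_single(bench, "complete"), bench.converged)

    masked = _apply_mechanism(config, mspec, panel, latent, seed=seed + 500_000)
    imp_spec = ImputationSpec(**{**config.imputation.__dict__,
                                 "seed": seed + 900_000})

    warm = None
    for method in config.methods:
        if method == "LD":
            res = run_ld(masked, template, **opts("LD"))
            add(tidy_single(res, "LD"), res.converged)
            if config.warm_start_from_ld and res.converged:
                warm = res.params
        elif method == "MI-MV":
            pf = run_mi_mv(masked, template, imp_spec, start=warm,
                           **opts("MI-MV"))
            add(pf.tidy(), pf.converged)
        elif method == "PMI-MV":
            pf = run_pmi_mv(masked, template, imp_spec, start=warm,
                            **opts("PMI-MV"))
            add(pf.tidy(), pf.converged)
        elif method == "MI-FS":
            pf = run_mi_fs(masked, template, imp_spec,
                           config.scoring_template(), start=warm,
                           **opts("MI-FS"))
            add(pf.tidy(), pf.converged)
    return pd.concat(rows, ignore_index=True)


def performance_measures(estimates, ses, cis, truth: float,
                         benchmark_ses=None) -> dict:
    """Summary measures over H replications of one (method, parameter).

    ``cis`` is an (H, 2) array of interval bounds.  Relative bias is absent
    (NaN) when the truth is zero; dSEfull is absent without benchmark SEs.
    """
    est = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    cis = np.asarray(cis, dtype=float).reshape(len(est), 2)
    H = len(est)
    dev = est - truth
    bias = dev.mean()
    rel = np.nan if truth == 0 else (dev / truth).mean()
    mcse = est.std(ddof=1) if H >= 2 else np.nan
    rmse = float(np.sqrt((dev ** 2).mean()))
    se_mean = ses.mean()
    dse = (se_mean - np.asarray(benchmark_ses, dtype=float).mean()
           if benchmark_ses is not None and len(benchmark_ses) else np.nan)
    covered = (cis[:, 0] <= truth) & (truth <= cis[:, 1])
    sig = (cis[:, 0] > 0) | (cis[:, 1] < 0)
    return {
        "bias": bias, "relative_bias": rel, "se_mean": se_mean,
        "mcse": mcse, "rmse": rmse, "dse_full": float(dse),
        "power": 100.0 * sig.mean(), "coverage": 100.0 * covered.mean(),
        "H": H,
    }


@dataclass
class PerfSummary:
    """Per (condition, method, parameter) performance table + raw estimates."""

    summary: pd.DataFrame
    raw: pd.DataFrame
    config: StudyConfig
    excluded: dict[str, int]

    def by_group(self) -> pd.DataFrame:
        """Average the measures within the reporting parameter groups."""
        rows = []
        metrics = ["bias", "relative_bias", "se_mean", "mcse", "rmse",
                   "dse_full", "power", "coverage"]
        for method in self.summary["method"].unique():
            for group, params in PARAMETER_GROUPS.items():
                sub = self.summary[(self.summary["method"] == method)
                                   & self.summary["parameter"].isin(params)]
                if sub.empty:
                    continue
                row = {"method": method, "group": group}
                row.update(sub[metrics].mean(numeric_only=True).to_dict())
                rows.append(row)
        return pd.DataFrame(rows).sort_values(["method", "group"]).reset_index(drop=True)

    def save(self, prefix) -> None:
        self.summary.to_csv(f"{prefix}_summary.csv", index=False,
                            float_format="%.10g")
        self.raw.to_csv(f"{prefix}_raw.csv", index=False, float_format="%.10g")


def run_condition(config: StudyConfig) -> PerfSummary:
    """Loop run_replication over H, aggregate with performance_measures.

    Replications whose fit (or any pooled component fit) failed to converge
    are excluded from that method's summaries; the counts are reported.
    """
    mspec = calibrate_condition(config)
    raws = []
    for h in range(config.H):
        raws.append(run_replication(config, h, mspec))
    raw = pd.concat(raws, ignore_index=True)
    raw.insert(0, "autocorr", config.autocorr)
    raw.insert(1, "mechanism", config.mechanism)

    truth = config.truth()
    bench_se = {}
    if config.fit_complete_benchmark:
        b = raw[(raw["method"] == "complete") & raw["converged"]]
        for par, g in b.groupby("parameter"):
            bench_se[par] = g["se"].to_numpy()

    rows = []
    excluded = {}
    for method in raw["method"].unique():
        sub = raw[raw["method"] == method]
        n_total = sub["rep"].nunique()
        ok = sub[sub["converged"]]
        excluded[method] = n_total - ok["rep"].nunique()
        for par, g in ok.groupby("parameter"):
            meas = performance_measures(
                g["estimate"], g["se"],
                g[["ci_lower", "ci_upper"]].to_numpy(),
                truth[par], bench_se.get(par))
            rows.append({"autocorr": config.autocorr,
                         "mechanism": config.mechanism,
                         "method": method, "parameter": par, **meas})
    summary = pd.DataFrame(rows)
    return PerfSummary(summary=summary, raw=raw, config=config,
                       excluded=excluded)


def typeI_rates(perf: PerfSummary) -> pd.Series:
    """Type-I error per zero-truth parameter: the power of those parameters.

    Only meaningful for a null-effects configuration.
    """
    if not perf.config.null_effects:
        raise ValueError("typeI_rates requires a null-effects study")
    truth = perf.config.truth()
    nulls = [p for p, v in truth.items() if v == 0.0]
    sub = perf.summary[perf.summary["parameter"].isin(nulls)
                       & (perf.summary["method"] != "complete")]
    out = sub.set_index(["method", "parameter"])["power"]
    out.name = "typeI_percent"
    return out
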