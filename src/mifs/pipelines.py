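"""The four missing-data handling strategies and Rubin's-rules pooling.

* LD      — list-wise deletion of covariate-incomplete occasions; missing
            dependent variables handled by FIML within the state-space fit.
* MI-MV   — chained-equations imputation of dependent variables and
            covariates (manifest variables only), fit per imputation, pool.
* PMI-MV  — as MI-MV, but imputed dependent-variable values are discarded
            before fitting (missing y handled by FIML); only covariates keep
            their imputations.
* MI-FS   — factor scores estimated from the incomplete panel by a
            covariate-free state-space fit enter the imputation model along
            with their lags; otherwise as MI-MV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputationSpec, ImputedSet, run_chained_equations
from .model import PFAResults, estimate_factor_scores, fit_ml
from .panel import PanelData
from .params import ModelParams

__all__ = ["PooledFit", "run_ld", "run_mi_mv", "run_pmi_mv", "run_mi_fs",
           "rubin_pool", "tidy_single"]


@dataclass
class PooledFit:
    """Rubin-pooled estimates across m imputations.

    ``table`` is indexed by parameter with columns estimate, W (within
    variance), B (between variance), T (total variance), se, df, ci_lower,
    ci_upper.  Invariant: T = W + (1 + 1/m) B.
    """

    method: str
    m: int
    table: pd.DataFrame
    fits: list[PFAResults]
    imputations: ImputedSet | None = None
    converged: bool = True

    @property
    def estimates(self) -> dict[str, float]:
        return self.table["estimate"].to_dict()

    def tidy(self) -> pd.DataFrame:
        out = self.table.reset_index(names="parameter")
        out.insert(0, "method", self.method)
        out["m"] = self.m
        return out[["method", "parameter", "estimate", "se",
                    "ci_lower", "ci_upper", "df", "m"]]

    def to_csv(self, path) -> None:
        self.tidy().to_csv(path, index=False, float_format="%.10g")


def tidy_single(res: PFAResults, method: str) -> pd.DataFrame:
    """Single-fit analogue of PooledFit.tidy() with z-based 95% CIs."""
    s = res.summary()
    out = pd.DataFrame({
        "method": method,
        "parameter": s.index,
        "estimate": s["estimate"].to_numpy(),
        "se": s["se"].to_numpy(),
        "ci_lower": s["ci_lower"].to_numpy(),
        "ci_upper": s["ci_upper"].to_numpy(),
        "df": np.inf,
        "m": 1,
    })
    return out


def rubin_pool(fits: list[PFAResults], m: int | None = None,
               method: str = "MI", imputations: ImputedSet | None = None,
               alpha: float = 0.05) -> PooledFit:
    """Pool m fits: Qbar = mean estimate, W = mean SE^2, B = between-imputation
    variance, T = W + (1 + 1/m) B; df by the Barnard-Rubin small-sample
    formula with complete-data df = n_used - k; CI = Qbar +- t(df) sqrt(T)."""
    if not fits:
        raise ValueError("rubin_pool needs at least one fit")
    m = len(fits) if m is None else m
    if m != len(fits):
        raise ValueError(f"m={m} but {len(fits)} fits supplied")
    names = fits[0].names
    for f in fits[1:]:
        if f.names != names:
            raise ValueError("fits do not share a parameter set")
    est = np.array([[f.estimates[n] for n in names] for f in fits])
    se2 = np.array([[f.bse[n] ** 2 for n in names] for f in fits])
    qbar = est.mean(axis=0)
    W = se2.mean(axis=0)
    B = est.var(axis=0, ddof=1) if m > 1 else np.zeros(len(names))
    T = W + (1.0 + 1.0 / m) * B
    dfcom = fits[0].n_used - len(names)
    df = np.empty(len(names))
    for i in range(len(names)):
        if not np.isfinite(T[i]) or T[i] <= 0:
            df[i] = np.nan
            continue
        gamma = (1.0 + 1.0 / m) * B[i] / T[i]
        df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - gamma)
        if gamma > 0 and m > 1:
            df_m = (m - 1.0) / gamma ** 2
            df[i] = 1.0 / (1.0 / df_m + 1.0 / df_obs)
        else:
            df[i] = df_obs
    se = np.sqrt(T)
    with np.errstate(invalid="ignore"):
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    table = pd.DataFrame({
        "estimate": qbar, "W": W, "B": B, "T": T, "se": se, "df": df,
        "ci_lower": qbar - tcrit * se, "ci_upper": qbar + tcrit * se,
    }, index=pd.Index(names, name="parameter"))
    return PooledFit(method=method, m=m, table=table, fits=list(fits),
                     imputations=imputations,
                     converged=all(f.converged for f in fits))


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def run_ld(panel: PanelData, template: ModelParams, **fit_options) -> PFAResults:
    """Drop occasions with any missing covariate (remaining rows treated as
    consecutive), then a single FIML fit; missing y values are kept."""
    if panel.r == 0:
        return fit_ml(panel, template, **fit_options)
    keep = ~panel.frame[panel.x_cols].isna().any(axis=1)
    frac = keep.mean()
    if frac < 0.10:
        raise ValueError(
            f"list-wise deletion would keep only {frac:.1%} of rows; "
            "LD is not advisable here")
    sub = panel.frame.loc[keep].copy()
    sub["time"] = sub.groupby("id", sort=False).cumcount() + 1
    return fit_ml(PanelData(sub), template, **fit_options)


def _fit_imputations(datasets: list[PanelData], template: ModelParams,
                     start=None, **fit_options) -> list[PFAResults]:
    fits = []
    for ds in datasets:
        res = fit_ml(ds, template, start=start if start is not None else
                     (fits[0].params if fits else None), **fit_options)
        fits.append(res)
    return fits


def _no_missing_shortcut(panel, template, spec, method, fit_options):
    """With zero missing cells the engine is the identity and each pipeline
    is exactly the single complete-data fit (B = 0 after pooling)."""
    res = fit_ml(panel, template, **fit_options)
    return rubin_pool([res] * spec.m, method=method)


def run_mi_mv(panel: PanelData, template: ModelParams,
              spec: ImputationSpec, **fit_options) -> PooledFit:
    """MI with manifest variables only (no factor scores)."""
    if not panel.mask.to_numpy().any():
        return _no_missing_shortcut(panel, template, spec, "MI-MV", fit_options)
    spec_mv = replace(spec, include_factor_scores=False)
    imp = run_chained_equations(panel, None, spec_mv)
    fits = _fit_imputations(imp.datasets, template, **fit_options)
    return rubin_pool(fits, method="MI-MV", imputations=imp)


def run_pmi_mv(panel: PanelData, template: ModelParams,
               spec: ImputationSpec, **fit_options) -> PooledFit:
    """Partial MI: imputed dependent-variable values are discarded before each
    fit (original y missingness restored; FIML handles it), so only the
    covariate imputations differ across the m fits."""
    if not panel.mask.to_numpy().any():
        return _no_missing_shortcut(panel, template, spec, "PMI-MV", fit_options)
    spec_mv = replace(spec, include_factor_scores=False)
    imp = run_chained_equations(panel, None, spec_mv)
    ymask = panel.frame[panel.y_cols].isna()
    datasets = []
    for ds in imp.datasets:
        d = ds.copy()
        for c in panel.y_cols:
            d.frame.loc[ymask[c].to_numpy(), c] = np.nan
        datasets.append(d)
    if all(d.frame.equals(datasets[0].frame) for d in datasets[1:]):
        # covariates were complete: discarding imputed y leaves m identical
        # panels, so a single fit represents them all
        fit_options.pop("start", None)
        res = fit_ml(datasets[0], template, **fit_options)
        return rubin_pool([res] * len(datasets), method="PMI-MV",
                          imputations=imp)
    fits = _fit_imputations(datasets, template, **fit_options)
    return rubin_pool(fits, method="PMI-MV", imputations=imp)


def run_mi_fs(panel: PanelData, template: ModelParams, spec: ImputationSpec,
              scoring_template: ModelParams, scoring_options: dict | None = None,
              **fit_options) -> PooledFit:
    """MI with factor scores: covariate-free fit on the incomplete panel,
    smoothed scores (and their lags) enter the imputation model, then fit per
    completed panel and pool."""
    if not panel.mask.to_numpy().any():
        fit_options.pop("start", None)
        return _no_missing_shortcut(panel, template, spec, "MI-FS", fit_options)
    scores, score_fit = estimate_factor_scores(
        panel, scoring_template,
        **({"gtol": 1e-5} if scoring_options is None else scoring_options))
    if not score_fit.converged:
        raise RuntimeError(
            "factor-score stage did not converge; aborting MI-FS (llf="
            f"{score_fit.llf:.2f})")
    spec_fs = replace(spec, include_factor_scores=True)
    imp = run_chained_equations(panel, scores, spec_fs)
    # warm start: shared parameters from the factor-score stage
    warm = fit_options.pop("start", None)
    if warm is None:
        from .model import ProcessFactorModel
        mod0 = ProcessFactorModel(imp.datasets[0], template)
        warm = mod0.start_values()
        for i, n in enumerate(template.free_names):
            if n in score_fit.estimates:
                warm[i] = score_fit.estimates[n]
    fits = _fit_imputations(imp.datasets, template, start=warm, **fit_options)
    pooled = rubin_pool(fits, method="MI-FS", imputations=imp)
    pooled.score_fit = score_fit
    return pooled
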