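"""Fully-conditional-specification (chained equations) multiple imputation.

Continuous targets use predictive mean matching (PMM): a Bayesian linear
regression draw on the observed cases, then each missing case receives the
*observed* value of one of the k donors whose predicted means are closest to
its own prediction.  Binary targets use a logistic fit with an approximate
normal posterior draw of the coefficients.  The predictor set can include the
other analysis variables, longitudinal factor scores, lag-1 (optionally
lead-1) columns of all of these, missingness indicators, and fully observed
auxiliaries.  Convergence across the m chains is judged by the potential
scale reduction statistic on per-iteration chain means of the imputed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import LatentPaths, PanelData

__all__ = ["ImputationSpec", "ImputedSet", "build_design", "pmm_step",
           "logistic_step", "run_chained_equations", "rhat"]


@dataclass
class ImputationSpec:
    """Configuration of one chained-equations run."""

    m: int = 5
    n_iter: int = 30
    donors: int = 5
    include_factor_scores: bool = True
    include_lags: bool = True
    include_leads: bool = False
    include_indicators: bool = True
    include_other_manifest: bool = True
    methods: dict[str, str] = field(default_factory=dict)  # col -> pmm|logistic
    predictor_matrix: dict[str, list[str]] | None = None
    #: impute lag/lead columns as variables in their own right (the chained
    #: data matrix is then not forced to be internally consistent, but the
    #: slow feedback loop of passively synced lags is cut).  False re-derives
    #: lag/lead columns from the working values at every iteration.
    sync_lags: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")
        for col, meth in self.methods.items():
            if meth not in ("pmm", "logistic"):
                raise ValueError(f"unknown method {meth!r} for {col}")


def _is_binary(values: np.ndarray) -> bool:
    obs = values[~np.isnan(values)]
    return obs.size > 0 and np.isin(obs, (0.0, 1.0)).all()


def _method_for(col: str, values: np.ndarray, spec: ImputationSpec) -> str:
    if col in spec.methods:
        return spec.methods[col]
    return "logistic" if _is_binary(values) else "pmm"


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(panel: PanelData, scores: LatentPaths | None,
                 spec: ImputationSpec):
    """Augment the panel with scores, lags/leads and missingness indicators.

    Returns (design DataFrame, predictor map target -> predictor columns,
    target list).  Lag cells at a person's first occasion (and lead cells at
    the last) are left missing; the engine fills them once from the column's
    observed values and they stay fixed.
    """
    if spec.include_factor_scores and scores is None:
        raise ValueError("include_factor_scores=True requires factor scores")
    frame = panel.frame.copy()
    fs_cols: list[str] = []
    if spec.include_factor_scores:
        if len(scores.states) != len(frame):
            raise ValueError("factor scores not aligned with panel")
        for k, c in enumerate(scores.factor_cols):
            col = f"fs{k + 1}"
            frame[col] = scores.values[:, k]
            fs_cols.append(col)

    yx = panel.y_cols + panel.x_cols
    ind_cols = []
    if spec.include_indicators:
        for c in yx:
            frame[f"R_{c}"] = frame[c].isna().astype(float)
            ind_cols.append(f"R_{c}")

    lag_sources = yx + fs_cols
    lag_cols, lead_cols = [], []
    g = frame.groupby("id", sort=False)
    if spec.include_lags:
        for c in lag_sources:
            frame[f"L1_{c}"] = g[c].shift(1)
            lag_cols.append(f"L1_{c}")
    if spec.include_leads:
        for c in lag_sources:
            frame[f"F1_{c}"] = g[c].shift(-1)
            lead_cols.append(f"F1_{c}")

    targets = [c for c in yx if frame[c].isna().any()]
    predictors = {}
    for t in targets:
        if spec.predictor_matrix is not None:
            pool = list(spec.predictor_matrix[t])
        else:
            pool = []
            for c in yx:
                if c == t:
                    continue
                if (not spec.include_other_manifest and t in panel.y_cols
                        and c in panel.y_cols):
                    continue
                pool.append(c)
            pool += fs_cols + lag_cols + lead_cols
            pool += [c for c in ind_cols if c != f"R_{t}"]
            pool += panel.z_cols
        if t in pool:
            raise ValueError(f"target {t} predicts itself")
        predictors[t] = pool
    return frame, predictors, targets


# ---------------------------------------------------------------------------
# univariate steps
# ---------------------------------------------------------------------------

def _drop_degenerate(X_obs: np.ndarray) -> np.ndarray:
    """Indices of columns that are non-constant and not duplicates of an
    earlier kept column, judged on the observed rows."""
    keep = []
    for j in range(X_obs.shape[1]):
        col = X_obs[:, j]
        if np.ptp(col) == 0.0:
            continue
        if any(np.array_equal(col, X_obs[:, i]) for i in keep):
            continue
        keep.append(j)
    return np.array(keep, dtype=int)


def _bayes_lstsq(X, y, rng, ridge=1e-5):
    """Posterior draw for normal linear regression (mice-style)."""
    from scipy.linalg import cho_factor, cho_solve

    n, k = X.shape
    S = X.T @ X
    scale = np.diag(S).mean()
    try:
        cf = cho_factor(S, lower=True)
        Sreg = S
    except np.linalg.LinAlgError:
        warnings.warn("singular imputation design; ridge fallback applied")
        Sreg = S + ridge * scale * np.eye(k)
        cf = cho_factor(Sreg, lower=True)
    beta_hat = cho_solve(cf, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - k, 1)
    sigma2 = resid @ resid / rng.chisquare(df)
    # beta* ~ N(beta_hat, sigma2 * Sreg^-1); L^-T z has covariance Sreg^-1
    from scipy.linalg import solve_triangular
    L = np.tril(cf[0])
    zdraw = rng.standard_normal(k)
    beta_star = beta_hat + np.sqrt(sigma2) * solve_triangular(
        L.T, zdraw, lower=False)
    return beta_hat, beta_star


def pmm_step(target: np.ndarray, X: np.ndarray, miss: np.ndarray,
             donors: int, rng, clean: bool = True) -> np.ndarray:
    """Predictive mean matching imputation of ``target[miss]``.

    ``X`` must be complete (current working values).  Every imputed value is
    an observed value of the target column.  ``clean=False`` skips the
    degenerate-column guard (callers that pre-clean the design).
    """
    obs = ~miss
    n_obs = int(obs.sum())
    k = donors
    if n_obs < k + 2:
        k = max(1, n_obs - 2)
        warnings.warn(f"too few observed cases for {donors} donors; using {k}")
    if clean:
        X = X[:, _drop_degenerate(X[obs])]
    Xa = np.column_stack([np.ones(len(target)), X])
    beta_hat, beta_star = _bayes_lstsq(Xa[obs], target[obs], rng)
    yhat_obs = Xa[obs] @ beta_hat
    yhat_mis = Xa[miss] @ beta_star
    yobs = target[obs]
    # k nearest predicted-mean donors via one sort + windowed search
    order = np.argsort(yhat_obs, kind="stable")
    ys = yhat_obs[order]
    pos = np.searchsorted(ys, yhat_mis)
    offs = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offs[None, :], 0, n_obs - 1)
    dist = np.abs(ys[cand] - yhat_mis[:, None])
    nearest = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    choice = rng.integers(0, k, size=len(yhat_mis))
    picked = cand[np.arange(len(yhat_mis)), nearest[np.arange(len(yhat_mis)),
                                                    choice]]
    return yobs[order[picked]]


def _irls_logistic(X, y, ridge=1e-5, max_iter=30, tol=1e-8):
    n, k = X.shape
    beta = np.zeros(k)
    scale = ridge * np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        grad = X.T @ (y - p) - scale @ beta
        info = (X * W[:, None]).T @ X + scale
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            scale = 1e-2 * np.eye(k)
            continue
        beta = beta + step
        if np.abs(step).max() < tol:
            break
        if np.abs(beta).max() > 25:  # separation guard
            warnings.warn("separation in logistic imputation; ridge fallback")
            scale = 1e-1 * np.eye(k)
            beta = np.clip(beta, -25, 25)
    p = expit(X @ beta)
    W = np.clip(p * (1 - p), 1e-10, None)
    info = (X * W[:, None]).T @ X + scale
    return beta, info


def logistic_step(target: np.ndarray, X: np.ndarray, miss: np.ndarray,
                  rng, clean: bool = True) -> np.ndarray:
    """Bernoulli imputation from a logistic fit with a posterior normal draw."""
    obs = ~miss
    yobs = target[obs]
    classes = np.unique(yobs)
    if len(classes) < 2:
        warnings.warn("single observed class; imputing the observed class")
        return np.full(int(miss.sum()), classes[0])
    if clean:
        X = X[:, _drop_degenerate(X[obs])]
    Xa = np.column_stack([np.ones(len(target)), X])
    beta_hat, info = _irls_logistic(Xa[obs], yobs)
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta_hat)))
    except np.linalg.LinAlgError:
        L = np.diag(np.sqrt(np.clip(np.diag(cov), 0, None)))
    beta_star = beta_hat + L @ rng.standard_normal(len(beta_hat))
    p_mis = expit(Xa[miss] @ beta_star)
    return (rng.random(len(p_mis)) < p_mis).astype(float)


# ---------------------------------------------------------------------------
# the chained-equations engine
# ---------------------------------------------------------------------------

@dataclass
class ImputedSet:
    """m completed panels plus chain diagnostics."""

    datasets: list[PanelData]
    traces: pd.DataFrame           # chain, iteration, variable, mean, sd
    rhat: pd.Series
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return len(self.datasets)

    def max_rhat(self) -> float:
        return float(self.rhat.max()) if len(self.rhat) else 1.0

    def save(self, prefix) -> None:
        import json
        from dataclasses import asdict

        for i, ds in enumerate(self.datasets):
            ds.to_csv(f"{prefix}_imp{i + 1}.csv")
        self.traces.to_csv(f"{prefix}_traces.csv", index=False)
        self.rhat.rename("rhat").to_csv(f"{prefix}_rhat.csv")
        with open(f"{prefix}_config.json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2, default=str)


def run_chained_equations(panel: PanelData, scores: LatentPaths | None,
                          spec: ImputationSpec) -> ImputedSet:
    """Gibbs-style chained equations: per chain, initialize missing cells by
    draws from observed values, then iterate univariate imputations over all
    y targets (column order) followed by all x targets, refreshing lag/lead
    columns from working values at the start of every iteration."""
    design, predictors, targets = build_design(panel, scores, spec)
    y_targets = [t for t in targets if t in panel.y_cols]
    x_targets = [t for t in targets if t in panel.x_cols]
    ordered = y_targets + x_targets

    fs_cols = [c for c in design.columns if c.startswith("fs")]
    ind_cols = [c for c in design.columns if c.startswith("R_")]
    lag_like = [c for c in design.columns if c.startswith(("L1_", "F1_"))]
    if not spec.sync_lags:
        # lag/lead columns are imputation targets in their own right
        yx = panel.y_cols + panel.x_cols
        for t in lag_like:
            if not design[t].isna().any():
                continue
            pool = yx + fs_cols + [c for c in lag_like if c != t] \
                + ind_cols + panel.z_cols
            predictors[t] = pool
            ordered.append(t)

    if not [t for t in ordered if t in panel.y_cols + panel.x_cols]:
        empty = pd.DataFrame(columns=["chain", "iteration", "variable",
                                      "mean", "sd", "n"])
        return ImputedSet([panel.copy() for _ in range(spec.m)], empty,
                          pd.Series(dtype=float), spec)

    miss = {t: design[t].isna().to_numpy() for t in ordered}
    methods = {t: _method_for(t, design[t].to_numpy(), spec) for t in ordered}
    lag_sources = panel.y_cols + panel.x_cols + fs_cols
    person_first = design.groupby("id", sort=False).cumcount().to_numpy() == 0
    person_last = design.groupby("id", sort=False).cumcount(ascending=False).to_numpy() == 0

    ss = np.random.SeedSequence(spec.seed)
    chain_seeds = ss.spawn(spec.m)
    datasets = []
    trace_rows = []

    for chain in range(spec.m):
        rng = np.random.default_rng(chain_seeds[chain])
        work = {c: design[c].to_numpy().copy() for c in design.columns
                if c not in ("id", "time")}
        # initialize missing target cells from observed values
        for t in ordered:
            obsvals = work[t][~miss[t]]
            work[t][miss[t]] = rng.choice(obsvals, size=miss[t].sum(), replace=True)
        # boundary lag/lead cells: one fixed draw from the source column
        boundary_fill = {}
        if spec.sync_lags:
            for c in lag_sources:
                src = design[c].to_numpy()
                pool = src[~np.isnan(src)]
                if spec.include_lags:
                    boundary_fill[f"L1_{c}"] = rng.choice(pool, size=person_first.sum())
                if spec.include_leads:
                    boundary_fill[f"F1_{c}"] = rng.choice(pool, size=person_last.sum())
        else:
            # lag columns of fully observed sources (factor scores) still
            # carry missing boundary cells; they are not modelled, so fill
            # them once from the observed values
            for c in lag_like:
                if c not in ordered:
                    v = work[c]
                    nan = np.isnan(v)
                    if nan.any():
                        pool = v[~nan]
                        v[nan] = rng.choice(pool, size=nan.sum())

        def refresh_lags():
            for c in lag_sources:
                v = work[c]
                if spec.include_lags:
                    lag = np.empty_like(v)
                    lag[1:] = v[:-1]
                    lag[person_first] = boundary_fill[f"L1_{c}"]
                    work[f"L1_{c}"] = lag
                if spec.include_leads:
                    lead = np.empty_like(v)
                    lead[:-1] = v[1:]
                    lead[person_last] = boundary_fill[f"F1_{c}"]
                    work[f"F1_{c}"] = lead

        keep_cache: dict[str, np.ndarray] = {}
        for it in range(1, spec.n_iter + 1):
            if spec.sync_lags:
                refresh_lags()
            for t in ordered:
                X = np.column_stack([work[c] for c in predictors[t]])
                if np.isnan(X).any():
                    bad = [c for c in predictors[t] if np.isnan(work[c]).any()]
                    raise RuntimeError(
                        f"chain {chain + 1}, iteration {it}, target {t}: "
                        f"incomplete predictors {bad}")
                # degenerate predictor columns (constants / exact duplicates
                # on the observed rows) are structural; detect once per chain
                if t not in keep_cache:
                    keep_cache[t] = _drop_degenerate(X[~miss[t]])
                X = X[:, keep_cache[t]]
                try:
                    if methods[t] == "pmm":
                        imputed = pmm_step(work[t], X, miss[t], spec.donors,
                                           rng, clean=False)
                    else:
                        imputed = logistic_step(work[t], X, miss[t], rng,
                                                clean=False)
                except Exception as err:
                    raise RuntimeError(
                        f"imputation failed at chain {chain + 1}, iteration "
                        f"{it}, variable {t}: {err}") from err
                work[t][miss[t]] = imputed
                vals = work[t][miss[t]]
                trace_rows.append((chain + 1, it, t, vals.mean(),
                                   vals.std(ddof=1) if len(vals) > 1 else 0.0,
                                   len(vals)))

        completed = panel.copy()
        for t in ordered:
            if t in panel.y_cols + panel.x_cols:
                completed.frame[t] = work[t]
        datasets.append(completed)

    traces = pd.DataFrame(
        trace_rows,
        columns=["chain", "iteration", "variable", "mean", "sd", "n"])
    rh = rhat(traces) if spec.m >= 2 and spec.n_iter >= 2 else pd.Series(dtype=float)
    return ImputedSet(datasets, traces, rh, spec)


def rhat(traces: pd.DataFrame) -> pd.Series:
    """Potential scale reduction across imputation chains, per variable.

    Each chain's draws are the imputed values of the variable over the
    retained (second-half) iterations; the statistic compares the
    within-chain variance of those draws to the variance of the draws pooled
    across chains, exactly as in the multi-chain MCMC diagnostic:

        var+ = (n - 1)/n W + B/n,   rhat = sqrt(var+ / W)

    with n draws per chain, W the mean within-chain variance and
    B = n Var(chain means).  The per-chain moments are reconstructed exactly
    from the per-iteration (mean, sd, n-cells) trace records.  Values below 1
    are floored at 1; zero within-chain variance reports 1 as well.
    """
    need = {"chain", "iteration", "variable", "mean", "sd", "n"}
    if not need.issubset(traces.columns):
        raise ValueError(f"traces must have columns {sorted(need)}")
    if traces["chain"].nunique() < 2:
        raise ValueError("rhat needs at least 2 chains")
    out = {}
    for var, g in traces.groupby("variable"):
        iters = np.sort(g["iteration"].unique())
        if len(iters) < 2:
            raise ValueError("rhat needs at least 2 retained iterations")
        kept_iters = iters[len(iters) // 2:]
        if len(kept_iters) < 2:
            kept_iters = iters
        kept = g[g["iteration"].isin(kept_iters)]
        chain_means, chain_vars, n_draws = [], [], None
        for _, c in kept.groupby("chain"):
            ncell = c["n"].to_numpy()
            m_it = c["mean"].to_numpy()
            s_it = c["sd"].to_numpy()
            n = int(ncell.sum())
            mc = (ncell * m_it).sum() / n
            # sum of squared deviations about the chain mean
            ssq = ((ncell - 1) * s_it ** 2 + ncell * (m_it - mc) ** 2).sum()
            chain_means.append(mc)
            chain_vars.append(ssq / max(n - 1, 1))
            n_draws = n
        W = float(np.mean(chain_vars))
        if W <= 0:
            out[var] = 1.0
            continue
        B = n_draws * float(np.var(chain_means, ddof=1))
        var_plus = (n_draws - 1) / n_draws * W + B / n_draws
        out[var] = float(max(1.0, np.sqrt(var_plus / W)))
    return pd.Series(out).sort_index()
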