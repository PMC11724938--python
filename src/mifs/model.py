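"""State-space PFA core: simulation, filtering, smoothing, ML estimation.

``ProcessFactorModel`` is the model object (built from a :class:`PanelData`
and a :class:`ModelParams` template whose ``free_map`` names the estimated
entries); ``fit`` returns a :class:`PFAResults` carrying maximum-likelihood
estimates obtained by numerical optimization of the prediction-error
decomposition of the Gaussian log-likelihood, standard errors from the
inverse numerical Hessian, and the usual diagnostics.  Thin module-level
functions (``simulate_panel``, ``kalman_filter``, ``kalman_smoother``,
``neg_loglik``, ``fit_ml``, ``estimate_factor_scores``) expose the same
operations functionally.

Missing manifest values are handled by full-information maximum likelihood:
each occasion contributes only its observed rows to the likelihood, and fully
missing occasions contribute a pure time update.  Occasions with missing
*covariate* values (when the model uses covariates) are excluded from the
likelihood and the remaining rows are treated as consecutive, mirroring
list-wise deletion of covariate-incomplete rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kalman
from .panel import LatentPaths, PanelData
from .params import ModelParams, stationary_moments

__all__ = [
    "ProcessFactorModel",
    "PFAResults",
    "simulate_panel",
    "default_covariate_gen",
    "default_aux_gen",
    "kalman_filter",
    "kalman_smoother",
    "neg_loglik",
    "fit_ml",
    "estimate_factor_scores",
]

_BARRIER = 1e10


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def default_covariate_gen(rng, n_persons, n_times, r):
    """x1 ~ Bernoulli(0.5), x2 ~ N(0, 1), i.i.d. over persons and occasions."""
    out = np.empty((n_persons * n_times, r))
    for j in range(r):
        if j == 0:
            out[:, j] = rng.binomial(1, 0.5, size=len(out)).astype(float)
        else:
            out[:, j] = rng.standard_normal(len(out))
    return out


def default_aux_gen(rng, n_persons, n_times, s):
    """Fully observed auxiliaries z ~ Uniform(-3, 3)."""
    return rng.uniform(-3.0, 3.0, size=(n_persons * n_times, s))


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix: Cholesky when PD, eigen-based otherwise
    (exact zeros stay exact for degenerate covariances)."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_panel(params: ModelParams, n_persons: int, n_times: int,
                   seed: int, covariate_gen=default_covariate_gen,
                   aux_gen=default_aux_gen, n_aux: int = 2,
                   burn_in: int = 0, allow_unstable: bool = False):
    """Simulate a complete panel from the state-space model.

    Latent states follow eta_t = alpha + F eta_{t-1} + B x_t + zeta_t with the
    initial state drawn from N(init_mean, init_cov); observations are
    y_t = tau + Lambda eta_t + A x_t + eps_t.  Returns (PanelData,
    LatentPaths of kind 'true').  Deterministic given ``seed``.
    """
    params.validate()
    if not params.is_stable and not allow_unstable:
        raise ValueError("transition matrix is unstable; pass allow_unstable=True "
                         "to simulate anyway")
    rng = np.random.default_rng(seed)
    q, p, r = params.q, params.p, params.r
    n, T = n_persons, n_times
    Ttot = T + burn_in

    x = covariate_gen(rng, n, Ttot, r) if r else np.zeros((n * Ttot, 0))
    x = np.asarray(x, dtype=float).reshape(n * Ttot, r)
    z = aux_gen(rng, n, Ttot, n_aux) if n_aux else np.zeros((n * Ttot, 0))
    z = np.asarray(z, dtype=float).reshape(n * Ttot, n_aux)

    L0 = _psd_sqrt(params.init_cov)
    Lq = _psd_sqrt(params.process_noise_cov)
    eta = np.empty((n, Ttot, q))
    eta[:, 0] = params.init_mean + rng.standard_normal((n, q)) @ L0.T
    xs = x.reshape(n, Ttot, r)
    for t in range(1, Ttot):
        drift = params.dyn_intercept + eta[:, t - 1] @ params.transition.T
        if r:
            drift = drift + xs[:, t] @ params.dyn_covariate_weights.T
        eta[:, t] = drift + rng.standard_normal((n, q)) @ Lq.T

    eps_sd = np.sqrt(np.diag(params.meas_noise_cov))
    yflat = (params.meas_intercept
             + eta.reshape(n * Ttot, q) @ params.loadings.T
             + (x @ params.meas_covariate_weights.T if r else 0.0)
             + rng.standard_normal((n * Ttot, p)) * eps_sd)

    keep = np.tile(np.arange(Ttot) >= burn_in, n)
    ids = np.repeat(np.arange(1, n + 1), Ttot)[keep]
    times = np.tile(np.arange(1, Ttot + 1) - burn_in, n)[keep]
    data = {"id": ids, "time": times}
    for j in range(p):
        data[f"y{j + 1}"] = yflat[keep, j]
    for j in range(r):
        data[f"x{j + 1}"] = x[keep, j]
    for j in range(n_aux):
        data[f"z{j + 1}"] = z[keep, j]
    panel = PanelData(pd.DataFrame(data))

    states = pd.DataFrame({"id": ids, "time": times})
    etaflat = eta.reshape(n * Ttot, q)[keep]
    for k in range(q):
        states[f"f{k + 1}"] = etaflat[:, k]
    latent = LatentPaths(states, np.zeros((keep.sum(), q, q)), kind="true")
    return panel, latent


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class ProcessFactorModel:
    """Linear Gaussian state-space model for a person x time panel.

    Parameters
    ----------
    data : PanelData
        Long-format panel; manifest variables may be missing.
    template : ModelParams
        Parameter structure with ``free_map`` naming the estimated entries.
    init : {'stationary', 'fixed'}
        'stationary' (default for fitting) re-derives the initial state
        distribution from the current dynamics: init_cov solves the Lyapunov
        equation implied by (F, S_zeta) and init_mean is
        (I - F)^-1 (alpha + B xbar) with xbar the sample covariate mean.
        'fixed' uses the template's init_mean / init_cov as given.
    """

    def __init__(self, data: PanelData, template: ModelParams,
                 init: str = "stationary"):
        template.validate()
        if init not in ("stationary", "fixed"):
            raise ValueError("init must be 'stationary' or 'fixed'")
        if template.p != data.p:
            raise ValueError(f"template has p={template.p} indicators, panel has {data.p}")
        if template.r and template.uses_covariates and template.r != data.r:
            raise ValueError(f"template has r={template.r} covariates, panel has {data.r}")
        self.data = data
        self.template = template
        self.init = init

        frame = data.frame
        use = np.ones(len(frame), dtype=bool)
        if template.uses_covariates and data.r:
            use = ~frame[data.x_cols].isna().any(axis=1).to_numpy()
        self.n_excluded = int((~use).sum())
        sub = frame.loc[use]
        self._row_index = sub.index.to_numpy()
        y = sub[data.y_cols].to_numpy()
        self._obs = (~np.isnan(y)).astype(np.uint8)
        self._y = np.nan_to_num(y)
        self._x = (sub[data.x_cols].to_numpy()
                   if template.uses_covariates and data.r else
                   np.zeros((len(sub), 0)))
        counts = sub.groupby("id", sort=False).size().to_numpy()
        self._starts = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._ids = sub["id"].to_numpy()
        self._times = sub["time"].to_numpy()
        self._xbar = self._x.mean(axis=0) if self._x.shape[1] else np.zeros(0)
        self.n_used = int(len(sub))

    # -- likelihood ------------------------------------------------------
    def _init_moments(self, params: ModelParams):
        if self.init == "fixed":
            return params.init_mean, params.init_cov
        mu, gamma = stationary_moments(params)
        if params.r and self._x.shape[1]:
            mu = np.linalg.solve(
                np.eye(params.q) - params.transition,
                params.dyn_intercept + params.dyn_covariate_weights @ self._xbar)
        return mu, gamma

    def _run_filter(self, params: ModelParams, store: bool):
        a1, P1 = self._init_moments(params)
        r = self._x.shape[1]
        amat = params.meas_covariate_weights if r else np.zeros((params.p, 0))
        B = params.dyn_covariate_weights if r else np.zeros((params.q, 0))
        return _kalman.filter_loglik(
            self._y, self._obs, self._x, self._starts,
            params.meas_intercept, params.loadings, amat,
            np.diag(params.meas_noise_cov).copy(),
            params.transition, params.dyn_intercept, B,
            params.process_noise_cov, a1, P1, store)

    def loglike(self, params: ModelParams) -> float:
        """Prediction-error-decomposition log-likelihood (observed rows only)."""
        if self.init == "stationary" and not params.is_stable:
            return -np.inf
        ll = self._run_filter(params, store=False)[0]
        return float(ll)

    def neg_loglik(self, params: ModelParams) -> float:
        return -self.loglike(params)

    def _negll_natural(self, theta: np.ndarray) -> float:
        params = self.template.with_natural(theta)
        if self.init == "stationary":
            rho = np.max(np.abs(np.linalg.eigvals(params.transition)))
            if rho >= 0.999:
                return _BARRIER * (1.0 + rho - 0.999)
        val = -self._run_filter(params, store=False)[0] if self.init == "fixed" \
            else self.neg_loglik(params)
        if not np.isfinite(val):
            return _BARRIER
        return val

    # -- filtering / smoothing -------------------------------------------
    def _paths(self, est, cov, kind) -> LatentPaths:
        states = pd.DataFrame({"id": self._ids, "time": self._times})
        for k in range(self.template.q):
            states[f"f{k + 1}"] = est[:, k]
        return LatentPaths(states.reset_index(drop=True), cov, kind=kind)

    def filter(self, params: ModelParams):
        """Filtered states E[eta_t | y_1..t] plus occasion prediction errors.

        Returns (LatentPaths[filtered], DataFrame of per-occasion prediction
        errors v_j and innovation variances for the observed rows).
        """
        ll, att, Ptt, apred, Ppred = self._run_filter(params, store=True)
        if not np.isfinite(ll):
            bad = "singular innovation covariance encountered during filtering"
            raise np.linalg.LinAlgError(bad)
        # joint (occasion-level) one-step-ahead prediction errors
        lam, tau = params.loadings, params.meas_intercept
        pred = tau + apred @ lam.T
        if self._x.shape[1]:
            pred = pred + self._x @ params.meas_covariate_weights.T
        v = np.where(self._obs.astype(bool), self._y - pred, np.nan)
        svar = (np.einsum("pk,nkl,pl->np", lam, Ppred, lam)
                + np.diag(params.meas_noise_cov))
        innov = pd.DataFrame({"id": self._ids, "time": self._times})
        for j in range(params.p):
            innov[f"v{j + 1}"] = v[:, j]
            innov[f"s{j + 1}"] = np.where(np.isnan(v[:, j]), np.nan, svar[:, j])
        return self._paths(att, Ptt, "filtered"), innov

    def smooth(self, params: ModelParams) -> LatentPaths:
        """Fixed-interval smoothed states E[eta_t | y_1..Ti]."""
        ll, att, Ptt, apred, Ppred = self._run_filter(params, store=True)
        if not np.isfinite(ll):
            raise np.linalg.LinAlgError(
                "singular innovation covariance encountered during filtering")
        asm, Psm = _kalman.rts_smooth(att, Ptt, apred, Ppred,
                                      params.transition, self._starts)
        return self._paths(asm, Psm, "smoothed")

    # -- transforms between natural and optimizer scales -------------------
    def _transform_info(self):
        fm = self.template.free_map
        kinds = []
        for fp in fm:
            if fp.attr in ("process_noise_cov", "init_cov"):
                kinds.append("chol")
            elif fp.attr == "meas_noise_cov" and fp.index[0] == fp.index[1]:
                kinds.append("log")
            else:
                kinds.append("id")
        return kinds

    def _to_opt(self, theta):
        kinds = self._transform_info()
        fm = self.template.free_map
        u = np.array(theta, dtype=float)
        chol_attrs = {fp.attr for fp, k in zip(fm, kinds) if k == "chol"}
        for attr in chol_attrs:
            idxs = [i for i, fp in enumerate(fm) if fp.attr == attr]
            q = self.template.q
            M = getattr(self.template, attr).copy()
            for i in idxs:
                M[fm[i].index] = theta[i]
                M[fm[i].index[::-1]] = theta[i]
            L = np.linalg.cholesky(M)
            for i in idxs:
                a, b = fm[i].index
                u[i] = np.log(L[a, b]) if a == b else L[a, b]
        for i, k in enumerate(kinds):
            if k == "log":
                u[i] = np.log(theta[i])
        return u

    def _to_natural(self, u):
        kinds = self._transform_info()
        fm = self.template.free_map
        theta = np.array(u, dtype=float)
        chol_attrs = {fp.attr for fp, k in zip(fm, kinds) if k == "chol"}
        for attr in chol_attrs:
            idxs = [i for i, fp in enumerate(fm) if fp.attr == attr]
            q = self.template.q
            L = np.zeros((q, q))
            for i in idxs:
                a, b = fm[i].index
                L[a, b] = np.exp(u[i]) if a == b else u[i]
            M = L @ L.T
            for i in idxs:
                theta[i] = M[fm[i].index]
        for i, k in enumerate(kinds):
            if k == "log":
                theta[i] = np.exp(u[i])
        return theta

    # -- starting values ---------------------------------------------------
    def start_values(self) -> np.ndarray:
        """Moment-based starting values on the natural scale."""
        tmpl = self.template
        ymean = np.nanmean(np.where(self._obs.astype(bool), self._y, np.nan), axis=0)
        yvar = np.nanvar(np.where(self._obs.astype(bool), self._y, np.nan), axis=0)
        # anchor indicator per factor: loading fixed at 1
        free_load = {fp.index for fp in tmpl.free_map if fp.attr == "loadings"}
        anchors = []
        for k in range(tmpl.q):
            anchor = next(j for j in range(tmpl.p)
                          if tmpl.loadings[j, k] == 1.0 and (j, k) not in free_load)
            anchors.append(anchor)
        theta = []
        for fp in tmpl.free_map:
            if fp.attr == "transition" or fp.attr == "dyn_covariate_weights":
                theta.append(0.1)
            elif fp.attr == "dyn_intercept":
                theta.append(0.0)
            elif fp.attr == "meas_intercept":
                theta.append(ymean[fp.index[0]])
            elif fp.attr == "loadings":
                theta.append(1.0)
            elif fp.attr == "meas_noise_cov":
                theta.append(max(yvar[fp.index[0]] / 2.0, 1e-3))
            elif fp.attr in ("process_noise_cov", "init_cov"):
                a, b = fp.index
                theta.append(max(yvar[anchors[a]] / 2.0, 1e-3) if a == b else 0.0)
            elif fp.attr == "meas_covariate_weights":
                theta.append(0.0)
            else:  # pragma: no cover
                raise ValueError(f"no default start for {fp.attr}")
        return np.array(theta)

    # -- estimation --------------------------------------------------------
    def fit(self, start=None, compute_se: bool = True, gtol: float = 1e-6,
            maxiter: int = 500, n_restarts: int = 3, seed: int = 0) -> "PFAResults":
        """Maximize the likelihood over the transformed free parameters.

        Quasi-Newton (L-BFGS-B) with numerical gradients; up to ``n_restarts``
        jittered restarts if the optimizer does not report convergence.
        Standard errors come from the inverse numerical Hessian of the
        negative log-likelihood with respect to the natural parameters.
        """
        if not self.template.free_map:
            raise ValueError("template.free_map is empty: nothing to estimate")
        if self.n_used == 0:
            raise ValueError("no usable occasions after excluding missing-covariate rows")
        if start is None:
            theta0 = self.start_values()
        elif isinstance(start, ModelParams):
            theta0 = start.natural_vector()
        else:
            theta0 = np.asarray(start, dtype=float)

        def objective(u):
            return self._negll_natural(self._to_natural(u))

        rng = np.random.default_rng(seed)
        u0 = self._to_opt(theta0)
        best = None
        for attempt in range(n_restarts + 1):
            res = optimize.minimize(
                objective, u0, method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12,
                         "maxfun": 100000})
            if best is None or res.fun < best.fun:
                best = res
            if res.success and res.fun < _BARRIER / 2:
                best = res if res.fun <= best.fun else best
                break
            u0 = self._to_opt(theta0) + 0.1 * rng.standard_normal(len(u0))
        theta_hat = self._to_natural(best.x)
        params_hat = self.template.with_natural(theta_hat)
        converged = bool(best.success) and best.fun < _BARRIER / 2
        if self.init == "stationary":
            params_hat.init_mean, params_hat.init_cov = self._init_moments(params_hat)

        names = self.template.free_names
        bse = dict.fromkeys(names, np.nan)
        cov = np.full((len(names), len(names)), np.nan)
        se_ok = False
        if compute_se and converged:
            H = _num_hessian(self._negll_natural, theta_hat)
            try:
                cov = np.linalg.inv(H)
                d = np.diag(cov)
                if np.all(np.isfinite(d)) and np.all(d > 0):
                    bse = dict(zip(names, np.sqrt(d)))
                    se_ok = True
            except np.linalg.LinAlgError:
                pass
        return PFAResults(
            model=self, params=params_hat,
            estimates=dict(zip(names, theta_hat)), bse=bse,
            cov_params=cov, llf=-float(best.fun), converged=converged,
            se_available=se_ok, n_used=self.n_used, n_excluded=self.n_excluded,
            nit=int(best.nit))


def _num_hessian(fun, theta, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (fun(theta + ei) + fun(theta - ei) - 2.0 * f0) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class PFAResults:
    """Maximum-likelihood fit of a :class:`ProcessFactorModel`."""

    model: ProcessFactorModel
    params: ModelParams
    estimates: dict[str, float]
    bse: dict[str, float]
    cov_params: np.ndarray
    llf: float
    converged: bool
    se_available: bool
    n_used: int
    n_excluded: int = 0
    nit: int = 0

    @property
    def names(self) -> list[str]:
        return list(self.estimates)

    @property
    def k_params(self) -> int:
        return len(self.estimates)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        est = np.array(list(self.estimates.values()))
        se = np.array([self.bse[n] for n in self.names])
        return pd.DataFrame(
            {"lower": est - zc * se, "upper": est + zc * se}, index=self.names)

    def smooth(self) -> LatentPaths:
        return self.model.smooth(self.params)

    def filter(self):
        return self.model.filter(self.params)

    def summary(self) -> pd.DataFrame:
        est = np.array(list(self.estimates.values()))
        se = np.array([self.bse[n] for n in self.names])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        ci = self.conf_int()
        return pd.DataFrame({
            "estimate": est, "se": se, "z": z,
            "ci_lower": ci["lower"], "ci_upper": ci["upper"],
        }, index=self.names)

    def __repr__(self):
        return (f"PFAResults(llf={self.llf:.3f}, converged={self.converged}, "
                f"k={self.k_params}, n_used={self.n_used})")


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def kalman_filter(params: ModelParams, data: PanelData):
    """Filtered latent paths and per-occasion prediction errors."""
    return ProcessFactorModel(data, params, init="fixed").filter(params)


def kalman_smoother(params: ModelParams, data: PanelData) -> LatentPaths:
    """Fixed-interval smoothed latent paths."""
    return ProcessFactorModel(data, params, init="fixed").smooth(params)


def neg_loglik(params: ModelParams, data: PanelData) -> float:
    """Negative prediction-error-decomposition log-likelihood."""
    return ProcessFactorModel(data, params, init="fixed").neg_loglik(params)


def fit_ml(data: PanelData, template: ModelParams, **options) -> PFAResults:
    """ML fit of the free parameters in ``template`` to ``data``."""
    init = options.pop("init", "stationary")
    return ProcessFactorModel(data, template, init=init).fit(**options)


def estimate_factor_scores(data: PanelData, template: ModelParams,
                           **options):
    """Fit a covariate-free model and return smoothed factor scores.

    ``template`` must exclude covariate effects (B = A = 0 and not free).
    Returns (LatentPaths[smoothed], PFAResults).  Scores are defined at every
    (person, time), including fully missing occasions.
    """
    if template.uses_covariates:
        raise ValueError("factor-scoring template must exclude covariate effects")
    options.setdefault("compute_se", False)
    res = fit_ml(data, template, **options)
    return res.smooth(), res
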