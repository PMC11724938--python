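"""Time-invariant parameters of the linear Gaussian state-space / PFA model.

The model is

    eta_{i,t} = alpha + F eta_{i,t-1} + B x_{i,t} + zeta_{i,t},  zeta ~ N(0, S_zeta)
    y_{i,t}   = tau + Lambda eta_{i,t} + A x_{i,t} + eps_{i,t},  eps ~ N(0, S_eps)

with eta_{i,1} ~ N(mu_eta1, S_eta1).  ``ModelParams`` stores every matrix on the
natural scale plus a ``free_map`` naming the entries that are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla

__all__ = [
    "FreeParam",
    "ModelParams",
    "is_stable",
    "stationary_moments",
    "pfa_preset",
    "pfa_template",
    "pfa_true_values",
    "DEFAULT_COVARIATE_MOMENTS",
]

#: mean / covariance of the default covariate generator:
#: x1 ~ Bernoulli(0.5) (mean .5, var .25), x2 ~ N(0, 1), independent.
DEFAULT_COVARIATE_MOMENTS = (
    np.array([0.5, 0.0]),
    np.diag([0.25, 1.0]),
)


@dataclass(frozen=True)
class FreeParam:
    """One estimated entry: report name, owning matrix, (row, col) index."""

    name: str
    attr: str
    index: tuple[int, ...]


def _as_matrix(a, shape, name):
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape != shape:
        raise ValueError(f"{name} has shape {a.shape}, expected {shape}")
    return a


def _check_psd(mat, name, tol=1e-10):
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol:
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")


@dataclass
class ModelParams:
    transition: np.ndarray            # F, (q, q)
    process_noise_cov: np.ndarray     # S_zeta, (q, q)
    loadings: np.ndarray              # Lambda, (p, q)
    meas_noise_cov: np.ndarray        # S_eps, (p, p), diagonal in scope
    meas_intercept: np.ndarray | None = None      # tau, (p,)
    dyn_intercept: np.ndarray | None = None       # alpha, (q,)
    dyn_covariate_weights: np.ndarray | None = None   # B, (q, r)
    meas_covariate_weights: np.ndarray | None = None  # A, (p, r)
    init_mean: np.ndarray | None = None           # mu_eta1, (q,)
    init_cov: np.ndarray | None = None            # S_eta1, (q, q)
    free_map: list[FreeParam] = field(default_factory=list)

    def __post_init__(self):
        F = np.atleast_2d(np.asarray(self.transition, dtype=float))
        q = F.shape[0]
        Lam = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if Lam.shape[1] != q:
            raise ValueError(f"loadings must have {q} columns, got {Lam.shape[1]}")
        p = Lam.shape[0]
        self.transition = _as_matrix(F, (q, q), "transition")
        self.loadings = Lam
        self.process_noise_cov = _as_matrix(self.process_noise_cov, (q, q), "process_noise_cov")
        self.meas_noise_cov = _as_matrix(self.meas_noise_cov, (p, p), "meas_noise_cov")
        self.meas_intercept = (
            np.zeros(p) if self.meas_intercept is None
            else np.asarray(self.meas_intercept, dtype=float).reshape(p)
        )
        self.dyn_intercept = (
            np.zeros(q) if self.dyn_intercept is None
            else np.asarray(self.dyn_intercept, dtype=float).reshape(q)
        )
        if self.dyn_covariate_weights is None and self.meas_covariate_weights is None:
            r = 0
        elif self.dyn_covariate_weights is not None:
            r = np.atleast_2d(self.dyn_covariate_weights).shape[1]
        else:
            r = np.atleast_2d(self.meas_covariate_weights).shape[1]
        self.dyn_covariate_weights = (
            np.zeros((q, r)) if self.dyn_covariate_weights is None
            else _as_matrix(self.dyn_covariate_weights, (q, r), "dyn_covariate_weights")
        )
        self.meas_covariate_weights = (
            np.zeros((p, r)) if self.meas_covariate_weights is None
            else _as_matrix(self.meas_covariate_weights, (p, r), "meas_covariate_weights")
        )
        self.init_mean = (
            np.zeros(q) if self.init_mean is None
            else np.asarray(self.init_mean, dtype=float).reshape(q)
        )
        self.init_cov = (
            np.eye(q) if self.init_cov is None
            else _as_matrix(self.init_cov, (q, q), "init_cov")
        )

    # -- dimensions -----------------------------------------------------
    @property
    def q(self) -> int:
        return self.transition.shape[0]

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def r(self) -> int:
        return self.dyn_covariate_weights.shape[1]

    @property
    def uses_covariates(self) -> bool:
        return self.r > 0 and (
            np.any(self.dyn_covariate_weights != 0)
            or np.any(self.meas_covariate_weights != 0)
            or any(fp.attr in ("dyn_covariate_weights", "meas_covariate_weights")
                   for fp in self.free_map)
        )

    @property
    def is_stable(self) -> bool:
        return is_stable(self.transition)

    # -- validation -----------------------------------------------------
    def validate(self):
        _check_psd(self.process_noise_cov, "process_noise_cov")
        _check_psd(self.meas_noise_cov, "meas_noise_cov")
        _check_psd(self.init_cov, "init_cov")
        free_loadings = {fp.index for fp in self.free_map if fp.attr == "loadings"}
        if free_loadings:
            for k in range(self.q):
                col = [(j, k) for j in range(self.p) if self.loadings[j, k] != 0]
                anchored = any(idx not in free_loadings and self.loadings[idx] == 1.0
                               for idx in col)
                if not anchored:
                    raise ValueError(
                        f"factor {k}: one loading must be fixed at 1 for identification"
                    )
        return self

    # -- natural-parameter vector ---------------------------------------
    @property
    def free_names(self) -> list[str]:
        return [fp.name for fp in self.free_map]

    def natural_vector(self) -> np.ndarray:
        return np.array([getattr(self, fp.attr)[fp.index] for fp in self.free_map])

    def with_natural(self, theta) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.free_map),):
            raise ValueError("natural vector length does not match free_map")
        new = replace(self, free_map=self.free_map)
        for attr in {fp.attr for fp in self.free_map}:
            setattr(new, attr, getattr(new, attr).copy())
        for fp, val in zip(self.free_map, theta):
            mat = getattr(new, fp.attr)
            mat[fp.index] = val
            # keep covariance matrices symmetric
            if fp.attr in ("process_noise_cov", "init_cov") and fp.index[0] != fp.index[1]:
                mat[fp.index[::-1]] = val
        return new

    def true_values(self) -> dict[str, float]:
        return dict(zip(self.free_names, self.natural_vector()))


def is_stable(transition) -> bool:
    """True iff every eigenvalue of the transition matrix has modulus < 1."""
    F = np.atleast_2d(np.asarray(transition, dtype=float))
    if F.shape[0] != F.shape[1]:
        raise ValueError("transition matrix must be square")
    return bool(np.max(np.abs(np.linalg.eigvals(F))) < 1.0)


def stationary_moments(params: ModelParams, covariate_var=None, covariate_mean=None):
    """Stationary mean and covariance of the latent VAR with i.i.d. covariates.

    Solves mu = (I - F)^-1 (alpha + B E[x]) and the discrete Lyapunov equation
    Gamma = F Gamma F' + (B Var(x) B' + S_zeta).
    """
    F = params.transition
    q = params.q
    ev = np.linalg.eigvals(F)
    if np.max(np.abs(ev)) >= 1.0:
        bad = ev[np.argmax(np.abs(ev))]
        raise ValueError(
            f"transition matrix is unstable: eigenvalue {bad:.4g} has modulus >= 1"
        )
    r = params.r
    if covariate_var is None:
        covariate_var = np.zeros((r, r)) if r else np.zeros((0, 0))
    if covariate_mean is None:
        covariate_mean = np.zeros(r)
    covariate_var = np.atleast_2d(np.asarray(covariate_var, dtype=float))
    covariate_mean = np.asarray(covariate_mean, dtype=float).reshape(r)
    B = params.dyn_covariate_weights
    innov = params.process_noise_cov + (B @ covariate_var @ B.T if r else 0.0)
    gamma = sla.solve_discrete_lyapunov(F, innov)
    gamma = (gamma + gamma.T) / 2.0
    drive = params.dyn_intercept + (B @ covariate_mean if r else 0.0)
    mu = np.linalg.solve(np.eye(q) - F, drive)
    return mu, gamma


# ---------------------------------------------------------------------------
# PFA presets: bivariate latent VAR(1), six indicators, two covariates
# ---------------------------------------------------------------------------

def pfa_true_values(autocorr: str = "low", null_effects: bool = False) -> dict[str, float]:
    """True generating values for the simulation presets.

    ``autocorr`` 'low' sets both AR coefficients to 0.5, 'high' to 0.7.  With
    ``null_effects`` the cross-regressions and covariate coefficients are zeroed
    (type-I-error configuration).
    """
    a = {"low": 0.5, "high": 0.7}[autocorr]
    vals = {
        "a1": a, "a2": a, "b1": -0.2, "b2": -0.3,
        "c1": 0.3, "c2": -0.3, "d1": 0.5, "d2": -0.4,
        "szeta_11": 2.0, "szeta_21": 0.5, "szeta_22": 6.0,
        "mu_1": 3.0, "mu_2": 3.0, "mu_3": 3.0, "mu_4": 3.0, "mu_5": 3.0, "mu_6": 3.0,
        "lambda_1": 2.0, "lambda_2": 1.0, "lambda_3": 2.0, "lambda_4": 1.0,
        "seps_1": 1.0, "seps_2": 1.0, "seps_3": 1.0,
        "seps_4": 1.0, "seps_5": 1.0, "seps_6": 1.0,
    }
    if null_effects:
        for name in ("b1", "b2", "c1", "c2", "d1", "d2"):
            vals[name] = 0.0
    return vals


def _pfa_free_map(covariates: bool) -> list[FreeParam]:
    fm = [
        FreeParam("a1", "transition", (0, 0)),
        FreeParam("b1", "transition", (0, 1)),
        FreeParam("b2", "transition", (1, 0)),
        FreeParam("a2", "transition", (1, 1)),
    ]
    if covariates:
        fm += [
            FreeParam("c1", "dyn_covariate_weights", (0, 0)),
            FreeParam("d1", "dyn_covariate_weights", (0, 1)),
            FreeParam("c2", "dyn_covariate_weights", (1, 0)),
            FreeParam("d2", "dyn_covariate_weights", (1, 1)),
        ]
    fm += [
        FreeParam("szeta_11", "process_noise_cov", (0, 0)),
        FreeParam("szeta_21", "process_noise_cov", (1, 0)),
        FreeParam("szeta_22", "process_noise_cov", (1, 1)),
    ]
    fm += [FreeParam(f"mu_{j + 1}", "meas_intercept", (j,)) for j in range(6)]
    fm += [
        FreeParam("lambda_1", "loadings", (1, 0)),
        FreeParam("lambda_2", "loadings", (2, 0)),
        FreeParam("lambda_3", "loadings", (4, 1)),
        FreeParam("lambda_4", "loadings", (5, 1)),
    ]
    fm += [FreeParam(f"seps_{j + 1}", "meas_noise_cov", (j, j)) for j in range(6)]
    return fm


def _pfa_params(vals: dict[str, float], covariates: bool) -> ModelParams:
    F = np.array([[vals["a1"], vals["b1"]], [vals["b2"], vals["a2"]]])
    B = np.array([[vals["c1"], vals["d1"]], [vals["c2"], vals["d2"]]])
    Q = np.array([[vals["szeta_11"], vals["szeta_21"]],
                  [vals["szeta_21"], vals["szeta_22"]]])
    Lam = np.array([
        [1.0, 0.0], [vals["lambda_1"], 0.0], [vals["lambda_2"], 0.0],
        [0.0, 1.0], [0.0, vals["lambda_3"]], [0.0, vals["lambda_4"]],
    ])
    tau = np.array([vals[f"mu_{j + 1}"] for j in range(6)])
    R = np.diag([vals[f"seps_{j + 1}"] for j in range(6)])
    params = ModelParams(
        transition=F,
        process_noise_cov=Q,
        loadings=Lam,
        meas_noise_cov=R,
        meas_intercept=tau,
        dyn_covariate_weights=B if covariates else np.zeros((2, 2)),
        free_map=_pfa_free_map(covariates),
    )
    mu, gamma = stationary_moments(
        params,
        covariate_var=DEFAULT_COVARIATE_MOMENTS[1] if covariates else None,
        covariate_mean=DEFAULT_COVARIATE_MOMENTS[0] if covariates else None,
    )
    params.init_mean = mu
    params.init_cov = gamma
    return params.validate()


def pfa_preset(autocorr: str = "low", null_effects: bool = False) -> ModelParams:
    """Generating model at the true values (covariates included).

    The initial condition is set to the stationary mean/covariance implied by
    the dynamics and the default covariate moments.
    """
    return _pfa_params(pfa_true_values(autocorr, null_effects), covariates=True)


def pfa_template(autocorr: str = "low", covariates: bool = True,
                 null_effects: bool = False) -> ModelParams:
    """Estimation template: same structure, free_map for every estimated entry.

    ``covariates=False`` gives the factor-scoring model (B = A = 0 fixed).
    The stored values are the true generating values; ``fit`` replaces them
    with moment-based starting values unless told otherwise.
    """
    return _pfa_params(pfa_true_values(autocorr, null_effects), covariates=covariates)
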