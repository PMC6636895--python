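"""Parameterization and likelihood of the latent conditional Gaussian graphical model.

The model: outputs ``Y_X`` (p-dimensional) conditional on inputs ``Y_Z``
(m-dimensional) are multivariate normal,

    Y_X | Y_Z = z  ~  N( -(S_X - L_X)^{-1} (S_ZX - L_ZX)^T z ,  (S_X - L_X)^{-1} ),

where ``S_X`` (sparse, symmetric) is the conditional precision over the outputs,
``S_ZX`` (sparse) carries the direct input effects, and the low-rank pair
``(L_X, L_ZX)`` absorbs the contribution of marginalized latent variables:
if the joint conditional precision over (X, H) has blocks M_X, M_XH, M_H and the
inputs load on H through M_ZH, then L_X = M_XH M_H^{-1} M_XH^T and
L_ZX = M_ZH M_H^{-1} M_XH^T.  Only the differences S - L enter the likelihood;
the sparse/low-rank split is what the penalized estimators in this package
recover.

The log-likelihood is expressed through second-moment matrices only (the model
is zero-mean), which is what makes the estimators scale in n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Dataset",
    "SufficientStats",
    "CRFParameters",
    "ConditionalLaw",
    "suff_stats",
    "log_likelihood",
    "gradient",
    "conditional_distribution",
    "objective_value",
    "penalty_value",
    "conditional_mle",
    "penalty_to_paper",
    "penalty_from_paper",
]

SYM_TOL = 1e-10


class FeasibilityError(ValueError):
    """Raised when parameters violate S_X - L_X > 0 (strict) or L_X >= 0."""


def _as_2d(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def _check_symmetric(a, name, tol=SYM_TOL):
    scale = max(1.0, float(np.abs(a).max(initial=0.0)))
    dev = float(np.abs(a - a.T).max(initial=0.0))
    if dev > tol * scale:
        raise ValueError(f"{name} is not symmetric (max asymmetry {dev:.3e})")
    return 0.5 * (a + a.T)


@dataclass
class Dataset:
    """Observed data: an n x m input block and an n x p output block."""

    y_z: np.ndarray
    y_x: np.ndarray
    z_labels: list[str] | None = None
    x_labels: list[str] | None = None

    def __post_init__(self):
        self.y_x = _as_2d(self.y_x, "y_x")
        if self.y_z is None:
            self.y_z = np.empty((self.y_x.shape[0], 0))
        self.y_z = _as_2d(self.y_z, "y_z")
        if self.y_z.shape[0] != self.y_x.shape[0]:
            raise ValueError(
                f"row count mismatch: y_z has {self.y_z.shape[0]} rows, "
                f"y_x has {self.y_x.shape[0]}"
            )
        if self.z_labels is None:
            self.z_labels = [f"z{i + 1}" for i in range(self.y_z.shape[1])]
        if self.x_labels is None:
            self.x_labels = [f"x{i + 1}" for i in range(self.y_x.shape[1])]
        if len(self.z_labels) != self.y_z.shape[1]:
            raise ValueError("z_labels length does not match y_z columns")
        if len(self.x_labels) != self.y_x.shape[1]:
            raise ValueError("x_labels length does not match y_x columns")

    @property
    def n(self) -> int:
        return self.y_x.shape[0]

    @property
    def m(self) -> int:
        return self.y_z.shape[1]

    @property
    def p(self) -> int:
        return self.y_x.shape[1]


@dataclass
class SufficientStats:
    """Second-moment matrices Sigma_Z, Sigma_X, Sigma_ZX (1/n-scaled) and n."""

    sigma_z: np.ndarray
    sigma_x: np.ndarray
    sigma_zx: np.ndarray
    n: int

    def __post_init__(self):
        self.sigma_x = _check_symmetric(_as_2d(self.sigma_x, "sigma_x"), "sigma_x", 1e-8)
        self.sigma_z = _check_symmetric(_as_2d(self.sigma_z, "sigma_z"), "sigma_z", 1e-8)
        self.sigma_zx = _as_2d(self.sigma_zx, "sigma_zx")
        m, p = self.m, self.p
        if self.sigma_zx.shape != (m, p):
            raise ValueError(f"sigma_zx must be {m}x{p}, got {self.sigma_zx.shape}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, mat in (("sigma_z", self.sigma_z), ("sigma_x", self.sigma_x)):
            if mat.size:
                lo = float(np.linalg.eigvalsh(mat).min())
                if lo < -1e-8 * max(1.0, float(np.abs(mat).max())):
                    raise ValueError(f"{name} is not PSD (min eigenvalue {lo:.3e})")

    @property
    def m(self) -> int:
        return self.sigma_z.shape[0]

    @property
    def p(self) -> int:
        return self.sigma_x.shape[0]

    def joint(self) -> np.ndarray:
        """The stacked (m+p) x (m+p) second-moment matrix over (Z, X)."""
        return np.block([[self.sigma_z, self.sigma_zx], [self.sigma_zx.T, self.sigma_x]])


def suff_stats(data: Dataset) -> SufficientStats:
    """Second-moment matrices of a dataset.  No centering is applied: the model
    assumes zero-mean data (center upstream if needed)."""
    n = data.n
    return SufficientStats(
        sigma_z=data.y_z.T @ data.y_z / n,
        sigma_x=data.y_x.T @ data.y_x / n,
        sigma_zx=data.y_z.T @ data.y_x / n,
        n=n,
    )


@dataclass
class CRFParameters:
    """The four estimated blocks (S_X, L_X, S_ZX, L_ZX).

    ``S = [S_X; S_ZX]`` and ``L = [L_X; L_ZX]`` denote the (p+m) x p vertical
    stacks (X block on top).  Feasibility means S_X - L_X strictly PD and
    L_X PSD.
    """

    s_x: np.ndarray
    l_x: np.ndarray = None
    s_zx: np.ndarray = None
    l_zx: np.ndarray = None

    def __post_init__(self):
        self.s_x = _check_symmetric(_as_2d(self.s_x, "s_x"), "s_x")
        p = self.s_x.shape[0]
        if self.l_x is None:
            self.l_x = np.zeros((p, p))
        self.l_x = _check_symmetric(_as_2d(self.l_x, "l_x"), "l_x")
        if self.l_x.shape != (p, p):
            raise ValueError("l_x shape mismatch")
        if self.s_zx is None:
            self.s_zx = np.empty((0, p))
        self.s_zx = _as_2d(self.s_zx, "s_zx")
        m = self.s_zx.shape[0]
        if self.s_zx.shape[1] != p:
            raise ValueError("s_zx must have p columns")
        if self.l_zx is None:
            self.l_zx = np.zeros((m, p))
        self.l_zx = _as_2d(self.l_zx, "l_zx")
        if self.l_zx.shape != (m, p):
            raise ValueError("l_zx shape mismatch")

    @property
    def p(self) -> int:
        return self.s_x.shape[0]

    @property
    def m(self) -> int:
        return self.s_zx.shape[0]

    @property
    def S(self) -> np.ndarray:
        return np.vstack([self.s_x, self.s_zx])

    @property
    def L(self) -> np.ndarray:
        return np.vstack([self.l_x, self.l_zx])

    @property
    def r_x(self) -> np.ndarray:
        """Marginal conditional precision over X: S_X - L_X."""
        return self.s_x - self.l_x

    @property
    def r_zx(self) -> np.ndarray:
        return self.s_zx - self.l_zx

    def is_feasible(self, tol: float = 1e-10) -> bool:
        if float(np.linalg.eigvalsh(self.r_x).min()) <= 0.0:
            return False
        return float(np.linalg.eigvalsh(self.l_x).min()) >= -tol

    def copy(self) -> "CRFParameters":
        return CRFParameters(
            self.s_x.copy(), self.l_x.copy(), self.s_zx.copy(), self.l_zx.copy()
        )


@dataclass
class ConditionalLaw:
    """The implied conditional law: E[Y_X | Y_Z = z] = B^T z, Cov = PD matrix."""

    coefficient_map: np.ndarray  # m x p
    conditional_covariance: np.ndarray  # p x p, symmetric PD


def _chol_rx(params: CRFParameters):
    try:
        return cho_factor(params.r_x, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover - scipy raises its own
        raise FeasibilityError("S_X - L_X is not positive definite") from err


def log_likelihood(params: CRFParameters, stats: SufficientStats) -> float:
    """Conditional log-likelihood in sufficient-statistic form (per sample,
    without the -p/2 log(2 pi) constant):

    logdet(S_X-L_X) - Tr[Sigma_X (S_X-L_X)] - 2 Tr[Sigma_ZX (S_ZX-L_ZX)^T]
        - Tr[(S_X-L_X)^{-1} (S_ZX-L_ZX)^T Sigma_Z (S_ZX-L_ZX)].
    """
    if params.m != stats.m or params.p != stats.p:
        raise ValueError("parameter/stats dimension mismatch")
    r_x, r_zx = params.r_x, params.r_zx
    try:
        c, low = np.linalg.cholesky(r_x), True
    except np.linalg.LinAlgError as err:
        raise FeasibilityError("S_X - L_X is not positive definite") from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    val = logdet - float(np.sum(stats.sigma_x * r_x))
    if params.m:
        val -= 2.0 * float(np.sum(stats.sigma_zx * r_zx))
        # Tr(R_X^{-1} R_ZX^T Sigma_Z R_ZX) via triangular solves
        szr = stats.sigma_z @ r_zx  # m x p
        inv_term = cho_solve((c, low), (r_zx.T @ szr).T)  # p x p
        val -= float(np.trace(inv_term))
    return val


def _grad_R(r_x: np.ndarray, r_zx: np.ndarray, stats: SufficientStats):
    """Gradient of the log-likelihood with respect to (R_X, R_ZX) = (S-L) blocks."""
    c = np.linalg.cholesky(r_x)
    a = cho_solve((c, True), np.eye(r_x.shape[0]))  # R_X^{-1}
    a = 0.5 * (a + a.T)
    if r_zx.shape[0]:
        q = r_zx.T @ (stats.sigma_z @ r_zx)
        g_x = a - stats.sigma_x + a @ q @ a
        g_zx = -2.0 * stats.sigma_zx - 2.0 * stats.sigma_z @ (r_zx @ a)
    else:
        g_x = a - stats.sigma_x
        g_zx = np.empty((0, r_x.shape[0]))
    return 0.5 * (g_x + g_x.T), g_zx


def gradient(params: CRFParameters, stats: SufficientStats) -> CRFParameters:
    """Likelihood gradient, reported blockwise in a CRFParameters-shaped
    container.  Gradients of the symmetric blocks are symmetrized; the L-block
    gradients are the negations of the S-block gradients (the likelihood
    depends on S - L only)."""
    if not params.is_feasible(tol=1e-8):
        raise FeasibilityError("parameters are infeasible")
    g_x, g_zx = _grad_R(params.r_x, params.r_zx, stats)
    return CRFParameters(s_x=g_x, l_x=-g_x, s_zx=g_zx, l_zx=-g_zx)


def conditional_distribution(params: CRFParameters) -> ConditionalLaw:
    """The marginalized conditional law of the outputs given the inputs."""
    r_x, r_zx = params.r_x, params.r_zx
    try:
        c = np.linalg.cholesky(r_x)
    except np.linalg.LinAlgError as err:
        raise FeasibilityError("S_X - L_X is not positive definite") from err
    cov = cho_solve((c, True), np.eye(r_x.shape[0]))
    cov = 0.5 * (cov + cov.T)
    b = -r_zx @ cov  # -(S_ZX - L_ZX) (S_X - L_X)^{-1}, m x p
    return ConditionalLaw(coefficient_map=b, conditional_covariance=cov)


def penalty_value(
    params: CRFParameters, lam: float, gamma: float, penalize_diagonal: bool = True
) -> float:
    """lambda * (gamma ||S||_1 + (1-gamma) ||L||_*) on the stacked matrices."""
    l1 = float(np.abs(params.S).sum())
    if not penalize_diagonal:
        l1 -= float(np.abs(np.diag(params.s_x)).sum())
    nuc = float(np.linalg.svd(params.L, compute_uv=False).sum()) if params.L.size else 0.0
    return lam * (gamma * l1 + (1.0 - gamma) * nuc)


def objective_value(
    params: CRFParameters,
    stats: SufficientStats,
    lam: float,
    gamma: float,
    penalize_diagonal: bool = True,
) -> float:
    """Penalized negative log-likelihood: -l + lambda(gamma ||S||_1 + (1-gamma)||L||_*)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return -log_likelihood(params, stats) + penalty_value(
        params, lam, gamma, penalize_diagonal
    )


def conditional_mle(stats: SufficientStats, ridge: float = 0.0) -> CRFParameters:
    """Closed-form unpenalized MLE of the conditional model (no latent split):
    S_X = (Sigma_X - Sigma_ZX^T Sigma_Z^{-1} Sigma_ZX)^{-1},
    S_ZX = -Sigma_Z^{-1} Sigma_ZX S_X, with L = 0."""
    p, m = stats.p, stats.m
    if m:
        sz = stats.sigma_z + ridge * np.eye(m)
        b = np.linalg.solve(sz, stats.sigma_zx)  # m x p regression coefficients
        cond_cov = stats.sigma_x - stats.sigma_zx.T @ b
    else:
        b = np.empty((0, p))
        cond_cov = stats.sigma_x
    cond_cov = 0.5 * (cond_cov + cond_cov.T) + ridge * np.eye(p)
    s_x = np.linalg.inv(cond_cov)
    s_x = 0.5 * (s_x + s_x.T)
    s_zx = -b @ s_x
    return CRFParameters(s_x=s_x, s_zx=s_zx)


def penalty_to_paper(lam: float, gamma: float) -> tuple[float, float]:
    """Convert the (0,1)-parameterized penalty lambda(gamma||S||_1+(1-gamma)||L||_*)
    to the lambda_n(gamma_n ||S||_1 + ||L||_*) form: returns (lambda_n, gamma_n)."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly in (0, 1) for conversion")
    return lam * (1.0 - gamma), gamma / (1.0 - gamma)


def penalty_from_paper(lam_n: float, gamma_n: float) -> tuple[float, float]:
    """Inverse of :func:`penalty_to_paper`: returns (lambda, gamma) with gamma in (0,1)."""
    if gamma_n <= 0:
        raise ValueError("gamma_n must be positive")
    gamma = gamma_n / (1.0 + gamma_n)
    lam = lam_n * (1.0 + gamma_n)
    return lam, gamma
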