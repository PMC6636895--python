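"""Model / Results front-end for the four estimators.

``LSCGGM`` is the model object: it holds the data (or sufficient statistics),
the method configuration and preprocessing choices.  ``fit`` returns an
:class:`LSCGGMResults` carrying the estimated blocks, convergence diagnostics
and a ``summary()`` table; ``fit_path`` traces a regularization path.

Methods:

* ``lscggm`` - sparse + low-rank conditional model (the full estimator),
* ``scggm``  - sparse conditional model (low-rank component frozen at zero),
* ``lrps``   - low-rank plus sparse decomposition of the JOINT precision over
  (Z, X), with the relevant sub-blocks extracted afterwards,
* ``glasso`` - graphical lasso on the joint precision (lrps with L frozen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admm import FitResult, SolverOptions, fit_admm, kkt_report
from .core import (
    CRFParameters,
    Dataset,
    SufficientStats,
    conditional_distribution,
    suff_stats,
)
from .sdp import build_sdp, solve_sdp

__all__ = [
    "METHODS",
    "MethodConfig",
    "RegPath",
    "PathEntry",
    "LSCGGM",
    "LSCGGMResults",
    "fit_method",
    "regularization_path",
    "support_edges",
    "latent_rank",
    "lambda_max",
]

METHODS = ("lscggm", "lrps", "scggm", "glasso")
_CONDITIONAL = {"lscggm": False, "scggm": False, "lrps": True, "glasso": True}
_FREEZE_L = {"lscggm": False, "scggm": True, "lrps": False, "glasso": True}

SUPPORT_THRESHOLD = 1e-6
RANK_THRESHOLD = 1e-6


@dataclass
class MethodConfig:
    """A method plus its (lambda, gamma) grids."""

    method: str = "lscggm"
    lambdas: tuple = ()
    gammas: tuple = (0.5,)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        self.lambdas = tuple(float(v) for v in self.lambdas)
        self.gammas = tuple(float(v) for v in self.gammas)
        if any(l <= 0 for l in self.lambdas):
            raise ValueError("lambda grid must be positive")
        if list(self.lambdas) != sorted(self.lambdas, reverse=True):
            raise ValueError("lambda grid must be sorted decreasing")
        if not self.gammas:
            raise ValueError("gamma grid must be nonempty")
        hi = 1.0 if self.method in ("scggm", "glasso") else 1.0 - 1e-12
        if any(not 0.0 < g <= hi for g in self.gammas):
            raise ValueError("gamma values out of range for this method")
        if self.method in ("scggm", "glasso") and len(self.gammas) != 1:
            raise ValueError(f"{self.method} takes a singleton gamma grid")


def support_edges(s_x: np.ndarray, threshold: float = SUPPORT_THRESHOLD) -> set:
    """Undirected off-diagonal support of a (possibly asymmetric-up-to-solver-
    noise) square matrix, symmetrized by max(|.|, |.|^T)."""
    a = np.abs(np.asarray(s_x))
    a = np.maximum(a, a.T)
    p = a.shape[0]
    return {(i, j) for i in range(p) for j in range(i + 1, p) if a[i, j] > threshold}


def latent_rank(l_stacked: np.ndarray, rel_threshold: float = RANK_THRESHOLD) -> int:
    if l_stacked.size == 0:
        return 0
    s = np.linalg.svd(l_stacked, compute_uv=False)
    if s[0] <= 0:
        return 0
    return int(np.sum(s > rel_threshold * s[0]))


@dataclass
class PathEntry:
    lam: float
    gamma: float
    result: FitResult
    support: set
    rank: int


@dataclass
class RegPath:
    method: str
    entries: list = field(default_factory=list)

    def supports(self, gamma=None):
        return [e.support for e in self.entries if gamma is None or e.gamma == gamma]

    def gammas(self):
        seen = []
        for e in self.entries:
            if e.gamma not in seen:
                seen.append(e.gamma)
        return seen


class LSCGGM:
    """Latent sparse conditional Gaussian graphical model.

    Parameters
    ----------
    y_x : (n, p) array
        Outputs (the variables whose graph is the target).
    y_z : (n, m) array, optional
        Inputs to condition on; omit for a purely marginal model.
    method : one of "lscggm", "scggm", "lrps", "glasso"
    center, standardize : bool
        Column preprocessing applied before forming second moments.  The model
        itself assumes zero-mean data; simulator output is generated zero-mean
        so the defaults are off.
    penalize_diagonal : bool
        Whether the diagonal of S_X enters the l1 penalty (default True,
        matching the printed objective).
    """

    def __init__(
        self,
        y_x,
        y_z=None,
        method: str = "lscggm",
        x_names=None,
        z_names=None,
        center: bool = False,
        standardize: bool = False,
        penalize_diagonal: bool = True,
    ):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        self.penalize_diagonal = penalize_diagonal
        y_x = np.asarray(y_x, dtype=float)
        y_z = np.empty((y_x.shape[0], 0)) if y_z is None else np.asarray(y_z, dtype=float)
        if center or standardize:
            y_x = y_x - y_x.mean(axis=0)
            y_z = y_z - y_z.mean(axis=0) if y_z.size else y_z
        if standardize:
            y_x = y_x / y_x.std(axis=0)
            if y_z.size:
                y_z = y_z / y_z.std(axis=0)
        self.data = Dataset(y_z=y_z, y_x=y_x, z_labels=z_names, x_labels=x_names)
        self.stats = suff_stats(self.data)
        self._work_stats = self._working_stats()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x_cols=None, z_cols=None, z_prefix=None, **kwargs
    ) -> "LSCGGM":
        """Build from a DataFrame; input columns given explicitly or by prefix."""
        cols = list(df.columns)
        if z_cols is None and z_prefix is not None:
            z_cols = [c for c in cols if str(c).startswith(z_prefix)]
        z_cols = list(z_cols or [])
        if x_cols is None:
            x_cols = [c for c in cols if c not in set(z_cols)]
        x_cols = list(x_cols)
        return cls(
            y_x=df[x_cols].to_numpy(float),
            y_z=df[z_cols].to_numpy(float) if z_cols else None,
            x_names=[str(c) for c in x_cols],
            z_names=[str(c) for c in z_cols],
            **kwargs,
        )

    @classmethod
    def from_stats(cls, stats: SufficientStats, method: str = "lscggm", **kwargs):
        obj = cls.__new__(cls)
        obj.method = method
        obj.penalize_diagonal = kwargs.get("penalize_diagonal", True)
        obj.data = None
        obj.stats = stats
        obj._work_stats = obj._working_stats()
        return obj

    # -- internals ---------------------------------------------------------

    def _working_stats(self) -> SufficientStats:
        """Conditional stats for the conditional methods; the joint second
        moment recast as an m=0 problem for lrps/glasso."""
        if not _CONDITIONAL[self.method]:
            return self.stats
        joint = self.stats.joint()
        k = joint.shape[0]
        return SufficientStats(
            sigma_z=np.empty((0, 0)),
            sigma_x=joint,
            sigma_zx=np.empty((0, k)),
            n=self.stats.n,
        )

    def _extract(self, result: FitResult) -> CRFParameters:
        """Conditional-shape parameters.  For the joint methods the relevant
        sub-blocks of the joint sparse/low-rank components are extracted."""
        if not _CONDITIONAL[self.method]:
            return result.params
        m, p = self.stats.m, self.stats.p
        P = result.params
        return CRFParameters(
            s_x=P.s_x[m:, m:],
            l_x=P.l_x[m:, m:],
            s_zx=P.s_x[:m, m:],
            l_zx=P.l_x[:m, m:],
        )

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        lam: float,
        gamma: float = 0.5,
        options: SolverOptions | None = None,
        warm_start: CRFParameters | None = None,
        solver: str = "admm",
    ) -> "LSCGGMResults":
        if options is None:
            options = SolverOptions(penalize_diagonal=self.penalize_diagonal)
        freeze = _FREEZE_L[self.method]
        if solver == "admm":
            raw = fit_admm(
                self._work_stats, lam, gamma, options=options,
                warm_start=warm_start, freeze_L=freeze,
            )
        elif solver == "sdp":
            problem = build_sdp(self._work_stats, lam, gamma, freeze_L=freeze)
            raw = solve_sdp(problem, warm_start=warm_start)
        else:
            raise ValueError(f"unknown solver {solver!r}")
        raw.method = self.method
        return LSCGGMResults(self, raw)

    def lambda_max(self, gamma: float = 0.5, options: SolverOptions | None = None,
                   tol: float = 0.05) -> float:
        """Smallest lambda (within relative tol) giving an empty off-diagonal
        support of S_X, found by doubling + bisection."""
        if options is None:
            options = SolverOptions(
                tol_primal=1e-4, tol_dual=1e-4, max_iter=300,
                penalize_diagonal=self.penalize_diagonal,
            )
        hi = max(1e-3, float(np.abs(self._work_stats.joint()).max()))
        for _ in range(30):
            if not self.fit(hi, gamma, options=options).support:
                break
            hi *= 2.0
        lo = hi / 2.0
        # walk the bracket down until support appears at the lower end
        while lo > 1e-8 and not self.fit(lo, gamma, options=options).support:
            hi = lo
            lo /= 2.0
        while (hi - lo) / hi > tol:
            mid = np.sqrt(lo * hi)
            if self.fit(mid, gamma, options=options).support:
                lo = mid
            else:
                hi = mid
        return hi

    def fit_path(
        self,
        lambdas=None,
        gammas=(0.5,),
        n_lambda: int = 25,
        lambda_min_ratio: float = 0.01,
        warm_start: bool = True,
        options: SolverOptions | None = None,
    ) -> RegPath:
        """One fit per (lambda, gamma), warm-started along decreasing lambda
        within each gamma.  Individual non-convergences are recorded and the
        path continues."""
        if options is None:
            options = SolverOptions(penalize_diagonal=self.penalize_diagonal)
        path = RegPath(method=self.method)
        for gamma in gammas:
            lams = lambdas
            if lams is None:
                lmax = self.lambda_max(gamma)
                lams = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
            prev = None
            for lam in lams:
                res = self.fit(float(lam), float(gamma), options=options,
                               warm_start=prev if warm_start else None)
                if warm_start:
                    prev = res.raw.params
                path.entries.append(
                    PathEntry(float(lam), float(gamma), res.raw,
                              res.support, res.latent_rank)
                )
        return path


class LSCGGMResults:
    """Fit results: estimated blocks, diagnostics, summary."""

    def __init__(self, model: LSCGGM, raw: FitResult):
        self.model = model
        self.raw = raw
        self.params = model._extract(raw)

    # estimated blocks in the conditional shape
    @property
    def s_x(self):
        return self.params.s_x

    @property
    def l_x(self):
        return self.params.l_x

    @property
    def s_zx(self):
        return self.params.s_zx

    @property
    def l_zx(self):
        return self.params.l_zx

    @property
    def objective(self):
        return self.raw.objective

    @property
    def converged(self):
        return self.raw.converged

    @property
    def support(self) -> set:
        return support_edges(self.s_x)

    @property
    def latent_rank(self) -> int:
        return latent_rank(self.params.L)

    def conditional_law(self):
        return conditional_distribution(self.params)

    def kkt(self) -> dict:
        return kkt_report(
            self.raw, self.model._work_stats, self.raw.lam, self.raw.gamma,
            penalize_diagonal=self.model.penalize_diagonal,
        )

    def edge_list(self) -> list[tuple[str, str]]:
        labels = (
            self.model.data.x_labels
            if self.model.data is not None
            else [f"x{i + 1}" for i in range(self.params.p)]
        )
        return sorted((labels[i], labels[j]) for i, j in self.support)

    def summary(self) -> str:
        stats = self.model.stats
        rows = [
            ("method", self.raw.method),
            ("p (outputs)", stats.p),
            ("m (inputs)", stats.m),
            ("n (samples)", stats.n),
            ("lambda", f"{self.raw.lam:.6g}"),
            ("gamma", f"{self.raw.gamma:.6g}"),
            ("converged", self.raw.converged),
            ("iterations", self.raw.iterations),
            ("objective", f"{self.raw.objective:.6f}"),
            ("edges in S_X", len(self.support)),
            ("rank of L", self.latent_rank),
        ]
        if self.raw.primal_residuals:
            rows.append(("final primal residual", f"{self.raw.primal_residuals[-1]:.3e}"))
            rows.append(("final dual residual", f"{self.raw.dual_residuals[-1]:.3e}"))
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Latent sparse conditional GGM results", "=" * 42]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional front-end mirroring the module surface
# ---------------------------------------------------------------------------

def _model_from(config: MethodConfig, data_or_stats, **kwargs) -> LSCGGM:
    if isinstance(data_or_stats, SufficientStats):
        return LSCGGM.from_stats(data_or_stats, method=config.method, **kwargs)
    if isinstance(data_or_stats, Dataset):
        return LSCGGM(
            y_x=data_or_stats.y_x, y_z=data_or_stats.y_z,
            x_names=data_or_stats.x_labels, z_names=data_or_stats.z_labels,
            method=config.method, **kwargs,
        )
    raise TypeError("expected a Dataset or SufficientStats")


def fit_method(
    config: MethodConfig, data_or_stats, lam: float = None, gamma: float = None,
    options: SolverOptions | None = None, **kwargs
) -> LSCGGMResults:
    model = _model_from(config, data_or_stats, **kwargs)
    lam = config.lambdas[0] if lam is None else lam
    gamma = config.gammas[0] if gamma is None else gamma
    return model.fit(lam, gamma, options=options)


def regularization_path(
    config: MethodConfig, data_or_stats, warm_start: bool = True,
    options: SolverOptions | None = None, **kwargs
) -> RegPath:
    model = _model_from(config, data_or_stats, **kwargs)
    return model.fit_path(
        lambdas=config.lambdas or None, gammas=config.gammas,
        warm_start=warm_start, options=options,
    )


def lambda_max(data_or_stats, method: str = "lscggm", gamma: float = 0.5) -> float:
    config = MethodConfig(method=method, gammas=(gamma,))
    return _model_from(config, data_or_stats).lambda_max(gamma)
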