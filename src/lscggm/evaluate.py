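"""Support-recovery scoring: precision/recall curves over the lambda path,
AUC per gamma, volume under the surface (VUS) over the (lambda, gamma) grid,
sign/rank consistency checks, and identifiability diagnostics.

Edges are counted over the p(p-1)/2 undirected off-diagonal pairs of S_X;
an empty estimate has precision 1 by convention so curves start at recall 0.
AUC integrates the monotonized upper precision envelope over recall, and the
fixed-recall precision table reads that same envelope at recalls 0.1, ..., 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import RegPath, latent_rank, support_edges

__all__ = [
    "PRSurface",
    "DiagnosticsReport",
    "precision_recall",
    "pr_curve",
    "auc",
    "fixed_recall_precisions",
    "vus",
    "consistency_check",
    "sign_f1",
    "identifiability_bounds",
]


def precision_recall(est_support: set, true_support: set) -> tuple[float, float]:
    """Precision and recall of an estimated undirected edge set."""
    if not true_support:
        raise ValueError("true support is empty")
    est = set(est_support)
    inter = len(est & set(true_support))
    precision = inter / len(est) if est else 1.0
    recall = inter / len(true_support)
    return precision, recall


def pr_curve(path: RegPath, true_support: set, gamma=None) -> list[tuple[float, float]]:
    """(recall, precision) points traced along the lambda path, ordered by
    recall."""
    entries = [e for e in path.entries if gamma is None or e.gamma == gamma]
    if not entries:
        raise ValueError("path has no entries (for this gamma)")
    pts = []
    for e in entries:
        prec, rec = precision_recall(e.support, true_support)
        pts.append((rec, prec))
    return sorted(pts)


def _envelope(curve):
    """Recall break points and the suffix-max (monotonized) precision."""
    pts = sorted(curve)
    recalls = np.array([r for r, _ in pts])
    precisions = np.array([p for _, p in pts])
    suffmax = np.maximum.accumulate(precisions[::-1])[::-1]
    return recalls, suffmax


def interp_precision(curve, recall: float) -> float:
    """Monotonized-envelope precision at a recall level: the best precision
    among path points achieving at least that recall (0 if none does)."""
    recalls, suffmax = _envelope(curve)
    idx = np.searchsorted(recalls, recall, side="left")
    if idx >= len(recalls):
        return 0.0
    return float(suffmax[idx])


def auc(curve) -> float:
    """Area under the monotonized precision envelope, integrated over
    recall in [0, 1] (zero beyond the largest achieved recall)."""
    recalls, suffmax = _envelope(curve)
    area = recalls[0] * suffmax[0]
    if len(recalls) > 1:
        area += float(np.sum(np.diff(recalls) * suffmax[1:]))
    return float(area)


def fixed_recall_precisions(curve, recalls=None) -> dict:
    if recalls is None:
        recalls = [round(0.1 * i, 1) for i in range(1, 11)]
    return {r: interp_precision(curve, r) for r in recalls}


@dataclass
class PRSurface:
    """Per-gamma precision/recall curves with AUC and VUS summaries."""

    gammas: list
    curves: dict = field(default_factory=dict)  # gamma -> curve
    aucs: dict = field(default_factory=dict)  # gamma -> AUC

    @classmethod
    def from_path(cls, path: RegPath, true_support: set) -> "PRSurface":
        gammas = path.gammas()
        surf = cls(gammas=gammas)
        for g in gammas:
            c = pr_curve(path, true_support, gamma=g)
            surf.curves[g] = c
            surf.aucs[g] = auc(c)
        return surf

    @property
    def best_auc(self) -> float:
        return max(self.aucs.values())

    def vus(self) -> float:
        return vus([self.aucs[g] for g in self.gammas], self.gammas)

    def fixed_recall_table(self, recalls=None) -> dict:
        return {g: fixed_recall_precisions(self.curves[g], recalls) for g in self.gammas}


def vus(aucs, gammas) -> float:
    """Trapezoidal integral of AUC(gamma) over the gamma grid, normalized by
    the gamma range, in [0, 1]."""
    gammas = np.asarray(gammas, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if len(gammas) < 2:
        raise ValueError("need at least two gamma values for a VUS")
    order = np.argsort(gammas)
    g, a = gammas[order], aucs[order]
    return float(np.trapezoid(a, g) / (g[-1] - g[0]))


def sign_f1(est_s_x: np.ndarray, true_s_x: np.ndarray,
            threshold: float = 1e-6) -> float:
    """F1 of off-diagonal sign-pattern recovery of S_X: an estimated edge
    counts as a true positive only when its sign matches the truth."""
    p = est_s_x.shape[0]
    est = support_edges(est_s_x, threshold)
    true = support_edges(true_s_x, 0.0)
    if not est and not true:
        return 1.0
    tp = sum(
        1 for (i, j) in est & true
        if np.sign(est_s_x[i, j]) == np.sign(true_s_x[i, j])
    )
    prec = tp / len(est) if est else 1.0
    rec = tp / len(true) if true else 1.0
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)


def consistency_check(params, truth_params, support_threshold: float = 1e-6) -> dict:
    """Sign-pattern / rank / PSD agreement of a fit against the truth.

    ``params`` and ``truth_params`` are CRFParameters (the truth typically via
    GenerativeModel.params()).  Reports exact sign agreement of the stacked S
    (with the support threshold), rank agreement of L, the PSD status of L_X,
    and the error norms max(||S-S*||_inf, ||L-L*||_2).
    """
    S, S_true = params.S, truth_params.S
    sign_est = np.sign(np.where(np.abs(S) > support_threshold, S, 0.0))
    sign_true = np.sign(S_true)
    sign_match = bool(np.array_equal(sign_est, sign_true))
    rank_est = latent_rank(params.L)
    rank_true = latent_rank(truth_params.L, rel_threshold=1e-9)
    lmin = float(np.linalg.eigvalsh(params.l_x).min()) if params.l_x.size else 0.0
    err_s = float(np.abs(S - S_true).max(initial=0.0))
    err_l = (
        float(np.linalg.svd(params.L - truth_params.L, compute_uv=False).max(initial=0.0))
        if params.L.size else 0.0
    )
    return {
        "sign_match": sign_match,
        "rank_match": rank_est == rank_true,
        "rank_est": rank_est,
        "rank_true": rank_true,
        "l_x_psd": lmin >= -1e-8,
        "err_s_inf": err_s,
        "err_l_2": err_l,
        "max_error": max(err_s, err_l),
        "sign_f1_sx": sign_f1(params.s_x, truth_params.s_x, support_threshold),
    }


@dataclass
class DiagnosticsReport:
    max_degree: int
    mu_bound: float
    xi_bound: float
    latent_rank: int


def identifiability_bounds(truth_params) -> DiagnosticsReport:
    """Documented diagnostic proxies for the rank-sparsity incoherence
    quantities.

    * ``mu_bound``: the maximum row/column support cardinality of the stacked
      S* (sparsity patterns with few nonzeros per row/column have small
      spectral diffusivity; the degree is the computable upper-bound proxy).
    * ``xi_bound``: 2 max_i ||P_U e_i||_2 over the column and row spaces of
      the stacked L* (small when latent effects are diffuse; 2/sqrt(p) for a
      single uniform confounder, 2 when L* is diagonal).
    """
    S = truth_params.S
    nz = S != 0
    max_deg = int(max(nz.sum(axis=0).max(initial=0), nz.sum(axis=1).max(initial=0)))
    L = truth_params.L
    rank = latent_rank(L, rel_threshold=1e-9)
    if rank == 0:
        xi = 0.0
    else:
        u, s, vt = np.linalg.svd(L, full_matrices=False)
        u_r = u[:, :rank]
        v_r = vt[:rank].T
        col = float(np.sqrt((u_r ** 2).sum(axis=1)).max())
        row = float(np.sqrt((v_r ** 2).sum(axis=1)).max())
        xi = 2.0 * max(col, row)
    return DiagnosticsReport(
        max_degree=max_deg, mu_bound=float(max_deg), xi_bound=xi, latent_rank=rank
    )
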