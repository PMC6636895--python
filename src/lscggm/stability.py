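"""Complementary-pairs stability selection with expected-false-discovery
control, plus Jaccard similarity analysis across the gamma grid.

B complementary pairs of disjoint floor(n/2) subsamples are drawn; on each
subsample the lambda path is fitted and an edge is counted once per subsample
if it is selected anywhere along the path ("pointwise" max-over-path
counting).  The inclusion probability of an edge is the fraction of the 2B
subsamples selecting it.  The threshold tau on inclusion probabilities is the
smallest value whose bound on the expected number of falsely selected edges,

    E(V) <= q^2 / ((2 tau - 1) p_cand),      p_cand = p(p-1)/2,

meets the requested error budget (default: at most one falsely discovered
edge), where q is the average per-subsample selected-set size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admm import SolverOptions
from .core import Dataset
from .model import LSCGGM, MethodConfig

__all__ = [
    "StabilityResult",
    "GraphEstimate",
    "ev_bound",
    "tau_for_budget",
    "complementary_pairs_select",
    "jaccard",
    "gamma_similarity_matrix",
    "stable_region",
]


@dataclass
class GraphEstimate:
    """An undirected graph over the outputs, labeled by node names."""

    nodes: list
    edges: set

    def __post_init__(self):
        self.nodes = list(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loops are not allowed")


@dataclass
class StabilityResult:
    inclusion_probabilities: dict  # edge (i, j) -> probability
    selected: set
    tau: float
    B: int
    q: float
    gamma: float
    error_budget: float
    warning: str | None = None

    def graph(self, labels=None) -> GraphEstimate:
        if labels is None:
            p = 1 + max((j for _, j in self.inclusion_probabilities), default=0)
            labels = [f"x{i + 1}" for i in range(p)]
        return GraphEstimate(
            nodes=labels,
            edges={(labels[i], labels[j]) for i, j in self.selected},
        )


def ev_bound(q: float, tau: float, p_cand: int) -> float:
    """Meinshausen-Buhlmann bound on the expected number of false selections."""
    if tau <= 0.5:
        return np.inf
    return q * q / ((2.0 * tau - 1.0) * p_cand)


def tau_for_budget(q: float, p_cand: int, error_budget: float = 1.0) -> float:
    """Smallest threshold tau in (1/2, 1] meeting ev_bound <= error_budget,
    or a value > 1 when the budget is unachievable."""
    return 0.5 * (1.0 + q * q / (error_budget * p_cand))


def stability_lambda_grid(
    data: Dataset,
    config: MethodConfig,
    gamma: float | None = None,
    n_lambda: int = 6,
    q_target: float | None = None,
    error_budget: float = 1.0,
    options: SolverOptions | None = None,
):
    """A lambda region suited to stability selection: from the empty-support
    lambda_max down to the lambda at which the full-data fit selects about
    q_target edges.

    Subsample selected-set sizes drive the false-discovery bound through q^2,
    so the region must stay in the sparse part of the path; the default
    target is sqrt(0.8 x error_budget x p_cand), the largest average
    selected-set size for which a threshold tau <= 0.9 can still meet the
    budget.
    """
    gamma = config.gammas[0] if gamma is None else gamma
    p = data.p
    p_cand = p * (p - 1) // 2
    if q_target is None:
        q_target = np.sqrt(0.8 * error_budget * p_cand)
    model = LSCGGM(y_x=data.y_x, y_z=data.y_z, method=config.method)
    lam_max = model.lambda_max(gamma, options=options)
    lo, hi = lam_max / 64.0, lam_max
    for _ in range(12):
        mid = np.sqrt(lo * hi)
        size = len(model.fit(mid, gamma, options=options).support)
        if size > q_target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.1:
            break
    return np.geomspace(lam_max, hi, n_lambda)


def complementary_pairs_select(
    data: Dataset,
    config: MethodConfig,
    lambdas,
    gamma: float | None = None,
    B: int = 50,
    error_budget: float = 1.0,
    tau: float | None = None,
    seed: int = 0,
    options: SolverOptions | None = None,
    pointwise_per_lambda: bool = False,
) -> StabilityResult:
    """Complementary-pairs stability selection along a fixed lambda grid.

    ``tau`` overrides the error-budget calibration when given.  With
    ``pointwise_per_lambda`` the selection frequency is computed per lambda
    and the maximum over the path is taken afterwards (the alternative
    pointwise mode); the default counts an edge once per subsample if it is
    selected anywhere on the path.
    """
    if data.n < 4:
        raise ValueError("need n >= 4 for complementary pairs")
    if B < 1:
        raise ValueError("B must be >= 1")
    gamma = config.gammas[0] if gamma is None else gamma
    lambdas = tuple(sorted((float(l) for l in lambdas), reverse=True))
    p = data.p
    p_cand = p * (p - 1) // 2
    half = data.n // 2
    rng = np.random.default_rng(seed)

    n_points = len(lambdas) if pointwise_per_lambda else 1
    counts = [dict() for _ in range(n_points)]
    sizes = []
    for _ in range(B):
        perm = rng.permutation(data.n)
        for idx in (perm[:half], perm[half:2 * half]):
            sub = Dataset(y_z=data.y_z[idx], y_x=data.y_x[idx],
                          z_labels=data.z_labels, x_labels=data.x_labels)
            model = LSCGGM(y_x=sub.y_x, y_z=sub.y_z, method=config.method)
            path = model.fit_path(lambdas=lambdas, gammas=(gamma,),
                                  warm_start=True, options=options)
            union = set()
            for j, entry in enumerate(path.entries):
                if pointwise_per_lambda:
                    for e in entry.support:
                        counts[j][e] = counts[j].get(e, 0) + 1
                union |= entry.support
            if not pointwise_per_lambda:
                for e in union:
                    counts[0][e] = counts[0].get(e, 0) + 1
            sizes.append(len(union))

    n_sub = 2 * B
    probs = {}
    for cdict in counts:
        for e, c in cdict.items():
            probs[e] = max(probs.get(e, 0.0), c / n_sub)
    q = float(np.mean(sizes)) if sizes else 0.0

    warning = None
    if tau is None:
        tau = tau_for_budget(q, p_cand, error_budget)
        if tau > 1.0:
            warning = (
                f"error budget {error_budget} unachievable with q={q:.2f}: "
                "returning empty selection"
            )
            tau = np.inf
        tau = max(tau, 0.5 + 1.0 / (2 * n_sub))
    selected = {e for e, pr in probs.items() if pr >= tau}
    return StabilityResult(
        inclusion_probabilities=probs, selected=selected, tau=float(tau),
        B=B, q=q, gamma=gamma, error_budget=error_budget, warning=warning,
    )


def jaccard(g1: GraphEstimate, g2: GraphEstimate) -> float:
    """|E1 intersection E2| / |E1 union E2|; 1 when both edge sets are empty."""
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs are over different node sets")

    def norm(edges):
        return {tuple(sorted(e)) for e in edges}

    e1, e2 = norm(g1.edges), norm(g2.edges)
    union = e1 | e2
    if not union:
        return 1.0
    return len(e1 & e2) / len(union)


def gamma_similarity_matrix(graphs: list[GraphEstimate]) -> np.ndarray:
    """Pairwise Jaccard similarity of the graphs selected across the gamma
    grid; symmetric with unit diagonal."""
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    k = len(graphs)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = jaccard(graphs[i], graphs[j])
    return sim


def stable_region(sim: np.ndarray, threshold: float = 0.9) -> tuple[int, int]:
    """Largest contiguous index block whose pairwise similarities all exceed
    the threshold: returns (start, stop) as a half-open range."""
    k = sim.shape[0]
    best = (0, 1)
    for i in range(k):
        for j in range(i + 1, k + 1):
            if j - i <= best[1] - best[0]:
                continue
            block = sim[i:j, i:j]
            if block.min() >= threshold:
                best = (i, j)
    return best
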