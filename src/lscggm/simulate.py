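"""Structured ground-truth models and samplers for benchmarking.

The family of generative models is indexed by two integers (d_Z, d_H) with
p = 2^k outputs and m = p inputs:

* the graph over the outputs is a chain of p variables with every fifth link
  removed: (S*_X)_ij != 0 off the diagonal iff i = j + 1 and i != 0 (mod 5)
  (1-based indices);
* there are h = 2^{d_H} latent confounders, each impacting exactly p / 2^{d_H}
  outputs, and each output loads on exactly one confounder, so
  L*_X = M_XH M_H^{-1} M_XH^T has rank 2^{d_H};
* the input-effect matrix M*_ZX has rank exactly 2^{d_Z} with exactly
  p / 2^{d_Z} nonzero entries in every row and every column (a block design:
  2^{d_Z} groups of inputs act on disjoint output blocks with rank-one
  within-block structure);
* the inputs have no latent loading (M*_ZH = 0, hence L*_ZX = 0);
* input entries are drawn iid from a t-distribution with 4 degrees of
  freedom; outputs are drawn from the implied Gaussian conditional law.

Effect magnitudes are uniform on +/-[0.2, 0.4]; diagonals of the joint
conditional precision over (X, H) are set to the off-diagonal absolute row
sum plus 0.5 (strict diagonal dominance, hence positive definiteness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .core import CRFParameters, Dataset

__all__ = [
    "EffectConfig",
    "SimDesign",
    "GenerativeModel",
    "make_chain_SX",
    "make_latent_structure",
    "make_MZX",
    "make_model",
    "sample_dataset",
    "simulation_grid",
]


@dataclass
class EffectConfig:
    """Distribution settings for nonzero magnitudes."""

    low: float = 0.2
    high: float = 0.4
    diag_slack: float = 0.5
    mh_perturb: float = 0.05

    def draw(self, rng, size):
        mag = rng.uniform(self.low, self.high, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign


@dataclass
class SimDesign:
    k: int = 5
    d_z: int = 2
    d_h: int = 2
    n: int = 3000
    seed: int = 0
    effect_config: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("d_z", "d_h"):
            v = getattr(self, name)
            if not 0 <= v <= self.k:
                raise ValueError(f"{name} must lie in 0..k={self.k}")

    @property
    def p(self) -> int:
        return 2 ** self.k

    @property
    def m(self) -> int:
        return self.p

    @property
    def h(self) -> int:
        return 2 ** self.d_h


@dataclass
class GenerativeModel:
    """Ground-truth matrices of a design and the derived (S*, L*)."""

    m_x: np.ndarray  # p x p, = S*_X
    m_h: np.ndarray  # h x h PD
    m_xh: np.ndarray  # p x h
    m_zx: np.ndarray  # m x p, = S*_ZX
    design: SimDesign | None = None

    def __post_init__(self):
        joint = self.joint_precision()
        if np.linalg.eigvalsh(joint).min() <= 0:
            raise ValueError("joint conditional precision over (X, H) is not PD")

    @property
    def p(self) -> int:
        return self.m_x.shape[0]

    @property
    def m(self) -> int:
        return self.m_zx.shape[0]

    @property
    def h(self) -> int:
        return self.m_h.shape[0]

    def joint_precision(self) -> np.ndarray:
        return np.block([[self.m_x, self.m_xh], [self.m_xh.T, self.m_h]])

    @property
    def s_x(self) -> np.ndarray:
        return self.m_x

    @property
    def l_x(self) -> np.ndarray:
        lx = self.m_xh @ np.linalg.solve(self.m_h, self.m_xh.T)
        return 0.5 * (lx + lx.T)

    @property
    def s_zx(self) -> np.ndarray:
        return self.m_zx

    @property
    def l_zx(self) -> np.ndarray:
        return np.zeros_like(self.m_zx)  # M*_ZH = 0 in these designs

    @property
    def r_x(self) -> np.ndarray:
        """Marginal conditional precision of the outputs, S*_X - L*_X."""
        return self.s_x - self.l_x

    def params(self) -> CRFParameters:
        return CRFParameters(
            s_x=self.s_x, l_x=self.l_x, s_zx=self.s_zx, l_zx=self.l_zx
        )

    def true_edges(self) -> set:
        a = np.abs(self.m_x)
        a = np.maximum(a, a.T)
        p = self.p
        return {(i, j) for i in range(p) for j in range(i + 1, p) if a[i, j] > 0}


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def chain_edges(p: int) -> list[tuple[int, int]]:
    """0-based undirected chain edges with every fifth link removed
    (1-based rule: i = j + 1 and i != 0 mod 5)."""
    return [(i - 1, i - 2) for i in range(2, p + 1) if i % 5 != 0]


def make_chain_SX(p: int, effect_config: EffectConfig | None = None, seed=0) -> np.ndarray:
    """Chain-structured sparse conditional precision over the outputs."""
    if p < 2:
        raise ValueError("p must be >= 2")
    cfg = effect_config or EffectConfig()
    rng = _rng(seed)
    s = np.zeros((p, p))
    for i, j in chain_edges(p):
        v = cfg.draw(rng, ())
        s[i, j] = s[j, i] = v
    np.fill_diagonal(s, np.abs(s).sum(axis=1) + cfg.diag_slack)
    return s


def make_latent_structure(
    p: int, d_h: int, effect_config: EffectConfig | None = None, seed=0
) -> tuple[np.ndarray, np.ndarray]:
    """(M_H, M_XH): h = 2^{d_h} confounders, each impacting exactly p / h
    outputs, each output tied to exactly one confounder."""
    k = int(round(np.log2(p)))
    if 2 ** k != p:
        raise ValueError("p must be a power of two")
    if not 0 <= d_h <= k:
        raise ValueError("d_h must lie in 0..log2(p)")
    cfg = effect_config or EffectConfig()
    rng = _rng(seed)
    h = 2 ** d_h
    group = rng.permutation(np.repeat(np.arange(h), p // h))
    m_xh = np.zeros((p, h))
    m_xh[np.arange(p), group] = cfg.draw(rng, p)
    m_h = np.zeros((h, h))
    if h > 1:
        pert = rng.uniform(-cfg.mh_perturb, cfg.mh_perturb, size=(h, h))
        m_h = np.triu(pert, 1)
        m_h = m_h + m_h.T
    np.fill_diagonal(m_h, np.abs(m_h).sum(axis=1) + np.abs(m_xh).sum(axis=0) + cfg.diag_slack)
    return m_h, m_xh


def make_MZX(
    p: int, d_z: int, effect_config: EffectConfig | None = None, seed=0
) -> np.ndarray:
    """m x p input-effect matrix (m = p) of rank exactly 2^{d_z} with exactly
    p / 2^{d_z} nonzeros in every row and every column."""
    k = int(round(np.log2(p)))
    if 2 ** k != p:
        raise ValueError("p must be a power of two")
    if not 0 <= d_z <= k:
        raise ValueError("d_z must lie in 0..log2(p)")
    cfg = effect_config or EffectConfig()
    rng = _rng(seed)
    r = 2 ** d_z
    block = p // r
    row_perm = rng.permutation(p)
    col_perm = rng.permutation(p)
    lo, hi = np.sqrt(cfg.low), np.sqrt(cfg.high)
    m_zx = np.zeros((p, p))
    for g in range(r):
        rows = row_perm[g * block:(g + 1) * block]
        cols = col_perm[g * block:(g + 1) * block]
        a = rng.uniform(lo, hi, size=block) * rng.choice([-1.0, 1.0], size=block)
        b = rng.uniform(lo, hi, size=block) * rng.choice([-1.0, 1.0], size=block)
        m_zx[np.ix_(rows, cols)] = np.outer(a, b)
    return m_zx


def make_model(design: SimDesign) -> GenerativeModel:
    """Ground-truth model of a (d_Z, d_H) design, with joint diagonal
    dominance enforced across the (X, H) blocks."""
    rngs = [np.random.default_rng(s) for s in _seedseq(design.seed).spawn(3)]
    cfg = design.effect_config
    p = design.p
    s_x = make_chain_SX(p, cfg, rngs[0])
    m_h, m_xh = make_latent_structure(p, design.d_h, cfg, rngs[1])
    m_zx = make_MZX(p, design.d_z, cfg, rngs[2])
    # re-set the X-block diagonal for dominance over chain + latent loadings
    off = s_x - np.diag(np.diag(s_x))
    np.fill_diagonal(
        s_x, np.abs(off).sum(axis=1) + np.abs(m_xh).sum(axis=1) + cfg.diag_slack
    )
    return GenerativeModel(m_x=s_x, m_h=m_h, m_xh=m_xh, m_zx=m_zx, design=design)


def sample_dataset(model: GenerativeModel, n: int, seed=0) -> Dataset:
    """Inputs iid t(4); outputs from the marginalized Gaussian conditional law
    (mean -(S*_X - L*_X)^{-1} S*_ZX^T z, covariance (S*_X - L*_X)^{-1})."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    p, m = model.p, model.m
    r_x = model.r_x
    c = np.linalg.cholesky(r_x)  # r_x = c c^T
    y_z = rng.standard_t(df=4, size=(n, m))
    # mean = -Y_Z S_ZX R_X^{-1}; noise cov R_X^{-1} via triangular solves
    tmp = solve_triangular(c, (y_z @ model.s_zx).T, lower=True)
    mean = -solve_triangular(c.T, tmp, lower=False).T
    g = rng.standard_normal((n, p))
    noise = solve_triangular(c.T, g.T, lower=False).T
    return Dataset(y_z=y_z, y_x=mean + noise)


def simulation_grid(
    k: int = 5,
    n: int = 3000,
    reps: int = 20,
    base_seed: int = 0,
    d_values=(2, 3, 4, 5),
    effect_config: EffectConfig | None = None,
):
    """Enumerate all (d_Z, d_H) designs x replicates with per-dataset seeds
    derived deterministically (counter-based) from base_seed.

    Yields (SimDesign, GenerativeModel, Dataset) triples; any triple can be
    regenerated in isolation from (base_seed, d_z, d_h, rep).
    """
    cfg = effect_config or EffectConfig()
    for d_z in d_values:
        for d_h in d_values:
            for rep in range(reps):
                model_seed = np.random.SeedSequence(
                    base_seed, spawn_key=(d_z, d_h, rep, 0)
                )
                data_seed = np.random.SeedSequence(
                    base_seed, spawn_key=(d_z, d_h, rep, 1)
                )
                design = SimDesign(
                    k=k, d_z=d_z, d_h=d_h, n=n,
                    seed=model_seed, effect_config=cfg,
                )
                model = make_model(design)
                data = sample_dataset(model, n, np.random.default_rng(data_seed))
                yield design, model, data
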