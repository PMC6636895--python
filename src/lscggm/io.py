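"""Delimited-matrix I/O, preprocessing transforms, and reproducible runs.

Matrices travel as TSV (CSV accepted) with a header row of column names and
no row names; values are written with 17 significant digits so a write/read
round trip is exact for float64.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "read_matrix",
    "write_matrix",
    "quantile_normalize",
    "RunConfig",
    "run",
]

logger = logging.getLogger("lscggm")


def read_matrix(path) -> pd.DataFrame:
    """Read a delimited numeric matrix (TSV default, CSV accepted by
    extension or sniffing); validates rectangularity and finiteness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "," if ("," in header and "\t" not in header) else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    ncol = df.shape[1]
    for i, row in enumerate(df.itertuples(index=False)):
        for j, v in enumerate(row):
            fv = pd.to_numeric(v, errors="coerce")
            if pd.isna(fv) or not np.isfinite(fv):
                raise ValueError(
                    f"{path}: non-numeric or missing cell at data row {i + 1}, "
                    f"column '{df.columns[j]}'"
                )
    out = df.astype(float)
    return out


def write_matrix(matrix, path, columns=None, sep="\t") -> None:
    """Write a matrix with a header row at full (17 significant digit)
    precision."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        matrix = np.asarray(matrix, dtype=float)
        if columns is None:
            columns = [f"c{i + 1}" for i in range(matrix.shape[1])]
        df = pd.DataFrame(matrix, columns=columns)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def quantile_normalize(column) -> np.ndarray:
    """Map a numeric vector to standard-normal quantiles of its mid-ranks
    ((rank - 0.5)/n, ties averaged), then standardize to population mean 0 /
    sd 1."""
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D column")
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.all(x == x[0]):
        raise ValueError("constant column cannot be quantile normalized")
    ranks = rankdata(x, method="average")
    z = norm.ppf((ranks - 0.5) / n)
    z = z - z.mean()
    return z / z.std()


@dataclass
class RunConfig:
    """A fully seeded, serializable description of one analysis run."""

    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    # either input paths ...
    data_path: str | None = None
    z_cols: list = None
    z_prefix: str | None = None
    center: bool = False
    standardize: bool = False
    # ... or a simulation design
    simulate: dict | None = None  # {k, d_z, d_h, n}
    # what to do
    method: str = "lscggm"
    lam: float | None = None
    gamma: float = 0.5
    gammas: list = None
    n_lambda: int = 10
    stability: dict | None = None  # {B, error_budget}
    solver: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path_or_str) -> "RunConfig":
        text = (
            Path(path_or_str).read_text()
            if Path(str(path_or_str)).exists()
            else str(path_or_str)
        )
        return cls(**json.loads(text))

    def to_json(self) -> str:
        doc = {k: v for k, v in self.__dict__.items()}
        return json.dumps(doc, indent=1, default=str)


def _load_or_simulate(config: RunConfig):
    from .core import Dataset
    from .simulate import SimDesign, make_model, sample_dataset

    if config.simulate is not None:
        spec = dict(config.simulate)
        design = SimDesign(
            k=int(spec.get("k", 3)), d_z=int(spec.get("d_z", 2)),
            d_h=int(spec.get("d_h", 2)), n=int(spec.get("n", 500)),
            seed=config.seed,
        )
        model = make_model(design)
        data = sample_dataset(model, design.n, seed=config.seed + 1)
        return data, model
    if config.data_path is None:
        raise ValueError("config needs either data_path or a simulate block")
    df = read_matrix(config.data_path)
    cols = list(df.columns)
    z_cols = config.z_cols or (
        [c for c in cols if str(c).startswith(config.z_prefix)]
        if config.z_prefix else []
    )
    x_cols = [c for c in cols if c not in set(z_cols)]
    y_z = df[z_cols].to_numpy(float) if z_cols else None
    y_x = df[x_cols].to_numpy(float)
    if config.center or config.standardize:
        y_x = y_x - y_x.mean(axis=0)
        if y_z is not None:
            y_z = y_z - y_z.mean(axis=0)
    if config.standardize:
        y_x = y_x / y_x.std(axis=0)
        if y_z is not None:
            y_z = y_z / y_z.std(axis=0)
    return Dataset(y_z=y_z, y_x=y_x, z_labels=[str(c) for c in z_cols],
                   x_labels=[str(c) for c in x_cols]), None


def run(config: RunConfig) -> Path:
    """Execute a run: load or simulate data, fit (single fit or path, with
    optional stability selection), and write results + echoed config + log to
    the output directory.  Deterministic given the config."""
    from . import __version__
    from .admm import SolverOptions
    from .model import LSCGGM, MethodConfig
    from .stability import complementary_pairs_select

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        logger.info("lscggm version %s, numpy %s", __version__, np.__version__)
        logger.info("seed=%d method=%s", config.seed, config.method)
        (out / "config.json").write_text(config.to_json())

        data, truth = _load_or_simulate(config)
        opts = SolverOptions(**config.solver) if config.solver else None
        model = LSCGGM(y_x=data.y_x, y_z=data.y_z, method=config.method,
                       x_names=data.x_labels, z_names=data.z_labels)
        results: dict = {"method": config.method, "seed": config.seed,
                         "n": data.n, "p": data.p, "m": data.m}

        if truth is not None:
            write_matrix(truth.s_x, out / "truth_S_X.tsv", columns=data.x_labels)
            write_matrix(truth.l_x, out / "truth_L_X.tsv", columns=data.x_labels)
            write_matrix(truth.s_zx, out / "truth_S_ZX.tsv", columns=data.x_labels)
            write_matrix(data.y_z, out / "Y_Z.tsv", columns=data.z_labels)
            write_matrix(data.y_x, out / "Y_X.tsv", columns=data.x_labels)

        if config.stability is not None:
            lam_max = model.lambda_max(config.gamma)
            lambdas = np.geomspace(lam_max, lam_max * 0.05, config.n_lambda)
            sres = complementary_pairs_select(
                data, MethodConfig(method=config.method, gammas=(config.gamma,)),
                lambdas, B=int(config.stability.get("B", 50)),
                error_budget=float(config.stability.get("error_budget", 1.0)),
                seed=config.seed, options=opts,
            )
            rows = sorted(
                ((data.x_labels[i], data.x_labels[j], pr)
                 for (i, j), pr in sres.inclusion_probabilities.items()),
                key=lambda r: -r[2],
            )
            pd.DataFrame(rows, columns=["node_a", "node_b", "inclusion_probability"]
                         ).to_csv(out / "stability_edges.tsv", sep="\t", index=False)
            results["stability"] = {
                "tau": sres.tau, "q": sres.q, "B": sres.B,
                "n_selected": len(sres.selected),
                "selected": sorted(
                    [data.x_labels[i], data.x_labels[j]] for i, j in sres.selected
                ),
                "warning": sres.warning,
            }
        elif config.lam is not None:
            fit = model.fit(config.lam, config.gamma, options=opts)
            write_matrix(fit.s_x, out / "S_X.tsv", columns=data.x_labels)
            write_matrix(fit.l_x, out / "L_X.tsv", columns=data.x_labels)
            if data.m:
                write_matrix(fit.s_zx, out / "S_ZX.tsv", columns=data.x_labels)
                write_matrix(fit.l_zx, out / "L_ZX.tsv", columns=data.x_labels)
            results["fit"] = {
                "lambda": fit.raw.lam, "gamma": fit.raw.gamma,
                "objective": fit.objective, "converged": bool(fit.converged),
                "iterations": fit.raw.iterations,
                "edges": sorted(map(list, fit.edge_list())),
                "latent_rank": fit.latent_rank,
            }
            logger.info("fit: %d iterations, objective %.6f",
                        fit.raw.iterations, fit.objective)
        else:
            gammas = tuple(config.gammas or (config.gamma,))
            path = model.fit_path(gammas=gammas, n_lambda=config.n_lambda,
                                  options=opts)
            results["path"] = [
                {"lambda": e.lam, "gamma": e.gamma, "edges": len(e.support),
                 "rank": e.rank, "objective": e.result.objective,
                 "converged": bool(e.result.converged)}
                for e in path.entries
            ]

        (out / "results.json").write_text(json.dumps(results, indent=1))
        logger.info("run complete")
    except Exception:
        logger.exception("run failed")
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)
    return out
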