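"""File formats: long-format tube CSV, wide matrix CSV, JSON fit artifacts.

Tube exchange format is long CSV with columns (tube_id, x, y), mirroring
how microscopy line-scan exports are shared. The preprocessing path uses
a wide CSV (first column tube_id, header row = grid positions, empty
cells = missing) so missingness stays explicit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cnls import SingleFit, TubeData
from .cmm import PopulationFit
from .core import ModelConstants, ReferenceSolution
from .preprocess import IntensityMatrix

__all__ = [
    "read_tubes_csv", "write_tubes_csv", "read_matrix_csv", "write_matrix_csv",
    "single_fit_to_dict", "population_fit_to_dict", "write_json", "load_config",
]


def read_tubes_csv(path: str | Path) -> list[TubeData]:
    """Read long-format (tube_id, x, y) CSV into a list of tubes."""
    df = pd.read_csv(path)
    required = {"tube_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(f"{path}: non-numeric {col} at rows {bad[:10]}")
    dup = df.duplicated(subset=["tube_id", "x"])
    if dup.any():
        raise ValueError(f"{path}: duplicated (tube_id, x) pairs at rows "
                         f"{df.index[dup].tolist()[:10]}")
    tubes = []
    for tube_id, grp in df.groupby("tube_id", sort=False):
        tubes.append(TubeData(x=grp["x"].to_numpy(), y=grp["y"].to_numpy(),
                              tube_id=str(tube_id)))
    return tubes


def write_tubes_csv(tubes: list[TubeData], path: str | Path) -> None:
    frames = [pd.DataFrame({"tube_id": t.tube_id, "x": t.x, "y": t.y}) for t in tubes]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> IntensityMatrix:
    """Read a wide matrix CSV (tube_id column + position headers, blanks = missing)."""
    df = pd.read_csv(path)
    if df.columns[0] != "tube_id":
        raise ValueError(f"{path}: first column must be 'tube_id'")
    grid = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return IntensityMatrix(values=values, grid=grid,
                           tube_ids=[str(t) for t in df["tube_id"]])


def write_matrix_csv(matrix: IntensityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=[repr(float(g)) for g in matrix.grid])
    df.insert(0, "tube_id", matrix.tube_ids)
    df.to_csv(path, index=False)


def _mat(m) -> list | None:
    return np.asarray(m).tolist() if m is not None else None


def single_fit_to_dict(fit: SingleFit, consts: ModelConstants | None = None,
                       ref: ReferenceSolution | None = None,
                       options: dict | None = None) -> dict:
    out = {
        "tube_id": fit.tube_id,
        "shape": {"lam": fit.shape.lam, "mu": fit.shape.mu},
        "rates": {"knf": fit.rates.knf, "kpf": fit.rates.kpf},
        "sigma": fit.sigma,
        "cov_shape_mu_lam": _mat(fit.cov_shape),
        "ci_shape": fit.ci_shape(),
        "n": fit.n,
        "rss": fit.rss,
        "on_boundary": fit.on_boundary,
        "converged": fit.converged,
        "n_restarts_used": fit.n_restarts_used,
    }
    if consts is not None:
        out["constants"] = {"alpha": consts.alpha, "d1": consts.d1,
                            "l0": consts.l0, "rtot": consts.rtot}
    if ref is not None:
        out["reference"] = {"alpha": ref.alpha, "c": ref.c, "peak": ref.peak,
                            "mass": ref.mass, "hash": ref.content_hash()}
    if options is not None:
        out["options"] = options
    return out


def population_fit_to_dict(fit: PopulationFit, consts: ModelConstants | None = None,
                           ref: ReferenceSolution | None = None,
                           options: dict | None = None) -> dict:
    out = {
        "theta0": {"lam": fit.theta0.lam, "mu": fit.theta0.mu},
        "Sigma0_mu_lam": _mat(fit.Sigma0),
        "Sigma0_raw_mu_lam": _mat(fit.Sigma0_raw),
        "eigvals_raw": _mat(fit.eigvals_raw),
        "sigma": fit.sigma,
        "rates0": {"knf": fit.rates0.knf, "kpf": fit.rates0.kpf},
        # simple-mean CLT (sample covariance of per-tube estimates / m)
        "cov_theta0_mu_lam": _mat(fit.cov_theta0),
        "cov_theta0_method": "simple-mean CLT",
        "ci_theta0": {k: list(v) for k, v in fit.ci_theta0.items()},
        "ci_rates": {k: list(v) for k, v in fit.ci_rates.items()},
        "rho_shape": fit.rho_shape,
        "rho_rates": fit.rho_rates,
        "m": fit.m,
        "n_dropped": fit.n_dropped,
        "per_tube": [single_fit_to_dict(f) for f in fit.per_tube],
    }
    if consts is not None:
        out["constants"] = {"alpha": consts.alpha, "d1": consts.d1,
                            "l0": consts.l0, "rtot": consts.rtot}
    if ref is not None:
        out["reference"] = {"alpha": ref.alpha, "c": ref.c, "peak": ref.peak,
                            "mass": ref.mass, "hash": ref.content_hash()}
    if options is not None:
        out["options"] = options
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config; returns an empty dict for an empty file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
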