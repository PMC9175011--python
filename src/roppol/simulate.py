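"""Synthetic tube generators reproducing the published simulation designs.

Three generators cover the three stages of the pipeline:

* single tubes: the true profile lam * U_alpha(mu x) on a uniform grid
  over [-15, 15] plus i.i.d. Gaussian noise (the study grids pair step
  sizes 0.6 / 0.3 / 0.1 with n = 51 / 101 / 301);
* populations: per-tube (mu_i, lam_i) drawn from a bivariate normal
  truncated to the feasible set by rejection, then observed as above;
* "raw" tube-by-position matrices emulating microscope exports: a common
  173-point grid at 0.1205 um spacing, a positive baseline offset (so
  profiles do not vanish at the boundary), sparse outliers, and
  missing-at-random entries (~25%) — the inputs the preprocessing stage
  is built to clean.

All randomness flows from a numpy Generator; a fixed seed gives
bit-reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnls import TubeData
from .core import ModelConstants, ReferenceSolution, ShapeParams, evaluate_profile

__all__ = ["SimulationDesign", "RawMatrix", "simulate_single", "simulate_population",
           "simulate_raw_matrix"]

# default population covariance of (mu, lam): SD 0.06 each, correlation 0.8
_DEFAULT_SIGMA = ((0.06 ** 2, 0.8 * 0.06 ** 2), (0.8 * 0.06 ** 2, 0.06 ** 2))


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for one simulated dataset.

    step 0.1 / 0.3 / 0.6 on [-15, 15] gives n = 301 / 101 / 51 points.
    Sigma is the population covariance of (mu, lam), in that order.
    """

    grid_halfwidth: float = 15.0
    step: float = 0.1
    sigma: float = 0.2
    m: int = 50
    theta0: ShapeParams = field(default_factory=lambda: ShapeParams(lam=0.6, mu=1.0))
    Sigma: tuple = _DEFAULT_SIGMA
    seed: int = 0

    @property
    def n(self) -> int:
        return int(round(2.0 * self.grid_halfwidth / self.step)) + 1

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(-self.grid_halfwidth, self.grid_halfwidth, self.n)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_single(shape: ShapeParams, design: SimulationDesign,
                    ref: ReferenceSolution, rng: np.random.Generator | None = None,
                    tube_id: str = "tube") -> TubeData:
    """One tube: y_j = lam U_alpha(mu x_j) + N(0, sigma^2) on the design grid."""
    rng = design.rng() if rng is None else rng
    x = design.grid
    y = evaluate_profile(shape, ref, x)
    if design.sigma > 0:
        y = y + rng.normal(0.0, design.sigma, size=x.size)
    return TubeData(x=x, y=y, tube_id=tube_id)


def _draw_feasible_params(design: SimulationDesign, consts: ModelConstants,
                          ref: ReferenceSolution, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample (mu, lam) pairs from MVN truncated to the feasible set."""
    mean = np.array([design.theta0.mu, design.theta0.lam])
    cov = np.asarray(design.Sigma, dtype=float)
    out = np.empty((size, 2))
    got = 0
    attempts = 0
    while got < size:
        draw = rng.multivariate_normal(mean, cov, size=size, method="eigh")
        attempts += size
        ok = ((draw > 0).all(axis=1)
              & (draw[:, 0] * consts.rtot - draw[:, 1] * ref.mass > 0))
        take = draw[ok][: size - got]
        out[got:got + take.shape[0]] = take
        got += take.shape[0]
        if attempts >= 100 * size and got < 0.01 * attempts:
            raise RuntimeError(
                "population design infeasible: acceptance rate below 1% "
                f"({got}/{attempts} draws feasible)")
    return out


def simulate_population(design: SimulationDesign, consts: ModelConstants,
                        ref: ReferenceSolution,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[list[TubeData], pd.DataFrame]:
    """A population of m tubes with per-tube parameters from the truncated MVN.

    Returns the tubes plus a truth table (tube_id, mu, lam) for recovery
    scoring.
    """
    rng = design.rng() if rng is None else rng
    params = _draw_feasible_params(design, consts, ref, design.m, rng)
    tubes, rows = [], []
    for i, (mu_i, lam_i) in enumerate(params):
        shape = ShapeParams(lam=float(lam_i), mu=float(mu_i))
        tube_id = f"T{i + 1}"
        tubes.append(simulate_single(shape, design, ref, rng=rng, tube_id=tube_id))
        rows.append({"tube_id": tube_id, "mu": float(mu_i), "lam": float(lam_i)})
    return tubes, pd.DataFrame(rows)


@dataclass
class RawMatrix:
    """A simulated raw acquisition: observed (with NaN), complete, and truth.

    observed : m x n matrix with missing entries as NaN
    complete : the same matrix before masking (baseline + noise + outliers)
    clean    : noise-free profiles plus baseline (imputation/denoising target)
    """

    grid: np.ndarray
    observed: np.ndarray
    complete: np.ndarray
    clean: np.ndarray
    truth: pd.DataFrame
    baseline: float
    tube_ids: list[str]


def simulate_raw_matrix(design: SimulationDesign, consts: ModelConstants,
                        ref: ReferenceSolution, missing_frac: float = 0.25,
                        baseline_frac: float = 0.2, outlier_rate: float = 0.01,
                        n_grid: int = 173, grid_step: float = 0.1205,
                        m: int = 12,
                        rng: np.random.Generator | None = None) -> RawMatrix:
    """Raw tube-by-position matrix on the common microscope grid.

    The grid is the centered 173-point, 0.1205-um-step reference grid of
    the real acquisitions. A shared positive baseline (baseline_frac of
    the population peak intensity — a synthetic fixture standing in for
    uncalibrated background fluorescence) is added so profiles do not
    vanish at the edges; outliers of +-5 sigma occur at outlier_rate;
    missing_frac of all entries are blanked at random.
    """
    rng = design.rng() if rng is None else rng
    grid = (np.arange(n_grid) - (n_grid - 1) / 2.0) * grid_step
    params = _draw_feasible_params(design, consts, ref, m, rng)
    peak0 = design.theta0.lam * ref.peak
    baseline = baseline_frac * peak0

    clean = np.empty((m, n_grid))
    rows = []
    for i, (mu_i, lam_i) in enumerate(params):
        shape = ShapeParams(lam=float(lam_i), mu=float(mu_i))
        clean[i] = evaluate_profile(shape, ref, grid) + baseline
        rows.append({"tube_id": f"T{i + 1}", "mu": float(mu_i), "lam": float(lam_i)})

    complete = clean + rng.normal(0.0, design.sigma, size=clean.shape)
    if outlier_rate > 0:
        hits = rng.random(clean.shape) < outlier_rate
        signs = rng.choice([-1.0, 1.0], size=clean.shape)
        complete = complete + hits * signs * 5.0 * design.sigma

    observed = complete.copy()
    if missing_frac > 0:
        mask = rng.random(clean.shape) < missing_frac
        observed[mask] = np.nan

    return RawMatrix(grid=grid, observed=observed, complete=complete, clean=clean,
                     truth=pd.DataFrame(rows), baseline=float(baseline),
                     tube_ids=[r["tube_id"] for r in rows])
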