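"""Preprocessing of raw tube-by-position intensity matrices.

Raw line-scan exports share a common position grid but differ in which
grid points each tube was actually measured at, so the matrix has
missing entries; intensities are relative and ride on a background
baseline, so profiles do not vanish at the membrane edges as the model
requires. Two steps repair this:

* iterative-PCA imputation and denoising: missing cells are filled by an
  EM-style loop (column-mean start; rank-k truncated SVD of the
  column-centered matrix; refill only the missing cells; iterate), after
  which every cell is replaced by the rank-k reconstruction, removing
  outliers and excess noise while respecting between-tube correlation;
* boundary normalization: y = (y_raw - yB) / yB with yB the pooled mean
  intensity over all cells with |x| above a cut (default 8 um), yielding
  profiles that vanish at the boundaries on the normalized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["IntensityMatrix", "impute_and_denoise", "boundary_normalize"]


@dataclass
class IntensityMatrix:
    """Tubes x positions intensity matrix; NaN marks a missing entry."""

    values: np.ndarray
    grid: np.ndarray
    tube_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (tubes x positions)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 tubes")
        if self.values.shape[1] != self.grid.size:
            raise ValueError("grid length must match the number of columns")
        if not (np.diff(self.grid) > 0).all():
            raise ValueError("grid must be strictly increasing")
        if not self.tube_ids:
            self.tube_ids = [f"T{i + 1}" for i in range(self.values.shape[0])]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def _rank_k_reconstruction(x: np.ndarray, n_axes: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered truncated-SVD reconstruction; returns (recon, singular values)."""
    col_means = x.mean(axis=0)
    xc = x - col_means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    recon = u[:, :n_axes] @ np.diag(s[:n_axes]) @ vt[:n_axes] + col_means
    return recon, s


def impute_and_denoise(matrix: IntensityMatrix, n_axes: int, tol: float = 1e-6,
                       max_iter: int = 500) -> tuple[IntensityMatrix, float, bool]:
    """Iterative-PCA imputation followed by rank-n_axes projection.

    Missing cells are initialized with column means and refined by
    repeating {column-center, rank-n_axes SVD reconstruction, refill only
    the missing cells} until the relative change on the imputed cells
    drops below ``tol`` or ``max_iter`` is reached (the result is then
    returned with ``converged=False`` and a warning). Observed cells are
    untouched during the iteration; the final projection replaces every
    cell by the rank-n_axes reconstruction (denoising).

    Returns (completed matrix, fraction of variance carried by the
    retained axes, converged flag).
    """
    x = matrix.values.copy()
    mask = matrix.missing_mask
    if n_axes >= min(x.shape):
        raise ValueError(
            f"n_axes must be < min(n_tubes, n_positions) = {min(x.shape)}")

    col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    x[mask] = np.broadcast_to(col_means, x.shape)[mask]

    converged = True
    if mask.any():
        converged = False
        for _ in range(max_iter):
            recon, _ = _rank_k_reconstruction(x, n_axes)
            new_vals = recon[mask]
            scale = max(float(np.linalg.norm(x[mask])), 1e-12)
            delta = float(np.linalg.norm(new_vals - x[mask])) / scale
            x[mask] = new_vals
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"iterative-PCA imputation did not converge in {max_iter} "
                "iterations; returning the last iterate", stacklevel=2)

    recon, s = _rank_k_reconstruction(x, n_axes)
    total = float(np.sum(s ** 2))
    var_explained = float(np.sum(s[:n_axes] ** 2) / total) if total > 0 else 1.0
    out = IntensityMatrix(values=recon, grid=matrix.grid.copy(),
                          tube_ids=list(matrix.tube_ids))
    return out, var_explained, converged


def boundary_normalize(matrix: IntensityMatrix, boundary_cut: float = 8.0,
                       per_tube: bool = False,
                       ) -> tuple[IntensityMatrix, float | np.ndarray]:
    """Standardize intensities against the boundary level: (y - yB) / yB.

    yB is the mean over all observed cells at positions |x| > boundary_cut,
    pooled across tubes by default (``per_tube=True`` instead normalizes
    each tube by its own boundary mean). The normalized boundary-region
    mean is zero by construction. Returns (normalized matrix, yB).
    """
    sel = np.abs(matrix.grid) > boundary_cut
    if not sel.any():
        raise ValueError(f"no grid points with |x| > {boundary_cut}")
    vals = matrix.values
    if per_tube:
        yb = np.nanmean(vals[:, sel], axis=1)
        if (yb <= 0).any():
            raise ValueError("nonpositive per-tube boundary mean; cannot normalize")
        out_vals = (vals - yb[:, None]) / yb[:, None]
        return IntensityMatrix(out_vals, matrix.grid.copy(), list(matrix.tube_ids)), yb
    yb = float(np.nanmean(vals[:, sel]))
    if yb <= 0:
        raise ValueError(f"nonpositive boundary mean {yb}; cannot normalize")
    out_vals = (vals - yb) / yb
    return IntensityMatrix(out_vals, matrix.grid.copy(), list(matrix.tube_ids)), yb
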