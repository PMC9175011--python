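"""Population-level constrained method of moments (CMM).

Across tubes the shape parameters theta_i = (mu_i, lam_i) are random
draws from a distribution on the feasible set with mean theta_0 and
covariance Sigma_0; only these two moments are assumed (no likelihood).
The estimator averages per-tube least-squares fits, removes the
estimation-noise bias sigma^2 * mean_i (J_i^T J_i)^-1 from the sample
covariance of the per-tube estimates, projects the result onto the
positive-semidefinite cone by eigenvalue clipping, and propagates the
uncertainty of theta_0-hat into the feedback rates by the delta method.

All 2-vectors and 2x2 matrices are ordered (mu, lam).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cnls import FitOptions, SingleFit, TubeData, fit_single, profile_jacobian
from .core import ModelConstants, Rates, ReferenceSolution, ShapeParams, rates_from_shape

__all__ = ["PopulationFit", "fit_population", "psd_project", "delta_method_rates"]


def psd_project(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project a symmetric matrix onto the PSD cone by clipping eigenvalues.

    Returns (projected matrix, original eigenvalues). A matrix that is
    already PSD is returned unchanged (up to symmetrization round-off).
    """
    sym = (m + m.T) / 2.0
    eigvals, q = np.linalg.eigh(sym)
    if (eigvals >= 0).all():
        return sym, eigvals
    return q @ np.diag(np.clip(eigvals, 0.0, None)) @ q.T, eigvals


@dataclass
class PopulationFit:
    """Output of the population fit.

    theta0 : population-mean shape parameters
    Sigma0 : bias-corrected, PSD-projected population covariance (mu, lam)
    Sigma0_raw : before PSD projection (may have a negative eigenvalue)
    sigma : pooled residual noise SD
    rates0 : theta0 converted to (knf, kpf)
    cov_theta0 : asymptotic covariance of theta0-hat (simple-mean CLT:
        sample covariance of the per-tube estimates divided by m)
    """

    theta0: ShapeParams
    Sigma0: np.ndarray
    Sigma0_raw: np.ndarray
    eigvals_raw: np.ndarray
    sigma: float
    rates0: Rates
    cov_theta0: np.ndarray
    ci_theta0: dict[str, tuple[float, float]]
    ci_rates: dict[str, tuple[float, float]]
    rho_shape: float
    rho_rates: float
    cov_rates0: np.ndarray
    per_tube: list[SingleFit]
    m: int
    n_dropped: int = 0

    @property
    def theta0_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_theta0))


def _rates_vec(theta: np.ndarray, consts: ModelConstants, ref: ReferenceSolution) -> np.ndarray:
    r = rates_from_shape(ShapeParams(lam=theta[1], mu=theta[0]), consts, ref)
    return np.array([r.knf, r.kpf])


def _rates_jacobian(theta: np.ndarray, consts: ModelConstants, ref: ReferenceSolution,
                    step_rel: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of (mu, lam) -> (knf, kpf)."""
    jac = np.empty((2, 2))
    for j in range(2):
        h = step_rel * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (_rates_vec(tp, consts, ref) - _rates_vec(tm, consts, ref)) / (2 * h)
    return jac


def delta_method_rates(theta0: ShapeParams, cov_theta0: np.ndarray,
                       consts: ModelConstants, ref: ReferenceSolution,
                       boundary_tol: float = 1e-6,
                       ) -> tuple[Rates, np.ndarray, dict[str, tuple[float, float]], float]:
    """Propagate shape-parameter uncertainty into the rates.

    Returns (rates, covariance of the rates, 95% CIs, implied correlation
    of knf and kpf).  Requires theta0 strictly inside the feasible set.
    """
    slack = theta0.mu * consts.rtot - theta0.lam * ref.mass
    if slack <= boundary_tol:
        raise ValueError("boundary case: delta-method inference withheld "
                         f"(constraint slack {slack})")
    th = np.array([theta0.mu, theta0.lam])
    phi = _rates_vec(th, consts, ref)
    jac = _rates_jacobian(th, consts, ref)
    cov = jac @ np.asarray(cov_theta0, dtype=float) @ jac.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ci = {"knf": (phi[0] - 1.96 * se[0], phi[0] + 1.96 * se[0]),
          "kpf": (phi[1] - 1.96 * se[1], phi[1] + 1.96 * se[1])}
    denom = se[0] * se[1]
    rho = float(cov[0, 1] / denom) if denom > 0 else float("nan")
    return Rates(knf=float(phi[0]), kpf=float(phi[1])), cov, ci, rho


def _correlation(cov: np.ndarray) -> float:
    denom = np.sqrt(cov[0, 0] * cov[1, 1])
    return float(cov[0, 1] / denom) if denom > 0 else float("nan")


def fit_population(tubes: list[TubeData], consts: ModelConstants,
                   ref: ReferenceSolution,
                   options: FitOptions | None = None) -> PopulationFit:
    """Constrained method-of-moments fit of a tube population.

    Steps: per-tube CNLS fits (unfittable tubes are dropped with a
    warning, never silently); theta0-hat = unweighted mean of the
    per-tube estimates; pooled sigma^2 = sum RSS_i / sum (n_i - 2);
    Sigma0-hat = sample covariance (divisor m-1) minus
    sigma^2 * mean_i (J_i^T J_i)^-1, PSD-projected; rates and delta-method
    CIs from theta0-hat.
    """
    if len(tubes) < 2:
        raise ValueError("need at least 2 tubes")

    fits: list[SingleFit] = []
    kept_tubes: list[TubeData] = []
    dropped = 0
    for tube in tubes:
        try:
            fits.append(fit_single(tube, consts, ref, options))
            kept_tubes.append(tube)
        except (RuntimeError, ValueError) as exc:
            dropped += 1
            warnings.warn(f"dropping tube {tube.tube_id!r}: {exc}", stacklevel=2)
    m = len(fits)
    if m < 2:
        raise ValueError(f"fewer than 2 tubes fitted ({dropped} dropped)")

    theta = np.array([[f.shape.mu, f.shape.lam] for f in fits])
    theta0_vec = theta.mean(axis=0)
    theta0 = ShapeParams(lam=float(theta0_vec[1]), mu=float(theta0_vec[0]))

    rss_total = sum(f.rss for f in fits)
    dof_total = sum(f.n - 2 for f in fits)
    sigma2 = rss_total / dof_total

    sample_cov = np.cov(theta, rowvar=False, ddof=1)
    t_inv_mean = np.zeros((2, 2))
    for f, tube in zip(fits, kept_tubes):
        j = profile_jacobian(f.shape, ref, tube.x)
        t_inv_mean += np.linalg.inv(j.T @ j)
    t_inv_mean /= m
    sigma0_raw = sample_cov - sigma2 * t_inv_mean
    sigma0, eigvals_raw = psd_project(sigma0_raw)

    rates0_plain = rates_from_shape(theta0, consts, ref)
    cov_theta0 = sample_cov / m
    se_theta0 = np.sqrt(np.diag(cov_theta0))
    ci_theta0 = {
        "mu": (theta0.mu - 1.96 * se_theta0[0], theta0.mu + 1.96 * se_theta0[0]),
        "lam": (theta0.lam - 1.96 * se_theta0[1], theta0.lam + 1.96 * se_theta0[1]),
    }
    rates0, cov_rates_clt, ci_rates, _ = delta_method_rates(theta0, cov_theta0, consts, ref)
    assert np.isclose(rates0.knf, rates0_plain.knf)

    # population-level correlations: Sigma0 propagated through the rate map
    jac = _rates_jacobian(np.array([theta0.mu, theta0.lam]), consts, ref)
    cov_rates_pop = jac @ sigma0 @ jac.T
    rho_shape = _correlation(sigma0)
    rho_rates = _correlation(cov_rates_pop)

    return PopulationFit(theta0=theta0, Sigma0=sigma0, Sigma0_raw=sigma0_raw,
                         eigvals_raw=eigvals_raw, sigma=float(np.sqrt(sigma2)),
                         rates0=rates0, cov_theta0=cov_theta0, ci_theta0=ci_theta0,
                         ci_rates=ci_rates, rho_shape=rho_shape, rho_rates=rho_rates,
                         cov_rates0=cov_rates_clt, per_tube=fits, m=m,
                         n_dropped=dropped)
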