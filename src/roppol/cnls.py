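"""Single-tube constrained nonlinear least squares (CNLS).

One tube contributes observations y_j = lam * U_alpha(mu * x_j) + eps_j
with i.i.d. errors of mean 0 and variance sigma^2.  The pair (lam, mu)
is estimated by least squares under the existence constraint
mu * Rtot - lam * |U_alpha| > 0, handled by the reparametrization
nu = mu / lam which turns the constraint into the box nu > |U_alpha|/Rtot.
The fitted shape is then converted to the mechanistic rates and, off the
constraint boundary, equipped with normal-theory standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import ModelConstants, Rates, ReferenceSolution, ShapeParams, rates_from_shape

__all__ = ["TubeData", "FitOptions", "SingleFit", "initial_values", "fit_single",
           "asymptotic_covariance"]


@dataclass
class TubeData:
    """Observations (x_j, y_j) from one tube; x in micrometres, unsorted OK."""

    x: np.ndarray
    y: np.ndarray
    tube_id: str = "tube"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if self.x.size < 5:
            raise ValueError(f"need at least 5 observations, got {self.x.size}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("x and y must be finite")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the constrained fit.

    boundary_tol : slack in nu below which the existence constraint is
        declared active and normal-theory inference withheld
    n_restarts : perturbed restarts tried when the default start fails or
        lands on the boundary (multimodality guard: the calibration
        equation can have two roots, so the RSS surface can be bimodal)
    """

    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 1000
    boundary_tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    eps_bound: float = 1e-8


@dataclass
class SingleFit:
    """Result of a single-tube fit.

    cov_shape is the 2x2 asymptotic covariance of (mu_hat, lam_hat);
    it is None when the existence constraint is active (boundary case,
    for which plain normal asymptotics do not apply).
    """

    shape: ShapeParams
    rates: Rates
    sigma: float
    cov_shape: np.ndarray | None
    n: int
    rss: float
    on_boundary: bool
    converged: bool
    tube_id: str = "tube"
    n_restarts_used: int = 0

    def ci_shape(self, level_z: float = 1.96) -> dict[str, tuple[float, float]] | None:
        """95% normal CIs for mu and lam, or None in the boundary case."""
        if self.cov_shape is None:
            return None
        se = np.sqrt(np.diag(self.cov_shape))
        return {
            "mu": (self.shape.mu - level_z * se[0], self.shape.mu + level_z * se[0]),
            "lam": (self.shape.lam - level_z * se[1], self.shape.lam + level_z * se[1]),
        }


def initial_values(data: TubeData, ref: ReferenceSolution,
                   consts: ModelConstants | None = None) -> ShapeParams:
    """Raw starting values for (lam, mu) from the data themselves.

    lam0 = y0 / U_alpha(0) with y0 the observation nearest x = 0 (ties
    broken toward the smaller |x|, then the smaller x), and
    mu0 = lam0 |U_alpha| / sum_{i>=2} y_(i) (x_(i) - x_(i-1)): the
    left-Riemann estimate of the profile integral lam |U_alpha| / mu.
    Clipped into the feasible set when constants are supplied.
    """
    order0 = np.lexsort((data.x, np.abs(data.x)))
    y0 = data.y[order0[0]]
    lam0 = y0 / ref.peak
    if lam0 <= 0:
        lam0 = 1e-4

    order = np.argsort(data.x, kind="stable")
    xs, ys = data.x[order], data.y[order]
    riemann = float(np.sum(ys[1:] * np.diff(xs)))
    if riemann <= 0:
        warnings.warn("nonpositive Riemann-sum integral in initial values; "
                      "falling back to mu0 = 1", stacklevel=2)
        mu0 = 1.0
    else:
        mu0 = lam0 * ref.mass / riemann

    if mu0 <= 0:
        mu0 = 1.0
    if consts is not None:
        nu_min = ref.mass / consts.rtot
        if mu0 / lam0 <= nu_min:
            mu0 = lam0 * nu_min * (1.0 + 1e-3)
    return ShapeParams(lam=float(lam0), mu=float(mu0))


def _model_and_jac(params: np.ndarray, x: np.ndarray, ref: ReferenceSolution):
    """Model values and Jacobian columns in the (lam, nu) parametrization."""
    lam, nu = params
    mu = lam * nu
    z = mu * x
    uv = ref.u(z)
    ud = ref.du(z)
    m = lam * uv
    # d m / d lam = U(mu x) + mu x U'(mu x);  d m / d nu = lam^2 x U'(mu x)
    dlam = uv + z * ud
    dnu = lam * lam * x * ud
    return m, dlam, dnu


def fit_single(data: TubeData, consts: ModelConstants, ref: ReferenceSolution,
               options: FitOptions | None = None) -> SingleFit:
    """Constrained least-squares fit of one tube.

    Minimizes sum_j (y_j - lam U_alpha(lam nu x_j))^2 over lam > 0,
    nu > |U_alpha|/Rtot (trust-region reflective with box bounds, analytic
    Jacobian), maps back to (mu, lam) = (lam*nu, lam), and estimates
    sigma^2 = RSS / (n - 2).
    """
    opts = options or FitOptions()
    if data.n <= 2:
        raise ValueError("need n > 2 observations for sigma^2 = RSS/(n-2)")

    nu_min = ref.mass / consts.rtot
    lb = np.array([opts.eps_bound, nu_min + opts.eps_bound])

    def residual(p):
        m, _, _ = _model_and_jac(p, data.x, ref)
        return m - data.y

    def jac(p):
        _, dlam, dnu = _model_and_jac(p, data.x, ref)
        return np.column_stack([dlam, dnu])

    start = initial_values(data, ref, consts)
    p0 = np.maximum([start.lam, start.nu], lb * (1.0 + 1e-6))

    def run(p):
        return least_squares(residual, p, jac=jac, bounds=(lb, np.inf),
                             method="trf", xtol=opts.xtol, ftol=opts.ftol,
                             gtol=opts.gtol, max_nfev=opts.max_nfev)

    res = run(p0)
    restarts = 0
    boundary = (res.x[1] - nu_min) < opts.boundary_tol
    if not res.success or boundary:
        rng = np.random.default_rng(opts.seed)
        best = res if res.success else None
        for _ in range(opts.n_restarts):
            restarts += 1
            p_try = p0 * np.exp(rng.normal(0.0, 0.3, size=2))
            p_try = np.maximum(p_try, lb * (1.0 + 1e-6))
            r = run(p_try)
            if r.success and (best is None or r.cost < best.cost):
                best = r
        if best is not None:
            res = best
        if res is None or not res.success:
            raise RuntimeError(
                f"CNLS failed to converge for tube {data.tube_id!r}: {res.message}")
        boundary = (res.x[1] - nu_min) < opts.boundary_tol

    lam, nu = res.x
    shape = ShapeParams(lam=float(lam), mu=float(lam * nu))
    rss = float(2.0 * res.cost)
    sigma2 = rss / (data.n - 2)
    rates = rates_from_shape(shape, consts, ref)
    fit = SingleFit(shape=shape, rates=rates, sigma=float(np.sqrt(sigma2)),
                    cov_shape=None, n=data.n, rss=rss, on_boundary=bool(boundary),
                    converged=bool(res.success), tube_id=data.tube_id,
                    n_restarts_used=restarts)
    if not boundary:
        fit.cov_shape = asymptotic_covariance(fit, data, ref)
    return fit


def profile_jacobian(shape: ShapeParams, ref: ReferenceSolution, x: np.ndarray) -> np.ndarray:
    """n x 2 Jacobian of R(x; mu, lam) = lam U_alpha(mu x), columns (d/dmu, d/dlam)."""
    x = np.asarray(x, dtype=float)
    z = shape.mu * x
    return np.column_stack([shape.lam * x * ref.du(z), ref.u(z)])


def asymptotic_covariance(fit: SingleFit, data: TubeData,
                          ref: ReferenceSolution) -> np.ndarray:
    """Normal-theory covariance of (mu_hat, lam_hat): sigma^2 K^-1 / n.

    K is the sample mean of grad R grad R^T over the design points,
    gradients taken from the reference interpolant and its derivative.
    Withheld (raises) in the boundary case, where these asymptotics fail.
    """
    if fit.on_boundary:
        raise ValueError("boundary case not supported: existence constraint active")
    G = profile_jacobian(fit.shape, ref, data.x)
    K = G.T @ G / data.n
    return fit.sigma ** 2 * np.linalg.inv(K) / data.n
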