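"""Core machinery for the steady-state ROP1 polarity model.

The active-ROP1 concentration profile R(x) on the pollen tube membrane,
x being the arc-length coordinate with the apical tip at x = 0, obeys a
stationary balance between linear deactivation (negative feedback, rate
``knf``), superlinear self-activation (positive feedback, rate ``kpf``,
exponent ``alpha > 1``) damped by depletion of the free cytosolic pool
(total free ROP1 ``Rtot``), and lateral membrane diffusion ``D1``:

    -D1 R'' = -knf R + kpf (1 - int R / Rtot) R^alpha,   R(+-L0) = 0.

Every positive solution is a scaled, compressed copy of a single canonical
bell shape: R(x) = lam * U_alpha(mu * x), where U_alpha is the positive
solution of the nondimensionalized problem

    -u'' = -u + u^alpha on [-c, c],   u(+-c) = 0,

mu = sqrt(knf / D1), and lam solves a scalar calibration equation whose
root structure (zero, one, or two positive roots) is governed by a
discriminant. This module solves the reference problem, evaluates the
discriminant, finds the calibration roots, and converts between the shape
parameters (lam, mu) and the mechanistic rates (knf, kpf).

Conventions: wherever the pair appears as a plain 2-vector or 2x2 matrix
the ordering is (mu, lam).
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_bvp, simpson, trapezoid
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = [
    "ModelConstants",
    "Rates",
    "ShapeParams",
    "ReferenceSolution",
    "SolvabilityReport",
    "closed_form_reference",
    "solve_reference",
    "discriminant",
    "solve_lambda",
    "evaluate_profile",
    "rates_from_shape",
    "membrane_fraction",
    "rescale_rates",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed mechanistic constants of the polarity model.

    alpha : superlinearity exponent of the positive feedback (> 1)
    d1    : lateral diffusion coefficient, working units
    l0    : membrane half-length, micrometres
    rtot  : total free ROP1, intensity * micrometre units
    """

    alpha: float = 1.2
    d1: float = 0.2
    l0: float = 15.0
    rtot: float = 30.0

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError(f"alpha must be > 1, got {self.alpha}")
        for name in ("d1", "l0", "rtot"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class Rates:
    """Feedback rates: knf (negative, deactivation), kpf (positive, activation)."""

    knf: float
    kpf: float

    def __post_init__(self) -> None:
        if not (self.knf > 0 and self.kpf > 0):
            raise ValueError(f"rates must be positive, got knf={self.knf}, kpf={self.kpf}")


@dataclass(frozen=True)
class ShapeParams:
    """Shape parameters of a profile R(x) = lam * U_alpha(mu * x).

    lam : peak-scale multiplier (intensity units)
    mu  : spatial compression (1/micrometre); mu = sqrt(knf / D1)
    """

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.mu > 0):
            raise ValueError(f"shape parameters must be positive, got lam={self.lam}, mu={self.mu}")

    @property
    def nu(self) -> float:
        """Reparametrization nu = mu / lam used by the constrained fit."""
        return self.mu / self.lam


def closed_form_reference(alpha: float, x) -> np.ndarray | float:
    """Infinite-domain ground state of -u'' = -u + u^alpha.

    u(x) = ((alpha+1)/2)^(1/(alpha-1)) * sech^(2/(alpha-1))((alpha-1) x / 2).

    Exact on the whole real line; serves as the large-c limit of
    :func:`solve_reference` and as the solver's initial guess.
    """
    if not alpha > 1:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    x = np.asarray(x, dtype=float)
    amp = ((alpha + 1.0) / 2.0) ** (1.0 / (alpha - 1.0))
    sech = 1.0 / np.cosh((alpha - 1.0) * x / 2.0)
    out = amp * sech ** (2.0 / (alpha - 1.0))
    return out if out.shape else float(out)


def _closed_form_derivative(alpha: float, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    amp = ((alpha + 1.0) / 2.0) ** (1.0 / (alpha - 1.0))
    a = (alpha - 1.0) / 2.0
    sech = 1.0 / np.cosh(a * x)
    return amp * (2.0 / (alpha - 1.0)) * sech ** (2.0 / (alpha - 1.0)) * (-a * np.tanh(a * x))


class ReferenceSolution:
    """The canonical bell shape U_alpha on [-c, c] with its peak and mass.

    Attributes
    ----------
    alpha, c : problem parameters
    grid, values : the stored solution table (uniform grid)
    peak : U_alpha(0) = max of the profile
    mass : |U_alpha| = integral of U_alpha over [-c, c]
    """

    def __init__(self, alpha: float, c: float, grid: np.ndarray, values: np.ndarray,
                 peak: float | None = None, mass: float | None = None):
        self.alpha = float(alpha)
        self.c = float(c)
        self.grid = np.asarray(grid, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.peak = float(peak) if peak is not None else float(self.values.max())
        if mass is not None:
            self.mass = float(mass)
        else:
            self.mass = float(trapezoid(self.values, self.grid))
        self._spline = CubicSpline(self.grid, self.values, bc_type="natural")
        self._dspline = self._spline.derivative()

    def u(self, x) -> np.ndarray:
        """Evaluate U_alpha(x); zero outside [-c, c] (Dirichlet extension)."""
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) <= self.c
        out = np.zeros_like(x)
        out[inside] = np.clip(self._spline(x[inside]), 0.0, None)
        return out

    def du(self, x) -> np.ndarray:
        """Evaluate U_alpha'(x); zero outside [-c, c]."""
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) <= self.c
        out = np.zeros_like(x)
        out[inside] = self._dspline(x[inside])
        return out

    # -- plain-text persistence -------------------------------------------

    def to_text(self) -> str:
        buf = _io.StringIO()
        buf.write(f"# alpha={self.alpha!r}\n# c={self.c!r}\n")
        buf.write(f"# peak={self.peak!r}\n# mass={self.mass!r}\n")
        buf.write("# x u\n")
        for xi, ui in zip(self.grid, self.values):
            buf.write(f"{float(xi)!r} {float(ui)!r}\n")
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceSolution":
        meta: dict[str, float] = {}
        xs, us = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = float(val)
                continue
            a, b = line.split()
            xs.append(float(a))
            us.append(float(b))
        return cls(meta["alpha"], meta["c"], np.array(xs), np.array(us),
                   peak=meta.get("peak"), mass=meta.get("mass"))

    def content_hash(self) -> str:
        """Short digest of the solution table, embedded in fit outputs."""
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ReferenceSolution(alpha={self.alpha}, c={self.c}, "
                f"peak={self.peak:.6f}, mass={self.mass:.6f}, n={self.grid.size})")


def solve_reference(alpha: float = 1.2, c: float = 15.0, n_mesh: int = 401,
                    n_out: int = 2001, tol: float = 1e-10) -> ReferenceSolution:
    """Solve -u'' = -u + u^alpha on [-c, c] with zero boundary values.

    The problem has at least two solutions (u = 0 and the positive ground
    state); the collocation solver is seeded with the closed-form
    infinite-domain ground state so it converges to the positive one.

    Parameters
    ----------
    alpha : superlinearity exponent, > 1
    c : domain half-width
    n_mesh : initial collocation mesh size (>= 51)
    n_out : size of the uniform output grid the solution is stored on
    tol : collocation residual tolerance

    Returns
    -------
    ReferenceSolution with mass |U_alpha| computed by composite trapezoid
    on the output grid (cross-checked against Simpson).
    """
    if not alpha > 1:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    if not c > 0:
        raise ValueError(f"c must be > 0, got {c}")
    if n_mesh < 51:
        raise ValueError(f"n_mesh must be >= 51, got {n_mesh}")

    def rhs(x, y):
        u = y[0]
        # sign-safe power: iterates may dip slightly below zero
        return np.vstack([y[1], u - np.sign(u) * np.abs(u) ** alpha])

    def bc(ya, yb):
        return np.array([ya[0], yb[0]])

    x0 = np.linspace(-c, c, n_mesh)
    y0 = np.vstack([closed_form_reference(alpha, x0), _closed_form_derivative(alpha, x0)])
    sol = solve_bvp(rhs, bc, x0, y0, tol=tol, max_nodes=200_000)
    if not sol.success:
        raise RuntimeError(
            f"reference BVP solver failed for alpha={alpha}, c={c}: {sol.message}")

    grid = np.linspace(-c, c, n_out)
    values = np.clip(sol.sol(grid)[0], 0.0, None)
    values[0] = values[-1] = 0.0
    peak = float(values.max())
    if peak < 1e-6:
        raise RuntimeError(
            f"reference BVP converged to the trivial solution for alpha={alpha}, "
            f"c={c}; try a different initial guess")

    mass_trap = float(trapezoid(values, grid))
    mass_simp = float(simpson(values, x=grid))
    if abs(mass_trap - mass_simp) > 1e-4 * mass_simp:
        raise RuntimeError(
            f"quadrature inconsistency for |U_alpha|: trapezoid {mass_trap} vs "
            f"Simpson {mass_simp}; refine n_out")
    return ReferenceSolution(alpha, c, grid, values, peak=peak, mass=mass_trap)


@dataclass(frozen=True)
class SolvabilityReport:
    """Outcome of the lam calibration for a given set of rates.

    discriminant : value of the existence discriminant (<= 0 means solvable)
    n_roots : 0, 1 (tangency) or 2 positive roots
    roots : the positive roots, increasing
    lam_star : stationary point of the calibration function, which is the
        unique root in the tangency case
    """

    discriminant: float
    n_roots: int
    roots: tuple[float, ...]
    lam_star: float


def discriminant(rates: Rates, consts: ModelConstants, ref: ReferenceSolution) -> float:
    """Existence discriminant for the polarity profile.

    Returns knf/kpf - (1/alpha) * ((alpha-1)/alpha * sqrt(knf/D1) *
    Rtot / |U_alpha|)^(alpha-1).  A positive steady-state profile exists
    iff the returned value is <= 0.
    """
    a = consts.alpha
    mu = np.sqrt(rates.knf / consts.d1)
    return float(rates.knf / rates.kpf
                 - (1.0 / a) * ((a - 1.0) / a * mu * consts.rtot / ref.mass) ** (a - 1.0))


def _calibration_lhs(lam: float, rates: Rates, consts: ModelConstants,
                     ref: ReferenceSolution) -> float:
    """Left-hand side of the scalar calibration equation for lam."""
    a = consts.alpha
    nu_c = np.sqrt(consts.d1 / rates.knf) * ref.mass / consts.rtot
    return rates.knf / rates.kpf - lam ** (a - 1.0) + lam ** a * nu_c


def solve_lambda(rates: Rates, consts: ModelConstants, ref: ReferenceSolution,
                 tangency_tol: float = 1e-9) -> SolvabilityReport:
    """Find all positive roots of the lam calibration equation.

    The calibration function f(lam) = knf/kpf - lam^(alpha-1)
    + lam^alpha * sqrt(D1/knf) |U_alpha| / Rtot decreases to a unique
    minimum at lam* = (alpha-1)/alpha * mu Rtot / |U_alpha| (where its
    value equals the discriminant) and increases beyond; the membrane-mass
    bound lam |U_alpha| / mu <= Rtot caps the search at
    lam_max = mu Rtot / |U_alpha|, where f = knf/kpf > 0.  Roots are
    therefore bracketed on (0, lam*) and (lam*, lam_max).

    Never raises for an unsolvable configuration: a positive discriminant
    simply yields a zero-root report.
    """
    a = consts.alpha
    mu = np.sqrt(rates.knf / consts.d1)
    nu_c = np.sqrt(consts.d1 / rates.knf) * ref.mass / consts.rtot
    lam_star = (a - 1.0) / (a * nu_c)
    disc = discriminant(rates, consts, ref)

    f = lambda lam: _calibration_lhs(lam, rates, consts, ref)

    if disc > tangency_tol:
        return SolvabilityReport(disc, 0, (), lam_star)
    if abs(disc) <= tangency_tol:
        return SolvabilityReport(disc, 1, (lam_star,), lam_star)

    lam_max = mu * consts.rtot / ref.mass
    lo = brentq(f, 0.0, lam_star, xtol=1e-14, rtol=8.9e-16)
    hi = brentq(f, lam_star, lam_max, xtol=1e-14, rtol=8.9e-16)
    for root in (lo, hi):
        if abs(f(root)) > 1e-8:
            raise RuntimeError(f"calibration root {root} has residual {f(root)}")
    return SolvabilityReport(disc, 2, (float(lo), float(hi)), lam_star)


def evaluate_profile(shape: ShapeParams, ref: ReferenceSolution, x) -> np.ndarray:
    """Evaluate R(x) = lam * U_alpha(mu x) at the given positions."""
    return shape.lam * ref.u(shape.mu * np.asarray(x, dtype=float))


def rates_from_shape(shape: ShapeParams, consts: ModelConstants,
                     ref: ReferenceSolution) -> Rates:
    """Invert the shape parameters into the mechanistic feedback rates.

    knf = D1 mu^2 and kpf = D1 mu^2 / (lam^(alpha-1)
    - lam^alpha |U_alpha| / (mu Rtot)); requires the strict feasibility
    constraint mu Rtot - lam |U_alpha| > 0.
    """
    a = consts.alpha
    slack = shape.mu * consts.rtot - shape.lam * ref.mass
    if not slack > 0:
        raise ValueError(
            "constraint mu*Rtot - lam*|U_alpha| > 0 violated "
            f"(mu={shape.mu}, lam={shape.lam}, slack={slack})")
    knf = consts.d1 * shape.mu ** 2
    denom = shape.lam ** (a - 1.0) - shape.lam ** a * ref.mass / (shape.mu * consts.rtot)
    return Rates(knf=float(knf), kpf=float(knf / denom))


def membrane_fraction(shape: ShapeParams, consts: ModelConstants,
                      ref: ReferenceSolution) -> float:
    """Fraction r = lam |U_alpha| / (mu Rtot) of ROP1 residing on the membrane."""
    r = shape.lam * ref.mass / (shape.mu * consts.rtot)
    if r >= 1:
        raise ValueError(
            f"membrane mass exceeds total free ROP1 (fraction {r} >= 1)")
    return float(r)


def rescale_rates(rates: Rates, alpha: float, r0: float) -> Rates:
    """Rate shift induced by renormalizing intensities by a constant R0.

    Dividing the profile (and Rtot) by R0 leaves knf unchanged and maps
    kpf -> kpf * R0^(alpha-1).
    """
    if not r0 > 0:
        raise ValueError(f"R0 must be > 0, got {r0}")
    return Rates(knf=rates.knf, kpf=rates.kpf * r0 ** (alpha - 1.0))
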