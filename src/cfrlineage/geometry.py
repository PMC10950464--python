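"""Analytic spiral-escape model of trajectory separation.

A minimal planar model for differentiation trajectories leaving a
multi-potent state at the origin: dr/dt = a*r (exponential radial escape)
and dtheta/dt = b/(1 + c*r) (rotation that dies off far from the origin).
Trajectories are logarithmic-type spirals that straighten into rays toward
N = 3 symmetric fates.  Clustering with disc-like clusters of radius r0 can
only keep the three fates apart when consecutive spiral arms stay at least
one cluster diameter apart; this module provides the closed-form trajectory
shape, the separation criterion and its thresholds, the generalization to
arbitrary monotone kinetics f(r), g(r) via the transfer function
F(r) = exp(-int_r^inf g/f ds), the concavity-based separation theorem
checker, and the N-fate threshold a/b >= N log N / (2 pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

__all__ = [
    "GeomParams",
    "GeneralKinetics",
    "SeparationVerdict",
    "r_of_theta",
    "theta0",
    "separation_radius",
    "critical_b",
    "well_separated",
    "general_F",
    "concavity_report",
    "theorem_check",
    "nfate_threshold",
    "separation_threshold_E",
]


@dataclass(frozen=True)
class GeomParams:
    """Rates of the specific spiral model.

    a_rad : radial expansion rate (per time).
    b_ang : angular rate at the origin (per time); larger b means more
            spiralling before escape.
    c_sat : saturation scale; rotation shuts off for r >> 1/c_sat.
    """

    a_rad: float = 0.1
    b_ang: float = 0.5
    c_sat: float = 10.0

    def __post_init__(self) -> None:
        if self.a_rad <= 0 or self.b_ang <= 0 or self.c_sat <= 0:
            raise ValueError("all rates must be strictly positive")


@dataclass(frozen=True)
class GeneralKinetics:
    """User-supplied kinetics rdot = a*f(r), thetadot = b*g(r).

    Required: f(0) = 0, f non-decreasing; g(0) = 1, g positive,
    non-increasing, g(r) -> 0 as r -> infinity.  ``validate`` checks these
    numerically on a log-spaced grid since f and g are black boxes.
    """

    f_radial: Callable[[float], float]
    g_angular: Callable[[float], float]

    def validate(self, r_lo: float = 1e-4, r_hi: float = 1e4, n: int = 200) -> None:
        grid = np.logspace(math.log10(r_lo), math.log10(r_hi), n)
        if abs(self.f_radial(0.0)) > 1e-12:
            raise ValueError("f(0) must be 0")
        fv = np.array([self.f_radial(r) for r in grid])
        gv = np.array([self.g_angular(r) for r in grid])
        if np.any(np.diff(fv) < -1e-12):
            raise ValueError("f must be non-decreasing")
        if abs(self.g_angular(0.0) - 1.0) > 1e-9:
            raise ValueError("g(0) must be 1")
        # g may underflow to exactly 0 in the far tail; negatives are an error
        if np.any(gv < 0) or gv[0] <= 0:
            raise ValueError("g must be positive")
        if np.any(np.diff(gv) > 1e-12):
            raise ValueError("g must be non-increasing")
        if gv[-1] > 0.1:
            raise ValueError("g must decay toward 0 at large r")


@dataclass(frozen=True)
class SeparationVerdict:
    """Outcome of the well-separation test for cluster radius r0.

    expansion_ratio_E = exp(2*pi*a/(3*b)) is the radial growth factor per
    third-turn; required_radius R(E) is the smallest cluster radius at which
    consecutive arms stay one cluster diameter apart (non-positive when any
    radius works).  ``separated`` is the closed-form verdict,
    ``separated_numeric`` the ODE-integration oracle, ``already_radial``
    flags the degenerate case where the trajectory reaches its asymptotic
    ray within the compared third-turn.
    """

    r0: float
    expansion_ratio_E: float
    required_radius: float
    separated: bool
    separated_numeric: bool
    already_radial: bool = False

    def __post_init__(self) -> None:
        if self.expansion_ratio_E <= 1:
            raise ValueError("expansion_ratio_E must exceed 1")


def r_of_theta(theta: float, gp: GeomParams) -> float:
    """Trajectory shape r(theta) = e^{a theta/b} / (c (1 - e^{a theta/b})).

    The constant of integration is fixed so theta -> 0 from below as
    r -> infinity; hence theta < 0 along the whole trajectory.
    """
    if theta >= 0:
        raise ValueError("trajectory is defined for theta < 0")
    u = math.exp(gp.a_rad * theta / gp.b_ang)
    return u / (gp.c_sat * (1.0 - u))


def theta0(r0: float, gp: GeomParams) -> float:
    """Angle at which the trajectory crosses radius r0 (always negative)."""
    if r0 <= 0:
        raise ValueError("r0 must be strictly positive")
    return (gp.b_ang / gp.a_rad) * math.log(gp.c_sat * r0 / (1.0 + gp.c_sat * r0))


def separation_radius(E: float, c_sat: float) -> float:
    """Minimum cluster radius R(E) = (3 - E) / (3 c (E - 1)) for separation.

    Negative exactly when E > 3, i.e. when the spiral grows by more than a
    factor 3 per third-turn, so separation then holds for every r0 —
    equivalently for any number of clusters.
    """
    if E <= 1:
        raise ValueError("E must exceed 1")
    return (3.0 - E) / (3.0 * c_sat * (E - 1.0))


def separation_threshold_E(c_sat: float = 1.0, hi: float = 100.0) -> float:
    """Smallest E > 1 at and above which R(E) <= 0, found by bracketing.

    R is continuous and strictly decreasing on (1, inf), so the threshold is
    its unique root (independent of c_sat).
    """
    lo = 1.0 + 1e-9
    return float(brentq(lambda E: separation_radius(E, c_sat), lo, hi, xtol=1e-12))


def critical_b(a_rad: float) -> float:
    """Angular-rate threshold 2*pi*a/(3*log 3).

    For b below this value, E > 3 and trajectories are well-separated for
    every cluster radius; equivalently a/b >= (3 log 3)/(2 pi) ~ 0.52.
    """
    if a_rad <= 0:
        raise ValueError("a_rad must be strictly positive")
    return 2.0 * math.pi * a_rad / (3.0 * math.log(3.0))


def _r_after_third_turn_numeric(gp: GeomParams, r0: float) -> float:
    """Integrate dr/dtheta = (a/b) r (1 + c r) over one third-turn from
    (theta0, r0).  Independent of the closed form r(theta)."""
    th0 = theta0(r0, gp)

    def rhs(theta, r):
        return (gp.a_rad / gp.b_ang) * r[0] * (1.0 + gp.c_sat * r[0])

    sol = solve_ivp(
        rhs,
        (th0, th0 + 2.0 * math.pi / 3.0),
        [r0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    return float(sol.y[0, -1])


def well_separated(gp: GeomParams, r0: float) -> SeparationVerdict:
    """Test whether three symmetric spiral trajectories stay one cluster
    diameter (2*r0) apart, comparing consecutive arms along the theta0 ray.

    Closed form: separated iff r(theta0 + 2 pi/3) >= 3 r0, equivalently
    r0 >= R(E) with E = exp(2 pi a / (3 b)).  A numerical verdict obtained
    by integrating the trajectory ODE over the third-turn is reported
    alongside; the two must agree.  If theta0 + 2 pi/3 >= 0 the inner arm
    has already straightened into its ray before the comparison point, so
    the trajectories cannot re-approach: separated by construction.
    """
    if r0 <= 0:
        raise ValueError("r0 must be strictly positive")
    E = math.exp(2.0 * math.pi * gp.a_rad / (3.0 * gp.b_ang))
    R = separation_radius(E, gp.c_sat)
    th0 = theta0(r0, gp)
    if th0 + 2.0 * math.pi / 3.0 >= 0.0:
        return SeparationVerdict(
            r0=r0,
            expansion_ratio_E=E,
            required_radius=R,
            separated=True,
            separated_numeric=True,
            already_radial=True,
        )
    sep_closed = r0 >= R
    r_turn = _r_after_third_turn_numeric(gp, r0)
    sep_numeric = r_turn >= 3.0 * r0 * (1.0 - 1e-9)  # oracle at solver tolerance
    return SeparationVerdict(
        r0=r0,
        expansion_ratio_E=E,
        required_radius=R,
        separated=sep_closed,
        separated_numeric=sep_numeric,
    )


def general_F(gk: GeneralKinetics, r: float, tol: float = 1e-10) -> float:
    """Transfer function F(r) = exp(-int_r^inf g(s)/f(s) ds).

    F(0) = 0, F is increasing and F -> 1 as r -> infinity; along a
    trajectory F(r) = exp(a*theta/b).  The semi-infinite integral is done by
    adaptive quadrature with the infinite tail handled by scipy's
    transformation; integrability near r is the caller's responsibility (a
    non-integrable g/f raises from the quadrature).
    """
    if r < 0:
        raise ValueError("r must be nonnegative")
    if r == 0:
        return 0.0
    val, _ = quad(
        lambda s: gk.g_angular(s) / gk.f_radial(s),
        r,
        np.inf,
        epsabs=tol,
        epsrel=tol,
        limit=400,
    )
    return math.exp(-val)


def concavity_report(
    gk: GeneralKinetics, r_lo: float = 1e-4, r_hi: float = 1e4, n: int = 200
) -> dict:
    """Check concavity of F via second differences on a log-spaced grid.

    Symbolic differentiation is unavailable for black-box kinetics, so
    concavity is certified numerically: nonpositive (up to quadrature noise)
    second differences at every interior grid point.
    """
    grid = np.logspace(math.log10(r_lo), math.log10(r_hi), n)
    F = np.array([general_F(gk, r) for r in grid])
    h1 = np.diff(grid)[:-1]
    h2 = np.diff(grid)[1:]
    second = 2.0 * (h1 * F[2:] - (h1 + h2) * F[1:-1] + h2 * F[:-2]) / (h1 * h2 * (h1 + h2))
    concave = bool(np.all(second <= 1e-8))
    return {
        "grid": grid,
        "F": F,
        "second_differences": second,
        "concave": concave,
        "max_second_difference": float(second.max()),
    }


def theorem_check(
    gk: GeneralKinetics,
    a_rad: float,
    b_ang: float,
    trials: int = 100,
    seed: int = 0,
    r0_range: tuple[float, float] = (1e-3, 1e2),
) -> dict:
    """Verify the separation theorem numerically on random cluster radii.

    For concave F and a/b >= (3 log 3)/(2 pi), the inequality
    F(r0) * exp(2 pi a / (3 b)) >= F(3 r0) must hold for every r0; each
    violation (beyond quadrature tolerance) is recorded.  Also reports the
    concavity chord bound F(3 r0)/3 <= F(r0) (the lambda = 1/3 instance of
    the concavity definition with the other endpoint at zero).
    """
    rep = concavity_report(gk)
    if not rep["concave"]:
        raise ValueError("kinetics failed the numerical concavity check")
    at_or_above = a_rad >= nfate_threshold(3) * b_ang
    rng = np.random.default_rng(seed)
    lo, hi = r0_range
    r0s = np.exp(rng.uniform(math.log(lo), math.log(hi), size=trials))
    E = math.exp(2.0 * math.pi * a_rad / (3.0 * b_ang))
    violations = []
    chord_violations = []
    for r0 in r0s:
        F1 = general_F(gk, float(r0))
        F3 = general_F(gk, float(3.0 * r0))
        if F1 * E < F3 * (1.0 - 1e-8):
            violations.append(float(r0))
        if F3 / 3.0 > F1 * (1.0 + 1e-8):
            chord_violations.append(float(r0))
    return {
        "threshold_satisfied": at_or_above,
        "expansion_ratio_E": E,
        "n_trials": trials,
        "violations": violations,
        "chord_violations": chord_violations,
    }


def nfate_threshold(N: int) -> float:
    """Required a/b ratio N log N / (2 pi) for N symmetric fates.

    Specializes to (3 log 3)/(2 pi) ~ 0.52 for the three-fate model and is
    strictly increasing in N: more fates demand faster radial escape per
    unit rotation.
    """
    if not isinstance(N, (int, np.integer)) or N < 2:
        raise ValueError("N must be an integer >= 2")
    return N * math.log(N) / (2.0 * math.pi)
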