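"""Cross-repressilator model of cyclical fate restriction (CFR).

Three transcription factors (TFs) x1, x2, x3 mutually inhibit each other
through two directed rings of repression with strengths ``alpha`` and
``beta``.  A slowly increasing exogenous signal g(t) drives the cell from a
symmetric multi-potent state through a Hopf bifurcation into one of three
differentiated states where a single TF dominates.  This module provides the
drift field, deterministic (ODE) and stochastic (Euler--Maruyama SDE)
simulation, the symmetric equilibrium, and the closed-form linear-stability
analysis of its circulant Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "CFRParams",
    "SignalParams",
    "SimSettings",
    "Trajectory",
    "StabilityResult",
    "signal_g",
    "drift",
    "simulate_ode",
    "simulate_sde",
    "simulate_sde_ensemble",
    "symmetric_equilibrium",
    "linear_stability",
    "hopf_scan",
]


@dataclass(frozen=True)
class CFRParams:
    """Kinetic parameters of the cross-repressilator.

    b_prod : basal production rate (concentration/time).
    alpha  : inhibition strength of the first repression ring; controls the
             amount of spiralling (twisting) of differentiation trajectories.
    beta   : inhibition strength of the second ring.
    d_deg  : first-order degradation rate (1/time).
    hill_h : Hill exponent of the inhibitory response.
    """

    b_prod: float = 1e-3
    alpha: float = 1000.0
    beta: float = 0.1
    d_deg: float = 0.1
    hill_h: float = 3.0

    def __post_init__(self) -> None:
        for name in ("b_prod", "alpha", "beta", "d_deg", "hill_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.hill_h < 1:
            raise ValueError("hill_h must be >= 1")


@dataclass(frozen=True)
class SignalParams:
    """Exogenous signal g(t) = g_amp * t / (t + g_tau)."""

    g_amp: float = 4.0
    g_tau: float = 2000.0

    def __post_init__(self) -> None:
        if self.g_amp <= 0 or self.g_tau <= 0:
            raise ValueError("g_amp and g_tau must be strictly positive")


@dataclass(frozen=True)
class SimSettings:
    """Integration window, step, noise amplitude and seed for one cell."""

    t_start: float = 0.0
    t_end: float = 2000.0
    dt: float = 0.1
    sigma: float = 0.01
    seed: int = 0
    x0: tuple[float, float, float] = (0.097, 0.09, 0.1)

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if any(x <= 0 for x in self.x0):
            raise ValueError("x0 components must be strictly positive")


@dataclass
class Trajectory:
    """One simulated cell path: times and the 3-component TF state."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 3):
            raise ValueError("states must be (len(times), 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("states must be nonnegative")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path) -> None:
        """Write ``t,x1,x2,x3`` rows at full float precision."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "t": self.times,
                "x1": self.states[:, 0],
                "x2": self.states[:, 1],
                "x3": self.states[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class StabilityResult:
    """Eigenstructure of the circulant Jacobian at the symmetric equilibrium.

    The complex pair governs the oscillatory (Hopf) instability transverse to
    the diagonal; the real eigenvalue acts along the (1,1,1) direction.
    """

    x_star: float
    eig_real_pair: float
    eig_imag_pair: float
    eig_real_sym: float

    def __post_init__(self) -> None:
        if self.eig_imag_pair < 0:
            raise ValueError("eig_imag_pair must be nonnegative")


def signal_g(t, p: SignalParams = SignalParams()):
    """Exogenous signalling input g(t) = g_amp * t / (t + g_tau).

    Rises from 0 at t=0 toward the saturation level g_amp; with the defaults
    g(2000) = 2.  Accepts scalars or arrays; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("signal_g requires t >= 0")
    out = p.g_amp * t / (t + p.g_tau)
    return float(out) if out.ndim == 0 else out


def drift(state, t: float, p: CFRParams, s: SignalParams = SignalParams()):
    """Deterministic rate of change of the three TF levels.

    Component i has a constant basal production b, a signal-driven
    production g(t) attenuated by an OR-gate of the two Hill-type
    inhibitions — alpha from the next TF in cyclic order and beta from the
    previous — and first-order degradation d_deg * x_i.  The uninhibited
    basal term keeps every level above ~b/d, which is what prevents
    unphysically negative or vanishing TF levels.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (3,):
        raise ValueError("state must be a 3-vector")
    if np.any(x < 0):
        raise ValueError("state components must be nonnegative")
    g = signal_g(t, s)
    xh = x**p.hill_h
    out = np.empty(3)
    for i in range(3):
        j = (i + 1) % 3  # alpha-ring partner
        k = (i + 2) % 3  # beta-ring partner
        out[i] = (
            p.b_prod
            + g / ((1.0 + p.alpha * xh[j]) * (1.0 + p.beta * xh[k]))
            - p.d_deg * x[i]
        )
    return out


def simulate_ode(
    p: CFRParams, s: SignalParams = SignalParams(), settings: SimSettings = SimSettings()
) -> Trajectory:
    """Integrate the noise-free system with an adaptive high-order scheme.

    The solution is evaluated on the same uniform dt-grid that the SDE
    integrator stores, so the two are directly comparable.  Tolerances are
    tight (rtol 1e-8, atol 1e-10) because this path serves as ground truth
    for validating the stochastic integrator at sigma = 0.
    """
    t_eval = np.arange(
        settings.t_start,
        settings.t_end + 0.5 * settings.dt,
        settings.dt,
    )

    def rhs(t, x):
        return drift(np.maximum(x, 0.0), t, p, s)

    sol = solve_ivp(
        rhs,
        (settings.t_start, settings.t_end),
        np.asarray(settings.x0, dtype=float),
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, np.maximum(sol.y.T, 0.0))


def simulate_sde(
    p: CFRParams, s: SignalParams = SignalParams(), settings: SimSettings = SimSettings()
) -> Trajectory:
    """Euler--Maruyama sample path of the CFR SDE.

    Increment per component: drift*dt + sigma*x*sqrt(dt)*N(0,1) with
    independent standard normals per component per step.  The multiplicative
    noise keeps relative fluctuations bounded, so levels stay positive in
    practice; states are nevertheless floored at zero after each step as a
    guard.  Fully reproducible from ``settings.seed``.
    """
    n_steps = int(round((settings.t_end - settings.t_start) / settings.dt))
    dt = settings.dt
    sqdt = math.sqrt(dt)
    rng = np.random.default_rng(settings.seed)
    normals = rng.standard_normal((n_steps, 3))

    b, alpha, beta, d, h = p.b_prod, p.alpha, p.beta, p.d_deg, p.hill_h
    g_amp, g_tau = s.g_amp, s.g_tau
    sigma = settings.sigma

    out = np.empty((n_steps + 1, 3))
    x1, x2, x3 = settings.x0
    out[0] = (x1, x2, x3)
    t = settings.t_start
    # scalar inner loop: small fixed dimension makes per-step array overhead
    # the bottleneck otherwise
    for n in range(n_steps):
        g = g_amp * t / (t + g_tau)
        x1h = x1**h
        x2h = x2**h
        x3h = x3**h
        f1 = b + g / ((1.0 + alpha * x2h) * (1.0 + beta * x3h)) - d * x1
        f2 = b + g / ((1.0 + alpha * x3h) * (1.0 + beta * x1h)) - d * x2
        f3 = b + g / ((1.0 + alpha * x1h) * (1.0 + beta * x2h)) - d * x3
        w1, w2, w3 = normals[n]
        x1 += f1 * dt + sigma * x1 * sqdt * w1
        x2 += f2 * dt + sigma * x2 * sqdt * w2
        x3 += f3 * dt + sigma * x3 * sqdt * w3
        if x1 < 0.0:
            x1 = 0.0
        if x2 < 0.0:
            x2 = 0.0
        if x3 < 0.0:
            x3 = 0.0
        t = settings.t_start + (n + 1) * dt
        out[n + 1] = (x1, x2, x3)

    times = settings.t_start + dt * np.arange(n_steps + 1)
    return Trajectory(times, out)


def simulate_sde_ensemble(
    p: CFRParams,
    s: SignalParams = SignalParams(),
    settings: SimSettings = SimSettings(),
    n_paths: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler--Maruyama sample paths for ``n_paths`` independent cells at once.

    Identical scheme to :func:`simulate_sde` but vectorized across paths,
    which is what makes ensemble-based snapshot generation affordable.
    Returns ``(times, states)`` with states of shape
    (n_steps + 1, n_paths, 3).  Paths are mutually independent and the whole
    ensemble is reproducible from ``settings.seed``.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    n_steps = int(round((settings.t_end - settings.t_start) / settings.dt))
    dt = settings.dt
    sqdt = math.sqrt(dt)
    rng = np.random.default_rng(settings.seed)
    b, alpha, beta, d, h = p.b_prod, p.alpha, p.beta, p.d_deg, p.hill_h
    sigma = settings.sigma

    x = np.tile(np.asarray(settings.x0, dtype=float), (n_paths, 1))
    out = np.empty((n_steps + 1, n_paths, 3))
    out[0] = x
    t = settings.t_start
    for n in range(n_steps):
        g = s.g_amp * t / (t + s.g_tau)
        xh = x**h
        inh = (1.0 + alpha * xh[:, [1, 2, 0]]) * (1.0 + beta * xh[:, [2, 0, 1]])
        f = b + g / inh - d * x
        x = x + f * dt + sigma * x * sqdt * rng.standard_normal((n_paths, 3))
        np.maximum(x, 0.0, out=x)
        t = settings.t_start + (n + 1) * dt
        out[n + 1] = x
    times = settings.t_start + dt * np.arange(n_steps + 1)
    return times, out


def symmetric_equilibrium(p: CFRParams, g_level: float) -> float:
    """Positive root x* of d*x = b + g / ((1 + alpha*x^h)(1 + beta*x^h)).

    On the diagonal x1 = x2 = x3 the three equations coincide.  The residual
    d*x - b - g/(...) is strictly increasing in x, negative at x = 0 and
    positive for large x, so the root is unique.  Solved by bracketing to
    relative tolerance 1e-10 or better.
    """
    if g_level < 0:
        raise ValueError("g_level must be nonnegative")

    def resid(x):
        xh = x**p.hill_h
        return (
            p.d_deg * x
            - p.b_prod
            - g_level / ((1.0 + p.alpha * xh) * (1.0 + p.beta * xh))
        )

    hi = max((p.b_prod + g_level) / p.d_deg, 1.0)
    while resid(hi) < 0:
        hi *= 2.0
    return brentq(resid, 0.0, hi, rtol=1e-12, xtol=1e-300)


def _hill_partials(p: CFRParams, g_level: float, x_star: float) -> tuple[float, float]:
    """(A, B): magnitudes of the Jacobian off-diagonals at the equilibrium.

    Only the signal-driven production term is inhibited, so the partial
    derivatives scale with g_level, not with b + g.
    """
    num = g_level
    xh = x_star**p.hill_h
    da = 1.0 + p.alpha * xh
    db = 1.0 + p.beta * xh
    common = num * p.hill_h * x_star ** (p.hill_h - 1.0)
    A = common * p.alpha / (da * da * db)
    B = common * p.beta / (da * db * db)
    return A, B


def linear_stability(p: CFRParams, g_level: float) -> StabilityResult:
    """Closed-form eigenvalues of the circulant Jacobian at x*.

    The Jacobian has diagonal -d and off-diagonals -A (alpha ring) and -B
    (beta ring), where A and B are the Hill-term partial derivatives.  Its
    eigenvalues are -d - A - B (along the diagonal direction) and the complex
    pair -d + (A+B)/2 +/- i*sqrt(3)*|A-B|/2.  The imaginary part is
    proportional to alpha - beta near the bifurcation, so stronger ring
    asymmetry means faster spiralling.
    """
    x_star = symmetric_equilibrium(p, g_level)
    A, B = _hill_partials(p, g_level, x_star)
    return StabilityResult(
        x_star=x_star,
        eig_real_pair=-p.d_deg + (A + B) / 2.0,
        eig_imag_pair=math.sqrt(3.0) * abs(A - B) / 2.0,
        eig_real_sym=-p.d_deg - A - B,
    )


def jacobian_at_equilibrium(p: CFRParams, g_level: float) -> np.ndarray:
    """Explicit 3x3 Jacobian at the symmetric equilibrium (oracle helper)."""
    x_star = symmetric_equilibrium(p, g_level)
    A, B = _hill_partials(p, g_level, x_star)
    J = np.full((3, 3), 0.0)
    for i in range(3):
        J[i, i] = -p.d_deg
        J[i, (i + 1) % 3] = -A
        J[i, (i + 2) % 3] = -B
    return J


def hopf_scan(p: CFRParams, s: SignalParams, t_grid) -> float | None:
    """Earliest grid time at which the symmetric equilibrium is unstable.

    Evaluates the real part of the complex eigenvalue pair, -d + (A+B)/2, at
    g(t) for each t and returns the first time it is positive, or None if
    the equilibrium stays stable over the whole grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    for t in t_grid:
        res = linear_stability(p, signal_g(float(t), s))
        if res.eig_real_pair > 0:
            return float(t)
    return None
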