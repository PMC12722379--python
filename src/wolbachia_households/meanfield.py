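"""Deterministic mean-field model: steady states, stability and basins.

The densities of wildtype (``N_m``) and Wolbachia-infected (``N_w``) female
mosquitoes per household follow

    dN_m/dt = b Z_m F(N_m + N_w) - d N_m
    dN_w/dt = b Z_w F(N_m + N_w) - delta d N_w

with the same effective-parent terms and larval density factor as the
stochastic model, evaluated at real-valued densities.  When cytoplasmic
incompatibility and vertical transmission are strong the system is bistable:
a wildtype-only state E1 and a Wolbachia-only state E2 are both stable and a
coexistence saddle E3 separates their basins.  The minimum infected fraction
whose trajectory converges to E2 is the invasion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ModelParams, density_inverse, larval_density

__all__ = [
    "vector_field",
    "SteadyStates",
    "steady_states",
    "stability",
    "classify_basin",
    "invasion_threshold",
    "boundary_states",
]

_RHS_TOL = 1e-9


def vector_field(state, params: ModelParams) -> tuple[float, float]:
    """Right-hand side of the mean-field system at real-valued densities."""
    N_m, N_w = state
    if N_m < 0 or N_w < 0:
        raise ValueError(f"densities must be non-negative, got {state}")
    n = N_m + N_w
    if n == 0:
        return (0.0, 0.0)
    dens = larval_density(n, params)
    phi, u, v = params.phi, params.u, params.v
    leak = (1.0 - v) * phi * N_w
    z_m = N_m / n * (N_m + leak) + N_w / n * ((1.0 - u) * N_m + leak)
    z_w = v * phi * N_w
    return (
        params.b * z_m * dens - params.d * N_m,
        params.b * z_w * dens - params.d * params.delta * N_w,
    )


@dataclass(frozen=True)
class SteadyStates:
    """The four steady states with existence flags and stability labels.

    ``E0`` is total absence, ``E1`` the wildtype-only and ``E2`` the
    Wolbachia-only state (closed-form inversions of the density curve), and
    ``E3`` the coexistence point located numerically (``None`` when not
    found).  ``stability`` maps the names of existing states to
    {"stable", "unstable", "saddle"}.
    """

    E0: tuple[float, float]
    E1: tuple[float, float] | None
    E2: tuple[float, float] | None
    E3: tuple[float, float] | None
    stability: dict


def _jacobian(params: ModelParams, point, step: float = 1e-7) -> np.ndarray:
    """Finite-difference Jacobian, one-sided at the coordinate axes."""
    point = np.asarray(point, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        lo = point.copy()
        hi = point.copy()
        if point[j] >= step:
            lo[j] -= step
            hi[j] += step
        else:  # stay inside the non-negative quadrant
            hi[j] += step
        f_hi = np.asarray(vector_field(hi, params))
        f_lo = np.asarray(vector_field(lo, params))
        J[:, j] = (f_hi - f_lo) / (hi[j] - lo[j])
    return J


def stability(params: ModelParams, point, tol: float = _RHS_TOL) -> str:
    """Classify a steady state as stable, unstable or saddle.

    The origin is classified from the analytic boundary growth rates
    (``b - d`` along the wildtype axis, ``b v phi - delta d`` along the
    infected axis); elsewhere the eigenvalues of a finite-difference Jacobian
    are used.
    """
    f = np.asarray(vector_field(point, params))
    if np.linalg.norm(f) >= max(tol, 1e-6):
        raise ValueError(f"{tuple(point)} is not a steady state (|rhs|={np.linalg.norm(f):.2e})")
    if tuple(np.round(point, 12)) == (0.0, 0.0):
        eigs = np.array([params.b - params.d,
                         params.b * params.v * params.phi - params.delta * params.d])
    else:
        eigs = np.linalg.eigvals(_jacobian(params, point)).real
    if np.all(eigs < 0):
        return "stable"
    if np.all(eigs > 0):
        return "unstable"
    return "saddle"


def _find_coexistence(params: ModelParams, E1, E2) -> tuple[float, float] | None:
    """Locate the interior saddle by root finds seeded on the E1-E2 segment."""
    if E1 is None or E2 is None:
        return None
    e1 = np.asarray(E1)
    e2 = np.asarray(E2)
    for lam in np.linspace(0.1, 0.9, 9):
        start = (1 - lam) * e1 + lam * e2
        sol = root(lambda y: vector_field(np.maximum(y, 0.0), params), start, tol=1e-12)
        y = np.maximum(sol.x, 0.0)
        if not sol.success or np.linalg.norm(vector_field(y, params)) > _RHS_TOL:
            continue
        if y[0] > 1e-6 and y[1] > 1e-6:  # interior only
            return (float(y[0]), float(y[1]))
    return None


def steady_states(params: ModelParams, locate_coexistence: bool = True) -> SteadyStates:
    """All steady states of the mean-field system.

    E1 exists iff ``d/b < 1`` and E2 iff ``delta d / (b v phi) < 1`` (the
    respective density-curve inversions must land below the carrying
    capacity).
    """
    E1 = E2 = E3 = None
    ratio1 = params.d / params.b
    if 0.0 < ratio1 < 1.0:
        try:
            E1 = (density_inverse(ratio1, params), 0.0)
        except ValueError:
            E1 = None
    denom = params.b * params.v * params.phi
    ratio2 = params.delta * params.d / denom if denom > 0 else np.inf
    if 0.0 < ratio2 < 1.0:
        try:
            E2 = (0.0, density_inverse(ratio2, params))
        except ValueError:
            E2 = None
    if locate_coexistence:
        E3 = _find_coexistence(params, E1, E2)
    stab = {"E0": stability(params, (0.0, 0.0))}
    for name, pt in (("E1", E1), ("E2", E2), ("E3", E3)):
        if pt is not None:
            stab[name] = stability(params, pt)
    return SteadyStates(E0=(0.0, 0.0), E1=E1, E2=E2, E3=E3, stability=stab)


def classify_basin(
    initial,
    params: ModelParams,
    t_max: float = 5000.0,
    eps: float = 1e-3,
    _ss: SteadyStates | None = None,
) -> str:
    """Attractor label of the trajectory started at ``initial``.

    Integrates the mean-field system until the trajectory is within ``eps``
    of a stable steady state, returning ``"E1"`` (wildtype-only), ``"E2"``
    (Wolbachia-only) or ``"E0"`` (extinct); ``"unresolved"`` if no attractor
    is approached by ``t_max`` days.
    """
    ss = _ss if _ss is not None else steady_states(params, locate_coexistence=False)
    attractors = [("E0", np.zeros(2))] if ss.stability.get("E0") == "stable" else []
    for name, pt in (("E1", ss.E1), ("E2", ss.E2)):
        if pt is not None and ss.stability.get(name) == "stable":
            attractors.append((name, np.asarray(pt)))

    y = np.asarray(initial, dtype=float)
    if y[0] == 0.0 and y[1] == 0.0:
        return "E0"
    rhs = lambda t, state: vector_field(np.maximum(state, 0.0), params)
    t = 0.0
    chunk = 250.0
    while t < t_max:
        for name, pt in attractors:
            if np.linalg.norm(y - pt) < eps:
                return name
        sol = solve_ivp(rhs, (t, t + chunk), y, rtol=1e-9, atol=1e-9)
        y = np.maximum(sol.y[:, -1], 0.0)
        t += chunk
    for name, pt in attractors:
        if np.linalg.norm(y - pt) < eps:
            return name
    return "unresolved"


def invasion_threshold(
    params: ModelParams, N0: float, resolution: float = 1e-3
) -> float | None:
    """Minimum infected fraction of an N0-strong household that invades.

    Bisects the infected proportion p on ``((1-p) N0, p N0)`` between the
    wildtype-only and Wolbachia-only basins; ``None`` when the
    Wolbachia-only state is infeasible or unstable.
    """
    if not 0 < N0 <= params.C:
        raise ValueError(f"N0 must lie in (0, C={params.C}], got {N0}")
    ss = steady_states(params, locate_coexistence=False)
    if ss.E2 is None or ss.stability.get("E2") != "stable":
        return None

    def invades(p: float) -> bool:
        return classify_basin(((1 - p) * N0, p * N0), params, _ss=ss) == "E2"

    if not invades(1.0):
        return None
    lo, hi = 0.0, 1.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if invades(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def boundary_states(params: ModelParams, min_m: int = 1) -> list[tuple[int, int]]:
    """Integer states on the deterministic invasion boundary.

    For each wildtype count m, the smallest infected count w whose mean-field
    trajectory converges to the Wolbachia-only state.  These are the minimal
    deterministic release sizes against a resident population of m wildtypes.
    """
    ss = steady_states(params, locate_coexistence=False)
    out = []
    for m in range(min_m, params.C):
        for w in range(1, params.C - m + 1):
            if classify_basin((float(m), float(w)), params, _ss=ss) == "E2":
                out.append((m, w))
                break
    return out
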