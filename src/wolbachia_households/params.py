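"""Model parameters, larval density dependence and per-state event rates.

The model describes a household population of adult female mosquitoes split
into wildtype (count ``m``) and Wolbachia-infected (count ``w``) individuals.
Males are implicitly assumed equal in number and are not tracked.  Four events
change the state:

* wildtype birth at total rate ``b * Z_m * F(m + w)``,
* Wolbachia-infected birth at total rate ``b * Z_w * F(m + w)``,
* wildtype death at rate ``d * m``,
* infected death at rate ``d * delta * w``,

where ``Z_m`` and ``Z_w`` are the effective numbers of adults producing
wildtype and infected offspring (accounting for cytoplasmic incompatibility
``u``, vertical transmission ``v`` and the reproductive fitness cost
``1 - phi``), and ``F`` is a larval intraspecific-competition factor that
vanishes once the adult population reaches the reproductive carrying
capacity ``C``.

This module is the single source of truth for all transition rates; the
deterministic mean-field model and the CTMC generator are both built on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

__all__ = [
    "ModelParams",
    "EventRates",
    "tutorial_params",
    "full_params",
    "PRESETS",
    "default_h",
    "larval_density",
    "density_inverse",
    "effective_parents",
    "event_rates",
    "calibrate_birth_rate",
]

#: base coefficient of the exponential larval-competition curve; the curve
#: parameter is h = 0.19 * 100**k after rescaling densities to one household
#: area (100 m^2).
_H_COEFF = 0.19


def default_h(k: float) -> float:
    """Exact larval-competition coefficient ``0.19 * 100**k``.

    The rounded two-decimal value often quoted (0.76 for k=0.3) is not used
    internally: third-decimal agreement of the quasi-stationary distribution
    requires the exact value.
    """
    return _H_COEFF * 100.0**k


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for the household mosquito model.

    Parameters
    ----------
    b : float
        Maximum per-capita wildtype birth rate (1/day).
    d : float
        Per-capita wildtype death rate (1/day).
    delta : float
        Mortality cost multiplier of infection; infected death rate is
        ``delta * d`` (dimensionless, >= 1).
    phi : float
        Reproductive fitness multiplier in [0, 1]; the fitness cost of
        infection is ``1 - phi`` and the infected birth rate is ``phi * b``.
    u : float
        Cytoplasmic-incompatibility probability in [0, 1]: probability that
        offspring of an infected male and a wildtype female are not viable.
    v : float
        Vertical transmission probability in [0, 1]: probability that an
        infected female's offspring inherit the infection.
    C : int
        Reproductive carrying capacity; births stop once the female
        population reaches ``C``, which also caps the CTMC state space.
    k, h : float
        Larval competition parameters of the exponential density curve
        ``exp(-h * N**k)``.  ``h`` defaults to the exact ``0.19 * 100**k``.
    density : str
        ``"exp"`` for the exponential curve (alias ``"F"``) or ``"linear"``
        for the linear ramp ``1 - N/C`` (alias ``"G"``).
    """

    b: float
    d: float
    delta: float = 1.0
    phi: float = 1.0
    u: float = 1.0
    v: float = 1.0
    C: int = 30
    k: float = 0.3
    h: float | None = None
    density: str = "exp"

    def __post_init__(self) -> None:
        dens = {"F": "exp", "G": "linear"}.get(self.density, self.density)
        object.__setattr__(self, "density", dens)
        if self.h is None:
            object.__setattr__(self, "h", default_h(self.k))
        if not self.b > 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if not self.delta >= 1:
            raise ValueError(f"delta must be >= 1, got {self.delta}")
        for name in ("phi", "u", "v"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not (isinstance(self.C, int) and self.C >= 1):
            raise ValueError(f"C must be a positive integer, got {self.C}")
        if not self.h > 0:
            raise ValueError(f"h must be positive, got {self.h}")
        if not 0.0 < self.k <= 1.0:
            raise ValueError(f"k must lie in (0, 1], got {self.k}")
        if self.density not in ("exp", "linear"):
            raise ValueError(f"unknown density kind {self.density!r}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {
            "b": self.b, "d": self.d, "delta": self.delta, "phi": self.phi,
            "u": self.u, "v": self.v, "C": self.C, "k": self.k, "h": self.h,
            "density": self.density,
        }


class EventRates(NamedTuple):
    """Per-state transition rates (1/day) of the four demographic events."""

    wt_birth: float
    wolb_birth: float
    wt_death: float
    wolb_death: float

    @property
    def total(self) -> float:
        return self.wt_birth + self.wolb_birth + self.wt_death + self.wolb_death


def tutorial_params(**overrides) -> ModelParams:
    """Small-household preset: up to three female mosquitoes.

    Uses the literal b = 0.3 (wildtype-only deterministic steady state near 2)
    and fitness cost 1 - phi = 0.15, with perfect CI and vertical
    transmission.
    """
    base = dict(b=0.3, d=0.12, delta=1.0, phi=0.85, u=1.0, v=1.0, C=3)
    base.update(overrides)
    return ModelParams(**base)


def full_params(**overrides) -> ModelParams:
    """Realistic-household preset: up to thirty female mosquitoes.

    b = 0.54 (4.52 d), chosen so that the wildtype-only deterministic steady
    state is close to ten females per household; fitness cost 0.15; perfect
    CI and vertical transmission unless overridden (set ``v=0.9`` for the
    imperfect-transmission variant).
    """
    base = dict(b=0.54, d=0.12, delta=1.0, phi=0.85, u=1.0, v=1.0, C=30)
    base.update(overrides)
    return ModelParams(**base)


PRESETS = {"tutorial": tutorial_params, "full": full_params}


def larval_density(N: float, params: ModelParams) -> float:
    """Larval intraspecific-competition factor in [0, 1].

    ``exp(-h * N**k)`` (exponential kind) or ``1 - N/C`` (linear kind) for
    ``N < C``; exactly zero for ``N >= C``.  Non-increasing in ``N``.
    """
    if N < 0:
        raise ValueError(f"population size must be non-negative, got {N}")
    if N >= params.C:
        return 0.0
    if params.density == "exp":
        return math.exp(-params.h * N**params.k)
    return 1.0 - N / params.C


def density_inverse(y: float, params: ModelParams) -> float:
    """Population size N in (0, C) with larval_density(N) == y, for y in (0, 1)."""
    if not 0.0 < y < 1.0:
        raise ValueError(f"density value must lie in (0, 1), got {y}")
    if params.density == "exp":
        N = (-math.log(y) / params.h) ** (1.0 / params.k)
    else:
        N = params.C * (1.0 - y)
    if N >= params.C:
        raise ValueError(
            f"density value {y} is attained only at or beyond the carrying capacity"
        )
    return N


def effective_parents(state: tuple[int, int], params: ModelParams) -> tuple[float, float]:
    """Effective numbers of adults producing wildtype and infected offspring.

    For counts ``(m, w)`` with ``m + w > 0``::

        Z_m = m/(m+w) * (m + (1-v) phi w) + w/(m+w) * ((1-u) m + (1-v) phi w)
        Z_w = v phi w

    The first ``Z_m`` term covers matings with wildtype males; the second
    covers matings with infected males, where a fraction ``u`` of the
    offspring of wildtype females is lost to cytoplasmic incompatibility.
    Imperfect vertical transmission (``v < 1``) routes a share of infected
    females' offspring to the wildtype pool.
    """
    m, w = state
    n = m + w
    if n <= 0:
        raise ValueError("effective parents are undefined at (0, 0)")
    phi, u, v = params.phi, params.u, params.v
    leak = (1.0 - v) * phi * w
    z_m = m / n * (m + leak) + w / n * ((1.0 - u) * m + leak)
    z_w = v * phi * w
    return z_m, z_w


def event_rates(state: tuple[int, int], params: ModelParams) -> EventRates:
    """Transition rates of the four events out of a household state.

    The absorbing state (0, 0) returns all-zero rates, so the same function
    serves both the full generator and the transient sub-generator.
    """
    m, w = state
    if m < 0 or w < 0:
        raise ValueError(f"counts must be non-negative, got {state}")
    if m + w > params.C:
        raise ValueError(f"state {state} exceeds the carrying capacity C={params.C}")
    if m + w == 0:
        return EventRates(0.0, 0.0, 0.0, 0.0)
    dens = larval_density(m + w, params)
    z_m, z_w = effective_parents(state, params)
    return EventRates(
        wt_birth=params.b * z_m * dens,
        wolb_birth=params.b * z_w * dens,
        wt_death=params.d * m,
        wolb_death=params.d * params.delta * w,
    )


def calibrate_birth_rate(target: float, params: ModelParams) -> float:
    """Birth rate b such that the wildtype-only steady state equals ``target``.

    The wildtype-only steady state solves ``F(N) = d/b``, so
    ``b = d / F(target)``.
    """
    if not 0.0 < target < params.C:
        raise ValueError(
            f"target steady state must lie in (0, C={params.C}), got {target}"
        )
    dens = larval_density(target, params)
    if dens <= 0.0:
        raise ValueError("larval density vanishes at the requested steady state")
    return params.d / dens
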