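"""Reversion to wildtype under imperfect vertical transmission (v < 1).

When a share ``1 - v`` of infected females' offspring are wildtype, a
household that has reached a Wolbachia-only state can drift back through the
mixed states into the wildtype-only class before going extinct.  Reversion is
operationalised as hitting the wildtype-only class from the merged
Wolbachia/mixed class, exactly as the hitting-system computation prescribes.

Conditioning on the mixed state via which the Wolbachia-only set was first
entered gives an entry distribution over the Wolbachia-only states; the
headline reversion probability and expected reversion time weight the
per-entry-state values by that distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .hitting import class_hitting_probability, conditional_hitting_time
from .statespace import WILDTYPE_ONLY, WOLBACHIA_MIXED, Generator

__all__ = [
    "EntryDistribution",
    "entry_distribution",
    "reversion_probability",
    "reversion_time",
    "average_reversion_probability",
    "average_reversion_time",
    "reversion_grid",
]


def _require_reversion(gen: Generator) -> None:
    if WOLBACHIA_MIXED not in gen.class_names:
        raise ValueError(
            "reversion requires imperfect vertical transmission (v < 1); "
            f"this generator has v={gen.params.v}"
        )


def _partition(gen: Generator):
    """Split the merged class into Wolbachia-only and mixed index lists."""
    sl = gen.class_slice(WOLBACHIA_MIXED)
    states = gen.space.states
    wolb = [i for i in range(sl.start, sl.stop) if states[i][0] == 0]
    mixed = [i for i in range(sl.start, sl.stop) if states[i][0] > 0]
    return sl, wolb, mixed


@dataclass(frozen=True)
class EntryDistribution:
    """First-entry distribution over the Wolbachia-only states.

    ``conditioned`` sums to one given that the Wolbachia-only set is reached
    at all; ``mass`` is the unconditioned probability of reaching it from the
    initial mixed state.
    """

    initial: tuple[int, int]
    states: tuple[tuple[int, int], ...]
    conditioned: np.ndarray = field(repr=False)
    mass: float


def _entry_matrix(gen: Generator):
    """Entry-location probabilities for every mixed initial state at once.

    Restricting the hitting system to the mixed sub-block: row (m, w), column
    (0, w') holds the probability that the Wolbachia-only set is first
    entered at (0, w') starting from mixed state (m, w).
    """
    sl, wolb, mixed = _partition(gen)
    Q_mm = gen.Q[np.ix_(mixed, mixed)]
    Q_mw = gen.Q[np.ix_(mixed, wolb)]
    entries = lu_solve(lu_factor(Q_mm), -Q_mw)
    mixed_states = [gen.space.states[i] for i in mixed]
    wolb_states = [gen.space.states[i] for i in wolb]
    return mixed_states, wolb_states, entries


def entry_distribution(gen: Generator, initial: tuple[int, int]) -> EntryDistribution:
    """Distribution of the first Wolbachia-only state reached from ``initial``."""
    _require_reversion(gen)
    m, w = initial
    if m <= 0 or w <= 0:
        raise ValueError(f"initial state must be mixed (both counts > 0), got {initial}")
    mixed_states, wolb_states, entries = _entry_matrix(gen)
    row = entries[mixed_states.index(initial)]
    mass = float(row.sum())
    if mass <= 0:
        raise RuntimeError("the Wolbachia-only set is unreachable; rate assembly is broken")
    return EntryDistribution(
        initial=initial,
        states=tuple(wolb_states),
        conditioned=row / mass,
        mass=mass,
    )


def _per_state_reversion(gen: Generator):
    """Reversion probability and conditional time for every merged-class state."""
    prob = class_hitting_probability(gen, WILDTYPE_ONLY, WOLBACHIA_MIXED)
    time = conditional_hitting_time(gen, WILDTYPE_ONLY, WOLBACHIA_MIXED, _prob=prob)
    return prob, time


def reversion_grid(gen: Generator) -> pd.DataFrame:
    """Reversion summary for every mixed initial state.

    One row per mixed state (m, w): the probability of entering the
    Wolbachia-only set at all, the entry-weighted reversion probability and
    the entry-weighted expected reversion time (days, conditional on
    reversion from each entry state).
    """
    _require_reversion(gen)
    mixed_states, wolb_states, entries = _entry_matrix(gen)
    prob, time = _per_state_reversion(gen)
    sl = gen.class_slice(WOLBACHIA_MIXED)
    offset = {s: i for i, s in enumerate(gen.space.states[sl])}
    widx = [offset[s] for s in wolb_states]
    r_w = prob[widx]
    t_w = time[widx]
    mass = entries.sum(axis=1)
    cond = entries / mass[:, None]
    rows = []
    for i, (m, w) in enumerate(mixed_states):
        rows.append(
            {
                "m": m,
                "w": w,
                "entry_mass": mass[i],
                "reversion_probability": float(cond[i] @ r_w),
                "reversion_time": float(cond[i] @ t_w),
            }
        )
    return pd.DataFrame(rows)


def reversion_probability(gen: Generator, initial: tuple[int, int]) -> float:
    """Probability of reversion after entering the Wolbachia-only set.

    The per-entry-state probabilities of reaching the wildtype-only class,
    weighted by the conditioned entry distribution for the given initial
    mixed state.
    """
    grid = reversion_grid(gen)
    row = grid[(grid.m == initial[0]) & (grid.w == initial[1])]
    if row.empty:
        raise ValueError(f"{initial} is not a mixed state of this model")
    return float(row.reversion_probability.iloc[0])


def reversion_time(gen: Generator, initial: tuple[int, int]) -> float:
    """Expected days until reversion, entry-weighted as in `reversion_probability`.

    Each entry state contributes its expected reversion time conditional on
    reversion from that state, weighted by the conditioned entry
    distribution.
    """
    grid = reversion_grid(gen)
    row = grid[(grid.m == initial[0]) & (grid.w == initial[1])]
    if row.empty:
        raise ValueError(f"{initial} is not a mixed state of this model")
    return float(row.reversion_time.iloc[0])


def average_reversion_probability(gen: Generator) -> float:
    """Equal-weight mean of the reversion probability over all mixed states."""
    return float(reversion_grid(gen).reversion_probability.mean())


def average_reversion_time(gen: Generator) -> float:
    """Equal-weight mean of the expected reversion time over all mixed states."""
    return float(reversion_grid(gen).reversion_time.mean())
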