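"""Hitting probabilities and times, extinction times and release sizing.

A stochastic release from a mixed household state eventually enters either
the wildtype-only or the Wolbachia-only class (entering the latter is a
successful invasion).  The entry-location probabilities solve the linear
system ``-Q_src a(target) = q(target)`` on the source-class block, where
``q(target)`` collects the one-step rates into the target state.  Expected
entry times conditional on entering solve the companion system in the
products ``a* tau*`` so that states that cannot reach the target never
contribute.  Expected extinction times of a class whose only exit is the
absorbing state solve ``Q_k tau = -1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .statespace import (
    MIXED,
    WILDTYPE_ONLY,
    WOLBACHIA_MIXED,
    WOLBACHIA_ONLY,
    Generator,
)

__all__ = [
    "HittingResult",
    "hit_location_probabilities",
    "class_hitting_probability",
    "conditional_hitting_time",
    "hitting_result",
    "invasion_grid",
    "expected_extinction_time",
    "min_release_size",
]


@dataclass(frozen=True)
class HittingResult:
    """Per-source-state probabilities and conditional times for a target class."""

    source_label: str
    target_label: str
    states: tuple[tuple[int, int], ...]
    probability: np.ndarray = field(repr=False)
    time: np.ndarray = field(repr=False)  # NaN where the probability is 0


def _default_source(gen: Generator, target_label: str) -> str:
    if WOLBACHIA_MIXED in gen.class_names:
        if target_label != WILDTYPE_ONLY:
            raise ValueError(
                "with imperfect vertical transmission only the wildtype-only "
                "class can be a hitting target"
            )
        return WOLBACHIA_MIXED
    return MIXED


def _lu(gen: Generator, source_label: str):
    return lu_factor(gen.class_block(source_label))


def hit_location_probabilities(
    gen: Generator,
    target_state: tuple[int, int],
    source_label: str | None = None,
) -> np.ndarray:
    """Probability of first entering the target's class *at* ``target_state``.

    Solved from ``-Q_src a = q(target_state)`` over the source class; returns
    the zero vector when the target is not reachable in one step from the
    source class.
    """
    target_label = gen.labels[gen.space.index[target_state]]
    if source_label is None:
        source_label = _default_source(gen, target_label)
    if target_label == source_label:
        raise ValueError("target state lies inside the source class")
    rates = gen.Q[gen.class_slice(source_label), gen.space.index[target_state]]
    if not rates.any():
        return np.zeros_like(rates)
    return lu_solve(_lu(gen, source_label), -rates)


def class_hitting_probability(
    gen: Generator,
    target_label: str,
    source_label: str | None = None,
) -> np.ndarray:
    """Probability of ever entering the target class from each source state.

    The sum over all entry states of the target class of the entry-location
    probabilities; a single solve with the summed rate vector.
    """
    if source_label is None:
        source_label = _default_source(gen, target_label)
    rates_to_target = gen.block(source_label, target_label).sum(axis=1)
    return lu_solve(_lu(gen, source_label), -rates_to_target)


def conditional_hitting_time(
    gen: Generator,
    target_label: str,
    source_label: str | None = None,
    _prob: np.ndarray | None = None,
) -> np.ndarray:
    """Expected days until the target class is entered, given that it is.

    Solves the source-class system in the unknowns ``z = a* tau*`` (zero on
    the target class itself), then divides by the hitting probabilities;
    entries with zero hitting probability are NaN.
    """
    if source_label is None:
        source_label = _default_source(gen, target_label)
    a = _prob if _prob is not None else class_hitting_probability(gen, target_label, source_label)
    z = lu_solve(_lu(gen, source_label), -a)
    time = np.full_like(a, np.nan)
    pos = a > 0
    time[pos] = z[pos] / a[pos]
    return time


def hitting_result(
    gen: Generator, target_label: str, source_label: str | None = None
) -> HittingResult:
    """Bundle hitting probabilities and conditional times for one target."""
    if source_label is None:
        source_label = _default_source(gen, target_label)
    prob = class_hitting_probability(gen, target_label, source_label)
    time = conditional_hitting_time(gen, target_label, source_label, _prob=prob)
    return HittingResult(
        source_label=source_label,
        target_label=target_label,
        states=tuple(gen.class_states(source_label)),
        probability=prob,
        time=time,
    )


def invasion_grid(gen: Generator) -> pd.DataFrame:
    """Invasion probability and conditional time for every transient state.

    States already in the Wolbachia-only class have probability 1 and time 0;
    wildtype-only states have probability 0 and undefined time.
    """
    res = hitting_result(gen, WOLBACHIA_ONLY)
    lookup = {s: (p, t) for s, p, t in zip(res.states, res.probability, res.time)}
    rows = []
    for (m, w), label in zip(gen.space.states, gen.labels):
        if label == WOLBACHIA_ONLY:
            p, t = 1.0, 0.0
        elif label == WILDTYPE_ONLY:
            p, t = 0.0, np.nan
        else:
            p, t = lookup[(m, w)]
        rows.append({"m": m, "w": w, "invasion_probability": p, "conditional_time": t})
    return pd.DataFrame(rows)


def expected_extinction_time(gen: Generator, class_label: str) -> np.ndarray:
    """Expected days until absorption from each state of a terminal class.

    Only valid for a class whose sole exit is the absorbing state (the
    wildtype-only class always; the Wolbachia-only class when vertical
    transmission is perfect).  Solves ``Q_k tau = -1``.
    """
    sl = gen.class_slice(class_label)
    outside = gen.Q[sl].sum(axis=1) - gen.Q[sl, sl].sum(axis=1)
    scale = np.abs(gen.Q[sl, sl].diagonal()).max()
    if np.abs(outside).max() > 1e-12 * max(scale, 1.0):
        raise ValueError(
            f"class {class_label!r} has exits other than the absorbing state; "
            "its absorption time is not defined by the class block alone"
        )
    block = gen.class_block(class_label)
    return np.linalg.solve(block, -np.ones(block.shape[0]))


def min_release_size(
    gen: Generator,
    threshold: float,
    total: int | None = None,
    wildtype: int | None = None,
) -> int | None:
    """Smallest infected release achieving the invasion-probability threshold.

    Either the household total is fixed (``total``: releases replace
    wildtypes, states ``(total - w, w)``) or the resident wildtype count is
    fixed (``wildtype``: releases add, states ``(wildtype, w)``).  Returns
    ``None`` when no admissible release reaches the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if (total is None) == (wildtype is None):
        raise ValueError("specify exactly one of total= or wildtype=")
    if total is not None and not 0 < total <= gen.params.C:
        raise ValueError(f"total={total} must lie in 1..C={gen.params.C}")
    if wildtype is not None and not 0 <= wildtype < gen.params.C:
        raise ValueError(f"wildtype={wildtype} must lie in 0..C-1={gen.params.C - 1}")
    res = hitting_result(gen, WOLBACHIA_ONLY)
    lookup = dict(zip(res.states, res.probability))
    if total is not None:
        candidates = [(total - w, w) for w in range(1, total + 1)]
    else:
        candidates = [(wildtype, w) for w in range(1, gen.params.C - wildtype + 1)]
    for m, w in candidates:
        prob = 1.0 if m == 0 else lookup[(m, w)]
        if prob >= threshold:
            return w
    return None
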