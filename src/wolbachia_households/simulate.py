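"""Exact stochastic simulation of the household chain.

Event-by-event simulation with exponential holding times (the stochastic
simulation algorithm of Gillespie): the exact Monte-Carlo counterpart of the
analytic machinery, used to cross-validate hitting probabilities, hitting and
extinction times, entry distributions and reversion statistics.

All per-state rates and jump targets are precomputed once per parameter set,
so a run is a tight loop over the embedded jump chain.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, event_rates
from .statespace import StateSpace, enumerate_states

__all__ = ["Trajectory", "EnsembleSummary", "gillespie_trajectory", "ensemble_summary"]

_ABSORB = -1


@dataclass(frozen=True)
class Trajectory:
    """One realisation: jump times, visited states and outcome bookkeeping.

    ``terminal`` is "absorbed", "t_max" or "class_entry" (when the run was
    stopped at its first entry into a single-type class).  ``outcome`` labels
    which single-type class, if any, was entered first: "entered_wildtype",
    "entered_wolbachia", "extinct_direct" (started at (0, 0)) or
    "unresolved".
    """

    times: np.ndarray = field(repr=False)
    states: list[tuple[int, int]] = field(repr=False)
    terminal: str
    outcome: str
    seed: int | None
    first_wolbachia_entry: tuple[int, int] | None = None
    first_wildtype_entry: tuple[int, int] | None = None
    first_wolbachia_time: float | None = None
    first_wildtype_time: float | None = None


class _Tables:
    """Flattened per-state rate tables for the jump loop."""

    def __init__(self, params: ModelParams):
        space = enumerate_states(params.C)
        self.space = space
        n = len(space)
        self.total = [0.0] * n
        self.cum = [()] * n
        self.targets = [()] * n
        moves = ((1, 0), (0, 1), (-1, 0), (0, -1))
        for i, (m, w) in enumerate(space.states):
            rates = event_rates((m, w), params)
            cum, tgt, acc = [], [], 0.0
            for (dm, dw), rate in zip(moves, rates):
                if rate <= 0:
                    continue
                acc += rate
                cum.append(acc)
                nxt = (m + dm, w + dw)
                tgt.append(_ABSORB if nxt == (0, 0) else space.index[nxt])
            self.total[i] = acc
            self.cum[i] = tuple(cum)
            self.targets[i] = tuple(tgt)


_TABLE_CACHE: dict[tuple, _Tables] = {}


def _tables(params: ModelParams) -> _Tables:
    key = tuple(sorted(params.as_dict().items()))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _Tables(params)
    return _TABLE_CACHE[key]


def _classify(state: tuple[int, int]) -> str | None:
    m, w = state
    if m > 0 and w == 0:
        return "wildtype"
    if w > 0 and m == 0:
        return "wolbachia"
    return None


def gillespie_trajectory(
    params: ModelParams,
    initial: tuple[int, int],
    t_max: float,
    seed: int | None = None,
    rng: random.Random | None = None,
    stop_on_entry: str | None = None,
    record_path: bool = True,
) -> Trajectory:
    """Simulate one household realisation.

    Reproducible: a given ``seed`` yields a bit-identical trajectory.
    ``stop_on_entry`` in {"wildtype", "wolbachia", "any"} terminates the run
    at the first entry into the corresponding single-type class (useful when
    only invasion outcomes are of interest).
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    m, w = initial
    if m < 0 or w < 0 or m + w > params.C:
        raise ValueError(f"initial state {initial} is not admissible for C={params.C}")
    if rng is None:
        rng = random.Random(seed)
    tables = _tables(params)
    space = tables.space

    times = [0.0]
    path = [initial]
    if initial == (0, 0):
        return Trajectory(
            times=np.array(times), states=path, terminal="absorbed",
            outcome="extinct_direct", seed=seed,
        )

    i = space.index[initial]
    t = 0.0
    first = {"wildtype": None, "wolbachia": None}
    ftime = {"wildtype": None, "wolbachia": None}
    start_class = _classify(initial)
    if start_class is not None:
        first[start_class] = initial
        ftime[start_class] = 0.0
    terminal = "t_max"
    total, cum, targets = tables.total, tables.cum, tables.targets
    states_list = space.states
    rand = rng.random

    while True:
        q = total[i]
        t += -math.log(1.0 - rand()) / q
        if t > t_max:
            break
        r = rand() * q
        c = cum[i]
        j = 0
        while r > c[j]:
            j += 1
        i = targets[i][j]
        if i == _ABSORB:
            times.append(t)
            path.append((0, 0))
            terminal = "absorbed"
            break
        state = states_list[i]
        if record_path:
            times.append(t)
            path.append(state)
        cls = _classify(state)
        if cls is not None and first[cls] is None:
            first[cls] = state
            ftime[cls] = t
            if stop_on_entry in (cls, "any"):
                if not record_path:
                    times.append(t)
                    path.append(state)
                terminal = "class_entry"
                break

    entered = [(ftime[c], c) for c in ("wildtype", "wolbachia") if ftime[c] is not None]
    if entered:
        outcome = "entered_" + min(entered)[1]
    elif terminal == "absorbed":
        outcome = "extinct_direct"
    else:
        outcome = "unresolved"
    return Trajectory(
        times=np.asarray(times), states=path, terminal=terminal, outcome=outcome,
        seed=seed,
        first_wolbachia_entry=first["wolbachia"], first_wildtype_entry=first["wildtype"],
        first_wolbachia_time=ftime["wolbachia"], first_wildtype_time=ftime["wildtype"],
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Outcome statistics of repeated independent realisations."""

    n: int
    seed: int | None
    outcome_counts: dict
    wolbachia_entry_states: Counter
    wildtype_entry_states: Counter
    wolbachia_entry_times: np.ndarray = field(repr=False)
    wildtype_entry_times: np.ndarray = field(repr=False)
    absorption_times: np.ndarray = field(repr=False)
    #: runs that entered a Wolbachia-only state and later a wildtype-only one
    reversion_count: int = 0
    reversion_delays: np.ndarray = field(default=None, repr=False)

    def frequency(self, outcome: str) -> float:
        return self.outcome_counts.get(outcome, 0) / self.n

    def standard_error(self, outcome: str) -> float:
        p = self.frequency(outcome)
        return math.sqrt(p * (1 - p) / self.n)


def ensemble_summary(
    params: ModelParams,
    initial: tuple[int, int],
    n: int,
    t_max: float,
    seed: int | None = None,
    stop_on_entry: str | None = None,
) -> EnsembleSummary:
    """Run ``n`` independent realisations and tally outcomes.

    Entry-state tallies feed the entry-distribution cross-checks; reversion
    bookkeeping counts runs that visit a Wolbachia-only state and
    subsequently a wildtype-only state, with the delay between the two.
    """
    if n < 1:
        raise ValueError(f"need at least one run, got n={n}")
    rng = random.Random(seed)
    counts: Counter = Counter()
    w_entry, m_entry = Counter(), Counter()
    w_times, m_times, abs_times, rev_delays = [], [], [], []
    rev = 0
    for _ in range(n):
        traj = gillespie_trajectory(
            params, initial, t_max, rng=rng,
            stop_on_entry=stop_on_entry, record_path=False,
        )
        counts[traj.outcome] += 1
        if traj.first_wolbachia_entry is not None:
            w_entry[traj.first_wolbachia_entry] += 1
            w_times.append(traj.first_wolbachia_time)
        if traj.first_wildtype_entry is not None:
            m_entry[traj.first_wildtype_entry] += 1
            m_times.append(traj.first_wildtype_time)
        if traj.terminal == "absorbed":
            abs_times.append(float(traj.times[-1]))
        if (
            traj.first_wolbachia_time is not None
            and traj.first_wildtype_time is not None
            and traj.first_wildtype_time > traj.first_wolbachia_time
        ):
            rev += 1
            rev_delays.append(traj.first_wildtype_time - traj.first_wolbachia_time)
    return EnsembleSummary(
        n=n, seed=seed, outcome_counts=dict(counts),
        wolbachia_entry_states=w_entry, wildtype_entry_states=m_entry,
        wolbachia_entry_times=np.asarray(w_times),
        wildtype_entry_times=np.asarray(m_times),
        absorption_times=np.asarray(abs_times),
        reversion_count=rev, reversion_delays=np.asarray(rev_delays),
    )
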