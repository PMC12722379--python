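"""State-space enumeration, communicating classes and generator assembly.

The CTMC lives on ``{(0,0)} ∪ S`` where ``S = {(m, w) : 0 < m + w <= C}`` is
the set of transient states and (0, 0) — both populations extinct — is
absorbing.  With perfect vertical transmission (v = 1) the transient space
splits into three communicating classes:

* wildtype-only states ``(m, 0)``,
* Wolbachia-only states ``(0, w)``,
* mixed states ``(m, w)`` with both counts positive.

The mixed class can reach the other two but not vice versa.  With v < 1 the
infected females occasionally produce wildtype offspring, which merges the
Wolbachia-only and mixed states into a single class.

States are ordered class-major — wildtype-only by ascending m, Wolbachia-only
by ascending w, then mixed lexicographically — so every class is a contiguous
block of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components

from .params import ModelParams, event_rates

__all__ = [
    "WILDTYPE_ONLY",
    "WOLBACHIA_ONLY",
    "MIXED",
    "WOLBACHIA_MIXED",
    "StateSpace",
    "enumerate_states",
    "classify_states",
    "Generator",
    "build_generator",
    "build_jump_matrix",
    "generator_table",
    "export_generator",
]

WILDTYPE_ONLY = "wildtype_only"
WOLBACHIA_ONLY = "wolbachia_only"
MIXED = "mixed"
#: merged Wolbachia-only + mixed class under imperfect vertical transmission
WOLBACHIA_MIXED = "wolbachia_mixed"

#: single-step displacements of the four events, in EventRates order
_MOVES = ((1, 0), (0, 1), (-1, 0), (0, -1))


@dataclass(frozen=True)
class StateSpace:
    """Ordered transient states of the household chain for a given cap C."""

    C: int
    states: tuple[tuple[int, int], ...]
    index: dict[tuple[int, int], int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state) -> bool:
        return state in self.index


def enumerate_states(C: int) -> StateSpace:
    """Enumerate the C(C+3)/2 transient states in class-major order."""
    if not (isinstance(C, int) and C >= 1):
        raise ValueError(f"carrying capacity must be a positive integer, got {C}")
    states = [(m, 0) for m in range(1, C + 1)]
    states += [(0, w) for w in range(1, C + 1)]
    states += [(m, w) for m in range(1, C) for w in range(1, C - m + 1)]
    return StateSpace(C=C, states=tuple(states), index={s: i for i, s in enumerate(states)})


def classify_states(space: StateSpace, v: float) -> list[str]:
    """Communicating-class label of every transient state.

    Three classes for v = 1; two (wildtype-only and the merged
    Wolbachia/mixed class) for v < 1.
    """
    labels = []
    for m, w in space.states:
        if w == 0:
            labels.append(WILDTYPE_ONLY)
        elif v < 1.0:
            labels.append(WOLBACHIA_MIXED)
        elif m == 0:
            labels.append(WOLBACHIA_ONLY)
        else:
            labels.append(MIXED)
    return labels


@dataclass(frozen=True)
class Generator:
    """Transition-rate matrix of the household CTMC with its block views.

    ``Q00`` is the full generator over ``{(0,0)} ∪ S`` with the absorbing
    state first; its rows sum to zero.  ``Q`` is the transient sub-generator:
    its diagonal still includes the rates into (0, 0), so ``Q`` does not
    conserve probability and all its eigenvalues have negative real part.
    ``a`` holds the absorption rates.
    """

    params: ModelParams
    space: StateSpace
    Q00: np.ndarray = field(repr=False)
    Q: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = field(repr=False)

    @property
    def states(self) -> tuple[tuple[int, int], ...]:
        return self.space.states

    @property
    def class_names(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.labels)
        return tuple(seen)

    def class_states(self, label: str) -> list[tuple[int, int]]:
        return [s for s, l in zip(self.space.states, self.labels) if l == label]

    def class_slice(self, label: str) -> slice:
        idx = [i for i, l in enumerate(self.labels) if l == label]
        if not idx:
            raise KeyError(f"no class {label!r} in this generator (v={self.params.v})")
        lo, hi = idx[0], idx[-1] + 1
        if hi - lo != len(idx):  # guaranteed by class-major ordering
            raise AssertionError("class states are not contiguous")
        return slice(lo, hi)

    def class_block(self, label: str) -> np.ndarray:
        """Diagonal block of Q for one communicating class."""
        sl = self.class_slice(label)
        return self.Q[sl, sl]

    def block(self, from_label: str, to_label: str) -> np.ndarray:
        """Off-diagonal block of rates from one class into another."""
        return self.Q[self.class_slice(from_label), self.class_slice(to_label)]


def _transient_matrix(params: ModelParams, space: StateSpace) -> tuple[np.ndarray, np.ndarray]:
    n = len(space)
    Q = np.zeros((n, n))
    a = np.zeros(n)
    for i, (m, w) in enumerate(space.states):
        rates = event_rates((m, w), params)
        for (dm, dw), rate in zip(_MOVES, rates):
            if rate <= 0.0:
                continue
            target = (m + dm, w + dw)
            Q[i, i] -= rate
            if target == (0, 0):
                a[i] += rate
            else:
                Q[i, space.index[target]] += rate
    return Q, a


def _scc_labels(Q: np.ndarray) -> np.ndarray:
    graph = csr_matrix((np.abs(Q) > 0).astype(np.int8))
    _, comp = connected_components(graph, directed=True, connection="strong")
    return comp


def build_generator(params: ModelParams) -> Generator:
    """Assemble the generator and verify the class structure.

    The closed-form class labels are cross-checked against the strongly
    connected components of the positive-rate graph; a mismatch is a hard
    error (it would indicate a rate bug, not a modelling choice).
    """
    space = enumerate_states(params.C)
    Q, a = _transient_matrix(params, space)
    labels = tuple(classify_states(space, params.v))

    comp = _scc_labels(Q)
    by_label: dict[str, set[int]] = {}
    for lab, c in zip(labels, comp):
        by_label.setdefault(lab, set()).add(int(c))
    comps = list(by_label.values())
    if any(len(c) != 1 for c in comps) or len(set().union(*comps)) != len(comps):
        raise RuntimeError(
            "communicating classes from the rate graph disagree with the "
            "closed-form classification"
        )

    n = len(space)
    Q00 = np.zeros((n + 1, n + 1))
    Q00[1:, 1:] = Q
    Q00[1:, 0] = a
    return Generator(params=params, space=space, Q00=Q00, Q=Q, a=a, labels=labels)


def build_jump_matrix(gen: Generator) -> np.ndarray:
    """Next-state probabilities of the embedded jump chain.

    Row i is ``-q_ij / q_ii`` off the diagonal for states with positive exit
    rate, zero on the diagonal; a state with no exits (here only the
    absorbing (0, 0)) keeps probability 1 on itself.
    """
    Q00 = gen.Q00
    q = -np.diag(Q00)
    S = np.zeros_like(Q00)
    active = q > 0
    S[active] = Q00[active] / q[active, None]
    np.fill_diagonal(S, 0.0)
    S[~active, ~active] = 1.0
    return S


def _state_strs(states) -> list[str]:
    return [f"({m},{w})" for m, w in states]


def generator_table(gen: Generator) -> pd.DataFrame:
    """Long-format (from, to, rate) table of all positive transition rates."""
    all_states = [(0, 0), *gen.space.states]
    rows = []
    Q00 = gen.Q00
    for i, src in enumerate(all_states):
        for j, dst in enumerate(all_states):
            if i != j and Q00[i, j] > 0:
                rows.append(
                    {"from_m": src[0], "from_w": src[1],
                     "to_m": dst[0], "to_w": dst[1], "rate": Q00[i, j]}
                )
    return pd.DataFrame(rows)


def export_generator(gen: Generator, csv_path, mtx_path=None) -> None:
    """Write the generator as a rate-triplet CSV and optionally MatrixMarket."""
    generator_table(gen).to_csv(csv_path, index=False)
    if mtx_path is not None:
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), coo_matrix(gen.Q00))
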