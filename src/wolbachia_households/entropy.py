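"""Next-jump entropy of each household state.

The entropy ``H_i = -sum_j s_ij log s_ij`` of row i of the embedded jump
matrix measures how uncertain the next state is given the current one:
zero for the absorbing state and for states with a single possible event
(e.g. a full household where only deaths can occur), and largest for evenly
mixed states where four birth/death events compete at similar rates.
Natural logarithm by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .statespace import Generator, build_jump_matrix

__all__ = ["state_entropy", "entropy_table"]


def state_entropy(jump: np.ndarray, base: float | None = None) -> np.ndarray:
    """Entropy of each row of a jump matrix, with 0 log 0 := 0.

    A state with probability 1 of staying put (the absorbing state) has zero
    entropy.  ``base`` rescales from nats (default) to the given log base.
    """
    S = np.asarray(jump, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(S > 0, S * np.log(S), 0.0)
    H = -terms.sum(axis=1)
    H[np.abs(H) < 1e-15] = 0.0
    if base is not None:
        H = H / np.log(base)
    return H


def entropy_table(gen: Generator, base: float | None = None) -> pd.DataFrame:
    """Per-state entropy table, absorbing state included."""
    H = state_entropy(build_jump_matrix(gen), base=base)
    states = [(0, 0), *gen.space.states]
    return pd.DataFrame(
        {"m": [s[0] for s in states], "w": [s[1] for s in states], "entropy": H}
    )
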