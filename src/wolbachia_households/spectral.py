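"""Class-wise eigenanalysis, quasi-stationary distribution and transients.

Every communicating-class block of the transient generator is strictly
sub-stochastic and irreducible, so it has a unique simple eigenvalue of
minimal magnitude, ``-alpha`` with ``alpha > 0``, and a strictly positive
left eigenvector (Perron-Frobenius).  Conditional on non-extinction, the
chain's distribution converges to the quasi-stationary distribution (QSD):
the normalised left eigenvector of the class with the overall smallest
``alpha``, embedded in the full transient space.

The spectral gap between the two slowest classes gives the damping ratio
``rho = exp(alpha_2 - alpha_1) > 1``; the time until the slow class holds x
times the probability mass of the faster one is ``log(x)/log(rho)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig, expm

from .statespace import Generator

__all__ = [
    "ClassSpectrum",
    "class_spectrum",
    "quasi_stationary_distribution",
    "transient_distribution",
    "point_mass",
    "class_mass",
    "DampingRatio",
    "damping_ratio",
]

_CLAMP = 1e-12


@dataclass(frozen=True)
class ClassSpectrum:
    """Decay rate and quasi-stationary profile of one communicating class."""

    label: str
    alpha: float
    distribution: np.ndarray = field(repr=False)  # normalised left eigenvector


def class_spectrum(gen: Generator, label: str) -> ClassSpectrum:
    """Minimal-magnitude eigenpair of a class block.

    Returns ``alpha > 0`` (the block's slowest decay rate, i.e. the negated
    eigenvalue of maximal real part) and the associated left eigenvector
    normalised to sum to one over the class.
    """
    block = gen.class_block(label)
    vals, lvecs = eig(block, left=True, right=False)
    j = int(np.argmax(vals.real))
    lam = vals[j]
    if abs(lam.imag) > 1e-9:
        raise RuntimeError(
            f"dominant eigenvalue of class {label!r} has imaginary part {lam.imag:.2e}; "
            "the class block should satisfy Perron-Frobenius"
        )
    vec = lvecs[:, j]
    vec = vec.real if abs(vec.imag).max() <= 1e-9 else np.abs(vec)
    if vec.sum() < 0:
        vec = -vec
    vec = np.where(np.abs(vec) < _CLAMP, 0.0, vec)
    if vec.min() < -1e-9:
        raise RuntimeError(f"left eigenvector of class {label!r} is not sign-consistent")
    vec = np.clip(vec, 0.0, None)
    return ClassSpectrum(label=label, alpha=float(-lam.real), distribution=vec / vec.sum())


def quasi_stationary_distribution(gen: Generator) -> np.ndarray:
    """QSD over the transient states.

    Computes the per-class spectra, selects the class with the smallest decay
    rate and embeds its normalised left eigenvector (zeros elsewhere).  A tie
    between class decay rates within 1e-12 would make the QSD ill-defined and
    raises an error.
    """
    spectra = [class_spectrum(gen, label) for label in gen.class_names]
    spectra.sort(key=lambda s: s.alpha)
    if len(spectra) > 1 and abs(spectra[0].alpha - spectra[1].alpha) < 1e-12:
        raise RuntimeError(
            "two communicating classes share the minimal decay rate "
            f"({spectra[0].label!r} and {spectra[1].label!r}); the QSD is not unique"
        )
    best = spectra[0]
    qsd = np.zeros(len(gen.space))
    qsd[gen.class_slice(best.label)] = best.distribution
    return qsd


def point_mass(gen: Generator, state: tuple[int, int]) -> np.ndarray:
    """Initial distribution over {(0,0)} ∪ S concentrated at one state."""
    p0 = np.zeros(len(gen.space) + 1)
    if state == (0, 0):
        p0[0] = 1.0
    else:
        p0[1 + gen.space.index[state]] = 1.0
    return p0


def transient_distribution(
    p0: np.ndarray, t: float, gen: Generator, conditioned: bool = False
) -> np.ndarray:
    """Propagate a distribution over {(0,0)} ∪ S for t days.

    ``P(t) = P(0) exp(Q00 t)`` via the matrix exponential.  With
    ``conditioned=True`` the result is restricted to the transient states and
    renormalised, i.e. conditioned on non-extinction; otherwise the full
    vector (absorbing state first) is returned.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (len(gen.space) + 1,):
        raise ValueError("initial distribution must cover the absorbing state and S")
    p = p0 @ expm(gen.Q00 * t)
    if not conditioned:
        return p
    trans = p[1:]
    total = trans.sum()
    if total <= 0:
        raise RuntimeError("no probability mass left outside the absorbing state")
    return trans / total


def class_mass(dist: np.ndarray, gen: Generator) -> dict[str, float]:
    """Total probability mass per communicating class.

    Accepts either a full vector (absorbing state first) or a transient-only
    vector as produced by the conditioned view.
    """
    dist = np.asarray(dist, dtype=float)
    trans = dist[1:] if dist.shape == (len(gen.space) + 1,) else dist
    return {label: float(trans[gen.class_slice(label)].sum()) for label in gen.class_names}


@dataclass(frozen=True)
class DampingRatio:
    """Damping ratio between the two slowest-decaying classes."""

    rho: float
    spectral_gap: float

    def time_to_ratio(self, x: float) -> float:
        """Days until the slow class holds x times the fast class's mass."""
        if x <= 1:
            raise ValueError(f"mass ratio must exceed 1, got {x}")
        return float(np.log(x) / self.spectral_gap)


def damping_ratio(alpha1: float, alpha2: float) -> DampingRatio:
    """Damping ratio from the decay rates of the slow (alpha1) and fast class."""
    if not 0 < alpha1 < alpha2:
        raise ValueError(
            f"need 0 < alpha1 < alpha2 (slow class first), got {alpha1}, {alpha2}"
        )
    gap = alpha2 - alpha1
    return DampingRatio(rho=float(np.exp(gap)), spectral_gap=float(gap))
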