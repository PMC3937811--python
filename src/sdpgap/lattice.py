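"""Lamellar lattice model: modified Caille theory (MCT) structure factor,
domain-size averaging, and MLV/ULV intensity assembly.

Multilamellar vesicles scatter as a 1-D lamellar lattice whose quasi-Bragg
peaks are damped and power-law broadened by thermal bending fluctuations;
the Caille parameter eta sets the fluctuation amplitude.  Positionally
uncorrelated bilayers add a purely diffuse |F|^2 term with weight N_diff.
Unoriented suspensions carry the 1/q^2 Lorentz factor, and the instrument
is modelled by Gaussian q-resolution smearing plus a constant background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EULER_GAMMA",
    "LatticeParams",
    "InstrumentModel",
    "caille_structure_factor",
    "averaged_structure_factor",
    "resolution_convolve",
    "intensity_mlv",
    "intensity_ulv",
    "index_lamellar",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass
class LatticeParams:
    """State of the lamellar stack: repeat distance d (A), number of
    positionally correlated bilayers N, Caille fluctuation parameter eta,
    diffuse-scattering weight N_diff, and an optional spread of N for
    domain-size averaging."""

    d: float
    N: int
    eta: float
    N_diff: float = 0.0
    domain_spread: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 1 <= self.N <= 1000:
            raise ValueError("N must lie in [1, 1000]")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must lie in [0, 1)")
        if self.N_diff < 0:
            raise ValueError("N_diff must be non-negative")
        if self.domain_spread < 0:
            raise ValueError("domain_spread must be non-negative")


@dataclass
class InstrumentModel:
    """Gaussian beam resolution width (1/A), additive constant background
    and overall intensity scale."""

    beam_sigma: float = 0.0
    background: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.beam_sigma < 0:
            raise ValueError("beam_sigma must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def caille_structure_factor(q, lat: LatticeParams):
    """MCT structure factor of a stack of N correlated bilayers:

        S(q) = N + 2 sum_{k=1}^{N-1} (N - k) cos(k q d)
                   * exp[-(d/2pi)^2 q^2 eta gamma_E] * (pi k)^{-(d/2pi)^2 q^2 eta}

    with gamma_E the Euler-Mascheroni constant.  eta = 0 restores the ideal
    finite-lattice interference function (S(2 pi k / d) = N^2).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if lat.N < 1:
        raise ValueError("N must be >= 1")
    N = int(lat.N)
    if N == 1:
        return np.ones_like(q)
    alpha = (lat.d / (2.0 * np.pi)) ** 2 * q**2 * lat.eta  # (nq,)
    k = np.arange(1, N, dtype=float)  # (N-1,)
    damp = np.exp(-alpha * EULER_GAMMA)  # (nq,)
    # (pi k)^(-alpha): exp(-alpha * log(pi k)), outer over (k, q)
    powers = np.exp(-np.log(np.pi * k)[:, None] * alpha[None, :])
    terms = (N - k)[:, None] * np.cos(np.outer(k, q * lat.d)) * powers
    return N + 2.0 * damp * terms.sum(axis=0)


def averaged_structure_factor(q, lat: LatticeParams):
    """Domain-size averaged structure factor: Gaussian weights over integer
    stack sizes centred on N with std ``domain_spread``, truncated at N >= 1
    and renormalised.  Zero spread passes straight through."""
    if lat.domain_spread == 0.0:
        return caille_structure_factor(q, lat)
    s = lat.domain_spread
    lo = max(1, int(np.floor(lat.N - 3.0 * s)))
    hi = min(1000, int(np.ceil(lat.N + 3.0 * s)))
    sizes = np.arange(lo, hi + 1)
    w = np.exp(-((sizes - lat.N) ** 2) / (2.0 * s**2))
    w = w / w.sum()
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.zeros_like(q)
    for n_i, w_i in zip(sizes, w):
        sub = LatticeParams(lat.d, int(n_i), lat.eta, lat.N_diff)
        out += w_i * caille_structure_factor(q, sub)
    return out


def resolution_convolve(q_grid, I, beam_sigma: float):
    """Gaussian q-resolution smearing on a (near-)uniform grid, with edge
    handling by nearest-value extension.  A zero width is the identity."""
    q = np.asarray(q_grid, dtype=float)
    I = np.asarray(I, dtype=float)
    if q.size < 3:
        raise ValueError("grid must have at least 3 points")
    if beam_sigma < 0:
        raise ValueError("beam_sigma must be non-negative")
    if beam_sigma == 0.0:
        return I.copy()
    dq = float(np.mean(np.diff(q)))
    half = max(1, int(np.ceil(4.0 * beam_sigma / dq)))
    kern = np.exp(-((np.arange(-half, half + 1) * dq) ** 2) / (2.0 * beam_sigma**2))
    kern /= kern.sum()
    padded = np.concatenate([np.full(half, I[0]), I, np.full(half, I[-1])])
    return np.convolve(padded, kern, mode="valid")


def intensity_mlv(q_grid, F, S, lat: LatticeParams, inst: InstrumentModel):
    """Assemble the MLV powder intensity:

        I(q) = scale [S(q) + N_diff] |F(q)|^2 / q^2,  smeared,  + background

    The 1/q^2 Lorentz factor applies to both the Bragg and the diffuse term
    (isotropically oriented lamellae).
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive (Lorentz factor)")
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    I = inst.scale * (S + lat.N_diff) * np.abs(F) ** 2 / q**2
    I = resolution_convolve(q, I, inst.beam_sigma)
    return I + inst.background


def index_lamellar(q, I) -> float:
    """First-pass estimate of the lamellar repeat distance d = 2 pi / q_1
    from the position of the dominant quasi-Bragg peak.

    With the 1/q^2 Lorentz factor the first-order peak dominates an MLV
    pattern, so the global intensity maximum indexes it; the estimate is
    only used to seed search bounds (the repeat distance itself is always
    refined by the fit).
    """
    q = np.asarray(q, dtype=float)
    I = np.asarray(I, dtype=float)
    q1 = float(q[np.argmax(I)])
    if q1 <= 0:
        raise ValueError("cannot index: peak at non-positive q")
    return 2.0 * np.pi / q1


def intensity_ulv(q_grid, F, inst: InstrumentModel):
    """Unilamellar-vesicle intensity: pure form-factor scattering, S == 1,
    no interparticle interference (vesicle-size oscillations not modelled)."""
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive (Lorentz factor)")
    F = np.asarray(F, dtype=float)
    I = inst.scale * np.abs(F) ** 2 / q**2
    I = resolution_convolve(q, I, inst.beam_sigma)
    return I + inst.background
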