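"""Harmonic-superposition thermodynamics.

The total partition function of the landscape is approximated as a sum of
classical harmonic-well contributions, one per minimum:

    Z(T) = sum_i  exp(-V_i / k_B T) / (o_i * prod_j (beta h nu_ij))

where ``o_i`` is the point-group order and the product runs over the kappa
normal-mode frequencies of minimum i.  Factors common to all minima
(``(beta h)^kappa``) cancel from occupation probabilities and free-energy
differences and are dropped, so per-minimum log-weights reduce to

    ln w_i = -V_i / (k_B T) - log_prod_i - ln o_i .

Only free-energy *differences* between minima are meaningful outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL, T_DEFAULT, beta
from .ktn_io import KTN, Minimum

__all__ = [
    "OccupationTable",
    "log_weight",
    "log_weights",
    "equilibrium_occupations",
    "heat_capacity_curve",
]


@dataclass
class OccupationTable:
    """Equilibrium occupation probabilities and free energies at one temperature.

    ``F`` drops a common additive constant; differences ``F_i - F_j`` equal
    ``-k_B T ln(p_i / p_j)`` exactly.
    """

    T: float
    ids: np.ndarray
    p: np.ndarray
    F: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.ids.tolist(), self.p.tolist()))


def log_weight(minimum: Minimum, T: float) -> float:
    """Dimensionless log Boltzmann weight of one minimum (common terms dropped)."""
    b = beta(T)
    return -minimum.V * b - minimum.log_prod - np.log(minimum.pg_order)


def log_weights(ktn: KTN, T: float) -> np.ndarray:
    """Vector of per-minimum log-weights in storage order."""
    b = beta(T)
    V = np.array([m.V for m in ktn.minima])
    lp = np.array([m.log_prod for m in ktn.minima])
    pg = np.array([m.pg_order for m in ktn.minima])
    return -V * b - lp - np.log(pg)


def equilibrium_occupations(ktn: KTN, T: float = T_DEFAULT) -> OccupationTable:
    """Equilibrium occupation probability and free energy of every minimum."""
    if ktn.n_minima == 0:
        raise ValueError("cannot compute occupations of an empty network")
    lw = log_weights(ktn, T)
    lz = logsumexp(lw)
    p = np.exp(lw - lz)
    p /= p.sum()  # exact renormalisation
    F = -KB_KCAL * T * lw
    return OccupationTable(
        T=T, ids=np.array([m.id for m in ktn.minima]), p=p, F=F
    )


def mean_potential_energy(ktn: KTN, T: float) -> float:
    """Occupation-weighted mean potential energy <V>_p (kcal/mol)."""
    occ = equilibrium_occupations(ktn, T)
    V = np.array([m.V for m in ktn.minima])
    return float(occ.p @ V)


def heat_capacity_curve(ktn: KTN, T_grid) -> np.ndarray:
    """Constant-volume heat capacity C_v(T) in units of k_B.

    For classical harmonic wells::

        C_v / k_B = kappa + (<V^2> - <V>^2) / (k_B T)^2

    with averages over the equilibrium occupations at each T.  The first term
    is the intra-well vibrational contribution, the second the inter-well
    fluctuation that peaks at landscape transitions.
    """
    if ktn.kappa is None:
        raise ValueError("KTN.kappa (vibrational DOF count) must be set for C_v")
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    if np.any(T_grid <= 0):
        raise ValueError("temperatures must be positive")
    V = np.array([m.V for m in ktn.minima])
    out = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        p = equilibrium_occupations(ktn, T).p
        mean = p @ V
        var = p @ (V - mean) ** 2
        out[k] = ktn.kappa + var / (KB_KCAL * T) ** 2
    return out
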