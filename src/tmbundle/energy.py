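"""Coarse-grained bundle energy.

Two terms: (i) a residue-pair-specific short-range contact potential
acting between Calpha sites of *different* helices, extended by signed
wells between side-chain centroids of charged residues (attractive for
opposite charges, repulsive for like charges); (ii) harmonic membrane
restraints that keep every helix upright and vertically centered.

Energies are expressed in units of k_B * K (k_B = 1), so Metropolis
temperatures are plain kelvins.

The packaged pair table is a declared stand-in: a hydropathy-derived
contact matrix rescaled so that the deepest hydrophobic well is
~300 k_B K.  It is a swappable input (see :func:`load_pair_table`).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import CANONICAL_AA, BundleConfiguration

__all__ = [
    "PairPotentialTable",
    "MembraneRestraintParams",
    "default_pair_table",
    "pair_energy",
    "helix_pair_energy",
    "membrane_energy",
    "helix_membrane_energy",
    "total_energy",
    "INFINITE_ENERGY",
]

#: sentinel for overlapping sites; finite-arithmetic safe (never NaN)
INFINITE_ENERGY = np.inf

_N_AA = len(CANONICAL_AA)

# Kyte-Doolittle hydropathy, used to synthesize the default contact matrix
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}


@dataclass(frozen=True)
class PairPotentialTable:
    """Symmetric 20x20 well depths/contact distances plus charge-well parameters."""

    epsilon: np.ndarray                 # (20, 20), k_B K, >= 0
    sigma: np.ndarray                   # (20, 20), Angstrom
    cutoff: float = 12.0                # Angstrom, wells shifted to 0 here
    min_sequence_separation: int = 1    # unused: only inter-helix pairs scored
    epsilon_charge: float = 300.0       # k_B K, centroid-centroid well magnitude
    sigma_charge: float = 4.0           # Angstrom, charge-well center
    charge_width: float = 1.0           # Angstrom, Gaussian charge-well width

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        if eps.shape != (_N_AA, _N_AA) or sig.shape != (_N_AA, _N_AA):
            raise ValueError("epsilon and sigma must be 20x20")
        if not np.allclose(eps, eps.T) or not np.allclose(sig, sig.T):
            raise ValueError("epsilon and sigma must be symmetric")
        if np.any(sig <= 0):
            raise ValueError("sigma must be positive")
        if self.cutoff <= sig.max() or self.cutoff <= self.sigma_charge:
            raise ValueError("cutoff must exceed every contact distance")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "sigma", sig)


def default_pair_table(
    epsilon_max: float = 300.0,
    epsilon_min: float = 5.0,
    sigma_ca: float = 5.0,
    cutoff: float = 12.0,
    epsilon_charge: float = 300.0,
    sigma_charge: float = 4.0,
) -> PairPotentialTable:
    """Hydropathy-product contact matrix (stand-in for a statistical table).

    eps_ij = eps_min + (eps_max - eps_min) * s_i * s_j with s the min-max
    normalized Kyte-Doolittle hydropathy, so the strongest hydrophobic
    pair (Ile-Ile) reaches ``epsilon_max``.
    """
    h = np.array([_KD[a] for a in CANONICAL_AA])
    s = (h - h.min()) / (h.max() - h.min())
    eps = epsilon_min + (epsilon_max - epsilon_min) * np.outer(s, s)
    sig = np.full((_N_AA, _N_AA), sigma_ca)
    return PairPotentialTable(
        epsilon=eps,
        sigma=sig,
        cutoff=cutoff,
        epsilon_charge=epsilon_charge,
        sigma_charge=sigma_charge,
    )


@dataclass(frozen=True)
class MembraneRestraintParams:
    """Harmonic tilt/z restraints per helix; tilt beyond max_tilt is forbidden."""

    k_tilt: float = 2000.0      # k_B K per rad^2
    max_tilt: float = np.pi / 2
    k_z: float = 10.0           # k_B K per A^2
    target_z: float = 0.0

    def __post_init__(self) -> None:
        if self.k_tilt < 0 or self.k_z < 0:
            raise ValueError("force constants must be non-negative")


def _well(r2: np.ndarray, eps: np.ndarray, sig2, cutoff: float) -> float:
    """Sum of shifted 12-6 wells over pairs with r < cutoff.

    ``u(r) = eps * [(sig/r)^12 - 2 (sig/r)^6] - u_raw(cutoff)``.
    Returns INFINITE_ENERGY on exact overlap.
    """
    mask = r2 < cutoff * cutoff
    if not np.any(mask):
        return 0.0
    r2m = r2[mask]
    if np.any(r2m <= 0.0):
        return INFINITE_ENERGY
    sig2m = sig2[mask] if isinstance(sig2, np.ndarray) else sig2
    epsm = eps[mask] if isinstance(eps, np.ndarray) else eps
    s6 = (sig2m / r2m) ** 3
    s6c = (sig2m / (cutoff * cutoff)) ** 3
    u = epsm * ((s6 * s6 - 2.0 * s6) - (s6c * s6c - 2.0 * s6c))
    return float(np.sum(u))


def _charge_well(r2: np.ndarray, sign: np.ndarray, table: PairPotentialTable) -> float:
    """Signed, bounded Gaussian wells between charged side-chain centroids.

    ``u(r) = -sign * eps_c * [g(r) - g(cutoff)]`` with ``g`` a unit Gaussian
    centered on the contact distance; sign = +1 for opposite charges
    (attractive, depth ~eps_c at contact) and -1 for like charges (the
    exact mirror).  A bounded well is used here instead of a 12-6 form so
    the repulsive mirror cannot become attractive at short range.
    """
    mask = r2 < table.cutoff**2
    if not mask.any():
        return 0.0
    r = np.sqrt(r2[mask])
    two_w2 = 2.0 * table.charge_width**2
    g = np.exp(-((r - table.sigma_charge) ** 2) / two_w2)
    gc = np.exp(-((table.cutoff - table.sigma_charge) ** 2) / two_w2)
    return float((-sign[mask] * table.epsilon_charge * (g - gc)).sum())


def helix_pair_energy(helix_a, helix_b, table: PairPotentialTable) -> float:
    """Contact energy between two helices (Calpha wells + signed charge wells)."""
    ca_a, ca_b = helix_a.ca_global(), helix_b.ca_global()
    codes_a = helix_a.segment.codes()
    codes_b = helix_b.segment.codes()
    eps = table.epsilon[np.ix_(codes_a, codes_b)]
    sig2 = table.sigma[np.ix_(codes_a, codes_b)] ** 2
    e = _well(cdist(ca_a, ca_b, "sqeuclidean"), eps, sig2, table.cutoff)
    if not np.isfinite(e):
        return INFINITE_ENERGY
    if len(helix_a.sc_local) and len(helix_b.sc_local):
        sc_a, sc_b = helix_a.sc_global(), helix_b.sc_global()
        # opposite charges -> attractive well, like charges -> exactly
        # mirrored repulsive well (equal magnitude parameters).
        sign = -np.outer(helix_a.sc_charge, helix_b.sc_charge).astype(float)
        r2 = cdist(sc_a, sc_b, "sqeuclidean")
        e += _charge_well(r2, sign, table)
    return e


def pair_energy(config: BundleConfiguration, table: PairPotentialTable) -> float:
    """Total inter-helix contact energy (intra-helix pairs excluded)."""
    total = 0.0
    for i in range(len(config.helices)):
        for j in range(i + 1, len(config.helices)):
            e = helix_pair_energy(config.helices[i], config.helices[j], table)
            if not np.isfinite(e):
                return INFINITE_ENERGY
            total += e
    return total


def helix_membrane_energy(helix, params: MembraneRestraintParams) -> float:
    axis_z = abs(float(helix.axis()[2]))
    tilt = float(np.arccos(min(1.0, axis_z)))
    if tilt > params.max_tilt:
        return INFINITE_ENERGY
    dz = float(helix.center()[2]) - params.target_z
    return params.k_tilt * tilt * tilt + params.k_z * dz * dz


def membrane_energy(config: BundleConfiguration, params: MembraneRestraintParams) -> float:
    """Sum of per-helix harmonic tilt and z-center restraints."""
    total = 0.0
    for h in config.helices:
        e = helix_membrane_energy(h, params)
        if not np.isfinite(e):
            return INFINITE_ENERGY
        total += e
    return total


def total_energy(
    config: BundleConfiguration,
    table: PairPotentialTable,
    params: MembraneRestraintParams,
) -> float:
    ep = pair_energy(config, table)
    if not np.isfinite(ep):
        return INFINITE_ENERGY
    em = membrane_energy(config, params)
    if not np.isfinite(em):
        return INFINITE_ENERGY
    return ep + em


def load_pair_table(path, **kwargs) -> PairPotentialTable:
    """Read a pair table from TSV rows ``aa_i  aa_j  epsilon  sigma``.

    Missing pairs default to the packaged stand-in values; extra keyword
    arguments override cutoff/charge parameters.
    """
    import pandas as pd

    base = default_pair_table()
    eps = base.epsilon.copy()
    sig = base.sigma.copy()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"aa_i", "aa_j", "epsilon", "sigma"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    idx = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    for row in df.itertuples(index=False):
        try:
            i, j = idx[row.aa_i], idx[row.aa_j]
        except KeyError as exc:
            raise ValueError(f"unknown amino acid {exc.args[0]!r} in pair table") from None
        eps[i, j] = eps[j, i] = float(row.epsilon)
        sig[i, j] = sig[j, i] = float(row.sigma)
    merged = dict(cutoff=base.cutoff, epsilon_charge=base.epsilon_charge,
                  sigma_charge=base.sigma_charge)
    merged.update(kwargs)
    return PairPotentialTable(epsilon=eps, sigma=sig, **merged)
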