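"""Trajectory analytics: superposition RMSD, helicity, salt-bridge distances
and lock-state classification.

A :class:`Trajectory` is a stack of coordinate frames over a shared site
topology (chain id, residue number, site name).  Both coarse-grained
models (CA + CB centroid pseudo-atoms) and externally produced all-atom
multi-model PDB input are handled uniformly.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "SaltBridgePair",
    "LockState",
    "LockSeries",
    "ca_rmsd_series",
    "helicity_series",
    "min_distance_series",
    "lock_state_series",
]


@dataclass
class Trajectory:
    """Coordinate frames (n_frames, n_sites, 3) over a fixed topology."""

    coords: np.ndarray
    chain_ids: np.ndarray     # (n_sites,) str
    residue_numbers: np.ndarray  # (n_sites,) int
    site_names: np.ndarray    # (n_sites,) str, e.g. "CA", "CB", "NZ"
    time_per_frame: float | None = None   # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_sites, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.coords.shape[1]
        self.chain_ids = np.asarray(self.chain_ids)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.site_names = np.asarray(self.site_names)
        if not (len(self.chain_ids) == len(self.residue_numbers) == len(self.site_names) == n):
            raise ValueError("topology arrays must match the number of sites")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def site_mask(self, chain_id=None, residue_number=None, site_name=None) -> np.ndarray:
        mask = np.ones(self.coords.shape[1], dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if residue_number is not None:
            mask &= self.residue_numbers == residue_number
        if site_name is not None:
            mask &= self.site_names == site_name
        return mask


@dataclass(frozen=True)
class SaltBridgePair:
    """A candidate salt bridge, scored by minimal inter-residue site distance."""

    acidic: tuple      # (chain_id, residue_number)
    basic: tuple
    formed_cutoff: float = 4.5   # Angstrom

    def __post_init__(self) -> None:
        if self.formed_cutoff <= 0:
            raise ValueError("formed_cutoff must be positive")


class LockState(str, Enum):
    LOCKED_INTRA = "locked_intra"
    SWITCHED_INTER = "switched_inter"
    BOTH = "both"
    NEITHER = "neither"


@dataclass
class LockSeries:
    states: list
    intra_distance: np.ndarray
    inter_distance: np.ndarray
    switch_frame: int | None
    dwell: int


def ca_rmsd_series(traj: Trajectory, reference_frame: int = 0,
                   selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame least-squares superposition RMSD over selected CA sites."""
    if selection is None:
        selection = traj.site_mask(site_name="CA")
    selection = np.asarray(selection)
    if selection.dtype == bool:
        idx = np.where(selection)[0]
    else:
        idx = selection.astype(int)
    if len(idx) < 3:
        raise ValueError("RMSD needs at least 3 selected sites")
    ref = traj.coords[reference_frame, idx]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coords[f, idx]
        x_c = x - x.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, x_c)
        out[f] = rssd / np.sqrt(len(idx))
    return out


def _virtual_torsion(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four points."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # sign convention: right-handed helices give positive virtual torsion
    return float(np.degrees(np.arctan2(-y, x)))


def helicity_series(traj: Trajectory, selection: np.ndarray | None = None,
                    n_total: int | None = None,
                    d13_range=(4.5, 6.0), torsion_range=(35.0, 65.0)) -> np.ndarray:
    """Per-frame helical fraction from Calpha geometry.

    A window of residues i..i+3 (consecutive numbering within one chain)
    is helical iff d(CA_i, CA_i+3) lies in ``d13_range`` and the virtual
    torsion of the four CAs lies in ``torsion_range``; all four residues
    of a passing window count as helical.  The fraction divides by
    ``n_total`` when given (e.g. a full-domain residue count including
    unmodeled loops), else by the number of selected residues.
    """
    if selection is None:
        selection = traj.site_mask(site_name="CA")
    idx = np.where(np.asarray(selection))[0]
    if len(idx) < 4:
        raise ValueError("helicity needs at least 4 consecutive CA sites")
    # group by chain, order by residue number
    windows = []
    for chain in np.unique(traj.chain_ids[idx]):
        sub = idx[traj.chain_ids[idx] == chain]
        sub = sub[np.argsort(traj.residue_numbers[sub])]
        res = traj.residue_numbers[sub]
        for a in range(len(sub) - 3):
            if res[a + 3] - res[a] == 3:
                windows.append(sub[a:a + 4])
    if not windows:
        raise ValueError("selection contains no run of >= 4 consecutive residues")
    denom = n_total if n_total is not None else len(idx)
    lo_d, hi_d = d13_range
    lo_t, hi_t = torsion_range
    fractions = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        helical = set()
        xyz = traj.coords[f]
        for w in windows:
            p = xyz[w]
            d13 = float(np.linalg.norm(p[3] - p[0]))
            if not (lo_d <= d13 <= hi_d):
                continue
            tor = _virtual_torsion(*p)
            if lo_t <= tor <= hi_t:
                helical.update(w.tolist())
        fractions[f] = len(helical) / denom
    return fractions


def _residue_sites(traj: Trajectory, chain_id: str, residue_number: int) -> np.ndarray:
    idx = np.where(traj.site_mask(chain_id=chain_id, residue_number=residue_number))[0]
    if len(idx) == 0:
        raise ValueError(f"residue {chain_id}{residue_number} not in topology")
    return idx


def min_distance_series(traj: Trajectory, pair: SaltBridgePair) -> np.ndarray:
    """Per-frame minimum over all site pairs between the two residues."""
    ia = _residue_sites(traj, *pair.acidic)
    ib = _residue_sites(traj, *pair.basic)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = np.sqrt(cdist(traj.coords[f, ia], traj.coords[f, ib],
                               "sqeuclidean").min())
    return out


def lock_state_series(traj: Trajectory, intra_pair: SaltBridgePair,
                      inter_pair: SaltBridgePair, dwell: int = 10) -> LockSeries:
    """Classify each frame by which salt bridge is formed; find the switch.

    The switch frame is the first frame at which the inter-molecular
    bridge is formed and the intra-molecular one is broken, with that
    condition sustained for ``dwell`` consecutive frames.  The state
    depends on geometry only, not on residue labels.
    """
    d_intra = min_distance_series(traj, intra_pair)
    d_inter = min_distance_series(traj, inter_pair)
    intra_on = d_intra < intra_pair.formed_cutoff
    inter_on = d_inter < inter_pair.formed_cutoff
    states = []
    for a, b in zip(intra_on, inter_on):
        if a and b:
            states.append(LockState.BOTH)
        elif a:
            states.append(LockState.LOCKED_INTRA)
        elif b:
            states.append(LockState.SWITCHED_INTER)
        else:
            states.append(LockState.NEITHER)
    switched = inter_on & ~intra_on
    switch_frame = None
    n = len(switched)
    run = 0
    for f in range(n):
        run = run + 1 if switched[f] else 0
        if run >= min(dwell, n):
            switch_frame = f - run + 1
            break
    return LockSeries(states=states, intra_distance=d_intra,
                      inter_distance=d_inter, switch_frame=switch_frame,
                      dwell=dwell)
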