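"""Docking of a single partner TM helix onto a selected bundle model.

The partner helix is sampled by the same REMC machinery with the bundle
frozen (optionally mobile), under a harmonic restraint on the minimal
site distance of a designated acidic/basic residue pair.  Charge-swap
mutations (e.g. D->K on the bundle plus K->D on the partner) are applied
by rebuilding the residue's side-chain centroid; the Calpha trace is
untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (BundleConfiguration, CANONICAL_AA, HelixSegment, RigidHelix,
                   _sidechain_sites, build_ideal_helix)
from .energy import MembraneRestraintParams, PairPotentialTable
from .remc import Ensemble, MCSettings, ReplicaSchedule, resolve_restraint, run_remc

__all__ = ["SaltBridgeRestraint", "dock_partner", "apply_mutation",
           "DEFAULT_TAPASIN_TM"]

#: packaged default partner helix: a TM segment bracketing the conserved
#: lysine at 428 and carrying the FxxxFxxxGxxKxxxW motif (chain B).
DEFAULT_TAPASIN_TM = HelixSegment(
    helix_id="TPN", chain_id="B", start_res=417, end_res=433,
    sequence="FLLLFGAVGLLKVLLWA",
)

_ACIDIC = {"D", "E"}
_BASIC = {"K", "R"}


@dataclass(frozen=True)
class SaltBridgeRestraint:
    """Harmonic restraint pulling an acidic/basic residue pair together."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    target_distance: float = 3.5   # Angstrom, minimal site distance
    force_constant: float = 10.0   # k_B K per A^2

    def __post_init__(self) -> None:
        if self.target_distance <= 0 or self.force_constant < 0:
            raise ValueError("invalid restraint parameters")

    def validate_against(self, config: BundleConfiguration) -> None:
        """Both residues must exist and be oppositely charged (either order)."""
        aas = []
        for chain, res in ((self.chain_a, self.res_a), (self.chain_b, self.res_b)):
            for h in config.helices:
                seg = h.segment
                if seg.chain_id == chain and seg.start_res <= res <= seg.end_res:
                    aas.append(seg.sequence[res - seg.start_res])
                    break
            else:
                raise ValueError(f"restraint residue {chain}{res} not found")
        pair = set()
        for aa in aas:
            if aa in _ACIDIC:
                pair.add("acidic")
            elif aa in _BASIC:
                pair.add("basic")
        if pair != {"acidic", "basic"}:
            raise ValueError(
                f"restraint pair must be one acidic and one basic residue, got {aas}"
            )


def _initial_partner_pose(bundle: BundleConfiguration, partner: RigidHelix,
                          restraints, rng: np.random.Generator) -> RigidHelix:
    """Place the partner outside the bundle, roughly facing the restrained residue."""
    centers = np.array([h.center() for h in bundle.helices])
    centroid = centers.mean(axis=0)
    direction = None
    if restraints:
        r = restraints[0]
        for chain, res in ((r.chain_a, r.res_a), (r.chain_b, r.res_b)):
            for h in bundle.helices:
                seg = h.segment
                if seg.chain_id == chain and seg.start_res <= res <= seg.end_res:
                    site = h.ca_global()[res - seg.start_res]
                    direction = site - centroid
                    direction[2] = 0.0
                    break
            if direction is not None:
                break
    if direction is None or np.linalg.norm(direction) < 1e-9:
        direction = np.array([1.0, 0.0, 0.0])
    direction = direction / np.linalg.norm(direction)
    radius = float(np.linalg.norm((centers - centroid)[:, :2], axis=1).max()) + 10.0
    spin = rng.uniform(0.0, 2 * np.pi)
    c, s = np.cos(spin), np.sin(spin)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = centroid + radius * direction
    t[2] = 0.0
    return partner.with_pose(rot, t)


def dock_partner(
    bundle: BundleConfiguration,
    partner_segment: HelixSegment,
    restraints,
    schedule: ReplicaSchedule,
    settings: MCSettings,
    table: PairPotentialTable,
    membrane_params: MembraneRestraintParams,
    *,
    mobile_bundle: bool = False,
) -> tuple[BundleConfiguration, Ensemble]:
    """REMC docking of ``partner_segment`` onto ``bundle``.

    Returns (lowest-energy sampled complex, full saved ensemble).  With
    ``mobile_bundle=False`` (default) only the partner helix moves, so
    all bundle-internal distances are preserved exactly.
    """
    restraints = list(restraints)
    partner = build_ideal_helix(partner_segment)
    rng = np.random.default_rng(settings.rng_seed)
    partner = _initial_partner_pose(bundle, partner, restraints, rng)
    complex0 = BundleConfiguration(
        helices=bundle.helices + (partner,), frame=bundle.frame
    )
    for r in restraints:
        r.validate_against(complex0)
    templates = [build_ideal_helix(h.segment) for h in complex0.helices]
    resolved = [
        resolve_restraint(templates, r.chain_a, r.res_a, r.chain_b, r.res_b,
                          r.target_distance, r.force_constant)
        for r in restraints
    ]
    mobile = (list(range(len(complex0.helices))) if mobile_bundle
              else [len(complex0.helices) - 1])
    segments = [h.segment for h in complex0.helices]
    ensemble = run_remc(
        segments, table, membrane_params, schedule, settings,
        initial=complex0, mobile=mobile, restraints=resolved,
    )
    best = int(np.argmin(ensemble.energies))
    return ensemble.configurations[best], ensemble


def apply_mutation(config: BundleConfiguration, chain_id: str, residue_number: int,
                   new_aa: str) -> BundleConfiguration:
    """Point-mutate one residue; rebuilds its side-chain centroid site.

    The Calpha trace and the helix pose are unchanged, so mutating back
    restores the original configuration (and energy) exactly.
    """
    if new_aa not in CANONICAL_AA:
        raise ValueError(f"invalid amino acid {new_aa!r}")
    for idx, h in enumerate(config.helices):
        seg = h.segment
        if seg.chain_id == chain_id and seg.start_res <= residue_number <= seg.end_res:
            pos = residue_number - seg.start_res
            new_seq = seg.sequence[:pos] + new_aa + seg.sequence[pos + 1:]
            new_seg = replace(seg, sequence=new_seq)
            sc_local, sc_res, charges = _sidechain_sites(h.ca_local, new_seq)
            new_h = RigidHelix(
                segment=new_seg, ca_local=h.ca_local, sc_local=sc_local,
                sc_res_index=sc_res, sc_charge=charges,
                rotation=h.rotation, translation=h.translation,
            )
            return config.replace_helix(idx, new_h)
    raise ValueError(f"residue {chain_id}{residue_number} not found in any segment")
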