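"""Domain types and rigid-body geometry for coarse-grained TM helix bundles.

Conventions
-----------
Right-handed coordinate frame with the membrane normal along +z, the
cytosol at -z and the bilayer midplane at z = 0.  "Clockwise viewed from
the cytosol" therefore means clockwise when looking from -z towards +z.
Residue numbering is 1-based and inclusive.

Each residue carries a single C-alpha interaction site.  Charged
residues (D, E, K, R) carry one additional side-chain centroid
pseudo-site, offset radially outward from the helix axis, so that
salt-bridge geometry is representable at coarse-grained resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CANONICAL_AA",
    "RESIDUE_CHARGE",
    "HelixSegment",
    "RigidHelix",
    "MembraneFrame",
    "BundleConfiguration",
    "build_ideal_helix",
    "place_helix",
    "global_coords",
    "initialize_bundle",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: formal side-chain charge sign at neutral pH (coarse model)
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

# ideal alpha-helix parameters (Calpha trace)
CA_CA_DISTANCE = 3.8        # Angstrom, consecutive Calpha
RISE_PER_RESIDUE = 1.5      # Angstrom along the helix axis
TWIST_PER_RESIDUE = np.deg2rad(100.0)
SIDECHAIN_OFFSET = 2.4      # Angstrom, Calpha -> side-chain centroid, radial

# radius of the Calpha spiral implied by the three constants above:
# |p(i+1)-p(i)|^2 = (2 r sin(twist/2))^2 + rise^2 = d^2
HELIX_RADIUS = float(
    np.sqrt(CA_CA_DISTANCE**2 - RISE_PER_RESIDUE**2)
    / (2.0 * np.sin(TWIST_PER_RESIDUE / 2.0))
)

_ORTHO_TOL = 1e-8


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a one-letter sequence onto integer codes (alphabetical order)."""
    try:
        return np.array([_AA_INDEX[a] for a in sequence], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - message detail
        raise ValueError(f"non-canonical residue letter {exc.args[0]!r}") from None


@dataclass(frozen=True)
class HelixSegment:
    """A contiguous stretch of sequence modeled as one rigid TM helix."""

    helix_id: str
    chain_id: str
    start_res: int
    end_res: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end_res < self.start_res:
            raise ValueError(
                f"segment {self.helix_id}: end_res {self.end_res} < start_res {self.start_res}"
            )
        n = self.end_res - self.start_res + 1
        if len(self.sequence) != n:
            raise ValueError(
                f"segment {self.helix_id}: sequence length {len(self.sequence)} "
                f"does not match span {self.start_res}-{self.end_res} ({n} residues)"
            )
        bad = set(self.sequence) - set(CANONICAL_AA)
        if bad:
            raise ValueError(
                f"segment {self.helix_id}: non-canonical residue letter(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.start_res, self.end_res + 1)

    def codes(self) -> np.ndarray:
        return encode_sequence(self.sequence)


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=_ORTHO_TOL):
        raise ValueError("rotation matrix is not proper (det != +1)")
    return rotation


def _sidechain_sites(ca_local: np.ndarray, sequence: str):
    """Side-chain centroid sites for charged residues.

    Placed ``SIDECHAIN_OFFSET`` from the Calpha along the local radial
    direction (away from the helix z-axis); degenerate on-axis Calphas
    fall back to +x.
    """
    idx = [i for i, aa in enumerate(sequence) if aa in RESIDUE_CHARGE]
    sc_res = np.array(idx, dtype=np.intp)
    if not idx:
        return np.zeros((0, 3)), sc_res, np.zeros(0, dtype=np.intp)
    radial = ca_local[sc_res].copy()
    radial[:, 2] = 0.0
    norms = np.linalg.norm(radial, axis=1)
    radial[norms < 1e-12] = (1.0, 0.0, 0.0)
    norms = np.where(norms < 1e-12, 1.0, norms)
    sc_local = ca_local[sc_res] + SIDECHAIN_OFFSET * radial / norms[:, None]
    charges = np.array([RESIDUE_CHARGE[sequence[i]] for i in idx], dtype=np.intp)
    return sc_local, sc_res, charges


@dataclass(frozen=True)
class RigidHelix:
    """A posed rigid helix: local interaction sites plus a rotation/translation."""

    segment: HelixSegment
    ca_local: np.ndarray          # (n, 3) Calpha sites, helix frame
    sc_local: np.ndarray          # (m, 3) side-chain centroid sites, helix frame
    sc_res_index: np.ndarray      # (m,) 0-based residue index of each centroid
    sc_charge: np.ndarray         # (m,) +1 / -1
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def ca_global(self) -> np.ndarray:
        return self.ca_local @ self.rotation.T + self.translation

    def sc_global(self) -> np.ndarray:
        return self.sc_local @ self.rotation.T + self.translation

    def axis(self) -> np.ndarray:
        """Helix axis direction (local +z) in the global frame."""
        return self.rotation[:, 2].copy()

    def center(self) -> np.ndarray:
        """Centroid of the Calpha trace (== translation; local trace is centered)."""
        return self.translation.copy()

    def with_pose(self, rotation: np.ndarray, translation: np.ndarray) -> "RigidHelix":
        return replace(
            self,
            rotation=np.asarray(rotation, dtype=float),
            translation=np.asarray(translation, dtype=float),
        )

    def n_sites(self) -> int:
        return len(self.ca_local) + len(self.sc_local)


@dataclass(frozen=True)
class MembraneFrame:
    """Implicit membrane slab: normal fixed to +z, midplane at z = 0."""

    half_thickness: float = 15.0

    def __post_init__(self) -> None:
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")


@dataclass(frozen=True)
class BundleConfiguration:
    """Poses of all helices in a shared membrane frame."""

    helices: tuple
    frame: MembraneFrame = field(default_factory=MembraneFrame)

    def __post_init__(self) -> None:
        object.__setattr__(self, "helices", tuple(self.helices))
        ids = [h.segment.helix_id for h in self.helices]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate helix ids: {ids}")

    def __len__(self) -> int:
        return len(self.helices)

    def helix(self, helix_id: str) -> RigidHelix:
        for h in self.helices:
            if h.segment.helix_id == helix_id:
                return h
        raise KeyError(f"no helix with id {helix_id!r}")

    def replace_helix(self, index: int, helix: RigidHelix) -> "BundleConfiguration":
        helices = list(self.helices)
        helices[index] = helix
        return replace(self, helices=tuple(helices))

    def ca_arrays(self) -> list:
        return [h.ca_global() for h in self.helices]

    def segments(self) -> list:
        return [h.segment for h in self.helices]


def build_ideal_helix(segment: HelixSegment) -> RigidHelix:
    """Construct an ideal alpha-helix for ``segment`` with identity pose.

    The Calpha trace spirals about the local z-axis (3.8 A consecutive
    spacing, 1.5 A rise, 100 deg twist per residue) and is centered so the
    Calpha centroid sits at the local origin.
    """
    n = len(segment)
    i = np.arange(n)
    theta = i * TWIST_PER_RESIDUE
    ca = np.column_stack(
        [
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            i * RISE_PER_RESIDUE,
        ]
    )
    ca -= ca.mean(axis=0)
    sc_local, sc_res, charges = _sidechain_sites(ca, segment.sequence)
    return RigidHelix(
        segment=segment,
        ca_local=ca,
        sc_local=sc_local,
        sc_res_index=sc_res,
        sc_charge=charges,
    )


def place_helix(helix: RigidHelix, rotation: np.ndarray, translation: np.ndarray) -> RigidHelix:
    """Apply a global-frame rigid transform on top of the current pose.

    Global sites map as ``x -> rotation @ x + translation``; local
    coordinates are untouched.
    """
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=float).reshape(3)
    new_r = rotation @ helix.rotation
    new_t = rotation @ helix.translation + translation
    return helix.with_pose(new_r, new_t)


def global_coords(config: BundleConfiguration) -> np.ndarray:
    """All interaction sites in the global frame, deterministically ordered.

    Helices appear in declared order; within a helix, sites follow residue
    order with each charged residue's centroid directly after its Calpha.
    """
    blocks = []
    for h in config.helices:
        ca = h.ca_global()
        sc = h.sc_global()
        if len(sc) == 0:
            blocks.append(ca)
            continue
        out = []
        sc_by_res = {int(r): sc[j] for j, r in enumerate(h.sc_res_index)}
        for i in range(len(ca)):
            out.append(ca[i])
            if i in sc_by_res:
                out.append(sc_by_res[i])
        blocks.append(np.array(out))
    if not blocks:
        return np.zeros((0, 3))
    return np.vstack(blocks)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # N->C inversion: pi rotation about x


def initialize_bundle(
    segments: Sequence[HelixSegment],
    rng_seed,
    placement_radius: float,
    *,
    max_tilt: float = 0.1,
    antiparallel: bool = True,
    directions: Sequence[int] | None = None,
    frame: MembraneFrame | None = None,
) -> BundleConfiguration:
    """Seedable starting state: helix centers on a circle in the membrane plane.

    Centers are placed in declared order at increasing azimuth (which puts
    the bundle in the clockwise-viewed-from-cytosol circulation class),
    each helix gets a random azimuthal spin, a random tilt within
    ``max_tilt`` of the membrane normal, and consecutive helices alternate
    N->C direction unless ``directions`` overrides (+1 = N-terminus at -z).
    """
    segments = list(segments)
    if not segments:
        raise ValueError("at least one segment required")
    if placement_radius <= 0:
        raise ValueError("placement_radius must be positive")
    if directions is None:
        directions = [1 if (k % 2 == 0 or not antiparallel) else -1 for k in range(len(segments))]
    if len(directions) != len(segments) or any(d not in (-1, 1) for d in directions):
        raise ValueError("directions must give +1/-1 per segment")
    rng = np.random.default_rng(rng_seed)
    frame = frame or MembraneFrame()

    n = len(segments)
    helices = []
    for k, seg in enumerate(segments):
        h = build_ideal_helix(seg)
        rot = np.eye(3) if directions[k] == 1 else _FLIP_X
        spin = rng.uniform(0.0, 2.0 * np.pi)
        rot = _rotation_about(np.array([0.0, 0.0, 1.0]), spin) @ rot
        if max_tilt > 0:
            tilt = rng.uniform(0.0, max_tilt)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            tilt_axis = np.array([np.cos(phi), np.sin(phi), 0.0])
            rot = _rotation_about(tilt_axis, tilt) @ rot
        azimuth = 2.0 * np.pi * k / n
        t = placement_radius * np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
        helices.append(h.with_pose(rot, t))
    return BundleConfiguration(helices=tuple(helices), frame=frame)
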