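"""DRMS-based clustering of saved ensembles and bundle topology checks.

DRMS between two configurations is the RMS difference of corresponding
inter-helix Calpha distances; intra-helix distances are rigid-identical
under the sampler's moves and are excluded so they cannot dilute the
signal.  Clustering is greedy leader-style over energy-ordered members
with a distance cutoff, followed by one center re-selection pass.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import BundleConfiguration

__all__ = ["ClusterResult", "drms", "drms_vector", "cluster_ensemble", "bundle_handedness"]


def _check_compatible(a: BundleConfiguration, b: BundleConfiguration) -> None:
    sa = [(s.helix_id, s.start_res, s.end_res) for s in a.segments()]
    sb = [(s.helix_id, s.start_res, s.end_res) for s in b.segments()]
    if sa != sb:
        raise ValueError(f"configurations differ in composition: {sa} vs {sb}")


def drms_vector(config: BundleConfiguration) -> np.ndarray:
    """Flattened vector of all inter-helix Calpha-Calpha distances."""
    ca = config.ca_arrays()
    parts = [cdist(ca[i], ca[j]).ravel()
             for i in range(len(ca)) for j in range(i + 1, len(ca))]
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def drms(config_a: BundleConfiguration, config_b: BundleConfiguration) -> float:
    """RMS deviation of corresponding inter-helix Calpha distances (Angstrom)."""
    _check_compatible(config_a, config_b)
    va, vb = drms_vector(config_a), drms_vector(config_b)
    if len(va) == 0:
        return 0.0
    return float(np.sqrt(np.mean((va - vb) ** 2)))


@dataclass
class ClusterResult:
    labels: np.ndarray            # per-configuration cluster id, -1 = noise
    centers: list                 # one BundleConfiguration per kept cluster
    center_indices: list          # ensemble index of each center
    cutoff: float
    sizes: np.ndarray             # per kept cluster
    mean_energies: np.ndarray     # per kept cluster

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _pairwise_drms(vectors: np.ndarray) -> np.ndarray:
    """All-pairs DRMS from a (m, p) matrix of distance vectors (via GEMM)."""
    sq = np.einsum("ij,ij->i", vectors, vectors)
    d2 = sq[:, None] + sq[None, :] - 2.0 * vectors @ vectors.T
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2 / vectors.shape[1])


def cluster_ensemble(ensemble, cutoff: float = 4.0, min_size_fraction: float = 0.05,
                     max_center_members: int = 4000) -> ClusterResult:
    """Greedy leader clustering of an :class:`~tmbundle.remc.Ensemble`.

    Configurations are visited by ascending energy (ties broken by
    ensemble index); each joins the first founder within ``cutoff`` DRMS,
    otherwise founds a new cluster.  Centers are then re-selected as the
    member with minimal mean DRMS to co-members.  Clusters smaller than
    ``min_size_fraction`` of the ensemble are reported as noise (-1).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    configs = ensemble.configurations
    energies = np.asarray(ensemble.energies, dtype=float)
    n = len(configs)
    if n == 0:
        raise ValueError("ensemble is empty")
    p = None
    vectors = []
    for c in configs:
        v = drms_vector(c)
        if p is None:
            p = len(v)
        vectors.append(v)
    vectors = np.asarray(vectors)

    order = np.lexsort((np.arange(n), energies))
    founders: list[int] = []
    labels = np.full(n, -1, dtype=int)
    for idx in order:
        v = vectors[idx]
        assigned = False
        for ci, f in enumerate(founders):
            d = np.sqrt(np.mean((v - vectors[f]) ** 2)) if p else 0.0
            if d <= cutoff:
                labels[idx] = ci
                assigned = True
                break
        if not assigned:
            labels[idx] = len(founders)
            founders.append(idx)

    min_size = min_size_fraction * n
    centers, center_indices, sizes, mean_energies = [], [], [], []
    new_labels = np.full(n, -1, dtype=int)
    for ci in range(len(founders)):
        members = np.where(labels == ci)[0]
        if len(members) < min_size:
            continue
        sel = members
        if len(members) > max_center_members:
            # center estimated on a deterministic subsample for tractability
            sel = members[np.linspace(0, len(members) - 1, max_center_members).astype(int)]
        dm = _pairwise_drms(vectors[sel]) if p else np.zeros((len(sel), len(sel)))
        mean_d = dm.sum(axis=1) / max(len(sel) - 1, 1)
        center = int(sel[int(np.argmin(mean_d))])
        new_id = len(centers)
        new_labels[members] = new_id
        centers.append(configs[center])
        center_indices.append(center)
        sizes.append(len(members))
        mean_energies.append(float(energies[members].mean()))

    return ClusterResult(
        labels=new_labels,
        centers=centers,
        center_indices=center_indices,
        cutoff=float(cutoff),
        sizes=np.array(sizes, dtype=int),
        mean_energies=np.array(mean_energies),
    )


def bundle_handedness(config: BundleConfiguration) -> str:
    """Circulation sense of helix centers in declared order, seen from the cytosol.

    Returns ``"clockwise"`` or ``"counterclockwise"`` as viewed from -z
    (the cytosolic side in this package's convention).  Computed from the
    signed area of the polygon of helix centers projected on the membrane
    plane: positive circulation about +z appears clockwise from -z.
    """
    if len(config.helices) < 3:
        raise ValueError("handedness needs at least 3 helices")
    centers = np.array([h.center() for h in config.helices])[:, :2]
    centers = centers - centers.mean(axis=0)
    nxt = np.roll(centers, -1, axis=0)
    signed_area = 0.5 * float(np.sum(centers[:, 0] * nxt[:, 1] - centers[:, 1] * nxt[:, 0]))
    span = float(np.abs(centers).max())
    if span <= 0 or abs(signed_area) < 1e-9 * max(span * span, 1.0):
        raise ValueError("helix centers are (near-)collinear; handedness undefined")
    return "clockwise" if signed_area > 0 else "counterclockwise"
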