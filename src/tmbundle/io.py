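"""Readers/writers for the pipeline's exchange formats.

Models, ensembles, complexes and trajectories travel as (multi-MODEL)
PDB; segments, observations, restraints and reports as TSV; sequences as
FASTA.  Coarse-grained sites are written as CA atoms plus CB pseudo-atoms
for charged-residue side-chain centroids.
"""
from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .core import BundleConfiguration, HelixSegment, MembraneFrame, build_ideal_helix
from .dock import SaltBridgeRestraint
from .score import CrosslinkObservation
from .traj import Trajectory

__all__ = [
    "ParseError",
    "read_segments",
    "read_crosslinks",
    "write_crosslinks",
    "read_restraints",
    "read_fasta",
    "packaged_path",
    "tap1_segments",
    "tap1_crosslinks",
    "tapasin_segment",
    "write_models",
    "read_models",
    "configs_from_pdb",
    "trajectory_from_pdb",
    "write_ensemble",
    "write_provenance",
]

STANDIN_NOTICES = [
    "pair potential: packaged hydropathy-derived contact table is a stand-in "
    "for an adapted statistical residue-pair potential; swappable via TSV",
    "model score: coarse-grained contact+restraint energy is a stand-in for "
    "all-atom relax/rescore stages, which are out of scope",
    "exposure: foreign-helix neighbor counting is a stand-in for "
    "surface-area-based exposure",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------- TSV

def _read_tsv(path, required_columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_segments(path) -> list:
    """TSV with columns helix_id, chain_id, start_res, end_res, sequence."""
    df = _read_tsv(path, ["helix_id", "chain_id", "start_res", "end_res", "sequence"])
    if df.empty:
        raise ParseError(f"{path}: no segments defined")
    if df["helix_id"].duplicated().any():
        dup = df["helix_id"][df["helix_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate helix_id {dup!r}")
    segments = []
    for row in df.itertuples(index=False):
        try:
            segments.append(HelixSegment(
                helix_id=row.helix_id, chain_id=row.chain_id,
                start_res=int(row.start_res), end_res=int(row.end_res),
                sequence=row.sequence,
            ))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return segments


def read_crosslinks(path, segments=None) -> list:
    """TSV with columns residue, dimer_formed (0/1), blocked_by_tapasin (0/1/NA), note."""
    df = _read_tsv(path, ["residue", "dimer_formed", "blocked_by_tapasin"])
    if df.empty:
        raise ParseError(f"{path}: observation table is empty")
    if df["residue"].duplicated().any():
        dup = df["residue"][df["residue"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate observation row for residue {dup}")
    spans = None
    if segments is not None:
        spans = [(s.start_res, s.end_res) for s in segments]
    obs = []
    for row in df.itertuples(index=False):
        res = int(row.residue)
        if spans is not None and not any(a <= res <= b for a, b in spans):
            raise ParseError(f"{path}: residue {res} lies outside every declared segment")
        blocked_raw = row.blocked_by_tapasin.strip().upper()
        blocked = None if blocked_raw in ("NA", "", "NONE") else bool(int(blocked_raw))
        obs.append(CrosslinkObservation(
            residue=res,
            dimer_formed=bool(int(row.dimer_formed)),
            blocked_by_tapasin=blocked,
            note=getattr(row, "note", ""),
        ))
    return obs


def write_crosslinks(path, observations) -> None:
    rows = []
    for o in observations:
        blocked = "NA" if o.blocked_by_tapasin is None else int(o.blocked_by_tapasin)
        rows.append({"residue": o.residue, "dimer_formed": int(o.dimer_formed),
                     "blocked_by_tapasin": blocked, "note": o.note})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraints(path) -> list:
    df = _read_tsv(path, ["chain_a", "res_a", "chain_b", "res_b", "target", "k"])
    return [
        SaltBridgeRestraint(
            chain_a=r.chain_a, res_a=int(r.res_a),
            chain_b=r.chain_b, res_b=int(r.res_b),
            target_distance=float(r.target), force_constant=float(r.k),
        )
        for r in df.itertuples(index=False)
    ]


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------- packaged data

def packaged_path(name: str):
    return resources.files("tmbundle.data") / name


def tap1_segments() -> list:
    """The four TM spans of the TAP1 accessory domain (curated fixture)."""
    return read_segments(packaged_path("tap1_segments.tsv"))


def tap1_crosslinks(segments=None) -> list:
    """Curated 16-position cysteine-scanning observation table."""
    return read_crosslinks(packaged_path("tap1_crosslinks.tsv"), segments=segments)


def tapasin_segment() -> HelixSegment:
    return read_segments(packaged_path("tapasin_tm.tsv"))[0]


# ------------------------------------------------------------------- PDB

_ELEMENT = {"CA": "C", "CB": "C"}


def _validate_pdb_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinate record"
                    ) from None


def _config_atom_array(config: BundleConfiguration) -> struc.AtomArray:
    chain_ids, res_ids, res_names, atom_names, coords = [], [], [], [], []
    for h in config.helices:
        seg = h.segment
        ca = h.ca_global()
        sc = h.sc_global()
        sc_by_res = {int(r): sc[j] for j, r in enumerate(h.sc_res_index)}
        for i, resnum in enumerate(seg.residue_numbers):
            aa3 = ProteinSequence.convert_letter_1to3(seg.sequence[i])
            for name, xyz in (("CA", ca[i]),) + (
                (("CB", sc_by_res[i]),) if i in sc_by_res else ()
            ):
                chain_ids.append(seg.chain_id)
                res_ids.append(int(resnum))
                res_names.append(aa3)
                atom_names.append(name)
                coords.append(xyz)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords)
    arr.chain_id = np.asarray(chain_ids)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.asarray(res_names)
    arr.atom_name = np.asarray(atom_names)
    arr.element = np.asarray([_ELEMENT.get(a, "C") for a in atom_names])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_models(path, configs) -> None:
    """Write one or more configurations as a (multi-MODEL) PDB file."""
    configs = list(configs)
    if not configs:
        raise ValueError("no configurations to write")
    arrays = [_config_atom_array(c) for c in configs]
    structure = arrays[0] if len(arrays) == 1 else struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(str(path))


def read_models(path) -> Trajectory:
    """Read a (multi-MODEL) PDB into a Trajectory (site topology + frames)."""
    _validate_pdb_lines(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return Trajectory(
        coords=coords,
        chain_ids=np.asarray(stack.chain_id),
        residue_numbers=np.asarray(stack.res_id, dtype=int),
        site_names=np.asarray(stack.atom_name),
    )


trajectory_from_pdb = read_models


def configs_from_pdb(path, segments, frame: MembraneFrame | None = None) -> list:
    """Reconstruct posed configurations from a multi-MODEL PDB.

    Each helix pose is recovered by least-squares fitting the ideal local
    Calpha trace onto the model's CA coordinates (exact for rigid models
    up to PDB coordinate precision).
    """
    traj = read_models(path)
    frame = frame or MembraneFrame()
    templates = [build_ideal_helix(s) for s in segments]
    sel = []
    for seg in segments:
        idx = []
        for resnum in seg.residue_numbers:
            m = np.where((traj.chain_ids == seg.chain_id)
                         & (traj.residue_numbers == resnum)
                         & (traj.site_names == "CA"))[0]
            if len(m) != 1:
                raise ParseError(
                    f"{path}: expected exactly one CA for {seg.chain_id}{resnum}, "
                    f"found {len(m)}"
                )
            idx.append(int(m[0]))
        sel.append(np.array(idx))
    configs = []
    for f in range(traj.n_frames):
        helices = []
        for tmpl, idx in zip(templates, sel):
            target = traj.coords[f, idx]
            centroid = target.mean(axis=0)
            rot, _ = Rotation.align_vectors(target - centroid, tmpl.ca_local)
            r = rot.as_matrix()
            helices.append(tmpl.with_pose(r, centroid))
        configs.append(BundleConfiguration(helices=tuple(helices), frame=frame))
    return configs


def write_ensemble(pdb_path, tsv_path, ensemble) -> None:
    """Ensemble as multi-MODEL PDB plus a TSV of (model_index, energy)."""
    write_models(pdb_path, ensemble.configurations)
    pd.DataFrame({
        "model_index": np.arange(len(ensemble)),
        "energy": ensemble.energies,
    }).to_csv(tsv_path, sep="\t", index=False)


def write_provenance(path, seed, settings: dict, extra: dict | None = None) -> None:
    """Config-echo log: seeds, settings, versions, stand-in notices."""
    import tmbundle

    payload = {
        "tmbundle_version": tmbundle.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "settings": settings,
        "standin_notices": STANDIN_NOTICES,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
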