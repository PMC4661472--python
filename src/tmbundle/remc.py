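"""Replica-exchange Monte Carlo over rigid-body helix moves.

Each MC step attempts one single-helix rigid move (uniform translation in
a cube, rotation about a random axis through the helix center) per
replica; adjacent-temperature replicas exchange configurations with the
standard swap criterion on an alternating even/odd pairing.  Energies are
in k_B K (k_B = 1), so the temperature ladder is used directly.

The configuration occupying the lowest-temperature slot is recorded every
``save_interval`` steps; with the protocol defaults (1e6 steps, interval
100) this keeps 1e4 configurations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import BundleConfiguration, HelixSegment, MembraneFrame, RigidHelix, \
    _rotation_about, build_ideal_helix, initialize_bundle
from .energy import INFINITE_ENERGY, MembraneRestraintParams, PairPotentialTable

__all__ = [
    "ReplicaSchedule",
    "MCSettings",
    "Ensemble",
    "propose_move",
    "metropolis_accept",
    "exchange_sweep",
    "run_remc",
]


@dataclass(frozen=True)
class ReplicaSchedule:
    """Ascending temperature ladder in kelvin."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("temperatures must be a non-empty 1-D sequence")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(np.diff(t) < 0):
            raise ValueError("temperatures must be ascending")
        object.__setattr__(self, "temperatures", t)

    def __len__(self) -> int:
        return len(self.temperatures)

    @classmethod
    def geometric(cls, n: int = 20, t_min: float = 100.0, t_max: float = 300.0) -> "ReplicaSchedule":
        """Geometrically spaced ladder (default 20 replicas, 100-300 K)."""
        return cls(np.geomspace(t_min, t_max, n))


@dataclass(frozen=True)
class MCSettings:
    n_steps: int = 1_000_000
    save_temperature_index: int = 0
    save_interval: int = 100
    max_translation: float = 0.5    # Angstrom per move (pilot-calibrated)
    max_rotation: float = 0.1       # rad per move
    exchange_interval: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.save_interval < 1 or self.exchange_interval < 1:
            raise ValueError("step counts and intervals must be >= 1")
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ValueError("move amplitudes must be non-negative")


@dataclass
class Ensemble:
    """Saved configurations from one temperature slot, with provenance."""

    configurations: list
    energies: np.ndarray
    temperature: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.configurations) != len(self.energies):
            raise ValueError("configurations and energies must have equal length")

    def __len__(self) -> int:
        return len(self.configurations)


def _draw_move(rng: np.random.Generator, indices: np.ndarray, settings: MCSettings):
    """(helix index, translation, rotation matrix) for one proposal."""
    u = rng.random(5)
    k = int(indices[int(u[0] * len(indices))])
    dt = (2.0 * u[1:4] - 1.0) * settings.max_translation
    v = rng.standard_normal(3)
    norm = (v[0] * v[0] + v[1] * v[1] + v[2] * v[2]) ** 0.5
    axis = v / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    angle = (2.0 * u[4] - 1.0) * settings.max_rotation
    return k, dt, _rotation_about(axis, angle)


def propose_move(config: BundleConfiguration, rng: np.random.Generator,
                 settings: MCSettings, mobile: Sequence[int] | None = None):
    """Return (new configuration, moved helix id); exactly one helix altered.

    The rotation is applied about the moved helix's own center, so
    translation and rotation are independent degrees of freedom, and the
    proposal density is symmetric (reverse move equally likely).
    """
    if len(config.helices) == 0:
        raise ValueError("configuration has no helices")
    indices = np.asarray(mobile if mobile is not None else range(len(config.helices)))
    k, dt, rot = _draw_move(rng, indices, settings)
    h = config.helices[k]
    new_h = h.with_pose(rot @ h.rotation, h.translation + dt)
    return config.replace_helix(k, new_h), h.segment.helix_id


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_e / T)); T in K, k_B = 1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    if not np.isfinite(delta_e):
        return False
    return rng.random() < np.exp(-delta_e / temperature)


def exchange_sweep(replica_states: Sequence, schedule: ReplicaSchedule,
                   rng: np.random.Generator, parity: int = 0):
    """Attempt swaps of adjacent temperature slots.

    ``replica_states`` is one ``(state, energy)`` pair per temperature
    slot; pairs ``(parity, parity+1), (parity+2, ...)`` are attempted with
    acceptance ``min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)])``.  States move
    between slots; temperatures stay fixed to slots.  Returns the new
    slot list and the indices of accepted swaps.
    """
    if len(replica_states) != len(schedule):
        raise ValueError(
            f"{len(replica_states)} replica states for {len(schedule)} temperatures"
        )
    states = list(replica_states)
    temps = schedule.temperatures
    accepted = []
    for i in range(parity % 2, len(states) - 1, 2):
        e_i, e_j = states[i][1], states[i + 1][1]
        log_p = (1.0 / temps[i] - 1.0 / temps[i + 1]) * (e_i - e_j)
        if log_p >= 0 or rng.random() < np.exp(log_p):
            states[i], states[i + 1] = states[i + 1], states[i]
            accepted.append(i)
    return states, accepted


# ---------------------------------------------------------------------------
# fast internal state: poses + cached site arrays + incremental energy terms
# ---------------------------------------------------------------------------

_Z_AXIS = np.array([0.0, 0.0, 1.0])


def _membrane_term(rot, t, params: MembraneRestraintParams) -> float:
    axis_z = abs(float(rot[2, 2]))
    tilt = float(np.arccos(min(1.0, axis_z)))
    if tilt > params.max_tilt:
        return INFINITE_ENERGY
    dz = float(t[2]) - params.target_z
    return params.k_tilt * tilt * tilt + params.k_z * dz * dz


class ResolvedRestraint:
    """Harmonic restraint on the minimal site distance of one residue pair."""

    __slots__ = ("helix_a", "rows_ca_a", "rows_sc_a", "helix_b", "rows_ca_b",
                 "rows_sc_b", "target", "k")

    def __init__(self, helix_a, rows_ca_a, rows_sc_a, helix_b, rows_ca_b,
                 rows_sc_b, target, k):
        self.helix_a, self.helix_b = helix_a, helix_b
        self.rows_ca_a, self.rows_sc_a = rows_ca_a, rows_sc_a
        self.rows_ca_b, self.rows_sc_b = rows_ca_b, rows_sc_b
        self.target, self.k = float(target), float(k)

    def _sites(self, ca_list, sc_list, helix, rows_ca, rows_sc):
        pts = [ca_list[helix][rows_ca]]
        if len(rows_sc):
            pts.append(sc_list[helix][rows_sc])
        return np.vstack(pts)

    def energy(self, ca_list, sc_list) -> float:
        a = self._sites(ca_list, sc_list, self.helix_a, self.rows_ca_a, self.rows_sc_a)
        b = self._sites(ca_list, sc_list, self.helix_b, self.rows_ca_b, self.rows_sc_b)
        d = float(np.sqrt(cdist(a, b, "sqeuclidean").min()))
        return self.k * (d - self.target) ** 2

    def min_distance(self, ca_list, sc_list) -> float:
        a = self._sites(ca_list, sc_list, self.helix_a, self.rows_ca_a, self.rows_sc_a)
        b = self._sites(ca_list, sc_list, self.helix_b, self.rows_ca_b, self.rows_sc_b)
        return float(np.sqrt(cdist(a, b, "sqeuclidean").min()))


def resolve_restraint(templates: Sequence[RigidHelix], chain_a, res_a, chain_b,
                      res_b, target, k) -> ResolvedRestraint:
    """Bind a (chain, residue) pair restraint to helix/site indices."""

    def locate(chain, res):
        for hi, h in enumerate(templates):
            seg = h.segment
            if seg.chain_id == chain and seg.start_res <= res <= seg.end_res:
                ridx = res - seg.start_res
                sc_rows = np.where(h.sc_res_index == ridx)[0]
                return hi, np.array([ridx]), sc_rows
        raise ValueError(f"restraint residue {chain}{res} not in any segment")

    ha, ca_a, sc_a = locate(chain_a, res_a)
    hb, ca_b, sc_b = locate(chain_b, res_b)
    return ResolvedRestraint(ha, ca_a, sc_a, hb, ca_b, sc_b, target, k)


class _RowParams:
    """Per-helix precomputed well parameters against all *other* helices.

    Columns are the concatenation of the other helices' sites in ascending
    helix order; ``bounds`` are cumulative column offsets so per-pair block
    sums fall out of one cumulative sum.
    """

    __slots__ = ("others", "eps", "sig2", "shift", "bounds",
                 "ceps", "cbounds", "csig", "cw2", "cshift", "cut2")

    def __init__(self, k: int, segments, charges, table: PairPotentialTable):
        n_h = len(segments)
        self.others = [j for j in range(n_h) if j != k]
        codes_k = segments[k].codes()
        codes_o = (np.concatenate([segments[j].codes() for j in self.others])
                   if self.others else np.zeros(0, dtype=np.intp))
        self.eps = table.epsilon[np.ix_(codes_k, codes_o)]
        self.sig2 = table.sigma[np.ix_(codes_k, codes_o)] ** 2
        cut2 = table.cutoff**2
        s6c = (self.sig2 / cut2) ** 3
        self.shift = self.eps * (s6c * s6c - 2.0 * s6c)
        self.cut2 = cut2
        self.bounds = np.cumsum([0] + [len(segments[j]) for j in self.others])
        q_k = charges[k]
        q_o = (np.concatenate([charges[j] for j in self.others])
               if self.others else np.zeros(0, dtype=np.intp))
        if len(q_k) and len(q_o):
            # signed bounded Gaussian charge wells (see energy._charge_well)
            self.ceps = -np.outer(q_k, q_o).astype(float) * table.epsilon_charge
            self.csig = table.sigma_charge
            self.cw2 = 2.0 * table.charge_width**2
            self.cshift = np.exp(-((table.cutoff - table.sigma_charge) ** 2) / self.cw2)
        else:
            self.ceps = None
            self.csig, self.cw2, self.cshift = 0.0, 1.0, 0.0
        self.cbounds = np.cumsum([0] + [len(charges[j]) for j in self.others])


try:  # optional compiled kernels; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(error_model="numpy", cache=False)
    def _row_ca_kernel(ca_k, ca_o, eps, sig2, shift, cut2, bounds, row):
        for blk in range(len(bounds) - 1):
            s = 0.0
            for j in range(bounds[blk], bounds[blk + 1]):
                xo, yo, zo = ca_o[j, 0], ca_o[j, 1], ca_o[j, 2]
                for i in range(ca_k.shape[0]):
                    dx = ca_k[i, 0] - xo
                    dy = ca_k[i, 1] - yo
                    dz = ca_k[i, 2] - zo
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < cut2:
                        w = sig2[i, j] / r2
                        s6 = w * w * w
                        s += eps[i, j] * (s6 * (s6 - 2.0)) - shift[i, j]
            row[blk] += s

    @_njit(error_model="numpy", cache=False)
    def _row_sc_kernel(sc_k, sc_o, ceps, csig, cw2, cshift, cut2, bounds, row):
        for blk in range(len(bounds) - 1):
            s = 0.0
            for j in range(bounds[blk], bounds[blk + 1]):
                xo, yo, zo = sc_o[j, 0], sc_o[j, 1], sc_o[j, 2]
                for i in range(sc_k.shape[0]):
                    dx = sc_k[i, 0] - xo
                    dy = sc_k[i, 1] - yo
                    dz = sc_k[i, 2] - zo
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < cut2:
                        d = r2 ** 0.5 - csig
                        g = np.exp(-(d * d) / cw2)
                        s += -ceps[i, j] * (g - cshift)
            row[blk] += s

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False


def _row_energies(new_ca, new_sc, ca_list, sc_list, rp: _RowParams) -> np.ndarray:
    """Energy of one helix against each other helix (length n_h - 1)."""
    if not rp.others:
        return np.zeros(0)
    ca_o = (ca_list[rp.others[0]] if len(rp.others) == 1
            else np.concatenate([ca_list[j] for j in rp.others]))
    if _HAVE_NUMBA:
        row = np.zeros(len(rp.others))
        _row_ca_kernel(new_ca, ca_o, rp.eps, rp.sig2, rp.shift, rp.cut2,
                       rp.bounds, row)
        if rp.ceps is not None and len(new_sc):
            sc_o = np.concatenate([sc_list[j] for j in rp.others])
            if len(sc_o):
                _row_sc_kernel(new_sc, sc_o, rp.ceps, rp.csig, rp.cw2,
                               rp.cshift, rp.cut2, rp.cbounds, row)
        return row
    r2 = cdist(new_ca, ca_o, "sqeuclidean")
    w = rp.sig2 / r2              # overlap -> inf, rejected downstream
    s6 = w * w * w
    u = rp.eps * (s6 * (s6 - 2.0)) - rp.shift
    col = np.where(r2 < rp.cut2, u, 0.0).sum(axis=0)
    cs = np.concatenate(([0.0], np.cumsum(col)))
    row = cs[rp.bounds[1:]] - cs[rp.bounds[:-1]]
    if rp.ceps is not None and len(new_sc):
        sc_o = np.concatenate([sc_list[j] for j in rp.others])
        if len(sc_o):
            r2 = cdist(new_sc, sc_o, "sqeuclidean")
            g = np.exp(-((np.sqrt(r2) - rp.csig) ** 2) / rp.cw2)
            col = np.where(r2 < rp.cut2, -rp.ceps * (g - rp.cshift), 0.0).sum(axis=0)
            cs = np.concatenate(([0.0], np.cumsum(col)))
            row = row + (cs[rp.cbounds[1:]] - cs[rp.cbounds[:-1]])
    return row


class _ReplicaState:
    """Mutable per-replica state with incremental energy bookkeeping."""

    __slots__ = ("rot", "t", "ca", "sc", "pair", "mem", "restr", "total")

    def __init__(self, templates, poses, row_params, params, restraints):
        self.rot = [np.array(r, dtype=float) for r, _ in poses]
        self.t = [np.array(t, dtype=float) for _, t in poses]
        self.ca = [tm.ca_local @ r.T + t for tm, (r, t) in zip(templates, poses)]
        self.sc = [tm.sc_local @ r.T + t for tm, (r, t) in zip(templates, poses)]
        n = len(templates)
        self.pair = np.zeros((n, n))
        for k in range(n):
            rp = row_params[k]
            row = _row_energies(self.ca[k], self.sc[k], self.ca, self.sc, rp)
            for j, e in zip(rp.others, row):
                self.pair[k, j] = e
        self.pair = 0.5 * (self.pair + self.pair.T)  # each pair computed twice
        self.mem = np.array([_membrane_term(r, t, params)
                             for r, t in zip(self.rot, self.t)])
        self.restr = np.array([r.energy(self.ca, self.sc) for r in restraints])
        self.total = (float(np.triu(self.pair, 1).sum()) + float(self.mem.sum())
                      + float(self.restr.sum()))

    def snapshot(self):
        return [(r.copy(), t.copy()) for r, t in zip(self.rot, self.t)]


def _attempt_move(state: _ReplicaState, k, dt, rot, templates, row_params,
                  params, restraints, restraints_by_helix, temperature, u_accept):
    """One Metropolis move of helix k; mutates state on acceptance."""
    new_rot = rot @ state.rot[k]
    new_t = state.t[k] + dt
    tm = templates[k]
    new_ca = tm.ca_local @ new_rot.T + new_t
    new_sc = tm.sc_local @ new_rot.T + new_t

    new_mem = _membrane_term(new_rot, new_t, params)
    if not np.isfinite(new_mem):
        return False
    rp = row_params[k]
    row = _row_energies(new_ca, new_sc, state.ca, state.sc, rp)
    delta = (new_mem - state.mem[k]) + row.sum() - state.pair[k, rp.others].sum()
    new_restr = {}
    for ri in restraints_by_helix.get(k, ()):
        r = restraints[ri]
        ca_l, sc_l = list(state.ca), list(state.sc)
        ca_l[k], sc_l[k] = new_ca, new_sc
        e = r.energy(ca_l, sc_l)
        new_restr[ri] = e
        delta += e - state.restr[ri]

    # metropolis with a pre-drawn uniform (consumed whether or not needed)
    if delta > 0:
        if not np.isfinite(delta) or u_accept >= np.exp(-delta / temperature):
            return False
    state.rot[k], state.t[k] = new_rot, new_t
    state.ca[k], state.sc[k] = new_ca, new_sc
    state.mem[k] = new_mem
    state.pair[k, rp.others] = row
    state.pair[rp.others, k] = row
    for ri, e in new_restr.items():
        state.restr[ri] = e
    state.total += delta
    return True


def run_remc(
    segments: Sequence[HelixSegment],
    table: PairPotentialTable,
    membrane_params: MembraneRestraintParams,
    schedule: ReplicaSchedule,
    settings: MCSettings,
    *,
    initial: BundleConfiguration | None = None,
    mobile: Sequence[int] | None = None,
    restraints: Sequence[ResolvedRestraint] = (),
    placement_radius: float = 10.0,
    directions: Sequence[int] | None = None,
    frame: MembraneFrame | None = None,
) -> Ensemble:
    """Run the full REMC protocol and return the low-T saved ensemble.

    Deterministic given ``settings.rng_seed``.  If ``initial`` is given it
    seeds every replica; otherwise each replica starts from its own
    random circular placement.  ``mobile`` restricts moves to a subset of
    helices (used for docking with a frozen bundle).
    """
    segments = list(segments)
    rng = np.random.default_rng(settings.rng_seed)
    templates = [build_ideal_helix(s) for s in segments]
    n_h = len(templates)
    charges = [tm.sc_charge for tm in templates]
    row_params = [_RowParams(k, segments, charges, table) for k in range(n_h)]
    mobile_idx = np.asarray(mobile if mobile is not None else range(n_h), dtype=np.intp)
    restraints = list(restraints)
    restraints_by_helix: dict = {}
    for ri, r in enumerate(restraints):
        restraints_by_helix.setdefault(r.helix_a, []).append(ri)
        if r.helix_b != r.helix_a:
            restraints_by_helix.setdefault(r.helix_b, []).append(ri)

    n_rep = len(schedule)

    def errstate():
        return np.errstate(divide="ignore", over="ignore")

    states = []
    for rep in range(n_rep):
        if initial is not None:
            poses = [(h.rotation, h.translation) for h in initial.helices]
        else:
            cfg = initialize_bundle(segments, rng, placement_radius,
                                    directions=directions, frame=frame)
            poses = [(h.rotation, h.translation) for h in cfg.helices]
        with errstate():
            st = _ReplicaState(templates, poses, row_params, membrane_params,
                               restraints)
        if not np.isfinite(st.total):
            raise RuntimeError(
                f"replica {rep}: infinite energy at initialization (overlapping sites)"
            )
        states.append(st)

    temps = schedule.temperatures
    saved_poses, saved_energies = [], []
    acc = np.zeros(n_rep)
    att = np.zeros(n_rep)
    exch_acc = np.zeros(max(n_rep - 1, 1))
    exch_att = np.zeros(max(n_rep - 1, 1))
    parity = 0
    slot_of = list(range(n_rep))  # slot -> state index (states stay in a flat list)

    # pre-drawn randoms in blocks: one (k, dt, angle, accept) row and one
    # normal triple per move; refilled when exhausted
    block = 8192
    u_buf = np.empty((0, 6))
    n_buf = np.empty((0, 3))
    ptr = 0
    n_mob = len(mobile_idx)
    max_t, max_r = settings.max_translation, settings.max_rotation

    with errstate():
      for step in range(settings.n_steps):
        for slot in range(n_rep):
            st = states[slot_of[slot]]
            if ptr >= len(u_buf):
                u_buf = rng.random((block, 6))
                n_buf = rng.standard_normal((block, 3))
                ptr = 0
            u = u_buf[ptr]
            v = n_buf[ptr]
            ptr += 1
            k = int(mobile_idx[int(u[0] * n_mob)])
            dt = (2.0 * u[1:4] - 1.0) * max_t
            norm = (v[0] * v[0] + v[1] * v[1] + v[2] * v[2]) ** 0.5
            axis = v / norm if norm > 1e-12 else _Z_AXIS
            rot = _rotation_about(axis, (2.0 * u[4] - 1.0) * max_r)
            att[slot] += 1
            if _attempt_move(st, k, dt, rot, templates, row_params,
                             membrane_params, restraints, restraints_by_helix,
                             temps[slot], u[5]):
                acc[slot] += 1
        if n_rep > 1 and (step + 1) % settings.exchange_interval == 0:
            for i in range(parity, n_rep - 1, 2):
                e_i = states[slot_of[i]].total
                e_j = states[slot_of[i + 1]].total
                exch_att[i] += 1
                log_p = (1.0 / temps[i] - 1.0 / temps[i + 1]) * (e_i - e_j)
                if log_p >= 0 or rng.random() < np.exp(log_p):
                    slot_of[i], slot_of[i + 1] = slot_of[i + 1], slot_of[i]
                    exch_acc[i] += 1
            parity = 1 - parity
        if (step + 1) % settings.save_interval == 0:
            st = states[slot_of[settings.save_temperature_index]]
            saved_poses.append(st.snapshot())
            saved_energies.append(st.total)

    frame = frame or (initial.frame if initial is not None else MembraneFrame())
    configs = []
    for poses in saved_poses:
        helices = tuple(tm.with_pose(r, t) for tm, (r, t) in zip(templates, poses))
        configs.append(BundleConfiguration(helices=helices, frame=frame))
    provenance = {
        "settings": settings,
        "schedule": list(map(float, temps)),
        "seed": settings.rng_seed,
        "acceptance_rate_per_temperature": (acc / np.maximum(att, 1)).tolist(),
        "exchange_rate_per_pair": (exch_acc / np.maximum(exch_att, 1)).tolist(),
        "n_restraints": len(restraints),
    }
    return Ensemble(
        configurations=configs,
        energies=np.array(saved_energies),
        temperature=float(temps[settings.save_temperature_index]),
        provenance=provenance,
    )
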