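"""End-to-end assembly/selection pipeline: REMC -> DRMS clustering -> ranking.

One call bundles the stages the way the acceptance workflow uses them,
with the desk-scale defaults calibrated by pilot runs (10 replicas,
1e5 steps, one kept configuration every 25 steps).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterResult, bundle_handedness, cluster_ensemble
from .energy import MembraneRestraintParams, PairPotentialTable, default_pair_table
from .remc import Ensemble, MCSettings, ReplicaSchedule, run_remc
from .score import ModelScore, rank_models

__all__ = ["SelectionResult", "assemble_and_select"]


@dataclass
class SelectionResult:
    ensemble: Ensemble
    clusters: ClusterResult
    ranked: list                 # (model, ModelScore), best first
    selected: object             # BundleConfiguration
    selected_score: ModelScore
    selected_handedness: str

    @property
    def n_matched(self) -> int:
        return self.selected_score.n_matched


def assemble_and_select(
    segments,
    observations,
    seed: int,
    *,
    n_steps: int = 100_000,
    n_replicas: int = 10,
    save_interval: int = 25,
    exchange_interval: int = 100,
    max_translation: float = 0.5,
    max_rotation: float = 0.1,
    placement_radius: float = 10.0,
    cluster_cutoff: float = 4.0,
    min_size_fraction: float = 0.05,
    exposure_threshold: float = 0.5,
    table: PairPotentialTable | None = None,
    membrane_params: MembraneRestraintParams | None = None,
    candidates: str = "members",
) -> SelectionResult:
    """Assemble, cluster and select one model against the observation table.

    ``candidates`` controls which configurations enter the ranking stage:
    ``"members"`` (every member of a kept cluster, the analog of analyzing
    many models per cluster) or ``"centers"`` (cluster centers only).
    Deterministic given ``seed``.
    """
    table = table or default_pair_table()
    membrane_params = membrane_params or MembraneRestraintParams()
    schedule = ReplicaSchedule.geometric(n_replicas)
    settings = MCSettings(
        n_steps=n_steps, save_interval=save_interval,
        exchange_interval=exchange_interval, max_translation=max_translation,
        max_rotation=max_rotation, rng_seed=seed,
    )
    ensemble = run_remc(segments, table, membrane_params, schedule, settings,
                        placement_radius=placement_radius)
    clusters = cluster_ensemble(ensemble, cutoff=cluster_cutoff,
                                min_size_fraction=min_size_fraction)
    if candidates == "centers":
        idx = list(clusters.center_indices)
    elif candidates == "members":
        idx = np.where(clusters.labels >= 0)[0].tolist()
        if not idx:  # all noise (tiny ensembles): fall back to everything
            idx = list(range(len(ensemble)))
    else:
        raise ValueError(f"unknown candidates mode {candidates!r}")
    models = [ensemble.configurations[i] for i in idx]
    energies = [float(ensemble.energies[i]) for i in idx]
    ranked = rank_models(models, observations, energies=energies,
                         exposure_threshold=exposure_threshold)
    selected, score = ranked[0]
    return SelectionResult(
        ensemble=ensemble,
        clusters=clusters,
        ranked=ranked,
        selected=selected,
        selected_score=score,
        selected_handedness=bundle_handedness(selected),
    )
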