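"""Model selection against cysteine cross-link / accessibility observations.

A residue's lipid exposure is approximated by foreign-helix neighbor
counting (a coarse-grained stand-in for surface-area methods): residues
with few Calpha sites of *other* helices nearby are surface/lipid
accessible and able to form inter-molecular disulfide dimers; buried
residues are not.  Models are ranked by cross-link match count first and
coarse-grained energy second, mirroring a two-axis score-vs-restraints
selection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import BundleConfiguration

__all__ = [
    "CrosslinkObservation",
    "ExposureProfile",
    "ModelScore",
    "exposure_profile",
    "match_crosslinks",
    "rank_models",
    "ranking_table",
    "interface_residues",
    "blocking_consistency",
    "scored_subset",
]

# Neighbor shell ~ first coordination shell of the 5 A Calpha contact
# distance: inward-facing residues of a packed 4-helix bundle then count
# ~4-6 foreign sites, lipid-facing ones 0-1, so a 0.5 exposure threshold
# separates the two faces.  Larger shells saturate and classify every
# residue as buried.
DEFAULT_EXPOSURE_RADIUS = 6.0    # Angstrom neighbor shell
DEFAULT_SATURATION_COUNT = 6     # neighbor count mapping to exposure 0
DEFAULT_EXPOSURE_THRESHOLD = 0.5


@dataclass(frozen=True)
class CrosslinkObservation:
    """One engineered-cysteine position and its observed behavior."""

    residue: int
    dimer_formed: bool
    blocked_by_tapasin: bool | None = None   # None = unknown / not scored
    note: str = ""


@dataclass(frozen=True)
class ExposureProfile:
    """Per-residue exposure fractions keyed by (chain_id, residue_number)."""

    values: dict

    def of(self, chain_id: str, residue: int) -> float:
        return self.values[(chain_id, residue)]


@dataclass
class ModelScore:
    n_matched: int
    n_total: int
    matched_residues: list = field(default_factory=list)
    violated_residues: list = field(default_factory=list)
    energy_score: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.n_matched <= self.n_total):
            raise ValueError("0 <= n_matched <= n_total violated")


def exposure_profile(
    config: BundleConfiguration,
    radius: float = DEFAULT_EXPOSURE_RADIUS,
    saturation_count: int = DEFAULT_SATURATION_COUNT,
) -> ExposureProfile:
    """exposure = clamp(1 - n_foreign_neighbors / saturation_count, 0, 1).

    Neighbors are Calpha sites of other helices within ``radius``.
    """
    ca = config.ca_arrays()
    values = {}
    for i, h in enumerate(config.helices):
        counts = np.zeros(len(ca[i]), dtype=int)
        for j in range(len(ca)):
            if j == i:
                continue
            counts += (cdist(ca[i], ca[j], "sqeuclidean") < radius * radius).sum(axis=1)
        expo = np.clip(1.0 - counts / saturation_count, 0.0, 1.0)
        for r, e in zip(h.segment.residue_numbers, expo):
            values[(h.segment.chain_id, int(r))] = float(e)
    return ExposureProfile(values=values)


def scored_subset(observations, exclude_note_tokens=("proline",)):
    """Default scored set: drop observations whose note flags a perturbing
    mutation (the proline positions that aggregate on oxidation)."""
    tokens = tuple(t.lower() for t in exclude_note_tokens)
    return [o for o in observations
            if not any(t in o.note.lower() for t in tokens)]


def match_crosslinks(
    config: BundleConfiguration,
    observations,
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
    *,
    chain_id: str = "A",
    radius: float = DEFAULT_EXPOSURE_RADIUS,
    saturation_count: int = DEFAULT_SATURATION_COUNT,
) -> ModelScore:
    """Score a model's exposure pattern against dimer-formation flags.

    A dimer-forming position matches iff its exposure >= threshold
    (accessible at the bundle surface); a non-dimer-forming position
    matches iff exposure < threshold (buried).  Every observation passed
    in is scored; pre-filter with :func:`scored_subset` if needed.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("observations must be non-empty")
    profile = exposure_profile(config, radius=radius, saturation_count=saturation_count)
    matched, violated = [], []
    for o in obs:
        key = (chain_id, o.residue)
        if key not in profile.values:
            raise ValueError(f"observed residue {o.residue} lies outside all segments")
        exposed = profile.values[key] >= exposure_threshold
        (matched if exposed == bool(o.dimer_formed) else violated).append(o.residue)
    return ModelScore(
        n_matched=len(matched),
        n_total=len(obs),
        matched_residues=matched,
        violated_residues=violated,
    )


def rank_models(models, observations, energies=None, **match_kwargs):
    """Order models by descending match count, then ascending energy.

    Returns a list of ``(model, ModelScore)``; the first entry is the
    selected model.  ``energies`` supplies the coarse-grained energy score
    per model (NaN if omitted; NaN ranks last among equal match counts).
    """
    models = list(models)
    if not models:
        raise ValueError("at least one model required")
    if energies is None:
        energies = [float("nan")] * len(models)
    energies = [float(e) for e in energies]
    scored = []
    for m, e in zip(models, energies):
        s = match_crosslinks(m, observations, **match_kwargs)
        s.energy_score = e
        scored.append((m, s))

    def key(item):
        _, s = item
        e = s.energy_score
        return (-s.n_matched, np.inf if np.isnan(e) else e)

    scored.sort(key=key)
    return scored


def ranking_table(ranked) -> pd.DataFrame:
    """Two-axis report (energy score vs cross-link matches) for ranked models."""
    rows = [
        {
            "rank": i,
            "energy_score": s.energy_score,
            "n_matched": s.n_matched,
            "n_total": s.n_total,
            "violated_residues": ";".join(map(str, s.violated_residues)),
        }
        for i, (_, s) in enumerate(ranked)
    ]
    return pd.DataFrame(rows)


def _helix_sites(helix) -> np.ndarray:
    sc = helix.sc_global()
    ca = helix.ca_global()
    return np.vstack([ca, sc]) if len(sc) else ca


def interface_residues(
    complex_config: BundleConfiguration,
    partner_id: str,
    contact_cutoff: float = 8.0,
):
    """Bundle residues with any site within ``contact_cutoff`` of the partner.

    Returns ``{helix_id: [residue numbers]}`` for all non-partner helices.
    """
    partner = complex_config.helix(partner_id)  # KeyError if unknown
    p_sites = _helix_sites(partner)
    out = {}
    cut2 = contact_cutoff * contact_cutoff
    for h in complex_config.helices:
        if h.segment.helix_id == partner_id:
            continue
        close = (cdist(h.ca_global(), p_sites, "sqeuclidean") < cut2).any(axis=1)
        if len(h.sc_local):
            sc_close = (cdist(h.sc_global(), p_sites, "sqeuclidean") < cut2).any(axis=1)
            for row, ridx in zip(sc_close, h.sc_res_index):
                if row:
                    close[ridx] = True
        res = [int(r) for r, c in zip(h.segment.residue_numbers, close) if c]
        out[h.segment.helix_id] = res
    return out


def blocking_consistency(
    complex_config: BundleConfiguration,
    partner_id: str,
    observations,
    contact_cutoff: float = 8.0,
):
    """Check tapasin-blocking flags against the complex interface.

    A blocked position must lie in the partner interface; an unblocked
    position must not.  Observations with unknown blocking are skipped.
    Returns (matched residues, violated residues).
    """
    iface = interface_residues(complex_config, partner_id, contact_cutoff)
    in_iface = {r for residues in iface.values() for r in residues}
    matched, violated = [], []
    for o in observations:
        if o.blocked_by_tapasin is None:
            continue
        ok = (o.residue in in_iface) == bool(o.blocked_by_tapasin)
        (matched if ok else violated).append(o.residue)
    return matched, violated
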