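import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tmbundle.core import (BundleConfiguration, HelixSegment, build_ideal_helix,
                           initialize_bundle, place_helix)
from tmbundle.score import (CrosslinkObservation, ModelScore, blocking_consistency,
                            exposure_profile, interface_residues, match_crosslinks,
                            rank_models, ranking_table, scored_subset)
from tmbundle.synth import make_synthetic_crosslinks, make_truth_bundle

from conftest import random_rigid_transform, single_site_helix, toy_config


class TestExposureProfile:
    def test_isolated_helix_fully_exposed(self):
        h = build_ideal_helix(HelixSegment("H", "A", 1, 20, "L" * 20))
        profile = exposure_profile(toy_config(h))
        assert all(v == 1.0 for v in profile.values.values())

    def test_saturated_residue_fully_buried(self):
        center = single_site_helix("C", "L", [0, 0, 0])
        # surround with >= saturation_count foreign sites inside the shell
        others = [single_site_helix(f"H{i}", "L",
                                    [3.0 * np.cos(a), 3.0 * np.sin(a), 0],
                                    residue=10 + i)
                  for i, a in enumerate(np.linspace(0, 2 * np.pi, 8, endpoint=False))]
        profile = exposure_profile(toy_config(center, *others),
                                   radius=6.0, saturation_count=6)
        assert profile.of("A", 1) == 0.0

    def test_matches_brute_force_neighbor_count(self, segments):
        cfg = initialize_bundle(segments, 3, 9.0)
        radius, n_max = 6.0, 6
        profile = exposure_profile(cfg, radius=radius, saturation_count=n_max)
        ca = cfg.ca_arrays()
        for i, h in enumerate(cfg.helices):
            foreign = np.vstack([ca[j] for j in range(len(ca)) if j != i])
            for r_i, resnum in enumerate(h.segment.residue_numbers):
                n = int((np.linalg.norm(foreign - ca[i][r_i], axis=1) < radius).sum())
                expected = min(1.0, max(0.0, 1.0 - n / n_max))
                assert profile.of("A", int(resnum)) == pytest.approx(expected)


class TestMatchCrosslinks:
    def test_isolated_helix_all_dimer_matched(self):
        h = build_ideal_helix(HelixSegment("H", "A", 1, 10, "L" * 10))
        obs = [CrosslinkObservation(residue=r, dimer_formed=True)
               for r in range(1, 11)]
        score = match_crosslinks(toy_config(h), obs)
        assert score.n_matched == score.n_total == 10
        assert score.violated_residues == []

    def test_self_consistency_with_derived_observations(self):
        truth = make_truth_bundle(4, 12, "clockwise", 7.0, seed=5)
        residues = [r for s in truth.segments() for r in s.residue_numbers]
        obs = make_synthetic_crosslinks(truth, residues, threshold=0.5,
                                        noise_rate=0.0, seed=0)
        score = match_crosslinks(truth, obs, exposure_threshold=0.5)
        assert score.n_matched == score.n_total

    def test_residue_outside_segments_rejected(self):
        h = build_ideal_helix(HelixSegment("H", "A", 1, 10, "L" * 10))
        with pytest.raises(ValueError, match="outside"):
            match_crosslinks(toy_config(h),
                             [CrosslinkObservation(residue=99, dimer_formed=True)])

    def test_empty_observations_rejected(self):
        h = build_ideal_helix(HelixSegment("H", "A", 1, 10, "L" * 10))
        with pytest.raises(ValueError):
            match_crosslinks(toy_config(h), [])

    def test_rigid_motion_invariance(self, segments, observations, rng):
        obs = scored_subset(observations)
        cfg = initialize_bundle(segments, 4, 9.0)
        s0 = match_crosslinks(cfg, obs)
        rot, t = random_rigid_transform(rng)
        moved = BundleConfiguration(
            helices=tuple(place_helix(h, rot, t) for h in cfg.helices),
            frame=cfg.frame)
        s1 = match_crosslinks(moved, obs)
        assert s0.n_matched == s1.n_matched
        assert s0.matched_residues == s1.matched_residues

    def test_threshold_monotonicity_for_dimer_positives(self, segments):
        cfg = initialize_bundle(segments, 8, 9.0)
        residues = [r for s in segments for r in s.residue_numbers]
        obs = [CrosslinkObservation(residue=int(r), dimer_formed=True)
               for r in residues]
        counts = [match_crosslinks(cfg, obs, exposure_threshold=t).n_matched
                  for t in (0.9, 0.7, 0.5, 0.3, 0.1, 0.0)]
        assert counts == sorted(counts)  # lowering threshold never decreases

    def test_expected_match_rate_under_noise(self):
        # with flip probability p the expected match fraction is 1 - p;
        # binomial check over >= 50 replicates
        truth = make_truth_bundle(4, 12, "clockwise", 7.0, seed=2)
        residues = [r for s in truth.segments() for r in s.residue_numbers]
        p = 0.2
        fractions = []
        for rep in range(50):
            obs = make_synthetic_crosslinks(truth, residues, threshold=0.5,
                                            noise_rate=p, seed=rep)
            s = match_crosslinks(truth, obs, exposure_threshold=0.5)
            fractions.append(s.n_matched / s.n_total)
        n = 50 * len(residues)
        se = np.sqrt(p * (1 - p) / n)
        assert np.mean(fractions) == pytest.approx(1 - p, abs=4 * se)


class TestRankModels:
    def test_single_model_selected(self, segments, observations):
        cfg = initialize_bundle(segments, 0, 9.0)
        ranked = rank_models([cfg], scored_subset(observations))
        assert ranked[0][0] is cfg

    def test_energy_tie_break(self, segments, observations):
        cfg = initialize_bundle(segments, 0, 9.0)
        ranked = rank_models([cfg, cfg], scored_subset(observations),
                             energies=[5.0, 3.0])
        assert ranked[0][1].energy_score == 3.0

    def test_matches_brute_force_argmax(self, segments, observations, rng):
        obs = scored_subset(observations)
        models = [initialize_bundle(segments, int(s), 9.0) for s in range(10)]
        energies = rng.uniform(-100, 100, 10)
        ranked = rank_models(models, obs, energies=energies)
        scores = [(match_crosslinks(m, obs).n_matched, -e)
                  for m, e in zip(models, energies)]
        best = max(range(10), key=lambda i: scores[i])
        assert ranked[0][0] is models[best]

    def test_ranking_table_shape(self, segments, observations):
        models = [initialize_bundle(segments, s, 9.0) for s in range(3)]
        ranked = rank_models(models, scored_subset(observations),
                             energies=[1.0, 2.0, 3.0])
        df = ranking_table(ranked)
        assert list(df.columns) == ["rank", "energy_score", "n_matched",
                                    "n_total", "violated_residues"]
        assert len(df) == 3

    def test_no_models_rejected(self, observations):
        with pytest.raises(ValueError):
            rank_models([], scored_subset(observations))


class TestInterfaceResidues:
    def test_distant_partner_empty(self, segments):
        cfg = initialize_bundle(segments, 0, 9.0)
        partner = single_site_helix("TPN", "K", [500.0, 0, 0],
                                    chain_id="B", residue=428)
        complex_cfg = BundleConfiguration(helices=cfg.helices + (partner,),
                                          frame=cfg.frame)
        iface = interface_residues(complex_cfg, "TPN")
        assert all(len(v) == 0 for v in iface.values())

    def test_matches_brute_force_thresholding(self, segments):
        cfg = initialize_bundle(segments, 0, 9.0)
        partner = build_ideal_helix(HelixSegment("TPN", "B", 417, 433,
                                                 "FLLLFGAVGLLKVLLWA"))
        partner = partner.with_pose(np.eye(3), [14.0, 0.0, 0.0])
        complex_cfg = BundleConfiguration(helices=cfg.helices + (partner,),
                                          frame=cfg.frame)
        cutoff = 8.0
        iface = interface_residues(complex_cfg, "TPN", contact_cutoff=cutoff)
        p_sites = np.vstack([partner.ca_global(), partner.sc_global()])
        for h in cfg.helices:
            expected = []
            for i, resnum in enumerate(h.segment.residue_numbers):
                sites = [h.ca_global()[i]]
                for j, ridx in enumerate(h.sc_res_index):
                    if ridx == i:
                        sites.append(h.sc_global()[j])
                dmin = cdist(np.array(sites), p_sites).min()
                if dmin < cutoff:
                    expected.append(int(resnum))
            assert iface[h.segment.helix_id] == expected

    def test_unknown_partner_rejected(self, segments):
        cfg = initialize_bundle(segments, 0, 9.0)
        with pytest.raises(KeyError):
            interface_residues(cfg, "NOPE")


class TestObservationTable:
    def test_packaged_table_structure(self, observations):
        assert len(observations) == 16
        assert sum(o.dimer_formed for o in observations) == 12
        assert sum(bool(o.blocked_by_tapasin) for o in observations) == 7
        no_dimer = sorted(o.residue for o in observations if not o.dimer_formed)
        assert no_dimer == [31, 32, 108, 149]
        blocked = sorted(o.residue for o in observations if o.blocked_by_tapasin)
        assert blocked == [33, 34, 67, 68, 69, 70, 107]

    def test_scored_subset_drops_prolines(self, observations):
        scored = scored_subset(observations)
        assert len(scored) == 14
        assert {108, 149}.isdisjoint({o.residue for o in scored})

    def test_model_score_invariant(self):
        with pytest.raises(ValueError):
            ModelScore(n_matched=5, n_total=3)


class TestBlockingConsistency:
    def test_blocked_residue_must_touch_partner(self):
        bundle_helix = build_ideal_helix(HelixSegment("TM1", "A", 1, 10, "L" * 10))
        partner = single_site_helix("TPN", "K", [6.0, 0, 0], chain_id="B",
                                    residue=428)
        cfg = toy_config(bundle_helix, partner)
        obs = [CrosslinkObservation(residue=5, dimer_formed=True,
                                    blocked_by_tapasin=True),
               CrosslinkObservation(residue=6, dimer_formed=True,
                                    blocked_by_tapasin=None)]
        matched, violated = blocking_consistency(cfg, "TPN", obs,
                                                 contact_cutoff=8.0)
        assert matched == [5] and violated == []
        far = [CrosslinkObservation(residue=5, dimer_formed=True,
                                    blocked_by_tapasin=False)]
        matched, violated = blocking_consistency(cfg, "TPN", far,
                                                 contact_cutoff=8.0)
        assert matched == [] and violated == [5]
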