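import numpy as np
import pytest

from tmbundle.core import HelixSegment, build_ideal_helix, initialize_bundle
from tmbundle.energy import MembraneRestraintParams
from tmbundle.remc import (Ensemble, MCSettings, ReplicaSchedule, exchange_sweep,
                           metropolis_accept, propose_move, run_remc)

from conftest import toy_config


class TestReplicaSchedule:
    def test_protocol_defaults(self):
        # published protocol: 20 replicas between 100 and 300 K
        s = ReplicaSchedule.geometric()
        assert len(s) == 20
        assert s.temperatures[0] == pytest.approx(100.0)
        assert s.temperatures[-1] == pytest.approx(300.0)
        assert np.all(np.diff(s.temperatures) > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ReplicaSchedule(np.array([300.0, 100.0]))
        with pytest.raises(ValueError):
            ReplicaSchedule(np.array([-1.0, 100.0]))
        with pytest.raises(ValueError):
            ReplicaSchedule(np.array([]))


class TestMCSettings:
    def test_protocol_saved_count(self):
        # 1e6 steps saving every 100 keeps 1e4 configurations
        s = MCSettings()
        assert s.n_steps // s.save_interval == 10_000

    def test_validation(self):
        with pytest.raises(ValueError):
            MCSettings(n_steps=0)
        with pytest.raises(ValueError):
            MCSettings(save_interval=0)
        with pytest.raises(ValueError):
            MCSettings(max_translation=-1.0)


class TestMetropolis:
    def test_nonpositive_delta_always_accepted(self, rng):
        for delta in (0.0, -1.0, -1e9, -np.inf):
            assert metropolis_accept(delta, 100.0, rng)

    def test_acceptance_frequency_at_delta_equal_t(self, rng):
        n = 20_000
        acc = sum(metropolis_accept(100.0, 100.0, rng) for _ in range(n))
        assert acc / n == pytest.approx(np.exp(-1.0), abs=0.02)

    def test_high_temperature_limit(self, rng):
        n = 2000
        acc = sum(metropolis_accept(1.0, 1e9, rng) for _ in range(n))
        assert acc / n > 0.999

    def test_infinite_delta_rejected(self, rng):
        assert not metropolis_accept(np.inf, 100.0, rng)

    def test_bad_temperature(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestProposeMove:
    @pytest.fixture()
    def config(self, segments):
        return initialize_bundle(segments, 0, 10.0)

    def test_zero_amplitude_is_noop(self, config, rng):
        settings = MCSettings(max_translation=0.0, max_rotation=0.0)
        new, _ = propose_move(config, rng, settings)
        for a, b in zip(config.helices, new.helices):
            np.testing.assert_allclose(a.ca_global(), b.ca_global(), atol=1e-12)

    def test_exactly_one_helix_moves(self, config, rng):
        new, moved_id = propose_move(config, rng, MCSettings())
        changed = [a.segment.helix_id for a, b in zip(config.helices, new.helices)
                   if not np.array_equal(a.translation, b.translation)
                   or not np.array_equal(a.rotation, b.rotation)]
        assert changed == [moved_id]

    def test_selection_frequencies_uniform(self, config, rng):
        # binomial bound computed independently: p=1/4, n=1e4 ->
        # sd(freq) = sqrt(p(1-p)/n) ~ 0.0043, so +-0.02 is ~4.6 sigma
        counts = {}
        settings = MCSettings()
        for _ in range(10_000):
            _, moved = propose_move(config, rng, settings)
            counts[moved] = counts.get(moved, 0) + 1
        for helix_id, c in counts.items():
            assert c / 10_000 == pytest.approx(0.25, abs=0.02)

    def test_moved_helix_stays_rigid(self, config, rng):
        from scipy.spatial.distance import pdist
        new, moved_id = propose_move(config, rng, MCSettings())
        a = config.helix(moved_id).ca_global()
        b = new.helix(moved_id).ca_global()
        np.testing.assert_allclose(pdist(a), pdist(b), atol=1e-9)

    def test_mobile_subset_respected(self, config, rng):
        for _ in range(50):
            _, moved = propose_move(config, rng, MCSettings(), mobile=[2])
            assert moved == config.helices[2].segment.helix_id

    def test_empty_config_rejected(self, rng):
        from tmbundle.core import BundleConfiguration
        with pytest.raises(ValueError):
            propose_move(BundleConfiguration(helices=()), rng, MCSettings())


class TestExchangeSweep:
    def test_equal_energies_always_swap(self, rng):
        sched = ReplicaSchedule(np.array([100.0, 200.0]))
        states = [("a", 5.0), ("b", 5.0)]
        new, accepted = exchange_sweep(states, sched, rng)
        assert accepted == [0]
        assert [s[0] for s in new] == ["b", "a"]

    def test_favorable_swap_always_accepted(self, rng):
        # hot replica holds the lower energy -> log p > 0
        sched = ReplicaSchedule(np.array([100.0, 200.0]))
        states = [("cold", 100.0), ("hot", -100.0)]
        new, accepted = exchange_sweep(states, sched, rng)
        assert accepted == [0]

    def test_equal_temperatures_always_swap(self, rng):
        sched = ReplicaSchedule(np.array([100.0, 100.0]))
        states = [("a", -50.0), ("b", 70.0)]
        for _ in range(10):
            states, accepted = exchange_sweep(states, sched, rng)
            assert accepted == [0]

    def test_parity_alternation(self, rng):
        sched = ReplicaSchedule(np.array([100.0, 150.0, 200.0, 300.0]))
        states = [(i, 0.0) for i in range(4)]
        _, acc0 = exchange_sweep(states, sched, rng, parity=0)
        _, acc1 = exchange_sweep(states, sched, rng, parity=1)
        assert acc0 == [0, 2] and acc1 == [1]

    def test_mismatched_counts_rejected(self, rng):
        sched = ReplicaSchedule(np.array([100.0, 200.0]))
        with pytest.raises(ValueError):
            exchange_sweep([("a", 1.0)], sched, rng)


class TestRunRemc:
    def test_saved_count_and_determinism(self, segments, table, membrane_params):
        settings = MCSettings(n_steps=500, save_interval=10, rng_seed=3)
        sched = ReplicaSchedule.geometric(4)
        a = run_remc(segments, table, membrane_params, sched, settings)
        b = run_remc(segments, table, membrane_params, sched, settings)
        assert len(a) == 500 // 10
        np.testing.assert_array_equal(a.energies, b.energies)
        for ca, cb in zip(a.configurations[-1].helices, b.configurations[-1].helices):
            np.testing.assert_array_equal(ca.translation, cb.translation)

    def test_saved_temperature_is_lowest_slot(self, segments, table, membrane_params):
        sched = ReplicaSchedule.geometric(4)
        ens = run_remc(segments, table, membrane_params, sched,
                       MCSettings(n_steps=100, save_interval=50, rng_seed=0))
        assert ens.temperature == pytest.approx(sched.temperatures[0])

    def test_overlapping_initial_state_aborts(self, table, membrane_params):
        a = HelixSegment("A", "A", 1, 5, "LLLLL")
        b = HelixSegment("B", "A", 10, 14, "LLLLL")
        ha, hb = build_ideal_helix(a), build_ideal_helix(b)
        cfg = toy_config(ha, hb)  # identical poses -> exact overlap
        with pytest.raises(RuntimeError, match="infinite energy"):
            run_remc([a, b], table, membrane_params,
                     ReplicaSchedule(np.array([100.0])),
                     MCSettings(n_steps=10, save_interval=10), initial=cfg)

    def test_single_helix_equipartition(self, table):
        # harmonic closed forms: <z^2> = T / (2 k_z); tilt has two
        # transverse degrees of freedom, so <tilt^2> = T / k_tilt
        params = MembraneRestraintParams(k_tilt=2000.0, k_z=10.0)
        seg = HelixSegment("H", "A", 1, 15, "L" * 15)
        t_run = 150.0
        ens = run_remc([seg], table, params, ReplicaSchedule(np.array([t_run])),
                       MCSettings(n_steps=60_000, save_interval=10, rng_seed=7,
                                  max_translation=1.0, max_rotation=0.2))
        zs = np.array([c.helices[0].center()[2] for c in ens.configurations])
        tilts = np.array([np.arccos(min(1.0, abs(c.helices[0].axis()[2])))
                          for c in ens.configurations])
        burn = len(zs) // 5
        assert np.mean(zs[burn:] ** 2) == pytest.approx(t_run / (2 * 10.0), rel=0.2)
        assert np.mean(tilts[burn:] ** 2) == pytest.approx(t_run / 2000.0, rel=0.2)

    def test_acceptance_and_exchange_rates_logged(self, segments, table,
                                                  membrane_params):
        ens = run_remc(segments, table, membrane_params,
                       ReplicaSchedule.geometric(4),
                       MCSettings(n_steps=2000, save_interval=100,
                                  exchange_interval=20, rng_seed=2))
        prov = ens.provenance
        assert len(prov["acceptance_rate_per_temperature"]) == 4
        # schedule sanity: exchange acceptance strictly positive in equilibrium
        assert all(r > 0 for r in prov["exchange_rate_per_pair"])

    def test_burn_in_energy_descends_on_average(self, segments, table,
                                                membrane_params):
        ens = run_remc(segments, table, membrane_params,
                       ReplicaSchedule.geometric(4),
                       MCSettings(n_steps=20_000, save_interval=100, rng_seed=11))
        e = ens.energies
        assert np.mean(e[-50:]) < np.mean(e[:10])


def test_two_well_detailed_balance(rng):
    # 1-D double well: E(x) = h for x in the shallow well, 0 in the deep
    # well; Metropolis hopping must reproduce the Boltzmann occupancy
    # ratio exp(-h/T) within 3 standard errors
    h = 30.0
    for t in (50.0, 100.0):
        state = 0
        occ = np.zeros(2)
        n = 40_000
        for _ in range(n):
            target = 1 - state
            delta = h if target == 1 else -h
            if metropolis_accept(delta, t, rng):
                state = target
            occ[state] += 1
        ratio = occ[1] / occ[0]
        expected = np.exp(-h / t)
        # SE of the ratio estimated from effective samples
        se = expected / np.sqrt(occ[1])
        assert abs(ratio - expected) < 3 * max(se, 0.01 * expected) + 0.01
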