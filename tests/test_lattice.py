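"""Unit tests for the disordered Ising simulator."""

import numpy as np
import pytest

from latticeews.lattice import (
    ForcingProtocol,
    LatticeDeletionError,
    LatticeSpec,
    NoTransitionError,
    _metropolis_kernel,
    critical_temperature,
    detect_transition_time,
    metropolis_update,
    net_magnetization,
    sample_lattice,
    simulate_run,
)

ONSAGER_TC = 2.0 / np.log(1.0 + np.sqrt(2.0))


class TestCriticalTemperature:
    def test_onsager_closed_form(self):
        assert critical_temperature(1.0) == pytest.approx(ONSAGER_TC, abs=1e-12)

    def test_linearity_in_coupling(self):
        assert critical_temperature(2.0) == pytest.approx(
            2 * critical_temperature(1.0), abs=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rejects_nonpositive_coupling(self, bad):
        with pytest.raises(ValueError):
            critical_temperature(bad)


class TestSampleLattice:
    def test_zero_sd_gives_uniform_bonds(self):
        spec = LatticeSpec(side_length=32, coupling_mean=1.3, coupling_sd=0.0,
                           n_deletion_ellipses=0, seed=1)
        couplings, mask = sample_lattice(spec)
        assert np.all(couplings == 1.3)
        assert mask.all()

    def test_bond_sample_mean_within_three_se(self):
        spec = LatticeSpec(side_length=128, coupling_mean=1.0, coupling_sd=0.1,
                           n_deletion_ellipses=0, seed=2)
        couplings, _ = sample_lattice(spec)
        n = couplings.size  # 2 * 128^2 bonds
        se = 0.1 / np.sqrt(n)
        assert abs(couplings.mean() - 1.0) < 3 * se

    def test_ellipses_delete_sites_and_reject_half_deleted(self):
        spec = LatticeSpec(side_length=32, n_deletion_ellipses=3,
                           deletion_axis_range=(3.0, 6.0), seed=3)
        _, mask = sample_lattice(spec)
        assert 0 < (~mask).sum() < mask.size / 2
        huge = LatticeSpec(side_length=32, n_deletion_ellipses=8,
                           deletion_axis_range=(15.0, 20.0), seed=3)
        with pytest.raises(LatticeDeletionError):
            sample_lattice(huge)

    def test_reproducible_from_seed(self):
        spec = LatticeSpec(side_length=48, n_deletion_ellipses=2, seed=11)
        c1, m1 = sample_lattice(spec)
        c2, m2 = sample_lattice(spec)
        assert np.array_equal(c1, c2) and np.array_equal(m1, m2)


class TestMetropolis:
    @staticmethod
    def _aligned(side=8):
        spins = np.ones((side, side), dtype=np.int8)
        couplings = np.ones((2, side, side))
        return spins, couplings

    def test_negative_energy_flip_always_accepted(self):
        # a lone opposed spin relaxes back regardless of the uniform draw
        spins, couplings = self._aligned()
        spins[4, 4] = -1
        _metropolis_kernel(
            spins, couplings[0], couplings[1],
            np.array([4]), np.array([4]), np.array([0.999999]), 2.0, 0.0,
        )
        assert spins[4, 4] == 1

    def test_boltzmann_acceptance_threshold(self):
        # flipping inside the aligned phase costs dE = 8J; at T = 2 the
        # acceptance probability is exp(-4)
        p_accept = np.exp(-4.0)
        for u, flipped in [(p_accept - 1e-6, True), (p_accept + 1e-6, False)]:
            spins, couplings = self._aligned()
            _metropolis_kernel(
                spins, couplings[0], couplings[1],
                np.array([4]), np.array([4]), np.array([u]), 2.0, 0.0,
            )
            assert (spins[4, 4] == -1) == flipped

    def test_domain_errors(self):
        spins, couplings = self._aligned()
        li, lj = np.nonzero(np.ones((8, 8), dtype=bool))
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            metropolis_update(spins, couplings, li, lj, rng, -1.0, 0.0, 10)
        with pytest.raises(ValueError):
            metropolis_update(spins, couplings, li, lj, rng, 2.0, 0.0, 0)

    def test_global_flip_symmetry_at_zero_field(self):
        # with h = 0 the dynamics are invariant under global spin reversal:
        # mirrored initial states driven by the same randomness stay mirrored
        side = 16
        couplings = np.ones((2, side, side))
        mask = np.ones((side, side), dtype=bool)
        li, lj = (a.astype(np.int64) for a in np.nonzero(mask))
        rng_a = np.random.default_rng(42)
        rng_b = np.random.default_rng(42)
        spins_a = np.random.default_rng(1).choice(
            np.array([-1, 1], dtype=np.int8), size=(side, side)
        )
        spins_b = (-spins_a).copy()
        for _ in range(20):
            metropolis_update(spins_a, couplings, li, lj, rng_a, 2.5, 0.0, 500)
            metropolis_update(spins_b, couplings, li, lj, rng_b, 2.5, 0.0, 500)
        assert np.array_equal(spins_a, -spins_b)


class TestNetMagnetization:
    def test_examples(self):
        mask = np.ones((4, 4), dtype=bool)
        assert net_magnetization(np.ones((4, 4)), mask) == 1.0
        half = np.ones((4, 4)); half[:2] = -1
        assert net_magnetization(half, mask) == 0.0

    def test_masking_semantics(self):
        frame = np.where((np.indices((4, 4)).sum(0) % 2).astype(bool), -1, 1)
        mask = frame == 1  # delete every -1 site
        assert net_magnetization(frame, mask) == 1.0
        with pytest.raises(ValueError):
            net_magnetization(frame, np.zeros((4, 4), dtype=bool))


class TestDetectTransitionTime:
    def test_tanh_inflection(self):
        t = np.arange(600)
        m = np.tanh((t - 300) / 20)
        assert detect_transition_time(m) == 300

    def test_step_function(self):
        m = np.where(np.arange(200) < 140, -0.9, 0.9)
        assert detect_transition_time(m) == 140

    def test_constant_raises(self):
        with pytest.raises(NoTransitionError):
            detect_transition_time(np.full(50, 0.3))

    def test_linear_series_returns_valid_index(self):
        idx = detect_transition_time(np.linspace(0, 1, 100))
        assert 0 < idx < 100

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detect_transition_time(np.array([0.0, 1.0]))


class TestSimulateRun:
    SPEC = LatticeSpec(side_length=24, coupling_sd=0.0, n_deletion_ellipses=0, seed=5)

    def test_snapshot_count_and_determinism(self):
        prot = ForcingProtocol(order="second", control="T", start_value=3.5,
                               end_value=3.0, n_steps=40, run_class="null")
        run1 = simulate_run(self.SPEC, prot, flips_per_snapshot=500,
                            burn_in_intervals=5, seed=9)
        run2 = simulate_run(self.SPEC, prot, flips_per_snapshot=500,
                            burn_in_intervals=5, seed=9)
        assert run1.n_steps == 40
        assert np.array_equal(run1.spins, run2.spins)
        assert run1.forcing.shape == (40,)

    def test_disordered_null_run_stays_unmagnetized(self):
        t_c = critical_temperature(1.0)
        prot = ForcingProtocol(order="second", control="T", start_value=2 * t_c,
                               end_value=2 * t_c, n_steps=60, run_class="null")
        run = simulate_run(self.SPEC, prot, flips_per_snapshot=2000,
                           burn_in_intervals=20, seed=4)
        assert np.abs(run.magnetization_series()).max() < 0.35
        assert run.transition_index is None

    def test_second_order_ramp_orders_the_lattice(self):
        # slow quench through T_c on a small lattice ends ordered
        t_c = critical_temperature(1.0)
        prot = ForcingProtocol(order="second", control="T",
                               start_value=1.5 * t_c, end_value=0.5 * t_c,
                               n_steps=300, run_class="transition")
        run = simulate_run(self.SPEC, prot, flips_per_snapshot=3000,
                           burn_in_intervals=20, seed=8)
        m = run.magnetization_series()
        assert abs(m[-1]) > 0.8
        assert run.transition_index == int(np.argmax(run.forcing < t_c))

    def test_masked_sites_never_flip(self):
        spec = LatticeSpec(side_length=24, n_deletion_ellipses=2,
                           deletion_axis_range=(3.0, 5.0), seed=13)
        prot = ForcingProtocol(order="second", control="T", start_value=3.0,
                               end_value=2.8, n_steps=20, run_class="null")
        run = simulate_run(spec, prot, flips_per_snapshot=500,
                           burn_in_intervals=2, seed=13)
        assert (run.spins[:, ~run.mask] == 0).all()
        assert (np.abs(run.spins[:, run.mask]) == 1).all()
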