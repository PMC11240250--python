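import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from phipchip import (
    RelaxationParams,
    SequenceParams,
    SpinSystem,
    UnsupportedSystemError,
    evolve,
    optimize_sequence,
    pulse,
    s2hm,
    singlet_state,
    st_mixing,
    transfer_efficiency,
)
from phipchip.spin import (
    hamiltonian,
    singlet_projector,
    spin_operators,
    triplet0_projector,
    unitary_transfer_bound,
)


def proton_pair(j_hz=10.0):
    return SpinSystem(("1H", "1H"), (0.0, 0.0), ((0.0, j_hz), (j_hz, 0.0)))


class TestSingletState:
    def test_unit_trace_and_scalar_order(self, fumarate):
        rho = singlet_state(fumarate)
        assert np.trace(rho.matrix) == pytest.approx(1.0, abs=1e-12)
        ix, iy, iz = spin_operators(fumarate)
        dot = ix[0] @ ix[1] + iy[0] @ iy[1] + iz[0] @ iz[1]
        assert rho.expectation(dot) == pytest.approx(-0.75, abs=1e-12)

    def test_requires_proton_pair(self, fumarate):
        with pytest.raises(TypeError):
            singlet_state(fumarate, pair=(0, 2))

    @settings(max_examples=25, derandomize=True)
    @given(angle=st.floats(0.0, 2 * np.pi), phase=st.floats(0.0, 2 * np.pi))
    def test_invariant_under_nonselective_hard_pulses(self, angle, phase):
        system = proton_pair()
        rho = singlet_state(system)
        proj = singlet_projector(system)
        after = pulse(rho, system, "1H", angle, phase)
        assert after.expectation(proj) == pytest.approx(rho.expectation(proj), abs=1e-12)


class TestEvolve:
    def test_zero_duration_is_identity(self, fumarate):
        rho = singlet_state(fumarate)
        assert np.allclose(evolve(rho, fumarate, 0.0).matrix, rho.matrix)

    def test_preserves_trace_hermiticity_spectrum(self, fumarate):
        rho = singlet_state(fumarate)
        rho = pulse(rho, fumarate, "1H", 0.7, 0.3)  # something non-trivial
        out = evolve(rho, fumarate, 0.0371)
        assert abs(np.trace(out.matrix) - 1.0) < 1e-12
        assert np.max(np.abs(out.matrix - out.matrix.conj().T)) < 1e-12
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(out.matrix)),
            np.sort(np.linalg.eigvalsh(rho.matrix)),
            atol=1e-12,
        )

    @settings(max_examples=20, derandomize=True)
    @given(j=st.floats(-50.0, 50.0), t=st.floats(0.0, 0.2))
    def test_equivalent_pair_singlet_is_stationary(self, j, t):
        system = proton_pair(j)
        rho = singlet_state(system)
        proj = singlet_projector(system)
        out = evolve(rho, system, t)
        assert out.expectation(proj) == pytest.approx(1.0, abs=1e-10)


class TestPulse:
    def test_zero_and_full_rotations_are_identity_on_observables(self, fumarate):
        rho = singlet_state(fumarate)
        rho = st_mixing(rho, fumarate, 30.0, 0.004)  # put some T0 in
        for angle in (0.0, 2 * np.pi):
            out = pulse(rho, fumarate, "1H", angle)
            assert np.allclose(out.matrix, rho.matrix, atol=1e-12)

    def test_purge_moves_t0_to_outer_triplets_keeping_singlet(self, fumarate):
        rho = singlet_state(fumarate)
        mixed = st_mixing(rho, fumarate, 40.0, 1.0 / (4 * 40.0))  # partial S0->T0
        ps, pt0 = singlet_projector(fumarate), triplet0_projector(fumarate)
        s_before, t0_before = mixed.expectation(ps), mixed.expectation(pt0)
        assert t0_before > 0.1  # the mixing really populated T0
        out = pulse(mixed, fumarate, "1H", np.pi / 2)
        assert out.expectation(ps) == pytest.approx(s_before, abs=1e-10)
        assert out.expectation(pt0) < t0_before  # redistributed into T+-

    def test_unknown_channel_rejected(self, fumarate):
        with pytest.raises(UnsupportedSystemError):
            pulse(singlet_state(fumarate), fumarate, "15N", np.pi)


class TestSTMixing:
    def test_zero_shift_difference_is_identity(self, fumarate):
        rho = singlet_state(fumarate)
        out = st_mixing(rho, fumarate, 0.0, 0.1)
        assert np.allclose(out.matrix, rho.matrix)

    def test_matches_two_level_rabi_formula(self):
        """For an isolated J=0 pair the S0 population is cos^2(pi delta t)."""
        system = proton_pair(j_hz=0.0)
        rho = singlet_state(system)
        proj_s = singlet_projector(system)
        delta = 25.0
        for t in np.linspace(0.0, 2.0 / delta, 17):
            out = st_mixing(rho, system, delta, t)
            assert out.expectation(proj_s) == pytest.approx(
                np.cos(np.pi * delta * t) ** 2, abs=1e-10
            )

    def test_complete_transfer_at_half_period(self):
        system = proton_pair(j_hz=0.0)
        out = st_mixing(singlet_state(system), system, 20.0, 1.0 / (2 * 20.0))
        assert out.expectation(triplet0_projector(system)) == pytest.approx(1.0, abs=1e-10)

    def test_outer_triplets_untouched(self, fumarate):
        ix, iy, iz = spin_operators(fumarate)
        # T+ population state on the pair
        dim = fumarate.dim
        up = np.zeros((2, 2), complex); up[0, 0] = 1.0
        rho_t_plus = np.kron(np.kron(up, up), np.eye(2) / 2)
        from phipchip.spin import DensityState

        rho = DensityState(rho_t_plus)
        out = st_mixing(rho, fumarate, 35.0, 0.123)
        assert np.allclose(out.matrix, rho.matrix, atol=1e-12)


class TestS2hM:
    def test_no_heteronuclear_coupling_means_no_transfer(self):
        system = SpinSystem(
            ("1H", "1H", "13C"), (0.0, 0.0, 0.0),
            ((0.0, 15.9, 0.0), (15.9, 0.0, 0.0), (0.0, 0.0, 0.0)),
        )
        eff = transfer_efficiency(system, SequenceParams(15.7e-3, 7, 7))
        assert eff == pytest.approx(0.0, abs=1e-10)

    def test_identity_state_yields_no_carbon_magnetization(self, fumarate):
        from phipchip.spin import DensityState

        rho = DensityState(np.eye(fumarate.dim) / fumarate.dim)
        out = s2hm(rho, fumarate, SequenceParams(15.7e-3, 7, 7))
        _, _, iz = spin_operators(fumarate)
        assert out.expectation(iz[2]) == pytest.approx(0.0, abs=1e-12)

    def test_unsupported_topology_rejected(self):
        system = proton_pair()
        with pytest.raises(UnsupportedSystemError):
            s2hm(singlet_state(system), system, SequenceParams(1e-2))

    def test_printed_parameters_sit_at_the_tau_grid_maximum(self, fumarate):
        """tau = 15.7 ms with n1 = n2 = 7 is within 2% of the best efficiency
        over the coarse tau grid."""
        taus = np.arange(5e-3, 30.0001e-3, 0.5e-3)
        effs = [transfer_efficiency(fumarate, SequenceParams(t, 7, 7)) for t in taus]
        eff_printed = transfer_efficiency(fumarate, SequenceParams(15.7e-3, 7, 7))
        assert eff_printed >= max(effs) * 0.98

    def test_agrees_with_independent_propagator(self, fumarate):
        """Efficiency from time-sliced scipy expm propagation equals the exact
        eigendecomposition result."""
        params = SequenceParams(15.7e-3, 2, 2)
        eff = transfer_efficiency(fumarate, params)

        h = hamiltonian(fumarate)
        ix, iy, iz = spin_operators(fumarate)
        slices = 200
        u_tau = np.linalg.matrix_power(expm(-1j * h * params.tau_s / slices), slices)
        u_pi = expm(-1j * np.pi * ix[2])
        u_purge = expm(-1j * (np.pi / 2) * (ix[0] + ix[1]))
        u_mid = expm(-1j * (np.pi / 2) * ix[2])
        u_fin = expm(-1j * (np.pi / 2) * iy[2])
        echo = u_tau @ u_pi @ u_tau
        u = u_purge
        for _ in range(params.n1):
            u = echo @ u
        u = u_mid @ u_tau @ u
        for _ in range(params.n2):
            u = echo @ u
        u = u_fin @ u
        rho = singlet_state(fumarate).matrix
        eff_oracle = 2 * np.real(np.trace(u @ rho @ u.conj().T @ iz[2]))
        assert eff == pytest.approx(eff_oracle, abs=1e-6)

    def test_purge_rescues_signal_from_t0_contamination(self, fumarate):
        """With S-T mixing having leaked population into |T0>, the purge pulse
        prevents the opposite-phase cancellation of the carbon signal."""
        rho = singlet_state(fumarate)
        contaminated = st_mixing(rho, fumarate, 40.0, 1.0 / (4 * 40.0))
        _, _, iz = spin_operators(fumarate)
        seq = dict(tau_s=15.7e-3, n1=7, n2=7)
        with_purge = s2hm(contaminated, fumarate, SequenceParams(**seq, purge=True))
        without = s2hm(contaminated, fumarate, SequenceParams(**seq, purge=False))
        assert with_purge.expectation(iz[2]) > without.expectation(iz[2])

    def test_sequence_preserves_trace_and_hermiticity(self, fumarate):
        out = s2hm(singlet_state(fumarate), fumarate, SequenceParams(12e-3, 3, 3))
        assert abs(np.trace(out.matrix) - 1.0) < 1e-12
        assert np.max(np.abs(out.matrix - out.matrix.conj().T)) < 1e-12


class TestTransferEfficiency:
    def test_bounded_by_unitary_limit(self, fumarate):
        bound = unitary_transfer_bound(fumarate)
        assert bound <= 1.0 + 1e-12
        for tau in (5e-3, 15.7e-3, 25e-3):
            eff = transfer_efficiency(fumarate, SequenceParams(tau, 7, 7))
            assert eff <= bound + 1e-9

    def test_vanishes_when_singlet_lifetime_collapses(self, fumarate):
        relax = RelaxationParams(t_singlet_s=1e-6, t1_carbon_s=30.0)
        eff = transfer_efficiency(fumarate, SequenceParams(15.7e-3, 7, 7), relax)
        assert abs(eff) < 1e-6

    def test_relaxation_only_attenuates(self, fumarate):
        params = SequenceParams(15.7e-3, 7, 7)
        ideal = transfer_efficiency(fumarate, params)
        relaxed = transfer_efficiency(
            fumarate, params, RelaxationParams(t_singlet_s=5.0, t1_carbon_s=5.0)
        )
        assert 0.0 < relaxed < ideal


class TestOptimizer:
    def test_singleton_grid_returns_that_point(self, fumarate):
        best, records = optimize_sequence(fumarate, [12e-3], [(3, 3)])
        assert best.tau_s == 12e-3 and (best.n1, best.n2) == (3, 3)
        assert len(records) == 1

    def test_map_symmetric_under_proton_relabelling(self):
        """Swapping the two carbon couplings (relabelling the protons) leaves
        the efficiency map unchanged."""
        a = SpinSystem(("1H", "1H", "13C"), (0.0,) * 3,
                       ((0.0, 15.9, 3.2), (15.9, 0.0, 6.8), (3.2, 6.8, 0.0)))
        b = SpinSystem(("1H", "1H", "13C"), (0.0,) * 3,
                       ((0.0, 15.9, 6.8), (15.9, 0.0, 3.2), (6.8, 3.2, 0.0)))
        taus = [10e-3, 15.7e-3, 20e-3]
        _, rec_a = optimize_sequence(a, taus, [(4, 4)])
        _, rec_b = optimize_sequence(b, taus, [(4, 4)])
        for ra, rb in zip(rec_a, rec_b):
            assert ra[3] == pytest.approx(rb[3], abs=1e-10)


def test_invalid_spin_system_definitions_rejected():
    with pytest.raises(ValueError):
        SpinSystem(("1H", "1H"), (0.0, 0.0), ((0.0, 5.0), (4.0, 0.0)))  # asymmetric
    with pytest.raises(UnsupportedSystemError):
        SpinSystem(("1H", "31P"), (0.0, 0.0), ((0.0, 5.0), (5.0, 0.0)))
    with pytest.raises(ValueError):
        SequenceParams(-1e-3)
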