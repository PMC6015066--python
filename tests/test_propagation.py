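import numpy as np
import pytest

from gnmflow import (
    InputError,
    IntegrationError,
    PerturbationSpec,
    build_kirchhoff,
    decompose,
    detect_excited,
    integrate_oracle,
    make_synthetic,
    project_perturbation,
    respond,
)
from gnmflow.propagation import default_time_grid
from conftest import random_structure


def chain3_node2_closed_form(t):
    # response of the far end of the 3-node chain to a unit displacement of
    # node 0, from the (0, 1, 3) eigensystem of the chain Laplacian
    return -0.5 * np.cos(t) + np.cos(np.sqrt(3) * t) / 6.0


class TestProjection:
    def test_two_node_amplitude(self, chain2):
        _, _, modes = chain2
        a, b = project_perturbation(modes, PerturbationSpec(0))
        assert a.shape == (1,)
        assert abs(a[0]) == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert b[0] == 0.0

    def test_null_perturbation(self, chain3):
        _, _, modes = chain3
        a, b = project_perturbation(
            modes, PerturbationSpec(1, displacement=0.0, initial_velocity=0.0))
        assert not a.any() and not b.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_amplitude_norm_identity(self, seed):
        # unit displacement minus its uniform-mode component has squared
        # norm 1 - 1/N
        structure = random_structure(seed)
        modes = decompose(build_kirchhoff(structure, 7.0))
        n = len(structure)
        a, _ = project_perturbation(modes, PerturbationSpec(seed % n))
        assert np.sum(a ** 2) == pytest.approx(1 - 1 / n, abs=1e-10)

    def test_out_of_range_residue(self, chain3):
        _, _, modes = chain3
        with pytest.raises(InputError):
            project_perturbation(modes, PerturbationSpec(3))


class TestRespond:
    def test_two_node_closed_form(self, chain2):
        _, _, modes = chain2
        t = np.linspace(0, 10, 101)
        traj = respond(modes, PerturbationSpec(0), t)
        expected = 0.5 * np.cos(np.sqrt(2) * t)
        assert np.allclose(traj.response[:, 0], expected, atol=1e-12)
        assert np.allclose(traj.response[:, 1], -expected, atol=1e-12)

    def test_chain3_far_node_closed_form(self, chain3):
        _, _, modes = chain3
        t = np.linspace(0, 15, 301)
        traj = respond(modes, PerturbationSpec(0), t)
        assert np.allclose(traj.response[:, 2], chain3_node2_closed_form(t),
                           atol=1e-12)
        assert traj.response[0, 2] == pytest.approx(-1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_initial_condition_projection_identity(self, seed):
        structure = random_structure(seed)
        modes = decompose(build_kirchhoff(structure, 7.0))
        n = len(structure)
        m = (seed * 7) % n
        traj = respond(modes, PerturbationSpec(m), np.array([0.0]))
        expected = -np.ones(n) / n
        expected[m] += 1.0
        assert np.allclose(traj.response[0], expected, atol=1e-10)

    @pytest.mark.parametrize("velocity", [0.0, 0.8])
    def test_parseval_bound(self, velocity):
        structure = random_structure(42, n=20)
        modes = decompose(build_kirchhoff(structure, 7.0))
        spec = PerturbationSpec(3, initial_velocity=velocity)
        traj = respond(modes, spec, np.linspace(0, 30, 2000))
        budget = np.sum(traj.modal_amplitudes ** 2
                        + traj.modal_velocity_amplitudes ** 2)
        assert np.all((traj.response ** 2).sum(axis=1) <= budget + 1e-9)

    def test_time_reversal_symmetry_zero_velocity(self, chain3):
        # pure cosine solution: dR(t) = dR(-t)
        _, _, modes = chain3
        t = np.linspace(0, 10, 50)
        fwd = respond(modes, PerturbationSpec(0), t)
        bwd = respond(modes, PerturbationSpec(0), -t[::-1])
        assert np.allclose(fwd.response, bwd.response[::-1], atol=1e-12)

    def test_velocity_term_reduces_to_cosine_solution(self, chain3):
        # with zero initial velocity, the general (cos + sin) solution must
        # collapse exactly to the pure cosine mode sum
        _, _, modes = chain3
        t = np.linspace(0, 10, 200)
        traj = respond(modes, PerturbationSpec(0, initial_velocity=0.0), t)
        u = modes.nonzero_eigenvectors
        pure_cosine = (u[0, :] * np.cos(np.outer(t, modes.omegas))) @ u.T
        assert np.array_equal(traj.response, pure_cosine)
        assert not traj.modal_velocity_amplitudes.any()

    def test_ring_rotation_symmetry(self):
        structure = make_synthetic("ring", 10, 5.0)
        modes = decompose(build_kirchhoff(structure, 7.0))
        t = np.linspace(0, 12, 121)
        r0 = respond(modes, PerturbationSpec(0), t).response
        r3 = respond(modes, PerturbationSpec(3), t).response
        assert np.allclose(np.roll(r0, 3, axis=1), r3, atol=1e-8)

    def test_empty_grid_errors(self, chain3):
        _, _, modes = chain3
        with pytest.raises(InputError):
            respond(modes, PerturbationSpec(0), np.array([]))


class TestDetectExcited:
    def test_low_threshold_excites_all_at_t0(self, chain3):
        # dR_i(0)^2 >= 1/9 for every node of the 3-chain
        _, _, modes = chain3
        traj = respond(modes, PerturbationSpec(0), default_time_grid(20, 0.001))
        table = detect_excited(traj, 0.01, "squared")
        assert table.n_excited == 3
        assert np.allclose(table.excitation_time, 0.0)

    def test_selective_threshold_and_first_crossing_time(self, chain3):
        _, _, modes = chain3
        grid = default_time_grid(20, 0.001)
        traj = respond(modes, PerturbationSpec(0), grid)
        table = detect_excited(traj, 0.2, "squared")
        assert list(table.excited) == [True, False, True]
        assert table.excitation_time[0] == 0.0
        assert table.peak_metric[1] == pytest.approx(1 / 9, abs=1e-6)
        # independent brute-force scan of the closed form at finer step
        fine = np.arange(0, 20, 1e-4)
        crossing = fine[chain3_node2_closed_form(fine) ** 2 >= 0.2][0]
        assert table.excitation_time[2] == pytest.approx(crossing, abs=1e-3)

    def test_threshold_above_peak_excites_nothing(self, chain3):
        _, _, modes = chain3
        traj = respond(modes, PerturbationSpec(0), np.linspace(0, 20, 2001))
        table = detect_excited(traj, 2.0, "amplitude")
        assert table.n_excited == 0
        assert np.all(np.isnan(table.excitation_time))

    def test_amplitude_and_squared_metrics_are_consistent(self, chain3):
        _, _, modes = chain3
        traj = respond(modes, PerturbationSpec(0), default_time_grid(10, 0.01))
        sq = detect_excited(traj, 0.04, "squared")
        amp = detect_excited(traj, 0.2, "amplitude")
        assert np.array_equal(sq.excited, amp.excited)
        assert np.allclose(sq.excitation_time, amp.excitation_time,
                           equal_nan=True)

    def test_dataframe_export_flags_source(self, chain3):
        structure, _, modes = chain3
        traj = respond(modes, PerturbationSpec(1), np.linspace(0, 5, 500))
        df = detect_excited(traj, 0.01, "squared").to_dataframe(structure)
        assert df.loc[1, "is_source"]
        assert list(df.columns[:4]) == ["serial", "chain", "residue_number",
                                        "residue_name"]


class TestIntegrateOracle:
    def test_two_node_agreement(self, chain2):
        _, kirchhoff, modes = chain2
        oracle = integrate_oracle(kirchhoff, PerturbationSpec(0),
                                  dt=1e-3, t_end=10.0)
        analytic = respond(modes, PerturbationSpec(0), oracle.time_grid)
        assert np.abs(oracle.response - analytic.response).max() < 1e-4

    @pytest.mark.parametrize("velocity", [0.0, 0.5])
    @pytest.mark.parametrize("seed", [1, 5])
    def test_random_network_agreement(self, seed, velocity):
        structure = random_structure(seed, lo=8, hi=25)
        kirchhoff = build_kirchhoff(structure, 7.0)
        modes = decompose(kirchhoff)
        spec = PerturbationSpec(2, initial_velocity=velocity)
        oracle = integrate_oracle(kirchhoff, spec, dt=2e-4, t_end=10.0)
        analytic = respond(modes, spec, oracle.time_grid)
        assert np.abs(oracle.response - analytic.response).max() < 1e-4

    def test_zero_perturbation_stays_zero(self, chain3):
        _, kirchhoff, _ = chain3
        spec = PerturbationSpec(0, displacement=0.0)
        oracle = integrate_oracle(kirchhoff, spec, dt=1e-3, t_end=5.0)
        assert not oracle.response.any()

    def test_energy_conservation(self, chain3):
        # symplectic integrator: no long-run drift; IntegrationError would
        # fire above 1% — here we just require a clean run over t_end = 50
        _, kirchhoff, _ = chain3
        integrate_oracle(kirchhoff, PerturbationSpec(0), dt=1e-3, t_end=50.0,
                         energy_tolerance=0.001)

    def test_coarse_step_warns(self, chain3):
        _, kirchhoff, _ = chain3
        with pytest.warns(UserWarning, match="omega_max"):
            integrate_oracle(kirchhoff, PerturbationSpec(0), dt=0.1,
                             t_end=1.0)
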