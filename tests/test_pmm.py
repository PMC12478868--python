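"""PMM core: Coulomb fields, Hamiltonian assembly, diagonalization, gaps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pmmredox as pr
from pmmredox.constants import COULOMB_EV_ANG

from conftest import make_geometry, make_qc


def frame_of(positions, charges, box=60.0, index=0, time_ps=0.0):
    return pr.EnvironmentFrame(positions=np.asarray(positions, dtype=float),
                               charges=np.asarray(charges, dtype=float),
                               box=np.full(3, float(box)),
                               time_ps=time_ps, index=index)


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

class TestComputeField:
    def test_unit_charge_at_one_angstrom(self, toy_geometry):
        r0 = np.array([30.0, 30.0, 30.0])
        geom = pr.Geometry(elements=toy_geometry.elements,
                           coords=toy_geometry.coords + r0)
        fr = frame_of([r0 + [1.0, 0.0, 0.0]], [1.0])
        field = pr.compute_field(fr, geom, r0, pbc_mode="none",
                                 clash_radius=0.0)
        assert field.potential == pytest.approx(COULOMB_EV_ANG)
        # field points away from the positive source, i.e. along -x
        assert field.field[0] == pytest.approx(-COULOMB_EV_ANG)
        np.testing.assert_allclose(field.field[1:], 0.0, atol=1e-12)

    def test_symmetric_dipole_pair(self, toy_geometry):
        r0 = np.array([30.0, 30.0, 30.0])
        geom = pr.Geometry(elements=toy_geometry.elements,
                           coords=toy_geometry.coords + r0)
        fr = frame_of([r0 + [3.0, 0, 0], r0 - [3.0, 0, 0]], [1.0, -1.0])
        field = pr.compute_field(fr, geom, r0, pbc_mode="none")
        assert field.potential == pytest.approx(0.0, abs=1e-12)
        assert abs(field.field[0]) > 0  # axis component survives
        np.testing.assert_allclose(field.field[1:], 0.0, atol=1e-12)

    def test_minimum_image_matches_nearest_image_oracle(self):
        """Brute force: fold each source to its nearest of 27 images."""
        rng = np.random.default_rng(13)
        box = 12.0
        r0 = np.array([1.0, 10.5, 6.0])  # near box faces
        geom = pr.Geometry(elements=("C", "N", "O"),
                           coords=r0 + rng.normal(0, 0.4, size=(3, 3)))
        positions = rng.uniform(0, box, size=(20, 3))
        charges = rng.normal(0, 0.5, size=20)
        fr = frame_of(positions, charges, box=box)
        field = pr.compute_field(fr, geom, r0, pbc_mode="minimum_image",
                                 clash_radius=0.4)

        shifts = box * np.array([(i, j, k) for i in (-1, 0, 1)
                                 for j in (-1, 0, 1) for k in (-1, 0, 1)])
        phi = 0.0
        evec = np.zeros(3)
        for p, q in zip(positions, charges):
            images = p + shifts
            d = r0 - images
            dist = np.linalg.norm(d, axis=1)
            near = np.argmin(dist)
            phi += COULOMB_EV_ANG * q / dist[near]
            evec += COULOMB_EV_ANG * q * d[near] / dist[near] ** 3
        assert field.potential == pytest.approx(phi, rel=1e-12)
        np.testing.assert_allclose(field.field, evec, rtol=1e-10)

    def test_clash_raises_naming_frame(self, toy_geometry):
        r0 = toy_geometry.geometric_center()
        fr = frame_of([r0 + [0.2, 0, 0]], [1.0], index=7)
        with pytest.raises(pr.ClashError, match="frame 7"):
            pr.compute_field(fr, toy_geometry, r0, pbc_mode="none")

    def test_per_atom_potentials_one_per_qc_atom(self, toy_geometry):
        r0 = np.array([30.0, 30.0, 30.0])
        geom = pr.Geometry(elements=toy_geometry.elements,
                           coords=toy_geometry.coords + r0)
        fr = frame_of([r0 + [5.0, 0, 0]], [1.0])
        field = pr.compute_field(fr, geom, r0, pbc_mode="none")
        assert field.atom_potentials.shape == (geom.n_atoms,)


# ---------------------------------------------------------------------------
# Hamiltonian assembly
# ---------------------------------------------------------------------------

def zero_field(n_qc_atoms, phi=0.0, evec=(0.0, 0.0, 0.0)):
    return pr.PerturbationField(potential=phi, field=np.asarray(evec),
                                atom_potentials=np.full(n_qc_atoms, phi))


class TestBuildHamiltonian:
    def test_zero_perturbation_is_diagonal(self, toy_species):
        qc = toy_species.oxidized
        for mode in ("dipole", "esp_diagonal"):
            h = pr.build_perturbed_hamiltonian(
                qc, zero_field(qc.geometry.n_atoms), mode=mode)
            np.testing.assert_allclose(h, np.diag(qc.energies), atol=1e-14)

    @pytest.mark.parametrize("mode", ["dipole", "esp_diagonal"])
    def test_uniform_potential_gauge_shift(self, toy_species, mode):
        """A constant potential adds exactly q_T * Phi in both modes,
        because every state's ESP charges sum to the total charge."""
        phi = 2.7
        for qc in (toy_species.oxidized, toy_species.reduced):
            h0 = pr.build_perturbed_hamiltonian(
                qc, zero_field(qc.geometry.n_atoms), mode=mode)
            h1 = pr.build_perturbed_hamiltonian(
                qc, zero_field(qc.geometry.n_atoms, phi=phi), mode=mode)
            np.testing.assert_allclose(
                h1 - h0, qc.total_charge * phi * np.eye(qc.n_states),
                atol=1e-12)

    def test_two_state_assembly_worked_example(self, toy_geometry):
        """eps = (0, 2) eV with coupling -E.mu01 = 0.5 eV gives
        [[0, 0.5], [0.5, 2]]."""
        states = (
            pr.ElectronicState(0, 0.0, np.zeros(3), np.zeros(4)),
            pr.ElectronicState(1, 2.0, np.zeros(3), np.zeros(4)),
        )
        qc = pr.QuantumCenter(
            name="twostate", redox="oxidized", total_charge=0.0,
            geometry=toy_geometry, states=states,
            transition_dipoles={(0, 1): np.array([-0.5, 0.0, 0.0])})
        field = pr.PerturbationField(potential=0.0,
                                     field=np.array([1.0, 0.0, 0.0]))
        h = pr.build_perturbed_hamiltonian(qc, field, mode="dipole")
        np.testing.assert_allclose(h, [[0.0, 0.5], [0.5, 2.0]], atol=1e-14)

    def test_esp_mode_requires_atom_potentials(self, toy_species):
        field = pr.PerturbationField(potential=0.0, field=np.zeros(3))
        with pytest.raises(pr.PmmRedoxError, match="per-atom"):
            pr.build_perturbed_hamiltonian(toy_species.oxidized, field,
                                           mode="esp_diagonal")


# ---------------------------------------------------------------------------
# diagonalization
# ---------------------------------------------------------------------------

def charpoly_roots(h: np.ndarray) -> np.ndarray:
    """Independent oracle: Faddeev-LeVerrier characteristic polynomial
    coefficients, then the companion-matrix root finder (np.roots uses the
    nonsymmetric eigensolver, a different code path from eigh)."""
    n = h.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    m = np.zeros_like(h)
    for k in range(1, n + 1):
        m = h @ m + coeffs[k - 1] * np.eye(n)
        coeffs[k] = -(h @ m).trace() / k
    roots = np.roots(coeffs)
    assert np.abs(roots.imag).max() < 1e-8
    return np.sort(roots.real)


class TestDiagonalize:
    def test_diagonal_input_identity(self):
        eps = np.array([-0.3, 1.1, 2.9])
        s = pr.diagonalize(np.diag(eps))
        np.testing.assert_allclose(s.eigenvalues, np.sort(eps), atol=1e-14)
        assert s.ground_energy == pytest.approx(-0.3)
        np.testing.assert_allclose(np.abs(s.ground_vector), [1, 0, 0],
                                   atol=1e-12)

    def test_two_state_closed_form(self):
        """[[0, 0.5], [0.5, 2]] has eigenvalues 1 -+ sqrt(1.25)."""
        s = pr.diagonalize(np.array([[0.0, 0.5], [0.5, 2.0]]))
        expected = np.array([1.0 - np.sqrt(1.25), 1.0 + np.sqrt(1.25)])
        np.testing.assert_allclose(s.eigenvalues, expected, atol=1e-12)
        assert s.ground_energy == pytest.approx(1.0 - np.sqrt(1.25))

    def test_matches_charpoly_oracle_n_up_to_4(self):
        rng = np.random.default_rng(17)
        for n in (2, 3, 4):
            for _ in range(25):
                a = rng.normal(0, 1.5, size=(n, n))
                h = 0.5 * (a + a.T)
                s = pr.diagonalize(h)
                np.testing.assert_allclose(s.eigenvalues, charpoly_roots(h),
                                           atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(pr.PmmRedoxError, match="asymmetric"):
            pr.diagonalize(np.array([[0.0, 1.0], [0.5, 2.0]]))

    def test_ground_vector_normalized(self):
        rng = np.random.default_rng(18)
        a = rng.normal(size=(4, 4))
        s = pr.diagonalize(0.5 * (a + a.T))
        assert np.linalg.norm(s.ground_vector) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.0, 3.0))
    def test_stabilizing_field_monotone_two_state(self, scale):
        """For a 2-state system the perturbed ground energy is non-
        increasing in the magnitude of a fixed-direction coupling field
        (level repulsion only pushes the ground state down)."""
        h = np.array([[0.0, 0.5 * scale], [0.5 * scale, 2.0]])
        h2 = np.array([[0.0, 0.5 * (scale + 0.1)],
                       [0.5 * (scale + 0.1), 2.0]])
        e1 = pr.diagonalize(h).ground_energy
        e2 = pr.diagonalize(h2).ground_energy
        assert e2 <= e1 + 1e-12


# ---------------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------------

def distant_probe_stream(r0, charges, distance=40.0, box=200.0):
    frames = tuple(
        frame_of([r0 + [distance, 0.0, 0.0]], [q], box=box, index=i,
                 time_ps=2.0 * i)
        for i, q in enumerate(charges))
    return pr.FrameStream(frames=frames)


class TestPerturbedEnergyTrajectory:
    def test_gas_phase_limit(self, toy_species):
        """With (numerically) vanishing perturbation the gap equals the
        unperturbed ground-state splitting every frame."""
        r0 = toy_species.oxidized.expansion_center()
        stream = distant_probe_stream(r0, [0.0, 0.0, 0.0])
        traj = pr.perturbed_energy_trajectory(toy_species, stream,
                                              mode="dipole",
                                              pbc_mode="none")
        expected = (toy_species.reduced.energies[0]
                    - toy_species.oxidized.energies[0])
        np.testing.assert_allclose(traj.gap, expected, atol=1e-12)

    @pytest.mark.parametrize("mode", ["dipole", "esp_diagonal"])
    def test_uniform_potential_shifts_gap_by_minus_phi(self, toy_species,
                                                       mode):
        """Uniform potential couples to the charge difference -1 e."""
        base = pr.perturbed_energy_trajectory(
            toy_species, distant_probe_stream(
                toy_species.oxidized.expansion_center(), [0.0]),
            mode=mode, pbc_mode="none")
        phi = 1.3
        n_at = toy_species.oxidized.geometry.n_atoms
        fld = zero_field(n_at, phi=phi)
        gaps = []
        for qc in (toy_species.oxidized, toy_species.reduced):
            h = pr.build_perturbed_hamiltonian(qc, fld, mode=mode)
            gaps.append(pr.diagonalize(h).ground_energy)
        gap_shifted = gaps[1] - gaps[0]
        assert gap_shifted - base.gap[0] == pytest.approx(-phi, abs=1e-12)

    def test_three_frames_match_single_frame_assembly(self, toy_species):
        """The driver must reproduce a hand-rolled per-frame pipeline."""
        r0 = toy_species.oxidized.expansion_center()
        stream = distant_probe_stream(r0, [1.0, -2.0, 0.5])
        traj = pr.perturbed_energy_trajectory(toy_species, stream,
                                              mode="esp_diagonal",
                                              pbc_mode="none")
        for i, fr in enumerate(stream):
            field = pr.compute_field(fr, toy_species.oxidized.geometry, r0,
                                     pbc_mode="none")
            u = [pr.diagonalize(pr.build_perturbed_hamiltonian(
                qc, field, mode="esp_diagonal")).ground_energy
                for qc in (toy_species.oxidized, toy_species.reduced)]
            assert traj.u_ox[i] == pytest.approx(u[0], abs=1e-14)
            assert traj.u_red[i] == pytest.approx(u[1], abs=1e-14)
            assert traj.gap[i] == pytest.approx(u[1] - u[0], abs=1e-14)

    def test_error_annotated_with_frame_index(self, toy_species):
        r0 = toy_species.oxidized.expansion_center()
        good = frame_of([r0 + [40.0, 0, 0]], [1.0], box=200.0, index=0,
                        time_ps=0.0)
        clash = frame_of([r0 + [0.1, 0, 0]], [1.0], box=200.0, index=1,
                         time_ps=2.0)
        stream = pr.FrameStream(frames=(good, clash))
        with pytest.raises(pr.ClashError, match="frame 1"):
            pr.perturbed_energy_trajectory(toy_species, stream,
                                           pbc_mode="none")

    def test_five_state_runs_both_modes(self, five_state_species):
        r0 = five_state_species.oxidized.expansion_center()
        stream = distant_probe_stream(r0, [1.0, -1.0])
        for mode in ("dipole", "esp_diagonal"):
            traj = pr.perturbed_energy_trajectory(five_state_species, stream,
                                                  mode=mode, pbc_mode="none")
            assert traj.gap.shape == (2,)
            assert np.all(np.isfinite(traj.gap))
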