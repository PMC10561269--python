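"""Geometry, Eckart alignment, and normal-mode transformation tests."""

import numpy as np
import pytest

from tgaspec import molgeom
from tgaspec.constants import UnknownIsotopeError, isotope_mass
from tgaspec.molgeom import (
    AtomicSystem,
    cart_to_nm,
    eckart_rotation,
    nm_to_cart,
    normal_mode_analysis,
    shift_to_com,
    substitute_isotopes,
    transform_derivatives,
)

from conftest import cartesian_harmonic_surface, random_proper_rotations


def diatomic(m1_label="H", m2_label="Cl", d=2.4) -> AtomicSystem:
    return AtomicSystem.from_labels([m1_label, m2_label], [0, 0, 0, 0, 0, d])


def diatomic_hessian(k: float) -> np.ndarray:
    """Cartesian Hessian of V = k/2 (z2 - z1 - d)^2 for a diatomic on z."""
    h = np.zeros((6, 6))
    h[2, 2] = h[5, 5] = k
    h[2, 5] = h[5, 2] = -k
    return h


class TestIsotopes:
    def test_identity_substitution(self, water):
        out = substitute_isotopes(water, {})
        assert out.labels == water.labels
        np.testing.assert_array_equal(out.masses, water.masses)
        np.testing.assert_array_equal(out.coords, water.coords)

    def test_substitution_changes_mass_not_coords(self, water):
        out = substitute_isotopes(water, {1: "D", 2: "D"})
        assert out.masses[1] == isotope_mass("D")
        assert out.masses[0] == water.masses[0]
        # coordinates bit-identical
        assert np.array_equal(out.coords, water.coords)

    def test_pes_bitwise_invariant_under_substitution(self, water):
        surface, _ = cartesian_harmonic_surface(water, [0.005, 0.008, 0.017])
        heavy = substitute_isotopes(shift_to_com(water), {1: "D"})
        light = shift_to_com(water)
        # masses never enter the potential
        assert surface.evaluate(heavy.coords)[0] == surface.evaluate(light.coords)[0]

    def test_unknown_tag_named_in_error(self, water):
        with pytest.raises(UnknownIsotopeError, match="Xx"):
            substitute_isotopes(water, {0: "Xx"})

    def test_bad_index(self, water):
        with pytest.raises(IndexError):
            substitute_isotopes(water, {7: "D"})

    def test_diatomic_reduced_mass_frequency_scaling(self):
        """H-X -> D-X scales the frequency by the closed-form reduced-mass ratio."""
        k = 0.3
        light = diatomic("H", "Cl")
        heavy = substitute_isotopes(light, {0: "D"})
        h = diatomic_hessian(k)
        w_light = normal_mode_analysis(light, h).frequencies[-1]
        w_heavy = normal_mode_analysis(heavy, h).frequencies[-1]

        def mu(system):
            m1, m2 = system.masses
            return m1 * m2 / (m1 + m2)

        assert w_heavy / w_light == pytest.approx(np.sqrt(mu(light) / mu(heavy)), rel=1e-12)


class TestCenterOfMass:
    def test_two_equal_masses(self):
        sys_ = AtomicSystem(("H", "H"), [1000.0, 1000.0], [0, 0, 0, 2, 0, 0])
        out = shift_to_com(sys_)
        np.testing.assert_allclose(out.coords3[:, 0], [-1.0, 1.0], atol=1e-15)

    def test_already_at_com_unchanged(self, water):
        once = shift_to_com(water)
        twice = shift_to_com(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-14)

    def test_random_system_com_is_zero(self, rng):
        sys_ = AtomicSystem.from_labels(
            ["C", "H", "H", "O", "N"], rng.uniform(-3, 3, 15)
        )
        out = shift_to_com(sys_)
        assert np.linalg.norm(out.center_of_mass()) < 1e-12


class TestEckart:
    def test_identity_alignment(self, water):
        ref = shift_to_com(water)
        align = eckart_rotation(ref, ref)
        np.testing.assert_allclose(align.rotation, np.eye(3), atol=1e-12)
        assert align.residual < 1e-20

    def test_recovers_rigid_rotation(self, water, rng):
        ref = shift_to_com(water)
        r0 = random_proper_rotations(rng, 1)[0]
        rotated = ref.with_coords((ref.coords3 @ r0.T).ravel())
        align = eckart_rotation(rotated, ref)
        assert align.residual < 1e-18
        np.testing.assert_allclose(align.rotation @ r0, np.eye(3), atol=1e-10)

    def test_beats_random_rotations(self, water, rng):
        """Kabsch residual is the minimum over sampled proper rotations."""
        ref = shift_to_com(water)
        rots = random_proper_rotations(rng, 300)
        for _ in range(5):
            pert = ref.with_coords(ref.coords + rng.normal(0, 0.1, ref.coords.size))
            align = eckart_rotation(pert, ref)
            pert0 = shift_to_com(pert)
            trial = np.einsum("kij,aj->kai", rots, pert0.coords3)
            res = np.einsum(
                "a,ka->k",
                pert0.masses,
                np.sum((trial - ref.coords3[None, :, :]) ** 2, axis=2),
            )
            assert align.residual <= res.min() + 1e-12

    def test_rotation_is_proper(self, water, rng):
        ref = shift_to_com(water)
        pert = ref.with_coords(ref.coords + rng.normal(0, 0.3, ref.coords.size))
        align = eckart_rotation(pert, ref)
        np.testing.assert_allclose(align.rotation.T @ align.rotation, np.eye(3), atol=1e-12)
        assert np.linalg.det(align.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_errors(self, water):
        ref = shift_to_com(water)
        other = AtomicSystem.from_labels(["O", "H"], np.zeros(6))
        with pytest.raises(ValueError, match="atom count"):
            eckart_rotation(other, ref)
        with pytest.raises(ValueError, match="COM"):
            eckart_rotation(ref, water)  # un-shifted reference


class TestNormalModeAnalysis:
    def test_diatomic_closed_form(self):
        k = 0.25
        sys_ = diatomic("H", "Cl")
        basis = normal_mode_analysis(sys_, diatomic_hessian(k))
        assert basis.n_modes == 1  # linear: 3N - 5
        m1, m2 = sys_.masses
        mu = m1 * m2 / (m1 + m2)
        assert basis.frequencies[0] == pytest.approx(np.sqrt(k / mu), rel=1e-10)

    def test_triatomic_retains_3_modes(self, water):
        freqs = np.array([0.004, 0.008, 0.017])
        _, hess = cartesian_harmonic_surface(water, freqs)
        basis = normal_mode_analysis(water, hess)
        assert basis.n_modes == 3
        np.testing.assert_allclose(basis.frequencies, freqs, rtol=1e-8)

    def test_mode_orthonormality(self, water):
        _, hess = cartesian_harmonic_surface(water, [0.004, 0.008, 0.017])
        basis = normal_mode_analysis(water, hess)
        gram = basis.modes.T @ basis.modes
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-12)

    def test_asymmetric_hessian_rejected(self, water):
        h = np.zeros((9, 9))
        h[0, 1] = 1.0
        with pytest.raises(ValueError, match="asymmetric"):
            normal_mode_analysis(water, h)

    def test_basis_json_roundtrip(self, water, tmp_path):
        _, hess = cartesian_harmonic_surface(water, [0.004, 0.008, 0.017])
        basis = normal_mode_analysis(water, hess)
        basis.to_json(tmp_path / "basis.json")
        loaded = molgeom.NormalModeBasis.from_json(tmp_path / "basis.json")
        np.testing.assert_allclose(loaded.frequencies, basis.frequencies, rtol=1e-12)
        np.testing.assert_allclose(loaded.modes, basis.modes, atol=1e-12)
        np.testing.assert_allclose(loaded.ref_system.masses, basis.ref_system.masses)


class TestCoordinateTransforms:
    @pytest.fixture
    def basis(self, water):
        _, hess = cartesian_harmonic_surface(water, [0.004, 0.008, 0.017])
        return normal_mode_analysis(water, hess)

    def test_reference_maps_to_zero(self, basis):
        q = cart_to_nm(basis.ref_system, basis)
        np.testing.assert_allclose(q, 0.0, atol=1e-12)

    def test_nm_to_cart_of_zero_is_reference(self, basis):
        out = nm_to_cart(np.zeros(3), basis)
        np.testing.assert_allclose(out.coords, basis.ref_system.coords, atol=1e-14)

    def test_displacement_along_single_mode(self, basis):
        q_in = np.array([0.0, 1.5, 0.0])
        system = nm_to_cart(q_in, basis)
        np.testing.assert_allclose(cart_to_nm(system, basis), q_in, atol=1e-10)

    def test_roundtrip_with_rigid_motion(self, basis, rng):
        """cart->nm->cart reproduces the Eckart-aligned input geometry."""
        q_in = rng.normal(0, 0.8, 3)
        displaced = nm_to_cart(q_in, basis)
        r0 = random_proper_rotations(rng, 1)[0]
        moved = displaced.with_coords(
            (displaced.coords3 @ r0.T + np.array([1.0, -2.0, 0.5])).ravel()
        )
        q, align = cart_to_nm(moved, basis, return_alignment=True)
        np.testing.assert_allclose(q, q_in, atol=1e-9)
        back = nm_to_cart(q, basis)
        aligned = align.apply(moved.coords3 - align.com_shift).ravel()
        err = np.sqrt(np.sum(basis.ref_system.masses3 * (back.coords - aligned) ** 2))
        assert err < 1e-10
        # undoing the alignment returns the original frame
        restored = nm_to_cart(q, basis, align)
        np.testing.assert_allclose(restored.coords, moved.coords, atol=1e-9)

    def test_output_com_matches_reference(self, basis, rng):
        out = nm_to_cart(rng.normal(0, 1.0, 3), basis)
        np.testing.assert_allclose(
            out.center_of_mass(), basis.ref_system.center_of_mass(), atol=1e-12
        )


class TestDerivativeTransforms:
    @pytest.fixture
    def setup(self, water):
        freqs = np.array([0.004, 0.008, 0.017])
        surface, hess = cartesian_harmonic_surface(water, freqs)
        basis = normal_mode_analysis(water, hess)
        return surface, hess, basis, freqs

    def test_zero_gradient_stays_zero(self, setup):
        _, hess, basis, _ = setup
        g_q, _ = transform_derivatives(np.zeros(9), hess, basis)
        np.testing.assert_allclose(g_q, 0.0, atol=1e-15)

    def test_hessian_diagonal_in_own_modes(self, setup):
        _, hess, basis, freqs = setup
        _, h_q = transform_derivatives(np.zeros(9), hess, basis)
        np.testing.assert_allclose(h_q, np.diag(freqs**2), atol=1e-12)

    def test_gradient_matches_finite_differences(self, setup, rng):
        surface, _, basis, _ = setup
        q0 = rng.normal(0, 0.5, 3)
        system = nm_to_cart(q0, basis)
        _, g_cart, h_cart = surface.evaluate(system.coords)
        g_q, _ = transform_derivatives(g_cart, h_cart, basis)
        step = 1e-5
        for j in range(3):
            e = np.zeros(3)
            e[j] = step
            vp = surface.evaluate(nm_to_cart(q0 + e, basis).coords)[0]
            vm = surface.evaluate(nm_to_cart(q0 - e, basis).coords)[0]
            assert g_q[j] == pytest.approx((vp - vm) / (2 * step), abs=1e-6)


class TestXYZ:
    def test_roundtrip(self, water, tmp_path):
        path = tmp_path / "mol.xyz"
        molgeom.write_xyz(path, water, comment="test geometry")
        loaded = molgeom.read_xyz(path)
        assert loaded.labels == water.labels
        np.testing.assert_allclose(loaded.coords, water.coords, atol=1e-10)

    def test_isotope_tags_in_comment(self, tmp_path):
        path = tmp_path / "mol.xyz"
        path.write_text("3\nisotope=2:D,3:D\nN 0 0 0\nH 0 0 1\nH 0 1 0\n")
        system = molgeom.read_xyz(path)
        assert system.masses[1] == isotope_mass("D")
        assert system.masses[2] == isotope_mass("D")
        assert system.masses[0] == isotope_mass("N")

    def test_isotope_label_column(self, tmp_path):
        path = tmp_path / "mol.xyz"
        path.write_text("2\n\nD 0 0 0\nCl 0 0 1.27\n")
        system = molgeom.read_xyz(path)
        assert system.masses[0] == isotope_mass("D")
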