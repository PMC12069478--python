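"""Deformation split, invariant values, numbering, gradients, mixed invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hypertab as ht
from hypertab.kinematics import (
    N_SLOTS,
    invariant_cderivs,
    slot_components,
    slots_available,
)

from conftest import random_deformation

FIBERS3 = ht.FiberFrame.from_vectors([1, 0, 0], [0, 1, 0], [0, 0, 1])
NO_FIBERS = ht.FiberFrame.from_vectors()


class TestDecompose:
    def test_identity(self):
        st_ = ht.decompose(np.eye(3))
        assert st_.J == pytest.approx(1.0)
        assert np.allclose(st_.Fbar, np.eye(3))
        assert np.allclose(st_.bbar, np.eye(3))

    def test_pure_dilatation_has_identity_shape_part(self):
        st_ = ht.decompose(2.0 * np.eye(3))
        assert st_.J == pytest.approx(8.0)
        assert np.allclose(st_.Fbar, np.eye(3))

    def test_simple_shear_is_isochoric(self):
        F = np.eye(3)
        F[0, 1] = 0.5
        st_ = ht.decompose(F)
        assert st_.J == pytest.approx(1.0)
        assert np.allclose(st_.Fbar, F)
        # bbar symmetric positive definite
        assert np.allclose(st_.bbar, st_.bbar.T)
        assert np.all(np.linalg.eigvalsh(st_.bbar) > 0)

    @pytest.mark.parametrize(
        "F",
        [np.diag([1.0, 1.0, -1.0]), np.zeros((3, 3))],
        ids=["negative-det", "singular"],
    )
    def test_nonpositive_determinant_rejected(self, F):
        with pytest.raises(ht.InvalidDeformationError):
            ht.decompose(F)

    def test_nonfinite_entries_rejected(self):
        F = np.eye(3)
        F[1, 2] = np.nan
        with pytest.raises(ht.InvalidDeformationError):
            ht.decompose(F)


class TestNumbering:
    @pytest.mark.parametrize(
        "family,alpha,beta,expected",
        [(4, 1, 1, 4), (4, 3, 3, 14), (5, 2, 3, 13), (5, 1, 1, 5), (4, 1, 2, 6)],
    )
    def test_slot_formula(self, family, alpha, beta, expected):
        assert ht.invariant_index(family, alpha, beta) == expected

    def test_bijection_onto_4_to_15(self):
        slots = {
            ht.invariant_index(fam, a, b)
            for fam in (4, 5)
            for a in (1, 2, 3)
            for b in range(a, 4)
        }
        assert slots == set(range(4, 16))
        for s in range(4, 16):
            fam, a, b = slot_components(s)
            assert ht.invariant_index(fam, a, b) == s

    def test_beta_below_alpha_rejected(self):
        with pytest.raises(ht.ConfigurationError):
            ht.invariant_index(4, 2, 1)

    def test_availability_grows_with_fiber_count(self):
        assert slots_available(0) == {1, 2, 3}
        assert slots_available(1) == {1, 2, 3, 4, 5}
        assert slots_available(3) == set(range(1, 16))


class TestInvariants:
    def test_reference_deviation_vanishes(self):
        inv = ht.compute_invariants(ht.decompose(np.eye(3)), FIBERS3)
        assert np.allclose(inv.dev[1:], 0.0, atol=1e-14)

    def test_uniaxial_isochoric_with_axial_fiber(self):
        F = np.diag([2.0, 2**-0.5, 2**-0.5])
        inv = ht.compute_invariants(ht.decompose(F), ht.FiberFrame.from_vectors([1, 0, 0]))
        assert inv.values[1] == pytest.approx(5.0)
        assert inv.values[4] == pytest.approx(4.0)
        assert inv.values[3] == pytest.approx(1.0)

    def test_simple_shear_isotropic_values(self):
        F = np.eye(3)
        F[0, 1] = 0.5
        inv = ht.compute_invariants(ht.decompose(F), NO_FIBERS)
        assert inv.values[1] == pytest.approx(3.25)
        assert inv.values[3] == pytest.approx(1.0)

    def test_unavailable_slot_raises(self):
        inv = ht.compute_invariants(ht.decompose(np.eye(3)), NO_FIBERS)
        with pytest.raises(ht.ConfigurationError):
            inv.require(4)

    def test_fiber_reference_values_are_zeta(self):
        frame = ht.FiberFrame.from_vectors([1, 0, 0], [np.cos(0.5), np.sin(0.5), 0])
        inv = ht.compute_invariants(ht.decompose(np.eye(3)), frame)
        assert inv.ref[6] == pytest.approx(np.cos(0.5))
        assert inv.values[6] == pytest.approx(np.cos(0.5))

    def test_objectivity_under_rotations(self, rng):
        from scipy.spatial.transform import Rotation

        F = random_deformation(rng, 0.2)
        base = ht.compute_invariants(ht.decompose(F), FIBERS3).values[1:]
        for _ in range(20):
            Q = Rotation.random(rng=rng).as_matrix()
            rot = ht.compute_invariants(ht.decompose(Q @ F), FIBERS3).values[1:]
            assert np.allclose(rot, base, rtol=1e-10)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_isochoric_insensitivity_to_volume_scaling(self, c, rng):
        F = random_deformation(rng, 0.2)
        a = ht.compute_invariants(ht.decompose(F), FIBERS3)
        b = ht.compute_invariants(ht.decompose(c * F), FIBERS3)
        iso = [1, 2] + list(range(4, 16))
        assert np.allclose([b.values[i] for i in iso], [a.values[i] for i in iso], rtol=1e-10)
        assert b.values[3] == pytest.approx(c**6 * a.values[3], rel=1e-10)


class TestGradients:
    def test_volumetric_gradient_at_reference(self):
        G = ht.invariant_gradients(ht.decompose(np.eye(3)), NO_FIBERS)
        assert np.allclose(G[3], 2.0 * np.eye(3))

    def test_isochoric_gradients_traceless(self, rng):
        for _ in range(5):
            F = random_deformation(rng, 0.25)
            G = ht.invariant_gradients(ht.decompose(F), FIBERS3)
            for slot in [1, 2] + list(range(4, 16)):
                assert abs(np.trace(G[slot])) < 1e-10 * max(1.0, np.linalg.norm(G[slot]))

    def test_matches_finite_differences_of_invariants(self, rng):
        """sum_i c_i G_i must equal (1/J) d(sum c_i I_i)/dF . F^t at 50 states."""
        for _ in range(50):
            F = random_deformation(rng, 0.15)
            coeff = rng.standard_normal(N_SLOTS + 1)
            G = ht.invariant_gradients(ht.decompose(F), FIBERS3)
            analytic = sum(coeff[s] * G[s] for s in range(1, N_SLOTS + 1))

            def phi(Fx):
                inv = ht.compute_invariants(ht.decompose(Fx), FIBERS3)
                return float(sum(coeff[s] * inv.values[s] for s in range(1, N_SLOTS + 1)))

            h = 1e-6
            grad = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    dF = np.zeros((3, 3))
                    dF[i, j] = h
                    grad[i, j] = (phi(F + dF) - phi(F - dF)) / (2 * h)
            fd = grad @ F.T / np.linalg.det(F)
            fd = 0.5 * (fd + fd.T)
            assert np.linalg.norm(analytic - fd) < 1e-6 * max(1.0, np.linalg.norm(fd))

    def test_second_cderivs_match_finite_differences(self, rng):
        """d2I/dC2 agrees with central differences of dI/dC."""
        F = random_deformation(rng, 0.2)
        state = ht.decompose(F)
        ders = invariant_cderivs(state, FIBERS3)
        C = F.T @ F
        h = 1e-6
        for slot in (1, 2, 3, 4, 9, 13):
            _, _, d2I = ders[slot]
            for (k, l) in [(0, 0), (0, 1), (1, 2)]:
                dC = np.zeros((3, 3))
                dC[k, l] = dC[l, k] = h

                def dIdC(Cx):
                    lam, V = np.linalg.eigh(Cx)
                    Fx = V @ np.diag(np.sqrt(lam)) @ V.T
                    return invariant_cderivs(ht.decompose(Fx), FIBERS3, [slot])[slot][1]

                fd = (dIdC(C + dC) - dIdC(C - dC)) / (2 * h)
                an = d2I[:, :, k, l] + (d2I[:, :, l, k] if k != l else 0.0)
                assert np.allclose(an, fd, rtol=1e-5, atol=1e-6)


class TestMixed:
    def _dispersion_def(self, kappa, slot4=4):
        c = np.zeros(N_SLOTS)
        c[0] = kappa
        c[slot4 - 1] = 1.0 - 3.0 * kappa
        return ht.MixedInvariantDef(101, c)

    def test_aligned_limit_is_pure_fiber_deviation(self):
        F = np.diag([1.3, 1.3**-0.5, 1.3**-0.5])
        inv = ht.compute_invariants(ht.decompose(F), ht.FiberFrame.from_vectors([1, 0, 0]))
        out = ht.evaluate_mixed(inv, [self._dispersion_def(0.0)])
        value, coeffs = out[101]
        assert value == pytest.approx(inv.dev[4])
        assert coeffs == {4: 1.0}

    def test_isotropic_limit_is_first_invariant_deviation(self):
        F = np.diag([1.3, 1.3**-0.5, 1.3**-0.5])
        inv = ht.compute_invariants(ht.decompose(F), ht.FiberFrame.from_vectors([1, 0, 0]))
        value, coeffs = ht.evaluate_mixed(inv, [self._dispersion_def(1.0 / 3.0)])[101]
        assert value == pytest.approx((inv.values[1] - 3.0) / 3.0)
        assert 4 not in coeffs  # 1 - 3*kappa = 0 drops the fiber slot

    @pytest.mark.parametrize("kappa", [0.0, 0.074, 1.0 / 3.0])
    def test_reference_value_vanishes(self, kappa):
        inv = ht.compute_invariants(
            ht.decompose(np.eye(3)), ht.FiberFrame.from_vectors([1, 0, 0])
        )
        value, _ = ht.evaluate_mixed(inv, [self._dispersion_def(kappa)])[101]
        assert value == pytest.approx(0.0, abs=1e-14)

    def test_coefficient_on_unavailable_slot_rejected(self):
        inv = ht.compute_invariants(ht.decompose(np.eye(3)), NO_FIBERS)
        with pytest.raises(ht.ConfigurationError):
            ht.evaluate_mixed(inv, [self._dispersion_def(0.074)])

    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ht.ConfigurationError):
            ht.MixedInvariantDef(101, np.zeros(N_SLOTS))


class TestFiberFrame:
    def test_zeta_symmetric_unit_diagonal(self):
        frame = ht.FiberFrame.from_vectors([1, 0, 0], [0.6, 0.8, 0])
        z = frame.zeta
        assert np.allclose(z, z.T)
        assert np.allclose(np.diag(z), 1.0)

    def test_off_unit_vector_normalized_with_warning(self):
        with pytest.warns(UserWarning):
            frame = ht.FiberFrame.from_vectors([2.0, 0, 0])
        assert np.allclose(frame.directions[0], [1, 0, 0])

    def test_more_than_three_families_rejected(self):
        with pytest.raises(ht.ConfigurationError):
            ht.FiberFrame.from_vectors([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    entries=st.lists(
        st.floats(-0.3, 0.3, allow_nan=False), min_size=9, max_size=9
    ),
    scale=st.floats(0.5, 2.0),
)
def test_volume_scaling_property(entries, scale):
    """I3 picks up c^6 under F -> cF while the shape invariants are untouched."""
    F = np.eye(3) + np.array(entries).reshape(3, 3)
    if np.linalg.det(F) < 0.3:
        return
    a = ht.compute_invariants(ht.decompose(F), NO_FIBERS)
    b = ht.compute_invariants(ht.decompose(scale * F), NO_FIBERS)
    assert b.values[1] == pytest.approx(a.values[1], rel=1e-9)
    assert b.values[2] == pytest.approx(a.values[2], rel=1e-9)
    assert b.values[3] == pytest.approx(scale**6 * a.values[3], rel=1e-9)
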