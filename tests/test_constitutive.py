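"""Constitutive oracles: energy values, stress/tangent consistency, the
plane-stress condition, and the material-table structure."""

import numpy as np
import pytest
import scipy.optimize as so

from sphincterfem import constitutive as ct


PRESETS = list(ct.MATERIALS)


def _state_with_equal_invariants(target=3.1):
    """Find F = diag(a, b), lam3 = 1/(a b) with I1 = I2 = target, J = 1."""

    def eqs(x):
        a, b = x
        F = np.diag([a, b])
        i1, i2, j = ct.invariants_of(F, 1.0 / (a * b))
        return [i1 - target, i2 - target]

    a, b = so.fsolve(eqs, [1.25, 1.0], xtol=1e-14)
    return ct.DeformationState(F=np.diag([a, b]), lam3=1.0 / (a * b))


class TestInvariants:
    def test_identity(self):
        i1, i2, j = ct.invariants_of(np.eye(2), 1.0)
        assert (i1, i2, j) == (3.0, 3.0, 1.0)

    def test_isochoric_inplane_stretch(self):
        lam = 1.3
        _, _, j = ct.invariants_of(np.diag([lam, 1 / lam]), 1.0)
        assert j == pytest.approx(1.0, abs=1e-14)

    def test_hand_evaluated_example(self):
        # C = diag(1.44, 1), lam3^2 = 1: direct arithmetic on the formulas
        i1, i2, j = ct.invariants_of(np.diag([1.2, 1.0]), 1.0)
        assert i1 == pytest.approx(3.44, abs=1e-12)
        assert i2 == pytest.approx((3.44**2 - (1.44**2 + 1 + 1)) / 2, abs=1e-12)
        assert j == pytest.approx(1.2, abs=1e-12)

    def test_inverted_state_rejected(self):
        with pytest.raises(ct.InvertedStateError):
            ct.invariants_of(np.diag([1.0, -1.0]), 1.0)


class TestStrainEnergy:
    @pytest.mark.parametrize("preset", PRESETS)
    def test_zero_at_reference(self, preset):
        st = ct.DeformationState(F=np.eye(2), lam3=1.0)
        assert abs(ct.strain_energy(ct.MATERIALS[preset], st)) <= 1e-12

    def test_spongy_value_at_equal_invariants(self):
        # I1 = I2 = 3.1 at J = 1: direct substitution into the polynomial
        # gives 0.1*89.12 + 0.1*82.60 + 0.01*(2064.50 + 2953.61 - 4737.35)
        st = _state_with_equal_invariants(3.1)
        W = ct.strain_energy(ct.MATERIALS["spongy"], st)
        assert W == pytest.approx(19.9796, abs=2e-3)

    def test_fibrotic_is_ten_times_spongy(self):
        st = _state_with_equal_invariants(3.08)
        Ws = ct.strain_energy(ct.MATERIALS["spongy"], st)
        Wf = ct.strain_energy(ct.MATERIALS["fibrotic"], st)
        assert Wf / Ws == pytest.approx(10.0, rel=1e-3)

    @pytest.mark.parametrize("preset", PRESETS)
    def test_nonnegative_at_working_strains(self, preset):
        mat = ct.MATERIALS[preset]
        lams = np.linspace(0.7, 1.4, 8)
        for l1 in lams:
            for l2 in lams:
                F = np.diag([l1, l2])
                lam3 = ct.plane_stress_stretch(mat, (F.T @ F)[None])[0]
                W = ct.strain_energy(mat, ct.DeformationState(F=F, lam3=lam3))
                assert W >= -1e-10

    def test_objectivity_under_rotation(self):
        rng = np.random.default_rng(7)
        mat = ct.MATERIALS["spongy"]
        for _ in range(10):
            F = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
            if np.linalg.det(F) <= 0.1:
                continue
            th = rng.uniform(0, 2 * np.pi)
            Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            lam3 = 1.05
            W1 = ct.strain_energy(mat, ct.DeformationState(F=F, lam3=lam3))
            W2 = ct.strain_energy(mat, ct.DeformationState(F=Q @ F, lam3=lam3))
            assert W2 == pytest.approx(W1, rel=1e-12, abs=1e-12)


class TestStressAndTangent:
    @pytest.mark.parametrize("preset", PRESETS)
    def test_zero_stress_at_reference(self, preset):
        S2d, S33 = ct.pk2_stress(
            ct.MATERIALS[preset], ct.DeformationState(F=np.eye(2), lam3=1.0)
        )
        assert np.abs(S2d).max() < 1e-12
        assert abs(S33) < 1e-12

    def test_stress_matches_energy_gradient(self):
        rng = np.random.default_rng(3)
        mat = ct.MATERIALS["spongy"]
        h = 1e-6
        for _ in range(4):
            F = np.eye(2) + 0.06 * rng.standard_normal((2, 2))
            lam3 = float(np.exp(0.04 * rng.standard_normal()))
            st = ct.DeformationState(F=F, lam3=lam3)
            S2d, S33 = ct.pk2_stress(mat, st)
            assert np.allclose(S2d, S2d.T)
            C = st.C2d
            comps = [C[0, 0], C[1, 1], lam3**2, C[0, 1]]
            S = np.array([S2d[0, 0], S2d[1, 1], S33, S2d[0, 1]])
            scale = np.abs(S).max() + mat.mu0

            def W_of(c):
                w, _, _ = ct._eval_kernel(mat, *[np.asarray(v) for v in c], True)
                return float(w)

            for i, f in enumerate([2.0, 2.0, 2.0, 1.0]):
                cp, cm = comps.copy(), comps.copy()
                cp[i] += h
                cm[i] -= h
                fd = f * (W_of(cp) - W_of(cm)) / (2 * h)
                assert abs(fd - S[i]) / scale < 1e-6

    def test_tangent_matches_stress_gradient_and_is_symmetric(self):
        rng = np.random.default_rng(11)
        mat = ct.MATERIALS["dense_connective"]
        h = 1e-7
        for _ in range(3):
            F = np.eye(2) + 0.05 * rng.standard_normal((2, 2))
            lam3 = float(np.exp(0.03 * rng.standard_normal()))
            st = ct.DeformationState(F=F, lam3=lam3)
            CC = ct.material_tangent(mat, st)
            assert np.abs(CC - CC.T).max() / np.abs(CC).max() < 1e-12
            C = st.C2d
            comps = [C[0, 0], C[1, 1], lam3**2, C[0, 1]]
            _, _, M = ct._eval_kernel(mat, *[np.asarray(v) for v in comps], True)
            scale = np.abs(M).max()

            def S_of(c):
                _, S, _ = ct._eval_kernel(mat, *[np.asarray(v) for v in c], True)
                return S

            for j in range(4):
                cp, cm = comps.copy(), comps.copy()
                cp[j] += h
                cm[j] -= h
                fd = (S_of(cp) - S_of(cm)) / (2 * h)
                assert np.abs(fd - M[:, j]).max() / scale < 1e-6

    def test_small_strain_shear_modulus(self):
        # simple shear under plane stress: sigma_12 / gamma -> mu0
        mat = ct.MATERIALS["spongy"]
        g = 1e-6
        F = np.array([[1.0, g], [0.0, 1.0]])
        st = ct.plane_stress_state(mat, F)
        S2d, _ = ct.pk2_stress(mat, st)
        sig = ct.cauchy_stress(st, S2d)
        assert sig[0, 1] / g == pytest.approx(mat.mu0, rel=1e-4)
        assert mat.mu0 == pytest.approx(343.44, abs=0.01)


class TestPlaneStress:
    def test_identity(self):
        lam3 = ct.plane_stress_stretch(ct.MATERIALS["spongy"], np.eye(2)[None])[0]
        assert lam3 == pytest.approx(1.0, abs=1e-10)

    def test_equibiaxial_near_incompressible(self):
        lam = 1.1
        C = np.diag([lam**2, lam**2])
        lam3 = ct.plane_stress_stretch(ct.MATERIALS["spongy"], C[None])[0]
        assert lam3 == pytest.approx(1.0 / lam**2, rel=0.01)

    @pytest.mark.parametrize("preset", PRESETS)
    def test_matches_scalar_energy_minimisation(self, preset):
        mat = ct.MATERIALS[preset]
        F = np.diag([1.2, 1.0])
        lam3 = ct.plane_stress_stretch(mat, (F.T @ F)[None])[0]

        def W_of(l3):
            return ct.strain_energy(mat, ct.DeformationState(F=F, lam3=l3))

        res = so.minimize_scalar(W_of, bounds=(0.2, 3.0), method="bounded",
                                 options={"xatol": 1e-12})
        assert lam3 == pytest.approx(res.x, abs=1e-8)

    def test_residual_below_tolerance(self):
        mat = ct.MATERIALS["fibrotic"]
        rng = np.random.default_rng(5)
        F = np.eye(2)[None] + 0.1 * rng.standard_normal((50, 2, 2))
        C = np.einsum("...ki,...kj->...ij", F, F)
        lam3 = ct.plane_stress_stretch(mat, C)
        _, S33 = ct.pk2_stress(mat, ct.DeformationState(F=F, lam3=lam3))
        assert np.abs(S33).max() <= 1e-8 * mat.mu0


class TestMaterialTable:
    def test_fibrotic_to_spongy_ratio_ten(self):
        s, f = ct.MATERIALS["spongy"], ct.MATERIALS["fibrotic"]
        for name in ("c10", "c01", "c20", "c02", "c11"):
            ratio = getattr(f, name) / getattr(s, name)
            assert ratio == pytest.approx(10.0, rel=5e-4)

    def test_d1_identical_across_presets(self):
        d1s = {m.d1 for m in ct.MATERIALS.values()}
        assert d1s == {8.00e-7}

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ct.MooneyRivlin5(c10=1.0, c01=1.0, c20=0, c02=0, c11=0, d1=-1.0)
        with pytest.raises(ValueError):
            ct.MooneyRivlin5(c10=-2.0, c01=1.0, c20=0, c02=0, c11=0, d1=1e-6)
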