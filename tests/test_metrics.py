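"""Opening metrics: areas, loss/recovery percentages, principal fields."""

import numpy as np
import pytest

from sphincterfem import constitutive as ct
from sphincterfem import meshing as msh
from sphincterfem import metrics as mt
from sphincterfem import solver as sv


class TestLumenArea:
    def test_undeformed_circle(self, annulus_solution):
        sol = annulus_solution
        zero = sv.SolutionField(
            case_id="x", domain=sol.domain, mesh=sol.mesh, materials=sol.materials,
            pressures=[0.0], displacements=[np.zeros_like(sol.mesh.nodes)], log=[],
        )
        assert mt.lumen_area(zero) == pytest.approx(np.pi * 1.0, rel=1e-3)  # mm^2

    def test_translation_invariance(self, annulus_solution):
        sol = annulus_solution
        shift = np.full_like(sol.mesh.nodes, 0.37e-3)
        moved = sv.SolutionField(
            case_id="x", domain=sol.domain, mesh=sol.mesh, materials=sol.materials,
            pressures=[0.0], displacements=[shift], log=[],
        )
        zero = sv.SolutionField(
            case_id="x", domain=sol.domain, mesh=sol.mesh, materials=sol.materials,
            pressures=[0.0], displacements=[np.zeros_like(shift)], log=[],
        )
        assert mt.lumen_area(moved) == pytest.approx(mt.lumen_area(zero), abs=1e-12)

    def test_unit_square_loop_exact(self):
        # clockwise square loop (solid-on-left convention for a hole)
        xy = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
        edges = np.array([[xy[i], xy[(i + 1) % 4]] for i in range(4)])
        area, lengths = mt._loop_signed_area_and_lengths(edges, quadratic=False)
        assert -area == pytest.approx(1.0, abs=1e-14)
        assert lengths.sum() == pytest.approx(4.0, abs=1e-12)

    def test_self_intersection_rejected(self, annulus_solution):
        sol = annulus_solution
        mesh = sol.mesh
        # swap two adjacent boundary nodes to force a bow-tie crossing
        u = np.zeros_like(mesh.nodes)
        a, b = (int(v) for v in mesh.edge_groups["lumen"][0][:2])
        u[a] = 1.5 * (mesh.nodes[b] - mesh.nodes[a])
        u[b] = 1.5 * (mesh.nodes[a] - mesh.nodes[b])
        bad = sv.SolutionField(
            case_id="x", domain=sol.domain, mesh=mesh, materials=sol.materials,
            pressures=[0.0], displacements=[u], log=[],
        )
        with pytest.raises(mt.GeometricValidityError):
            mt.lumen_area(bad)


class TestOpeningMetrics:
    # printed results table: (id, A, delta_l, delta_r)
    TABLE = [
        ("H0", 12.49, -44.83, None),
        ("H3", 13.27, -38.57, 6.26),
        ("H4", 13.47, -37.00, 7.83),
        ("H5", 13.81, -34.25, 10.58),
        ("H6", 13.86, -33.84, 10.99),
        ("H7", 13.97, -32.96, 11.87),
        ("H6b", 14.44, -29.18, 15.65),
    ]
    A_P0, A_H0 = 18.09, 12.49

    @pytest.mark.parametrize("cid,A,dl,dr", TABLE)
    def test_reported_percentages_reproduced(self, cid, A, dl, dr):
        """Loss/recovery arithmetic applied to the published areas matches
        every published percentage to within table rounding (0.05 pp)."""
        assert mt.opening_loss(A, self.A_P0, self.A_H0) == pytest.approx(dl, abs=0.05)
        if dr is not None:
            assert mt.opening_recovery(A, self.A_H0) == pytest.approx(dr, abs=0.05)

    def test_degenerate_values(self):
        assert mt.opening_loss(18.09, 18.09, 12.49) == 0.0
        assert mt.opening_recovery(12.49, 12.49) == 0.0
        with pytest.raises(ZeroDivisionError):
            mt.opening_loss(1.0, 1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            mt.opening_recovery(1.0, 0.0)


class TestPrincipalFields:
    def test_hydrostatic_and_shear_eigenvalues(self):
        hyd = mt._principal_from_sym2(np.array([[5.0, 0.0], [0.0, 5.0]]))
        assert np.allclose(hyd, [5.0, 5.0])
        shear = mt._principal_from_sym2(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert np.allclose(shear, [-3.0, 3.0])

    def test_uniaxial_hencky_strain(self):
        """One element under homogeneous stretch: max principal Hencky
        strain equals ln(lambda)."""
        lam = 1.3
        X = np.array([[0, 0], [1e-3, 0], [0, 1e-3]], dtype=float)
        nodes6 = np.vstack([X, 0.5 * (X[0] + X[1]), 0.5 * (X[1] + X[2]), 0.5 * (X[2] + X[0])])
        mesh = msh.Mesh(
            nodes=nodes6, tri=np.array([[0, 1, 2]]),
            elements=np.array([[0, 1, 2, 3, 4, 5]]),
            region_tag=np.array(["spongy_sane"]),
            edge_groups={"lumen": np.array([[0, 1, 3]]),
                         "outer": np.zeros((0, 3), int), "holes": []},
            h_coarse=1.0, h_fine=1.0,
        )
        F = np.diag([lam, 1.0])
        u = nodes6 @ (F - np.eye(2)).T
        sol = sv.SolutionField(
            case_id="x", domain=None, mesh=mesh,
            materials={"spongy_sane": ct.MATERIALS["spongy"]},
            pressures=[0.0], displacements=[u], log=[],
        )
        pf = mt.principal_fields(sol)
        assert pf["emax"].max() == pytest.approx(np.log(lam), abs=1e-10)
        green = mt.principal_fields(sol, measure="green")
        assert green["emax"].max() == pytest.approx(0.5 * (lam**2 - 1), abs=1e-10)


class TestBoundaryProfile:
    def test_arcs_partition_perimeter(self, p0_low):
        phys = mt.boundary_profile(p0_low, "physiological")
        fib = mt.boundary_profile(p0_low, "fibrotic")
        loop = mt._ordered_loop(p0_low.mesh.edge_groups["lumen"])
        xy = p0_low.mesh.nodes[loop] + p0_low.u[loop]
        _, lengths = mt._loop_signed_area_and_lengths(xy, p0_low.mesh.quadratic)
        total = lengths.sum()
        assert len(phys.s) + len(fib.s) == len(loop)
        assert phys.length + fib.length == pytest.approx(total, rel=1e-8)
        assert np.all(np.diff(phys.s) > 0) and np.all(np.diff(fib.s) > 0)

    def test_symmetric_annulus_profile_nearly_constant(self, annulus_solution):
        prof = mt.boundary_profile(annulus_solution, "physiological")
        mean = prof.s_max_Pa.mean()
        assert np.abs(prof.s_max_Pa - mean).max() / abs(mean) < 0.1
        assert np.all(np.diff(prof.s) > 0)
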