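"""Geometry synthesis: tagged regions, hole placement, case registry."""

import numpy as np
import pytest
import shapely

from sphincterfem import geometry as geo


class TestSphincterDomain:
    def test_sane_domain_has_five_regions_no_holes(self):
        dom = geo.build_case("P0")
        assert len(dom.regions) == 5
        labels = [l for l, _ in dom.regions]
        assert labels.count("epithelium") == 1
        assert labels.count("spongy_sane") == 4
        assert dom.holes == []

    def test_fibrotic_flag_tags_lower_parts(self):
        dom = geo.build_case("H0")
        labels = [l for l, _ in dom.regions]
        assert labels.count("spongy_fibrotic") == 2
        for label, poly in dom.regions:
            if label == "spongy_fibrotic":
                assert poly.centroid.y < 0

    def test_lumen_boundary_area(self):
        prm = geo.GeometryParams()
        dom = geo.build_sphincter_domain(prm)
        poly = shapely.geometry.Polygon(dom.lumen_boundary)
        assert poly.area == pytest.approx(np.pi * prm.lumen_radius**2, rel=1e-3)

    def test_bound_length_one_millimetre(self):
        dom = geo.build_case("H0")
        # upper-right and lower-right spongy parts share only the bound
        upper = [p for l, p in dom.regions[1:] if p.centroid.y > 0 and p.centroid.x > 0]
        lower = [p for l, p in dom.regions[1:] if p.centroid.y < 0 and p.centroid.x > 0]
        seg = upper[0].intersection(lower[0])
        assert seg.length == pytest.approx(1.0e-3, abs=1e-6)

    def test_region_tiling(self):
        dom = geo.build_case("H6")
        total = sum(p.area for _, p in dom.regions)
        assert total == pytest.approx(dom.body.area, rel=1e-10)

    def test_pins_on_vertical_axis(self):
        dom = geo.build_case("P0")
        assert np.allclose(dom.pin_points[:, 0], 0.0)
        assert dom.pin_points[0, 1] > 0 > dom.pin_points[1, 1]

    def test_invalid_radii_ordering_named(self):
        with pytest.raises(geo.GeometryError, match="radii ordering"):
            geo.GeometryParams(lumen_radius=3.0e-3, epithelium_thickness=2.0e-3,
                               outer_radius=4.0e-3)

    def test_deterministic_construction(self):
        a = geo.build_case("H6b")
        b = geo.build_case("H6b")
        for (la, pa), (lb, pb) in zip(a.regions, b.regions):
            assert la == lb and pa.equals_exact(pb, 0.0)
        assert all(np.array_equal(ca, cb) for (ca, _), (cb, _) in zip(a.holes, b.holes))


class TestHolePlacement:
    def test_zero_holes_leaves_domain_unchanged(self):
        dom = geo.build_case("H0")
        out = geo.place_holes(dom, geo.HoleSpec(count=0))
        assert out.holes == []

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_aligned_counts_contained(self, n):
        dom = geo.build_sphincter_domain(geo.GeometryParams(fibrotic_half=True))
        out = geo.place_holes(dom, geo.HoleSpec(count=n, arrangement="aligned"))
        assert len(out.holes) == n
        # all centres on a single arc around the lumen centre
        radii = [np.hypot(*c) for c, _ in out.holes]
        assert np.ptp(radii) < 1e-12
        # pairwise disjoint
        for i in range(n):
            for j in range(i + 1, n):
                dist = np.linalg.norm(out.holes[i][0] - out.holes[j][0])
                assert dist > out.holes[i][1] + out.holes[j][1]

    def test_staggered_alternates_radii(self):
        dom = geo.build_sphincter_domain(geo.GeometryParams(fibrotic_half=True))
        out = geo.place_holes(dom, geo.HoleSpec(count=6, arrangement="staggered"))
        radii = np.array([np.hypot(*c) for c, _ in out.holes])
        assert np.ptp(radii[0::2]) < 1e-12
        assert np.ptp(radii[1::2]) < 1e-12
        assert abs(radii[0] - radii[1]) == pytest.approx(0.6e-3, rel=1e-9)

    def test_overlapping_holes_rejected_with_indices(self):
        dom = geo.build_sphincter_domain(geo.GeometryParams(fibrotic_half=True))
        with pytest.raises(geo.HolePlacementError) as err:
            geo.place_holes(dom, geo.HoleSpec(count=7, radius=0.75e-3))
        assert err.value.indices

    def test_hole_outside_fibrotic_rejected(self):
        dom = geo.build_sphincter_domain(geo.GeometryParams(fibrotic_half=True))
        spec = geo.HoleSpec(count=3, arc_radius=2.0e-3)  # overlaps the epithelium
        with pytest.raises(geo.HolePlacementError):
            geo.place_holes(dom, spec)

    def test_drilling_requires_fibrotic_region(self):
        dom = geo.build_sphincter_domain(geo.GeometryParams(fibrotic_half=False))
        with pytest.raises(geo.HolePlacementError):
            geo.place_holes(dom, geo.HoleSpec(count=3))


class TestCaseRegistry:
    @pytest.mark.parametrize(
        "cid,fibrotic,count,arrangement",
        [
            ("P0", False, 0, None),
            ("H0", True, 0, None),
            ("H3", True, 3, "aligned"),
            ("H7", True, 7, "aligned"),
            ("H6b", True, 6, "staggered"),
        ],
    )
    def test_known_cases(self, cid, fibrotic, count, arrangement):
        params, spec = geo.case_registry(cid)
        assert params.fibrotic_half is fibrotic
        assert spec.count == count
        if arrangement:
            assert spec.arrangement == arrangement

    def test_unknown_case_raises(self):
        with pytest.raises(KeyError):
            geo.case_registry("H99")


class TestSerialisation:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        dom = geo.build_case("H3")
        path = tmp_path / "dom.yaml"
        geo.save_domain(dom, path)
        data = yaml.safe_load(path.read_text())
        assert len(data["regions"]) == 5
        assert len(data["holes"]) == 3
        assert data["params"]["bound_length"] == pytest.approx(1.0e-3)
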