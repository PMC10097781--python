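"""Idealized geometry generation, cavity volumes, and mesh I/O."""

import numpy as np
import pytest

from helixlv import (
    IdealizedGeometrySpec,
    cavity_volume_spread,
    compute_cavity_volume,
    fetal_geometry_spec,
    generate_idealized_lv,
)
from helixlv.geometry import (
    GeometryError,
    VOLUME_MATCHED_FAMILY,
    apply_septal_lean,
)
from helixlv.io import read_msh, write_msh


class TestSpecs:
    def test_symmetric_printed_dimensions(self):
        spec = fetal_geometry_spec("symmetric")
        assert spec.cavity_length == 16.00
        assert spec.basal_cavity_width == 13.40
        assert spec.wall_thickness == 3.0
        # closed-form half-prolate volume
        assert spec.cavity_volume == pytest.approx(
            (2 / 3) * np.pi * 16.0 * 6.7**2 / 1000.0
        )

    def test_hemisphere_radius_from_volume_match(self):
        # inverting V = (2/3) pi r^3 for the symmetric reference volume
        spec = fetal_geometry_spec("hemisphere")
        v_ref = fetal_geometry_spec("symmetric").cavity_volume
        r_expected = (1.5 * 1000.0 * v_ref / np.pi) ** (1 / 3)
        assert spec.cavity_length == pytest.approx(r_expected)
        assert spec.cavity_length == pytest.approx(8.956, abs=0.01)

    def test_hypertrophic_doubles_wall_same_cavity(self):
        sym = fetal_geometry_spec("symmetric")
        hyp = fetal_geometry_spec("hypertrophic")
        assert hyp.wall_thickness == 2 * sym.wall_thickness
        assert hyp.cavity_volume == pytest.approx(sym.cavity_volume)

    def test_long_keeps_ratio_and_volume(self):
        long_ = fetal_geometry_spec("long")
        assert long_.cavity_length == pytest.approx(1.5 * 16.0)
        assert long_.cavity_volume == pytest.approx(
            fetal_geometry_spec("symmetric").cavity_volume, rel=1e-9
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape="symmetric", wall_thickness=-1, cavity_length=16,
                 basal_cavity_width=13.4),
            dict(shape="symmetric", wall_thickness=7.0, cavity_length=16,
                 basal_cavity_width=13.4),  # wall >= width/2
            dict(shape="hemisphere", wall_thickness=3, cavity_length=10,
                 basal_cavity_width=13.4),  # not a hemisphere
            dict(shape="banana", wall_thickness=3, cavity_length=16,
                 basal_cavity_width=13.4),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            IdealizedGeometrySpec(**kwargs)


class TestMeshing:
    def test_dimensions_within_one_percent(self, coarse_mesh):
        pts = coarse_mesh.points
        spec = coarse_mesh.spec
        length = -pts[:, 2].min()
        assert length == pytest.approx(spec.cavity_length + spec.wall_thickness,
                                       rel=0.01)
        base = pts[np.abs(pts[:, 2]) < 1e-9]
        r = np.hypot(base[:, 0], base[:, 1])
        assert r.max() == pytest.approx(
            spec.basal_cavity_width / 2 + spec.wall_thickness, rel=0.01
        )
        assert r.min() == pytest.approx(spec.basal_cavity_width / 2, rel=0.01)

    def test_positive_jacobians_and_labels(self, coarse_mesh):
        assert coarse_mesh.min_jacobian() > 0
        assert set(coarse_mesh.facets) == {"endo", "epi", "base"}
        for faces in coarse_mesh.facets.values():
            assert len(faces) > 0

    def test_default_resolution_meets_element_minimum(self):
        mesh = generate_idealized_lv(fetal_geometry_spec("symmetric"))
        assert mesh.n_cells >= 2500

    def test_cavity_volume_closed_forms(self):
        # hemisphere with r = 10 mm cavity: (2/3) pi 1000 mm^3
        spec = IdealizedGeometrySpec("hemisphere", 2.0, 10.0, 20.0)
        mesh = generate_idealized_lv(spec, n_circ=28, n_long=14, n_trans=1,
                                     enforce_min_elements=False)
        assert compute_cavity_volume(mesh) * 1000 == pytest.approx(
            2094.4, rel=5e-3
        )

    def test_cavity_volume_mesh_convergence(self):
        spec = fetal_geometry_spec("symmetric")
        v = [
            compute_cavity_volume(
                generate_idealized_lv(spec, n_circ=n, n_long=n // 2, n_trans=1,
                                      enforce_min_elements=False)
            )
            for n in (32, 64)
        ]
        assert abs(v[1] - v[0]) / v[0] < 0.002

    def test_volume_matched_family_within_two_percent(self):
        volumes = {
            s: compute_cavity_volume(generate_idealized_lv(fetal_geometry_spec(s)))
            for s in VOLUME_MATCHED_FAMILY
        }
        assert cavity_volume_spread(volumes.values()) <= 2.0

    def test_septal_lean_preserves_wall_volume_and_labels(self, coarse_mesh):
        leaned = apply_septal_lean(coarse_mesh, 2.0)
        assert leaned.min_jacobian() > 0
        assert abs(leaned.wall_volume() - coarse_mesh.wall_volume()) < (
            0.01 * coarse_mesh.wall_volume()
        )
        for k in coarse_mesh.facets:
            assert np.array_equal(leaned.facets[k], coarse_mesh.facets[k])

    def test_excessive_lean_raises(self, coarse_mesh):
        from helixlv import make_asymmetric_fixture

        with pytest.raises(GeometryError):
            make_asymmetric_fixture(coarse_mesh, 60.0)


class TestIO:
    def test_msh_roundtrip(self, tiny_mesh, tmp_path):
        path = tmp_path / "lv.msh"
        write_msh(path, tiny_mesh, point_data={"z": tiny_mesh.points[:, 2]})
        back = read_msh(path)
        assert np.allclose(back.points, tiny_mesh.points)
        assert np.array_equal(back.cells, tiny_mesh.cells)
        for k in tiny_mesh.facets:
            assert np.array_equal(back.facets[k], tiny_mesh.facets[k])
        assert compute_cavity_volume(back) == pytest.approx(
            compute_cavity_volume(tiny_mesh)
        )
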