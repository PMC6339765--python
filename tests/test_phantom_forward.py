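"""Unit tests for the reduced quasi-static forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elastinv.mr_core import BREAST_MATERIALS, cauchy_stress_uniaxial, youngs_from_mr
from elastinv.phantom_forward import (
    STUDY_INSTANTS_S,
    DisplacementField,
    LinearParams,
    LoadSpec,
    PhantomGeometry,
    default_tumor_points,
    displacement_field_at,
    elastic_reference_field,
    load_field,
    sample_axial,
    save_field,
    solve_layer_stretches,
)

ALL_MATS = dict(BREAST_MATERIALS)


class TestGeometry:
    def test_defaults_valid(self, geometry):
        assert geometry.axial_mm == 100.0
        assert geometry.host_layer_bounds() == (15.0, 100.0)
        assert geometry.tumor_lateral_bounds() == (25.0, 35.0)

    def test_layer_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            PhantomGeometry(layers=(("fat", 10.0), ("fibroglandular", 80.0)))

    def test_tumor_outside_host_rejected(self):
        with pytest.raises(ValueError):
            PhantomGeometry(tumor_axial_mm=(10.0, 20.0))

    def test_column_segments(self, geometry):
        segs = geometry.column_segments(through_tumor=True)
        names = [s[0] for s in segs]
        assert names == ["fat", "fibroglandular", "tumor", "fibroglandular"]
        assert sum(bot - top for _, top, bot in segs) == pytest.approx(100.0)


class TestLoadSpec:
    def test_default_instants(self, load):
        assert load.sample_times_s == STUDY_INSTANTS_S

    def test_traction_sinusoid(self, load):
        assert load.traction_at(0.0) == 0.0
        assert load.traction_at(2.5) == pytest.approx(5000.0)
        assert load.traction_at(7.5) == pytest.approx(-5000.0)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            LoadSpec(sample_times_s=(1.0, 1.0))


class TestSolveLayerStretches:
    def test_zero_traction_identity(self, geometry):
        out = solve_layer_stretches(geometry, ALL_MATS, 0.0)
        assert all(lam == pytest.approx(1.0, abs=1e-10) for lam in out.values())

    def test_round_trip_through_stress_law(self, geometry, tumor):
        traction = -cauchy_stress_uniaxial(tumor, 0.95)
        out = solve_layer_stretches(geometry, ALL_MATS, traction)
        assert out["tumor"] == pytest.approx(0.95, abs=1e-8)

    def test_stress_continuity(self, geometry):
        traction = 3000.0
        out = solve_layer_stretches(geometry, ALL_MATS, traction)
        for name, lam in out.items():
            sigma = cauchy_stress_uniaxial(ALL_MATS[name], lam)
            assert abs(sigma - (-traction)) < 1e-6

    def test_missing_material_raises(self, geometry):
        with pytest.raises(KeyError, match="tumor"):
            solve_layer_stretches(
                geometry, {"fat": ALL_MATS["fat"],
                           "fibroglandular": ALL_MATS["fibroglandular"]}, 10.0)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(min_value=-8000.0, max_value=8000.0))
    def test_continuity_property(self, traction):
        geo = PhantomGeometry()
        out = solve_layer_stretches(geo, ALL_MATS, traction)
        for name, lam in out.items():
            assert abs(cauchy_stress_uniaxial(ALL_MATS[name], lam) + traction) < 1e-6


class TestDisplacementField:
    def test_zero_load_zero_field(self, geometry, load):
        f = displacement_field_at(geometry, ALL_MATS, load, t=0.0)
        assert np.allclose(f.ux_mm, 0.0) and np.allclose(f.uy_mm, 0.0)

    def test_fixed_face_row_zero(self, geometry, load):
        f = displacement_field_at(geometry, ALL_MATS, load, t=8.0)
        assert np.allclose(f.ux_mm[-1, :], 0.0)

    def test_homogeneous_linear_limit(self, load):
        geo = PhantomGeometry(layers=(("m", 100.0),),
                              tumor_axial_mm=(65.0, 75.0))
        e = 50000.0
        mats = {"m": LinearParams(e=e), "tumor": LinearParams(e=e)}
        f = displacement_field_at(geo, mats, load, t=8.0)
        traction = load.traction_at(8.0)
        # eps = -traction/E uniform, so u(z) = (traction/E) * (L - z)
        expected = (traction / e) * (geo.axial_mm - f.grid_axial_mm)
        assert np.allclose(f.ux_mm[:, 0], expected, rtol=1e-9, atol=1e-12)
        slope = np.polyfit(f.grid_axial_mm, f.ux_mm[:, 0], 1)[0]
        assert slope == pytest.approx(-traction / e, rel=0.01)

    def test_quasi_static_period_invariance(self, geometry, load):
        f1 = displacement_field_at(geometry, ALL_MATS, load, t=8.0)
        f2 = displacement_field_at(geometry, ALL_MATS, load, t=18.0)
        assert np.allclose(f1.ux_mm, f2.ux_mm)

    def test_small_load_matches_linear_elastic(self, geometry):
        tiny = LoadSpec(amplitude_pa=20.0)
        t = 2.5  # peak
        f_h = displacement_field_at(geometry, ALL_MATS, tiny, t)
        lin = {name: LinearParams(e=youngs_from_mr(p)) for name, p in ALL_MATS.items()}
        f_l = displacement_field_at(geometry, lin, tiny, t)
        scale = np.max(np.abs(f_l.ux_mm))
        assert np.max(np.abs(f_h.ux_mm - f_l.ux_mm)) < 0.01 * scale

    def test_monotone_in_traction(self, geometry):
        u = []
        for amp in (1000.0, 3000.0, 5000.0):
            f = displacement_field_at(geometry, ALL_MATS,
                                      LoadSpec(amplitude_pa=amp), t=2.5)
            u.append(np.max(np.abs(f.ux_mm)))
        assert u[0] < u[1] < u[2]

    def test_determinism(self, geometry, load):
        f1 = displacement_field_at(geometry, ALL_MATS, load, t=8.0)
        f2 = displacement_field_at(geometry, ALL_MATS, load, t=8.0)
        assert np.array_equal(f1.ux_mm, f2.ux_mm)
        assert np.array_equal(f1.uy_mm, f2.uy_mm)


class TestElasticReference:
    def test_zero_traction(self, geometry, load, known_materials):
        f = elastic_reference_field(geometry, load, t=0.0, e_pa=1.0,
                                    known_materials=known_materials)
        assert np.allclose(f.ux_mm, 0.0)

    def test_one_over_e_scaling(self, geometry, known_materials):
        tiny = LoadSpec(amplitude_pa=5.0)
        pts = default_tumor_points(geometry)
        ref_depth = geometry.tumor_axial_mm[1]
        f1 = elastic_reference_field(geometry, tiny, 2.5, e_pa=1000.0,
                                     known_materials=known_materials)
        f2 = elastic_reference_field(geometry, tiny, 2.5, e_pa=2000.0,
                                     known_materials=known_materials)
        y1 = sample_axial([f1], pts, relative_to_depth=ref_depth)
        y2 = sample_axial([f2], pts, relative_to_depth=ref_depth)
        assert np.allclose(y1, 2.0 * y2, rtol=0.01)

    def test_eight_instants(self, geometry, load, known_materials):
        fields = [elastic_reference_field(geometry, load, t,
                                          known_materials=known_materials)
                  for t in load.sample_times_s]
        assert len(fields) == 8
        assert [f.time_s for f in fields] == list(load.sample_times_s)


class TestSampleAxial:
    def _const_field(self, c):
        z = np.linspace(0.0, 100.0, 11)
        y = np.linspace(0.0, 60.0, 7)
        u = np.full((11, 7), c)
        return DisplacementField(z, y, u, np.zeros_like(u))

    def test_zero_field(self):
        f = self._const_field(0.0)
        out = sample_axial([f], [(70.0, 30.0), (66.0, 28.0)])
        assert np.allclose(out, 0.0)

    def test_constant_field(self):
        f = self._const_field(1.25)
        out = sample_axial([f], [(70.0, 30.0)])
        assert out[0] == pytest.approx(1.25)

    def test_bilinear_oracle(self):
        z = np.array([0.0, 10.0])
        y = np.array([0.0, 10.0])
        u = np.array([[0.0, 1.0], [2.0, 5.0]])
        f = DisplacementField(z, y, u, np.zeros_like(u))
        # manual bilinear interpolation at (2.5, 7.5)
        tz, ty = 0.25, 0.75
        expected = ((1 - tz) * (1 - ty) * 0.0 + (1 - tz) * ty * 1.0
                    + tz * (1 - ty) * 2.0 + tz * ty * 5.0)
        out = sample_axial([f], [(2.5, 7.5)])
        assert out[0] == pytest.approx(expected, rel=1e-12)

    def test_time_major_ordering(self):
        f1, f2 = self._const_field(1.0), self._const_field(2.0)
        out = sample_axial([f1, f2], [(70.0, 30.0), (66.0, 28.0)])
        assert np.allclose(out, [1.0, 1.0, 2.0, 2.0])

    def test_relative_to_depth(self, geometry, load):
        f = displacement_field_at(geometry, ALL_MATS, load, t=8.0)
        pts = [(70.0, 30.0)]
        raw = sample_axial([f], pts)
        rel = sample_axial([f], pts, relative_to_depth=75.0)
        at_face = sample_axial([f], [(75.0, 30.0)])
        assert rel[0] == pytest.approx(raw[0] - at_face[0], rel=1e-12)

    def test_outside_grid_raises(self):
        f = self._const_field(0.0)
        with pytest.raises(ValueError):
            sample_axial([f], [(150.0, 30.0)])


class TestDefaultTumorPoints:
    def test_twelve_points_inside(self, geometry):
        pts = default_tumor_points(geometry)
        assert len(pts) == 12
        z1, z2 = geometry.tumor_axial_mm
        y1, y2 = geometry.tumor_lateral_bounds()
        for z, y in pts:
            assert z1 < z < z2 and y1 < y < y2


class TestSerialization:
    def test_round_trip(self, tmp_path, geometry, load):
        f = displacement_field_at(geometry, ALL_MATS, load, t=8.0)
        path = tmp_path / "field.h5"
        save_field(path, f)
        back = load_field(path)
        assert np.array_equal(back.ux_mm, f.ux_mm)
        assert np.array_equal(back.uy_mm, f.uy_mm)
        assert back.time_s == f.time_s and back.role == f.role
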