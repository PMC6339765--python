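"""Unit tests for the iterative Mooney-Rivlin estimator."""

import numpy as np
import pytest

from elastinv.mr_core import BREAST_MATERIALS, stress_from_strain, youngs_from_mr
from elastinv.phantom_forward import (
    DisplacementField,
    default_tumor_points,
    displacement_field_at,
    elastic_reference_field,
)
from elastinv.inverse import (
    ObservationSet,
    StrainSchedule,
    Tolerances,
    assemble_observation,
    build_stress_set,
    estimate_modulus,
    fit_mr,
    iterate,
    observed_strains,
    percent_error,
)

ALL_MATS = dict(BREAST_MATERIALS)


def const_field(c: float, t: float = 0.0) -> DisplacementField:
    z = np.linspace(0.0, 100.0, 11)
    y = np.linspace(0.0, 60.0, 7)
    u = np.full((11, 7), c)
    return DisplacementField(z, y, u, np.zeros_like(u), time_s=t)


class TestObservationSet:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="congruent"):
            ObservationSet(np.ones(4), np.ones(3), [(70.0, 30.0)],
                           times=(1.0, 2.0, 3.0, 4.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="n_points"):
            ObservationSet(np.ones(5), np.ones(5), [(70.0, 30.0)],
                           times=(1.0, 2.0))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ObservationSet(np.ones(2), np.zeros(2), [(70.0, 30.0)],
                           times=(1.0, 2.0))


class TestEstimateModulus:
    def test_identical_vectors_give_reference_modulus(self):
        d = np.array([0.1, -0.2, 0.3])
        assert estimate_modulus(d, d, e_ref=1.0) == pytest.approx(1.0)

    def test_half_response_doubles_modulus(self):
        d = np.array([0.1, -0.2, 0.3])
        assert estimate_modulus(d, d / 2.0) == pytest.approx(2.0)

    def test_scaling_with_reference(self):
        d = np.array([1.0, 2.0])
        assert estimate_modulus(d, d / 5.0, e_ref=3.0) == pytest.approx(15.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero norm"):
            estimate_modulus(np.zeros(3), np.ones(3))

    def test_opposite_sign_rejected(self):
        d = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="slope"):
            estimate_modulus(d, -d)

    def test_incongruent_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            estimate_modulus(np.ones(3), np.ones(4))


class TestBuildStressSet:
    def test_proportional_without_jitter(self):
        eps = np.array([-0.02, -0.05, -0.1])
        sigma = build_stress_set(50000.0, eps)
        assert np.allclose(sigma, 50000.0 * eps)

    def test_jitter_spread(self):
        eps = np.full(2000, -0.05)
        rng = np.random.default_rng(4)
        sigma = build_stress_set(1000.0, eps, jitter_rel=0.1, rng=rng)
        rel = sigma / (1000.0 * eps) - 1.0
        assert abs(np.mean(rel)) < 0.01
        assert np.std(rel) == pytest.approx(0.1, rel=0.1)

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            build_stress_set(1000.0, np.array([0.0, -0.05]))


class TestFitMR:
    def test_exact_recovery_from_mr_law(self, tumor):
        eps = -np.linspace(0.01, 0.10, 10)
        sigma = stress_from_strain(tumor, eps)
        p = fit_mr(eps, sigma)
        assert p.c10 == pytest.approx(tumor.c10, rel=1e-9)
        assert p.c01 == pytest.approx(tumor.c01, rel=1e-9)

    def test_linear_law_recovers_modulus_sum(self):
        e = 90000.0
        eps = -np.linspace(0.01, 0.10, 10)
        p = fit_mr(eps, e * eps)
        assert youngs_from_mr(p) == pytest.approx(e, rel=0.02)

    def test_permutation_invariance(self, tumor):
        eps = -np.linspace(0.02, 0.2, 8)
        sigma = stress_from_strain(tumor, eps)
        perm = np.random.default_rng(1).permutation(len(eps))
        p1 = fit_mr(eps, sigma)
        p2 = fit_mr(eps[perm], sigma[perm])
        assert p1.c10 == pytest.approx(p2.c10)
        assert p1.c01 == pytest.approx(p2.c01)

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_mr(np.array([-0.05, -0.05]), np.array([-100.0, -100.0]))

    def test_incongruent_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            fit_mr(np.array([-0.05, -0.1]), np.array([-100.0]))

    def test_nonphysical_fit_rejected(self):
        eps = -np.linspace(0.01, 0.1, 5)
        with pytest.raises(ValueError, match="nonphysical"):
            fit_mr(eps, -1000.0 * eps)  # negative apparent modulus


class TestAssembleObservation:
    def test_matches_plain_sampling(self):
        fields = [const_field(1.0), const_field(2.0)]
        pts = [(70.0, 30.0), (66.0, 28.0)]
        out = assemble_observation(fields, pts)
        assert np.allclose(out, [1.0, 1.0, 2.0, 2.0])

    def test_baseline_first_differences_blocks(self):
        fields = [const_field(1.0), const_field(2.0), const_field(5.0)]
        pts = [(70.0, 30.0), (66.0, 28.0)]
        out = assemble_observation(fields, pts, baseline_first=True)
        assert np.allclose(out, [0.0, 0.0, 1.0, 1.0, 4.0, 4.0])

    def test_baseline_first_constant_fields_vanish(self):
        fields = [const_field(3.0)] * 4
        out = assemble_observation(fields, [(70.0, 30.0)], baseline_first=True)
        assert np.allclose(out, 0.0)


class TestObservedStrains:
    def test_lever_formula(self):
        eps = -0.04
        pts = [(70.0, 30.0), (66.0, 28.0)]
        ref_depth = 75.0
        y = np.array([-eps * (ref_depth - z) for z, _ in pts] * 2)
        obs = ObservationSet(y, np.ones_like(y), pts, times=(1.0, 2.0),
                             ref_depth_mm=ref_depth)
        assert np.allclose(observed_strains(obs), eps)

    def test_requires_relative_sampling(self):
        obs = ObservationSet(np.ones(2), np.ones(2), [(70.0, 30.0)],
                             times=(1.0, 2.0))
        with pytest.raises(ValueError, match="relative"):
            observed_strains(obs)

    def test_rejects_baseline_differenced(self):
        obs = ObservationSet(np.ones(2), np.ones(2), [(70.0, 30.0)],
                             times=(1.0, 2.0), ref_depth_mm=75.0,
                             baseline_first=True)
        with pytest.raises(ValueError, match="changes"):
            observed_strains(obs)


class TestTolerances:
    def test_resolved_defaults(self):
        y = np.array([0.0, -2.0, 1.0])
        t = Tolerances().resolved(y, e_realt=90000.0)
        assert t.e_displacement == pytest.approx(0.02)
        assert t.e_elastic == pytest.approx(900.0)
        assert t.e_displacement_prime == pytest.approx(0.002)
        assert t.e_elastic_prime == pytest.approx(90.0)

    def test_explicit_values_kept(self):
        t = Tolerances(e_displacement=0.5, max_iterations=7)
        r = t.resolved(np.ones(3), 1000.0)
        assert r.e_displacement == 0.5
        assert r.max_iterations == 7


class TestStrainSchedule:
    def test_defaults_valid(self):
        s = StrainSchedule()
        assert np.all(s.initial_strains < 0.0)
        assert len(s.initial_strains) == 10

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            StrainSchedule(initial_strains=np.array([0.0, -0.1]))
        with pytest.raises(ValueError):
            StrainSchedule(decay=0.0)
        with pytest.raises(ValueError):
            StrainSchedule(jitter_rel=-0.1)


def make_exact_observation(geometry, load, known_materials):
    pts = default_tumor_points(geometry)
    ref_depth = geometry.tumor_axial_mm[1]
    fields = [displacement_field_at(geometry, ALL_MATS, load, t)
              for t in load.sample_times_s]
    y = assemble_observation(fields, pts, ref_depth_mm=ref_depth)
    ref_fields = [elastic_reference_field(geometry, load, t, e_pa=1.0,
                                          known_materials=known_materials)
                  for t in load.sample_times_s]
    d = assemble_observation(ref_fields, pts, ref_depth_mm=ref_depth)
    return ObservationSet(y, d, pts, times=load.sample_times_s,
                          ref_depth_mm=ref_depth)


@pytest.fixture(scope="module")
def exact_obs(geometry, load, known_materials):
    return make_exact_observation(geometry, load, known_materials)


@pytest.fixture(scope="module")
def exact_result(exact_obs, geometry, load, known_materials):
    return iterate(exact_obs, geometry, known_materials, load)


class TestIterate:
    def test_converges_on_exact_data(self, exact_result):
        assert exact_result.converged
        assert exact_result.iterations <= 50

    def test_modulus_sum_recovered(self, exact_result, tumor):
        e_true = youngs_from_mr(tumor)
        assert percent_error(e_true, youngs_from_mr(exact_result.params)) < 2.0

    def test_forward_verification_residuals(self, exact_obs, exact_result):
        best = exact_result.best
        scale = np.max(np.abs(exact_obs.y_realt))
        assert best.disp_residual <= 0.01 * scale
        assert best.elastic_residual <= 0.01 * exact_result.e_realt

    def test_strain_scale_decays(self, exact_obs, geometry, load,
                                 known_materials):
        res = iterate(exact_obs, geometry, known_materials, load,
                      schedule=StrainSchedule(decay=0.8),
                      tol=Tolerances(e_displacement=0.0, e_elastic=0.0,
                                     max_iterations=4))
        scales = [r.strain_scale for r in res.trace]
        assert len(scales) == 4
        for a, b in zip(scales, scales[1:]):
            assert b == pytest.approx(0.8 * a, rel=1e-9)

    def test_cap_reached_reports_not_converged(self, exact_obs, geometry,
                                               load, known_materials):
        res = iterate(exact_obs, geometry, known_materials, load,
                      schedule=StrainSchedule(decay=1.0),
                      tol=Tolerances(e_displacement=0.0, e_elastic=0.0,
                                     max_iterations=3))
        assert not res.converged
        assert res.iterations == 3
        # best falls back to the smallest displacement residual
        assert res.best.disp_residual == min(r.disp_residual for r in res.trace)

    def test_to_dict_round_trip_fields(self, exact_result):
        d = exact_result.to_dict()
        assert d["converged"] is True
        assert d["c10_pa"] == exact_result.best.c10
        assert len(d["trace"]) == exact_result.iterations


class TestPercentError:
    def test_basic(self):
        assert percent_error(100.0, 89.0) == pytest.approx(11.0)
        assert percent_error(100.0, 111.0) == pytest.approx(11.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            percent_error(0.0, 1.0)
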