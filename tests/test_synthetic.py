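import dataclasses
import math

import numpy as np
import pytest

from gutmech import biomechanics as bm
from gutmech.synthetic import (
    GrowthCohortSpec,
    PeristalsisMovieSpec,
    ResponseLaw,
    TubePhantomSpec,
    cohort_to_frame,
    generate_calibration_data,
    generate_growth_cohort,
    generate_peristalsis_movie,
    generate_tube_image,
    incompressible_rescale,
)


def sinusoid_truth(length, d0, taper, amp, lam, n=200_001):
    """Independent oracle: arclength, mean diameter and volume of the
    analytic sinusoid tube by fine-grained quadrature."""
    # march x until arclength reaches `length`
    x = np.linspace(0.0, 4 * length, n)
    y = amp * np.sin(2 * np.pi * x / lam)
    seg = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, length, n)
    r = 0.5 * d0 * (1 + taper * s / length)
    volume = np.trapezoid(np.pi * r * r, s)
    mean_d = np.trapezoid(2 * r, s) / length
    assert cum[-1] > length  # oracle domain check
    return length, mean_d, volume


class TestTubePhantom:
    def test_cylinder_truth_closed_form(self):
        spec = TubePhantomSpec(midline_kind="straight", length_mm=10.0,
                               base_diameter_mm=0.4, scale_mm_per_px=0.01)
        truth = generate_tube_image(spec).truth
        assert truth.volume_mm3 == pytest.approx(math.pi * 0.2**2 * 10, rel=1e-6)
        assert truth.length_mm == 10.0
        assert truth.mean_diameter_mm == pytest.approx(0.4, rel=1e-9)

    def test_sinusoid_truth_vs_quadrature_oracle(self):
        spec = TubePhantomSpec(midline_kind="sinusoid", length_mm=10.0,
                               base_diameter_mm=0.4, bend_amplitude_mm=0.8,
                               bend_wavelength_mm=5.0, scale_mm_per_px=0.01)
        truth = generate_tube_image(spec).truth
        L, d, v = sinusoid_truth(10.0, 0.4, 0.0, 0.8, 5.0)
        assert truth.length_mm == pytest.approx(L, rel=1e-6)
        assert truth.volume_mm3 == pytest.approx(v, rel=1e-4)
        assert truth.mean_diameter_mm == pytest.approx(d, rel=1e-6)

    def test_taper_mean_diameter(self):
        spec = TubePhantomSpec(length_mm=10.0, base_diameter_mm=0.4,
                               taper=-0.5, scale_mm_per_px=0.01)
        truth = generate_tube_image(spec).truth
        profile = np.array(truth.diameter_profile)
        assert profile[-1, 1] == pytest.approx(0.2, rel=1e-9)   # tip diameter
        assert truth.mean_diameter_mm == pytest.approx(0.3, rel=1e-6)

    def test_raster_area_within_2pct(self):
        for scale in (0.02, 0.01):  # d/20 and d/40
            spec = TubePhantomSpec(length_mm=10.0, base_diameter_mm=0.4,
                                   scale_mm_per_px=scale)
            ph = generate_tube_image(spec)
            area = ph.mask.sum() * scale * scale
            analytic = 10.0 * 0.4 + math.pi * 0.2**2  # capped ends
            assert area == pytest.approx(analytic, rel=0.02)

    def test_deterministic(self):
        spec = TubePhantomSpec(midline_kind="spline", length_mm=10.0,
                               base_diameter_mm=0.4, bend_amplitude_mm=0.5,
                               noise_sd_px=1.0, scale_mm_per_px=0.02, seed=5)
        a = generate_tube_image(spec)
        b = generate_tube_image(spec)
        assert np.array_equal(a.image, b.image)
        assert a.truth == b.truth

    def test_self_overlap_rejected(self):
        spec = TubePhantomSpec(midline_kind="sinusoid", length_mm=10.0,
                               base_diameter_mm=0.9, bend_amplitude_mm=2.0,
                               bend_wavelength_mm=3.0, scale_mm_per_px=0.02)
        with pytest.raises(ValueError, match="overlap|curvature"):
            generate_tube_image(spec)

    def test_not_tubular_rejected(self):
        with pytest.raises(ValueError, match="tubular"):
            TubePhantomSpec(length_mm=1.0, base_diameter_mm=0.4)

    def test_mask_single_component_no_holes(self):
        spec = TubePhantomSpec(midline_kind="sinusoid", length_mm=10.0,
                               base_diameter_mm=0.4, bend_amplitude_mm=0.8,
                               bend_wavelength_mm=5.0, scale_mm_per_px=0.02)
        mask = generate_tube_image(spec).mask
        from scipy import ndimage
        _, n = ndimage.label(mask)
        assert n == 1
        assert np.array_equal(ndimage.binary_fill_holes(mask), mask)


class TestResponseLaw:
    def test_zero_stress_defaults(self):
        law = ResponseLaw()
        assert law.length_pct(0.0) == pytest.approx(-18.0)
        assert law.volume_pct(0.0) == pytest.approx(2.0)
        # diameter from the axisymmetric identity (1+dV) = (1+dl)(1+dd)^2
        expected = (math.sqrt(1.02 / 0.82) - 1) * 100
        assert law.diameter_pct(0.0) == pytest.approx(expected)

    def test_150_pa_anchor(self):
        law = ResponseLaw()
        assert law.length_pct(150.0) == pytest.approx(200.0)
        assert law.volume_pct(150.0) == pytest.approx(180.0)

    def test_identity_holds_at_any_stress(self):
        law = ResponseLaw()
        for sigma in (0.0, 60.0, 150.0):
            fl = 1 + law.length_pct(sigma) / 100
            fd = 1 + law.diameter_pct(sigma) / 100
            fv = 1 + law.volume_pct(sigma) / 100
            assert fl * fd * fd == pytest.approx(fv, rel=1e-12)


class TestGrowthCohort:
    def test_noise_free_records_on_the_line(self):
        spec = GrowthCohortSpec(n_specimens=9, mass_mg_choices=(0.0, 1.0, 1.5),
                                noise_sd_pct=(0.0, 0.0, 0.0), seed=3)
        law = spec.response_law
        for rec in generate_growth_cohort(spec):
            sigma = rec.stress.stress_Pa
            assert rec.rel_changes["length"] * 100 == pytest.approx(law.length_pct(sigma), abs=1e-9)
            assert rec.rel_changes["volume"] * 100 == pytest.approx(law.volume_pct(sigma), abs=1e-9)
            assert rec.rel_changes["diameter"] * 100 == pytest.approx(law.diameter_pct(sigma), abs=1e-9)

    def test_control_means(self):
        spec = GrowthCohortSpec(n_specimens=4, mass_mg_choices=(0.0,),
                                noise_sd_pct=(0.0, 0.0, 0.0), seed=1)
        for rec in generate_growth_cohort(spec):
            assert rec.stress.stress_Pa == 0.0
            assert rec.rel_changes["length"] == pytest.approx(-0.18)
            assert rec.rel_changes["volume"] == pytest.approx(0.02)

    def test_zero_stress_signs(self):
        # control behaviour: expected length change negative, volume ~ 0
        law = ResponseLaw()
        assert law.length_pct(0.0) < 0
        assert abs(law.volume_pct(0.0)) < 10

    def test_dry_mass_and_cells_follow_density_model(self):
        spec = GrowthCohortSpec(n_specimens=6, mass_mg_choices=(0.0, 1.0), seed=2)
        for rec in generate_growth_cohort(spec):
            rho = (spec.refs.rho_ctl_mg_mm3 if rec.load.mass_mg == 0
                   else spec.refs.rho_tension_mg_mm3)
            assert rec.dry_mass_final_mg == pytest.approx(rho * rec.after.volume_mm3)
            assert rec.cell_count_final == pytest.approx(
                spec.refs.n_cultured_cells_mm3 * rec.after.volume_mm3)

    def test_deterministic(self):
        spec = GrowthCohortSpec(n_specimens=2, seed=11)
        a = cohort_to_frame(generate_growth_cohort(spec))
        b = cohort_to_frame(generate_growth_cohort(spec))
        assert a.equals(b)

    def test_volumes_positive_under_heavy_noise(self):
        spec = GrowthCohortSpec(n_specimens=30, noise_sd_pct=(6.0, 80.0, 7.0), seed=4)
        frame = cohort_to_frame(generate_growth_cohort(spec))
        assert (frame["V1_mm3"] > 0).all()

    def test_incompressible_rescale_conserves_volume(self):
        from gutmech.morphometry import TubeMorphometry
        tm = TubeMorphometry(length_mm=10.0, mean_diameter_mm=0.4,
                             volume_mm3=math.pi * 0.04 * 10)
        scaled = incompressible_rescale(tm, 0.25)
        assert scaled.volume_mm3 == tm.volume_mm3
        # consistency: cylinder volume from scaled L, d also unchanged
        v = math.pi * scaled.mean_diameter_mm**2 / 4 * scaled.length_mm
        assert v == pytest.approx(tm.volume_mm3, rel=1e-12)


class TestPeristalsisMovie:
    def test_truth_by_construction(self):
        spec = PeristalsisMovieSpec(frames=600, frame_interval_s=2.0,
                                    wave_frequency_mHz=15.0, wave_speed_mm_s=0.1)
        _, truth = generate_peristalsis_movie(spec)
        assert truth.frequency_mHz == 15.0
        assert truth.speed_mm_s == 0.1
        assert truth.n_waves == 18
        assert truth.direction == "forward"

    def test_zero_frequency_static(self):
        spec = PeristalsisMovieSpec(frames=50, frame_interval_s=2.0,
                                    wave_frequency_mHz=0.0, wave_speed_mm_s=0.0)
        stack, truth = generate_peristalsis_movie(spec)
        assert truth.frequency_mHz == 0.0
        assert all(np.array_equal(stack[0], f) for f in stack)

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            PeristalsisMovieSpec(frames=600, frame_interval_s=2.0,
                                 wave_frequency_mHz=300.0)

    def test_too_short_movie(self):
        with pytest.raises(ValueError, match="period"):
            PeristalsisMovieSpec(frames=10, frame_interval_s=2.0,
                                 wave_frequency_mHz=10.0)

    def test_deterministic(self):
        spec = PeristalsisMovieSpec(frames=100, frame_interval_s=2.0,
                                    wave_frequency_mHz=20.0, wave_speed_mm_s=0.1)
        a, _ = generate_peristalsis_movie(spec)
        b, _ = generate_peristalsis_movie(spec)
        assert np.array_equal(a, b)


class TestCalibrationData:
    def test_exact_line(self):
        s = 3.3e6
        table = generate_calibration_data(s, [1.0, 2.0, 3.0, 4.0])
        force = table["mass_mg"] * 1e-6 * bm.STANDARD_GRAVITY_M_S2
        assert np.allclose(table["deflection_deg"], s * force)
        assert len(table) == 4

    def test_noise_reproducible(self):
        a = generate_calibration_data(3e6, [1, 2, 3, 4], noise_sd_deg=0.5, seed=9)
        b = generate_calibration_data(3e6, [1, 2, 3, 4], noise_sd_deg=0.5, seed=9)
        assert a.equals(b)
        c = generate_calibration_data(3e6, [1, 2, 3, 4], noise_sd_deg=0.5, seed=10)
        assert not a.equals(c)

    def test_non_increasing_masses_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_calibration_data(3e6, [2.0, 1.0, 3.0])
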