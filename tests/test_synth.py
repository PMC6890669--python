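"""Forward simulator: traction patterns, elastic response, bead rendering."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from tfmkit import (
    ElasticSubstrate,
    NoiseModel,
    VectorField2D,
    ar1_traction_schedule,
    forward_displacement,
    generate_traction_pattern,
    random_bead_field,
    render_bead_images,
    simulate_movie,
)


class TestGenerateTractionPattern:
    def test_zero_mean_and_peak_scaling(self):
        pat = generate_traction_pattern((64, 64), 1.6, 150.0, 8.0, seed=1)
        assert abs(pat.field.u_x.mean()) < 1e-12
        assert abs(pat.field.u_y.mean()) < 1e-12
        assert np.isclose(pat.field.magnitude().max(), 150.0)

    def test_deterministic_given_seed(self):
        a = generate_traction_pattern((32, 32), 1.6, 100.0, 8.0, seed=7)
        b = generate_traction_pattern((32, 32), 1.6, 100.0, 8.0, seed=7)
        assert np.array_equal(a.field.u_x, b.field.u_x)
        assert np.array_equal(a.field.u_y, b.field.u_y)
        c = generate_traction_pattern((32, 32), 1.6, 100.0, 8.0, seed=8)
        assert not np.array_equal(a.field.u_x, c.field.u_x)

    def test_peak_stress_rescale_is_linear(self):
        lo = generate_traction_pattern((32, 32), 1.6, 1e-3, 8.0, seed=3)
        hi = generate_traction_pattern((32, 32), 1.6, 1.0, 8.0, seed=3)
        assert np.allclose(lo.field.u_x * 1e3, hi.field.u_x)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"peak_stress": 0.0},
            {"peak_stress": -5.0},
            {"spacing": 0.0},
            {"correlation_length": 1.0},  # < 2 * spacing
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        params = dict(shape=(32, 32), spacing=1.6, peak_stress=100.0,
                      correlation_length=8.0, seed=0)
        params.update(kwargs)
        with pytest.raises(ValueError):
            generate_traction_pattern(**params)


class TestForwardDisplacement:
    def test_zero_traction_gives_zero_displacement(self, soft_substrate):
        tau = VectorField2D(np.zeros((32, 32)), np.zeros((32, 32)), spacing=1.6)
        u = forward_displacement(tau, soft_substrate)
        assert np.allclose(u.u_x, 0) and np.allclose(u.u_y, 0)

    def test_linearity_in_traction(self, soft_substrate):
        p1 = generate_traction_pattern((48, 48), 1.6, 100.0, 8.0, seed=1).field
        p2 = generate_traction_pattern((48, 48), 1.6, 100.0, 8.0, seed=2).field
        lhs = forward_displacement(2.0 * p1 + 3.0 * p2, soft_substrate)
        rhs = 2.0 * forward_displacement(p1, soft_substrate) + 3.0 * forward_displacement(
            p2, soft_substrate
        )
        assert np.allclose(lhs.u_x, rhs.u_x, atol=1e-12)
        assert np.allclose(lhs.u_y, rhs.u_y, atol=1e-12)

    def test_stiffness_scaling_is_exact(self, smooth_pattern, soft_substrate, stiff_substrate):
        """Fixed traction: displacements on 35 kPa are exactly 3/35 of 3 kPa."""
        u_soft = forward_displacement(smooth_pattern, soft_substrate)
        u_stiff = forward_displacement(smooth_pattern, stiff_substrate)
        assert np.allclose(u_stiff.u_x * (35.0 / 3.0), u_soft.u_x, rtol=1e-13)
        assert np.isclose(u_stiff.norm() / u_soft.norm(), 3.0 / 35.0, rtol=1e-13)

    def test_matches_boussinesq_point_load_solution(self):
        """A localized tangential load reproduces the analytic half-space
        surface response u_x(r) = F (1 + nu) / (pi E r) along the load axis,
        up to the unobservable additive constant of the periodic solver."""
        n, h = 256, 0.5
        E, nu = 3000.0, 0.45
        x = np.arange(n) * h
        X, Y = np.meshgrid(x, x)
        x0 = y0 = n * h / 2
        sig = 1.0
        g = np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sig**2))
        F = 1000.0  # pN
        tau_x = g / (g.sum() * h * h) * F
        tau_x -= tau_x.mean()
        fld = VectorField2D(tau_x, np.zeros_like(tau_x), spacing=h)
        u = forward_displacement(fld, ElasticSubstrate(E, nu))
        row = np.argmin(np.abs(x - y0))
        radii = np.array([4.0, 8.0, 16.0, 24.0, 32.0])  # h << r <= domain/4
        num = np.array([u.u_x[row, np.argmin(np.abs(x - (x0 + r)))] for r in radii])
        ana = F * (1 + nu) / (np.pi * E * radii)
        offset = np.mean(ana - num)  # zero-frequency mode convention
        rel_dev = np.abs((num + offset) - ana) / ana
        assert rel_dev.max() < 0.05

    def test_strain_energy_of_ground_truth_nonnegative(self, soft_substrate):
        """G is positive semidefinite: tau . u integrates to >= 0."""
        for seed in range(5):
            pat = generate_traction_pattern((48, 48), 1.6, 150.0, 8.0, seed=seed)
            u = forward_displacement(pat, soft_substrate)
            us = 0.5 * np.sum(pat.field.u_x * u.u_x + pat.field.u_y * u.u_y)
            assert us >= 0


class TestRenderBeadImages:
    def test_zero_displacement_zero_noise_identity(self, bead_scene):
        beads, _ = bead_scene
        ref, deformed = render_bead_images(beads, None, (256, 256), 0.2)
        assert np.array_equal(ref.pixels, deformed.pixels)

    def test_uniform_shift_detected_by_phase_correlation(self, bead_scene):
        beads, _ = bead_scene
        u = VectorField2D(
            np.full((33, 33), 3.7 * 0.2), np.zeros((33, 33)), spacing=8 * 0.2
        )
        ref, deformed = render_bead_images(beads, u, (256, 256), 0.2)
        shift, _, _ = phase_cross_correlation(
            ref.pixels, deformed.pixels, upsample_factor=100
        )
        # content moved +3.7 px in x => registration shift is (0, -3.7)
        assert abs(shift[1] + 3.7) < 0.05
        assert abs(shift[0]) < 0.05

    def test_rendering_linear_in_amplitude(self, bead_scene):
        beads, ref = bead_scene
        doubled = random_bead_field((256, 256), 0.2, seed=1)
        doubled.amplitudes = beads.amplitudes * 2.0
        doubled.positions = beads.positions
        ref2, _ = render_bead_images(doubled, None, (256, 256), 0.2)
        assert np.allclose(ref2.pixels, 2.0 * ref.pixels)

    def test_noise_statistics_match_configuration(self, bead_scene):
        beads, clean = bead_scene
        sd = 6.0
        noisy, _ = render_bead_images(
            beads, None, (256, 256), 0.2, noise=NoiseModel(gaussian_sd=sd), seed=5
        )
        resid = noisy.pixels - clean.pixels
        # background pixels (no clipping at zero distorting the estimate)
        bg = clean.pixels > 1.0
        assert abs(resid[bg].std() - sd) / sd < 0.1

    def test_noise_deterministic_under_seed(self, bead_scene, noise_20db):
        beads, _ = bead_scene
        a, _ = render_bead_images(beads, None, (128, 128), 0.2, noise=noise_20db, seed=9)
        b, _ = render_bead_images(beads, None, (128, 128), 0.2, noise=noise_20db, seed=9)
        assert np.array_equal(a.pixels, b.pixels)


class TestSimulateMovie:
    def test_movie_layout_and_cadence(self, soft_substrate):
        sched = [
            generate_traction_pattern((64, 64), 1.6, 100.0, 8.0, seed=s)
            for s in range(3)
        ]
        beads = random_bead_field((512, 512), 0.2, seed=2)
        movie = simulate_movie(
            sched, soft_substrate, beads, cadence=10.0,
            fov_shape_px=(256, 256), pixel_size=0.2,
        )
        assert len(movie.sequence) == 4  # 3 deformed + 1 reference
        assert movie.reference_index == 3
        assert np.allclose(movie.sequence.timestamps[:3], [0.0, 10.0, 20.0])
        assert len(movie.ground_truth) == 3
        # 48 frames at 10-min cadence span 470 min (~8 h recording)
        assert (48 - 1) * 10.0 == 470.0

    def test_ground_truth_energy_filled_and_nonnegative(self, soft_substrate):
        sched = [generate_traction_pattern((64, 64), 1.6, 100.0, 8.0, seed=5)]
        beads = random_bead_field((512, 512), 0.2, seed=2)
        movie = simulate_movie(
            sched, soft_substrate, beads, fov_shape_px=(256, 256), pixel_size=0.2
        )
        assert sched[0].ground_truth_strain_energy is not None
        assert sched[0].ground_truth_strain_energy >= 0

    def test_mismatched_grids_rejected(self, soft_substrate):
        sched = [
            generate_traction_pattern((64, 64), 1.6, 100.0, 8.0, seed=0),
            generate_traction_pattern((32, 32), 1.6, 100.0, 8.0, seed=1),
        ]
        beads = random_bead_field((512, 512), 0.2, seed=2)
        with pytest.raises(ValueError, match="grid"):
            simulate_movie(sched, soft_substrate, beads, fov_shape_px=(256, 256))


class TestAR1Schedule:
    def test_constant_schedule_limit(self, soft_substrate):
        """rho -> 1 limit: identical frames correlate perfectly at all lags."""
        pat = generate_traction_pattern((48, 48), 1.6, 100.0, 8.0, seed=0)
        from tfmkit import deformation_correlation

        fields = [forward_displacement(pat, soft_substrate)] * 5
        tab = deformation_correlation(fields)
        assert np.allclose(tab["correlation"], 1.0)

    def test_stationary_scale_and_determinism(self):
        sched = ar1_traction_schedule(10, 0.8, (48, 48), 1.6, 100.0, 8.0, seed=3)
        peak = max(p.field.magnitude().max() for p in sched)
        assert np.isclose(peak, 100.0)
        sched2 = ar1_traction_schedule(10, 0.8, (48, 48), 1.6, 100.0, 8.0, seed=3)
        assert np.array_equal(sched[3].field.u_x, sched2[3].field.u_x)
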