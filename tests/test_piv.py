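"""Displacement estimation: correlation, subpixel fit, validation, drift."""

import numpy as np
import pytest

from tfmkit import (
    ImageFrame,
    ImageSequence,
    PIVSettings,
    VectorField2D,
    estimate_displacement,
    random_bead_field,
    reference_from_sequence,
    register_sequence,
    render_bead_images,
    validate_and_fill,
)
from tfmkit.piv import ReferencePolicy


def _interior_mask(grid_shape, frame_shape, settings):
    """Nodes whose search region lies fully inside the frame."""
    ny, nx = grid_shape
    m = np.zeros((ny, nx), dtype=bool)
    w, st, sm = settings.window_size, settings.step, settings.search_margin
    for i in range(ny):
        for j in range(nx):
            r0, c0 = i * st, j * st
            m[i, j] = (
                r0 - sm >= 0
                and c0 - sm >= 0
                and r0 + w + sm <= frame_shape[0]
                and c0 + w + sm <= frame_shape[1]
            )
    return m


def _crop_pair(seed=1, shift=(5, -3), size=256, margin=8):
    """Exactly translated image pair built as two crops of one rendering."""
    big = size + 2 * margin
    beads = random_bead_field((big, big), 0.2, seed=seed)
    full, _ = render_bead_images(beads, None, (big, big), 0.2)
    dx, dy = shift
    ref = ImageFrame(full.pixels[margin : margin + size, margin : margin + size], 0.2)
    deformed = ImageFrame(
        full.pixels[margin - dy : margin - dy + size, margin - dx : margin - dx + size],
        0.2,
    )
    return ref, deformed


class TestEstimateDisplacement:
    def test_identity_pair_gives_zero_field(self, bead_scene):
        _, ref = bead_scene
        f = estimate_displacement(ref, ref)
        assert f.valid_mask.any()
        assert np.allclose(f.u_x[f.valid_mask], 0)
        assert np.allclose(f.u_y[f.valid_mask], 0)

    def test_integer_shift_recovered_exactly(self):
        """Interior nodes (search region fully inside the frame) report
        the rigid shift without any error; border nodes are best-effort
        and left to downstream validation."""
        ref, deformed = _crop_pair(shift=(5, -3))
        s = PIVSettings()
        f = estimate_displacement(ref, deformed, s)
        px = 0.2
        m = f.valid_mask & _interior_mask(f.shape, ref.shape, s)
        assert m.sum() > 0.6 * m.size
        assert np.abs(f.u_x[m] / px - 5).max() < 1e-12
        assert np.abs(f.u_y[m] / px + 3).max() < 1e-12

    def test_subpixel_shift_rms_below_005px(self, bead_scene):
        beads, _ = bead_scene
        u = VectorField2D(
            np.full((33, 33), 0.30 * 0.2), np.zeros((33, 33)), spacing=8 * 0.2
        )
        ref, deformed = render_bead_images(beads, u, (256, 256), 0.2)
        f = estimate_displacement(ref, deformed)
        m = f.valid_mask
        err = np.sqrt(np.mean((f.u_x[m] / 0.2 - 0.30) ** 2 + (f.u_y[m] / 0.2) ** 2))
        assert err < 0.05

    def test_shift_equivariance(self):
        """Translating both frames together leaves interior vectors unchanged."""
        ref_a, def_a = _crop_pair(shift=(3, 2), margin=16)
        # same scene, both crops moved by (8, 8)
        big = 256 + 32
        beads = random_bead_field((big, big), 0.2, seed=1)
        full, _ = render_bead_images(beads, None, (big, big), 0.2)
        ref_b = ImageFrame(full.pixels[24:280, 24:280], 0.2)
        def_b = ImageFrame(full.pixels[24 - 2 : 280 - 2, 24 - 3 : 280 - 3], 0.2)
        fa = estimate_displacement(ref_a, def_a)
        fb = estimate_displacement(ref_b, def_b)
        m = fa.valid_mask & fb.valid_mask
        # interior ring only (one extra node in from the validity boundary)
        inner = np.zeros_like(m)
        inner[3:-3, 3:-3] = True
        m &= inner
        assert np.allclose(fa.u_x[m], fb.u_x[m], atol=1e-9)

    def test_antisymmetry_on_noiseless_pair(self, bead_scene):
        beads, _ = bead_scene
        u = VectorField2D(
            np.full((33, 33), 0.4 * 0.2), np.full((33, 33), -0.25 * 0.2), spacing=1.6
        )
        ref, deformed = render_bead_images(beads, u, (256, 256), 0.2)
        fwd = estimate_displacement(ref, deformed)
        rev = estimate_displacement(deformed, ref)
        m = fwd.valid_mask & rev.valid_mask
        sum_px = np.sqrt(
            np.mean(
                ((fwd.u_x[m] + rev.u_x[m]) / 0.2) ** 2
                + ((fwd.u_y[m] + rev.u_y[m]) / 0.2) ** 2
            )
        )
        assert sum_px < 0.05

    def test_output_grid_geometry(self, bead_scene):
        _, ref = bead_scene
        s = PIVSettings(window_size=32, step=8)
        f = estimate_displacement(ref, ref, s)
        expected = (256 - 32) // 8 + 1
        assert f.shape == (expected, expected)
        assert np.isclose(f.spacing, 8 * 0.2)

    def test_constant_window_marked_invalid_not_raised(self):
        ref = ImageFrame(np.ones((64, 64)), 0.2)
        deformed = ImageFrame(np.ones((64, 64)), 0.2)
        f = estimate_displacement(ref, deformed, PIVSettings(window_size=16, step=8, search_margin=4))
        assert not f.valid_mask.all()

    def test_shape_mismatch_raises(self, bead_scene):
        _, ref = bead_scene
        other = ImageFrame(np.zeros((128, 128)), 0.2)
        with pytest.raises(ValueError, match="shape"):
            estimate_displacement(ref, other)


class TestValidateAndFill:
    def _smooth_field(self, seed=2, shape=(40, 40)):
        from tfmkit import generate_traction_pattern

        pat = generate_traction_pattern(shape, 1.6, 1.0, 8.0, seed=seed)
        return VectorField2D(pat.field.u_x.copy(), pat.field.u_y.copy(), spacing=1.6)

    def test_clean_field_unchanged(self):
        """A smooth displacement field with ordinary measurement noise —
        and no outliers — passes validation untouched: 0 replacements."""
        from tfmkit import ElasticSubstrate, forward_displacement, generate_traction_pattern

        pat = generate_traction_pattern((40, 40), 1.6, 200.0, 12.0, seed=2)
        u = forward_displacement(pat, ElasticSubstrate(3000.0, 0.45))
        rng = np.random.default_rng(0)
        f = VectorField2D(
            u.u_x + rng.normal(0, 0.01, u.shape),  # 0.05 px at 0.2 um/px
            u.u_y + rng.normal(0, 0.01, u.shape),
            spacing=1.6,
        )
        out = validate_and_fill(f)
        assert np.array_equal(out.u_x, f.u_x)
        assert np.array_equal(out.u_y, f.u_y)

    def test_single_spike_replaced_by_neighbor_median(self):
        ux = np.ones((5, 5))
        uy = np.zeros((5, 5))
        ux[2, 2] = 10.0
        f = VectorField2D(ux, uy, spacing=1.6)
        out = validate_and_fill(f)
        assert np.isclose(out.u_x[2, 2], 1.0)

    def test_90pct_of_injected_outliers_detected(self):
        f = self._smooth_field(seed=3)
        rng = np.random.default_rng(4)
        n_out = int(0.05 * f.u_x.size)
        idx = rng.choice(f.u_x.size, n_out, replace=False)
        scale = 10 * np.abs(f.u_x).max()
        f.u_x.ravel()[idx] += scale * rng.uniform(1, 3, n_out) * rng.choice([-1, 1], n_out)
        corrupted = f.u_x.ravel()[idx].copy()
        out = validate_and_fill(f)
        detected = ~np.isclose(out.u_x.ravel()[idx], corrupted)
        assert detected.mean() >= 0.90

    def test_mostly_invalid_field_hard_failure(self):
        f = self._smooth_field()
        f.valid_mask[:, :] = False
        f.valid_mask[:2, :2] = True
        with pytest.raises(RuntimeError, match="unusable"):
            validate_and_fill(f)

    def test_too_small_grid_rejected(self):
        f = VectorField2D(np.zeros((2, 5)), np.zeros((2, 5)), spacing=1.0)
        with pytest.raises(ValueError, match="3x3"):
            validate_and_fill(f)


class TestReferenceAndDrift:
    def _movie(self, n=4):
        beads = random_bead_field((128, 128), 0.2, seed=6)
        frames = []
        for i in range(n):
            img, _ = render_bead_images(beads, None, (128, 128), 0.2)
            frames.append(ImageFrame(img.pixels, 0.2, timestamp=10.0 * i))
        return ImageSequence(frames)

    def test_last_frame_policy(self):
        seq = self._movie(4)
        ref = reference_from_sequence(seq, "last_frame")
        assert ref is seq[3]

    def test_explicit_index_policy_and_bounds(self):
        seq = self._movie(4)
        assert reference_from_sequence(seq, "explicit_index", index=1) is seq[1]
        with pytest.raises(ValueError):
            reference_from_sequence(seq, ReferencePolicy.EXPLICIT_INDEX, index=9)

    def test_single_frame_sequence_degenerates(self):
        seq = self._movie(1)
        assert reference_from_sequence(seq, "last_frame") is seq[0]

    def test_injected_global_drift_detected(self):
        big = 160
        beads = random_bead_field((big, big), 0.2, seed=7)
        full, _ = render_bead_images(beads, None, (big, big), 0.2)
        ref = ImageFrame(full.pixels[16:144, 16:144], 0.2)
        drifted = ImageFrame(full.pixels[14:142, 16:144], 0.2)  # 2 px in y
        seq = ImageSequence([drifted, ref])
        corrected, shifts = register_sequence(seq, ref)
        # returned shift is the correction applied to the frame: content sits
        # 2 px down, so the correction is -2 px in y
        assert abs(shifts[0][0] + 2.0) < 0.1
        assert abs(shifts[0][1]) < 0.1
        assert np.allclose(shifts[1], 0.0)
        # correction actually registers the frame
        resid = corrected[0].pixels[8:-8, 8:-8] - ref.pixels[8:-8, 8:-8]
        assert np.abs(resid).max() < 0.05 * ref.pixels.max()
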