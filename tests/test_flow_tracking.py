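"""Tracker correctness against independent oracles.

The two oracles used here are (a) exhaustive integer-shift SSD search,
which needs no gradient machinery at all, and (b) analytic sub-pixel shift
construction via the Fourier shift theorem, where the applied displacement
is known exactly by construction.
"""

import numpy as np
import pytest

from pelviflow import (
    PhantomSpec,
    TrackerParams,
    build_pyramid,
    make_phantom,
    refine_displacement,
    track_pair,
    track_sequence,
)


def ssd_search(I, J, point, half, search):
    """Oracle: brute-force integer displacement minimizing windowed SSD."""
    x, y = point
    win_I = I[y - half : y + half + 1, x - half : x + half + 1]
    best, best_d = np.inf, (0, 0)
    for dy in range(-search, search + 1):
        for dx in range(-search, search + 1):
            win_J = J[y + dy - half : y + dy + half + 1, x + dx - half : x + dx + half + 1]
            ssd = float(np.sum((win_I - win_J) ** 2))
            if ssd < best:
                best, best_d = ssd, (dx, dy)
    return best_d


def fourier_shift(img, dx, dy):
    """Oracle construction: exact sub-pixel translation of a periodic image."""
    ky = np.fft.fftfreq(img.shape[0])[:, None]
    kx = np.fft.fftfreq(img.shape[1])[None, :]
    phase = np.exp(-2j * np.pi * (kx * dx + ky * dy))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * phase))


class TestPyramid:
    def test_shapes_halve_per_level(self, textured_image):
        img = np.zeros((256, 256))
        pyr = build_pyramid(img, levels=3, downscale=2)
        assert [p.shape for p in pyr] == [(256, 256), (128, 128), (64, 64)]

    def test_constant_image_stays_constant(self):
        pyr = build_pyramid(np.full((64, 64), 3.7), levels=3)
        for level in pyr:
            assert np.allclose(level, 3.7)

    def test_single_level_is_identity(self, textured_image):
        (only,) = build_pyramid(textured_image, levels=1)
        np.testing.assert_array_equal(only, textured_image)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            build_pyramid(np.zeros((16, 16)), levels=5, downscale=2)


class TestDisplacementEstimation:
    def test_identity_pair_gives_zero(self, textured_image):
        res = refine_displacement(textured_image, textured_image, (64.0, 64.0))
        assert res.converged
        assert np.linalg.norm(res.displacement) <= TrackerParams().eps_px

    def test_integer_shift_matches_ssd_oracle(self, textured_image):
        # periodic padding keeps the shifted frame exact; rolling rows by -2
        # and columns by +3 moves the window content by (dx, dy) = (3, -2)
        J = np.roll(textured_image, shift=(-2, 3), axis=(0, 1))
        point = (64, 64)
        oracle = ssd_search(textured_image, J, point, half=10, search=5)
        assert oracle == (3, -2)
        res = track_pair(textured_image, J, (64.0, 64.0))
        assert res.converged
        np.testing.assert_allclose(res.displacement, [3.0, -2.0], atol=0.05)

    def test_subpixel_shift_recovered(self, textured_image):
        dx, dy = 0.4, 0.25
        J = fourier_shift(textured_image, dx, dy)
        res = track_pair(textured_image, J, (64.0, 64.0))
        assert res.converged
        np.testing.assert_allclose(res.displacement, [dx, dy], atol=0.1)

    def test_large_shift_needs_pyramid(self, textured_image):
        # 12 px exceeds the 10 px window radius: single-level fails, 3 levels recover
        J = np.roll(textured_image, shift=(0, 12), axis=(0, 1))
        multi = track_pair(textured_image, J, (64.0, 64.0),
                           TrackerParams(pyramid_levels=3))
        np.testing.assert_allclose(multi.displacement, [12.0, 0.0], atol=0.1)

    def test_beyond_capture_range_flagged(self, textured_image):
        J = np.roll(textured_image, shift=(0, 45), axis=(0, 1))
        res = track_pair(textured_image, J, (64.0, 64.0), TrackerParams(pyramid_levels=1))
        assert not res.converged or np.linalg.norm(res.displacement - [45, 0]) > 1.0

    def test_textureless_window_is_singular(self):
        flat = np.zeros((64, 64))
        res = refine_displacement(flat, flat, (32.0, 32.0))
        assert res.singular and not res.converged

    def test_forward_backward_symmetry(self, textured_image):
        """On a rigid translation, backward displacement mirrors forward."""
        J = np.roll(textured_image, shift=(2, -3), axis=(0, 1))
        fwd = track_pair(textured_image, J, (64.0, 64.0))
        bwd = track_pair(J, textured_image, (64.0 + fwd.displacement[0],
                                             64.0 + fwd.displacement[1]))
        np.testing.assert_allclose(fwd.displacement + bwd.displacement, [0, 0], atol=0.05)


class TestSequenceTracking:
    def test_static_phantom_tracks_to_zero(self):
        spec = PhantomSpec(seed=3, descent_amplitude_mm=0.0, inclination_change_deg=0.0,
                           rim_rotation_deg=0.0, noise_sigma=0.0, n_frames=5)
        seq, truth = make_phantom(spec)
        tracks = track_sequence(seq, truth.roi_set)
        assert tracks["valid"].all()
        merged = tracks.merge(truth.positions, on=["structure", "frame"],
                              suffixes=("", "_true"))
        err = np.hypot(merged.x_px - merged.x_px_true, merged.y_px - merged.y_px_true)
        assert err.max() <= TrackerParams().eps_px

    def test_phantom_positions_within_one_mm(self, default_phantom):
        seq, truth = default_phantom
        tracks = track_sequence(seq, truth.roi_set)
        merged = tracks.merge(truth.positions, on=["structure", "frame"],
                              suffixes=("", "_true"))
        err_mm = np.hypot(merged.x_px - merged.x_px_true,
                          merged.y_px - merged.y_px_true) * seq.spacing_mm[0]
        assert err_mm.max() < 1.0
        assert tracks["valid"].all()
        assert err_mm.mean() < 1.0  # "sub-millimeter accuracy" regime

    def test_frame0_anchors_exact(self, default_phantom):
        seq, truth = default_phantom
        tracks = track_sequence(seq, truth.roi_set)
        f0 = tracks[tracks.frame == 0].set_index("structure")
        for name, win in truth.roi_set.items():
            assert f0.loc[name, "x_px"] == win.x
            assert f0.loc[name, "y_px"] == win.y

    def test_structure_leaving_frame_flagged_invalid(self):
        # exaggerated descent drives the distal rim out of the field of view
        spec = PhantomSpec(seed=5, descent_amplitude_mm=70.0, ugh_coupling=0.3,
                           lh_coupling=0.2, inclination_change_deg=0.0,
                           rim_rotation_deg=0.0, n_frames=20, allow_exit=True)
        seq, truth = make_phantom(spec)
        tracks = track_sequence(seq, truth.roi_set)
        distal = tracks[tracks.structure == "distal_rim"].sort_values("frame")
        valid = distal["valid"].to_numpy()
        assert valid[:3].all()  # early frames unaffected
        assert not valid[-1]  # lost by the end
        first_bad = int(np.argmin(valid))
        assert not valid[first_bad:].any()  # invalid tail is contiguous
        pubic = tracks[tracks.structure == "inferior_pubic_point"]
        assert pubic["valid"].all()


class TestShiftEquivariance:
    def test_integer_translation_of_scene(self, default_phantom):
        """Translating every frame by (a, b) px translates all tracks by (a, b)."""
        from pelviflow.io_formats import FrameSequence, RoiSet, RoiWindow

        seq, truth = default_phantom
        a, b = 5, -3
        shifted = FrameSequence(
            frames=np.roll(seq.frames, shift=(b, a), axis=(1, 2)),
            spacing_mm=seq.spacing_mm,
        )
        shifted_rois = RoiSet(entries={
            name: RoiWindow(w.x + a, w.y + b, w.w, w.h) for name, w in truth.roi_set.items()
        })
        t_orig = track_sequence(seq, truth.roi_set)
        t_shift = track_sequence(shifted, shifted_rois)
        merged = t_orig.merge(t_shift, on=["structure", "frame"], suffixes=("", "_s"))
        np.testing.assert_allclose(merged.x_px_s - merged.x_px, a, atol=0.05)
        np.testing.assert_allclose(merged.y_px_s - merged.y_px, b, atol=0.05)
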