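"""PICS construction against direct rotation-matrix arithmetic."""

import numpy as np
import pandas as pd
import pytest

from pelviflow import (
    PhantomSpec,
    PicsParams,
    apply_transform,
    assemble_kinematics,
    fit_pics,
    make_phantom,
    pics_series,
    track_sequence,
)
from pelviflow.io_formats import FrameSequence, TRACK_COLUMNS
from pelviflow.pics_coords import DegenerateGeometryError


def track_table_from_truth(truth):
    """Noise-free track table built from the phantom's exact positions."""
    df = truth.positions.copy()
    df["residual"] = 0.0
    df["fb_error_px"] = 0.0
    df["converged"] = True
    df["valid"] = True
    return df[TRACK_COLUMNS]


class TestFitPics:
    def test_pubic_point_maps_to_origin(self):
        T = fit_pics((13.0, 47.0), (120.0, 20.0))
        np.testing.assert_allclose(apply_transform(T, (13.0, 47.0)), [0, 0], atol=1e-12)

    def test_zero_offset_axis_alignment(self):
        T = fit_pics((0.0, 0.0), (110.0, 0.0), PicsParams(inclination_offset_deg=0))
        np.testing.assert_allclose(apply_transform(T, (110.0, 0.0)), [110, 0], atol=1e-9)

    def test_matches_hand_rotation_matrix(self):
        """Oracle: explicit 2x2 rotation arithmetic, written out independently.

        SCIPP axis 20 degrees above (cranial of) the image x-axis, offset
        34 degrees toward caudal: the PICS x-axis sits at -20+34 = 14
        degrees in image coordinates.
        """
        pubic = np.array([10.0, 50.0])
        scj = pubic + 100.0 * np.array([np.cos(np.deg2rad(-20)), np.sin(np.deg2rad(-20))])
        probe = np.array([40.0, 90.0])

        a = np.deg2rad(14.0)
        e_x = np.array([np.cos(a), np.sin(a)])
        e_y = np.array([-np.sin(a), np.cos(a)])
        expected = np.array([e_x @ (probe - pubic), e_y @ (probe - pubic)])

        T = fit_pics(pubic, scj, PicsParams(inclination_offset_deg=34))
        np.testing.assert_allclose(apply_transform(T, probe), expected, atol=1e-12)

    def test_quarter_turn_sign_convention(self):
        # SCIPP axis pointing caudally (+y), zero offset: PICS x is image +y
        T = fit_pics((0.0, 0.0), (0.0, 100.0), PicsParams(inclination_offset_deg=0))
        np.testing.assert_allclose(apply_transform(T, (1.0, 0.0)), [0, -1], atol=1e-12)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_pics((10.0, 10.0), (10.5, 10.2))

    def test_single_sign_flip_rejected(self):
        with pytest.raises(ValueError, match="reflection"):
            PicsParams(posterior_positive_x=False, caudal_positive_y=True)


class TestTransformProperties:
    def test_rigid_invariants_hold_for_arbitrary_geometry(self):
        """Property: for any non-degenerate landmark pair and offset, the
        fitted transform is a proper isometry with the pubic point at the
        origin."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        coords = st.floats(-500, 500, allow_nan=False)
        offsets = st.floats(-89, 89, allow_nan=False)

        @settings(max_examples=200, derandomize=True)
        @given(px=coords, py=coords, sx=coords, sy=coords, off=offsets)
        def check(px, py, sx, sy, off):
            pubic, scj = np.array([px, py]), np.array([sx, sy])
            if np.linalg.norm(scj - pubic) <= 1.0:
                return
            T = fit_pics(pubic, scj, PicsParams(inclination_offset_deg=off))
            assert np.linalg.det(T.matrix) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(apply_transform(T, pubic), [0, 0], atol=1e-9)
            out = apply_transform(T, np.stack([pubic, scj]))
            assert np.linalg.norm(out[1] - out[0]) == pytest.approx(
                np.linalg.norm(scj - pubic), rel=1e-9)

        check()

    def test_isometry(self):
        rng = np.random.default_rng(0)
        T = fit_pics((5.0, 80.0), (110.0, 30.0))
        pts = rng.uniform(0, 200, size=(20, 2))
        out = apply_transform(T, pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)

    def test_inverse_composes_to_identity(self):
        T = fit_pics((5.0, 80.0), (110.0, 30.0))
        pts = np.array([[10.0, 20.0], [150.0, 90.0]])
        back = apply_transform(T.inverse(), apply_transform(T, pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_pure_rotation_determinant(self):
        T = fit_pics((5.0, 80.0), (110.0, 30.0))
        assert np.linalg.det(T.matrix) == pytest.approx(1.0, abs=1e-12)


class TestPicsSeries:
    def test_global_rigid_motion_cancels_exactly_for_points(self):
        """Point pipeline: PICS coordinates invariant to the outer motion."""
        spec = PhantomSpec(seed=11, descent_amplitude_mm=0.0, rim_rotation_deg=0.0,
                           inclination_change_deg=12.0, global_drift_mm=(6.0, -4.0),
                           n_frames=8, allow_exit=True)
        seq, truth = make_phantom(spec)
        _, pics = pics_series(track_table_from_truth(truth), seq)
        for _, grp in pics.groupby("structure"):
            assert np.ptp(grp["x_pics_mm"]) < 1e-9
            assert np.ptp(grp["y_pics_mm"]) < 1e-9

    def test_global_rigid_motion_cancels_through_tracking(self):
        """End-to-end (imaging + tracking): constancy within 0.5 mm."""
        spec = PhantomSpec(seed=12, descent_amplitude_mm=0.0, rim_rotation_deg=0.0,
                           inclination_change_deg=10.0, global_drift_mm=(4.0, -3.0),
                           n_frames=15)
        seq, truth = make_phantom(spec)
        tracks = track_sequence(seq, truth.roi_set)
        _, pics = pics_series(tracks, seq)
        for _, grp in pics.groupby("structure"):
            assert np.ptp(grp["x_pics_mm"]) < 0.5
            assert np.ptp(grp["y_pics_mm"]) < 0.5

    def test_two_frame_scipp_rotation_matches_hand_computation(self):
        """Hand-built track table: the SCIPP line rotates 10 degrees between
        frames around the pubic point while a soft structure stays fixed in
        the pelvis frame; its PICS coordinates must not change."""
        pubic0, theta = np.array([50.0, 100.0]), np.deg2rad(10.0)
        scj0 = pubic0 + np.array([100.0, -20.0])
        soft0 = np.array([70.0, 140.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rows = []
        for frame, rot in ((0, np.eye(2)), (1, R)):
            for name, p0 in (("inferior_pubic_point", pubic0),
                             ("sacrococcygeal_joint", scj0), ("distal_rim", soft0)):
                p = rot @ (p0 - pubic0) + pubic0
                rows.append(dict(structure=name, frame=frame, x_px=p[0], y_px=p[1],
                                 residual=0.0, fb_error_px=0.0, converged=True, valid=True))
        tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
        seq = FrameSequence(np.zeros((2, 256, 256)), spacing_mm=(1, 1))
        _, pics = pics_series(tracks, seq)
        soft = pics[pics.structure == "distal_rim"].set_index("frame")
        np.testing.assert_allclose(
            soft.loc[1, ["x_pics_mm", "y_pics_mm"]].astype(float),
            soft.loc[0, ["x_pics_mm", "y_pics_mm"]].astype(float),
            atol=1e-9,
        )
        # and the hand value itself: rest-fit transform applied to soft0
        T0 = fit_pics(pubic0, scj0)
        np.testing.assert_allclose(
            soft.loc[0, ["x_pics_mm", "y_pics_mm"]].astype(float),
            apply_transform(T0, soft0), atol=1e-12,
        )

    def test_invalid_landmark_frame_is_flagged_not_interpolated(self, default_phantom):
        seq, truth = default_phantom
        tracks = track_table_from_truth(truth)
        mask = (tracks.structure == "inferior_pubic_point") & (tracks.frame == 7)
        tracks.loc[mask, "valid"] = False
        transforms, pics = pics_series(tracks, seq)
        assert transforms[7] is None
        frame7 = pics[pics.frame == 7]
        assert (~frame7["valid"]).all()
        assert pics[pics.frame == 6]["valid"].all()

    def test_hiatus_invariant_to_pics_rotation_choice(self, default_phantom):
        """Hiatus sizes are Euclidean distances: any inclination offset
        (or none) gives identical values to 1e-9 mm."""
        seq, truth = default_phantom
        tracks = track_table_from_truth(truth)
        _, pics_a = pics_series(tracks, seq, PicsParams(inclination_offset_deg=34))
        _, pics_b = pics_series(tracks, seq, PicsParams(inclination_offset_deg=0))
        kin_a = assemble_kinematics(pics_a, "s")
        kin_b = assemble_kinematics(pics_b, "s")
        np.testing.assert_allclose(kin_a["ugh_mm"], kin_b["ugh_mm"], atol=1e-9)
        np.testing.assert_allclose(kin_a["lh_mm"], kin_b["lh_mm"], atol=1e-9)
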