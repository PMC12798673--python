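"""Standardized pelvic coordinates from the tracked bony landmarks.

The Pelvic Inclination Correction System (PICS) removes variation in
patient positioning by anchoring a body-fixed frame on the SCIPP line, the
line from the inferior pubic point to the sacrococcygeal joint.  In the
midsagittal plane the construction reduces to a rigid in-plane rotation
plus translation:

* origin at the inferior pubic point;
* x-axis along the pubis->sacrococcygeal unit vector rotated by a fixed
  inclination offset (default 34 degrees, the published PICS convention),
  positive toward posterior;
* y-axis perpendicular, positive toward caudal, so both pessary "descent"
  and hiatus enlargement read as positive quantities.

With exactly two landmarks in 2D the transform is constructed analytically
from the axis direction; nothing is fitted by least squares.  The transform
is re-estimated on every frame from that frame's tracked landmarks, so any
global rigid motion of the pelvis (posture change during Valsalva) cancels
exactly in PICS coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pelviflow.io_formats import FrameSequence, PICS_TRACK_COLUMNS

__all__ = ["RigidTransform2D", "PicsParams", "fit_pics", "apply_transform", "pics_series"]


class DegenerateGeometryError(ValueError):
    """Raised when the two bony landmarks (nearly) coincide."""


@dataclass(frozen=True)
class PicsParams:
    """Configuration of the PICS construction.

    inclination_offset_deg is the standard rotation applied to the SCIPP
    axis; the sign flags select the axis polarity (defaults: +x posterior,
    +y caudal).  Flipping exactly one flag yields an improper (reflecting)
    frame and is rejected.
    """

    inclination_offset_deg: float = 34.0
    posterior_positive_x: bool = True
    caudal_positive_y: bool = True

    def __post_init__(self) -> None:
        if not (-90.0 < self.inclination_offset_deg < 90.0):
            raise ValueError("inclination offset must be in (-90, 90) degrees")
        if self.posterior_positive_x != self.caudal_positive_y:
            raise ValueError(
                "flipping exactly one axis sign would make the frame a reflection; "
                "flip both or neither"
            )


@dataclass(frozen=True)
class RigidTransform2D:
    """Scanner-mm -> PICS-mm mapping ``p' = M @ (p - origin)``.

    ``matrix`` is a proper rotation (rows are the PICS x- and y-axis unit
    vectors expressed in scanner coordinates); ``origin_mm`` is the
    inferior pubic point.
    """

    matrix: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=np.float64))
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, dtype=np.float64))

    @property
    def theta_rad(self) -> float:
        """Rotation angle such that M = R(-theta) in image-axis convention."""
        return float(np.arctan2(self.matrix[0, 1], self.matrix[0, 0]))

    def inverse(self) -> "RigidTransform2D":
        # p = M^T p' + origin, rewritten in the same (M, origin) form
        Mi = self.matrix.T
        return RigidTransform2D(matrix=Mi, origin_mm=-Mi.T @ self.origin_mm)


def fit_pics(pubic_mm, scj_mm, params: PicsParams | None = None) -> RigidTransform2D:
    """Construct the PICS transform from the two bony landmarks (mm).

    The x-axis is the unit vector from the inferior pubic point toward the
    sacrococcygeal joint, rotated in-plane by the inclination offset
    (positive offset rotates toward caudal in the image convention,
    y increasing downward).
    """
    params = params or PicsParams()
    pubic = np.asarray(pubic_mm, dtype=np.float64)
    scj = np.asarray(scj_mm, dtype=np.float64)
    u = scj - pubic
    norm = float(np.linalg.norm(u))
    if norm <= 1.0:
        raise DegenerateGeometryError(
            f"bony landmarks separated by {norm:.3f} mm (<= 1 mm): cannot define the SCIPP axis"
        )
    u /= norm
    a = np.deg2rad(params.inclination_offset_deg)
    c, s = np.cos(a), np.sin(a)
    e_x = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
    e_y = np.array([-e_x[1], e_x[0]])  # +90 deg in image convention -> caudal when e_x ~ +x
    if not params.posterior_positive_x:
        e_x = -e_x
        e_y = -e_y
    return RigidTransform2D(matrix=np.stack([e_x, e_y]), origin_mm=pubic)


def apply_transform(T: RigidTransform2D, points) -> np.ndarray:
    """Apply the rigid mapping to an (n, 2) array (or single point) of mm."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = (pts - T.origin_mm) @ T.matrix.T
    return out if np.asarray(points).ndim > 1 else out[0]


def pics_series(
    tracks: pd.DataFrame,
    seq: FrameSequence,
    params: PicsParams | None = None,
) -> tuple[dict[int, RigidTransform2D | None], pd.DataFrame]:
    """Per-frame PICS transforms and the track table in PICS millimetres.

    Pixel anchors are scaled to mm by the pixel spacing and mapped through
    the transform fitted from *that frame's* tracked bony landmarks, so
    changes of pelvic inclination during the maneuver are corrected frame
    by frame.  Frames whose bony landmarks are invalid or degenerate get
    transforms of ``None`` and all their rows flagged invalid — never
    interpolated.
    """
    params = params or PicsParams()
    row_mm, col_mm = seq.spacing_mm
    df = tracks.copy()
    df["x_mm"] = df["x_px"] * col_mm
    df["y_mm"] = df["y_px"] * row_mm

    transforms: dict[int, RigidTransform2D | None] = {}
    out_rows: list[dict] = []
    for frame, grp in df.groupby("frame", sort=True):
        by_struct = grp.set_index("structure")
        try:
            pub = by_struct.loc["inferior_pubic_point"]
            scj = by_struct.loc["sacrococcygeal_joint"]
        except KeyError as exc:
            raise ValueError(f"frame {frame}: missing bony landmark {exc}") from exc
        landmarks_ok = bool(pub["valid"]) and bool(scj["valid"])
        T: RigidTransform2D | None = None
        if landmarks_ok:
            try:
                T = fit_pics((pub["x_mm"], pub["y_mm"]), (scj["x_mm"], scj["y_mm"]), params)
            except DegenerateGeometryError:
                T = None
        transforms[int(frame)] = T
        for structure, row in by_struct.iterrows():
            if T is not None:
                p = apply_transform(T, (row["x_mm"], row["y_mm"]))
                x_pics, y_pics = float(p[0]), float(p[1])
                valid = bool(row["valid"])
            else:
                x_pics, y_pics = np.nan, np.nan
                valid = False
            out_rows.append(
                dict(structure=structure, frame=int(frame), x_pics_mm=x_pics,
                     y_pics_mm=y_pics, valid=valid)
            )

    pics_df = pd.DataFrame(out_rows, columns=PICS_TRACK_COLUMNS)
    return transforms, pics_df
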