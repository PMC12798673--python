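"""Per-frame biomechanical quantities derived from PICS-frame tracks.

* Urogenital hiatus (UGH) size: Euclidean distance from the inferior pubic
  point to the perineal body.
* Levator hiatus (LH) size: distance from the inferior pubic point to the
  anorectal angle.
* Pessary displacement: per-structure offset from the rest frame in PICS
  mm, reported as components and magnitude; the caudal (+y) component is
  "descent".
* Pessary axis angle: orientation of the distal->proximal rim vector
  against the PICS x-axis, degrees in (-180, 180].

Distances use the tracked upper-left window anchors (the package's
coordinate convention throughout); an optional window-centroid mode exists
for sensitivity checks but is not the default.  Hiatus sizes, being
Euclidean distances, are invariant to the PICS rotation and could equally
be computed in scanner mm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pelviflow.io_formats import KINEMATICS_COLUMNS

__all__ = [
    "hiatus_sizes",
    "displacement_from_rest",
    "pessary_axis_angle",
    "assemble_kinematics",
]

_COINCIDENT_RIM_MM = 1.0


def _pivot(pics_tracks: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    x = pics_tracks.pivot(index="frame", columns="structure", values="x_pics_mm")
    y = pics_tracks.pivot(index="frame", columns="structure", values="y_pics_mm")
    v = pics_tracks.pivot(index="frame", columns="structure", values="valid").astype(bool)
    return x, y, v


def _dist(x, y, a: str, b: str) -> pd.Series:
    return np.hypot(x[a] - x[b], y[a] - y[b])


def hiatus_sizes(pics_tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-frame UGH and LH sizes (mm) with validity flags."""
    x, y, v = _pivot(pics_tracks)
    for needed in ("inferior_pubic_point", "perineal_body", "anorectal_angle"):
        if needed not in x.columns:
            raise ValueError(f"pics track table lacks structure '{needed}'")
    out = pd.DataFrame(index=x.index)
    out["ugh_mm"] = _dist(x, y, "inferior_pubic_point", "perineal_body")
    out["lh_mm"] = _dist(x, y, "inferior_pubic_point", "anorectal_angle")
    out["ugh_valid"] = v["inferior_pubic_point"] & v["perineal_body"]
    out["lh_valid"] = v["inferior_pubic_point"] & v["anorectal_angle"]
    return out


def displacement_from_rest(
    pics_tracks: pd.DataFrame, structure: str, rest_frame: int = 0
) -> pd.DataFrame:
    """Per-frame displacement of one structure relative to the rest frame.

    Returns columns ``dx_mm``, ``dy_mm`` (PICS components; +y = caudal
    descent), ``disp_mm`` (magnitude) and ``valid``.  The rest frame is the
    fixed reference and must itself be valid.
    """
    sub = pics_tracks[pics_tracks["structure"] == structure].set_index("frame").sort_index()
    if sub.empty:
        raise ValueError(f"no rows for structure '{structure}'")
    if rest_frame not in sub.index:
        raise ValueError(f"rest frame {rest_frame} absent for structure '{structure}'")
    rest = sub.loc[rest_frame]
    if not bool(rest["valid"]):
        raise ValueError(
            f"rest frame {rest_frame} is invalid for '{structure}'; it is the "
            "displacement reference and cannot be imputed"
        )
    out = pd.DataFrame(index=sub.index)
    out["dx_mm"] = sub["x_pics_mm"] - rest["x_pics_mm"]
    out["dy_mm"] = sub["y_pics_mm"] - rest["y_pics_mm"]
    out["disp_mm"] = np.hypot(out["dx_mm"], out["dy_mm"])
    out["valid"] = sub["valid"].astype(bool)
    return out


def pessary_axis_angle(pics_tracks: pd.DataFrame) -> pd.DataFrame:
    """Orientation of the distal->proximal rim axis per frame, degrees.

    Angle measured from the PICS x-axis with the package's image-style
    sign convention (positive toward +y, i.e. caudal), mapped to
    (-180, 180].  Frames where the rims are closer than 1 mm are flagged
    invalid (orientation undefined).
    """
    x, y, v = _pivot(pics_tracks)
    for needed in ("distal_rim", "proximal_rim"):
        if needed not in x.columns:
            raise ValueError(f"pics track table lacks structure '{needed}'")
    dx = x["proximal_rim"] - x["distal_rim"]
    dy = y["proximal_rim"] - y["distal_rim"]
    sep = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    out = pd.DataFrame(index=x.index)
    out["pessary_angle_deg"] = ang
    out["valid"] = v["distal_rim"] & v["proximal_rim"] & (sep >= _COINCIDENT_RIM_MM)
    return out


def assemble_kinematics(
    pics_tracks: pd.DataFrame, subject_id: str, rest_frame: int = 0
) -> pd.DataFrame:
    """Join hiatus sizes, rim displacements and pessary angle per frame.

    One row per frame; ``valid`` is the conjunction of every constituent
    measure's validity, so a single lost structure invalidates the frame
    rather than silently biasing the correlations.
    """
    hiatus = hiatus_sizes(pics_tracks)
    distal = displacement_from_rest(pics_tracks, "distal_rim", rest_frame)
    proximal = displacement_from_rest(pics_tracks, "proximal_rim", rest_frame)
    angle = pessary_axis_angle(pics_tracks)

    out = pd.DataFrame(index=hiatus.index)
    out["subject"] = subject_id
    out["frame"] = out.index
    out["ugh_mm"] = hiatus["ugh_mm"]
    out["lh_mm"] = hiatus["lh_mm"]
    out["distal_disp_mm"] = distal["disp_mm"]
    out["distal_dx_mm"] = distal["dx_mm"]
    out["distal_dy_mm"] = distal["dy_mm"]
    out["proximal_disp_mm"] = proximal["disp_mm"]
    out["proximal_dx_mm"] = proximal["dx_mm"]
    out["proximal_dy_mm"] = proximal["dy_mm"]
    out["pessary_angle_deg"] = angle["pessary_angle_deg"]
    out["valid"] = (
        hiatus["ugh_valid"]
        & hiatus["lh_valid"]
        & distal["valid"]
        & proximal["valid"]
        & angle["valid"]
    )
    return out.reset_index(drop=True)[KINEMATICS_COLUMNS]
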