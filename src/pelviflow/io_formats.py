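"""Input/output layer: image sequences, ROI specifications, result tables.

Conventions used throughout the package:

* Pixel coordinates are 0-based, ``(x, y) = (column, row)``, origin at the
  centre of the top-left pixel.  ``x`` increases to the right, ``y``
  increases downward.
* The display convention is anterior at image left and cranial at image
  top; sequences loaded with other orientations are flipped on load so the
  rest of the pipeline never has to branch on orientation.
* Tables are plain CSV with a header row; columns carry their unit in the
  name (``_px`` or ``_mm``) and round-trip at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_STRUCTURES",
    "FrameSequence",
    "RoiWindow",
    "RoiSet",
    "load_sequence",
    "load_roi_set",
    "write_table",
    "read_table",
    "TRACK_COLUMNS",
    "PICS_TRACK_COLUMNS",
    "KINEMATICS_COLUMNS",
    "CORRELATION_COLUMNS",
]

#: The six structures every analysis needs: the two pessary rim
#: cross-sections, the two soft-tissue hiatus endpoints, and the two bony
#: landmarks that define the SCIPP line.
CANONICAL_STRUCTURES = (
    "distal_rim",
    "proximal_rim",
    "perineal_body",
    "anorectal_angle",
    "inferior_pubic_point",
    "sacrococcygeal_joint",
)

BONY_LANDMARKS = ("inferior_pubic_point", "sacrococcygeal_joint")


class FormatError(ValueError):
    """Raised when an input file does not match the expected format."""


class ConfigurationError(ValueError):
    """Raised when required configuration (e.g. pixel spacing) is absent."""


@dataclass
class FrameSequence:
    """An ordered stack of 2D intensity frames with physical pixel spacing.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; arbitrary intensity
        units (raw scanner values are preserved; trackers normalize
        internally).
    spacing_mm
        ``(row_mm, col_mm)`` physical size of one pixel.
    anterior_is_left, cranial_is_top
        Orientation flags.  :func:`load_sequence` normalizes to the
        canonical ``True``/``True`` convention by flipping the arrays.
    """

    frames: np.ndarray
    spacing_mm: tuple[float, float]
    anterior_is_left: bool = True
    cranial_is_top: bool = True
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be (n_frames, height, width), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise FormatError(f"a dynamic sequence needs >= 2 frames, got {self.frames.shape[0]}")
        row_mm, col_mm = self.spacing_mm
        if not (row_mm > 0 and col_mm > 0):
            raise ConfigurationError(f"pixel spacing must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(row_mm), float(col_mm))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def normalized(self) -> np.ndarray:
        """Frames linearly rescaled to [0, 1] by the per-sequence min/max.

        Tracker tolerances (texture thresholds, residuals) are defined on
        this scale so they are independent of scanner intensity units.
        A constant sequence maps to all zeros.
        """
        lo = float(self.frames.min())
        hi = float(self.frames.max())
        if hi - lo == 0:
            return np.zeros_like(self.frames)
        return (self.frames - lo) / (hi - lo)


@dataclass(frozen=True)
class RoiWindow:
    """A rectangular ROI window; ``(x, y)`` is the upper-left corner."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise FormatError(f"ROI window must have positive size, got {self.w}x{self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class RoiSet:
    """Named ROI windows on frame 0 of a sequence.

    All six canonical structures must be present; extra custom structures
    are allowed and tracked like any other.
    """

    entries: dict[str, RoiWindow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in CANONICAL_STRUCTURES if s not in self.entries]
        if missing:
            raise FormatError(f"ROI set is missing canonical structures: {', '.join(missing)}")

    def __getitem__(self, name: str) -> RoiWindow:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def validate_bounds(self, seq: FrameSequence, margin: int = 0) -> None:
        """Check every window (plus ``margin`` px) lies inside the frame."""
        for name, win in self.entries.items():
            if (
                win.x - margin < 0
                or win.y - margin < 0
                or win.x + win.w + margin > seq.width
                or win.y + win.h + margin > seq.height
            ):
                raise FormatError(
                    f"ROI '{name}' at ({win.x},{win.y}) size {win.w}x{win.h} "
                    f"(margin {margin}) exceeds the {seq.width}x{seq.height} frame"
                )


# ---------------------------------------------------------------------------
# sequence loading


def _load_nifti(path: Path, spacing_override) -> tuple[np.ndarray, tuple[float, float] | None]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim < 3:
        raise FormatError(f"NIfTI input must have >= 3 dimensions (last = time), got {data.ndim}")
    # collapse singleton mid-axes (e.g. a single-slice 3D+t acquisition)
    while data.ndim > 3:
        squeezable = [ax for ax in range(1, data.ndim - 1) if data.shape[ax] == 1]
        if not squeezable:
            raise FormatError(f"cannot interpret NIfTI shape {data.shape} as 2D+time")
        data = np.squeeze(data, axis=squeezable[0])
    # stored as (row, col, time); see save_sequence_nifti
    frames = np.moveaxis(data, -1, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else None
    if spacing is not None and min(spacing) <= 0:
        spacing = None
    return frames, spacing


def save_sequence_nifti(seq: FrameSequence, path) -> None:
    """Write a sequence as NIfTI with axes (row, col, time).

    Pixel spacing goes into the header zooms; the time step is set to 1.
    :func:`load_sequence` reads this back bit-identically.
    """
    import nibabel as nib

    data = np.moveaxis(seq.frames, 0, -1)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((seq.spacing_mm[0], seq.spacing_mm[1], 1.0))
    nib.save(img, str(path))


def _load_dicom_dir(path: Path) -> tuple[np.ndarray, tuple[float, float] | None]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"} or p.suffix == "")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {path}")
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    frames = np.stack([ds.pixel_array.astype(np.float64) for ds in datasets])
    spacing = None
    ps = getattr(datasets[0], "PixelSpacing", None)
    if ps is not None:
        spacing = (float(ps[0]), float(ps[1]))
    return frames, spacing


def _load_image_stack(paths: Iterable[Path]) -> np.ndarray:
    import imageio.v3 as iio

    arrays = []
    for p in paths:
        a = np.asarray(iio.imread(str(p)), dtype=np.float64)
        if a.ndim == 3:  # RGB(A): collapse to luminance
            a = a[..., :3].mean(axis=-1)
        arrays.append(a)
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise FormatError(f"frames have mixed shapes: {sorted(shapes)}")
    return np.stack(arrays)


def load_sequence(
    path,
    spacing_override: tuple[float, float] | None = None,
    anterior_is_left: bool = True,
    cranial_is_top: bool = True,
) -> FrameSequence:
    """Load a dynamic 2D+time sequence from NIfTI, DICOM, or an image stack.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file, a directory of DICOM files, a directory
        of PNG/TIFF frames (lexical order = acquisition order), or a glob
        pattern for such frames.
    spacing_override
        ``(row_mm, col_mm)``; required when the source carries no spacing
        (image stacks), overrides the header when given.
    anterior_is_left, cranial_is_top
        Orientation of the *input*.  The returned sequence is always flipped
        into the canonical anterior-left / cranial-top convention.
    """
    path = Path(path) if not (isinstance(path, str) and any(c in path for c in "*?[")) else path
    spacing: tuple[float, float] | None = None

    if isinstance(path, str):  # glob pattern
        from glob import glob

        files = sorted(Path(p) for p in glob(path))
        if not files:
            raise FormatError(f"glob pattern matched no files: {path}")
        frames = _load_image_stack(files)
        source = path
    elif path.is_dir():
        img_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if img_files:
            frames = _load_image_stack(img_files)
        else:
            frames, spacing = _load_dicom_dir(path)
        source = str(path)
    elif path.suffix in {".nii", ".gz"} or str(path).endswith(".nii.gz"):
        frames, spacing = _load_nifti(path, spacing_override)
        source = str(path)
    else:
        raise FormatError(f"unrecognized sequence input: {path}")

    if spacing_override is not None:
        spacing = (float(spacing_override[0]), float(spacing_override[1]))
    if spacing is None:
        raise ConfigurationError(
            "no pixel spacing in the input header and no spacing_override given"
        )
    if frames.shape[0] < 2:
        raise FormatError(f"a dynamic sequence needs >= 2 frames, got {frames.shape[0]}")

    # normalize display orientation once, here
    if not anterior_is_left:
        frames = frames[:, :, ::-1].copy()
    if not cranial_is_top:
        frames = frames[:, ::-1, :].copy()

    return FrameSequence(
        frames=frames,
        spacing_mm=spacing,
        anterior_is_left=True,
        cranial_is_top=True,
        source_id=source,
    )


def load_roi_set(path, seq: FrameSequence | None = None, margin: int = 0) -> RoiSet:
    """Read an ROI specification JSON and validate it against a sequence.

    Format::

        {"structures": {"distal_rim": {"x": 100, "y": 160, "w": 16, "h": 16}, ...}}

    Coordinates are 0-based pixels on frame 0, ``(x, y)`` the upper-left
    corner of the window.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "structures" not in doc or not isinstance(doc["structures"], Mapping):
        raise FormatError(f"ROI file {path} lacks a 'structures' mapping")
    entries = {}
    for name, win in doc["structures"].items():
        try:
            entries[name] = RoiWindow(int(win["x"]), int(win["y"]), int(win["w"]), int(win["h"]))
        except KeyError as exc:
            raise FormatError(f"ROI '{name}' is missing field {exc}") from exc
    rois = RoiSet(entries=entries)
    if seq is not None:
        rois.validate_bounds(seq, margin=margin)
    return rois


def save_roi_set(rois: RoiSet, path) -> None:
    doc = {
        "structures": {
            name: {"x": w.x, "y": w.y, "w": w.w, "h": w.h} for name, w in rois.items()
        }
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------------------
# tables

TRACK_COLUMNS = ["structure", "frame", "x_px", "y_px", "residual", "fb_error_px", "converged", "valid"]
PICS_TRACK_COLUMNS = ["structure", "frame", "x_pics_mm", "y_pics_mm", "valid"]
KINEMATICS_COLUMNS = [
    "subject",
    "frame",
    "ugh_mm",
    "lh_mm",
    "distal_disp_mm",
    "distal_dx_mm",
    "distal_dy_mm",
    "proximal_disp_mm",
    "proximal_dx_mm",
    "proximal_dy_mm",
    "pessary_angle_deg",
    "valid",
]
CORRELATION_COLUMNS = ["mode", "x_var", "y_var", "r", "ci_low", "ci_high", "p", "n"]

_SCHEMAS = {
    "track": TRACK_COLUMNS,
    "pics_track": PICS_TRACK_COLUMNS,
    "kinematics": KINEMATICS_COLUMNS,
    "correlation": CORRELATION_COLUMNS,
}


def _infer_kind(df: pd.DataFrame) -> str:
    cols = set(df.columns)
    for kind, schema in _SCHEMAS.items():
        if set(schema) <= cols:
            return kind
    raise FormatError(f"table columns {sorted(cols)} match no known schema")


def write_table(table: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a result table as CSV with header and full float precision."""
    if len(table) == 0:
        raise FormatError("refusing to write an empty table")
    kind = kind or _infer_kind(table)
    schema = _SCHEMAS[kind]
    missing = [c for c in schema if c not in table.columns]
    if missing:
        raise FormatError(f"table is missing column '{missing[0]}' required for kind '{kind}'")
    table[schema].to_csv(path, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a table back; columns are keyed by header name, order-free."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind '{kind}'")
    df = pd.read_csv(path)
    schema = _SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column '{missing[0]}' for table kind '{kind}'")
    return df[schema]
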