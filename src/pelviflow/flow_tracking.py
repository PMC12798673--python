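"""Pyramidal Lucas-Kanade tracking of ROI windows through a sequence.

The tracker estimates, for each structure and each consecutive frame pair,
the pure translation ``d`` minimizing the windowed SSD objective

    E(d) = sum_w ( I(p) - J(p + d) )^2

by Gauss-Newton iteration: accumulate the 2x2 gradient normal matrix
``G = sum [Ix^2, Ix*Iy; Ix*Iy, Iy^2]`` and the mismatch vector
``b = sum dI * (Ix, Iy)``, update ``d <- d + G^{-1} b``, and stop when the
update norm drops below ``eps_px``.  Sub-pixel sampling of ``J`` uses
edge-clamped bilinear interpolation; gradients are central differences on a
Gaussian-smoothed image.  A coarse-to-fine image pyramid extends the
capture range beyond the window radius, and a forward-backward consistency
check flags drifting tracks instead of hiding them.

Per-frame positions are chained (frame t -> t+1) from the frame-0 anchor;
the reported coordinate is the upper-left corner of the ROI window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from pelviflow.io_formats import FrameSequence, RoiSet, TRACK_COLUMNS

__all__ = [
    "TrackerParams",
    "StepResult",
    "build_pyramid",
    "refine_displacement",
    "track_pair",
    "track_sequence",
]


@dataclass(frozen=True)
class TrackerParams:
    """Tunable constants of the Lucas-Kanade tracker.

    window_half_px=10 gives the classic 21x21 tracking window; 3 pyramid
    levels at downscale 2 extend the capture range to roughly
    ``window_half_px * downscale**(levels-1)`` pixels of true motion.
    ``min_texture`` is the minimum smaller eigenvalue of the per-pixel-mean
    gradient normal matrix, on [0, 1]-normalized intensities, below which a
    window is declared textureless.
    """

    window_half_px: int = 10
    pyramid_levels: int = 3
    downscale: int = 2
    max_iter: int = 30
    eps_px: float = 0.01
    fb_max_px: float = 1.0
    min_texture: float = 1e-6
    grad_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.window_half_px < 1 or self.pyramid_levels < 1 or self.downscale < 2:
            raise ValueError("window_half_px >= 1, pyramid_levels >= 1, downscale >= 2 required")
        if self.max_iter < 1 or self.eps_px <= 0 or self.fb_max_px <= 0:
            raise ValueError("max_iter, eps_px and fb_max_px must be positive")


@dataclass
class StepResult:
    """Outcome of one displacement estimate between two frames."""

    displacement: np.ndarray  # (dx, dy) px
    residual: float  # mean squared window intensity difference
    converged: bool
    singular: bool  # textureless window: G nearly rank-deficient
    in_bounds: bool = True


def build_pyramid(image: np.ndarray, levels: int, downscale: int = 2) -> list[np.ndarray]:
    """Coarse-to-fine pyramid as a list ordered fine (level 0) to coarse.

    Each level is the previous one smoothed (anti-alias Gaussian,
    sigma = downscale / 2) and decimated by the integer downscale factor.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("build_pyramid expects a 2D image")
    levels = int(levels)
    downscale = int(downscale)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    min_dim = min(image.shape)
    if min_dim // downscale ** (levels - 1) < 2:
        raise ValueError(
            f"{levels} levels at downscale {downscale} exceed image size {image.shape}"
        )
    pyr = [image]
    for _ in range(levels - 1):
        sm = ndi.gaussian_filter(pyr[-1], sigma=downscale / 2.0, mode="nearest")
        pyr.append(sm[::downscale, ::downscale])
    return pyr


def _smooth_and_grad(image: np.ndarray, sigma: float):
    """Gaussian-smoothed image plus central-difference gradients."""
    sm = ndi.gaussian_filter(image, sigma=sigma, mode="nearest") if sigma > 0 else image
    gy, gx = np.gradient(sm)
    return sm, gx, gy


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    # bilinear with edge clamping; coords as (row, col)
    return ndi.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _window_grid(point, half):
    x, y = point
    off = np.arange(-half, half + 1, dtype=np.float64)
    xs, ys = np.meshgrid(x + off, y + off)
    return xs.ravel(), ys.ravel()


def refine_displacement(
    I: np.ndarray,
    J: np.ndarray,
    point: tuple[float, float],
    d0: tuple[float, float] = (0.0, 0.0),
    params: TrackerParams | None = None,
    precomputed: tuple | None = None,
) -> StepResult:
    """Single-level Gauss-Newton refinement of the window displacement.

    ``point`` is the window centre ``(x, y)`` in ``I``; the estimate starts
    from ``d0``.  ``precomputed`` may carry ``(I_sm, Ix, Iy, J_sm)`` to
    avoid re-smoothing when many windows share the same frame pair.
    """
    params = params or TrackerParams()
    if precomputed is not None:
        I_sm, Ix, Iy, J_sm = precomputed
    else:
        I_sm, Ix, Iy = _smooth_and_grad(np.asarray(I, dtype=np.float64), params.grad_sigma)
        J_sm = ndi.gaussian_filter(np.asarray(J, dtype=np.float64), params.grad_sigma, mode="nearest")

    half = params.window_half_px
    xs, ys = _window_grid(point, half)
    Iw = _sample(I_sm, xs, ys)
    gx = _sample(Ix, xs, ys)
    gy = _sample(Iy, xs, ys)

    G = np.array([[np.dot(gx, gx), np.dot(gx, gy)], [np.dot(gx, gy), np.dot(gy, gy)]])
    npix = xs.size
    tr, det = G[0, 0] + G[1, 1], G[0, 0] * G[1, 1] - G[0, 1] ** 2
    eig_min = (tr - np.sqrt(max(tr * tr - 4.0 * det, 0.0))) / 2.0
    if eig_min / npix < params.min_texture:
        dJ = Iw - _sample(J_sm, xs + d0[0], ys + d0[1])
        return StepResult(np.asarray(d0, dtype=np.float64), float(np.mean(dJ**2)), False, True)

    d = np.asarray(d0, dtype=np.float64).copy()
    converged = False
    resid = np.inf
    h, w = I_sm.shape
    in_bounds = True
    for _ in range(params.max_iter):
        Jw = _sample(J_sm, xs + d[0], ys + d[1])
        diff = Iw - Jw
        b = np.array([np.dot(diff, gx), np.dot(diff, gy)])
        upd = np.linalg.solve(G, b)
        d += upd
        if not (0 <= point[0] + d[0] <= w - 1 and 0 <= point[1] + d[1] <= h - 1):
            in_bounds = False
        if float(np.hypot(upd[0], upd[1])) < params.eps_px:
            converged = True
            break
    resid = float(np.mean((Iw - _sample(J_sm, xs + d[0], ys + d[1])) ** 2))
    return StepResult(d, resid, converged, False, in_bounds)


def track_pair(
    I: np.ndarray,
    J: np.ndarray,
    point: tuple[float, float],
    params: TrackerParams | None = None,
    pyramids: tuple[list, list] | None = None,
) -> StepResult:
    """Coarse-to-fine displacement of the window at ``point`` from I to J.

    Runs :func:`refine_displacement` on each pyramid level from coarsest to
    finest, scaling the running displacement by the downscale factor at
    each level change.  ``pyramids`` may carry precomputed
    ``(levels_I, levels_J)`` where each level is ``(sm, gx, gy)``.
    """
    params = params or TrackerParams()
    k = params.downscale
    if pyramids is None:
        pyr_I = [_smooth_and_grad(l, params.grad_sigma) for l in build_pyramid(I, params.pyramid_levels, k)]
        pyr_J = [_smooth_and_grad(l, params.grad_sigma) for l in build_pyramid(J, params.pyramid_levels, k)]
    else:
        pyr_I, pyr_J = pyramids

    levels = len(pyr_I)
    d = np.zeros(2)
    result = None
    for lvl in range(levels - 1, -1, -1):
        scale = float(k**lvl)
        p_l = (point[0] / scale, point[1] / scale)
        I_sm, Ix, Iy = pyr_I[lvl]
        J_sm = pyr_J[lvl][0]
        result = refine_displacement(
            None, None, p_l, tuple(d / scale), params, precomputed=(I_sm, Ix, Iy, J_sm)
        )
        d = result.displacement * scale
    assert result is not None
    return StepResult(d, result.residual, result.converged, result.singular, result.in_bounds)


def _precompute_pyramids(frames: np.ndarray, params: TrackerParams) -> list[list]:
    out = []
    for f in frames:
        levels = build_pyramid(f, params.pyramid_levels, params.downscale)
        out.append([_smooth_and_grad(l, params.grad_sigma) for l in levels])
    return out


def track_sequence(
    seq: FrameSequence, rois: RoiSet, params: TrackerParams | None = None
) -> pd.DataFrame:
    """Track every ROI through the whole sequence.

    Returns a track table (one row per structure and frame) with the
    tracked upper-left anchor in pixels, the forward residual, the
    forward-backward error, and convergence/validity flags.  Frame-0 rows
    reproduce the ROI anchors exactly.  Rows failing the forward-backward
    gate (or not converging) are flagged ``valid=False`` but chaining
    continues from the forward estimate; a structure whose window centre
    leaves the frame stays flagged invalid for all remaining frames.
    """
    params = params or TrackerParams()
    frames = seq.normalized()
    rois.validate_bounds(seq, margin=0)
    pyramids = _precompute_pyramids(frames, params)
    h, w = seq.height, seq.width

    rows: list[dict] = []
    warnings: list[str] = []
    for name, win in rois.items():
        half_size = np.array([win.w / 2.0, win.h / 2.0])
        center = np.array(win.center, dtype=np.float64)
        rows.append(
            dict(structure=name, frame=0, x_px=float(win.x), y_px=float(win.y),
                 residual=0.0, fb_error_px=0.0, converged=True, valid=True)
        )
        lost = False
        any_valid = True
        for t in range(seq.n_frames - 1):
            if lost:
                rows.append(
                    dict(structure=name, frame=t + 1, x_px=float(center[0] - half_size[0]),
                         y_px=float(center[1] - half_size[1]), residual=np.nan,
                         fb_error_px=np.nan, converged=False, valid=False)
                )
                continue
            fwd = track_pair(None, None, tuple(center), params, (pyramids[t], pyramids[t + 1]))
            new_center = center + fwd.displacement
            bwd = track_pair(None, None, tuple(new_center), params, (pyramids[t + 1], pyramids[t]))
            fb = float(np.linalg.norm(fwd.displacement + bwd.displacement))
            inside = bool(0 <= new_center[0] <= w - 1 and 0 <= new_center[1] <= h - 1)
            valid = fwd.converged and not fwd.singular and fb <= params.fb_max_px and inside
            rows.append(
                dict(structure=name, frame=t + 1, x_px=float(new_center[0] - half_size[0]),
                     y_px=float(new_center[1] - half_size[1]), residual=fwd.residual,
                     fb_error_px=fb, converged=bool(fwd.converged), valid=bool(valid))
            )
            center = new_center
            if not inside:
                lost = True

        struct_rows = [r for r in rows if r["structure"] == name and r["frame"] > 0]
        if struct_rows and not any(r["valid"] for r in struct_rows):
            warnings.append(f"structure '{name}': no valid tracked frame beyond frame 0")

    table = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    table.attrs["tracker_params"] = asdict(params)
    table.attrs["warnings"] = warnings
    return table
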