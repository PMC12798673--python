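"""Synthetic dynamic midsagittal pelvic phantom with exact ground truth.

No patient imaging ships with this package, so every upstream stage is
validated against a generated supine-Valsalva look-alike: bony landmarks
(inferior pubic point, sacrococcygeal joint, ~110 mm apart) move only by a
global rigid motion of the whole scene, while soft structures (the two
pessary rim cross-sections, perineal body, anorectal angle) additionally
deform in the pelvis frame — the distal rim descends caudally by
``descent_amplitude_mm * s(t)`` along a monotone strain profile ``s``, and
the hiatus endpoints move radially away from the pubic point so that the
true hiatus enlargement is exactly ``coupling * descent``.  The global
motion is applied *last*, so the per-frame PICS refit must undo exactly
this outer motion; pelvis-frame trajectories are the invariant truth.

Rendering composites, per frame, a fixed seeded texture patch per
structure (rims as hypointense discs on brighter tissue, echoing their MRI
appearance) onto a static low-frequency background with sub-pixel bilinear
resampling, then adds Gaussian intensity noise.  Because each patch
translates rigidly with its structure, the ground-truth trajectory *is*
the local image motion and tracking error is well defined.

A lightweight companion, :func:`make_kinematics_ensemble`, generates
kinematics tables directly (no imaging) with a controlled population
correlation between displacement and hiatus change, as the statistical
test substrate for the correlation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from pelviflow.io_formats import (
    CANONICAL_STRUCTURES,
    KINEMATICS_COLUMNS,
    FrameSequence,
    RoiSet,
    RoiWindow,
)
from pelviflow.pics_coords import PicsParams, apply_transform, fit_pics

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "strain_profile",
    "make_phantom",
    "make_kinematics_ensemble",
]

SOFT_STRUCTURES = ("distal_rim", "proximal_rim", "perineal_body", "anorectal_angle")

#: Rest-pose structure centres (mm, scanner frame, anterior left / cranial
#: top) for the default 256 mm field of view.  SCIPP separation ~111 mm;
#: rest UGH ~45 mm, rest LH ~62 mm; rim separation set by the spec field.
_BASE_LAYOUT = {
    "inferior_pubic_point": (88.0, 108.0),
    "sacrococcygeal_joint": (196.0, 82.0),
    "perineal_body": (98.0, 152.0),
    "anorectal_angle": (134.0, 150.0),
    "distal_rim": (118.0, 182.0),
}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    Defaults emulate a 30-frame supine Valsalva at 1 mm/px with 15 mm of
    distal-rim descent, hiatus coupling 0.9 mm/mm (UGH) and 0.7 mm/mm
    (LH), a 10 degree change of pelvic inclination, and a 70 mm rim
    separation (midsagittal cross-section of a size-3/4 ring pessary).
    """

    image_size: tuple[int, int] = (256, 256)
    mm_per_px: float = 1.0
    n_frames: int = 30
    profile: str = "smoothstep"
    descent_amplitude_mm: float = 15.0
    ugh_coupling: float = 0.9
    lh_coupling: float = 0.7
    inclination_change_deg: float = 10.0
    global_drift_mm: tuple[float, float] = (0.0, 0.0)
    rim_separation_mm: float = 70.0
    rim_radius_mm: float = 4.0
    rim_rotation_deg: float = 10.0
    noise_sigma: float = 0.01
    texture_scale: float = 1.5
    roi_half_px: int = 8
    seed: int = 0
    allow_exit: bool = False  # permit trajectories leaving the frame (failure-mode tests)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if min(self.image_size) <= 0 or self.mm_per_px <= 0:
            raise ValueError("image dimensions and spacing must be positive")
        if self.descent_amplitude_mm < 0 or self.ugh_coupling < 0 or self.lh_coupling < 0:
            raise ValueError("descent amplitude and couplings must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth emitted alongside the rendered sequence.

    ``positions``: scanner-frame upper-left ROI anchor per (structure,
    frame), in mm and px.  ``kinematics``: the true per-frame kinematics
    table (PICS frame).  ``roi_set``: frame-0 ROI windows whose anchors
    equal the frame-0 truth exactly.
    """

    positions: pd.DataFrame
    kinematics: pd.DataFrame
    roi_set: RoiSet
    spec: PhantomSpec


def strain_profile(frame_index: int, n_frames: int, kind: str = "smoothstep") -> float:
    """Monotone rest->maximal-strain progression s with s(0)=0, s(last)=1.

    ``linear`` ramps uniformly; ``smoothstep`` (default) is the cubic
    3u^2 - 2u^3 easing, zero-slope at both ends like a coached Valsalva;
    ``hold`` ramps linearly over the first half then holds maximal strain.
    """
    if not 0 <= frame_index < n_frames:
        raise ValueError(f"frame_index {frame_index} outside [0, {n_frames})")
    u = frame_index / (n_frames - 1)
    if kind == "linear":
        return float(u)
    if kind == "smoothstep":
        return float(u * u * (3.0 - 2.0 * u))
    if kind == "hold":
        return float(min(1.0, 2.0 * u))
    raise ValueError(f"unknown strain profile kind '{kind}'")


def _rot(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _rest_layout(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Rest-pose centres (mm), snapped to integer pixels.

    Snapping before any trajectory is derived keeps the emitted ROI
    anchors exact integers while the truth kinematics stay exactly the
    closed-form couplings.
    """
    scale = min(spec.image_size) * spec.mm_per_px / 256.0
    base = {k: np.array(v) * scale for k, v in _BASE_LAYOUT.items()}
    base["proximal_rim"] = base["distal_rim"] + spec.rim_separation_mm * np.array(
        [np.cos(np.deg2rad(-65.0)), np.sin(np.deg2rad(-65.0))]
    )
    return {k: np.round(v / spec.mm_per_px) * spec.mm_per_px for k, v in base.items()}


def _pelvis_frame_centers(spec: PhantomSpec, s: float) -> dict[str, np.ndarray]:
    """Structure centres at strain s in the pelvis frame (scanner mm, rest pose)."""
    base = _rest_layout(spec)
    if s == 0.0:
        return {k: v.copy() for k, v in base.items()}
    pubic = base["inferior_pubic_point"]
    dist0 = base["distal_rim"]
    prox0 = base["proximal_rim"]

    T0 = fit_pics(pubic, base["sacrococcygeal_joint"], PicsParams())
    caudal = T0.matrix[1]  # PICS +y expressed in scanner coords

    out = dict(
        inferior_pubic_point=pubic.copy(),
        sacrococcygeal_joint=base["sacrococcygeal_joint"].copy(),
    )
    descent = spec.descent_amplitude_mm * s
    out["distal_rim"] = dist0 + descent * caudal
    out["proximal_rim"] = out["distal_rim"] + _rot(np.deg2rad(spec.rim_rotation_deg) * s) @ (
        prox0 - dist0
    )
    for name, coupling in (("perineal_body", spec.ugh_coupling), ("anorectal_angle", spec.lh_coupling)):
        p0 = base[name]
        u = p0 - pubic
        r0 = np.linalg.norm(u)
        out[name] = pubic + (r0 + coupling * descent) * (u / r0)
    return out


def _global_motion(spec: PhantomSpec, s: float):
    center = np.array([spec.image_size[1], spec.image_size[0]]) * spec.mm_per_px / 2.0
    R = _rot(np.deg2rad(spec.inclination_change_deg) * s)
    drift = np.array(spec.global_drift_mm) * s

    def g(p: np.ndarray) -> np.ndarray:
        return R @ (p - center) + center + drift

    return g


def _true_centers(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Scanner-frame centre trajectories, (n_frames, 2) mm per structure."""
    out = {k: np.zeros((spec.n_frames, 2)) for k in CANONICAL_STRUCTURES}
    for t in range(spec.n_frames):
        s = strain_profile(t, spec.n_frames, spec.profile)
        pelvis = _pelvis_frame_centers(spec, s)
        g = _global_motion(spec, s) if s != 0.0 else (lambda p: p)
        for k in CANONICAL_STRUCTURES:
            out[k][t] = g(pelvis[k])
    return out


def _true_kinematics(spec: PhantomSpec, subject_id: str) -> pd.DataFrame:
    """True kinematics from pelvis-frame trajectories and the rest PICS fit.

    Because the global motion is the outermost operation and the PICS
    transform is refit per frame from the moved landmarks, PICS
    coordinates equal the rest-fit transform applied to pelvis-frame
    positions; all truth quantities follow from that identity.
    """
    base = _rest_layout(spec)
    T0 = fit_pics(base["inferior_pubic_point"], base["sacrococcygeal_joint"], PicsParams())

    rows = []
    rest = _pelvis_frame_centers(spec, 0.0)
    rest_pics = {k: apply_transform(T0, v) for k, v in rest.items()}
    ugh0 = np.linalg.norm(rest["perineal_body"] - rest["inferior_pubic_point"])
    lh0 = np.linalg.norm(rest["anorectal_angle"] - rest["inferior_pubic_point"])
    for t in range(spec.n_frames):
        s = strain_profile(t, spec.n_frames, spec.profile)
        pelvis = _pelvis_frame_centers(spec, s)
        pics = {k: apply_transform(T0, v) for k, v in pelvis.items()}
        d_dist = pics["distal_rim"] - rest_pics["distal_rim"]
        d_prox = pics["proximal_rim"] - rest_pics["proximal_rim"]
        axis = pics["proximal_rim"] - pics["distal_rim"]
        ang = np.degrees(np.arctan2(axis[1], axis[0]))
        if ang <= -180.0:
            ang += 360.0
        rows.append(
            dict(
                subject=subject_id,
                frame=t,
                ugh_mm=ugh0 + spec.ugh_coupling * spec.descent_amplitude_mm * s,
                lh_mm=lh0 + spec.lh_coupling * spec.descent_amplitude_mm * s,
                distal_disp_mm=float(np.linalg.norm(d_dist)),
                distal_dx_mm=float(d_dist[0]),
                distal_dy_mm=float(d_dist[1]),
                proximal_disp_mm=float(np.linalg.norm(d_prox)),
                proximal_dx_mm=float(d_prox[0]),
                proximal_dy_mm=float(d_prox[1]),
                pessary_angle_deg=float(ang),
                valid=True,
            )
        )
    return pd.DataFrame(rows, columns=KINEMATICS_COLUMNS)


def _make_patch(rng: np.random.Generator, radius_px: int, spec: PhantomSpec, kind: str):
    """Texture patch and soft radial mask for one structure."""
    size = 2 * radius_px + 1
    tex = ndi.gaussian_filter(rng.standard_normal((size, size)), spec.texture_scale)
    tex -= tex.min()
    if tex.max() > 0:
        tex /= tex.max()
    yy, xx = np.mgrid[0:size, 0:size] - radius_px
    rr = np.hypot(xx, yy)
    if kind == "bone":
        # high-contrast, strongly textured: landmark tracking must not be
        # the limiting error source in coordinate-normalization tests
        tex = 0.15 + 0.85 * tex
    elif kind == "rim":
        # hypointense disc (the pessary cross-section) on brighter tissue
        tex = 0.45 + 0.45 * tex
        rim_px = spec.rim_radius_mm / spec.mm_per_px
        tex = np.where(rr <= rim_px, 0.05 + 0.05 * tex, tex)
    else:
        tex = 0.35 + 0.55 * tex
    mask = np.clip((radius_px - 1.5 - rr) / 3.0 + 0.5, 0.0, 1.0)
    return tex, mask


def _render_frame(canvas, patches, centers_px):
    """Composite each patch at its (sub-pixel) centre onto a copy of canvas."""
    out = canvas.copy()
    h, w = out.shape
    for name, (tex, mask) in patches.items():
        cx, cy = centers_px[name]
        radius = (tex.shape[0] - 1) // 2
        ix, iy = int(np.floor(cx)), int(np.floor(cy))
        fx, fy = cx - ix, cy - iy
        # shift patch and mask by the fractional part (bilinear)
        size = tex.shape[0]
        rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
        coords = [rr - fy, cc - fx]
        tex_s = ndi.map_coordinates(tex, coords, order=1, mode="nearest")
        mask_s = ndi.map_coordinates(mask, coords, order=1, mode="constant", cval=0.0)
        y0, x0 = iy - radius, ix - radius
        ys, xs = slice(max(0, y0), min(h, y0 + size)), slice(max(0, x0), min(w, x0 + size))
        pys = slice(ys.start - y0, ys.stop - y0)
        pxs = slice(xs.start - x0, xs.stop - x0)
        m = mask_s[pys, pxs]
        out[ys, xs] = out[ys, xs] * (1.0 - m) + tex_s[pys, pxs] * m
    return out


def make_phantom(spec: PhantomSpec | None = None) -> tuple[FrameSequence, GroundTruth]:
    """Render a synthetic dynamic sequence and its exact ground truth.

    All randomness (background, textures, noise) derives from
    ``spec.seed``; identical specs give bit-identical output.  The emitted
    ROI set uses uniform ``2*roi_half_px`` square windows whose upper-left
    anchors coincide exactly with the frame-0 truth.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    mmpp = spec.mm_per_px

    centers_mm = _true_centers(spec)
    half = spec.roi_half_px
    patch_radius = max(12, half + 4)
    rest_px = {k: centers_mm[k][0] / mmpp for k in CANONICAL_STRUCTURES}

    # bounds check on the full trajectory
    for k in CANONICAL_STRUCTURES:
        px = centers_mm[k] / mmpp
        if not spec.allow_exit and (
            px[:, 0].min() < patch_radius
            or px[:, 1].min() < patch_radius
            or px[:, 0].max() > w - 1 - patch_radius
            or px[:, 1].max() > h - 1 - patch_radius
        ):
            raise GenerationError(f"trajectory of structure '{k}' leaves the field of view")

    background = ndi.gaussian_filter(rng.standard_normal((h, w)), 25.0)
    background -= background.min()
    if background.max() > 0:
        background /= background.max()
    background = 0.30 + 0.20 * background

    patches = {}
    for k in CANONICAL_STRUCTURES:
        kind = "bone" if k in ("inferior_pubic_point", "sacrococcygeal_joint") else (
            "rim" if k.endswith("_rim") else "soft"
        )
        patches[k] = _make_patch(rng, patch_radius, spec, kind)

    frames = np.empty((spec.n_frames, h, w))
    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    for t in range(spec.n_frames):
        centers_px = {k: centers_mm[k][t] / mmpp for k in CANONICAL_STRUCTURES}
        frame = _render_frame(background, patches, centers_px)
        if spec.noise_sigma > 0:
            frame = frame + noise_rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[t] = frame

    seq = FrameSequence(frames=frames, spacing_mm=(mmpp, mmpp), source_id=f"phantom(seed={spec.seed})")

    # truth anchors: window upper-left = centre - half window (axis-aligned)
    pos_rows = []
    for k in CANONICAL_STRUCTURES:
        for t in range(spec.n_frames):
            ax = centers_mm[k][t][0] / mmpp - half
            ay = centers_mm[k][t][1] / mmpp - half
            pos_rows.append(
                dict(structure=k, frame=t, x_px=ax, y_px=ay, x_mm=ax * mmpp, y_mm=ay * mmpp)
            )
    positions = pd.DataFrame(pos_rows)

    rois = RoiSet(
        entries={
            k: RoiWindow(int(round(rest_px[k][0] - half)), int(round(rest_px[k][1] - half)),
                         2 * half, 2 * half)
            for k in CANONICAL_STRUCTURES
        }
    )
    truth_kin = _true_kinematics(spec, subject_id=f"phantom_{spec.seed}")
    return seq, GroundTruth(positions=positions, kinematics=truth_kin, roi_set=rois, spec=spec)


# ---------------------------------------------------------------------------
# kinematics-only ensembles for the statistics layer


def make_kinematics_ensemble(
    n_subjects: int = 6,
    n_frames: int = 30,
    target_rho: float | None = None,
    per_subject_coupling_sd: float = 0.0,
    noise_sd: float | None = None,
    endpoint_noise_sd: float = 0.0,
    seed: int = 0,
    amplitude_range_mm: tuple[float, float] = (5.0, 20.0),
    base_coupling: float = 0.9,
    lh_coupling: float = 0.7,
    rest_ugh_mm: float = 40.0,
    rest_lh_mm: float = 55.0,
    profile: str = "smoothstep",
) -> tuple[list[pd.DataFrame], dict]:
    """Kinematics tables with a controlled displacement-hiatus correlation.

    Per subject: displacement follows a monotone strain profile with a
    random amplitude; hiatus change is ``coupling_i * displacement`` plus
    iid frame noise, where the subject couplings scatter around
    ``base_coupling`` with sd ``per_subject_coupling_sd`` (this subject-level
    heterogeneity is what degrades the start-end analysis most, since it
    hits the endpoints hardest).  ``endpoint_noise_sd`` adds a per-subject
    random hiatus offset that grows with strain — subject-level noise that
    lands fully on the endpoints, degrading the six-point start-end
    analysis while the pooled frame-by-frame cloud keeps its
    through-the-origin geometry.  Exactly one of ``target_rho`` /
    ``noise_sd`` must be given; with ``target_rho`` the frame-noise sd is
    solved from the realized design moments (the drawn amplitudes and
    couplings) so that the pooled framewise correlation of non-rest frames
    equals ``target_rho`` up to sampling noise of the residuals alone.
    """
    if (target_rho is None) == (noise_sd is None):
        raise ValueError("give exactly one of target_rho or noise_sd")
    rng = np.random.default_rng(seed)
    a_lo, a_hi = amplitude_range_mm
    s = np.array([strain_profile(t, n_frames, profile) for t in range(n_frames)])

    amps = rng.uniform(a_lo, a_hi, size=n_subjects)
    kappas = base_coupling + rng.normal(0.0, per_subject_coupling_sd, size=n_subjects)
    kappas_lh = lh_coupling + rng.normal(0.0, per_subject_coupling_sd, size=n_subjects)
    offsets = rng.normal(0.0, endpoint_noise_sd, size=n_subjects) if endpoint_noise_sd > 0 else np.zeros(n_subjects)

    if target_rho is not None:
        if not 0.0 < target_rho <= 1.0:
            raise ValueError("target_rho must be in (0, 1]")
        # realized pooled sample (rest frame excluded, as in the analysis)
        d = np.concatenate([a * s[1:] for a in amps])
        h0 = np.concatenate([k * a * s[1:] for a, k in zip(amps, kappas)])
        var_d = d.var()
        cov0 = np.mean(d * h0) - d.mean() * h0.mean()
        # rho^2 = cov0^2 / (var_d * (var_h0 + sigma^2))
        sigma2 = cov0**2 / (var_d * target_rho**2) - h0.var()
        if sigma2 < 0:
            raise ValueError(
                f"target_rho={target_rho} unattainable: coupling heterogeneity alone "
                "already depresses the pooled correlation below the target"
            )
        noise_sd = float(np.sqrt(sigma2))

    tables: list[pd.DataFrame] = []
    truths = {"noise_sd": noise_sd, "subjects": []}
    for i in range(n_subjects):
        amp = amps[i]
        kappa = kappas[i]
        kappa_lh = kappas_lh[i]
        disp = amp * s
        ugh = rest_ugh_mm + kappa * disp + offsets[i] * s + rng.normal(0.0, noise_sd, size=n_frames)
        lh = rest_lh_mm + kappa_lh * disp + offsets[i] * s + rng.normal(0.0, noise_sd, size=n_frames)
        ugh[0] = rest_ugh_mm  # rest frame is the noise-free reference
        lh[0] = rest_lh_mm
        tab = pd.DataFrame(
            dict(
                subject=f"S{i + 1}",
                frame=np.arange(n_frames),
                ugh_mm=ugh,
                lh_mm=lh,
                distal_disp_mm=disp,
                distal_dx_mm=0.0,
                distal_dy_mm=disp,
                proximal_disp_mm=disp,
                proximal_dx_mm=0.0,
                proximal_dy_mm=disp,
                pessary_angle_deg=0.0,
                valid=True,
            )
        )[KINEMATICS_COLUMNS]
        tables.append(tab)
        truths["subjects"].append(dict(subject=f"S{i + 1}", amplitude_mm=amp, ugh_coupling=kappa,
                                       lh_coupling=kappa_lh))
    return tables, truths
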