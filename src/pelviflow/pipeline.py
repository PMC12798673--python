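"""End-to-end orchestration: track -> PICS -> kinematics -> statistics.

A run takes either real inputs (per subject: a dynamic sequence plus an
ROI JSON) or a phantom ensemble specification, processes every subject
independently, and writes per-subject CSV tables, a pooled statistics
JSON (both correlation modes for both hiatus measures), trajectory and
scatter figures, and a plain-text log.  A subject that fails hard is
recorded and skipped; the run only exits non-zero when every subject
fails.  Given the same config and seed the outputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from pelviflow.correlation_stats import (
    cluster_bootstrap_ci,
    framewise_correlation,
    start_end_correlation,
)
from pelviflow.flow_tracking import TrackerParams, track_sequence
from pelviflow.io_formats import load_roi_set, load_sequence, write_table
from pelviflow.kinematics import assemble_kinematics
from pelviflow.phantom import PhantomSpec, make_phantom
from pelviflow.pics_coords import PicsParams, pics_series

__all__ = ["RunConfig", "SubjectInput", "run_pipeline"]

log = logging.getLogger("pelviflow")


@dataclass
class SubjectInput:
    subject_id: str
    sequence_path: str
    roi_path: str
    spacing_mm: tuple[float, float] | None = None


@dataclass
class RunConfig:
    """Full description of one analysis run."""

    out_dir: str
    subjects: list[SubjectInput] = field(default_factory=list)
    phantom_subjects: int = 0  # when > 0, simulate instead of loading
    phantom_overrides: dict = field(default_factory=dict)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    pics: PicsParams = field(default_factory=PicsParams)
    x_var: str = "distal_disp_mm"
    y_mode: str = "change"
    make_plots: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in {".yaml", ".yml"}:
                import yaml

                doc = yaml.safe_load(fh)
            else:
                doc = json.load(fh)
        subjects = [SubjectInput(**s) for s in doc.pop("subjects", [])]
        tracker = TrackerParams(**doc.pop("tracker", {}))
        pics = PicsParams(**doc.pop("pics", {}))
        return cls(subjects=subjects, tracker=tracker, pics=pics, **doc)


def _phantom_specs(config: RunConfig) -> list[PhantomSpec]:
    """One spec per simulated subject, seeds and descent amplitudes varied."""
    specs = []
    n = config.phantom_subjects
    for i in range(n):
        overrides = dict(config.phantom_overrides)
        overrides.setdefault("descent_amplitude_mm", 5.0 + 15.0 * i / max(n - 1, 1))
        specs.append(PhantomSpec(seed=config.seed * 1000 + i, **overrides))
    return specs


def _analyze_subject(seq, rois, subject_id, config: RunConfig):
    tracks = track_sequence(seq, rois, config.tracker)
    transforms, pics_tracks = pics_series(tracks, seq, config.pics)
    kin = assemble_kinematics(pics_tracks, subject_id)
    return tracks, pics_tracks, kin


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the statistics document as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> dict:
    log.info("run config: %s", json.dumps(_config_echo(config), indent=2))
    (out / "config_echo.json").write_text(json.dumps(_config_echo(config), indent=2))

    kin_tables: list[pd.DataFrame] = []
    pics_by_subject: dict[str, pd.DataFrame] = {}
    failures: list[str] = []

    if config.phantom_subjects > 0:
        inputs = [(f"phantom_{i}", spec) for i, spec in enumerate(_phantom_specs(config))]
    else:
        inputs = [(s.subject_id, s) for s in config.subjects]
    if not inputs:
        raise ValueError("run config lists no subjects")

    for subject_id, src in inputs:
        try:
            if isinstance(src, PhantomSpec):
                seq, truth = make_phantom(src)
                rois = truth.roi_set
            else:
                seq = load_sequence(src.sequence_path, spacing_override=src.spacing_mm)
                rois = load_roi_set(src.roi_path, seq)
            tracks, pics_tracks, kin = _analyze_subject(seq, rois, subject_id, config)
            sub_dir = out / subject_id
            sub_dir.mkdir(exist_ok=True)
            write_table(tracks, sub_dir / "tracks.csv", kind="track")
            write_table(pics_tracks, sub_dir / "pics_tracks.csv", kind="pics_track")
            write_table(kin, sub_dir / "kinematics.csv", kind="kinematics")
            for warning in tracks.attrs.get("warnings", []):
                log.warning("%s: %s", subject_id, warning)
            n_invalid = int((~kin["valid"].astype(bool)).sum())
            if n_invalid:
                log.warning("%s: %d invalid kinematics frames", subject_id, n_invalid)
            kin_tables.append(kin)
            pics_by_subject[subject_id] = pics_tracks
        except Exception as exc:  # keep processing remaining subjects
            log.error("subject %s failed: %s", subject_id, exc)
            failures.append(subject_id)

    if not kin_tables:
        raise RuntimeError(f"all {len(inputs)} subjects failed")

    stats = {"analyses": [], "diagnostics": {}, "failed_subjects": failures}
    for hiatus in ("ugh", "lh"):
        try:
            fw = framewise_correlation(kin_tables, config.x_var, hiatus, config.y_mode)
            stats["analyses"].append(fw.to_dict())
        except Exception as exc:
            log.error("framewise %s correlation failed: %s", hiatus, exc)
        try:
            se = start_end_correlation(kin_tables, config.x_var, hiatus)
            stats["analyses"].append(se.to_dict())
        except Exception as exc:
            log.error("start-end %s correlation failed: %s", hiatus, exc)
    try:
        lo, hi = cluster_bootstrap_ci(kin_tables, config.x_var, "ugh", config.y_mode,
                                      seed=config.seed)
        stats["diagnostics"]["ugh_framewise_cluster_bootstrap_ci"] = [lo, hi]
    except Exception as exc:
        log.warning("cluster bootstrap skipped: %s", exc)

    with open(out / "stats.json", "w") as fhj:
        json.dump(stats, fhj, indent=2)

    if config.make_plots:
        try:
            _make_plots(pics_by_subject, kin_tables, config, out)
        except Exception as exc:
            log.warning("plotting failed: %s", exc)

    log.info("run complete: %d subjects analyzed, %d failed", len(kin_tables), len(failures))
    return stats


def _config_echo(config: RunConfig) -> dict:
    doc = dataclasses.asdict(config)
    return doc


def _make_plots(pics_by_subject, kin_tables, config: RunConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # trajectory panel per subject in PICS coordinates
    n = len(pics_by_subject)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 4 * nrows), squeeze=False)
    for ax, (subject, pics_df) in zip(axes.ravel(), pics_by_subject.items()):
        for structure in ("distal_rim", "proximal_rim", "perineal_body", "anorectal_angle"):
            sub = pics_df[(pics_df["structure"] == structure) & pics_df["valid"]]
            ax.plot(sub["x_pics_mm"], sub["y_pics_mm"], ".-", ms=3, label=structure)
        ax.invert_yaxis()  # caudal is +y; plot descent downward
        ax.set_title(subject)
        ax.set_xlabel("PICS x (mm, posterior +)")
        ax.set_ylabel("PICS y (mm, caudal +)")
    axes.ravel()[0].legend(fontsize=7)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "trajectories.png", dpi=120)
    plt.close(fig)

    # pooled displacement-vs-hiatus-change scatter
    fig, ax = plt.subplots(figsize=(5, 4))
    for kin in kin_tables:
        sub = kin[kin["valid"].astype(bool)].sort_values("frame")
        if sub.empty:
            continue
        y = sub["ugh_mm"] - sub["ugh_mm"].iloc[0]
        ax.plot(sub[config.x_var], y, ".", ms=4, label=str(sub["subject"].iloc[0]))
    ax.set_xlabel(f"{config.x_var}")
    ax.set_ylabel("UGH change from rest (mm)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "displacement_vs_hiatus.png", dpi=120)
    plt.close(fig)
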