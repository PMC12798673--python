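"""Correlation and reproducibility statistics.

Pearson correlation between pessary displacement and hiatus size change is
computed in two modes:

* **framewise** — every valid (subject, frame) pair pooled into one sample,
  the frame-by-frame analysis; the confidence interval treats frames as
  independent observations, which is optimistic but matches how pooled
  frame counts enter the reported intervals.  A subject-level cluster
  bootstrap is available as a diagnostic beyond that convention.
* **start_end** — one point per subject: displacement and hiatus change
  between the first and last valid frames, the conventional two-frame
  analysis.

Inference follows the classical recipe: the 95% CI by Fisher's z
transformation, ``tanh(atanh(r) ± z_{1-a/2} / sqrt(n-3))``, and the
two-sided p-value from ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2``
degrees of freedom.  ICC(2,1) (two-way random effects, absolute agreement,
single measurement) quantifies tracking reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "IccResult",
    "pearson_ci",
    "correlation_from_summary",
    "framewise_correlation",
    "start_end_correlation",
    "cluster_bootstrap_ci",
    "icc_2_1",
]


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    """Raised when one of the series has zero variance."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    mode: str
    x_var: str
    y_var: str

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self) -> dict:
        """Report-style rounding: r and CI to 2 decimals, p to 3."""
        d = self.to_dict()
        d["r"] = round(d["r"], 2)
        d["ci_low"] = round(d["ci_low"], 2)
        d["ci_high"] = round(d["ci_high"], 2)
        d["p"] = round(d["p"], 3)
        return d


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_targets: int
    n_raters: int


def correlation_from_summary(r: float, n: int, alpha: float = 0.05) -> tuple[float, float, float]:
    """(ci_low, ci_high, p) from a correlation coefficient and sample size.

    This is the inference layer alone, applicable when only summary
    statistics are available.  |r| = 1 is returned as a degenerate interval
    [r, r] with p = 0.
    """
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 pairs for inference, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return r, r, 0.0
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    ci_low, ci_high = np.tanh(z - half), np.tanh(z + half)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(ci_low), float(ci_high), float(p)


def pearson_ci(
    x,
    y,
    alpha: float = 0.05,
    mode: str = "framewise",
    x_var: str = "x",
    y_var: str = "y",
) -> CorrelationResult:
    """Pearson r with Fisher-z CI and t-based two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 finite pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the series")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    ci_low, ci_high, p = correlation_from_summary(r, n, alpha)
    return CorrelationResult(r, ci_low, ci_high, p, n, mode, x_var, y_var)


def _subject_tables(tables) -> list[pd.DataFrame]:
    if isinstance(tables, pd.DataFrame):
        return [grp for _, grp in tables.groupby("subject", sort=True)]
    return list(tables)


def _xy_for_subject(
    tab: pd.DataFrame, x_var: str, hiatus: str, y_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = tab[tab["valid"].astype(bool)].sort_values("frame")
    if sub.empty:
        return np.array([]), np.array([])
    x = sub[x_var].to_numpy(dtype=np.float64)
    y = sub[f"{hiatus}_mm"].to_numpy(dtype=np.float64)
    if y_mode == "change":
        y = y - y[0]  # change from the first valid (rest) frame
    # the rest frame is the displacement reference (identically zero) and
    # carries no information; dropping it also makes one-frame-pair input
    # degenerate exactly to the start-end analysis
    return x[1:], y[1:]


def framewise_correlation(
    tables,
    x_var: str = "distal_disp_mm",
    hiatus: Literal["ugh", "lh"] = "ugh",
    y_mode: Literal["change", "raw"] = "change",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pooled frame-by-frame correlation across subjects.

    Defaults: x = distal-rim displacement magnitude, y = hiatus change from
    the rest frame (removes between-subject hiatus size offsets);
    ``y_mode='raw'`` correlates against absolute hiatus size instead.
    """
    xs, ys = [], []
    for tab in _subject_tables(tables):
        x, y = _xy_for_subject(tab, x_var, hiatus, y_mode)
        if x.size >= 1:  # at least one non-rest frame
            xs.append(x)
            ys.append(y)
    if not xs:
        raise InsufficientDataError("no subject contributed a valid non-rest frame")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    y_name = f"{hiatus}_{'change' if y_mode == 'change' else 'size'}_mm"
    return pearson_ci(x, y, alpha, mode="framewise", x_var=x_var, y_var=y_name)


def start_end_correlation(
    tables,
    x_var: str = "distal_disp_mm",
    hiatus: Literal["ugh", "lh"] = "ugh",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Start-to-end correlation: one (displacement, hiatus change) point per subject."""
    xs, ys = [], []
    for tab in _subject_tables(tables):
        sub = tab[tab["valid"].astype(bool)].sort_values("frame")
        if len(sub) < 2:
            continue
        first, last = sub.iloc[0], sub.iloc[-1]
        xs.append(last[x_var] - first[x_var])
        ys.append(last[f"{hiatus}_mm"] - first[f"{hiatus}_mm"])
    if len(xs) < 4:
        raise InsufficientDataError(
            f"start-end correlation needs >= 4 subjects with valid endpoints, got {len(xs)}"
        )
    y_name = f"{hiatus}_change_mm"
    return pearson_ci(xs, ys, alpha, mode="start_end", x_var=x_var, y_var=y_name)


def cluster_bootstrap_ci(
    tables,
    x_var: str = "distal_disp_mm",
    hiatus: Literal["ugh", "lh"] = "ugh",
    y_mode: Literal["change", "raw"] = "change",
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Subject-level bootstrap CI for the pooled framewise correlation.

    Diagnostic only: resamples whole subjects with replacement, which
    respects within-subject dependence that the pooled Fisher-z interval
    ignores.
    """
    subs = _subject_tables(tables)
    data = [_xy_for_subject(t, x_var, hiatus, y_mode) for t in subs]
    data = [(x, y) for x, y in data if x.size >= 2]
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(data), size=len(data))
        x = np.concatenate([data[i][0] for i in idx])
        y = np.concatenate([data[i][1] for i in idx])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rs.append(np.corrcoef(x, y)[0, 1])
    lo, hi = np.quantile(rs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def icc_2_1(measurements) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an (n targets x k raters) matrix with no missing
    cells.  Computed from the two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(measurements, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("measurements must be a 2D targets x raters matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise InsufficientDataError(f"need >= 3 targets and >= 2 raters, got {n}x{k}")
    if not np.all(np.isfinite(m)):
        raise ValueError("measurement matrix is incomplete; missing cells are not imputed")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        icc = 1.0 if msr == mse else 0.0
    else:
        icc = (msr - mse) / denom
    return IccResult(icc=float(icc), n_targets=n, n_raters=k)
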