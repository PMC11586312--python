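"""Logan graphical analysis and PET readouts.

Fixed conventions: frame mid-time is ``(start + end) / 2``; running
integrals use the trapezoid rule on frame mid-times with an implicit
``(0, 0)`` origin point; the equilibration-time search scans candidate
start frames from early to late and accepts the earliest segment whose
maximum relative deviation from its own fit is within the configured
bound (default 10%); fitted slopes below the VT floor (default 0) are
clamped to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "MOUSE_FRAME_DURATIONS_S",
    "HUMAN_FRAME_DURATIONS_S",
    "TimeActivityCurve",
    "InputFunction",
    "LoganFit",
    "LoganFitError",
    "extract_idif",
    "sphere_mask",
    "logan_vt",
    "vt_image",
    "static_mean",
    "normalize_to_reference",
    "suvr_image",
    "cohens_d",
    "voxelwise_regression",
    "VoxelwiseResult",
]

#: dynamic mouse acquisition: 6x10, 2x30, 3x60, 5x120, 5x300, 5x600 s (26 frames)
MOUSE_FRAME_DURATIONS_S: tuple[int, ...] = (10,) * 6 + (30,) * 2 + (60,) * 3 + (120,) * 5 + (300,) * 5 + (600,) * 5
#: dynamic human acquisition: 12x5, 6x10, 3x20, 7x60, 4x300, 3x600 s (35 frames, 60 min)
HUMAN_FRAME_DURATIONS_S: tuple[int, ...] = (5,) * 12 + (10,) * 6 + (20,) * 3 + (60,) * 7 + (300,) * 4 + (600,) * 3


@dataclass
class TimeActivityCurve:
    """Decay-corrected activity concentration per frame.

    ``frame_start`` / ``frame_end`` are in minutes, ``activity`` in
    kBq/ml.  Frames must be ordered and non-overlapping.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray
    activity: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_end = np.asarray(self.frame_end, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if not (len(self.frame_start) == len(self.frame_end) == len(self.activity)):
            raise ValueError("frame arrays must have equal length")
        if len(self.frame_start) == 0:
            raise ValueError("empty frame schedule")
        if np.any(self.frame_end <= self.frame_start):
            raise ValueError("frames must have positive duration")
        if np.any(np.diff(self.frame_start) < 0) or np.any(self.frame_start[1:] < self.frame_end[:-1] - 1e-9):
            raise ValueError("frames must be ordered and non-overlapping")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activities must be finite")

    @classmethod
    def from_durations(
        cls, durations_s: Sequence[float], activity: Sequence[float], **kw
    ) -> "TimeActivityCurve":
        d = np.asarray(durations_s, dtype=float) / 60.0
        end = np.cumsum(d)
        return cls(frame_start=end - d, frame_end=end, activity=np.asarray(activity, float), **kw)

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_start_min": self.frame_start,
                "frame_end_min": self.frame_end,
                "activity_kbq_ml": self.activity,
            }
        )


@dataclass
class InputFunction(TimeActivityCurve):
    """Blood/plasma input curve; ``source`` names the vascular VOI."""

    source: str = "left ventricle"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.activity < 0):
            raise ValueError("input activities must be non-negative")


def sphere_mask(
    shape: tuple[int, int, int],
    center: Sequence[float],
    diameter_mm: float = 5.0,
    voxel_size_mm: float = 1.0,
) -> np.ndarray:
    """Boolean sphere VOI (default diameter 5.0 mm, the carotid setting)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center)) * voxel_size_mm**2
    return r2 <= (diameter_mm / 2.0) ** 2


def extract_idif(
    volume: np.ndarray,
    voi_mask: np.ndarray,
    frame_durations_s: Sequence[float],
    source: str = "carotid",
) -> InputFunction:
    """Image-derived input function: per-frame mean over a vascular VOI.

    ``volume`` is 4-D with time on the last axis.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if voi_mask.shape != volume.shape[:3]:
        raise ValueError("mask shape does not match volume")
    if not voi_mask.any():
        raise ValueError("empty VOI mask")
    curve = volume[voi_mask].mean(axis=0)
    return InputFunction.from_durations(frame_durations_s, curve, source=source)


@dataclass
class LoganFit:
    """Result of a Logan graphical fit."""

    vt: float
    intercept: float
    t_star: float
    max_rel_error: float
    n_points: int
    slope_raw: float = float("nan")


class LoganFitError(RuntimeError):
    """No equilibration time satisfied the maximum-error criterion."""

    def __init__(self, best_error: float):
        super().__init__(
            f"no t* satisfies the maximum relative error criterion "
            f"(best achieved {best_error:.3g})"
        )
        self.best_error = best_error


def _cumtrapz0(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of y(t) with an implicit (0, 0) origin point."""
    tt = np.concatenate(([0.0], t))
    yy = np.concatenate(([0.0], y))
    return np.cumsum(0.5 * (yy[1:] + yy[:-1]) * np.diff(tt))


def logan_vt(
    tissue: TimeActivityCurve,
    input_fn: InputFunction,
    max_rel_error: float = 0.10,
    min_points: int = 3,
    vt_floor: float = 0.0,
    t_star: float | None = None,
) -> LoganFit:
    """Logan plot: slope of y = intCT/CT against x = intCp/CT after t*.

    t* is the earliest frame mid-time such that every later Logan point
    deviates from the segment's own least-squares line by at most
    ``max_rel_error`` relative to the fitted value.  With ``t_star``
    given, the search is skipped and the fixed segment is fitted (points
    with mid-time >= t_star); the criterion is still evaluated and
    reported but not enforced.  Negative slopes are clamped to
    ``vt_floor`` (set to None to disable clamping).
    """
    if not np.allclose(tissue.mid, input_fn.mid):
        raise ValueError("tissue and input schedules differ")
    if not np.any(input_fn.activity > 0):
        raise ValueError("input function is identically zero")
    t = tissue.mid
    ct = tissue.activity
    cp = input_fn.activity
    int_ct = _cumtrapz0(t, ct)
    int_cp = _cumtrapz0(t, cp)

    valid = ct > 0
    if valid.sum() < min_points:
        raise LoganFitError(float("inf"))
    tv = t[valid]
    x = int_cp[valid] / ct[valid]
    y = int_ct[valid] / ct[valid]

    def fit_from(i: int) -> tuple[float, float, float]:
        xs, ys = x[i:], y[i:]
        slope, icpt = np.polyfit(xs, ys, 1)
        pred = slope * xs + icpt
        denom = np.where(np.abs(pred) > 0, np.abs(pred), np.inf)
        err = float(np.max(np.abs(ys - pred) / denom))
        return slope, icpt, err

    if t_star is not None:
        idx = int(np.searchsorted(tv, t_star - 1e-12))
        if len(tv) - idx < min_points:
            raise LoganFitError(float("inf"))
        slope, icpt, err = fit_from(idx)
        chosen = idx
    else:
        best_err = float("inf")
        chosen = None
        for i in range(0, len(tv) - min_points + 1):
            slope, icpt, err = fit_from(i)
            best_err = min(best_err, err)
            if err <= max_rel_error:
                chosen = i
                break
        if chosen is None:
            raise LoganFitError(best_err)
        slope, icpt, err = fit_from(chosen)

    vt = float(slope)
    if vt_floor is not None and vt < vt_floor:
        vt = float(vt_floor)
    return LoganFit(
        vt=vt,
        intercept=float(icpt),
        t_star=float(tv[chosen]),
        max_rel_error=err,
        n_points=len(tv) - chosen,
        slope_raw=float(slope),
    )


def vt_image(
    volume: np.ndarray,
    input_fn: InputFunction,
    max_rel_error: float = 0.10,
    vt_floor: float = 0.0,
    t_star: float | None = None,
    min_points: int = 3,
) -> np.ndarray:
    """Voxelwise Logan VT map; voxels that cannot be fitted are NaN.

    Pass ``t_star`` (e.g. determined on a designated tissue-region curve)
    to fix the segment for all voxels instead of searching per voxel.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if volume.shape[3] != len(input_fn.activity):
        raise ValueError("frame count mismatch between volume and input function")
    out = np.full(volume.shape[:3], np.nan)
    schedule = dict(frame_start=input_fn.frame_start, frame_end=input_fn.frame_end)
    it = np.ndindex(volume.shape[:3])
    for idx in it:
        tac_vals = volume[idx]
        if not np.any(tac_vals > 0):
            continue
        tac = TimeActivityCurve(activity=tac_vals, **schedule)
        try:
            fit = logan_vt(
                tac,
                input_fn,
                max_rel_error=max_rel_error,
                vt_floor=vt_floor,
                t_star=t_star,
                min_points=min_points,
            )
        except LoganFitError:
            continue
        out[idx] = fit.vt
    return out


def static_mean(
    volume: np.ndarray,
    frame_durations_s: Sequence[float],
    window: tuple[float, float] = (20.0, 40.0),
) -> np.ndarray:
    """Duration-weighted mean over frames whose mid-times fall in ``window`` (min)."""
    volume = np.asarray(volume, dtype=float)
    d = np.asarray(frame_durations_s, dtype=float) / 60.0
    end = np.cumsum(d)
    mid = end - d / 2.0
    sel = (mid >= window[0]) & (mid <= window[1])
    if not sel.any():
        raise ValueError("no frames inside the static window")
    w = d[sel] / d[sel].sum()
    return np.tensordot(volume[..., sel], w, axes=([-1], [0]))


def normalize_to_reference(target, reference_mean: float):
    """Ratio readout (VT ratio or SUVR): target / reference."""
    reference_mean = float(reference_mean)
    if not reference_mean > 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(target, dtype=float) / reference_mean


def suvr_image(
    volume: np.ndarray,
    frame_durations_s: Sequence[float],
    reference_mask: np.ndarray,
    window: tuple[float, float] = (20.0, 40.0),
) -> np.ndarray:
    """Static-window SUVR image (default 20-40 min window)."""
    static = static_mean(volume, frame_durations_s, window)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != static.shape:
        raise ValueError("reference mask shape mismatch")
    if not reference_mask.any():
        raise ValueError("empty reference mask")
    return normalize_to_reference(static, static[reference_mask].mean())


def cohens_d(a: Iterable[float], b: Iterable[float]) -> float:
    """(mean_a - mean_b) / pooled SD, with (n-1)-weighted pooled variance.

    Returns NaN when the pooled SD is zero (undefined effect size).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


@dataclass
class VoxelwiseResult:
    """Voxelwise simple-regression map with cluster filtering applied."""

    t_map: np.ndarray
    p_map: np.ndarray
    cluster_map: np.ndarray  # 0 = background, 1..k = retained clusters
    clusters: pd.DataFrame = field(repr=False)
    p_thresh: float = 0.005
    k_min: int = 20


def voxelwise_regression(
    volumes: np.ndarray,
    covariate: Sequence[float],
    p_thresh: float = 0.005,
    k_min: int = 20,
) -> VoxelwiseResult:
    """Per-voxel simple linear regression of image value on a covariate.

    ``volumes`` is ``(n_subjects, x, y, z)``.  Voxels with two-sided
    ``p < p_thresh`` form a binary map; 6-connected 3-D clusters with
    size strictly greater than ``k_min`` are retained (deterministic
    scan-order labeling).
    """
    volumes = np.asarray(volumes, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("volumes must be (n, x, y, z)")
    n = volumes.shape[0]
    if covariate.shape != (n,):
        raise ValueError("covariate length does not match number of subjects")
    if n < 4:
        raise ValueError("need at least 4 subjects")

    xc = covariate - covariate.mean()
    sx = math.sqrt((xc**2).sum())
    if sx == 0:
        raise ValueError("covariate has zero variance")
    yc = volumes - volumes.mean(axis=0)
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.tensordot(xc, yc, axes=([0], [0])) / (sx * sy)
    r = np.clip(np.nan_to_num(r, nan=0.0), -0.9999999999, 0.9999999999)
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[sy == 0] = 1.0

    binary = p < p_thresh
    labeled, n_raw = ndimage.label(binary)  # default structure = 6-connectivity
    rows = []
    cluster_map = np.zeros_like(labeled)
    next_id = 0
    for lab in range(1, n_raw + 1):
        sel = labeled == lab
        size = int(sel.sum())
        if size <= k_min:
            continue
        next_id += 1
        cluster_map[sel] = next_id
        tt = np.where(sel, np.abs(t), -np.inf)
        peak = np.unravel_index(np.argmax(tt), tt.shape)
        rows.append(
            {
                "cluster_id": next_id,
                "size": size,
                "peak_t": float(t[peak]),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "min_p": float(p[sel].min()),
            }
        )
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_t", "peak_x", "peak_y", "peak_z", "min_p"]
    )
    return VoxelwiseResult(
        t_map=t, p_map=p, cluster_map=cluster_map, clusters=clusters, p_thresh=p_thresh, k_min=k_min
    )
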