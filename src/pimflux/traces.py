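"""Single-cluster intensity traces: extraction, normalization, synchronization.

A trace follows one cluster through a time-lapse with a user-supplied
rectangle per frame (the assay places these by hand); intensities use the
same rectangle/perimeter background rule as spot detection.  Frames without
a rectangle — cluster out of focus, neighbor too close — stay missing and
are never interpolated.  Converting clusters are aligned on the first frame
whose EGFP/mCherry ratio drops below 0.9, placed at t = +1 frame interval
so the last pre-drop frame sits at t = 0 (lysosomal entry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simkit import CHANNEL_EGFP, CHANNEL_MCHERRY, ImageStack2C
from .spotdetect import Rectangle, measure_rectangle

DROP_THRESHOLD_DEFAULT = 0.9


@dataclass
class Trace:
    """Per-frame two-channel intensities for one tracked cluster.

    Arrays are frame-indexed with NaN marking missing frames; ``valid``
    and ``flag_reasons`` record why a frame is missing.
    """

    cluster_id: int
    frame_interval: float                       # minutes
    mcherry: np.ndarray
    egfp: np.ndarray
    valid: np.ndarray = field(default=None)     # type: ignore[assignment]
    flag_reasons: dict[int, str] = field(default_factory=dict)
    mcherry_norm: np.ndarray | None = None
    egfp_norm: np.ndarray | None = None
    ratio: np.ndarray | None = None
    sync_offset: float | None = None            # minutes added to frame times

    def __post_init__(self) -> None:
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        self.egfp = np.asarray(self.egfp, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.mcherry) & np.isfinite(self.egfp)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.mcherry)

    def times(self) -> np.ndarray:
        t = np.arange(self.n_frames) * self.frame_interval
        return t + (self.sync_offset or 0.0)


def extract_trace(
    stack: ImageStack2C,
    per_frame_roi: dict[int, Rectangle],
    cluster_id: int = 0,
) -> Trace:
    """Measure both channels through per-frame rectangles.

    Frames absent from ``per_frame_roi`` stay missing; a rectangle falling
    outside the image marks that frame missing with a reason instead of
    failing.
    """
    n = stack.n_frames
    red_ch = stack.channel_index(CHANNEL_MCHERRY)
    green_ch = stack.channel_index(CHANNEL_EGFP)
    mch = np.full(n, np.nan)
    egf = np.full(n, np.nan)
    reasons: dict[int, str] = {}
    for f in range(n):
        rect = per_frame_roi.get(f)
        if rect is None:
            reasons[f] = "no_roi"
            continue
        try:
            mch[f], _ = measure_rectangle(stack.pixels[f, red_ch], rect)
            egf[f], _ = measure_rectangle(stack.pixels[f, green_ch], rect)
        except ValueError:
            reasons[f] = "roi_outside_image"
    return Trace(
        cluster_id=cluster_id,
        frame_interval=stack.frame_interval or 1.0,
        mcherry=mch, egfp=egf, flag_reasons=reasons,
    )


def normalize_trace(trace: Trace, baseline_n: int = 5) -> Trace:
    """Divide each channel by its mean over the first ``baseline_n`` valid frames.

    The baseline counts valid frames only (flagged frames are skipped, not
    consumed).  The ratio series is normalized EGFP over normalized mCherry.
    """
    valid_idx = np.flatnonzero(trace.valid)
    if len(valid_idx) < baseline_n:
        raise ValueError(
            f"need >= {baseline_n} valid frames for the baseline, have {len(valid_idx)}")
    base = valid_idx[:baseline_n]
    m0 = float(np.mean(trace.mcherry[base]))
    g0 = float(np.mean(trace.egfp[base]))
    if m0 <= 0 or g0 <= 0:
        raise ValueError("baseline mean must be positive in both channels")
    trace.mcherry_norm = trace.mcherry / m0
    trace.egfp_norm = trace.egfp / g0
    with np.errstate(divide="ignore", invalid="ignore"):
        trace.ratio = np.where(
            trace.mcherry_norm > 0, trace.egfp_norm / trace.mcherry_norm, np.nan)
    trace.ratio[~trace.valid] = np.nan
    return trace


def synchronize_traces(
    traces: list[Trace],
    drop_threshold: float = DROP_THRESHOLD_DEFAULT,
    frame_interval: float | None = None,
) -> dict:
    """Align traces on degradation onset and average per aligned timepoint.

    The first frame whose ratio falls below ``drop_threshold`` is shifted to
    t = +1 frame interval, so the last frame at or above threshold sits at
    t = 0 (lysosomal entry).  Traces that never drop are excluded and
    reported.  Returns aligned time grid, per-channel mean, s.e.m. and the
    contributing-trace count per timepoint (missing frames simply do not
    contribute).
    """
    if not traces:
        raise ValueError("no traces given")
    dt = frame_interval if frame_interval is not None else traces[0].frame_interval
    kept: list[Trace] = []
    excluded: list[int] = []
    for tr in traces:
        if tr.ratio is None:
            raise ValueError("traces must be normalized before synchronization")
        drops = np.flatnonzero((tr.ratio < drop_threshold) & tr.valid)
        if len(drops) == 0:
            excluded.append(tr.cluster_id)
            continue
        onset = int(drops[0])
        tr.sync_offset = dt - onset * dt   # puts the onset frame at +dt
        kept.append(tr)
    if not kept:
        return {"time": np.array([]), "mcherry_mean": np.array([]),
                "egfp_mean": np.array([]), "mcherry_sem": np.array([]),
                "egfp_sem": np.array([]), "n": np.array([], dtype=int),
                "excluded": excluded}

    # integer aligned index: frame - onset + 1
    offsets = [int(round(tr.sync_offset / dt)) for tr in kept]
    lo = min(o for o in offsets)
    hi = max(o + tr.n_frames for o, tr in zip(offsets, kept))
    width = hi - lo
    grid_g = np.full((len(kept), width), np.nan)
    grid_m = np.full((len(kept), width), np.nan)
    for i, (tr, off) in enumerate(zip(kept, offsets)):
        start = off - lo
        grid_m[i, start:start + tr.n_frames] = np.where(tr.valid, tr.mcherry_norm, np.nan)
        grid_g[i, start:start + tr.n_frames] = np.where(tr.valid, tr.egfp_norm, np.nan)
    n = np.sum(np.isfinite(grid_g), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN columns yield n=0
        mean_g = np.nanmean(grid_g, axis=0)
        mean_m = np.nanmean(grid_m, axis=0)
        sd_g = np.nanstd(grid_g, axis=0, ddof=1)
        sd_m = np.nanstd(grid_m, axis=0, ddof=1)
    sem_g = np.where(n > 1, sd_g / np.sqrt(np.maximum(n, 1)), 0.0)
    sem_m = np.where(n > 1, sd_m / np.sqrt(np.maximum(n, 1)), 0.0)
    time = (np.arange(width) + lo) * dt
    keep = n > 0
    return {
        "time": time[keep],
        "mcherry_mean": mean_m[keep], "egfp_mean": mean_g[keep],
        "mcherry_sem": sem_m[keep], "egfp_sem": sem_g[keep],
        "n": n[keep], "excluded": excluded,
    }


def frap_normalize(trace: Trace, bleach_frame: int) -> Trace:
    """Normalize a recovery trace to its mean pre-bleach intensity.

    Both channels are divided by their own mean over valid frames strictly
    before ``bleach_frame``; the normalized value at any later frame reads
    directly as the recovered fraction.
    """
    pre = np.flatnonzero(trace.valid[:bleach_frame])
    if len(pre) == 0:
        raise ValueError("no valid pre-bleach frames")
    m0 = float(np.mean(trace.mcherry[pre]))
    g0 = float(np.mean(trace.egfp[pre]))
    trace.mcherry_norm = trace.mcherry / m0 if m0 > 0 else np.full_like(trace.mcherry, np.nan)
    trace.egfp_norm = trace.egfp / g0 if g0 > 0 else np.full_like(trace.egfp, np.nan)
    return trace


def propagate_rois(
    stack: ImageStack2C,
    initial: Rectangle,
    max_step: float = 5.0,
    channel: str = CHANNEL_MCHERRY,
) -> dict[int, Rectangle]:
    """Synthetic convenience ROI propagator (the assay places ROIs by hand).

    Recenters the rectangle each frame on the local intensity maximum of
    the chosen channel within the previous rectangle, refusing moves larger
    than ``max_step`` px per frame (frame dropped, no gap closing).
    """
    ch = stack.channel_index(channel)
    rois: dict[int, Rectangle] = {0: initial}
    rect = initial
    h, w = stack.pixels.shape[2:]
    for f in range(1, stack.n_frames):
        img = stack.pixels[f, ch].astype(float)
        patch = img[rect.slices]
        pr, pc = np.unravel_index(np.argmax(patch), patch.shape)
        cr, cc = rect.center
        nr, nc = rect.row + pr, rect.col + pc
        if np.hypot(nr - cr, nc - cc) > max_step:
            continue
        r0 = int(round(nr - (rect.height - 1) / 2.0))
        c0 = int(round(nc - (rect.width - 1) / 2.0))
        r0 = min(max(r0, 0), h - rect.height)
        c0 = min(max(c0, 0), w - rect.width)
        rect = Rectangle(r0, c0, rect.height, rect.width)
        rois[f] = rect
    return rois
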