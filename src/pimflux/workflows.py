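"""Composed study workflows over the simulator and the analysis modules.

Each function runs one complete in-silico experiment — simulate, detect,
quantify, summarize — and returns both the measured quantities and the
matching ground truth, so validation studies (and the analysis drivers)
share a single code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import ratioflux, traces
from .simkit import GroundTruthLog, SimConfig, simulate_timelapse
from .spotdetect import DetectParams, Rectangle, detect_particles, detect_stack, particles_to_frame


def classify_timelapse(
    config: SimConfig,
    params: DetectParams | None = None,
    red_threshold: float = 0.3,
) -> tuple[pd.DataFrame, GroundTruthLog]:
    """Simulate, detect, ratio, normalize (live) and classify one time-lapse.

    Returns the classified cluster table (with ``time_min``) and the truth log.
    """
    params = params or DetectParams(snr=20.0)
    stack, log = simulate_timelapse(config)
    table = particles_to_frame(detect_stack(stack, params))
    if len(table):
        table["time_min"] = table["frame"] * (stack.frame_interval or 1.0)
    table = ratioflux.compute_raw_ratios(table)
    table, _ = ratioflux.normalize_live(table)
    table = ratioflux.classify_colors(table, red_threshold=red_threshold)
    return table, log


def fraction_red_vs_truth(
    table: pd.DataFrame, log: GroundTruthLog, frames: list[int]
) -> pd.DataFrame:
    """Pooled measured red fraction against true lysosomal fraction per frame."""
    per_cell = ratioflux.fraction_red(table)
    rows = []
    for f in frames:
        sub = per_cell[per_cell["frame"] == f]
        measured = (sub["n_red"].sum() / sub["n_total"].sum()) if len(sub) else np.nan
        rows.append({
            "frame": f,
            "measured_fraction_red": measured,
            "true_lysosomal_fraction": log.lysosomal_fraction(f),
        })
    out = pd.DataFrame(rows)
    out["abs_error"] = (out["measured_fraction_red"]
                        - out["true_lysosomal_fraction"]).abs()
    return out


def detection_fidelity(
    config: SimConfig,
    params: DetectParams | None = None,
    match_dist: float = 3.0,
) -> dict[str, float]:
    """Per-frame recall/precision of detection against simulator truth.

    A detection is a true positive when it is the unique match of a true
    cluster center within ``match_dist`` px.
    """
    params = params or DetectParams(snr=20.0)
    stack, log = simulate_timelapse(config)
    parts = detect_stack(stack, params, quantify=False)
    tp = fp = fn = 0
    for f in range(config.n_frames):
        truth = log.records[(log.records["frame"] == f) & log.records["active"]]
        det = [p for p in parts if p.frame == f]
        if len(truth) == 0:
            fp += len(det)
            continue
        tree = cKDTree(truth[["row", "col"]].to_numpy())
        matched: set[int] = set()
        frame_tp = 0
        for p in det:
            d, i = tree.query(p.center)
            if d <= match_dist and i not in matched:
                matched.add(i)
                frame_tp += 1
        tp += frame_tp
        fp += len(det) - frame_tp
        fn += len(truth) - frame_tp
    return {
        "recall": tp / max(tp + fn, 1),
        "precision": tp / max(tp + fp, 1),
        "n_true": tp + fn,
        "n_detected": tp + fp,
    }


def noise_only_false_positives(
    n_frames: int = 10,
    shape: tuple[int, int] = (256, 256),
    params: DetectParams | None = None,
    seed: int = 0,
    background: float = 100.0,
    noise_sd: float = 10.0,
) -> int:
    """Total detections on pure-noise frames (false-positive control)."""
    params = params or DetectParams(snr=20.0)
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    hits = 0
    for _ in range(n_frames):
        img = np.clip(rng.normal(background, noise_sd, size=shape), 0, None)
        hits += len(detect_particles(img, mask, params))
    return hits


def flux_recovery(
    config: SimConfig,
    t_start: float | None = None,
    t_end: float | None = None,
) -> dict[str, float]:
    """Measured clearance flux (red-count slope) vs the true entry-event rate.

    Both are per cell per hour over the same window; the truth counts the
    log's lysosomal-entry events.
    """
    table, log = classify_timelapse(config)
    per_cell = ratioflux.fraction_red(table)
    times = sorted(table["time_min"].dropna().unique())
    t0 = t_start if t_start is not None else times[0]
    t1 = t_end if t_end is not None else times[-1]
    flux = ratioflux.compute_flux(per_cell, t0, t1)
    n_cells = log.records["cell_id"].nunique()
    true_events = log.entry_events_between(t0 - 1e-9, t1)
    return {
        "measured_flux_per_hour": float(flux["flux_per_hour"].mean()),
        "true_flux_per_hour": true_events / n_cells / ((t1 - t0) / 60.0),
        "n_cells": n_cells,
        "window_min": (t0, t1),
    }


def converting_trace_ensemble(
    config: SimConfig,
    roi_half: int = 10,
    drop_threshold: float = 0.9,
) -> dict:
    """Extract per-cluster traces at truth positions, normalize and align them.

    Rectangles follow each cluster's true center per frame (the in-silico
    analogue of hand-placed ROIs); clusters whose ratio never drops are
    excluded by the synchronization step.
    """
    stack, log = simulate_timelapse(config)
    h, w = config.image_shape
    trace_list = []
    for cid, grp in log.records[log.records["active"]].groupby("cluster_id"):
        rois = {}
        for rec in grp.itertuples(index=False):
            r0 = int(round(rec.row)) - roi_half
            c0 = int(round(rec.col)) - roi_half
            size = 2 * roi_half + 1
            if r0 < 0 or c0 < 0 or r0 + size > h or c0 + size > w:
                continue
            rois[int(rec.frame)] = Rectangle(r0, c0, size, size)
        if len(rois) < config.n_frames:
            continue
        tr = traces.extract_trace(stack, rois, cluster_id=int(cid))
        try:
            trace_list.append(traces.normalize_trace(tr))
        except ValueError:
            continue
    ens = traces.synchronize_traces(trace_list, drop_threshold=drop_threshold,
                                    frame_interval=config.frame_interval)
    ens["n_traces"] = len(trace_list) - len(ens["excluded"])
    return ens


def size_direction(
    config: SimConfig,
    params: DetectParams | None = None,
) -> dict[str, float]:
    """Mean detected area of red vs yellow clusters at the final frame."""
    table, _ = classify_timelapse(config, params)
    last = table[table["frame"] == table["frame"].max()]
    red = last[last["color"] == ratioflux.COLOR_RED]["area"]
    yellow = last[last["color"] == ratioflux.COLOR_YELLOW]["area"]
    return {
        "red_mean_area": float(red.mean()) if len(red) else np.nan,
        "yellow_mean_area": float(yellow.mean()) if len(yellow) else np.nan,
        "n_red": len(red),
        "n_yellow": len(yellow),
    }
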