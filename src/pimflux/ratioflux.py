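"""EGFP/mCherry ratiometry: normalization, red/yellow classification, flux.

Operates on tidy particle tables (one row per particle per frame).  The
workflow mirrors the tandem-tag assay's quantification: raw ratio per
particle, per-cell normalization (live: early-frame mean; fixed: highest
Gaussian-mixture mode), strict ``< red_threshold`` red-classification, and
per-cell red-fraction / flux summaries.  The unit of replication is the
cell: population s.e.m. is always computed across cells, never particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

RED_THRESHOLD_DEFAULT = 0.3
DEFAULT_SIZE_BINS = (5.0, 10.0, 25.0, 50.0, np.inf)

COLOR_YELLOW = "yellow"
COLOR_RED = "red"
COLOR_EXCLUDED = "excluded"


@dataclass
class NormalizationModel:
    """Audit record of a normalization: mode, divisor and (fixed) mixture fit."""

    mode: str                      # "live_early_frames" | "fixed_gaussian"
    factor: float
    n_components: int | None = None
    means: tuple[float, ...] | None = None
    sds: tuple[float, ...] | None = None
    weights: tuple[float, ...] | None = None
    bic_1: float | None = None
    bic_2: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor <= 0:
            raise ValueError("normalization factor must be positive and finite")


def compute_raw_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``raw_ratio`` = I_egfp / I_mcherry; exclude non-positive mCherry.

    Records with I_mcherry <= 0 get ``color = 'excluded'`` with a reason and
    a missing ratio — never 0 or inf.  A negative EGFP integral (a
    statistically-zero signal pushed below zero by background noise) is kept
    and yields a negative raw ratio: censoring such records would
    systematically drop fully converted clusters.
    """
    out = table.copy()
    mch = out["I_mcherry"].to_numpy(dtype=float)
    egfp = out["I_egfp"].to_numpy(dtype=float)
    ok = mch > 0
    ratio = np.full(len(out), np.nan)
    ratio[ok] = egfp[ok] / mch[ok]
    out["raw_ratio"] = ratio
    if "color" not in out.columns:
        out["color"] = ""
    if "exclude_reason" not in out.columns:
        out["exclude_reason"] = ""
    out.loc[~ok, "color"] = COLOR_EXCLUDED
    out.loc[~ok, "exclude_reason"] = "nonpositive_mcherry"
    return out


def normalize_live(
    table: pd.DataFrame,
    window: int = 5,
    max_window: int = 10,
    min_particles: int = 3,
) -> tuple[pd.DataFrame, dict[int, NormalizationModel]]:
    """Per-cell normalization by the mean early-window raw ratio.

    For each cell the divisor is the mean raw ratio of particles with
    ``raw_ratio > 0`` in the first ``window`` frames; if fewer than
    ``min_particles`` qualify the window extends frame by frame up to
    ``max_window``.  Cells that still lack positive-ratio particles are
    marked unnormalizable and excluded downstream.
    """
    out = table.copy()
    out["norm_ratio"] = np.nan
    models: dict[int, NormalizationModel] = {}
    f0 = out["frame"].min() if len(out) else 0
    for cell, grp in out.groupby("cell_id"):
        w = window
        factor = np.nan
        while w <= max_window:
            early = grp[(grp["frame"] < f0 + w) & (grp["raw_ratio"] > 0)
                        & (grp["color"] != COLOR_EXCLUDED)]
            if len(early) >= min_particles:
                factor = float(early["raw_ratio"].mean())
                break
            w += 1
        idx = out["cell_id"] == cell
        if not np.isfinite(factor) or factor <= 0:
            out.loc[idx, "color"] = COLOR_EXCLUDED
            out.loc[idx, "exclude_reason"] = "cell_unnormalizable"
            continue
        models[int(cell)] = NormalizationModel(mode="live_early_frames", factor=factor)
        out.loc[idx, "norm_ratio"] = out.loc[idx, "raw_ratio"] / factor
    return out, models


def normalize_fixed(ratios: np.ndarray | list[float], k_max: int = 2,
                    random_state: int = 0) -> NormalizationModel:
    """Normalization divisor from a 1- or 2-component Gaussian mixture fit.

    Fits both component counts to the ratio histogram and keeps two
    components only when they improve BIC by at least 2; the divisor is the
    mean of the component with the largest mean (the double-positive,
    unconverted population).  A degenerate second component (weight < 1%)
    falls back to the single-Gaussian fit with a flag.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    flags: list[str] = []
    if len(x) < 50:
        flags.append("few_ratios")
    if len(x) == 0:
        raise ValueError("no finite ratios to normalize")
    if np.ptp(x) < 1e-12:
        return NormalizationModel(
            mode="fixed_gaussian", factor=float(x[0]), n_components=1,
            means=(float(x[0]),), sds=(0.0,), weights=(1.0,),
            flags=tuple(flags + ["degenerate_constant"]))

    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=random_state).fit(X)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(X)
    bic1, bic2 = float(gm1.bic(X)), float(gm2.bic(X))
    use_two = bic2 <= bic1 - 2.0 and float(gm2.weights_.min()) >= 0.01
    if bic2 <= bic1 - 2.0 and float(gm2.weights_.min()) < 0.01:
        flags.append("degenerate_component")
    gm = gm2 if use_two else gm1
    means = gm.means_.ravel()
    order = np.argsort(means)
    means = means[order]
    sds = np.sqrt(gm.covariances_.ravel())[order]
    weights = gm.weights_[order]
    return NormalizationModel(
        mode="fixed_gaussian",
        factor=float(means[-1]),
        n_components=int(gm.n_components),
        means=tuple(float(m) for m in means),
        sds=tuple(float(s) for s in sds),
        weights=tuple(float(w) for w in weights),
        bic_1=bic1, bic_2=bic2,
        flags=tuple(flags),
    )


def apply_fixed_normalization(table: pd.DataFrame,
                              model: NormalizationModel) -> pd.DataFrame:
    out = table.copy()
    out["norm_ratio"] = out["raw_ratio"] / model.factor
    return out


def classify_colors(table: pd.DataFrame,
                    red_threshold: float = RED_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Strict red/yellow split: red iff ``norm_ratio < red_threshold``.

    A normalized ratio of exactly the threshold is yellow.  Excluded
    records keep their label.
    """
    out = table.copy()
    valid = (out["color"] != COLOR_EXCLUDED) & out["norm_ratio"].notna()
    out.loc[valid & (out["norm_ratio"] < red_threshold), "color"] = COLOR_RED
    out.loc[valid & (out["norm_ratio"] >= red_threshold), "color"] = COLOR_YELLOW
    return out


def fraction_red(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell, per-frame red fraction: n_red / n_total (excluded dropped).

    Returns columns ``cell_id, frame, time_min?, n_total, n_yellow, n_red,
    fraction_red``; frames with zero valid particles are simply absent
    (missing, not 0).
    """
    valid = table[table["color"].isin([COLOR_RED, COLOR_YELLOW])]
    keys = ["cell_id", "frame"] + (["time_min"] if "time_min" in valid.columns else [])
    rows = []
    for key, grp in valid.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        n_red = int((grp["color"] == COLOR_RED).sum())
        rows.append(dict(zip(keys, key)) | {
            "n_total": len(grp),
            "n_yellow": len(grp) - n_red,
            "n_red": n_red,
            "fraction_red": n_red / len(grp),
        })
    return pd.DataFrame(rows)


def population_fraction_red(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Across-cell mean ± s.e.m. of the red fraction per frame."""
    rows = []
    for frame, grp in per_cell.groupby("frame"):
        vals = grp["fraction_red"].to_numpy()
        rows.append({
            "frame": frame,
            "mean_fraction_red": float(vals.mean()),
            "sem_fraction_red": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else 0.0,
            "n_cells": len(vals),
        })
    return pd.DataFrame(rows)


def compute_flux(counts: pd.DataFrame, t_start: float, t_end: float) -> pd.DataFrame:
    """Clearance events per hour per cell from red-count endpoints.

    ``counts`` must carry cell_id, time_min and n_red (as produced by
    :func:`fraction_red`); flux = (n_red(t_end) − n_red(t_start)) /
    (t_end − t_start in hours).  The population value is the across-cell
    mean of the per-cell fluxes.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if "time_min" not in counts.columns:
        raise ValueError("counts table must carry time_min")
    rows = []
    for cell, grp in counts.groupby("cell_id"):
        grp = grp.sort_values("time_min")

        def red_at(t: float) -> float | None:
            exact = grp[np.isclose(grp["time_min"], t)]
            if len(exact):
                return float(exact["n_red"].iloc[0])
            before = grp[grp["time_min"] <= t]
            return float(before["n_red"].iloc[-1]) if len(before) else None

        r0, r1 = red_at(t_start), red_at(t_end)
        if r0 is None or r1 is None:
            continue
        rows.append({
            "cell_id": cell,
            "flux_per_hour": (r1 - r0) / ((t_end - t_start) / 60.0),
        })
    return pd.DataFrame(rows)


def ratio_histogram(table: pd.DataFrame, bin_width: float = 0.05,
                    red_threshold: float = RED_THRESHOLD_DEFAULT) -> dict:
    """Density histogram of normalized ratios plus the percent below threshold.

    Mirrors the fixed-cell presentation: the headline number is the
    percentage of particles with ``norm_ratio < red_threshold``.
    """
    vals = table.loc[table["color"] != COLOR_EXCLUDED, "norm_ratio"].dropna().to_numpy()
    if len(vals) == 0:
        return {"edges": [], "density": [], "counts": [],
                "percent_below_threshold": None, "n": 0}
    hi = max(float(vals.max()), red_threshold) + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    density = counts / (counts.sum() * bin_width)
    return {
        "edges": edges.tolist(),
        "density": density.tolist(),
        "counts": counts.tolist(),
        "percent_below_threshold": 100.0 * float((vals < red_threshold).mean()),
        "n": int(len(vals)),
    }


def size_distribution(table: pd.DataFrame,
                      bin_edges: tuple[float, ...] = DEFAULT_SIZE_BINS) -> pd.DataFrame:
    """Fraction of particles per area bin, separately per color class.

    An empty class is simply absent from the output (missing, not zeros).
    Fractions within a class sum to 1 over the stated bins; particles whose
    area falls below the first edge are not binned.
    """
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for cls in (COLOR_YELLOW, COLOR_RED):
        sub = table[table["color"] == cls]
        areas = sub["area"].to_numpy(dtype=float)
        areas = areas[areas >= edges[0]]
        if len(areas) == 0:
            continue
        counts, _ = np.histogram(areas, bins=edges)
        for i in range(len(edges) - 1):
            rows.append({
                "color": cls,
                "bin_low": edges[i],
                "bin_high": edges[i + 1],
                "count": int(counts[i]),
                "fraction": counts[i] / counts.sum(),
            })
    return pd.DataFrame(rows)


def cell_integrated_ratio(table: pd.DataFrame, window: int = 5,
                          max_window: int = 10, min_frames: int = 3) -> pd.DataFrame:
    """Whole-cell ratio of summed intensities over time, early-window normalized.

    Per cell and frame: (Σ I_egfp) / (Σ I_mcherry) over all detected
    particles, then divided by that cell's mean over its first valid frames
    (same early-window rule as :func:`normalize_live`).  Frames whose summed
    mCherry is non-positive are missing.
    """
    rows = []
    for (cell, frame), grp in table.groupby(["cell_id", "frame"]):
        s_r = float(grp["I_mcherry"].sum())
        s_g = float(grp["I_egfp"].sum())
        rows.append({
            "cell_id": cell, "frame": frame,
            "ratio": s_g / s_r if s_r > 0 else np.nan,
            **({"time_min": float(grp["time_min"].iloc[0])}
               if "time_min" in grp.columns else {}),
        })
    out = pd.DataFrame(rows)
    out["norm_ratio"] = np.nan
    f0 = out["frame"].min() if len(out) else 0
    for cell, grp in out.groupby("cell_id"):
        w = window
        factor = np.nan
        while w <= max_window:
            early = grp[(grp["frame"] < f0 + w) & (grp["ratio"] > 0)]
            if len(early) >= min_frames:
                factor = float(early["ratio"].mean())
                break
            w += 1
        if np.isfinite(factor) and factor > 0:
            idx = out["cell_id"] == cell
            out.loc[idx, "norm_ratio"] = out.loc[idx, "ratio"] / factor
    return out
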