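"""End-to-end orchestration: simulate -> detect -> quantify -> summarize.

One :class:`PipelineConfig` drives a reproducible run; every stage's table
is written to the output directory, a run report reconciles record counts
across stages, and a checksum manifest covers all data artifacts so
identical config+seed runs can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import ratioflux
from .simkit import NoiseModel, SimConfig, simulate_timelapse
from .spotdetect import DetectParams, detect_stack, particles_to_frame

LIVE_SNR_DEFAULT = 20.0
FIXED_SNR_DEFAULT = 5.0


def _from_dict(cls, data: dict):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        if isinstance(value, dict) and key == "noise":
            value = _from_dict(NoiseModel, value)
        elif isinstance(value, dict) and key == "sim":
            value = _from_dict(SimConfig, value)
        elif isinstance(value, dict) and key in ("detect_live", "detect_fixed"):
            value = _from_dict(DetectParams, value)
        elif isinstance(value, list) and "tuple" in str(ftype):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """All thresholds of one run; every value is echoed into the run report."""

    sim: SimConfig = field(default_factory=SimConfig)
    detect_live: DetectParams = field(default_factory=lambda: DetectParams(snr=LIVE_SNR_DEFAULT))
    detect_fixed: DetectParams = field(default_factory=lambda: DetectParams(snr=FIXED_SNR_DEFAULT))
    mode: str = "live"                       # "live" | "fixed"
    red_threshold: float = 0.3
    norm_window: int = 5
    norm_max_window: int = 10
    sync_drop_threshold: float = 0.9
    size_bins: tuple[float, ...] = ratioflux.DEFAULT_SIZE_BINS
    flux_t_start: float | None = None        # minutes; default first frame
    flux_t_end: float | None = None          # minutes; default last frame
    seed: int | None = None                  # overrides sim.seed when set

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved_sim(self) -> SimConfig:
        sim = dataclasses.replace(self.sim)
        if self.seed is not None:
            sim.seed = self.seed
        return sim

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_echo: dict
    config_hash: str
    version: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)     # file -> sha256
    wall_clock_s: dict[str, float] = field(default_factory=dict)

    def counts_reconcile(self) -> bool:
        classified = self.stage_counts.get("classified_records", 0)
        excluded = sum(self.exclusions.values())
        return classified + excluded == self.stage_counts.get("particle_records", -1)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the configured live-cell stage graph and write all artifacts.

    Stages: simulate the time-lapse, detect+quantify particles on the
    mCherry channel, compute raw and normalized ratios, classify red/yellow,
    summarize red fractions, flux, the ratio histogram and the size
    distribution.  Deterministic given the config's seed; the checksum
    manifest covers every data artifact (the run report itself carries
    wall-clock times and is not part of the manifest).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_sim()
    report = RunReport(
        config_echo=dataclasses.asdict(config),
        config_hash=config.config_hash(),
        version=__version__,
        seed=sim.seed,
    )

    t0 = time.perf_counter()
    stack, log = simulate_timelapse(sim)
    report.wall_clock_s["simulate"] = time.perf_counter() - t0
    pio.write_stack(out / "stack.tif", stack)
    pio.write_roi_masks(out / "rois.tif", stack)
    pio.write_ground_truth(out / "ground_truth.csv", log)
    pio.write_config_echo(out / "sim_config.json", log)
    report.stage_counts["truth_records"] = len(log.records)

    t0 = time.perf_counter()
    params = config.detect_live if config.mode == "live" else config.detect_fixed
    particles = detect_stack(stack, params)
    report.wall_clock_s["detect"] = time.perf_counter() - t0
    table = particles_to_frame(particles)
    if len(table):
        table["time_min"] = table["frame"] * (stack.frame_interval or 1.0)
    pio.write_table(out / "particles.csv", table)
    report.stage_counts["particle_records"] = len(table)

    t0 = time.perf_counter()
    table = ratioflux.compute_raw_ratios(table)
    table, norm_models = ratioflux.normalize_live(
        table, window=config.norm_window, max_window=config.norm_max_window)
    table = ratioflux.classify_colors(table, red_threshold=config.red_threshold)
    pio.write_table(out / "clusters.csv", table)
    report.wall_clock_s["quantify"] = time.perf_counter() - t0
    excluded = table[table["color"] == ratioflux.COLOR_EXCLUDED]
    for reason, grp in excluded.groupby("exclude_reason"):
        report.exclusions[str(reason)] = len(grp)
    report.stage_counts["classified_records"] = int(
        table["color"].isin([ratioflux.COLOR_RED, ratioflux.COLOR_YELLOW]).sum())

    t0 = time.perf_counter()
    per_cell = ratioflux.fraction_red(table)
    pio.write_table(out / "fraction_red.csv", per_cell)
    pop = ratioflux.population_fraction_red(per_cell)
    pio.write_table(out / "fraction_red_population.csv", pop)
    times = sorted(table["time_min"].dropna().unique()) if len(table) else [0.0]
    t_start = config.flux_t_start if config.flux_t_start is not None else times[0]
    t_end = config.flux_t_end if config.flux_t_end is not None else times[-1]
    flux = (ratioflux.compute_flux(per_cell, t_start, t_end)
            if t_end > t_start and len(per_cell) else pd.DataFrame())
    pio.write_table(out / "flux.csv", flux)
    hist = ratioflux.ratio_histogram(table, red_threshold=config.red_threshold)
    sizes = ratioflux.size_distribution(table, bin_edges=config.size_bins)
    pio.write_table(out / "size_distribution.csv", sizes)
    summary = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "n_cells": int(table["cell_id"].nunique()) if len(table) else 0,
        "mean_flux_per_hour": float(flux["flux_per_hour"].mean()) if len(flux) else None,
        "flux_window_min": [t_start, t_end],
        "percent_red": hist["percent_below_threshold"],
        "normalization_factors": {str(c): m.factor for c, m in norm_models.items()},
    }
    pio.write_json(out / "summary.json", summary)
    report.wall_clock_s["summarize"] = time.perf_counter() - t0

    for name in ("stack.tif", "rois.tif", "ground_truth.csv", "sim_config.json",
                 "particles.csv", "clusters.csv", "fraction_red.csv",
                 "fraction_red_population.csv", "flux.csv",
                 "size_distribution.csv", "summary.json"):
        report.manifest[name] = pio.file_sha256(out / name)
    pio.write_json(out / "run_report.json", dataclasses.asdict(report))
    return report


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the tiny hand-checkable fixtures used throughout the test suite.

    All content is deterministic: a 5x5 rectangle patch whose integrated
    intensity is 72 by hand arithmetic, a 3-frame two-spot toy stack with
    its expected particle count, and a 100-row cytometry event table with
    a known 25% low-ratio fraction.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # 5x5 patch: perimeter 2, interior 10 -> background 2, integrated 72
    patch = np.full((5, 5), 2, dtype=np.int64)
    patch[1:4, 1:4] = 10
    p = out / "rect_5x5.csv"
    np.savetxt(p, patch, fmt="%d", delimiter=",")
    (out / "rect_5x5_expected.json").write_text(
        json.dumps({"integrated": 72.0, "background": 2.0}) + "\n")
    written["rect_5x5"] = p

    # toy stack: 3 frames, 2 channels, two fixed bright plateaus on flat bg
    frame = np.full((64, 64), 100, dtype=np.uint16)
    for r0, c0 in ((12, 12), (40, 44)):
        frame[r0:r0 + 3, c0:c0 + 3] = 3000
    pixels = np.stack([np.stack([frame, frame])] * 3)
    from .simkit import ImageStack2C

    stack = ImageStack2C(pixels=pixels, channels=("mCherry", "EGFP"),
                         pixel_size=0.16, frame_interval=10.0,
                         roi_masks=np.ones((64, 64), dtype=np.int32))
    pio.write_stack(out / "toy_stack.tif", stack)
    (out / "toy_stack_expected.json").write_text(
        json.dumps({"particles_per_frame": 2, "n_frames": 3}) + "\n")
    written["toy_stack"] = out / "toy_stack.tif"

    # event table: 25 of 100 events at low ratio 0.2, rest at 1.0
    n_low = 25
    gfp = np.concatenate([np.full(n_low, 200.0), np.full(100 - n_low, 1000.0)])
    mch = np.full(100, 1000.0)
    pd.DataFrame({"gfp": gfp, "mcherry": mch}).to_csv(out / "events.csv", index=False)
    (out / "events_expected.json").write_text(
        json.dumps({"percent_below_0.5": 25.0}) + "\n")
    written["events"] = out / "events.csv"
    return written
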