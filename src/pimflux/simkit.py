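"""Synthetic dual-channel (mCherry/EGFP) aggrephagy imaging simulator.

Generates time-lapse stacks, fixed-cell z-stacks and cytometry event tables
that carry the statistical structure the tandem-tag flux analyses assume:
clusters nucleate at induction, acquire a lysosomal-entry waiting time,
quench their EGFP to a residual floor on entry while mCherry persists, and
are rendered as 2-D Gaussian spots over a noisy camera background.  Every
run returns an exhaustive per-cluster per-frame ground-truth log so each
downstream measurement can be validated against construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNEL_MCHERRY = "mCherry"
CHANNEL_EGFP = "EGFP"

REGIMES = ("wildtype", "bafilomycin", "slow_large_impaired")

#: states a cluster can occupy; transitions are one-way
STATE_CYTOSOLIC = "cytosolic"
STATE_LYSOSOMAL = "lysosomal"


@dataclass
class NoiseModel:
    """Camera/photon noise: constant background, Poisson shot noise, Gaussian read noise."""

    background: float = 100.0        # photons/px
    read_sd: float = 5.0             # ADU, Gaussian
    poisson: bool = True

    def validate(self) -> None:
        if self.background < 0 or self.read_sd < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Rates are per hour; times in minutes; lengths in pixels unless noted.
    ``egfp_residual_fraction`` is the fluorescence floor reached after
    lysosomal pH quenching (the assay's ~70% EGFP loss corresponds to the
    default 0.3); ``egfp_lysosomal_decay_rate`` is the slower proteolytic
    loss of the remaining EGFP inside the lysosome, which carries converted
    clusters clearly below the red-classification threshold.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_frames: int = 96
    frame_interval: float = 10.0          # minutes
    pixel_size: float = 0.16              # µm/px
    n_cells: int = 1
    clusters_per_cell_mean: float = 77.0  # Poisson mean, matches ~77 clusters/cell at 1 h
    min_separation: float = 8.0           # px, dart-throwing placement floor
    cluster_sigma_range: tuple[float, float] = (1.5, 2.5)   # PSF sigma, px
    mcherry_amp_range: tuple[float, float] = (8000.0, 20000.0)  # integrated photons
    initial_ratio_mean: float = 1.0
    initial_ratio_sd: float = 0.1
    clearance_rate: float = 0.05          # lysosomal entry rate per cluster, events/h
    entry_delay_min: float = 120.0        # refractory period before the entry clock starts
    quench_halftime: float = 20.0         # minutes, EGFP pH-quench half-life after entry
    egfp_residual_fraction: float = 0.3   # fluorescence floor after quench
    egfp_lysosomal_decay_rate: float = 0.5  # per hour, proteolysis of residual EGFP
    merge_enabled: bool = True
    bleach_rate_egfp: float = 0.0         # fractional loss per frame
    bleach_rate_mcherry: float = 0.0
    drift_speed: float = 0.05             # px/frame bias toward the perinuclear anchor
    drift_jitter: float = 0.05            # px/frame random-walk sd
    noise: NoiseModel = field(default_factory=NoiseModel)
    regime: str = "wildtype"
    size_threshold_px: float = 30.0       # true footprint area gate for impaired regime
    impaired_factor: float = 0.2          # clearance multiplier for large clusters
    cell_competent_fraction: float = 1.0  # fraction of cells with active clearance
    expression_sigma: float = 0.8         # lognormal sd of cell-to-cell expression (cytometry)
    channel_noise_sigma: float = 0.05     # lognormal per-channel measurement scatter (cytometry)
    defocus_z0: float = 1.0               # µm, Gaussian defocus attenuation scale
    z_planes: int = 7
    z_step: float = 0.5                   # µm
    seed: int = 0

    def validate(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        for name in ("clearance_rate", "entry_delay_min", "quench_halftime",
                     "egfp_lysosomal_decay_rate", "bleach_rate_egfp",
                     "bleach_rate_mcherry", "drift_speed", "drift_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.egfp_residual_fraction <= 1.0):
            raise ValueError("egfp_residual_fraction must lie in [0, 1]")
        if not (0.0 <= self.cell_competent_fraction <= 1.0):
            raise ValueError("cell_competent_fraction must lie in [0, 1]")
        if self.n_frames < 1 or self.n_cells < 1:
            raise ValueError("n_frames and n_cells must be >= 1")
        self.noise.validate()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=list)


@dataclass
class ImageStack2C:
    """Registered multi-channel pixel data plus per-cell ROI label masks.

    ``pixels`` has shape (frames, channels, rows, cols); for fixed-cell
    z-stacks the leading axis is the focal plane (``axis_kind == "z"``).
    """

    pixels: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float
    frame_interval: float | None
    roi_masks: np.ndarray           # (rows, cols) int labels, 0 = outside any cell
    axis_kind: str = "time"         # "time" | "z"
    z_step: float | None = None

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in stack {self.channels}") from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.pixels[:, self.channel_index(name)]


@dataclass
class GroundTruthLog:
    """Tidy per-cluster per-frame truth plus run-level diagnostics.

    ``records`` columns: frame, time_min, cluster_id, cell_id, row, col,
    sigma, amp_mcherry, amp_egfp, state, entry_time_min (NaN if never
    lysosomal), merged_into (-1 if still independent), active.
    """

    records: pd.DataFrame
    config_json: str
    clip_fraction: float = 0.0
    density_warning: bool = False

    def lysosomal_fraction(self, frame: int) -> float:
        """Fraction of active clusters in the lysosomal state at ``frame``."""
        sub = self.records[(self.records["frame"] == frame) & self.records["active"]]
        if len(sub) == 0:
            return float("nan")
        return float((sub["state"] == STATE_LYSOSOMAL).mean())

    def entry_events_between(self, t0_min: float, t1_min: float) -> int:
        """Number of distinct clusters whose lysosomal entry fell in (t0, t1]."""
        per = self.records.groupby("cluster_id")["entry_time_min"].first()
        per = per.dropna()
        return int(((per > t0_min) & (per <= t1_min)).sum())


# ---------------------------------------------------------------------------
# cluster state simulation (shared by time-lapse, fixed and cytometry paths)
# ---------------------------------------------------------------------------


@dataclass
class _Cluster:
    cluster_id: int
    cell_id: int
    row: float
    col: float
    sigma: float
    amp_mcherry: float
    ratio0: float
    entry_time: float | None = None      # minutes; None while cytosolic
    merged_into: int = -1
    merge_time: float | None = None

    @property
    def active(self) -> bool:
        return self.merged_into < 0

    @property
    def true_area(self) -> float:
        """Effective footprint used by the size-dependent regime (px²)."""
        return 2.0 * math.pi * self.sigma ** 2


def _egfp_amplitude(cfg: SimConfig, cl: _Cluster, t_min: float) -> float:
    """True EGFP amplitude at time ``t_min`` (bleaching applied separately)."""
    amp0 = cl.amp_mcherry * cl.ratio0
    if cl.entry_time is None or t_min < cl.entry_time:
        return amp0
    dt = t_min - cl.entry_time
    resid = cfg.egfp_residual_fraction
    quench = resid + (1.0 - resid) * 0.5 ** (dt / cfg.quench_halftime) if cfg.quench_halftime > 0 \
        else resid
    decay = math.exp(-cfg.egfp_lysosomal_decay_rate * dt / 60.0)
    return amp0 * quench * decay


def _cell_geometry(cfg: SimConfig) -> list[tuple[float, float, float]]:
    """Lay cells out on a grid of disks; returns (center_row, center_col, radius)."""
    h, w = cfg.image_shape
    n = cfg.n_cells
    ncols = int(math.ceil(math.sqrt(n * w / h)))
    nrows = int(math.ceil(n / ncols))
    cell_h, cell_w = h / nrows, w / ncols
    radius = 0.42 * min(cell_h, cell_w)
    cells = []
    for i in range(n):
        r, c = divmod(i, ncols)
        cells.append(((r + 0.5) * cell_h, (c + 0.5) * cell_w, radius))
    return cells


def _make_roi_masks(cfg: SimConfig) -> np.ndarray:
    h, w = cfg.image_shape
    masks = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    for label, (cr, ccenter, rad) in enumerate(_cell_geometry(cfg), start=1):
        disk = (rr - cr) ** 2 + (cc - ccenter) ** 2 <= rad ** 2
        masks[disk & (masks == 0)] = label
    return masks


def _place_clusters(cfg: SimConfig, rng: np.random.Generator) -> list[_Cluster]:
    """Dart-throwing placement inside each cell disk with a separation floor."""
    clusters: list[_Cluster] = []
    next_id = 0
    for cell_id, (cr, cc, rad) in enumerate(_cell_geometry(cfg), start=1):
        n = rng.poisson(cfg.clusters_per_cell_mean)
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n and attempts < 200 * max(n, 1):
            attempts += 1
            rho = rad * 0.92 * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            r, c = cr + rho * math.sin(theta), cc + rho * math.cos(theta)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= cfg.min_separation ** 2
                   for pr, pc in placed):
                placed.append((r, c))
        if len(placed) < n:
            warnings.warn(
                f"cell {cell_id}: placed {len(placed)}/{n} clusters at "
                f"min_separation={cfg.min_separation}", stacklevel=2)
        for r, c in placed:
            sigma = rng.uniform(*cfg.cluster_sigma_range)
            amp = rng.uniform(*cfg.mcherry_amp_range)
            ratio0 = max(1e-3, rng.normal(cfg.initial_ratio_mean, cfg.initial_ratio_sd))
            clusters.append(_Cluster(next_id, cell_id, r, c, sigma, amp, ratio0))
            next_id += 1
    return clusters


def _effective_rate(cfg: SimConfig, cl: _Cluster, competent: bool) -> float:
    """Per-hour lysosomal entry rate for one cluster under the configured regime."""
    if cfg.regime == "bafilomycin" or not competent:
        return 0.0
    k = cfg.clearance_rate
    if cfg.regime == "slow_large_impaired" and cl.true_area >= cfg.size_threshold_px:
        k *= cfg.impaired_factor
    return k


def _simulate_states(
    cfg: SimConfig,
    clusters: list[_Cluster],
    times_min: np.ndarray,
    rng: np.random.Generator,
    spatial: bool = True,
) -> pd.DataFrame:
    """March the cluster ensemble through ``times_min`` and log truth per step.

    Entry is a per-step Bernoulli hazard 1 − exp(−k·Δt) once the refractory
    delay has elapsed, which compounds to the exponential waiting time; merge
    tests and drift are applied only when ``spatial`` is set.
    """
    competence = {cell_id: bool(rng.uniform() < cfg.cell_competent_fraction)
                  for cell_id in sorted({cl.cell_id for cl in clusters})}
    anchors = {cell_id: (cr, cc) for cell_id, (cr, cc, _)
               in enumerate(_cell_geometry(cfg), start=1)}

    rows: list[dict] = []
    prev_t = times_min[0]
    for step, t in enumerate(times_min):
        dt_h = max(0.0, (t - prev_t)) / 60.0
        # lysosomal-entry hazard
        for cl in clusters:
            if not cl.active or cl.entry_time is not None:
                continue
            if t < cfg.entry_delay_min:
                continue
            k = _effective_rate(cfg, cl, competence[cl.cell_id])
            if k <= 0.0 or dt_h <= 0.0:
                continue
            if rng.uniform() < -math.expm1(-k * dt_h):
                cl.entry_time = t
        if spatial and step > 0:
            _apply_drift(cfg, clusters, anchors, rng)
            if cfg.merge_enabled:
                _apply_merges(clusters, t)
        bleach_g = (1.0 - cfg.bleach_rate_egfp) ** step
        bleach_r = (1.0 - cfg.bleach_rate_mcherry) ** step
        for cl in clusters:
            state = (STATE_LYSOSOMAL if cl.entry_time is not None and t >= cl.entry_time
                     else STATE_CYTOSOLIC)
            rows.append({
                "frame": step,
                "time_min": float(t),
                "cluster_id": cl.cluster_id,
                "cell_id": cl.cell_id,
                "row": cl.row,
                "col": cl.col,
                "sigma": cl.sigma,
                "amp_mcherry": cl.amp_mcherry * bleach_r if cl.active else 0.0,
                "amp_egfp": _egfp_amplitude(cfg, cl, t) * bleach_g if cl.active else 0.0,
                "state": state,
                "entry_time_min": cl.entry_time if cl.entry_time is not None else np.nan,
                "merged_into": cl.merged_into,
                "active": cl.active,
            })
        prev_t = t
    columns = ["frame", "time_min", "cluster_id", "cell_id", "row", "col", "sigma",
               "amp_mcherry", "amp_egfp", "state", "entry_time_min", "merged_into",
               "active"]
    return pd.DataFrame(rows, columns=columns)


def _apply_drift(cfg: SimConfig, clusters: list[_Cluster],
                 anchors: dict[int, tuple[float, float]],
                 rng: np.random.Generator) -> None:
    for cl in clusters:
        if not cl.active:
            continue
        ar, ac = anchors[cl.cell_id]
        dr, dc = ar - cl.row, ac - cl.col
        dist = math.hypot(dr, dc)
        if dist > 1e-9 and cfg.drift_speed > 0:
            step = min(cfg.drift_speed, dist)
            cl.row += step * dr / dist
            cl.col += step * dc / dist
        if cfg.drift_jitter > 0:
            cl.row += rng.normal(0.0, cfg.drift_jitter)
            cl.col += rng.normal(0.0, cfg.drift_jitter)


def _apply_merges(clusters: list[_Cluster], t_min: float) -> None:
    """Coalesce cytosolic cluster pairs whose centers sit within one PSF sigma.

    Lysosome-enclosed clusters never merge.  Single-linkage through the
    surviving (lowest-id) cluster; amplitudes add, footprints add in area.
    """
    active = [cl for cl in clusters
              if cl.active and cl.entry_time is None]
    active.sort(key=lambda cl: cl.cluster_id)
    for i, a in enumerate(active):
        if not a.active:
            continue
        for b in active[i + 1:]:
            if not b.active or b.cell_id != a.cell_id:
                continue
            thresh = 0.5 * (a.sigma + b.sigma)
            if math.hypot(a.row - b.row, a.col - b.col) <= thresh:
                total = a.amp_mcherry + b.amp_mcherry
                a.row = (a.row * a.amp_mcherry + b.row * b.amp_mcherry) / total
                a.col = (a.col * a.amp_mcherry + b.col * b.amp_mcherry) / total
                a.ratio0 = (a.ratio0 * a.amp_mcherry + b.ratio0 * b.amp_mcherry) / total
                a.amp_mcherry = total
                a.sigma = math.sqrt(a.sigma ** 2 + b.sigma ** 2)
                b.merged_into = a.cluster_id
                b.merge_time = t_min


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_frame(
    cfg: SimConfig,
    frame_truth: pd.DataFrame,
    rng: np.random.Generator | None,
    noise: bool,
    amp_column: str,
    attenuation: float = 1.0,
) -> np.ndarray:
    """Render one channel of one frame: Gaussian spots + background + noise."""
    h, w = cfg.image_shape
    img = np.full((h, w), cfg.noise.background, dtype=np.float64)
    for rec in frame_truth.itertuples(index=False):
        if not rec.active:
            continue
        amp = getattr(rec, amp_column) * attenuation
        if amp <= 0:
            continue
        sig = rec.sigma
        half = int(math.ceil(5.0 * sig))
        r0, r1 = int(math.floor(rec.row)) - half, int(math.floor(rec.row)) + half + 1
        c0, c1 = int(math.floor(rec.col)) - half, int(math.floor(rec.col)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            continue
        yy = np.arange(r0c, r1c, dtype=np.float64) - rec.row
        xx = np.arange(c0c, c1c, dtype=np.float64) - rec.col
        g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * sig ** 2))
        img[r0c:r1c, c0c:c1c] += amp / (2.0 * math.pi * sig ** 2) * g
    if noise and rng is not None:
        if cfg.noise.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if cfg.noise.read_sd > 0:
            img += rng.normal(0.0, cfg.noise.read_sd, size=img.shape)
    return img


def _quantize(img: np.ndarray) -> tuple[np.ndarray, float]:
    clipped = np.clip(np.rint(img), 0, 65535)
    clip_frac = float(np.mean(img > 65535))
    return clipped.astype(np.uint16), clip_frac


def _density_warning(cfg: SimConfig, clusters: list[_Cluster]) -> bool:
    """True when mean nearest-neighbor distance < 2× max sigma (crowded field)."""
    if len(clusters) < 2:
        return False
    pts = np.array([(cl.row, cl.col) for cl in clusters])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    return bool(d[:, 1].mean() < 2.0 * max(cl.sigma for cl in clusters))


def simulate_timelapse(
    config: SimConfig, noise: bool = True
) -> tuple[ImageStack2C, GroundTruthLog]:
    """Simulate a two-channel live-cell time-lapse with ground truth.

    Clusters nucleate simultaneously at frame 0 (Poisson count per cell),
    wait out the entry delay, then enter lysosomes with exponential waiting
    times at the regime's effective clearance rate.  After entry the EGFP
    amplitude decays exponentially (half-life ``quench_halftime``) to
    ``egfp_residual_fraction`` of its initial value and is further reduced
    by slow intralysosomal proteolysis; mCherry is constant apart from
    optional bleaching.  Setting ``noise=False`` renders noiseless images
    (background still present) for oracle-style checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clusters = _place_clusters(config, rng)
    times = np.arange(config.n_frames, dtype=np.float64) * config.frame_interval
    truth = _simulate_states(config, clusters, times, rng, spatial=True)

    h, w = config.image_shape
    pixels = np.empty((config.n_frames, 2, h, w), dtype=np.uint16)
    clip_frac = 0.0
    grouped = dict(tuple(truth.groupby("frame"))) if len(truth) else {}
    empty = truth.iloc[0:0]
    for f in range(config.n_frames):
        ft = grouped.get(f, empty)
        red = _render_frame(config, ft, rng, noise, "amp_mcherry")
        green = _render_frame(config, ft, rng, noise, "amp_egfp")
        pixels[f, 0], cf_r = _quantize(red)
        pixels[f, 1], cf_g = _quantize(green)
        clip_frac = max(clip_frac, cf_r, cf_g)

    stack = ImageStack2C(
        pixels=pixels,
        channels=(CHANNEL_MCHERRY, CHANNEL_EGFP),
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        roi_masks=_make_roi_masks(config),
    )
    log = GroundTruthLog(
        records=truth,
        config_json=config.to_json(),
        clip_fraction=clip_frac,
        density_warning=_density_warning(config, clusters),
    )
    return stack, log


def simulate_fixed_snapshot(
    config: SimConfig, fix_time: float, noise: bool = True
) -> tuple[ImageStack2C, GroundTruthLog]:
    """Render one multi-z snapshot of the simulated state at ``fix_time`` minutes.

    The cluster ensemble is marched (with drift/merging) on the configured
    frame cadence up to ``fix_time``; the final state is rendered at
    ``z_planes`` focal offsets symmetric about 0, each attenuated by
    exp(−(z/defocus_z0)²).
    """
    if fix_time < 0:
        raise ValueError("fix_time must be >= 0")
    config.validate()
    rng = np.random.default_rng(config.seed)
    clusters = _place_clusters(config, rng)
    n_steps = max(1, int(round(fix_time / config.frame_interval)) + 1)
    times = np.linspace(0.0, fix_time, n_steps) if fix_time > 0 else np.array([0.0])
    truth = _simulate_states(config, clusters, times, rng, spatial=True)
    final = truth[truth["frame"] == truth["frame"].max()].copy()
    final["frame"] = 0

    nz = config.z_planes
    zs = (np.arange(nz) - (nz - 1) / 2.0) * config.z_step
    h, w = config.image_shape
    pixels = np.empty((nz, 2, h, w), dtype=np.uint16)
    clip_frac = 0.0
    for zi, z in enumerate(zs):
        att = math.exp(-((z / config.defocus_z0) ** 2)) if config.defocus_z0 > 0 else 1.0
        red = _render_frame(config, final, rng, noise, "amp_mcherry", attenuation=att)
        green = _render_frame(config, final, rng, noise, "amp_egfp", attenuation=att)
        pixels[zi, 0], cf_r = _quantize(red)
        pixels[zi, 1], cf_g = _quantize(green)
        clip_frac = max(clip_frac, cf_r, cf_g)

    stack = ImageStack2C(
        pixels=pixels,
        channels=(CHANNEL_MCHERRY, CHANNEL_EGFP),
        pixel_size=config.pixel_size,
        frame_interval=None,
        roi_masks=_make_roi_masks(config),
        axis_kind="z",
        z_step=config.z_step,
    )
    log = GroundTruthLog(
        records=final.reset_index(drop=True),
        config_json=config.to_json(),
        clip_fraction=clip_frac,
        density_warning=_density_warning(config, clusters),
    )
    return stack, log


def simulate_cytometry(
    config: SimConfig, sample_times: list[float]
) -> pd.DataFrame:
    """Simulate FACS-style per-cell events at each sample time.

    One event per cell per time: the true EGFP and mCherry amplitudes summed
    over that cell's clusters, scaled by a lognormal cell-to-cell expression
    factor common to both channels (which therefore cancels in the ratio)
    plus small independent per-channel measurement scatter.  Returns a tidy
    table with columns ``time_min, cell_id, gfp, mcherry, true_gfp,
    true_mcherry, lysosomal_fraction``.

    Cluster kinetics are non-spatial here (positions are irrelevant to a
    cytometer); merging and drift are skipped.
    """
    if not sample_times:
        raise ValueError("sample_times must be non-empty")
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts = np.maximum(rng.poisson(config.clusters_per_cell_mean, size=config.n_cells), 1)
    n_clusters = int(counts.sum())
    cell_of = np.repeat(np.arange(1, config.n_cells + 1), counts)
    sigma = rng.uniform(*config.cluster_sigma_range, size=n_clusters)
    amp_r = rng.uniform(*config.mcherry_amp_range, size=n_clusters)
    ratio0 = np.maximum(
        1e-3, rng.normal(config.initial_ratio_mean, config.initial_ratio_sd, n_clusters))

    competent = rng.uniform(size=config.n_cells) < config.cell_competent_fraction
    rate = np.full(n_clusters, config.clearance_rate)
    if config.regime == "bafilomycin":
        rate[:] = 0.0
    elif config.regime == "slow_large_impaired":
        large = 2.0 * math.pi * sigma ** 2 >= config.size_threshold_px
        rate[large] *= config.impaired_factor
    rate[~competent[cell_of - 1]] = 0.0

    # exponential waiting time after the refractory delay; inf where rate = 0
    waits = np.full(n_clusters, np.inf)
    pos = rate > 0
    waits[pos] = rng.exponential(1.0 / (rate[pos] / 60.0))   # minutes
    entry = config.entry_delay_min + waits

    expr = rng.lognormal(0.0, config.expression_sigma, size=config.n_cells)
    times = np.asarray(sorted(float(t) for t in sample_times))
    frames = []
    resid = config.egfp_residual_fraction
    for t in times:
        lys = entry <= t
        dt = np.where(lys, t - entry, 0.0)
        if config.quench_halftime > 0:
            quench = resid + (1.0 - resid) * 0.5 ** (dt / config.quench_halftime)
        else:
            quench = np.full(n_clusters, resid)
        decay = np.exp(-config.egfp_lysosomal_decay_rate * dt / 60.0)
        amp_g = amp_r * ratio0 * np.where(lys, quench * decay, 1.0)
        true_g = np.bincount(cell_of, weights=amp_g, minlength=config.n_cells + 1)[1:]
        true_r = np.bincount(cell_of, weights=amp_r, minlength=config.n_cells + 1)[1:]
        lys_frac = (np.bincount(cell_of, weights=lys.astype(float),
                                minlength=config.n_cells + 1)[1:] / counts)
        ng = rng.lognormal(0.0, config.channel_noise_sigma, size=config.n_cells)
        nr = rng.lognormal(0.0, config.channel_noise_sigma, size=config.n_cells)
        frames.append(pd.DataFrame({
            "time_min": t,
            "cell_id": np.arange(1, config.n_cells + 1),
            "gfp": expr * true_g * ng,
            "mcherry": expr * true_r * nr,
            "true_gfp": true_g,
            "true_mcherry": true_r,
            "lysosomal_fraction": lys_frac,
        }))
    return pd.concat(frames, ignore_index=True)
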