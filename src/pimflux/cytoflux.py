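"""FACS-style per-cell GFP/mCherry ratio-shift analysis.

Events (one per cell) carry a GFP and an mCherry intensity; after
positivity gating the GFP/mCherry ratio is analyzed on a log scale, where
cluster conversion produces a second, lower mode.  The converted-population
gate (ROI1) is a one-dimensional ratio cutoff — either fixed by the user or
placed at the fitted valley between the two log-ratio modes of a reference
sample — and the headline readout is the percentage of gated events below
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture


@dataclass
class GateSpec:
    """Positivity thresholds and the ROI1 (low-ratio) cutoff definition."""

    gfp_min: float = 0.0
    mcherry_min: float = 0.0
    roi1_cutoff: float | None = None    # ratio units; None → fit the valley
    roi1_source: str = "fixed"          # "fixed" | "fitted_valley"

    def __post_init__(self) -> None:
        if self.roi1_cutoff is not None and self.roi1_cutoff <= 0:
            raise ValueError("roi1_cutoff must be > 0")


@dataclass
class RatioModes:
    """1- or 2-component Gaussian description of the log-ratio distribution."""

    n_components: int
    means: tuple[float, ...]        # log-ratio scale, ascending
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    bic_1: float
    bic_2: float

    @property
    def bimodal(self) -> bool:
        return self.n_components == 2


def gate_positive(events: pd.DataFrame, spec: GateSpec) -> pd.DataFrame:
    """Keep events positive in both channels; compute their GFP/mCherry ratio.

    Input events are assumed singlets (scatter gating is upstream of this
    analysis).
    """
    out = events[(events["gfp"] > spec.gfp_min)
                 & (events["mcherry"] > spec.mcherry_min)].copy()
    out["ratio"] = out["gfp"] / out["mcherry"]
    return out


def fit_ratio_modes(gated: pd.DataFrame, random_state: int = 0) -> RatioModes:
    """Fit 1 vs 2 Gaussian components to the natural-log ratio distribution.

    Two components are kept only when they improve BIC by >= 2 and neither
    weight is degenerate (< 1%) — the same selection rule as the fixed-cell
    ratio normalization.
    """
    x = np.log(gated["ratio"].to_numpy(dtype=float))
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite ratios to fit")
    if np.ptp(x) < 1e-12:
        return RatioModes(1, (float(x[0]),), (0.0,), (1.0,), 0.0, 0.0)
    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=random_state).fit(X)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(X)
    bic1, bic2 = float(gm1.bic(X)), float(gm2.bic(X))
    use_two = bic2 <= bic1 - 2.0 and float(gm2.weights_.min()) >= 0.01
    gm = gm2 if use_two else gm1
    means = gm.means_.ravel()
    order = np.argsort(means)
    return RatioModes(
        n_components=int(gm.n_components),
        means=tuple(float(m) for m in means[order]),
        sds=tuple(float(s) for s in np.sqrt(gm.covariances_.ravel())[order]),
        weights=tuple(float(w) for w in gm.weights_[order]),
        bic_1=bic1, bic_2=bic2,
    )


def fitted_valley_cutoff(modes: RatioModes) -> float | None:
    """Ratio cutoff at the mixture-density minimum between the two log modes.

    Returns None for a unimodal fit (no valley to place a data-driven gate
    at).  The valley is the point between the component means where the two
    weighted component densities are equal; if the weighted densities never
    cross inside the interval, the midpoint is used.
    """
    if not modes.bimodal:
        return None
    (m1, m2), (s1, s2), (w1, w2) = modes.means, modes.sds, modes.weights
    s1, s2 = max(s1, 1e-9), max(s2, 1e-9)

    def diff(z: float) -> float:
        d1 = w1 / s1 * np.exp(-0.5 * ((z - m1) / s1) ** 2)
        d2 = w2 / s2 * np.exp(-0.5 * ((z - m2) / s2) ** 2)
        return d1 - d2

    a, b = m1 + 1e-9, m2 - 1e-9
    if b <= a:
        return float(np.exp(0.5 * (m1 + m2)))
    if diff(a) * diff(b) < 0:
        z = brentq(diff, a, b)
    else:
        z = 0.5 * (m1 + m2)
    return float(np.exp(z))


def percent_in_roi1(gated: pd.DataFrame, spec: GateSpec) -> float | None:
    """Percentage of gated events with ratio below the ROI1 cutoff.

    With ``roi1_cutoff`` unset the cutoff is fitted from this sample's
    log-ratio valley; a unimodal sample then reports 0% (no converted
    population resolvable).  An empty gated set reports missing (None).
    """
    if len(gated) == 0:
        return None
    cutoff = spec.roi1_cutoff
    if cutoff is None:
        cutoff = fitted_valley_cutoff(fit_ratio_modes(gated))
        if cutoff is None:
            return 0.0
    return 100.0 * float((gated["ratio"] < cutoff).mean())
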