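# Methods

## Assay model

The pipeline quantifies a tandem-tag (mCherry–EGFP) cluster-clearance
assay. A cluster is a diffraction-limited-to-small fluorescent punctum
carrying both fluorophores. Upon delivery to a lysosome its EGFP
fluorescence is quenched by the acidic lumen to a residual floor while
mCherry is essentially unaffected; the residual EGFP protein is then slowly
proteolyzed. The observable is the background-corrected EGFP/mCherry
intensity ratio of each detected cluster, normalized per cell, with a
strict `< 0.3` cut calling a cluster *red* (converted).

## Simulator

`simkit` generates the data the analyses assume, plus exhaustive truth.

**Kinetics.** All clusters nucleate at induction (t = 0); cells whose
clusters nucleate late are excluded from this kind of analysis in practice,
so late nucleation is not modeled. Each cluster waits out a refractory
`entry_delay_min` (default 120 min — conversion in this assay begins about
two hours after formation) and then enters a lysosome with an exponential
waiting time at rate `clearance_rate` (default 0.05/h per cluster: with
~70 clusters per cell this yields a few clearance events per hour per cell,
the scale such assays report). Entry is simulated as a per-frame Bernoulli
hazard 1 − exp(−k·Δt), which compounds exactly to the exponential law.

**Fluorescence.** After entry at time τ the EGFP amplitude follows

    A_g(t) = A_g(0) · [ρ + (1 − ρ)·2^(−(t−τ)/t_½)] · e^(−k_deg·(t−τ))

with residual fraction ρ (default 0.3, i.e. ~70 % fluorescence loss),
quench half-life t_½ (`quench_halftime`, default 20 min) and a slow
intralysosomal proteolysis rate k_deg (`egfp_lysosomal_decay_rate`, default
0.5/h). The proteolysis term reflects the fact that EGFP is degraded faster
than mCherry inside lysosomes; it is what carries a converted cluster's
ratio from the quench floor (≈ 0.3, exactly at the classification
boundary) clearly below the 0.3 threshold. Trace-shape studies that probe
the quench floor itself set k_deg = 0. mCherry is constant apart from
optional per-frame bleaching.

**Space and rendering.** Cells are disks on a grid; clusters are placed by
dart throwing with a minimum pairwise separation (default 8 px — analyzed
cells must show resolvable individual clusters), drift slowly toward a
perinuclear anchor, and cytosolic pairs closer than one PSF sigma merge
(amplitudes add, footprint areas add; lysosome-enclosed clusters do not
merge). Each cluster is rendered as an integrated-amplitude 2-D Gaussian
(σ from `cluster_sigma_range`, default 1.5–2.5 px) over a constant
background, with optional Poisson shot noise and Gaussian read noise,
quantized to 16-bit with saturation clipping (clip fraction logged). A
density warning is set when the mean nearest-neighbor distance falls below
2× the largest sigma. Fixed-cell snapshots render 7 z-planes at 0.5 µm
spacing with Gaussian defocus attenuation exp(−(z/z₀)²); cytometry events
sum each cell's true amplitudes and apply a lognormal per-cell expression
factor (common to both channels, so it cancels in the ratio) plus small
independent per-channel scatter.

**Regimes.** `wildtype`; `bafilomycin` (clearance rate forced to 0 —
acidification blocked); `slow_large_impaired` (clusters whose effective
footprint 2πσ² exceeds `size_threshold_px` have their clearance rate
multiplied by `impaired_factor` < 1, so red clusters skew small — the
signature of receptor-dependent clearance of large aggregates).
`cell_competent_fraction` makes a subset of cells non-clearing, which is
what produces bimodal cytometry populations; imaging analyses default it to
1 because live-cell cluster analyses include only cells showing clearance.

**What the simulator does not emulate.** Real PSFs (no Airy rings, no
chromatic offset), camera gain/offset calibration, cell migration,
division or death, autofluorescence and spectral bleedthrough, focus drift,
and late nucleation. Tests passing on these data therefore validate the
*accounting* — detection, intensity integration, normalization,
classification, synchronization — not robustness to those artifacts.

## Detection

The SNR threshold is `median(smoothed ROI) + SNR × 1.4826·MAD(smoothed
ROI)`, with a noise-sd floor of 1 intensity unit so constant synthetic
images cannot divide by zero. The median/MAD pair is robust to the bright
tail contributed by the spots themselves. Components are 8-connected;
"particles > 4 pixels" is read strictly (area ≥ 5). The rectangle is the
component bounding box grown by `box_margin` (default 2 px, so the
perimeter samples background rather than spot tails), clipped to the image
and re-padded to at least 3×3 so perimeter and interior are both
non-empty; rectangles touching the image border are flagged. Rectangles
whose centers fall within `merge_if_closer_than` (default 4 px) merge
transitively (single linkage) into a union rectangle. Coordinates are
0-based row/col, rectangles half-open.

## Ratiometry and classification

Raw ratios are undefined (missing, never 0 or ∞) when I_mCherry ≤ 0; such
records are excluded with a reason. A *negative* EGFP integral is kept: it
is a statistically-zero EGFP signal on a converted cluster, and its
negative ratio classifies red. Live normalization uses the mean raw ratio
of particles in the first 5 frames, extending frame by frame up to 10
until at least 3 positive-ratio particles are found (this reconciles the
"first 5–10 frames" per-cell rule with the "first five frames" trace
rule). Fixed normalization fits 1- and 2-component Gaussian mixtures to
the ratio histogram and keeps two components only when BIC improves by at
least 2 and neither weight is below 1 %; the divisor is the mean of the
highest-mean component. The red threshold is strict: a normalized ratio of
exactly 0.30 is yellow. Population statistics (mean ± s.e.m.) are always
computed across cells — the unit of replication — never across particles.
Flux is the red-count difference between two user-chosen timepoints
divided by the elapsed hours; the window is exposed rather than hard-coded
because endpoint choice changes the value by a few percent.

## Traces and synchronization

Traces use the same rectangle/perimeter rule through user-supplied
per-frame ROIs; frames without an ROI (out of focus, neighbor too close)
stay missing and are never interpolated. Each channel is normalized to its
own mean over the first five *valid* frames; the ratio is normalized EGFP
over normalized mCherry, so both channels plot on a common axis (a
raw-ratio mode is a trivial variant). Synchronization puts the first frame
with ratio < 0.9 at t = +1 frame interval, so the last pre-drop frame sits
at t = 0 (lysosomal entry); traces that never drop are excluded and
reported. Aligned ensemble means count only contributing valid traces per
timepoint. A convenience ROI propagator (nearest local maximum, max step
5 px/frame, no gap closing) is provided as synthetic plumbing — the assay
places these ROIs by hand.

## Cytometry

Events are gated positive in both channels, and the GFP/mCherry ratio is
fitted on the natural-log scale with the same 1-vs-2-component BIC rule.
The low-ratio gate (ROI1) is one-dimensional: a ratio cutoff, either fixed
by the user or placed at the point between the two fitted log-modes where
the weighted component densities are equal (midpoint fallback if they do
not cross). The data-driven cutoff is meant to be fitted once on a
late-timepoint reference sample and then frozen across conditions; a
unimodal sample has no valley and reports 0 % by construction when asked
to self-fit. Scatter (FSC/SSC singlet) gating and spectral compensation
are upstream of this analysis and out of scope.

## Numerical choices and degenerate inputs

- Determinism: one `numpy` Generator seeded from the config; identical
  config + seed reproduces stacks, logs and all derived artifacts
  byte-for-byte (run reports carry wall-clock times and are excluded from
  the checksum manifest).
- Empty ROIs, zero-cluster draws and all-constant images yield empty
  results, not errors; an empty color class is reported missing, never 0.
- Gaussian spots are rendered over ±5σ windows; the truncation error is
  < 0.1 %, so background-subtracted integrals match logged amplitudes
  within 1 %.
- Histogram bin width defaults to 0.05 normalized-ratio units; size bins
  default to [5,10), [10,25), [25,50), [50,∞) px² and are configurable
  everywhere.
- Mixture fits use 3 restarts for the 2-component model; degenerate
  components (< 1 % weight) fall back to the single Gaussian with a flag.

## Validation problem sizes

The validation studies (test suite and `scripts/acceptance.py`) run at
desk scale: 256–1280 px images, 1–10 cells, 14–60 clusters per cell,
24–100 frames, 2 000–4 000 cytometry cells, and 3–5 seeds per stochastic
claim. These sizes keep every study's sampling error well inside the
tolerance it is checked against (e.g. binomial error on a fraction of
order 0.5 with ≥ 200 clusters is ≈ 0.03).

## Known limitations

- The detection engine is a defensible reconstruction of the classic
  ImageJ-style puncta detector, not a line-for-line port; its SNR semantics
  (robust local background + SNR × robust sd) are documented above.
- Colocalization matching is greedy nearest-first one-to-one; it is exact
  for well-separated puncta but not a globally optimal assignment.
- The simulator's merge kinetics and drift speeds are plausibility-driven
  defaults (no quantitative literature values exist for this construct);
  they are configurable and default to gentle values.
- No hypothesis testing is included; exported tables are designed to drop
  into standard statistics tooling.
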