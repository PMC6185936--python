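# pimflux

Quantification pipeline for ratiometric tandem-tag (mCherry–EGFP)
aggrephagy assays, together with a synthetic two-channel microscopy
simulator that provides ground truth for every analysis stage.

## The problem

Inducible protein clusters carrying a tandem mCherry–EGFP tag report their
own delivery to lysosomes: EGFP fluorescence is quenched at lysosomal pH
(and the residual EGFP is degraded faster than mCherry), so a cluster
switches from *yellow* (EGFP⁺/mCherry⁺) to *red-only* upon lysosomal entry.
Counting red clusters over time therefore measures autophagic flux directly,
per cell, in events per hour.

This package implements the full quantification chain used with such
assays, for people who want to analyze dual-channel cluster-clearance data
or to validate such an analysis against simulated ground truth:

- **Spot detection** in the mCherry channel: Gaussian smoothing, a local
  signal-to-noise threshold (`threshold = median + SNR × robust σ`, SNR 20
  live / 5 fixed), 8-connected components strictly larger than 4 px, and a
  bounding rectangle per spot.
- **Rectangle/perimeter intensity accounting**: for a rectangle R with area
  A, background b = mean of R's 1-px perimeter and integrated intensity
  I = Σ<sub>R</sub> pixels − b·A, applied with the *identical* rectangle to
  both channels.
- **Ratiometry**: raw ratio r = I_EGFP / I_mCherry; live-cell normalization
  divides by the mean ratio of clusters in the first 5–10 frames, fixed-cell
  normalization divides by the mean of the highest Gaussian-mixture mode of
  the ratio histogram (1 vs 2 components chosen by BIC). A cluster is *red*
  iff its normalized ratio < 0.3 (strict).
- **Summaries**: per-cell red fraction over time, clearance flux
  (Δn_red/Δt in events/h/cell), ratio histograms, per-color size
  distributions, two-channel colocalization fractions.
- **Single-cluster traces**: per-frame ROI intensities, normalization to the
  first five valid frames, synchronization of traces at the first frame
  whose ratio drops below 0.9 (placed at t = +1 frame interval, so
  t = 0 marks lysosomal entry), and FRAP pre-bleach normalization.
- **Cytometry**: positivity gating of per-cell GFP/mCherry events, log-ratio
  bimodality fitting, and the percentage of cells in the low-ratio gate
  (ROI1).
- **Simulator** (`pimflux.simkit`): clusters nucleate at induction, enter
  lysosomes with exponential waiting times after a ~2 h delay, quench EGFP
  to a residual floor (default 0.3, i.e. ~70 % loss) while mCherry persists;
  rendered as 2-D Gaussian spots with Poisson + read noise. Regimes model a
  bafilomycin-like block (no conversion) and size-dependent impairment.
  Every run returns a per-cluster per-frame ground-truth log.

## Worked example

The numbered drivers under `analysis/` run the complete in-silico study
(two 16-h conditions, 2 cells × ~60 clusters each):

```bash
python analysis/01_simulate.py     # synthetic stacks + ground truth
python analysis/02_detect.py      # particle tables
python analysis/03_ratiometry.py  # red fractions, flux, sizes
python analysis/04_traces.py      # aligned single-cluster traces
python analysis/05_cytometry.py   # FACS-style ROI1 timecourse
```

Output of `03_ratiometry.py` on the default seed:

```
wildtype: fraction red at 8 h = 0.25
wildtype: fraction red at 16 h = 0.49
wildtype: mean flux = 1.62 clearance events/h/cell
bafilomycin: fraction red at 8 h = 0.00
bafilomycin: fraction red at 16 h = 0.00
bafilomycin: mean flux = 0.00 clearance events/h/cell
```

The wild-type red fraction grows as clusters convert (here with the default
per-cluster clearance rate of 0.05/h after a 2-h delay), while blocking
lysosomal acidification (bafilomycin regime) abolishes red clusters
entirely. `04_traces.py` prints the per-cluster conversion signature —

```
EGFP plateau (t >= 120 min): 0.302; mCherry: 1.012
```

— the aligned ensemble loses ~70 % of EGFP fluorescence upon lysosomal
entry while mCherry stays flat, and `05_cytometry.py` shows the converted
cell population appearing in the low-ratio gate over time and its absence
under bafilomycin.

A `pimflux` console script exposes the same stages
(`pimflux simulate|detect|quantify|trace|cyto|run|fixtures`); see
`pimflux --help`.

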