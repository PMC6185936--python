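#!/usr/bin/env python
"""Single-cluster trace analysis: follow converting clusters at 3-min
cadence, normalize to the first five frames, synchronize on the frame where
the EGFP/mCherry ratio first drops below 0.9, and average the ensemble.

The aligned EGFP curve falls to the configured residual (~0.3, i.e. ~70%
fluorescence loss) while mCherry stays flat — the per-cluster signature of
lysosomal entry.  Writes results/traces/aligned_ensemble.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pimflux import SimConfig
from pimflux.workflows import converting_trace_ensemble

OUT = Path(__file__).resolve().parents[1] / "results" / "traces"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        image_shape=(256, 256), n_frames=80, frame_interval=3.0,
        clusters_per_cell_mean=14, min_separation=25.0,
        clearance_rate=20.0, entry_delay_min=30.0,
        quench_halftime=20.0, egfp_residual_fraction=0.3,
        egfp_lysosomal_decay_rate=0.0, drift_speed=0.0, drift_jitter=0.0,
        seed=42)
    ens = converting_trace_ensemble(cfg)
    pd.DataFrame({
        "time_min": ens["time"],
        "mcherry_mean": ens["mcherry_mean"], "mcherry_sem": ens["mcherry_sem"],
        "egfp_mean": ens["egfp_mean"], "egfp_sem": ens["egfp_sem"],
        "n": ens["n"],
    }).to_csv(OUT / "aligned_ensemble.csv", index=False)
    late = (ens["time"] >= 120.0) & (ens["n"] >= 5)
    print(f"aligned {ens['n_traces']} converting clusters "
          f"(excluded {len(ens['excluded'])})")
    print(f"EGFP plateau (t >= 120 min): {np.nanmean(ens['egfp_mean'][late]):.3f}; "
          f"mCherry: {np.nanmean(ens['mcherry_mean'][late]):.3f}")


if __name__ == "__main__":
    main()
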