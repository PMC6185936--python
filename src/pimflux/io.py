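"""Reading and writing of stacks (multipage TIFF, TCYX), masks and tables.

All tables are tidy CSV; coordinates in every output are 0-based row/col
with half-open rectangles (documented in the column comments of each
writer).  Ground truth is one row per cluster per frame.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simkit import GroundTruthLog, ImageStack2C


def write_stack(path: str | Path, stack: ImageStack2C) -> None:
    """Write the pixel data as one TCYX multipage TIFF series."""
    tifffile.imwrite(
        str(path), stack.pixels, metadata={
            "axes": "TCYX",
            "channels": list(stack.channels),
            "pixel_size_um": stack.pixel_size,
            "frame_interval_min": stack.frame_interval,
            "axis_kind": stack.axis_kind,
        })


def read_stack(path: str | Path, roi_path: str | Path | None = None) -> ImageStack2C:
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixels.ndim == 3:       # single frame, CYX
        pixels = pixels[None]
    channels = tuple(meta.get("channels", ("mCherry", "EGFP")[: pixels.shape[1]]))
    rois = (tifffile.imread(str(roi_path)).astype(np.int32) if roi_path is not None
            else np.ones(pixels.shape[2:], dtype=np.int32))
    return ImageStack2C(
        pixels=pixels,
        channels=channels,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        frame_interval=meta.get("frame_interval_min"),
        roi_masks=rois,
        axis_kind=meta.get("axis_kind", "time"),
    )


def write_roi_masks(path: str | Path, stack: ImageStack2C) -> None:
    tifffile.imwrite(str(path), stack.roi_masks.astype(np.uint16))


def write_ground_truth(path: str | Path, log: GroundTruthLog) -> None:
    log.records.to_csv(path, index=False)


def write_config_echo(path: str | Path, log: GroundTruthLog) -> None:
    payload = json.loads(log.config_json)
    payload["clip_fraction"] = log.clip_fraction
    payload["density_warning"] = log.density_warning
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
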