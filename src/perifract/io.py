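"""Reading and writing the pipeline's file formats.

Radiographs travel as 8-bit grayscale uncompressed TIFF; tabular artifacts
(manifests, ground truth, FD records, descriptive tables) as CSV; ROI specs
and contrasts as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import Radiograph, RoiSpec
from .errors import InputError

MANIFEST_COLUMNS = ["path", "patient_id", "timepoint_months", "jaw", "sex", "age"]


def write_tiff(path, radiograph: Radiograph) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, radiograph.pixels, photometric="minisblack",
        resolution=(radiograph.dpi, radiograph.dpi), compression=None,
    )


def read_tiff(path, **meta) -> Radiograph:
    path = Path(path)
    if not path.exists():
        raise InputError(f"radiograph not found: {path}")
    px = tifffile.imread(path)
    if px.ndim == 3:  # collapse an accidental RGB scan to luminance
        px = px.mean(axis=-1)
    if px.dtype != np.uint8:
        px = np.clip(px, 0, 255).astype(np.uint8)
    return Radiograph(pixels=px, **meta)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"manifest is missing columns: {sorted(missing)}")
    return df


def write_roi_specs(path, specs: dict) -> None:
    """Serialize {patient_id: {side: RoiSpec}} to JSON."""
    payload = {
        pid: {side: spec.to_dict() for side, spec in sides.items()}
        for pid, sides in specs.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_roi_specs(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        pid: {side: RoiSpec(**d) for side, d in sides.items()}
        for pid, sides in payload.items()
    }
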