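"""Reading and writing phase images, label maps and tidy result tables.

Phase rasters travel as single-channel 32-bit float TIFF with a JSON sidecar
(`<stem>.json`) carrying the optics calibration, acquisition time and well
label; label maps as 16-bit TIFF. Tables are UTF-8 comma-separated with a
header row; floats are written with a fixed repr so repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .config import OpticsConfig
from .morphometry import CellRecord, GateSummary, LabelMap
from .phantoms import PhaseImage

CSV_FLOAT_FORMAT = "%.10g"


def write_phase_tiff(image: PhaseImage, path) -> Path:
    """Write an OPD raster as float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.opd.astype(np.float32))
    meta = {
        "optics": dataclasses.asdict(image.optics),
        "time_h": image.time_h,
        "well_id": image.well_id,
        "units": "opd_um",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_phase_image(path, optics: Optional[OpticsConfig] = None,
                     radians: bool = False, time_h: Optional[float] = None,
                     well_id: Optional[str] = None) -> PhaseImage:
    """Read a phase TIFF, taking calibration from its sidecar unless given.

    ``radians=True`` converts a phase raster in radians to OPD in µm via
    OPD = phi * wavelength / (2π).
    """
    path = Path(path)
    try:
        raster = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable phase image: {path}") from exc
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if optics is None:
        optics = OpticsConfig(**meta.get("optics", {}))
    opd = np.asarray(raster, dtype=np.float64)
    if radians or meta.get("units") == "phase_rad":
        opd = optics.phase_to_opd(opd)
    return PhaseImage(
        opd=opd, optics=optics,
        time_h=float(meta.get("time_h", 0.0)) if time_h is None else time_h,
        well_id=str(meta.get("well_id", "")) if well_id is None else well_id,
    )


def write_label_tiff(labels: LabelMap, path) -> Path:
    path = Path(path)
    if labels.n_objects > np.iinfo(np.uint16).max:
        raise ValueError("too many objects for a 16-bit label TIFF")
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    return path


def records_to_frame(records) -> pd.DataFrame:
    """Flatten CellRecords into a tidy one-row-per-object table."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        cx, cy = d.pop("centroid")
        d["centroid_x"], d["centroid_y"] = cx, cy
        rows.append(d)
    return pd.DataFrame(rows)


def write_csv(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path


def write_gate_summary(summary: GateSummary, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "n_total": summary.n_total,
        "n_cells": summary.n_cells,
        "n_debris": summary.n_debris,
        "debris_percent": summary.debris_percent,
    }, indent=1, sort_keys=True))
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
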