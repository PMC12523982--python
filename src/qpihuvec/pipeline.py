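"""End-to-end assay orchestration: simulate/load → segment → measure → fit.

Three runners mirror the study's three assay designs:

* ``run_morphology_assay`` — monolayer morphology over time bins: per-cell
  metrics, per-(well, bin) summaries with cell count as % of baseline, and the
  debris gate summary;
* ``run_tubulogenesis_assay`` — hourly tube networks: raw metrics plus
  percentages of the 1 h baseline, with per-cell morphometry only while single
  cells are still separable (early frames);
* ``run_dose_response_assay`` — a plate of wells at one time bin, reduced to
  mean shape readouts per well, fitted per experiment with the
  three-parameter logistic and summarised as a potency/efficacy table.

Every runner is deterministic given its inputs and config, and can write its
outputs plus a manifest (config echo, content hashes, row counts, timings).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as qio
from .config import RunConfig
from .morphometry import apply_size_gate, measure, pair_fluorescence, segment
from .phantoms import PhaseImage
from .pharmacology import derive_potency_table, fit_3pl
from .tube_network import (flag_boundary_branches, make_tube_mask,
                           network_metrics, normalize_timecourse,
                           skeletonize_and_graph)

__version__ = "0.1.0"

logger = logging.getLogger("qpihuvec")


@dataclass
class FrameInput:
    """One acquisition: a phase image (in memory or on disk) + optional fluorescence."""

    phase: Union[PhaseImage, str, Path]
    fluor: Union[np.ndarray, str, Path, None] = None
    well_id: Optional[str] = None
    time_h: Optional[float] = None

    def load(self, config: RunConfig) -> tuple[PhaseImage, Optional[np.ndarray]]:
        if isinstance(self.phase, PhaseImage):
            img = self.phase
        else:
            img = qio.read_phase_image(self.phase, time_h=self.time_h,
                                       well_id=self.well_id)
        if self.well_id is not None:
            img.well_id = self.well_id
        if self.time_h is not None:
            img.time_h = self.time_h
        fluor = self.fluor
        if fluor is not None and not isinstance(fluor, np.ndarray):
            import tifffile

            try:
                fluor = tifffile.imread(fluor)
            except (OSError, ValueError) as exc:
                raise OSError(f"unreadable fluorescence image: {self.fluor}") from exc
        return img, fluor


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    package_version: str = __version__
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)

    def add_stage(self, name: str, rows: int, wall_time_s: float) -> None:
        self.stages.append({"stage": name, "rows": rows,
                            "wall_time_s": round(wall_time_s, 3)})

    def add_file(self, path) -> None:
        self.files[str(Path(path).name)] = qio.sha256_of(path)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                   sort_keys=True))
        return path


def _measure_frame(img: PhaseImage, fluor, config: RunConfig):
    """segment → gate → measure → (fluorescence) for one frame."""
    labels = segment(img, min_seed_separation=config.min_seed_separation,
                     smoothing_scale=config.smoothing_scale)
    cells, debris, gate = apply_size_gate(labels, min_area=config.gate_min_area,
                                          strict=config.gate_strict)
    records = measure(img, cells, gate_min_area=config.gate_min_area,
                      gate_strict=config.gate_strict)
    if fluor is not None:
        records = pair_fluorescence(records, cells, fluor,
                                    config.fluorescence_background)
    logger.info("frame well=%s t=%.1fh: %d regions, %d cells, %d debris",
                img.well_id, img.time_h, gate.n_total, gate.n_cells, gate.n_debris)
    return records, gate


def _nearest_bin(t: float, bins: Sequence[float]) -> float:
    bins = np.asarray(bins, dtype=float)
    return float(bins[np.argmin(np.abs(bins - t))])


def run_morphology_assay(config: RunConfig, inputs: Sequence[FrameInput],
                         out_dir: Union[str, Path, None] = None):
    """Monolayer morphology assay over configured time bins.

    Returns ``(per_cell, summary, gate_table, manifest)``: the per-object
    table, per-(well, time-bin) means with cell count as % of the earliest
    bin, per-frame gate summaries, and the run manifest.
    """
    t0 = time.perf_counter()
    all_records: list[pd.DataFrame] = []
    gate_rows = []
    for frame in inputs:
        img, fluor = frame.load(config)
        records, gate = _measure_frame(img, fluor, config)
        df = qio.records_to_frame(records)
        if not df.empty:
            df["time_bin_h"] = _nearest_bin(img.time_h, config.morphology_time_bins_h)
        all_records.append(df)
        gate_rows.append({"well_id": img.well_id, "time_h": img.time_h,
                          "n_total": gate.n_total, "n_cells": gate.n_cells,
                          "n_debris": gate.n_debris,
                          "debris_percent": gate.debris_percent})
    per_cell = pd.concat([d for d in all_records if not d.empty],
                         ignore_index=True) if any(not d.empty for d in all_records) \
        else pd.DataFrame()
    gate_table = pd.DataFrame(gate_rows)

    if per_cell.empty:
        summary = pd.DataFrame()
    else:
        grouped = per_cell.groupby(["well_id", "time_bin_h"])
        summary = grouped.agg(
            n_cells=("object_id", "size"),
            mean_area=("area", "mean"),
            mean_dry_mass=("dry_mass", "mean"),
            mean_sphericity=("sphericity", "mean"),
            mean_length_width_ratio=("length_width_ratio", "mean"),
        ).reset_index()
        baseline_bin = min(config.morphology_time_bins_h)
        base = summary[summary["time_bin_h"] == baseline_bin] \
            .set_index("well_id")["n_cells"]
        summary["count_percent_of_baseline"] = [
            100.0 * row.n_cells / base[row.well_id]
            if row.well_id in base.index and base[row.well_id] > 0 else float("nan")
            for row in summary.itertuples()
        ]
        deb = gate_table.copy()
        deb["time_bin_h"] = [_nearest_bin(t, config.morphology_time_bins_h)
                             for t in deb["time_h"]]
        deb_pct = deb.groupby(["well_id", "time_bin_h"])["debris_percent"].mean()
        summary = summary.merge(deb_pct.rename("debris_percent").reset_index(),
                                on=["well_id", "time_bin_h"], how="left")

    manifest = RunManifest(config=config.to_dict())
    manifest.add_stage("morphology", len(per_cell), time.perf_counter() - t0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame_df in (("per_cell.csv", per_cell),
                               ("summary.csv", summary),
                               ("gate_summary.csv", gate_table)):
            manifest.add_file(qio.write_csv(frame_df, out / name))
        manifest.write(out / "manifest.json")
    return per_cell, summary, gate_table, manifest


def run_tubulogenesis_assay(config: RunConfig, inputs: Sequence[FrameInput],
                            out_dir: Union[str, Path, None] = None):
    """Tubulogenesis assay: per-frame network metrics + % of the baseline hour.

    Per-cell morphometry is emitted only for frames at or before
    ``config.cell_metrics_cutoff_h``, after which separate cells can no longer
    be segmented faithfully.
    """
    t0 = time.perf_counter()
    per_well: dict[str, list] = {}
    cell_frames = []
    for frame in inputs:
        img, fluor = frame.load(config)
        mask = make_tube_mask(img, smoothing_scale=config.smoothing_scale,
                              min_region_area=config.gate_min_area)
        graph = skeletonize_and_graph(mask, img.optics.pixel_size,
                                      prune_length=config.prune_length,
                                      junction_merge_radius=config.junction_merge_radius)
        graph = flag_boundary_branches(graph, img.extent,
                                       margin_px=config.boundary_margin_px)
        metrics = network_metrics(graph, time_h=img.time_h)
        per_well.setdefault(img.well_id, []).append(metrics)
        logger.info("network well=%s t=%.1fh: %d segments, %d junctions",
                    img.well_id, img.time_h, metrics.n_segments, metrics.n_junctions)
        if img.time_h <= config.cell_metrics_cutoff_h:
            records, _ = _measure_frame(img, fluor, config)
            df = qio.records_to_frame(records)
            cell_frames.append(df)
    tables = []
    for well, series in per_well.items():
        tab = normalize_timecourse(sorted(series, key=lambda m: m.time_h),
                                   baseline_time_h=config.tube_baseline_h)
        tab.insert(0, "well_id", well)
        tables.append(tab)
    metrics_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    per_cell = pd.concat([d for d in cell_frames if not d.empty],
                         ignore_index=True) if any(not d.empty for d in cell_frames) \
        else pd.DataFrame()

    manifest = RunManifest(config=config.to_dict())
    manifest.add_stage("tubulogenesis", len(metrics_table), time.perf_counter() - t0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.add_file(qio.write_csv(metrics_table, out / "network_metrics.csv"))
        manifest.add_file(qio.write_csv(per_cell, out / "early_per_cell.csv"))
        manifest.write(out / "manifest.json")
    return metrics_table, per_cell, manifest


REQUIRED_PLATE_COLUMNS = ("well", "condition", "log10_conc_M", "experiment")


def run_dose_response_assay(config: RunConfig, inputs: Sequence[FrameInput],
                            plate_map: pd.DataFrame,
                            response: str = "mean_length_width_ratio",
                            out_dir: Union[str, Path, None] = None):
    """Concentration–response assay on per-well shape readouts.

    ``plate_map`` columns: well, condition, log10_conc_M, experiment. Each
    well's frames are reduced to the mean cell length/width ratio (or
    ``response="mean_sphericity"``), curves are fitted per (condition,
    experiment) and summarised per condition. Conditions with fewer than 3
    distinct concentrations are skipped with a logged warning. Returns
    ``(potency_table, well_table, manifest)``.
    """
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in plate_map.columns]
    if missing:
        raise ValueError(f"plate map lacks required columns: {missing}")
    t0 = time.perf_counter()
    rows = []
    for frame in inputs:
        img, fluor = frame.load(config)
        records, gate = _measure_frame(img, fluor, config)
        lw = [r.length_width_ratio for r in records
              if np.isfinite(r.length_width_ratio)]
        rows.append({
            "well": img.well_id, "time_h": img.time_h,
            "n_cells": len(records),
            "mean_length_width_ratio": float(np.mean(lw)) if lw else float("nan"),
            "mean_sphericity": float(np.mean([r.sphericity for r in records]))
            if records else float("nan"),
        })
    well_table = pd.DataFrame(rows).merge(plate_map, on="well", how="inner")
    mapped_wells = set(plate_map["well"])
    unmapped = {r["well"] for r in rows} - mapped_wells
    if unmapped:
        raise ValueError(f"plate map does not cover wells: {sorted(unmapped)}")

    fits: dict[str, list] = {}
    for (condition, _experiment), sub in sorted(
            well_table.groupby(["condition", "experiment"], sort=True)):
        if sub["log10_conc_M"].nunique() < 3:
            logger.warning("condition %r: fewer than 3 concentrations, skipped",
                           condition)
            continue
        table = pd.DataFrame({"x": sub["log10_conc_M"], "y": sub[response]})
        fits.setdefault(condition, []).append(fit_3pl(table))
    potency = derive_potency_table(fits)

    manifest = RunManifest(config=config.to_dict())
    manifest.add_stage("dose_response", len(potency), time.perf_counter() - t0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.add_file(qio.write_csv(potency, out / "potency.csv"))
        manifest.add_file(qio.write_csv(well_table, out / "well_responses.csv"))
        manifest.write(out / "manifest.json")
    return potency, well_table, manifest
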