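"""Cell segmentation and per-object phase morphometrics.

Segments an OPD image into objects, applies the 400 µm² debris gate and
computes the per-cell metrics: area, dry mass, optical thickness, sphericity,
length/width ratio, with optional pairing against a co-registered
fluorescence channel.

The sphericity is the equal-volume-hemisphere surface ratio computed from the
2.5-D surface the phase image implies: cell thickness t = OPD / Δn, volume
V = Σ t · pixel_area, upper surface S = Σ sqrt(1 + |∇t|²) · pixel_area, and
sphericity = 2π r² / S with r = (3V / 2π)^(1/3), clipped to (0, 1]. It is not
invariant to the assumed refractive-index contrast Δn, which therefore must be
held fixed when sphericities are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_triangle
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import relabel_sequential, watershed

from .geometry import sphericity_from_vs
from .phantoms import PhaseImage

MIN_RELIABLE_PIXELS = 4


@dataclass
class LabelMap:
    """Integer object-label raster: 0 = background, ids contiguous from 1."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def areas(self) -> np.ndarray:
        """Per-object pixel-count areas in µm², indexed by object id − 1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]
        return counts * self.pixel_size**2


@dataclass
class CellRecord:
    """Morphology metrics of one segmented object."""

    object_id: int
    area: float                      # µm²
    dry_mass: float                  # pg
    mean_optical_thickness: float    # µm, mean OPD over object pixels
    max_optical_thickness: float     # µm
    sphericity: float                # (0, 1]
    length_width_ratio: float        # >= 1, NaN when the minor axis is degenerate
    centroid: tuple[float, float]    # (x, y) µm
    is_debris: bool = False
    time_h: float = 0.0
    well_id: str = ""
    fluorescence_mean: Optional[float] = None
    touches_border: bool = False
    unreliable: bool = False         # fewer than MIN_RELIABLE_PIXELS pixels


@dataclass
class GateSummary:
    """Outcome of the debris size gate over one image."""

    n_total: int
    n_cells: int
    n_debris: int

    def __post_init__(self) -> None:
        if self.n_cells + self.n_debris != self.n_total:
            raise ValueError("gate partition must be exhaustive and exclusive")

    @property
    def debris_percent(self) -> float:
        """Percent of segmented regions classed as debris; 0 for an empty image."""
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_debris / self.n_total


@dataclass
class GroupSummary:
    """Summary of one sphericity group in a fluorescence-pairing analysis."""

    n: int
    mean_fluorescence: float
    sem_fluorescence: float
    empty: bool = False


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(image: PhaseImage, min_seed_separation: float = 10.0,
            smoothing_scale: float = 2.0,
            threshold: Optional[float] = None) -> LabelMap:
    """Segment an OPD image into labelled objects.

    The foreground comes from a triangle threshold on the raw OPD histogram
    (or an explicit ``threshold`` in OPD µm): with mostly-empty fields the
    triangle rule lands at the background foot of the histogram, so object
    footprints are recovered to sub-pixel accuracy, where a balanced-classes
    rule like Otsu would bite several pixels into every object and bias area,
    dry mass and sphericity. Holes are filled, then touching cells are split
    by marker-based watershed on the Gaussian-smoothed (``smoothing_scale``
    µm) OPD topography with markers at local maxima at least
    ``min_seed_separation`` µm apart.
    """
    opd = image.opd
    if not np.all(np.isfinite(opd)):
        raise ValueError("phase image contains non-finite values")
    px = image.optics.pixel_size
    empty = LabelMap(np.zeros(opd.shape, dtype=np.int32), px)
    if not np.any(opd > 0):
        return empty

    sigma = smoothing_scale / px
    smoothed = gaussian(opd, sigma=sigma, preserve_range=True)
    if threshold is None:
        threshold = threshold_triangle(opd)
    binary = opd > threshold
    binary = ndimage.binary_fill_holes(binary)
    # drop sub-resolution specks that cannot carry metrics
    binary = _remove_small(binary, MIN_RELIABLE_PIXELS)
    if not binary.any():
        return empty

    min_dist = max(int(round(min_seed_separation / px)), 1)
    comp, _ = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    peaks = peak_local_max(smoothed, min_distance=min_dist, labels=comp,
                           exclude_border=False)
    markers = np.zeros(opd.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndimage.label(markers > 0, structure=np.ones((3, 3), dtype=int))
    labels = watershed(-smoothed, markers, mask=binary)

    # components the peak finder missed (flat plateaus) keep their own label
    missed = binary & (labels == 0)
    if missed.any():
        extra, n_extra = ndimage.label(missed, structure=np.ones((3, 3), dtype=int))
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    labels, _, _ = relabel_sequential(labels)
    return LabelMap(labels.astype(np.int32), px)


def _remove_small(binary: np.ndarray, min_pixels: int) -> np.ndarray:
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return binary
    counts = np.bincount(lab.ravel())
    keep = counts >= min_pixels
    keep[0] = False
    return keep[lab]


# ---------------------------------------------------------------------------
# size gate
# ---------------------------------------------------------------------------

def apply_size_gate(labels: LabelMap, min_area: float = 400.0,
                    strict: bool = True) -> tuple[LabelMap, LabelMap, GateSummary]:
    """Partition objects into cells and debris at the area gate.

    An object is kept as a cell iff its pixel-count area is over ``min_area``
    µm² (strictly, by default) — i.e. debris are the regions at or below the
    gate. Returns (cells, debris, summary) with both label maps relabelled
    contiguously.
    """
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    areas = labels.areas()
    if strict:
        is_cell = areas > min_area
    else:
        is_cell = areas >= min_area
    n_total = len(areas)
    cell_ids = np.flatnonzero(is_cell) + 1
    debris_ids = np.flatnonzero(~is_cell) + 1

    def subset(ids):
        mask = np.isin(labels.labels, ids)
        sub = np.where(mask, labels.labels, 0)
        sub, _, _ = relabel_sequential(sub)
        return LabelMap(sub.astype(np.int32), labels.pixel_size)

    summary = GateSummary(n_total=n_total, n_cells=int(is_cell.sum()),
                          n_debris=int((~is_cell).sum()))
    return subset(cell_ids), subset(debris_ids), summary


# ---------------------------------------------------------------------------
# per-object metrics
# ---------------------------------------------------------------------------

def measure(image: PhaseImage, labels: LabelMap,
            gate_min_area: float = 400.0,
            gate_strict: bool = True) -> list[CellRecord]:
    """Compute per-object morphology metrics over a label map.

    See the module docstring for the sphericity construction. Dry mass is
    Σ OPD · pixel_area / alpha over object pixels; optical thickness is the
    OPD in µm (mean and max per object); length/width is the major/minor axis
    ratio of the second-moment equivalent ellipse of the binary footprint.
    """
    if labels.labels.shape != image.opd.shape:
        raise ValueError(
            f"label map shape {labels.labels.shape} does not match image shape {image.opd.shape}")
    optics = image.optics
    px = optics.pixel_size
    pa = optics.pixel_area
    opd = image.opd
    thickness = opd / optics.delta_ri
    gy, gx = np.gradient(thickness, px)
    surf_density = np.sqrt(1.0 + gx * gx + gy * gy)

    records: list[CellRecord] = []
    lab = labels.labels
    border = np.zeros(lab.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for prop in regionprops(lab):
        oid = prop.label
        mask = lab == oid
        n_px = int(prop.area)
        area = n_px * pa
        opd_obj = opd[mask]
        dry_mass = float(opd_obj.sum()) * pa / optics.alpha
        mean_ot = float(opd_obj.mean())
        max_ot = float(opd_obj.max())
        volume = float(thickness[mask].sum()) * pa
        surface = float(surf_density[mask].sum()) * pa
        if volume > 0 and surface > 0:
            sph = min(sphericity_from_vs(volume, surface), 1.0)
        else:
            sph = 0.0
        minor = prop.axis_minor_length
        major = prop.axis_major_length
        lw = float(major / minor) if minor > 0 else float("nan")
        cy, cx = prop.centroid
        records.append(CellRecord(
            object_id=oid,
            area=area,
            dry_mass=dry_mass,
            mean_optical_thickness=mean_ot,
            max_optical_thickness=max_ot,
            sphericity=sph,
            length_width_ratio=max(lw, 1.0) if math.isfinite(lw) else lw,
            centroid=((cx + 0.5) * px, (cy + 0.5) * px),
            is_debris=(area <= gate_min_area) if gate_strict else (area < gate_min_area),
            time_h=image.time_h,
            well_id=image.well_id,
            touches_border=bool(np.any(border & mask)),
            unreliable=n_px < MIN_RELIABLE_PIXELS,
        ))
    return records


def pair_fluorescence(records: Sequence[CellRecord], labels: LabelMap,
                      fluor: np.ndarray,
                      background_threshold: float = 50.0) -> list[CellRecord]:
    """Attach per-object mean fluorescence, zeroing sub-background pixels.

    Pixels below ``background_threshold`` (arbitrary units) are set to zero
    before averaging over each object's pixels, so uniformly sub-threshold
    objects report 0 rather than a background-dominated mean.
    """
    fluor = np.asarray(fluor, dtype=float)
    if fluor.shape != labels.labels.shape:
        raise ValueError(
            f"fluorescence shape {fluor.shape} does not match label map shape "
            f"{labels.labels.shape}")
    cleaned = np.where(fluor >= background_threshold, fluor, 0.0)
    out = []
    for rec in records:
        mask = labels.labels == rec.object_id
        vals = cleaned[mask]
        out.append(replace(rec, fluorescence_mean=float(vals.mean()) if vals.size else 0.0))
    return out


def split_by_sphericity(records: Sequence[CellRecord],
                        boundary: float = 0.25) -> tuple[GroupSummary, GroupSummary]:
    """Group cells below vs at-or-above a sphericity boundary.

    Returns (low, high) summaries of mean fluorescence ± SEM; an empty group
    is flagged with ``empty=True`` and NaN statistics.
    """
    lows = [r.fluorescence_mean for r in records
            if r.sphericity < boundary and r.fluorescence_mean is not None]
    highs = [r.fluorescence_mean for r in records
             if r.sphericity >= boundary and r.fluorescence_mean is not None]

    def summarize(vals):
        if not vals:
            return GroupSummary(0, float("nan"), float("nan"), empty=True)
        arr = np.asarray(vals, dtype=float)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        return GroupSummary(len(arr), float(arr.mean()), sem)

    return summarize(lows), summarize(highs)
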