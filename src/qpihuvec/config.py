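"""Optics and run configuration.

All lengths are micrometres (µm) unless noted; masses are picograms (pg).
Phase images are stored as optical path difference (OPD) in µm; a radian-valued
input is converted via OPD = phi * wavelength / (2*pi).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class OpticsConfig:
    """Optical calibration needed to interpret a phase image.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength, µm.
    pixel_size : float
        Lateral sampling, µm per pixel.
    medium_ri : float
        Refractive index of the culture medium (dimensionless).
    object_ri : float
        Assumed mean refractive index of cellular material (dimensionless).
    alpha : float
        Specific refractive increment, µm³/pg; converts integrated OPD to
        dry mass.  The literature-standard 0.18 mL/g equals 0.18 µm³/pg.
    """

    wavelength: float = 0.640
    pixel_size: float = 0.5
    medium_ri: float = 1.337
    object_ri: float = 1.377
    alpha: float = 0.18

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.object_ri <= self.medium_ri:
            raise ValueError(
                f"object_ri ({self.object_ri}) must exceed medium_ri ({self.medium_ri})"
            )
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")

    @property
    def delta_ri(self) -> float:
        """Refractive-index contrast Δn = object_ri − medium_ri."""
        return self.object_ri - self.medium_ri

    @property
    def pixel_area(self) -> float:
        """Area of one pixel, µm²."""
        return self.pixel_size**2

    def phase_to_opd(self, phase_rad):
        """Convert a phase raster in radians to OPD in µm."""
        import numpy as np

        return np.asarray(phase_rad, dtype=np.float64) * self.wavelength / (2.0 * np.pi)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the study's default thresholds.

    Thresholds: ``gate_min_area`` (µm², objects strictly above are cells),
    ``fluorescence_background`` (arbitrary units, values below are zeroed),
    ``sphericity_boundary`` (single-cell grouping boundary).
    """

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    gate_min_area: float = 400.0
    gate_strict: bool = True
    fluorescence_background: float = 50.0
    sphericity_boundary: float = 0.25
    min_seed_separation: float = 10.0
    smoothing_scale: float = 2.0
    prune_length: float = 15.0
    junction_merge_radius: float = 5.0
    boundary_margin_px: int = 2
    morphology_time_bins_h: tuple = (0.0, 12.0, 24.0, 36.0)
    tube_baseline_h: float = 1.0
    cell_metrics_cutoff_h: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gate_min_area", "fluorescence_background",
                     "sphericity_boundary", "min_seed_separation",
                     "smoothing_scale", "prune_length", "junction_merge_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bins = tuple(float(t) for t in self.morphology_time_bins_h)
        if any(b >= a for b, a in zip(bins, bins[1:])):
            raise ValueError("time bins must be strictly increasing")
        self.morphology_time_bins_h = bins

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["morphology_time_bins_h"] = list(self.morphology_time_bins_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        optics = d.pop("optics", {})
        if isinstance(optics, dict):
            optics = OpticsConfig(**optics)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(optics=optics, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
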