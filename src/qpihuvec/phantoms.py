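"""Synthetic phantom generator with exact ground truth.

Generates the four kinds of input the analysis stages consume:

* single adherent-cell phase bumps (``render_cell``) and composite fields with
  sub-400 µm² debris (``render_field``),
* capillary-like tube networks drawn from a seeded planar graph
  (``render_network``),
* three-parameter-logistic dose–response tables (``simulate_dose_response``),
* morphology time-lapses with deterministic shape drift
  (``simulate_timelapse``).

Every generated object carries an analytic truth record so the measurement
stages can be verified against closed-form values rather than against
themselves. Images are ideal optical-path-difference (OPD) maps in µm; the
pixel at index (row, col) is centred at physical coordinate
((col + 0.5) * pixel_size, (row + 0.5) * pixel_size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import geometry as geo
from .config import OpticsConfig

DEBRIS_GATE_AREA = 400.0  # µm²; objects at or below are debris in truth records

_PROFILES: dict[str, Callable] = {
    "spherical_cap": lambda rho, a, b, h: geo.spherical_cap_profile(rho, a, h),
    "ellipsoidal_cap": lambda rho, a, b, h: geo.ellipsoidal_cap_profile(rho, h),
    "gaussian_bump": lambda rho, a, b, h: geo.gaussian_bump_profile(rho, h),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellPhantomSpec:
    """Geometry of one phantom cell.

    ``footprint_radii`` are the (major, minor) semi-axes of the base ellipse
    in µm (equal for spherical caps); ``height`` is the apex thickness in µm;
    ``orientation`` the major-axis angle in radians; ``dry_mass`` the target
    nonaqueous mass in pg, or None for the natural mass implied by the
    geometry and optics (no rescaling).
    """

    model: str
    footprint_radii: tuple[float, float]
    height: float
    centroid: Optional[tuple[float, float]] = None  # (x, y) µm; None = place me
    orientation: float = 0.0
    dry_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in _PROFILES:
            raise ValueError(f"unknown phantom model {self.model!r}")
        a, b = self.footprint_radii
        if a <= 0 or b <= 0:
            raise ValueError(f"footprint radii must be positive, got {self.footprint_radii}")
        if a < b:
            raise ValueError("major semi-axis must be >= minor semi-axis")
        if self.model == "spherical_cap" and not math.isclose(a, b):
            raise ValueError("spherical_cap requires equal footprint radii")
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.dry_mass is not None and self.dry_mass <= 0:
            raise ValueError(f"dry_mass must be positive, got {self.dry_mass}")

    @property
    def bounding_radius(self) -> float:
        return max(self.footprint_radii)


@dataclass
class PhaseImage:
    """Calibrated OPD raster (µm per pixel value) with acquisition metadata."""

    opd: np.ndarray
    optics: OpticsConfig
    time_h: float = 0.0
    well_id: str = ""

    def __post_init__(self) -> None:
        self.opd = np.asarray(self.opd, dtype=np.float64)
        if self.opd.ndim != 2 or min(self.opd.shape) < 2:
            raise ValueError(f"opd raster must be 2-D and at least 2x2, got shape {self.opd.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.opd.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width, height) of the field in µm."""
        ny, nx = self.opd.shape
        px = self.optics.pixel_size
        return nx * px, ny * px


@dataclass
class ObjectTruth:
    """Analytic per-object ground truth for one rendered phantom."""

    object_id: int
    model: str
    centroid: tuple[float, float]
    area: float
    dry_mass: float
    volume: float
    surface_area: float
    sphericity: float
    length_width_ratio: float
    is_debris: bool


@dataclass
class NetworkTruth:
    """Seed-graph tallies under the segment/junction/extremity/branch definitions."""

    n_segments: int
    n_junctions: int
    n_extremities: int
    n_branches: int
    total_length: float
    segment_lengths: list[float]

    @property
    def median_segment_length(self) -> float:
        return float(np.median(self.segment_lengths)) if self.segment_lengths else float("nan")


@dataclass
class DoseResponseTruth:
    top: float
    bottom: float
    log_ec50: float
    noise_sd: float
    n_replicates: int
    seed: int

    @property
    def span(self) -> float:
        return self.top - self.bottom

    @property
    def pec50(self) -> float:
        return -self.log_ec50


@dataclass
class FrameTruth:
    """Per-frame population truth for a simulated time-lapse."""

    time_h: float
    n_objects: int
    mean_sphericity: float
    mean_length_width_ratio: float


@dataclass
class PhantomTruth:
    objects: list[ObjectTruth] = field(default_factory=list)
    network: Optional[NetworkTruth] = None
    dose_response: Optional[DoseResponseTruth] = None
    frames: Optional[list[FrameTruth]] = None

    @property
    def debris_percent(self) -> float:
        if not self.objects:
            return 0.0
        n_debris = sum(o.is_debris for o in self.objects)
        return 100.0 * n_debris / len(self.objects)

    @property
    def total_dry_mass(self) -> float:
        return sum(o.dry_mass for o in self.objects)


# ---------------------------------------------------------------------------
# single-cell rendering
# ---------------------------------------------------------------------------

def _thickness_patch(spec: CellPhantomSpec, optics: OpticsConfig,
                     canvas: tuple[int, int]):
    """Physical-thickness raster of the spec on its local pixel window.

    Returns (rows slice, cols slice, thickness array µm).
    """
    px = optics.pixel_size
    a, b = spec.footprint_radii
    cx, cy = spec.centroid
    rmax = spec.bounding_radius
    ny, nx = canvas
    c0 = int(math.floor((cx - rmax) / px)) - 1
    c1 = int(math.ceil((cx + rmax) / px)) + 1
    r0 = int(math.floor((cy - rmax) / px)) - 1
    r1 = int(math.ceil((cy + rmax) / px)) + 1
    if c0 < 2 or r0 < 2 or c1 > nx - 2 or r1 > ny - 2:
        raise ValueError(
            f"phantom footprint (centroid ({cx:.1f}, {cy:.1f}) µm, radius "
            f"{rmax:.1f} µm) does not fit inside the {nx}x{ny}-pixel canvas "
            f"with a 2-pixel margin")
    cols = (np.arange(c0, c1) + 0.5) * px - cx
    rows = (np.arange(r0, r1) + 0.5) * px - cy
    X, Y = np.meshgrid(cols, rows)
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = X * ct + Y * st
    v = -X * st + Y * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    t = np.where(rho <= 1.0, _PROFILES[spec.model](np.minimum(rho, 1.0),
                                                   a, b, spec.height), 0.0)
    return slice(r0, r1), slice(c0, c1), t


def _object_truth(spec: CellPhantomSpec, optics: OpticsConfig,
                  object_id: int) -> tuple[ObjectTruth, float]:
    """Truth record plus the z-scale applied to hit ``spec.dry_mass``."""
    a, b = spec.footprint_radii
    natural = geo.solid_truth(spec.model, a, b, spec.height)
    natural_mass = optics.delta_ri * natural["volume"] / optics.alpha
    if spec.dry_mass is None:
        zscale = 1.0
        truth_geom = natural
        mass = natural_mass
    else:
        zscale = spec.dry_mass / natural_mass
        truth_geom = geo.scaled_solid_truth(spec.model, a, b, spec.height, zscale)
        mass = spec.dry_mass
    truth = ObjectTruth(
        object_id=object_id,
        model=spec.model,
        centroid=spec.centroid,
        area=truth_geom["area"],
        dry_mass=mass,
        volume=truth_geom["volume"],
        surface_area=truth_geom["surface_area"],
        sphericity=truth_geom["sphericity"],
        length_width_ratio=truth_geom["length_width_ratio"],
        is_debris=truth_geom["area"] < DEBRIS_GATE_AREA,
    )
    return truth, zscale


def _render_onto(opd: np.ndarray, spec: CellPhantomSpec, optics: OpticsConfig,
                 object_id: int) -> ObjectTruth:
    truth, zscale = _object_truth(spec, optics, object_id)
    rows, cols, t = _thickness_patch(spec, optics, opd.shape)
    patch = optics.delta_ri * t * zscale
    if spec.dry_mass is not None:
        # make the discrete integral exact, not just the continuous one
        total = patch.sum() * optics.pixel_area / optics.alpha
        if total > 0:
            patch *= spec.dry_mass / total
    opd[rows, cols] += patch
    return truth


def render_cell(spec: CellPhantomSpec, optics: OpticsConfig | None = None,
                canvas: tuple[int, int] = (128, 128),
                time_h: float = 0.0, well_id: str = "") -> tuple[PhaseImage, PhantomTruth]:
    """Render a single phantom cell onto a clean canvas.

    The OPD raster equals Δn × thickness; when ``spec.dry_mass`` is set the
    raster is rescaled so the integrated OPD × pixel area / alpha equals that
    mass exactly, and the truth record describes the rescaled solid.
    """
    optics = optics or OpticsConfig()
    if spec.centroid is None:
        ny, nx = canvas
        px = optics.pixel_size
        spec = replace(spec, centroid=(nx * px / 2.0, ny * px / 2.0))
    opd = np.zeros(canvas, dtype=np.float64)
    truth = _render_onto(opd, spec, optics, object_id=1)
    image = PhaseImage(opd=opd, optics=optics, time_h=time_h, well_id=well_id)
    return image, PhantomTruth(objects=[truth])


# ---------------------------------------------------------------------------
# composite fields with debris
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DebrisSpec:
    """Population of sub-gate debris specks: small spherical caps.

    ``area_range`` bounds the analytic footprint area (µm², strictly below the
    400 µm² gate); ``height_ratio`` sets cap height as a fraction of its base
    radius.
    """

    count: int
    area_range: tuple[float, float] = (50.0, 399.0)
    height_ratio: float = 0.4

    def __post_init__(self) -> None:
        lo, hi = self.area_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad debris area range {self.area_range}")
        if hi >= DEBRIS_GATE_AREA:
            raise ValueError(
                f"debris areas must stay below the {DEBRIS_GATE_AREA:.0f} µm² gate")
        if self.count < 0:
            raise ValueError("debris count must be >= 0")

    def draw(self, rng: np.random.Generator) -> list[CellPhantomSpec]:
        lo, hi = self.area_range
        areas = rng.uniform(lo, hi, size=self.count)
        out = []
        for area in areas:
            r = math.sqrt(area / math.pi)
            out.append(CellPhantomSpec(model="spherical_cap",
                                       footprint_radii=(r, r),
                                       height=self.height_ratio * r))
        return out


class PlacementError(RuntimeError):
    pass


def _place_specs(specs: Sequence[CellPhantomSpec], extent: tuple[float, float],
                 rng: np.random.Generator, min_gap: float,
                 max_attempts: int) -> list[CellPhantomSpec]:
    """Place specs without overlap by seeded rejection sampling.

    Overlap is tested on bounding circles inflated by ``min_gap``; a spatial
    hash keeps the test O(1) per attempt. Specs with a preset centroid keep it.
    """
    width, height = extent
    radii = [s.bounding_radius for s in specs]
    cell = max(radii) * 2.0 + min_gap if radii else 1.0
    grid: dict[tuple[int, int], list[int]] = {}
    placed_xy: list[tuple[float, float]] = []

    def ok(x, y, r):
        gi, gj = int(x // cell), int(y // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    xo, yo = placed_xy[k]
                    if math.hypot(x - xo, y - yo) < r + radii[k] + min_gap:
                        return False
        return True

    out: list[CellPhantomSpec] = []
    for i, spec in enumerate(specs):
        r = radii[i]
        pad = r + min_gap
        if spec.centroid is not None:
            x, y = spec.centroid
        else:
            for _attempt in range(max_attempts):
                x = rng.uniform(pad, width - pad)
                y = rng.uniform(pad, height - pad)
                if ok(x, y, r):
                    break
            else:
                raise PlacementError(
                    f"could not place object {i + 1}/{len(specs)} after "
                    f"{max_attempts} attempts; {len(out)} placed "
                    f"({len(out) / len(specs):.0%} of requested density)")
        gi, gj = int(x // cell), int(y // cell)
        grid.setdefault((gi, gj), []).append(i)
        placed_xy.append((x, y))
        out.append(replace(spec, centroid=(x, y)))
    return out


def render_field(cell_specs: Sequence[CellPhantomSpec],
                 debris_spec: DebrisSpec | None = None,
                 optics: OpticsConfig | None = None,
                 canvas: tuple[int, int] = (1024, 1024),
                 seed: int = 0, min_gap: float = 6.0,
                 max_attempts: int = 10_000,
                 time_h: float = 0.0, well_id: str = "") -> tuple[PhaseImage, PhantomTruth]:
    """Render a composite field of cells plus optional sub-gate debris.

    Specs without a centroid are placed by seeded rejection sampling with a
    ``min_gap`` µm clearance between bounding circles, so segmentation sees
    each object as a separate component.
    """
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    specs = list(cell_specs)
    if debris_spec is not None:
        specs += debris_spec.draw(rng)
    px = optics.pixel_size
    extent = (canvas[1] * px, canvas[0] * px)
    placed = _place_specs(specs, extent, rng, min_gap, max_attempts)
    opd = np.zeros(canvas, dtype=np.float64)
    truths = [_render_onto(opd, s, optics, object_id=i + 1)
              for i, s in enumerate(placed)]
    image = PhaseImage(opd=opd, optics=optics, time_h=time_h, well_id=well_id)
    return image, PhantomTruth(objects=truths)


# ---------------------------------------------------------------------------
# tube networks from a seeded planar graph
# ---------------------------------------------------------------------------

@dataclass
class SeedGraph:
    """Planar graph of tube centrelines.

    ``nodes`` maps node id → (x, y) µm. ``edges`` are (u, v, polyline) where
    the polyline is an (N, 2) µm array running from node u to node v (None →
    straight line). ``loops`` are closed polylines with no node on them.
    Node kinds follow from degree: 1 → extremity, ≥3 → junction; degree-2
    nodes are rejected because such points belong inside a segment polyline.
    """

    nodes: dict[int, tuple[float, float]]
    edges: list[tuple[int, int, Optional[np.ndarray]]]
    loops: list[np.ndarray] = field(default_factory=list)

    def degree(self) -> dict[int, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v, _ in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def validate(self) -> None:
        deg = self.degree()
        for n, d in deg.items():
            if d == 2:
                raise ValueError(
                    f"seed-graph node {n} has degree 2; degree-2 points belong "
                    "inside a segment polyline, not as nodes")
            if d == 0:
                raise ValueError(f"seed-graph node {n} is isolated")

    def edge_polyline(self, u: int, v: int, poly) -> np.ndarray:
        if poly is None:
            return np.array([self.nodes[u], self.nodes[v]], dtype=float)
        return np.asarray(poly, dtype=float)

    def truth(self) -> NetworkTruth:
        """Brute-force tallies over the adjacency, by the field definitions."""
        deg = self.degree()
        lengths = [geo.polyline_length(self.edge_polyline(u, v, p))
                   for u, v, p in self.edges]
        lengths += [geo.polyline_length(np.vstack([lp, lp[:1]]))
                    for lp in (np.asarray(l, dtype=float) for l in self.loops)]
        n_branches = sum(1 for u, v, _ in self.edges
                         if deg[u] == 1 or deg[v] == 1)
        return NetworkTruth(
            n_segments=len(self.edges) + len(self.loops),
            n_junctions=sum(1 for d in deg.values() if d >= 3),
            n_extremities=sum(1 for d in deg.values() if d == 1),
            n_branches=n_branches,
            total_length=float(sum(lengths)),
            segment_lengths=[float(x) for x in lengths],
        )

    def translated(self, dx: float, dy: float) -> "SeedGraph":
        nodes = {n: (x + dx, y + dy) for n, (x, y) in self.nodes.items()}
        edges = [(u, v, None if p is None else np.asarray(p, float) + [dx, dy])
                 for u, v, p in self.edges]
        loops = [np.asarray(l, float) + [dx, dy] for l in self.loops]
        return SeedGraph(nodes, edges, loops)

    def rotated90(self, extent: tuple[float, float]) -> "SeedGraph":
        """Rotate 90° counter-clockwise inside a square (side, side) µm frame."""
        side, _ = extent

        def rot(pt):
            x, y = pt
            return (side - y, x)

        nodes = {n: rot(xy) for n, xy in self.nodes.items()}
        edges = [(u, v, None if p is None else
                  np.array([rot(q) for q in np.asarray(p, float)]))
                 for u, v, p in self.edges]
        loops = [np.array([rot(q) for q in np.asarray(l, float)])
                 for l in self.loops]
        return SeedGraph(nodes, edges, loops)


def y_graph(arm_length: float = 100.0, center: tuple[float, float] = (0.0, 0.0),
            angles_deg: Sequence[float] = (90.0, 210.0, 330.0)) -> SeedGraph:
    """A Y: one junction with three straight arms ending in extremities."""
    cx, cy = center
    nodes = {0: (cx, cy)}
    edges = []
    for i, ang in enumerate(angles_deg, start=1):
        a = math.radians(ang)
        nodes[i] = (cx + arm_length * math.cos(a), cy + arm_length * math.sin(a))
        edges.append((0, i, None))
    return SeedGraph(nodes, edges)


def line_graph(length: float = 250.0,
               start: tuple[float, float] = (0.0, 0.0),
               angle_deg: float = 0.0) -> SeedGraph:
    a = math.radians(angle_deg)
    x0, y0 = start
    nodes = {0: (x0, y0), 1: (x0 + length * math.cos(a), y0 + length * math.sin(a))}
    return SeedGraph(nodes, [(0, 1, None)])


def loop_graph(side: float = 150.0,
               origin: tuple[float, float] = (0.0, 0.0)) -> SeedGraph:
    """A closed square loop with no junctions or extremities."""
    x0, y0 = origin
    poly = np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side],
                     [x0, y0 + side]], dtype=float)
    return SeedGraph(nodes={}, edges=[], loops=[poly])


def brick_lattice_graph(rows: int = 3, cols: int = 3, spacing: float = 100.0,
                        whisker: float = 40.0,
                        origin: tuple[float, float] = (0.0, 0.0)) -> SeedGraph:
    """A brick-wall lattice whose nodes are all degree 1 or 3.

    A (rows × cols)-cell rectangular grid has degree-4 interior crossings and
    degree-2 corners; the brick pattern drops alternate vertical links so all
    interior nodes are degree 3, and short whisker arms turn the would-be
    degree-2 rim nodes into degree-3 junctions with an extremity.
    """
    x0, y0 = origin
    nid = {}
    nodes = {}
    k = 0
    for i in range(rows + 1):
        for j in range(cols + 1):
            nid[(i, j)] = k
            nodes[k] = (x0 + j * spacing, y0 + i * spacing)
            k += 1
    edges = []
    for i in range(rows + 1):           # horizontal links, every row
        for j in range(cols):
            edges.append((nid[(i, j)], nid[(i, j + 1)], None))
    for i in range(rows):               # vertical links, brick pattern
        for j in range(cols + 1):
            if (i + j) % 2 == 0:
                edges.append((nid[(i, j)], nid[(i + 1, j)], None))
    g = SeedGraph(nodes, edges)
    deg = g.degree()
    for (i, j), n in list(nid.items()):  # whiskers fix degree-2 rim nodes
        if deg[n] == 2:
            x, y = nodes[n]
            dy = -whisker if i == 0 else whisker if i == rows else 0.0
            dx = -whisker if j == 0 and dy == 0.0 else whisker if j == cols and dy == 0.0 else 0.0
            if dx == 0.0 and dy == 0.0:
                dy = whisker
            nodes[k] = (x + dx, y + dy)
            edges.append((n, k, None))
            k += 1
    g = SeedGraph(nodes, edges)
    g.validate()
    return g


def _paint_capsule(opd: np.ndarray, p0, p1, half_width: float, tube_opd: float,
                   px: float) -> None:
    """Set ``tube_opd`` on pixels within ``half_width`` of segment p0-p1."""
    x0, y0 = p0
    x1, y1 = p1
    ny, nx = opd.shape
    r0 = max(int((min(y0, y1) - half_width) / px) - 1, 0)
    r1 = min(int((max(y0, y1) + half_width) / px) + 2, ny)
    c0 = max(int((min(x0, x1) - half_width) / px) - 1, 0)
    c1 = min(int((max(x0, x1) + half_width) / px) + 2, nx)
    if r0 >= r1 or c0 >= c1:
        return
    xs = (np.arange(c0, c1) + 0.5) * px
    ys = (np.arange(r0, r1) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    if L2 == 0:
        d2 = (X - x0) ** 2 + (Y - y0) ** 2
    else:
        t = np.clip(((X - x0) * dx + (Y - y0) * dy) / L2, 0.0, 1.0)
        d2 = (X - (x0 + t * dx)) ** 2 + (Y - (y0 + t * dy)) ** 2
    inside = d2 <= half_width * half_width
    sub = opd[r0:r1, c0:c1]
    sub[inside] = np.maximum(sub[inside], tube_opd)


def render_network(seed_graph: SeedGraph, tube_width: float = 12.0,
                   tube_opd: float = 0.3, optics: OpticsConfig | None = None,
                   canvas: tuple[int, int] = (512, 512),
                   time_h: float = 0.0, well_id: str = "") -> tuple[PhaseImage, PhantomTruth]:
    """Render a seeded tube network as a union of stadium-shaped tubes.

    Tube ends are rounded (the capsule geometry) so skeleton endpoints fall at
    the seed-graph node coordinates to within a pixel.
    """
    seed_graph.validate()
    optics = optics or OpticsConfig()
    px = optics.pixel_size
    opd = np.zeros(canvas, dtype=np.float64)
    half = tube_width / 2.0
    for u, v, poly in seed_graph.edges:
        pts = seed_graph.edge_polyline(u, v, poly)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            _paint_capsule(opd, p0, p1, half, tube_opd, px)
    for loop in seed_graph.loops:
        pts = np.vstack([np.asarray(loop, float), np.asarray(loop, float)[:1]])
        for p0, p1 in zip(pts[:-1], pts[1:]):
            _paint_capsule(opd, p0, p1, half, tube_opd, px)
    image = PhaseImage(opd=opd, optics=optics, time_h=time_h, well_id=well_id)
    return image, PhantomTruth(network=seed_graph.truth())


# ---------------------------------------------------------------------------
# dose–response simulation
# ---------------------------------------------------------------------------

def logistic3(x, top: float, bottom: float, log_ec50: float):
    """Three-parameter logistic with unit Hill slope.

    ``Y = Bottom + (Top - Bottom) / (10**(LogEC50 - X) + 1)`` with X the
    log10 molar concentration.
    """
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (np.power(10.0, log_ec50 - x) + 1.0)


def simulate_dose_response(top: float, bottom: float, log_ec50: float,
                           concentrations: Sequence[float],
                           n_replicates: int = 2, noise_sd: float = 0.0,
                           seed: int = 0, experiment_id: int = 0):
    """Simulate replicate well responses from the three-parameter logistic.

    Returns a tidy table (columns ``x``, ``y``, ``replicate_id``,
    ``experiment_id``) and the generating truth.
    """
    import pandas as pd

    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("concentration list must not be empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        mu = logistic3(concentrations, top, bottom, log_ec50)
        y = mu + rng.normal(0.0, noise_sd, size=len(concentrations)) if noise_sd > 0 else mu
        for x, yy in zip(concentrations, y):
            rows.append((x, float(yy), rep, experiment_id))
    table = pd.DataFrame(rows, columns=["x", "y", "replicate_id", "experiment_id"])
    truth = DoseResponseTruth(top=top, bottom=bottom, log_ec50=log_ec50,
                              noise_sd=noise_sd, n_replicates=n_replicates,
                              seed=seed)
    return table, PhantomTruth(dose_response=truth)


# ---------------------------------------------------------------------------
# time-lapse simulation with deterministic shape drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeDrift:
    """Deterministic per-hour drift of the population's shape.

    ``lw_per_h`` is added to each cell's length/width ratio per hour at
    constant footprint area; ``height_ratio_per_h`` is added to the
    height/minor-radius ratio per hour (cap rounding when positive,
    flattening when negative).
    """

    lw_per_h: float = 0.0
    height_ratio_per_h: float = 0.0


def _drift_spec(spec: CellPhantomSpec, drift: ShapeDrift, t_h: float) -> CellPhantomSpec:
    a0, b0 = spec.footprint_radii
    ratio = max(a0 / b0 + drift.lw_per_h * t_h, 1.0)
    area = a0 * b0  # keep footprint area fixed under elongation drift
    b = math.sqrt(area / ratio)
    a = ratio * b
    k = spec.height / b0 + drift.height_ratio_per_h * t_h
    k = max(k, 1e-3)
    model = spec.model
    if model == "spherical_cap" and not math.isclose(a, b):
        model = "ellipsoidal_cap"  # elongation turns caps into hemi-ellipsoids
    return replace(spec, model=model, footprint_radii=(a, b), height=k * b)


def simulate_timelapse(population: Sequence[CellPhantomSpec],
                       shape_drift: ShapeDrift = ShapeDrift(),
                       frames: int = 2, interval_h: float = 3.0,
                       optics: OpticsConfig | None = None,
                       canvas: tuple[int, int] = (1024, 1024),
                       seed: int = 0, well_id: str = "") -> tuple[list[PhaseImage], PhantomTruth]:
    """Simulate a morphology time-lapse with deterministic shape drift.

    Cells are placed once (seeded) and drift in shape, not position. The
    truth carries per-frame mean analytic sphericity, mean length/width ratio
    and object count.
    """
    if frames < 2:
        raise ValueError("a time-lapse needs at least 2 frames")
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    px = optics.pixel_size
    extent = (canvas[1] * px, canvas[0] * px)
    # place at the most-elongated shape so drifted frames never overlap
    t_end = (frames - 1) * interval_h
    widest = [_drift_spec(s, shape_drift, t_end if shape_drift.lw_per_h > 0 else 0.0)
              for s in population]
    placed = _place_specs(widest, extent, rng, min_gap=6.0, max_attempts=10_000)
    base = [replace(s, centroid=p.centroid) for s, p in zip(population, placed)]

    images: list[PhaseImage] = []
    frame_truths: list[FrameTruth] = []
    all_objects: list[ObjectTruth] = []
    for f in range(frames):
        t_h = f * interval_h
        opd = np.zeros(canvas, dtype=np.float64)
        truths = [_render_onto(opd, _drift_spec(s, shape_drift, t_h), optics, i + 1)
                  for i, s in enumerate(base)]
        images.append(PhaseImage(opd=opd, optics=optics, time_h=t_h, well_id=well_id))
        frame_truths.append(FrameTruth(
            time_h=t_h, n_objects=len(truths),
            mean_sphericity=float(np.mean([t.sphericity for t in truths])),
            mean_length_width_ratio=float(np.mean([t.length_width_ratio for t in truths])),
        ))
        all_objects.extend(truths)
    return images, PhantomTruth(objects=all_objects, frames=frame_truths)
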