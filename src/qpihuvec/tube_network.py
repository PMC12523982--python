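"""Skeleton-graph quantification of capillary-like tube networks.

A phase image of tube-forming cells is binarised, thinned to a one-pixel
skeleton and converted into a planar graph whose elements follow the standard
tubulogenesis vocabulary:

* **segment** — a tube between two nodes,
* **junction** — a node where ≥ 3 segments meet,
* **extremity** — a free skeleton endpoint (degree 1),
* **branch** — a segment with at least one extremity endpoint.

Metrics are the segment/junction/branch/extremity counts, the total network
length and the median segment length, with optional normalisation of a time
series to a baseline hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import gaussian, threshold_triangle
from skimage.morphology import skeletonize

from .phantoms import PhaseImage

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class Node:
    id: int
    kind: str                      # "junction" | "extremity"
    coordinate: tuple[float, float]  # (x, y) µm


@dataclass
class Edge:
    segment_id: int
    u: Optional[int]               # endpoint node ids; None/None for a pure loop
    v: Optional[int]
    polyline: np.ndarray           # (N, 2) skeleton coordinates, µm
    length: float                  # µm, chord-resampled arc length
    is_branch: bool = False
    touches_boundary: bool = False


@dataclass
class NetworkGraph:
    nodes: list[Node]
    edges: list[Edge]
    pixel_size: float

    def node(self, nid: int) -> Node:
        return next(n for n in self.nodes if n.id == nid)

    def degree(self) -> dict[int, int]:
        deg = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            if e.u is not None:
                deg[e.u] += 1
            if e.v is not None:
                deg[e.v] += 1
        return deg

    def validate(self) -> None:
        deg = self.degree()
        kinds = {n.id: n.kind for n in self.nodes}
        for nid, d in deg.items():
            if kinds[nid] == "junction" and d < 3:
                raise AssertionError(f"junction node {nid} has degree {d} < 3")
            if kinds[nid] == "extremity" and d != 1:
                raise AssertionError(f"extremity node {nid} has degree {d} != 1")
        for e in self.edges:
            endpoint_kinds = {kinds[x] for x in (e.u, e.v) if x is not None}
            if e.is_branch != ("extremity" in endpoint_kinds):
                raise AssertionError(
                    f"edge {e.segment_id} branch flag inconsistent with endpoints")


@dataclass
class NetworkMetrics:
    """The tubulogenesis readouts extracted from one network graph."""

    n_segments: int
    n_junctions: int
    n_branches: int
    n_extremities: int
    total_length: float
    median_segment_length: float
    time_h: float = float("nan")


# ---------------------------------------------------------------------------
# binarisation
# ---------------------------------------------------------------------------

def make_tube_mask(image: PhaseImage, smoothing_scale: float = 2.0,
                   threshold: Optional[float] = None,
                   max_hole_area: float = 200.0,
                   min_region_area: float = 400.0) -> np.ndarray:
    """Binarise a tube-network phase image.

    Foreground = smoothed OPD above a triangle threshold (or an explicit OPD
    threshold), with holes below ``max_hole_area`` µm² filled and specks below
    ``min_region_area`` µm² removed. Returns a boolean raster.
    """
    opd = image.opd
    if not np.all(np.isfinite(opd)):
        raise ValueError("phase image contains non-finite values")
    if not np.any(opd > 0):
        return np.zeros(opd.shape, dtype=bool)
    px = image.optics.pixel_size
    smoothed = gaussian(opd, sigma=smoothing_scale / px, preserve_range=True)
    if threshold is None:
        threshold = threshold_triangle(opd)
    binary = opd > threshold
    binary = _fill_small_holes(binary, int(max_hole_area / px**2))
    binary = _remove_small_regions(binary, int(min_region_area / px**2))
    return binary if binary.any() else np.zeros(opd.shape, dtype=bool)


def _fill_small_holes(binary: np.ndarray, max_pixels: int) -> np.ndarray:
    holes, n = ndimage.label(~binary)
    if n == 0:
        return binary
    counts = np.bincount(holes.ravel())
    # the hole component touching the border is true background, never filled
    border_ids = np.unique(np.concatenate([
        holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]))
    fill = (counts <= max_pixels)
    fill[border_ids] = False
    fill[0] = False
    return binary | fill[holes]


def _remove_small_regions(binary: np.ndarray, min_pixels: int) -> np.ndarray:
    lab, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return binary
    counts = np.bincount(lab.ravel())
    keep = counts >= max(min_pixels, 1)
    keep[0] = False
    return keep[lab]


# ---------------------------------------------------------------------------
# skeleton → graph
# ---------------------------------------------------------------------------

def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _EIGHT, mode="constant") - skel


def _trace_from(start, first, node_of, skel_set, visited):
    """Walk a degree-2 chain from node pixel ``start`` through ``first``.

    Returns (path pixel list incl. both terminal node pixels, end node pixel)
    or (path, None) when the walk returns to a node pixel via ``first`` being
    itself a node pixel (handled by the caller).
    """
    path = [start, first]
    prev, cur = start, first
    while cur not in node_of:
        visited.add(cur)
        nxt = None
        for di, dj in _NEIGHBORS:
            q = (cur[0] + di, cur[1] + dj)
            if q != prev and q in skel_set:
                # prefer a non-visited or node pixel; skip stepping back onto
                # the path (corner adjacencies)
                if q in node_of or q not in visited:
                    nxt = q
                    break
        if nxt is None:
            return path, None  # dead end without an endpoint pixel: isolated
        path.append(nxt)
        prev, cur = cur, nxt
    return path, cur


_CHORD_STEP = 8  # pixels between chord knots for arc-length estimation


def _step_length(path: Sequence[tuple[int, int]], px: float) -> float:
    """Arc length of a pixel chain, µm.

    Euclidean length of the chain resampled every ``_CHORD_STEP`` pixels:
    raw single-pixel steps (1/√2) overestimate oblique runs by up to 8%
    (the classic chamfer bias), while 8-pixel chords stay within ~0.6% at
    every orientation for the gently curved centrelines tubes produce.
    """
    pts = list(path[::_CHORD_STEP])
    if pts[-1] != path[-1]:
        pts.append(path[-1])
    if len(pts) < 2:
        return 0.0
    arr = np.asarray(pts, dtype=float)
    return float(np.hypot(*np.diff(arr, axis=0).T).sum()) * px


def _pixel_xy(p: tuple[int, int], px: float) -> tuple[float, float]:
    return ((p[1] + 0.5) * px, (p[0] + 0.5) * px)


def skeletonize_and_graph(mask: np.ndarray, pixel_size: float,
                          prune_length: float = 15.0,
                          junction_merge_radius: float = 5.0) -> NetworkGraph:
    """Thin a binary tube mask to a skeleton and extract the network graph.

    Skeleton pixels are classified by 8-neighbour count (1 → endpoint, ≥ 3 →
    junction pixel); 8-connected junction-pixel clusters closer than
    ``junction_merge_radius`` µm are merged into single junction nodes, as are
    junctions connected by a segment shorter than that radius (a wide crossing
    thins into two nearby Y-points). Maximal degree-2 chains become edges whose
    length is the chord-resampled Euclidean arc length of the chain; closed
    chains without any node become one self-contained loop segment. Spur edges shorter than
    ``prune_length`` µm are then removed iteratively, dissolving any junction
    whose degree falls to 2.
    """
    mask = np.asarray(mask, dtype=bool)
    skel = skeletonize(mask)
    px = pixel_size
    if not skel.any():
        return NetworkGraph([], [], px)
    ncount = _neighbor_count(skel)
    skel_pixels = list(zip(*np.nonzero(skel)))
    skel_set = set(skel_pixels)

    endpoint_px = [p for p in skel_pixels if ncount[p] == 1]
    junction_mask = skel & (ncount >= 3)
    jlab, n_j = ndimage.label(junction_mask, structure=_EIGHT)

    # merge junction clusters whose pixels are within the merge radius
    parent = list(range(n_j + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    if n_j > 1 and junction_merge_radius > 0:
        jc = np.nonzero(junction_mask)
        coords = np.column_stack(jc).astype(float)
        ids = jlab[jc]
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(junction_merge_radius / px):
            if ids[a] != ids[b]:
                union(int(ids[a]), int(ids[b]))

    node_of: dict[tuple[int, int], int] = {}
    node_pixels: dict[int, list[tuple[int, int]]] = {}
    next_id = 0
    cluster_node: dict[int, int] = {}
    for p in zip(*np.nonzero(junction_mask)):
        root = find(int(jlab[p]))
        if root not in cluster_node:
            cluster_node[root] = next_id
            next_id += 1
        nid = cluster_node[root]
        node_of[p] = nid
        node_pixels.setdefault(nid, []).append(p)
    kind: dict[int, str] = {nid: "junction" for nid in node_pixels}
    for p in endpoint_px:
        if p in node_of:
            continue
        node_of[p] = next_id
        node_pixels[next_id] = [p]
        kind[next_id] = "extremity"
        next_id += 1

    # trace edges between node pixels
    visited: set[tuple[int, int]] = set()
    raw_edges: list[tuple[int, int, list]] = []
    seen_direct: set[frozenset] = set()
    for p, nid in list(node_of.items()):
        for di, dj in _NEIGHBORS:
            q = (p[0] + di, p[1] + dj)
            if q not in skel_set:
                continue
            if q in node_of:
                if node_of[q] != nid:
                    key = frozenset((p, q))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        raw_edges.append((nid, node_of[q], [p, q]))
                continue
            if q in visited:
                continue
            path, endp = _trace_from(p, q, node_of, skel_set, visited)
            if endp is None:
                continue
            raw_edges.append((nid, node_of[endp], path))

    # pure cycles: remaining unvisited degree-2 pixels
    remaining = [p for p in skel_pixels
                 if p not in visited and p not in node_of and ncount[p] == 2]
    remaining_set = set(remaining)
    loops: list[list] = []
    while remaining_set:
        start = min(remaining_set)
        path = [start]
        remaining_set.discard(start)
        prev, cur = None, start
        while True:
            nxt = None
            for di, dj in _NEIGHBORS:
                q = (cur[0] + di, cur[1] + dj)
                if q in remaining_set and q != prev:
                    nxt = q
                    break
            if nxt is None:
                break
            path.append(nxt)
            remaining_set.discard(nxt)
            prev, cur = cur, nxt
        path.append(start)  # close the loop for the length metric
        loops.append(path)

    # assemble a mutable graph, then contract short junction-junction edges
    nodes: dict[int, Node] = {}
    for nid, pix in node_pixels.items():
        arr = np.asarray(pix, dtype=float)
        cy, cx = arr[:, 0].mean(), arr[:, 1].mean()
        nodes[nid] = Node(nid, kind[nid], ((cx + 0.5) * px, (cy + 0.5) * px))
    edges: list[dict] = []
    for u, v, path in raw_edges:
        edges.append(dict(u=u, v=v, path=path, length=_step_length(path, px)))
    for path in loops:
        edges.append(dict(u=None, v=None, path=path, length=_step_length(path, px)))

    _contract_short_junction_links(nodes, edges, junction_merge_radius)
    _prune_spurs(nodes, edges, prune_length)

    return _finalize(nodes, edges, px)


def _contract_short_junction_links(nodes: dict, edges: list,
                                   merge_radius: float) -> None:
    changed = True
    while changed:
        changed = False
        for e in edges:
            if e["u"] is None or e["u"] == e["v"]:
                continue
            if (nodes[e["u"]].kind == "junction" and nodes[e["v"]].kind == "junction"
                    and e["length"] < merge_radius):
                keep, drop = e["u"], e["v"]
                edges.remove(e)
                for other in edges:
                    if other["u"] == drop:
                        other["u"] = keep
                    if other["v"] == drop:
                        other["v"] = keep
                ku = np.asarray(nodes[keep].coordinate)
                kv = np.asarray(nodes[drop].coordinate)
                nodes[keep] = replace(nodes[keep], coordinate=tuple((ku + kv) / 2.0))
                del nodes[drop]
                changed = True
                break


def _degrees(nodes: dict, edges: list) -> dict[int, int]:
    deg = {nid: 0 for nid in nodes}
    for e in edges:
        if e["u"] is not None:
            deg[e["u"]] += 1
        if e["v"] is not None:
            deg[e["v"]] += 1
    return deg


def _prune_spurs(nodes: dict, edges: list, prune_length: float) -> None:
    """Iteratively drop sub-threshold spur edges and dissolve degree-2 junctions."""
    while True:
        deg = _degrees(nodes, edges)
        spur = None
        for e in edges:
            if e["u"] is None:
                continue
            uk, vk = nodes[e["u"]].kind, nodes[e["v"]].kind
            if e["length"] >= prune_length:
                continue
            # a spur hangs off a junction and ends free
            if uk == "extremity" and vk == "junction" and deg[e["u"]] == 1:
                spur = (e, e["u"])
                break
            if vk == "extremity" and uk == "junction" and deg[e["v"]] == 1:
                spur = (e, e["v"])
                break
        if spur is None:
            break
        e, leaf = spur
        edges.remove(e)
        del nodes[leaf]
        _normalize_degrees(nodes, edges)


def _normalize_degrees(nodes: dict, edges: list) -> None:
    """Restore node-kind invariants after a removal.

    Junctions that fall to degree 2 dissolve (their two edges merge); degree-1
    junctions become extremities; isolated nodes disappear.
    """
    changed = True
    while changed:
        changed = False
        deg = _degrees(nodes, edges)
        for nid in list(nodes):
            if nodes[nid].kind != "junction":
                continue
            d = deg.get(nid, 0)
            if d == 2:
                incident = [e for e in edges if nid in (e["u"], e["v"])]
                if len(incident) == 1:
                    # both endpoints on this node: the edge closes into a loop
                    e = incident[0]
                    e["u"] = e["v"] = None
                else:
                    e1, e2 = incident
                    _merge_edges(e1, e2, nid)
                    edges.remove(e2)
                del nodes[nid]
                changed = True
                break
            if d == 1:
                nodes[nid] = replace(nodes[nid], kind="extremity")
                changed = True
            elif d == 0:
                del nodes[nid]
                changed = True
                break


def _merge_edges(e1: dict, e2: dict, via: int) -> None:
    """Concatenate e2 onto e1 through their shared node ``via``."""
    p1 = e1["path"] if e1["v"] == via else list(reversed(e1["path"]))
    far1 = e1["u"] if e1["v"] == via else e1["v"]
    p2 = e2["path"] if e2["u"] == via else list(reversed(e2["path"]))
    far2 = e2["v"] if e2["u"] == via else e2["u"]
    e1["path"] = list(p1) + list(p2)[1:]
    e1["u"], e1["v"] = far1, far2
    e1["length"] = e1["length"] + e2["length"]


def _finalize(nodes: dict, edges: list, px: float) -> NetworkGraph:
    id_map = {old: new for new, old in enumerate(sorted(nodes))}
    out_nodes = [replace(nodes[old], id=id_map[old]) for old in sorted(nodes)]
    kinds = {n.id: n.kind for n in out_nodes}
    out_edges = []
    for sid, e in enumerate(edges):
        u = id_map[e["u"]] if e["u"] is not None else None
        v = id_map[e["v"]] if e["v"] is not None else None
        poly = np.array([((c + 0.5) * px, (r + 0.5) * px) for r, c in e["path"]])
        is_branch = any(kinds.get(x) == "extremity" for x in (u, v) if x is not None)
        out_edges.append(Edge(segment_id=sid, u=u, v=v, polyline=poly,
                              length=e["length"], is_branch=is_branch))
    return NetworkGraph(out_nodes, out_edges, px)


# ---------------------------------------------------------------------------
# metrics and normalisation
# ---------------------------------------------------------------------------

def network_metrics(graph: NetworkGraph, time_h: float = float("nan")) -> NetworkMetrics:
    """Counts, total length and median segment length of a network graph."""
    lengths = [e.length for e in graph.edges]
    return NetworkMetrics(
        n_segments=len(graph.edges),
        n_junctions=sum(1 for n in graph.nodes if n.kind == "junction"),
        n_branches=sum(1 for e in graph.edges if e.is_branch),
        n_extremities=sum(1 for n in graph.nodes if n.kind == "extremity"),
        total_length=float(sum(lengths)),
        median_segment_length=float(np.median(lengths)) if lengths else float("nan"),
        time_h=time_h,
    )


def flag_boundary_branches(graph: NetworkGraph, image_extent: tuple[float, float],
                           margin: float | None = None,
                           margin_px: int = 2) -> NetworkGraph:
    """Flag edges whose polyline enters the image-boundary margin band.

    Branches ending at the frame edge are often clipped segments rather than
    true free-ending protrusions, so they are flagged — never deleted — and
    downstream summaries can be computed with and without them.
    ``image_extent`` is the physical (width, height) of the frame in µm;
    ``margin`` defaults to ``margin_px`` pixels.
    """
    if margin is None:
        margin = margin_px * graph.pixel_size
    w, h = image_extent
    new_edges = []
    for e in graph.edges:
        xy = e.polyline
        near = (np.any(xy[:, 0] < margin) or np.any(xy[:, 0] > w - margin)
                or np.any(xy[:, 1] < margin) or np.any(xy[:, 1] > h - margin))
        new_edges.append(replace(e, touches_boundary=bool(near)))
    return NetworkGraph(list(graph.nodes), new_edges, graph.pixel_size)


_NORMALIZED_FIELDS = ("n_segments", "n_junctions", "n_branches",
                      "n_extremities", "total_length", "median_segment_length")


def normalize_timecourse(series: Sequence[NetworkMetrics],
                         baseline_time_h: float = 1.0) -> pd.DataFrame:
    """Express a metric time series as percentages of the baseline hour.

    Returns a tidy frame with the raw metrics and, per metric, a
    ``<metric>_pct`` column equal to 100 × value / baseline value; the
    baseline row is 100% everywhere. A zero baseline leaves that metric's
    percentages as NaN (undefined rather than infinite).
    """
    if not series:
        raise ValueError("empty metric series")
    times = [m.time_h for m in series]
    base = [m for m in series if m.time_h == baseline_time_h]
    if not base:
        raise ValueError(
            f"no entry at baseline time {baseline_time_h} h (times: {sorted(times)})")
    base = base[0]
    rows = []
    for m in series:
        row = {"time_h": m.time_h}
        for f in _NORMALIZED_FIELDS:
            val = getattr(m, f)
            ref = getattr(base, f)
            row[f] = val
            row[f + "_pct"] = 100.0 * val / ref if ref else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).sort_values("time_h").reset_index(drop=True)
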