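"""Vessel centerline graphs.

A :class:`VesselGraph` is the pipeline's central structure: ordered
centerline polylines with per-point radii, endpoint adjacency, and two
per-segment labels — artery/vein and main/branch.  The main/branch split
follows the clinical criterion that only the largest-caliber vessels
originating at the optic disk count as main vessels; everything that
splits off them is a branch vessel.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass
class VesselSegment:
    """An ordered centerline polyline with per-point radius estimates.

    Coordinates are 0-based ``(row, col)`` with pixel centers at integers.
    """

    seg_id: int
    points: np.ndarray  # (n, 2) float, (row, col)
    radius_px: np.ndarray  # (n,) float
    av_label: str = "unknown"  # artery | vein | unknown
    hierarchy_label: str = "unknown"  # main | branch | unknown

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.radius_px = np.atleast_1d(np.asarray(self.radius_px, dtype=np.float64))
        if self.radius_px.size == 1:
            self.radius_px = np.full(len(self.points), float(self.radius_px[0]))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("segment points must be (n, 2)")
        if len(self.radius_px) != len(self.points):
            raise ValueError("radius_px must match points length")
        if not np.all(np.isfinite(self.radius_px)):
            raise ValueError("radius must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radius_px))

    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def report_class(self) -> str:
        """Combined label, e.g. ``branch_artery`` (or ``unknown``)."""
        if "unknown" in (self.av_label, self.hierarchy_label):
            return "unknown"
        return f"{self.hierarchy_label}_{self.av_label}"


@dataclass
class VesselGraph:
    segments: list[VesselSegment] = field(default_factory=list)
    adjacency: dict[int, set[int]] = field(default_factory=dict)
    disk_center: tuple[float, float] | None = None
    disk_radius_px: float | None = None

    def __post_init__(self) -> None:
        ids = [s.seg_id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValueError("segment ids must be unique")
        for s in self.segments:
            self.adjacency.setdefault(s.seg_id, set())
        # adjacency must be symmetric
        for sid, nbrs in self.adjacency.items():
            for n in nbrs:
                self.adjacency.setdefault(n, set()).add(sid)

    def __len__(self) -> int:
        return len(self.segments)

    def segment(self, seg_id: int) -> VesselSegment:
        for s in self.segments:
            if s.seg_id == seg_id:
                return s
        raise KeyError(seg_id)

    def total_length(self) -> float:
        return sum(s.arc_length() for s in self.segments)


# ---------------------------------------------------------------------------
# rasterization


def _densify(points: np.ndarray, radius: np.ndarray, step: float = 0.25):
    """Resample a polyline (and its radius profile) at a fixed arc step."""
    points = np.asarray(points, float)
    if len(points) < 2:
        return points, np.asarray(radius, float)
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    if total <= 0:
        return points[:1], np.asarray(radius[:1], float)
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    rows = np.interp(si, s, points[:, 0])
    cols = np.interp(si, s, points[:, 1])
    rad = np.interp(si, s, radius)
    return np.stack([rows, cols], axis=1), rad


def rasterize_graph(graph: VesselGraph, shape: tuple[int, int]) -> np.ndarray:
    """Binary tube mask of a graph: pixels within each segment's radius.

    Deterministic, so a mask built from a graph always equals a second
    rasterization of the same graph exactly.
    """
    mask = np.zeros(shape, dtype=bool)
    for seg in graph.segments:
        _rasterize_tube(mask, seg.points, seg.radius_px)
    return mask


def _rasterize_tube(mask: np.ndarray, points: np.ndarray, radius: np.ndarray) -> None:
    shape = mask.shape
    pts, rad = _densify(points, radius, step=0.25)
    if len(pts) == 0:
        return
    rmax = float(np.max(rad))
    lo = np.maximum(np.floor(pts.min(axis=0) - rmax - 1), 0).astype(int)
    hi = np.minimum(np.ceil(pts.max(axis=0) + rmax + 2), shape).astype(int)
    if np.any(hi <= lo):
        return
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    tree = cKDTree(pts)
    dist, idx = tree.query(grid, k=1, distance_upper_bound=rmax + 1.0)
    ok = np.isfinite(dist)
    inside = np.zeros(len(grid), bool)
    inside[ok] = dist[ok] <= rad[np.clip(idx[ok], 0, len(rad) - 1)]
    mask[lo[0]:hi[0], lo[1]:hi[1]] |= inside.reshape(rr.shape)


# ---------------------------------------------------------------------------
# centerline extraction


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _order_component(coords: np.ndarray) -> np.ndarray:
    """Order skeleton pixels of one component endpoint-to-endpoint.

    Works for open paths and for cycles (starts anywhere on a cycle).
    """
    n = len(coords)
    if n <= 2:
        return coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=1.5, output_type="ndarray")
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    degrees = np.array([len(a) for a in adj])
    endpoints = np.flatnonzero(degrees <= 1)
    start = int(endpoints[0]) if len(endpoints) else 0
    order = [start]
    visited = np.zeros(n, bool)
    visited[start] = True
    cur = start
    while True:
        nxt = [j for j in adj[cur] if not visited[j]]
        if not nxt:
            break
        if len(nxt) > 1:
            # prefer the 4-connected / nearest continuation
            dists = np.linalg.norm(coords[nxt] - coords[cur], axis=1)
            nxt = [nxt[int(np.argmin(dists))]]
        cur = nxt[0]
        visited[cur] = True
        order.append(cur)
    return coords[order]


def _smooth_polyline(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Sub-pixel smoothing: centered moving average, endpoints pinned."""
    if len(points) < window:
        return points
    kernel = np.ones(window) / window
    out = points.astype(float).copy()
    for k in (0, 1):
        sm = np.convolve(points[:, k], kernel, mode="same")
        # fix edge shrinkage from zero padding
        norm = np.convolve(np.ones(len(points)), kernel, mode="same")
        out[:, k] = sm / norm
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def extract_centerlines(mask: np.ndarray, min_length_px: float = 10.0) -> VesselGraph:
    """Skeletonize a binary vessel mask into an ordered centerline graph.

    The skeleton is broken at junction pixels (>= 3 skeleton neighbors),
    spurs shorter than ``min_length_px`` are pruned, each remaining
    segment is ordered endpoint to endpoint and lightly smoothed, and a
    per-point radius is estimated from the distance transform of the mask.
    Labels are left ``unknown``.
    """
    from skimage.morphology import skeletonize

    mask = np.asarray(mask, bool)
    if not mask.any():
        warnings.warn("empty mask: returning empty graph")
        return VesselGraph()
    skel = skeletonize(mask)
    nb_count = ndimage.convolve(skel.astype(np.uint8), _NEIGH, mode="constant")
    junctions = skel & (nb_count >= 3)
    body = skel & ~junctions
    labels, n_lab = ndimage.label(body, structure=np.ones((3, 3)))
    edt = ndimage.distance_transform_edt(mask)

    segments: list[VesselSegment] = []
    endpoint_info: list[tuple[int, np.ndarray]] = []  # (seg_id, endpoint coord)
    sid = 0
    for lab in range(1, n_lab + 1):
        coords = np.argwhere(labels == lab).astype(float)
        if len(coords) < 5:
            continue
        ordered = _order_component(coords)
        length = np.sum(np.linalg.norm(np.diff(ordered, axis=0), axis=1))
        if length < min_length_px:
            continue
        pts = _smooth_polyline(ordered)
        rad = ndimage.map_coordinates(edt, pts.T, order=1, mode="nearest")
        seg = VesselSegment(sid, pts, rad)
        segments.append(seg)
        endpoint_info.append((sid, ordered[0]))
        endpoint_info.append((sid, ordered[-1]))
        sid += 1

    if not segments:
        warnings.warn("no component longer than min_length_px: empty graph")
        return VesselGraph()

    adjacency: dict[int, set[int]] = {s.seg_id: set() for s in segments}
    jxy = np.argwhere(junctions).astype(float)
    if len(jxy) and endpoint_info:
        jtree = cKDTree(jxy)
        # cluster junction pixels that touch each other
        jlabels, _ = ndimage.label(junctions, structure=np.ones((3, 3)))
        ep_ids = np.array([e[0] for e in endpoint_info])
        ep_pts = np.array([e[1] for e in endpoint_info])
        d, idx = jtree.query(ep_pts, k=1)
        near = d <= 2.5
        clusters = np.full(len(ep_pts), -1, int)
        jc = jlabels[tuple(jxy[idx].astype(int).T)]
        clusters[near] = jc[near]
        for c in np.unique(clusters[clusters >= 0]):
            members = np.unique(ep_ids[clusters == c])
            for a in members:
                for b in members:
                    if a != b:
                        adjacency[int(a)].add(int(b))

    return VesselGraph(segments=segments, adjacency=adjacency)


# ---------------------------------------------------------------------------
# main / branch split


def split_main_branch(
    graph: VesselGraph,
    disk_center: tuple[float, float],
    disk_radius_px: float,
    caliber_quantile: float = 0.8,
) -> VesselGraph:
    """Label segments main/branch by caliber-guided region growing.

    Growing starts from segments intersecting the optic disk.  At each
    junction the main label is passed on only to the largest-caliber
    neighbor, and only if its mean radius is at least
    ``caliber_quantile`` times the parent's — a deterministic reading of
    the rule that main vessels are the largest vessels originating at
    the disk, with everything else a branch.  Ties break to the lower
    segment id.
    """
    if not 0 < caliber_quantile < 1:
        raise ValueError("caliber_quantile must be in (0, 1)")
    if not graph.segments:
        return graph
    center = np.asarray(disk_center, float)
    graph.disk_center = (float(center[0]), float(center[1]))
    graph.disk_radius_px = float(disk_radius_px)

    for s in graph.segments:
        s.hierarchy_label = "branch"
    by_id = {s.seg_id: s for s in graph.segments}

    seeds = []
    for s in graph.segments:
        d = np.linalg.norm(s.points - center, axis=1)
        if np.any(d <= disk_radius_px + np.maximum(s.radius_px, 1.0)):
            seeds.append(s.seg_id)
    if not seeds:
        warnings.warn("no segment touches the optic disk: all labelled branch")
        return graph

    # Grow outward only: each queue entry carries the endpoint through
    # which the segment was entered, and the main label is passed on
    # only at the far endpoint.  This keeps a junction from handing the
    # label back to the sibling of a continuation.
    queue: deque = deque()
    for sid in sorted(seeds):
        seg = by_id[sid]
        seg.hierarchy_label = "main"
        ends = (seg.points[0], seg.points[-1])
        entry = min(ends, key=lambda e: np.linalg.norm(e - center))
        queue.append((sid, entry))
    while queue:
        sid, entry = queue.popleft()
        parent = by_id[sid]
        ends = (parent.points[0], parent.points[-1])
        far = max(ends, key=lambda e: np.linalg.norm(e - entry))
        children = []
        for cid in graph.adjacency.get(sid, ()):  # neighbors at the far junction
            child = by_id[cid]
            if child.hierarchy_label == "main":
                continue
            cends = (child.points[0], child.points[-1])
            d_far = [np.linalg.norm(e - far) for e in cends]
            d_entry = [np.linalg.norm(e - entry) for e in cends]
            # adjacent at the far junction, not the one we entered through
            if min(d_far) < min(d_entry):
                children.append((cid, cends[int(np.argmin(d_far))]))
        if not children:
            continue
        children.sort(key=lambda c: (-by_id[c[0]].mean_radius, c[0]))
        best_id, best_entry = children[0]
        best = by_id[best_id]
        if best.mean_radius >= caliber_quantile * parent.mean_radius:
            best.hierarchy_label = "main"
            queue.append((best_id, best_entry))
    return graph
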