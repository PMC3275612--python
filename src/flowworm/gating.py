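"""Ordered polygon-region schemes along a unidirectional data trajectory.

An asynchronous population traces a connected, one-way "worm" through
expression space.  Discretizing it means laying a globally ordered sequence
of polygon regions along the worm's modal ridge (the backbone), with the
dividing sides of consecutive regions perpendicular to the local slope and
*shared exactly* between neighbours, so regions can neither overlap nor
leave gaps.  Regions may live in different bivariate views and carry a
boolean gate context (e.g. mitotic vs interphase), with one global order
running across all of them.

Geometry operates in display coordinates: each view names an axis transform
(linear, log10 or asinh) and events are transformed before any
point-in-polygon test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .events import EventTable, combine_gates

__all__ = [
    "ViewSpec",
    "PolygonRegion",
    "Backbone",
    "RegionScheme",
    "Segmented1D",
    "ValidationReport",
    "trace_backbone",
    "build_orthogonal_regions",
    "validate_scheme",
    "assign_events",
    "segment_histogram_1d",
    "ridge_anchors",
]


# -- views and transforms -----------------------------------------------------

@dataclass(frozen=True)
class ViewSpec:
    """A bivariate display: two channels plus their axis transforms."""

    x_channel: str
    y_channel: str
    x_transform: str = "linear"
    y_transform: str = "linear"
    cofactor: float = 5.0  # asinh cofactor / log10 floor scale

    def key(self) -> tuple:
        return (self.x_channel, self.y_channel, self.x_transform,
                self.y_transform, self.cofactor)

    def _apply(self, values, name):
        values = np.asarray(values, dtype=float)
        if name == "linear":
            return values
        if name == "asinh":
            return np.arcsinh(values / self.cofactor)
        if name == "log10":
            return np.log10(np.maximum(values, self.cofactor * 1e-3))
        raise ValueError(f"unknown transform {name!r}")

    def transform(self, events: EventTable) -> np.ndarray:
        """Events → (n, 2) array of display coordinates."""
        events.require(self.x_channel, self.y_channel)
        return np.column_stack([
            self._apply(events[self.x_channel], self.x_transform),
            self._apply(events[self.y_channel], self.y_transform),
        ])

    def to_dict(self) -> dict:
        return {"x_channel": self.x_channel, "y_channel": self.y_channel,
                "x_transform": self.x_transform, "y_transform": self.y_transform,
                "cofactor": self.cofactor}


# -- domain types -------------------------------------------------------------

@dataclass
class PolygonRegion:
    """One ordered region: a simple polygon in a view, under a gate context."""

    global_index: int
    view: ViewSpec
    vertices: np.ndarray
    gate_context: str | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("a region needs at least 3 vertices")
        if not self.polygon.is_valid:
            raise ValueError(
                f"region {self.global_index}: self-intersecting polygon")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class Backbone:
    """Ordered anchors tracing the modal path of the data in one view."""

    view: ViewSpec
    anchors: np.ndarray

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.ndim != 2 or self.anchors.shape[0] < 2:
            raise ValueError("backbone needs at least 2 anchors")
        if np.any(np.all(np.diff(self.anchors, axis=0) == 0, axis=1)):
            raise ValueError("consecutive anchors must be distinct")

    @property
    def arc(self) -> np.ndarray:
        """Cumulative arc length at each anchor, starting at 0."""
        steps = np.linalg.norm(np.diff(self.anchors, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, fractions) -> np.ndarray:
        """Points on the polyline at the given arc-length fractions."""
        f = np.atleast_1d(np.asarray(fractions, dtype=float))
        s = f * self.length
        arc = self.arc
        out = np.column_stack([np.interp(s, arc, self.anchors[:, 0]),
                               np.interp(s, arc, self.anchors[:, 1])])
        return out

    def tangent_at(self, fractions, window: float = 0.02) -> np.ndarray:
        """Unit tangents at arc fractions, smoothed over ±window of arc."""
        f = np.atleast_1d(np.asarray(fractions, dtype=float))
        lo = np.clip(f - window, 0.0, 1.0)
        hi = np.clip(f + window, 0.0, 1.0)
        d = self.point_at(hi) - self.point_at(lo)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return d / norm

    def project(self, points: np.ndarray) -> np.ndarray:
        """Arc-length fraction of the nearest polyline point for each point.

        Used to place region boundaries at event quantiles along the worm.
        """
        pts = np.asarray(points, dtype=float)
        a = self.anchors[:-1]
        b = self.anchors[1:]
        ab = b - a                                   # (m, 2)
        denom = (ab * ab).sum(axis=1)                # (m,)
        # vectorized point-to-segment projection over all segments
        diff = pts[:, None, :] - a[None, :, :]       # (n, m, 2)
        t = np.clip((diff * ab[None]).sum(-1) / denom[None], 0.0, 1.0)
        proj = a[None] + t[..., None] * ab[None]
        d2 = ((pts[:, None, :] - proj) ** 2).sum(-1)
        seg = np.argmin(d2, axis=1)
        arc = self.arc
        s = arc[seg] + t[np.arange(len(pts)), seg] * np.sqrt(denom[seg])
        return s / self.length


@dataclass
class RegionScheme:
    """Globally ordered regions across one or more views: the discretized worm."""

    regions: list[PolygonRegion]
    description: str = ""

    def __post_init__(self):
        idx = [r.global_index for r in self.regions]
        if len(set(idx)) != len(idx):
            raise ValueError("global_index values must be unique")
        self.regions = sorted(self.regions, key=lambda r: r.global_index)

    @property
    def views(self) -> list[ViewSpec]:
        seen, out = set(), []
        for r in self.regions:
            if r.view.key() not in seen:
                seen.add(r.view.key())
                out.append(r.view)
        return out

    def to_json(self, path=None):
        payload = {
            "description": self.description,
            "regions": [{
                "global_index": r.global_index,
                "view": r.view.to_dict(),
                "gate_context": r.gate_context,
                "vertices": r.vertices.tolist(),
            } for r in self.regions],
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "RegionScheme":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        regions = [PolygonRegion(global_index=r["global_index"],
                                 view=ViewSpec(**r["view"]),
                                 vertices=np.asarray(r["vertices"]),
                                 gate_context=r.get("gate_context"))
                   for r in payload["regions"]]
        return cls(regions, payload.get("description", ""))


# -- backbone tracing ---------------------------------------------------------

def _smoothed_density(xy: np.ndarray, bins: int = 128):
    """Binned 2-D histogram smoothed with a Silverman-width Gaussian."""
    n = len(xy)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - 0.02 * span
    hi = hi + 0.02 * span
    H, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins,
                               range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    bw = xy.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)  # Silverman, d=2
    widths = np.array([xe[1] - xe[0], ye[1] - ye[0]])
    sigma = np.maximum(bw / widths, 0.75)
    D = ndimage.gaussian_filter(H, sigma=sigma)
    return D, xe, ye


def trace_backbone(events: EventTable, view: ViewSpec, anchors=None,
                   start=None, bins: int = 128, n_anchors: int = 60,
                   density_floor: float = 0.02) -> Backbone:
    """Trace the two-dimensional peak range (the backbone) of a view.

    With ``anchors`` supplied they are returned verbatim (manual mode — the
    workflow of drawing the ridge by eye).  Otherwise the ridge of a smoothed
    2-D histogram is skeletonized and walked from the endpoint nearest
    ``start`` (display coordinates); disconnected high-density regions raise
    with the advice to supply manual anchors.
    """
    if anchors is not None:
        return Backbone(view, np.asarray(anchors, dtype=float))
    xy = view.transform(events)
    if len(xy) < 1000:
        raise ValueError("need at least 1000 events in view to trace a backbone")
    try:
        from skimage.morphology import skeletonize
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("automatic tracing requires scikit-image") from exc
    import networkx as nx

    D, xe, ye = _smoothed_density(xy, bins=bins)
    mask = D >= density_floor * D.max()
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        masses = ndimage.sum_labels(D, labels, index=np.arange(1, n_comp + 1))
        if np.sort(masses)[-2] > 0.05 * masses.sum():
            raise ValueError(
                "density ridge is disconnected; supply manual anchors")
        mask = labels == (1 + int(np.argmax(masses)))
    skel = skeletonize(mask)
    px = np.argwhere(skel)
    if len(px) < 2:
        raise ValueError("ridge too small to trace; supply manual anchors")

    g = nx.Graph()
    index = {tuple(p): i for i, p in enumerate(px)}
    for i, (r, c) in enumerate(px):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=float(np.hypot(dr, dc)))
    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len)
        g = g.subgraph(comps[-1]).copy()
    ends = [v for v in g.nodes if g.degree[v] == 1]
    if not ends:
        raise ValueError("ridge forms a loop; supply manual anchors")

    centers = np.column_stack([
        0.5 * (xe[px[:, 0]] + xe[px[:, 0] + 1]),
        0.5 * (ye[px[:, 1]] + ye[px[:, 1] + 1]),
    ])
    if start is not None:
        start = np.asarray(start, dtype=float)
        first = min(ends, key=lambda v: np.sum((centers[v] - start) ** 2))
    else:
        first = min(ends, key=lambda v: (centers[v][0], centers[v][1]))
    # farthest endpoint (graph distance) gives the full ridge run
    dist = nx.single_source_dijkstra_path_length(g, first)
    last = max((v for v in ends if v in dist), key=dist.get)
    path = nx.dijkstra_path(g, first, last)
    pts = centers[path]
    # drop zero-length steps, then resample to n_anchors by arc length
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0])
    bb = Backbone(view, pts[keep])
    if len(bb.anchors) > n_anchors:
        bb = Backbone(view, bb.point_at(np.linspace(0, 1, n_anchors)))
    return bb


def ridge_anchors(xy: np.ndarray, axis: int = 0, n_bins: int = 20,
                  ascending: bool = True,
                  min_count: int | None = None) -> np.ndarray:
    """Quantile-binned median ridge: anchors along a monotone stretch.

    Bin events by quantiles of one display coordinate and take the median of
    the other per bin — a robust, data-driven backbone for stretches where
    one channel changes monotonically.  ``min_count`` (events per usable
    bin) defaults to a third of the expected bin occupancy.
    """
    xy = np.asarray(xy, dtype=float)
    key = xy[:, axis]
    if min_count is None:
        min_count = max(5, len(xy) // (3 * n_bins))
    qs = np.quantile(key, np.linspace(0, 1, n_bins + 1))
    anchors = []
    for lo, hi in zip(qs[:-1], qs[1:]):
        sel = (key >= lo) & (key <= hi)
        if sel.sum() < min_count:
            continue
        anchors.append(np.median(xy[sel], axis=0))
    if not anchors:
        raise ValueError("no bin reached min_count; too few events for a ridge")
    anchors = np.asarray(anchors)
    order = np.argsort(anchors[:, axis])
    if not ascending:
        order = order[::-1]
    return anchors[order]


# -- region construction ------------------------------------------------------

def build_orthogonal_regions(backbone: Backbone, n_regions: int | None = None,
                             half_width=1.0, boundaries=None,
                             gate_context: str | None = None,
                             start_index: int = 0,
                             tangent_window: float = 0.02) -> list[PolygonRegion]:
    """Consecutive quadrilaterals whose dividing sides are ⊥ to the backbone.

    Boundary positions are arc-length fractions (``boundaries``, including 0
    and 1) or ``n_regions`` equal spans.  Each dividing side's two vertices
    are computed once and shared by both neighbouring regions, so adjacent
    regions coincide exactly along their common edge — no overlap, no gap.
    ``half_width`` is a scalar or one value per boundary.
    """
    if boundaries is None:
        if n_regions is None or n_regions < 1:
            raise ValueError("need n_regions >= 1 or explicit boundaries")
        boundaries = np.linspace(0.0, 1.0, n_regions + 1)
    else:
        boundaries = np.asarray(boundaries, dtype=float)
        if boundaries.ndim != 1 or boundaries.size < 2 \
                or not np.all(np.diff(boundaries) > 0):
            raise ValueError("boundaries must be increasing arc fractions")
    hw = np.broadcast_to(np.asarray(half_width, dtype=float), boundaries.shape).copy()
    if np.any(hw <= 0):
        raise ValueError("half_width must be positive everywhere")

    pts = backbone.point_at(boundaries)
    tans = backbone.tangent_at(boundaries, window=tangent_window)
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])
    left = pts + hw[:, None] * normals
    right = pts - hw[:, None] * normals

    regions = []
    for i in range(len(boundaries) - 1):
        verts = np.array([left[i], right[i], right[i + 1], left[i + 1]])
        try:
            region = PolygonRegion(global_index=start_index + i,
                                   view=backbone.view, vertices=verts,
                                   gate_context=gate_context)
        except ValueError as exc:
            raise ValueError(
                f"regions {start_index + i} and {start_index + i + 1}: dividing "
                "sides cross at a high-curvature point; use fewer regions or a "
                "narrower half_width") from exc
        regions.append(region)
    return regions


# -- validation and assignment ------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of checking a scheme against data (and truth, if available)."""

    overlap_pairs: list[tuple[int, int]]
    unassigned_fraction: float
    region_counts: dict[int, int]
    min_events: int
    median_u: dict[int, float] | None = None
    u_monotone: bool | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def n_overlaps(self) -> int:
        return len(self.overlap_pairs)

    @property
    def ok(self) -> bool:
        return self.n_overlaps == 0 and (self.u_monotone is not False)


def _context_mask(events: EventTable, context: str | None) -> np.ndarray:
    if context is None or context.strip().upper() in ("", "ALL"):
        return np.ones(events.n_events, dtype=bool)
    return combine_gates(events.masks, context).mask


def validate_scheme(scheme: RegionScheme, events: EventTable,
                    truth_u=None, min_events: int = 50) -> ValidationReport:
    """Check non-overlap, coverage, occupancy and (with truth) temporal order.

    Within a (view, gate-context) group, consecutive regions may share edges
    but must not share area.  With per-event truth positions available, the
    median true position u must increase strictly with global order — the
    computational analogue of verifying unidirectional passage with a pulse
    label.
    """
    messages: list[str] = []
    overlaps: list[tuple[int, int]] = []
    groups: dict[tuple, list[PolygonRegion]] = {}
    for r in scheme.regions:
        groups.setdefault((r.view.key(), r.gate_context), []).append(r)
    for members in groups.values():
        for i, ra in enumerate(members):
            pa = ra.polygon
            for rb in members[i + 1:]:
                inter = pa.intersection(rb.polygon).area
                if inter > 1e-9 * min(pa.area, rb.polygon.area):
                    overlaps.append((ra.global_index, rb.global_index))

    labels = assign_events(events, scheme)
    gated = np.zeros(events.n_events, dtype=bool)
    for context in {r.gate_context for r in scheme.regions}:
        gated |= _context_mask(events, context)
    n_gated = int(gated.sum())
    unassigned = float(((labels < 0) & gated).sum() / max(n_gated, 1))

    counts = {r.global_index: int((labels == r.global_index).sum())
              for r in scheme.regions}
    min_count = min(counts.values()) if counts else 0
    if min_count < min_events:
        low = [k for k, v in counts.items() if v < min_events]
        messages.append(f"regions {low} hold fewer than {min_events} events")

    median_u = None
    monotone = None
    if truth_u is not None:
        truth_u = np.asarray(truth_u, dtype=float)
        median_u = {r.global_index: float(np.median(truth_u[labels == r.global_index]))
                    for r in scheme.regions if counts[r.global_index] > 0}
        seq = [median_u[k] for k in sorted(median_u)]
        monotone = bool(np.all(np.diff(seq) > 0))
        if not monotone:
            messages.append("median true position u is not strictly increasing")
    return ValidationReport(overlaps, unassigned, counts, min_count,
                            median_u, monotone, messages)


def assign_events(events: EventTable, scheme: RegionScheme) -> np.ndarray:
    """Per-event segment label (region global_index; −1 = unassigned).

    Regions are tested in global order within the event's passing gate
    context; the first polygon that covers the point (boundary inclusive)
    wins, which resolves shared-edge ties deterministically toward the
    earlier region.
    """
    labels = np.full(events.n_events, -1, dtype=int)
    coords: dict[tuple, np.ndarray] = {}
    contexts: dict[str | None, np.ndarray] = {}
    for region in scheme.regions:
        key = region.view.key()
        if key not in coords:
            coords[key] = shapely.points(region.view.transform(events))
        if region.gate_context not in contexts:
            contexts[region.gate_context] = _context_mask(events, region.gate_context)
        candidates = np.flatnonzero((labels < 0) & contexts[region.gate_context])
        if candidates.size == 0:
            continue
        inside = shapely.covers(region.polygon, coords[key][candidates])
        labels[candidates[inside]] = region.global_index
    return labels


# -- 1-D segmentation ---------------------------------------------------------

@dataclass
class Segmented1D:
    """Contiguous-interval segmentation of a 1-D histogram."""

    labels: np.ndarray
    counts: np.ndarray
    medians: np.ndarray
    boundaries: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.counts.size

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def segment_histogram_1d(values, boundaries) -> Segmented1D:
    """Split 1-D values into ordered contiguous intervals.

    ``boundaries`` are the interior thresholds (strictly increasing); the
    first and last intervals are open-ended so the terminal segments enclose
    the full measurement variation of the bounding clusters.  Returns counts
    and medians per interval plus the per-event interval label.
    """
    values = np.asarray(values, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.ndim != 1 or boundaries.size < 1 \
            or not np.all(np.diff(boundaries) > 0):
        raise ValueError("boundaries must be strictly increasing")
    labels = np.searchsorted(boundaries, values, side="left")
    m = boundaries.size + 1
    counts = np.bincount(labels, minlength=m)
    medians = np.full(m, np.nan)
    for k in range(m):
        if counts[k]:
            medians[k] = np.median(values[labels == k])
        else:
            warnings.warn(f"interval {k} is empty; center undefined")
    return Segmented1D(labels, counts, medians, boundaries)
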