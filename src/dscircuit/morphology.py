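"""Dendritic morphometry from SWC skeletons.

Implements the arbor measurements used to characterize bistratified
retinal ganglion cells: ON/OFF stratification split by normalized IPL
depth, Sholl intersection profiles at 5 µm ring spacing on the x–y
projection, convex-hull area, dendrite–soma center-of-mass offset and
its angle relative to the retinal ventral axis, and the asymmetry index

    AI = |P1S − SP2| / (P1S + SP2),

where P1 and P2 are the intersections of the line through the soma and
the dendritic center of mass with the convex-hull border, and P1S, SP2
the distances from each intersection to the soma.  AI = 0 for a soma at
the hull center, 1 for a soma on the hull border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "Skeleton",
    "DendriteSubset",
    "MorphMetrics",
    "split_on_off",
    "sholl_profile",
    "hull_and_com",
    "asymmetry_index",
    "summary_metrics",
]


class InvalidGeometryError(ValueError):
    """Soma outside the convex hull, or hull degenerate."""


@dataclass
class Skeleton:
    """Neuronal tree: node table with 3D coordinates, parent links, and
    a per-node normalized IPL depth (0 = INL border, 1 = GCL border)."""

    node_ids: np.ndarray       # (N,) int
    xyz: np.ndarray            # (N, 3) µm
    radius: np.ndarray         # (N,) µm
    parent: np.ndarray         # (N,) int, -1 for the root
    types: np.ndarray          # (N,) int SWC compartment codes; soma = 1
    depth_norm: np.ndarray | None = None   # (N,) in [0, 1]
    ventral_axis_deg: float = 0.0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {int(i): k for k, i in enumerate(self.node_ids)}
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, got "
                             f"{roots.size}")
        self._root = int(roots[0])
        for k, p in enumerate(self.parent):
            if p != -1 and int(p) not in self._index:
                raise ValueError(f"node {self.node_ids[k]} has unknown "
                                 f"parent {p}")
        if not self._connected():
            raise ValueError("skeleton is not a connected tree")
        if self.depth_norm is not None and (
                np.any(self.depth_norm < -1e-9)
                or np.any(self.depth_norm > 1 + 1e-9)):
            raise ValueError("depth_norm must lie in [0, 1]")

    def _connected(self) -> bool:
        # walking parent links from every node must reach the root
        # without revisiting (also rules out cycles)
        for k in range(len(self.node_ids)):
            seen = set()
            while k != self._root:
                if k in seen:
                    return False
                seen.add(k)
                k = self._index[int(self.parent[k])]
        return True

    # ------------------------------------------------------------- access
    @property
    def soma_index(self) -> int:
        return self._root

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self._root]

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) array of (child, parent) positional indices."""
        child = np.flatnonzero(self.parent != -1)
        par = np.array([self._index[int(p)] for p in self.parent[child]])
        return np.column_stack([child, par])

    def edge_lengths(self, projected: bool = False) -> np.ndarray:
        e = self.edges
        a, b = self.xyz[e[:, 0]], self.xyz[e[:, 1]]
        if projected:
            a, b = a[:, :2], b[:, :2]
        return np.linalg.norm(a - b, axis=1)

    @property
    def n_children(self) -> np.ndarray:
        counts = np.zeros(len(self.node_ids), dtype=int)
        for _, p in self.edges:
            counts[p] += 1
        return counts

    # ----------------------------------------------------------------- io
    @classmethod
    def from_swc(cls, path: str | Path, depth_range: tuple[float, float]
                 | None = None, ventral_axis_deg: float = 0.0) -> "Skeleton":
        """Read a standard 7-column SWC file.

        ``depth_range`` maps the z coordinate linearly onto normalized
        IPL depth (z at the INL border → 0, z at the GCL border → 1);
        by default the skeleton's own z extent is used.
        """
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append([float(x) for x in parts[:7]])
        arr = np.asarray(rows)
        if arr.shape[1] != 7:
            raise ValueError("SWC rows must have 7 columns")
        z = arr[:, 4]
        if depth_range is None:
            span = z.max() - z.min()
            depth = (z - z.min()) / span if span > 0 \
                else np.full_like(z, 0.5)
        else:
            z0, z1 = depth_range
            depth = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
        return cls(node_ids=arr[:, 0].astype(int),
                   types=arr[:, 1].astype(int),
                   xyz=arr[:, 2:5].copy(), radius=arr[:, 5].copy(),
                   parent=arr[:, 6].astype(int),
                   depth_norm=depth, ventral_axis_deg=ventral_axis_deg)

    def to_swc(self, path: str | Path) -> None:
        lines = ["# id type x y z radius parent"]
        for i in range(len(self.node_ids)):
            x, y, z = self.xyz[i]
            lines.append(f"{self.node_ids[i]} {self.types[i]} "
                         f"{x:.4f} {y:.4f} {z:.4f} "
                         f"{self.radius[i]:.4f} {self.parent[i]}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DendriteSubset:
    """Edges of a skeleton restricted to one stratification band."""

    points_xy: np.ndarray      # (M, 2) endpoints of kept edges, projected
    edge_index: np.ndarray     # indices into Skeleton.edges
    total_length_um: float     # summed 3D edge length


@dataclass
class MorphMetrics:
    total_length_um: float
    n_tips: int
    n_branch_points: int
    hull_area_um2: float
    hull_area_on_um2: float | None
    hull_area_off_um2: float | None
    com_distance_um: float
    asymmetry_angle_deg: float
    ai: float
    on_off_index: float | None
    sholl: list[tuple[float, int]]


def _edge_subsets(skel: Skeleton, on_band=(0.55, 0.80),
                  off_band=(0.20, 0.45)):
    if max(on_band[0], off_band[0]) < min(on_band[1], off_band[1]):
        raise ValueError("ON and OFF depth bands overlap")
    if skel.depth_norm is None:
        raise ValueError("skeleton has no depth information")
    e = skel.edges
    mid = 0.5 * (skel.depth_norm[e[:, 0]] + skel.depth_norm[e[:, 1]])

    def dist(band):
        lo, hi = band
        return np.where(mid < lo, lo - mid, np.where(mid > hi, mid - hi, 0.0))

    return e, dist(on_band) <= dist(off_band)


def split_on_off(skel: Skeleton, on_band=(0.55, 0.80),
                 off_band=(0.20, 0.45)):
    """Assign edges to the ON or OFF stratum by midpoint depth (edges
    outside both bands go to the nearer band) and return the two
    subsets plus the ON–OFF index (L_ON − L_OFF)/(L_ON + L_OFF)."""
    e, is_on = _edge_subsets(skel, on_band, off_band)
    lengths = skel.edge_lengths()

    def subset(mask):
        idx = np.flatnonzero(mask)
        pts = skel.xyz[e[idx].ravel(), :2] if idx.size else \
            np.empty((0, 2))
        return DendriteSubset(points_xy=pts, edge_index=idx,
                              total_length_um=float(lengths[idx].sum()))

    on, off = subset(is_on), subset(~is_on)
    total = on.total_length_um + off.total_length_um
    index = ((on.total_length_um - off.total_length_um) / total
             if total > 0 else 0.0)
    return on, off, float(index)


def sholl_profile(skel: Skeleton, spacing_um: float = 5.0
                  ) -> list[tuple[float, int]]:
    """Sholl intersections on the x–y projection.

    Rings are centered on the soma at multiples of ``spacing_um``; an
    edge crosses the ring of radius r when its endpoint distances
    satisfy d_near < r ≤ d_far (crossings counted per edge segment).
    Radii run from one spacing to just beyond the farthest node.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    soma = skel.soma_xyz[:2]
    d = np.linalg.norm(skel.xyz[:, :2] - soma, axis=1)
    e = skel.edges
    d_near = np.minimum(d[e[:, 0]], d[e[:, 1]])
    d_far = np.maximum(d[e[:, 0]], d[e[:, 1]])
    r_max = d.max()
    n_rings = int(np.floor(r_max / spacing_um)) + 1
    profile = []
    for k in range(1, n_rings + 1):
        r = k * spacing_um
        profile.append((r, int(np.sum((d_near < r) & (r <= d_far)))))
    return profile


def _subset_geometry(skel: Skeleton, subset: str):
    if subset == "total":
        e = skel.edges
        idx = np.arange(e.shape[0])
    else:
        e, is_on = _edge_subsets(skel)
        idx = np.flatnonzero(is_on if subset == "ON" else ~is_on)
    if idx.size == 0:
        raise ValueError(f"{subset} subset is empty")
    points = skel.xyz[np.unique(e[idx].ravel()), :2]
    a = skel.xyz[e[idx, 0], :2]
    b = skel.xyz[e[idx, 1], :2]
    w = np.linalg.norm(a - b, axis=1)          # projected edge lengths
    mid = 0.5 * (a + b)
    return points, mid, w


def hull_and_com(skel: Skeleton, subset: str = "total"):
    """Convex-hull area (µm²), dendrite–soma center-of-mass distance
    (µm) and its angular deviation from the ventral axis (degrees, in
    [0, 180]) for the total, ON, or OFF skeleton projection.

    The dendritic center of mass is the projected-edge-length-weighted
    mean of projected edge midpoints, so resampling node density does
    not move it.
    """
    points, mid, w = _subset_geometry(skel, subset)
    try:
        hull = ConvexHull(points)
    except Exception as exc:   # qhull raises on degenerate input
        raise InvalidGeometryError(f"degenerate hull: {exc}") from exc
    area = float(hull.volume)   # 2D ConvexHull: volume is the area
    if w.sum() <= 0:
        raise ValueError("zero total projected length")
    com = np.average(mid, axis=0, weights=w)
    soma = skel.soma_xyz[:2]
    vec = com - soma
    dist = float(np.linalg.norm(vec))
    bearing = np.rad2deg(np.arctan2(vec[1], vec[0])) % 360.0
    deviation = abs((bearing - skel.ventral_axis_deg + 180.0) % 360.0 - 180.0)
    return area, dist, float(deviation)


def asymmetry_index(skel: Skeleton, subset: str = "total",
                    symmetric_tol_um: float = 1e-9):
    """Asymmetry index from the soma→center-of-mass line's hull chord.

    Returns (ai, symmetric_flag); when the center of mass coincides
    with the soma the line direction is undefined and ai = 0 by the
    symmetric-limit convention.
    """
    points, mid, w = _subset_geometry(skel, subset)
    hull = ConvexHull(points)
    verts = points[hull.vertices]              # counter-clockwise
    soma = skel.soma_xyz[:2]
    com = np.average(mid, axis=0, weights=w)
    vec = com - soma
    if np.linalg.norm(vec) <= symmetric_tol_um:
        return 0.0, True
    u = vec / np.linalg.norm(vec)

    # intersect the parametric line soma + t*u with every hull edge
    ts = []
    n = verts.shape[0]
    for i in range(n):
        p, q = verts[i], verts[(i + 1) % n]
        d = q - p
        denom = u[0] * (-d[1]) - u[1] * (-d[0])
        if abs(denom) < 1e-15:
            continue
        rhs = p - soma
        t = (rhs[0] * (-d[1]) - rhs[1] * (-d[0])) / denom
        s = (u[0] * rhs[1] - u[1] * rhs[0]) / denom
        if -1e-9 <= s <= 1 + 1e-9:
            ts.append(t)
    if not ts:
        raise InvalidGeometryError("line does not intersect hull")
    t_pos = max(ts)
    t_neg = min(ts)
    if t_pos < -1e-9 or t_neg > 1e-9:
        raise InvalidGeometryError("soma lies outside the convex hull")
    sp2 = max(t_pos, 0.0)      # soma -> hull border along +u (toward COM)
    p1s = max(-t_neg, 0.0)     # hull border -> soma along -u
    ai = abs(p1s - sp2) / (p1s + sp2)
    return float(ai), False


def summary_metrics(skel: Skeleton, on_band=(0.55, 0.80),
                    off_band=(0.20, 0.45),
                    sholl_spacing_um: float = 5.0) -> MorphMetrics:
    """Aggregate all morphometrics into one record."""
    lengths = skel.edge_lengths()
    children = skel.n_children
    soma = skel.soma_index
    tips = int(np.sum((children == 0)
                      & (np.arange(children.size) != soma)))
    branch = int(np.sum((children >= 2)
                        & (np.arange(children.size) != soma)))
    try:
        area, com_dist, angle = hull_and_com(skel, "total")
        ai, _ = asymmetry_index(skel)
    except InvalidGeometryError:
        # e.g. a collinear arbor: counts and Sholl remain meaningful
        area = com_dist = angle = ai = float("nan")
    on_off = None
    area_on = area_off = None
    if skel.depth_norm is not None and np.ptp(skel.depth_norm) > 0:
        _, _, on_off = split_on_off(skel, on_band, off_band)
        for name in ("ON", "OFF"):
            try:
                a, _, _ = hull_and_com(skel, name)
            except (ValueError, InvalidGeometryError):
                a = None
            if name == "ON":
                area_on = a
            else:
                area_off = a
    return MorphMetrics(
        total_length_um=float(lengths.sum()), n_tips=tips,
        n_branch_points=branch, hull_area_um2=area,
        hull_area_on_um2=area_on, hull_area_off_um2=area_off,
        com_distance_um=com_dist, asymmetry_angle_deg=angle, ai=ai,
        on_off_index=on_off,
        sholl=sholl_profile(skel, sholl_spacing_um),
    )
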