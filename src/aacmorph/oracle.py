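"""Brute-force cross-checks for the polygon-based marker pipeline.

Every quantity here is recomputed from first principles with a completely
different toolchain from the main implementation — matplotlib path
point-in-polygon tests on fine regular grids, Euclidean distance
transforms, k-d-tree nearest-neighbour projection, and exact
segment/polygon crossing arithmetic — so that agreement between the two
routes is meaningful evidence of correctness rather than shared code.

Polygons are passed as plain (N, 2) vertex arrays ("rings", closed or
open).  These functions are slow by design and intended for validation,
not analysis.
"""

from __future__ import annotations

import math

import numpy as np
from matplotlib.path import Path
from scipy import ndimage
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# Raster primitives
# ---------------------------------------------------------------------------

def raster_mask(polys: list[np.ndarray], frame: tuple, resolution: float) -> np.ndarray:
    """Union mask of closed polygons given as (N, 2) vertex arrays.

    A cell is set iff its centre is inside at least one polygon
    (matplotlib even-odd test).  ``frame`` is (minx, miny, maxx, maxy).
    """
    minx, miny, maxx, maxy = frame
    nx = max(1, int(math.ceil((maxx - minx) / resolution)))
    ny = max(1, int(math.ceil((maxy - miny) / resolution)))
    xs = minx + (np.arange(nx) + 0.5) * resolution
    ys = miny + (np.arange(ny) + 0.5) * resolution
    grid = np.zeros((ny, nx), dtype=bool)
    for verts in polys:
        verts = np.asarray(verts, dtype=float)
        path = Path(verts, closed=False)
        j0 = max(0, int((verts[:, 0].min() - minx) / resolution) - 1)
        j1 = min(nx, int(math.ceil((verts[:, 0].max() - minx) / resolution)) + 1)
        i0 = max(0, int((verts[:, 1].min() - miny) / resolution) - 1)
        i1 = min(ny, int(math.ceil((verts[:, 1].max() - miny) / resolution)) + 1)
        if j1 <= j0 or i1 <= i0:
            continue
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = path.contains_points(pts).reshape(gy.shape)
        grid[i0:i1, j0:j1] |= inside
    return grid


def mask_area(grid: np.ndarray, resolution: float) -> float:
    return float(grid.sum()) * resolution ** 2


def dilate_mask_edt(grid: np.ndarray, resolution: float, radius: float) -> np.ndarray:
    """Dilation with a disc of given radius via the distance transform."""
    if radius <= 0 or not grid.any():
        return grid.copy()
    dist = ndimage.distance_transform_edt(~grid, sampling=resolution)
    return dist <= radius


def count_components(grid: np.ndarray) -> int:
    """8-connectivity component count of a binary mask."""
    _, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=bool))
    return int(n)


def label_components(grid: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(grid, structure=np.ones((3, 3), dtype=bool))
    return labels


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _resample_polyline(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~``step`` spacing; returns points and their
    cumulative arclengths."""
    pts = np.asarray(pts, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0.0, total, max(2, int(math.ceil(total / step)) + 1))
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y]), s


def _ring_sample_points(ring: np.ndarray, step: float) -> np.ndarray:
    """Boundary (resampled at ``step``) plus interior grid points of one
    closed polygon ring."""
    ring = np.asarray(ring, dtype=float)
    closed = np.vstack([ring, ring[:1]])
    boundary, _ = _resample_polyline(closed, step)
    # keep the exact vertices: projection extremes live at sharp corners
    boundary = np.vstack([boundary, ring])
    minx, miny = ring.min(axis=0)
    maxx, maxy = ring.max(axis=0)
    xs = np.arange(minx, maxx + step, step)
    ys = np.arange(miny, maxy + step, step)
    pts = [boundary]
    if len(xs) and len(ys):
        gx, gy = np.meshgrid(xs, ys)
        grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = Path(ring, closed=False).contains_points(grid_pts)
        if inside.any():
            pts.append(grid_pts[inside])
    return np.vstack(pts)


def _locate_on_polyline(rp: np.ndarray, s: np.ndarray, tree: cKDTree,
                        qpts: np.ndarray, k: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Arclength of (and distance to) the nearest point of a resampled
    polyline: exact projection onto the segments adjacent to each of the
    ``k`` nearest resampled vertices (flat distance basins can span
    several vertices, so refining around only the single nearest one can
    miss the true argmin by a fraction of a millimetre)."""
    k = min(k, len(rp))
    d0, idx_k = tree.query(qpts, k=k)
    if k == 1:
        d0, idx_k = d0[:, None], idx_k[:, None]
    best_s = s[idx_k[:, 0]].astype(float).copy()
    best_d = d0[:, 0].astype(float).copy()
    for j in range(k):
        idx = idx_k[:, j]
        for off in (-1, 0):
            i0 = idx + off
            valid = (i0 >= 0) & (i0 + 1 < len(rp))
            a = rp[np.clip(i0, 0, len(rp) - 2)]
            b = rp[np.clip(i0 + 1, 1, len(rp) - 1)]
            ab = b - a
            denom = np.einsum("ij,ij->i", ab, ab)
            t = np.einsum("ij,ij->i", qpts - a, ab) / np.where(denom > 0, denom, 1.0)
            t = np.clip(t, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(qpts - proj, axis=1)
            better = valid & (d < best_d)
            seg_len = s[np.clip(i0 + 1, 1, len(rp) - 1)] - s[np.clip(i0, 0, len(rp) - 2)]
            cand_s = s[np.clip(i0, 0, len(rp) - 2)] + t * seg_len
            best_s[better] = cand_s[better]
            best_d[better] = d[better]
    return best_s, best_d


def _run_intervals(arclengths: np.ndarray, gap: float) -> list[tuple[float, float]]:
    """Intervals formed by sorted arclength samples, bridging gaps up to
    ``gap``."""
    if len(arclengths) == 0:
        return []
    v = np.sort(arclengths)
    breaks = np.nonzero(np.diff(v) > gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(v) - 1]])
    return [(float(v[a]), float(v[b])) for a, b in zip(starts, ends)]


def _union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total = 0.0
    lo, hi = intervals[0]
    for a, b in intervals[1:]:
        if a <= hi:
            hi = max(hi, b)
        else:
            total += hi - lo
            lo, hi = a, b
    return total + (hi - lo)


# ---------------------------------------------------------------------------
# Projection oracles
# ---------------------------------------------------------------------------

def wall_coverage_lengths(dep_rings: list[np.ndarray],
                          ant_pts: np.ndarray, post_pts: np.ndarray,
                          resolution: float = 0.05) -> dict[str, float]:
    """Covered arclength per wall by nearest-point projection.

    Each deposit is sampled densely (boundary plus interior grid at the
    raster resolution); every sample is projected to the nearest point of
    its nearer wall (k-d tree on walls resampled at the same resolution,
    refined to exact segment projection).  A deposit's footprint per wall
    is the min-to-max span of its projected samples; the per-wall coverage
    is the union of all deposits' spans, clipped to [0, wall length].
    """
    walls = {}
    for name, pts in (("anterior", ant_pts), ("posterior", post_pts)):
        rp, s = _resample_polyline(pts, resolution)
        walls[name] = (rp, s, cKDTree(rp))
    intervals = {"anterior": [], "posterior": []}
    for ring in dep_rings:
        qpts = _ring_sample_points(ring, resolution)
        s_a, d_a = _locate_on_polyline(*walls["anterior"], qpts)
        s_p, d_p = _locate_on_polyline(*walls["posterior"], qpts)
        # same 15% dominance margin as the marker definition: near-tie
        # samples are internal and not projected
        clear = np.abs(d_a - d_p) >= 0.15 * np.minimum(d_a, d_p)
        for name, arcl, mine in (("anterior", s_a, clear & (d_a <= d_p)),
                                 ("posterior", s_p, clear & (d_a > d_p))):
            if mine.any():
                intervals[name].append((float(arcl[mine].min()),
                                        float(arcl[mine].max())))
    out = {}
    for name, ivs in intervals.items():
        total = walls[name][1][-1]
        clipped = [(max(a, 0.0), min(b, total)) for a, b in ivs if b > 0 and a < total]
        out[name] = _union_length(clipped)
    return out


def midline_coverage_length(dep_rings: list[np.ndarray], midline_pts: np.ndarray,
                            region_ring: np.ndarray,
                            resolution: float = 0.05) -> float:
    """Longitudinal extent covered by deposits.

    Each deposit's in-region samples are projected onto the midline; the
    deposit contributes its min-to-max projected arclength span, and the
    spans are unioned.
    """
    rp, s = _resample_polyline(midline_pts, resolution)
    tree = cKDTree(rp)
    region_path = Path(np.asarray(region_ring, dtype=float), closed=False)
    intervals = []
    for ring in dep_rings:
        qpts = _ring_sample_points(ring, resolution)
        qpts = qpts[region_path.contains_points(qpts)]
        if len(qpts) == 0:
            continue
        arcl, _ = _locate_on_polyline(rp, s, tree, qpts)
        intervals.append((float(arcl.min()), float(arcl.max())))
    return _union_length(intervals)


# ---------------------------------------------------------------------------
# Thickness oracle (exact segment clipping)
# ---------------------------------------------------------------------------

def _segment_ring_intervals(p: np.ndarray, q: np.ndarray,
                            ring: np.ndarray) -> list[tuple[float, float]]:
    """Chord-parameter intervals (t in [0, 1] along p->q) lying inside a
    closed polygon ring, by exact edge-crossing arithmetic."""
    ring = np.asarray(ring, dtype=float)
    a = ring
    b = np.roll(ring, -1, axis=0)
    d = q - p
    e = b - a
    w = p - a
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (e[:, 0] * w[:, 1] - e[:, 1] * w[:, 0]) / denom
        u = (d[0] * w[:, 1] - d[1] * w[:, 0]) / denom
    ok = (np.abs(denom) > 1e-14) & (t > 0.0) & (t < 1.0) & (u >= 0.0) & (u < 1.0)
    ts = np.sort(np.concatenate([[0.0], t[ok], [1.0]]))
    path = Path(ring, closed=False)
    mids = p[None, :] + ((ts[:-1] + ts[1:]) / 2.0)[:, None] * d[None, :]
    inside = path.contains_points(mids)
    return [(float(ts[k]), float(ts[k + 1])) for k in range(len(ts) - 1) if inside[k]]


def thickness_ratio(dep_rings: list[np.ndarray],
                    ant_pts: np.ndarray, post_pts: np.ndarray,
                    region_ring: np.ndarray,
                    station_step: float = 0.5,
                    resolution: float = 0.05) -> float:
    """Mean calcified-chord-fraction over stations on both walls.

    Stations are evenly spaced in arclength; each chord runs to the
    nearest point of the opposite wall (k-d tree at half the raster
    resolution).  The calcified fraction of a chord is computed by exact
    clipping of the segment against the deposit polygons (union of
    crossing intervals), restricted to the in-region part of the chord.
    """
    resampled = {}
    for name, pts in (("anterior", ant_pts), ("posterior", post_pts)):
        rp, _ = _resample_polyline(pts, resolution / 2)
        resampled[name] = (rp, cKDTree(rp))

    dep_rings = [np.asarray(r, dtype=float) for r in dep_rings]
    bboxes = [(r[:, 0].min(), r[:, 1].min(), r[:, 0].max(), r[:, 1].max())
              for r in dep_rings]

    def stations_of(pts):
        # same station rule as the marker: interval midpoints in arclength
        pts = np.asarray(pts, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(1, int(round(cum[-1] / station_step)))
        s = (np.arange(n) + 0.5) * (cum[-1] / n)
        return np.column_stack([np.interp(s, cum, pts[:, 0]),
                                np.interp(s, cum, pts[:, 1])])

    ratios = []
    for name, opp in (("anterior", "posterior"), ("posterior", "anterior")):
        stations = stations_of({"anterior": ant_pts, "posterior": post_pts}[name])
        opp_pts, opp_tree = resampled[opp]
        _, idx = opp_tree.query(stations)
        for p, q in zip(stations, opp_pts[idx]):
            width = float(np.hypot(*(q - p)))
            if width <= 1e-9:
                continue
            lo = np.minimum(p, q)
            hi = np.maximum(p, q)
            ivs = []
            for ring, (bx0, by0, bx1, by1) in zip(dep_rings, bboxes):
                if bx1 < lo[0] or bx0 > hi[0] or by1 < lo[1] or by0 > hi[1]:
                    continue
                ivs.extend(_segment_ring_intervals(p, q, ring))
            if not ivs:
                ratios.append(0.0)
                continue
            reg_ivs = _segment_ring_intervals(p, q, np.asarray(region_ring, dtype=float))
            covered = _union_length(_intersect_interval_sets(ivs, reg_ivs))
            ratios.append(covered)
    return float(np.mean(ratios)) if ratios else 0.0


def _intersect_interval_sets(a: list[tuple[float, float]],
                             b: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Intersection of two interval unions."""
    out = []
    # merge union-of-a first to avoid double counting overlapping deposits
    merged_a = []
    for lo, hi in sorted(a):
        if merged_a and lo <= merged_a[-1][1]:
            merged_a[-1] = (merged_a[-1][0], max(merged_a[-1][1], hi))
        else:
            merged_a.append((lo, hi))
    for lo1, hi1 in merged_a:
        for lo2, hi2 in sorted(b):
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return out
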