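"""Geometric substrate for the calcification markers.

Builds the lumbar aortic region between the two annotated wall polylines,
parametrizes walls by arclength, projects deposits onto the nearer wall,
rasterizes polygon sets into binary masks, performs morphological dilation
(Minkowski sum with a disc, emulating the peri-calcific inflamed plaque),
and merges deposit outlines into connected components.

All lengths are millimetres.  Region construction assumes the annotation is
in the canonical frame (vertebral axis vertical, see :func:`canonicalize`);
:func:`aacmorph.markers.compute_panel` canonicalizes automatically, which
also makes every marker invariant under rigid motions of the annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .annotation import AnnotationSet, DepositOutline, VertebraLandmarks, WallPolyline

#: study structuring-element radius: 200 px x 0.0446 mm/px
DEFAULT_SE_RADIUS_MM = 8.92
#: default raster cell size, close to the native 0.0446 mm pixel pitch
DEFAULT_RASTER_RES_MM = 0.05

_MAX_RASTER_CELLS = 10**8
_BUFFER_QUAD_SEGS = 64


class RegionError(ValueError):
    """The aortic region cannot be built from the given walls/landmarks."""


@dataclass(frozen=True)
class StructuringElement:
    """Disc structuring element for plaque simulation, radius in mm."""

    radius_mm: float = DEFAULT_SE_RADIUS_MM

    def __post_init__(self):
        if self.radius_mm < 0:
            raise ValueError(f"structuring element radius must be >= 0, got {self.radius_mm}")


@dataclass(frozen=True)
class WallParam:
    """Arclength parametrization of one wall polyline."""

    side: str
    points: np.ndarray              # (N, 2)
    cumlen: np.ndarray              # (N,) cumulative arclength, starts at 0
    line: LineString = field(repr=False, default=None)

    @property
    def length(self) -> float:
        return float(self.cumlen[-1])


def param_wall(w: WallPolyline | np.ndarray, side: str = "") -> WallParam:
    """Cumulative Euclidean arclength parametrization of a polyline."""
    if isinstance(w, WallPolyline):
        pts, side = w.points, w.side
    else:
        pts = np.asarray(w, dtype=float)
    if len(pts) < 2:
        raise ValueError("wall polyline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError(f"wall[{side}]: degenerate (zero-length) segment")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return WallParam(side=side, points=pts, cumlen=cum, line=LineString(pts))


# ---------------------------------------------------------------------------
# Canonical frame
# ---------------------------------------------------------------------------

def canonical_rotation(vertebrae: dict[str, VertebraLandmarks]) -> np.ndarray:
    """Rotation matrix mapping the L1-superior -> L4-inferior vertebral axis
    onto the +y direction."""
    top = vertebrae["L1"].corners[[0, 1]].mean(axis=0)
    bot = vertebrae["L4"].corners[[2, 3]].mean(axis=0)
    axis = bot - top
    theta = math.atan2(axis[0], axis[1])  # angle away from +y
    c, s = math.cos(theta), math.sin(theta)
    # rotate by -theta about the origin so that axis -> +y
    return np.array([[c, -s], [s, c]])


def canonicalize(a: AnnotationSet) -> AnnotationSet:
    """Rotate an annotation so the vertebral column axis points caudally
    (+y).  Translation is irrelevant to every marker and is not removed."""
    rot = canonical_rotation(a.vertebrae)
    return a.transformed(lambda pts: pts @ rot.T)


# ---------------------------------------------------------------------------
# Aortic region
# ---------------------------------------------------------------------------

def _clip_polyline_y(pts: np.ndarray, ylo: float, yhi: float) -> np.ndarray:
    """Clip a y-monotone polyline to the band ylo <= y <= yhi."""
    y = pts[:, 1]
    if np.any(np.diff(y) < 0):
        raise RegionError("wall polyline is not y-monotone in the canonical frame")
    if y[0] > ylo + 1e-9 or y[-1] < yhi - 1e-9:
        raise RegionError(
            f"wall vertical extent [{y[0]:.3f}, {y[-1]:.3f}] does not cover the "
            f"vertebral range [{ylo:.3f}, {yhi:.3f}]")

    def interp_at(level: float) -> np.ndarray:
        i = int(np.searchsorted(y, level, side="left"))
        i = min(max(i, 1), len(y) - 1)
        y0, y1 = y[i - 1], y[i]
        t = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
        return pts[i - 1] + t * (pts[i] - pts[i - 1])

    inside = (y > ylo + 1e-12) & (y < yhi - 1e-12)
    middle = pts[inside]
    out = [interp_at(ylo)]
    for p in middle:
        out.append(p)
    out.append(interp_at(yhi))
    arr = np.asarray(out)
    # drop duplicates created when a vertex coincides with a cut level
    keep = np.concatenate([[True], np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-12])
    return arr[keep]


def _arclength_at_level(wall: WallParam, level: float) -> float:
    """Arclength along a y-monotone clipped wall at a given y level."""
    y = wall.points[:, 1]
    i = int(np.searchsorted(y, level, side="left"))
    i = min(max(i, 1), len(y) - 1)
    y0, y1 = y[i - 1], y[i]
    t = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    p = wall.points[i - 1] + t * (wall.points[i] - wall.points[i - 1])
    return float(wall.cumlen[i - 1] + np.linalg.norm(p - wall.points[i - 1]))


@dataclass
class AortaRegion:
    """Lumbar aortic region between the walls, L1 superior to L4 inferior.

    ``sections[k][side]`` is the (lo, hi) arclength interval on the clipped
    ``side`` wall adjacent to vertebra L{k+1}; the four intervals partition
    [0, wall length].
    """

    boundary: Polygon
    walls: dict[str, WallParam]             # clipped, re-parametrized from 0
    sections: list[dict[str, tuple[float, float]]]
    cut_levels: np.ndarray                  # (5,) y levels, cranial -> caudal
    midline: LineString

    @property
    def area(self) -> float:
        return float(self.boundary.area)

    @property
    def cranial_cut(self) -> LineString:
        return LineString([self.walls["anterior"].points[0],
                           self.walls["posterior"].points[0]])

    @property
    def caudal_cut(self) -> LineString:
        return LineString([self.walls["anterior"].points[-1],
                           self.walls["posterior"].points[-1]])


def build_aorta_region(walls: dict[str, WallPolyline],
                       vertebrae: dict[str, VertebraLandmarks],
                       midline_samples: int = 201) -> AortaRegion:
    """Construct the scored aortic region and its per-vertebra wall sections.

    The cranial and caudal cuts run at the L1 superior and L4 inferior
    endplate levels; each wall is cut into four sections at the mid-levels
    between consecutive vertebrae's facing endplates.
    """
    labs = ("L1", "L2", "L3", "L4")
    sup = [vertebrae[l].superior_level() for l in labs]
    inf = [vertebrae[l].inferior_level() for l in labs]
    levels = np.array([
        sup[0],
        0.5 * (inf[0] + sup[1]),
        0.5 * (inf[1] + sup[2]),
        0.5 * (inf[2] + sup[3]),
        inf[3],
    ])
    if np.any(np.diff(levels) <= 0):
        raise RegionError(f"vertebral cut levels are not increasing: {levels}")

    clipped: dict[str, WallParam] = {}
    for side in ("anterior", "posterior"):
        pts = _clip_polyline_y(walls[side].points, levels[0], levels[-1])
        clipped[side] = param_wall(pts, side)

    ant, post = clipped["anterior"], clipped["posterior"]
    if ant.line.crosses(post.line):
        raise RegionError("anterior and posterior walls cross inside the region")

    ring = np.vstack([ant.points, post.points[::-1]])
    boundary = Polygon(ring)
    if not boundary.is_valid or boundary.area <= 0:
        raise RegionError("region boundary polygon is invalid or degenerate")

    sections = []
    for k in range(4):
        entry = {}
        for side, wp in clipped.items():
            lo = _arclength_at_level(wp, levels[k])
            hi = _arclength_at_level(wp, levels[k + 1])
            entry[side] = (lo, hi)
        sections.append(entry)

    t = np.linspace(0.0, 1.0, midline_samples)
    mid = np.array([
        0.5 * (np.asarray(ant.line.interpolate(ti * ant.length).coords[0])
               + np.asarray(post.line.interpolate(ti * post.length).coords[0]))
        for ti in t
    ])
    # smooth the longitudinal axis: the raw midpoint chain inherits the
    # walls' annotation jitter, whose kinks make nearest-point projection
    # onto the axis ill-conditioned (sub-mm skipped arcs); a moving
    # average over a few mm removes the jitter while preserving the
    # vessel's global curvature.  Endpoints stay fixed.
    if len(mid) > 9:
        kernel = np.ones(9) / 9.0
        padded = np.vstack([2 * mid[0] - mid[8:0:-1], mid, 2 * mid[-1] - mid[-2:-10:-1]])
        sm = np.column_stack([np.convolve(padded[:, 0], kernel, mode="same"),
                              np.convolve(padded[:, 1], kernel, mode="same")])
        mid = sm[8:-8]
        mid[0], mid[-1] = padded[8], padded[-9]
    midline = LineString(mid)

    return AortaRegion(boundary=boundary, walls=clipped, sections=sections,
                       cut_levels=levels, midline=midline)


# ---------------------------------------------------------------------------
# Deposit sampling and projection
# ---------------------------------------------------------------------------

def _sample_polygon(poly: Polygon, step: float, interior_step: float) -> np.ndarray:
    """Dense boundary samples (original vertices preserved) plus a sparse
    interior grid of a polygon."""
    ext = shapely.segmentize(poly.exterior, step)
    pts = [np.asarray(ext.coords)]
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx + interior_step, interior_step)
    ys = np.arange(miny, maxy + interior_step, interior_step)
    if len(xs) and len(ys):
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        if inside.any():
            pts.append(np.column_stack([gx.ravel()[inside], gy.ravel()[inside]]))
    return np.vstack(pts)


def _merge_intervals(vals: np.ndarray, gap: float) -> list[tuple[float, float]]:
    """Merge sorted scalar samples into intervals, bridging gaps <= ``gap``."""
    if len(vals) == 0:
        return []
    v = np.sort(vals)
    out = []
    lo = hi = v[0]
    for x in v[1:]:
        if x - hi <= gap:
            hi = x
        else:
            out.append((float(lo), float(hi)))
            lo = hi = x
    out.append((float(lo), float(hi)))
    return out


def _prune_clip(intervals, L: float, eps: float = 1e-9):
    out = []
    for lo, hi in intervals:
        lo, hi = max(lo, 0.0), min(hi, L)
        if hi - lo > eps:
            out.append((lo, hi))
    return out


def union_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of possibly overlapping closed intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1] + 1e-12:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(float(a), float(b)) for a, b in out]


def intervals_length(intervals) -> float:
    return float(sum(hi - lo for lo, hi in union_intervals(list(intervals))))


def project_deposit_to_wall(d: DepositOutline | Polygon, wall: WallParam,
                            sample_step: float = 0.2,
                            gap: float = 0.8) -> list[tuple[float, float]]:
    """Arclength intervals on a wall covered by the nearest-point projection
    of a deposit's footprint (boundary plus interior samples).

    Intervals are merged (sample gaps below ``gap`` mm are bridged), clipped
    to [0, wall length] and pruned of zero-length degenerates.
    """
    poly = d.polygon if isinstance(d, DepositOutline) else d
    pts = _sample_polygon(poly, sample_step, 5 * sample_step)
    s = shapely.line_locate_point(wall.line, shapely.points(pts))
    return _prune_clip(_merge_intervals(np.asarray(s, dtype=float), gap), wall.length)


#: a sample belongs to a wall only if it is at least this much (relative)
#: nearer to it than to the other wall; closer-to-tie samples count as
#: internal (mid-lumen) and are not projected
WALL_TIE_MARGIN = 0.15


def project_deposits_to_walls(deposits: list[Polygon], region: AortaRegion,
                              sample_step: float = 0.2) -> dict[str, list[tuple[float, float]]]:
    """Project each deposit onto its nearer wall (point-wise split for
    mid-lumen lesions) and return merged coverage intervals per wall.

    A deposit's footprint on a wall is the interval *hull* of its
    projected samples — the wall stretch shadowed by the lesion.  The hull
    is preferred over the raw projection image because the nearest-point
    map onto a polyline skips sub-millimetre arcs around concave kinks,
    which makes the raw image's gap structure numerically unstable; the
    hull endpoints, in contrast, are well conditioned.  Samples essentially
    equidistant from both walls (within ``WALL_TIE_MARGIN``) are treated as
    internal and not projected: exactly at a tie the projected arclength is
    discontinuous, so tie-zone samples would make the footprint endpoints
    depend on sampling noise.  Intervals are unioned across deposits and
    clipped to the in-region wall arclength.
    """
    ant, post = region.walls["anterior"], region.walls["posterior"]
    cover = {"anterior": [], "posterior": []}
    for poly in deposits:
        if poly.is_empty:
            continue
        # fine boundary step: the hull endpoints come from extreme
        # boundary points, so the sampling error enters directly; the
        # interior is sampled as densely as the nominal step because the
        # strip of a mid-lumen deposit nearer the far wall can be thin
        pts = _sample_polygon(poly, sample_step / 4, sample_step)
        geoms = shapely.points(pts)
        d_ant = shapely.distance(geoms, ant.line)
        d_post = shapely.distance(geoms, post.line)
        clear = np.abs(d_ant - d_post) >= WALL_TIE_MARGIN * np.minimum(d_ant, d_post)
        for side, wp, mask in (("anterior", ant, clear & (d_ant <= d_post)),
                               ("posterior", post, clear & (d_ant > d_post))):
            if not mask.any():
                continue
            s = np.asarray(shapely.line_locate_point(wp.line, geoms[mask]),
                           dtype=float)
            cover[side].append((float(s.min()), float(s.max())))
    return {side: union_intervals(_prune_clip(ivs, region.walls[side].length))
            for side, ivs in cover.items()}


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass
class BinaryMask:
    """Axis-aligned binary raster; cell (i, j) is centred at
    (x0 + (j+0.5)*res, y0 + (i+0.5)*res)."""

    origin: tuple[float, float]
    resolution: float
    grid: np.ndarray            # (ny, nx) bool

    @property
    def count(self) -> int:
        return int(self.grid.sum())

    @property
    def area(self) -> float:
        return self.count * self.resolution ** 2

    def same_frame(self, other: "BinaryMask", tol: float = 1e-9) -> bool:
        return (self.grid.shape == other.grid.shape
                and abs(self.resolution - other.resolution) <= tol
                and abs(self.origin[0] - other.origin[0]) <= tol
                and abs(self.origin[1] - other.origin[1]) <= tol)


def rasterize(polys: list[Polygon], frame: tuple[float, float, float, float],
              resolution: float = DEFAULT_RASTER_RES_MM) -> BinaryMask:
    """Rasterize a union of polygons: a cell is set iff its centre lies
    inside the union.  ``frame`` is (minx, miny, maxx, maxy) in mm."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    minx, miny, maxx, maxy = frame
    nx = max(1, int(math.ceil((maxx - minx) / resolution)))
    ny = max(1, int(math.ceil((maxy - miny) / resolution)))
    if nx * ny > _MAX_RASTER_CELLS:
        raise MemoryError(f"raster would need {nx * ny} cells (> {_MAX_RASTER_CELLS})")
    grid = np.zeros((ny, nx), dtype=bool)
    for poly in polys:
        if poly.is_empty:
            continue
        pminx, pminy, pmaxx, pmaxy = poly.bounds
        j0 = max(0, int((pminx - minx) / resolution) - 1)
        j1 = min(nx, int(math.ceil((pmaxx - minx) / resolution)) + 1)
        i0 = max(0, int((pminy - miny) / resolution) - 1)
        i1 = min(ny, int(math.ceil((pmaxy - miny) / resolution)) + 1)
        if j1 <= j0 or i1 <= i0:
            continue
        xs = minx + (np.arange(j0, j1) + 0.5) * resolution
        ys = miny + (np.arange(i0, i1) + 0.5) * resolution
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        grid[i0:i1, j0:j1] |= inside
    return BinaryMask(origin=(minx, miny), resolution=resolution, grid=grid)


# ---------------------------------------------------------------------------
# Morphological dilation
# ---------------------------------------------------------------------------

def dilate_polygons(footprint, se: StructuringElement):
    """Minkowski sum of a (multi)polygon footprint with a disc, via polygon
    buffering with a 256-segment circle approximation."""
    # radii below coordinate round-off act as the identity (a buffer by a
    # denormal radius would degenerate the polygon instead)
    if se.radius_mm < 1e-12:
        return footprint
    return footprint.buffer(se.radius_mm, quad_segs=_BUFFER_QUAD_SEGS)


def dilate_mask(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Binary dilation of a raster mask with a disc footprint."""
    r_cells = se.radius_mm / mask.resolution
    n = int(math.floor(r_cells))
    if n == 0:
        return BinaryMask(mask.origin, mask.resolution, mask.grid.copy())
    yy, xx = np.ogrid[-n:n + 1, -n:n + 1]
    disc = (xx ** 2 + yy ** 2) <= r_cells ** 2
    out = ndimage.binary_dilation(mask.grid, structure=disc)
    return BinaryMask(mask.origin, mask.resolution, out)


def dilate(obj, se: StructuringElement):
    """Dispatch: polygons are buffered, masks binarily dilated."""
    if isinstance(obj, BinaryMask):
        return dilate_mask(obj, se)
    if isinstance(obj, (Polygon, MultiPolygon)):
        return dilate_polygons(obj, se)
    if isinstance(obj, (list, tuple)):
        return dilate_polygons(unary_union([p.polygon if isinstance(p, DepositOutline) else p
                                            for p in obj]), se)
    raise TypeError(f"cannot dilate object of type {type(obj)!r}")


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

@dataclass
class DepositComponent:
    """A maximal group of deposit outlines whose footprints touch/overlap."""

    members: list[int]
    footprint: Polygon | MultiPolygon


def connected_components(deposits: list[DepositOutline | Polygon]) -> list[DepositComponent]:
    """Merge deposit outlines whose closed footprints intersect or touch.

    Touching-but-not-overlapping outlines count as one component, so the
    count is stable under subdividing a deposit into abutting parts.
    """
    polys = [d.polygon if isinstance(d, DepositOutline) else d for d in deposits]
    n = len(polys)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = shapely.STRtree(polys) if n else None
    for i in range(n):
        for j in tree.query(polys[i], predicate="intersects"):
            j = int(j)
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [DepositComponent(members=sorted(ms),
                             footprint=unary_union([polys[k] for k in ms]))
            for ms in groups.values()]
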