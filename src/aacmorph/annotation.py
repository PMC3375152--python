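"""Domain types, validation and JSON I/O for lumbar radiograph annotations.

An annotation of one digitized lateral lumbar radiograph consists of the
corner and mid points of vertebrae L1-L4, the anterior and posterior
abdominal aorta wall polylines, and closed outlines of the calcified
deposits, all drawn by an observer in pixel coordinates and converted here
to millimetres.

Coordinate convention
---------------------
Image-style axes: origin at the top-left of the radiograph, ``x``
increasing anterior -> posterior, ``y`` increasing cranial -> caudal.
Coordinates are 0-based continuous positions (not pixel-centre indices) and
are stored in millimetres after conversion with ``pixel_size_mm``.
Superior vertebral corners therefore have smaller ``y`` than inferior
corners, and anterior points smaller ``x`` than posterior points.

Deposit outlines are stored *open*: the first vertex is not repeated at the
end.  Readers accept either form and normalize.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from shapely.geometry import LineString, Polygon

VERTEBRA_LABELS = ("L1", "L2", "L3", "L4")
WALL_SIDES = ("anterior", "posterior")

#: pixel pitch of the study scanner, 44.6 um, in mm
DEFAULT_PIXEL_SIZE_MM = 0.0446


class SchemaError(ValueError):
    """The annotation file does not conform to the documented JSON schema."""


class AnnotationGeometryError(ValueError):
    """An annotation element violates a geometric invariant."""


def _as_points(obj, what: str) -> np.ndarray:
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SchemaError(f"{what}: expected an Nx2 point list, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SchemaError(f"{what}: non-finite coordinate")
    return arr


@dataclass(frozen=True)
class VertebraLandmarks:
    """Corner and mid-edge landmarks of one lumbar vertebra.

    ``corners`` rows are ordered anterior-superior, posterior-superior,
    posterior-inferior, anterior-inferior; ``mid_points`` rows are the
    anterior and posterior mid-edge points.
    """

    label: str
    corners: np.ndarray      # (4, 2) mm
    mid_points: np.ndarray   # (2, 2) mm

    def superior_level(self) -> float:
        """y of the superior endplate (mean of the two superior corners)."""
        return float(self.corners[[0, 1], 1].mean())

    def inferior_level(self) -> float:
        """y of the inferior endplate (mean of the two inferior corners)."""
        return float(self.corners[[2, 3], 1].mean())


@dataclass(frozen=True)
class WallPolyline:
    """One aortic wall outline, ordered cranial -> caudal."""

    side: str                # "anterior" | "posterior"
    points: np.ndarray       # (N, 2) mm

    @property
    def line(self) -> LineString:
        return LineString(self.points)


@dataclass(frozen=True)
class DepositOutline:
    """Closed simple polygon outlining one calcified deposit (open ring)."""

    vertices: np.ndarray     # (N, 2) mm, N >= 3, first vertex not repeated

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class AnnotationSet:
    """One observer's full annotation of one radiograph, in mm."""

    image_id: str
    observer_id: str
    session_id: str
    pixel_size_mm: float
    vertebrae: dict[str, VertebraLandmarks]
    walls: dict[str, WallPolyline]
    deposits: list[DepositOutline] = field(default_factory=list)

    def transformed(self, fn) -> "AnnotationSet":
        """Return a copy with ``fn`` ((N,2) array -> (N,2) array) applied to
        every coordinate array."""
        vert = {
            lab: VertebraLandmarks(lab, fn(v.corners), fn(v.mid_points))
            for lab, v in self.vertebrae.items()
        }
        walls = {s: WallPolyline(s, fn(w.points)) for s, w in self.walls.items()}
        deps = [DepositOutline(fn(d.vertices)) for d in self.deposits]
        return AnnotationSet(
            self.image_id, self.observer_id, self.session_id,
            self.pixel_size_mm, vert, walls, deps,
        )


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def _normalize_ring(vertices: np.ndarray) -> np.ndarray:
    """Drop a duplicated closure vertex if present."""
    if len(vertices) >= 4 and np.allclose(vertices[0], vertices[-1], atol=1e-12):
        return vertices[:-1]
    return vertices


def annotation_from_dict(doc: dict) -> AnnotationSet:
    for key in ("image_id", "observer_id", "session_id", "pixel_size_mm",
                "units", "vertebrae", "walls", "deposits"):
        if key not in doc:
            raise SchemaError(f"missing top-level key '{key}'")
    units = doc["units"]
    if units not in ("px", "mm"):
        raise SchemaError(f"units must be 'px' or 'mm', got {units!r}")
    pixel_size = float(doc["pixel_size_mm"])
    if not pixel_size > 0:
        raise SchemaError(f"pixel_size_mm must be positive, got {pixel_size}")
    scale = pixel_size if units == "px" else 1.0

    vertebrae: dict[str, VertebraLandmarks] = {}
    for lab in VERTEBRA_LABELS:
        if lab not in doc["vertebrae"]:
            raise SchemaError(f"missing vertebra label '{lab}'")
        entry = doc["vertebrae"][lab]
        corners = _as_points(entry.get("corners"), f"vertebrae[{lab}].corners") * scale
        mids = _as_points(entry.get("mid_points"), f"vertebrae[{lab}].mid_points") * scale
        if corners.shape[0] != 4:
            raise SchemaError(f"vertebrae[{lab}]: expected 4 corners, got {corners.shape[0]}")
        if mids.shape[0] != 2:
            raise SchemaError(f"vertebrae[{lab}]: expected 2 mid points, got {mids.shape[0]}")
        vertebrae[lab] = VertebraLandmarks(lab, corners, mids)

    walls: dict[str, WallPolyline] = {}
    for side, pts in doc["walls"].items():
        if side not in WALL_SIDES:
            raise SchemaError(f"unknown wall side '{side}'")
        arr = _as_points(pts, f"walls[{side}]") * scale
        if arr.shape[0] < 2:
            raise SchemaError(f"walls[{side}]: need at least 2 points")
        walls[side] = WallPolyline(side, arr)
    for side in WALL_SIDES:
        if side not in walls:
            raise SchemaError(f"missing wall side '{side}'")

    deposits = []
    for i, ring in enumerate(doc["deposits"]):
        arr = _normalize_ring(_as_points(ring, f"deposits[{i}]") * scale)
        if arr.shape[0] < 3:
            raise SchemaError(f"deposits[{i}]: need at least 3 vertices")
        poly = Polygon(arr)
        if not poly.is_valid:
            raise AnnotationGeometryError(f"deposits[{i}]: self-intersecting polygon")
        if poly.area <= 0:
            raise AnnotationGeometryError(f"deposits[{i}]: zero enclosed area")
        deposits.append(DepositOutline(arr))

    return AnnotationSet(
        image_id=str(doc["image_id"]),
        observer_id=str(doc["observer_id"]),
        session_id=str(doc["session_id"]),
        pixel_size_mm=pixel_size,
        vertebrae=vertebrae,
        walls=walls,
        deposits=deposits,
    )


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read an annotation JSON file, converting coordinates to mm."""
    with open(path) as fh:
        doc = json.load(fh)
    return annotation_from_dict(doc)


def annotation_to_dict(a: AnnotationSet) -> dict:
    return {
        "image_id": a.image_id,
        "observer_id": a.observer_id,
        "session_id": a.session_id,
        "pixel_size_mm": a.pixel_size_mm,
        "units": "mm",
        "vertebrae": {
            lab: {
                "corners": a.vertebrae[lab].corners.tolist(),
                "mid_points": a.vertebrae[lab].mid_points.tolist(),
            }
            for lab in VERTEBRA_LABELS
        },
        "walls": {s: a.walls[s].points.tolist() for s in WALL_SIDES},
        "deposits": [d.vertices.tolist() for d in a.deposits],
    }


def write_annotation(a: AnnotationSet, path: str | Path) -> None:
    """Write an annotation as JSON (mm units). Round-trips to <=1e-9 mm."""
    with open(path, "w") as fh:
        json.dump(annotation_to_dict(a), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_annotation(a: AnnotationSet, bbox_margin_mm: float = 10.0) -> list[str]:
    """Check all annotation invariants; return human-readable violations.

    Reports rather than raises: an empty list means the annotation is valid.
    ``bbox_margin_mm`` is the dilation applied to the wall bounding box when
    checking that deposits lie near the aorta.
    """
    violations: list[str] = []

    if not a.pixel_size_mm > 0:
        violations.append(f"pixel_size_mm: must be positive, got {a.pixel_size_mm}")

    for lab in VERTEBRA_LABELS:
        if lab not in a.vertebrae:
            violations.append(f"vertebrae: missing label {lab}")
    for lab, v in a.vertebrae.items():
        c = v.corners
        if not np.all(np.isfinite(c)) or not np.all(np.isfinite(v.mid_points)):
            violations.append(f"vertebrae[{lab}]: non-finite coordinate")
            continue
        # superior corners cranial of inferior corners
        if not (c[0, 1] < c[3, 1] and c[1, 1] < c[2, 1]):
            violations.append(f"vertebrae[{lab}]: superior corners must be cranial (smaller y) of inferior corners")
        # anterior points anterior of posterior points
        if not (c[0, 0] < c[1, 0] and c[3, 0] < c[2, 0]):
            violations.append(f"vertebrae[{lab}]: anterior corners must have smaller x than posterior corners")

    y_range = None
    if all(lab in a.vertebrae for lab in VERTEBRA_LABELS):
        y_range = (a.vertebrae["L1"].superior_level(),
                   a.vertebrae["L4"].inferior_level())

    for side in WALL_SIDES:
        if side not in a.walls:
            violations.append(f"walls: missing side {side}")
            continue
        pts = a.walls[side].points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            violations.append(f"walls[{side}]: duplicate consecutive points (arclength not strictly increasing)")
        elif not LineString(pts).is_simple:
            violations.append(f"walls[{side}]: self-intersecting polyline")
        if y_range is not None:
            if pts[:, 1].min() > y_range[0] + 1e-9 or pts[:, 1].max() < y_range[1] - 1e-9:
                violations.append(
                    f"walls[{side}]: vertical extent [{pts[:, 1].min():.3f}, {pts[:, 1].max():.3f}] "
                    f"does not span the L1-L4 landmark range [{y_range[0]:.3f}, {y_range[1]:.3f}]")

    if all(s in a.walls for s in WALL_SIDES):
        allw = np.vstack([a.walls[s].points for s in WALL_SIDES])
        lo = allw.min(axis=0) - bbox_margin_mm
        hi = allw.max(axis=0) + bbox_margin_mm
        for i, d in enumerate(a.deposits):
            poly = Polygon(d.vertices)
            if not poly.is_valid:
                violations.append(f"deposits[{i}]: self-intersecting polygon")
                continue
            if poly.area <= 0:
                violations.append(f"deposits[{i}]: non-positive area")
            v = d.vertices
            if np.any(v < lo) or np.any(v > hi):
                violations.append(
                    f"deposits[{i}]: outside the dilated wall bounding box "
                    f"(margin {bbox_margin_mm} mm)")
    return violations
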