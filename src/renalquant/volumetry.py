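"""Contour geometry and slice-based kidney volumetry.

Kidney volume is measured by drawing planar contours around renal tissue
(excluding the renal pelvis) on coronal slices and summing contour area times
slice thickness.  Two protocols are supported:

* ``every`` — a contour on every slice containing renal tissue;
* ``alternate`` — contours on the first and last kidney slices and every
  alternate slice in between, with cross-sectional AREA linearly interpolated
  on the non-contoured slices.

The interpolation target is the scalar per-slice area, not a morphed shape:
this makes the two protocols provably identical whenever the area profile is
affine in slice index, and makes the alternate-slice volume a chord-under-
curve underestimate for dome-shaped (concave) area profiles.

Coordinates are continuous in-plane millimetres: a voxel centre at array
index (row, col) sits at (x, y) = (col * dx, row * dy).  Array axis order is
(slice, row, col) with spacing (dz, dy, dx).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Point, Polygon
from skimage import measure

__all__ = [
    "Contour", "ROISet", "contour_area", "mask_to_contours",
    "volume_every_slice", "volume_alternate_slice", "slice_areas",
]


@dataclass
class Contour:
    """A closed planar polygon on one slice (last->first edge implied)."""

    slice_index: int
    vertices: np.ndarray  # (n, 2) float, (x, y) in mm
    label: str = "WK"
    hole: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) mm")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class ROISet:
    """A set of contours belonging to one observer on one image stack."""

    contours: list[Contour]
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm
    observer_id: str = ""
    slice_count: int = 0

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")
        if self.slice_count:
            for c in self.contours:
                if not 0 <= c.slice_index < self.slice_count:
                    raise ValueError(
                        f"contour slice {c.slice_index} outside stack of "
                        f"{self.slice_count} slices")

    def on_slice(self, slice_index: int, label: str | None = None) -> list[Contour]:
        return [c for c in self.contours
                if c.slice_index == slice_index
                and (label is None or c.label == label)]

    def labelled(self, label: str) -> "ROISet":
        return replace(self, contours=[c for c in self.contours if c.label == label])

    def slices(self, label: str | None = None) -> list[int]:
        return sorted({c.slice_index for c in self.contours
                       if label is None or c.label == label})


def contour_area(c: Contour) -> float:
    """Absolute (orientation-independent) shoelace area in mm^2."""
    v = c.vertices
    if len(v) < 3:
        raise ValueError("degenerate contour: fewer than 3 vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


def signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0


def mask_to_contours(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    slice_index: int,
    label: str = "WK",
    min_area_frac: float = 0.5,
) -> list[Contour]:
    """Trace a 2-D boolean mask into boundary contours at the half-voxel level.

    Returns outer contours plus interior boundaries marked as holes (a ring is
    a hole when it is enclosed by an odd number of other rings).  Rings whose
    area is below ``min_area_frac`` voxel areas are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    _, dy, dx = spacing
    rings: list[np.ndarray] = []
    for rc in measure.find_contours(mask.astype(float), 0.5):
        if np.allclose(rc[0], rc[-1]):
            rc = rc[:-1]
        if len(rc) < 3:
            continue
        xy = np.column_stack([rc[:, 1] * dx, rc[:, 0] * dy])
        if abs(signed_area(xy)) < min_area_frac * dx * dy:
            continue
        rings.append(xy)
    polys = [Polygon(r) for r in rings]
    out: list[Contour] = []
    for i, ring in enumerate(rings):
        # probe with a point on ring i itself: Polygon(ring_i) is filled, so
        # its interior representative point could sit inside a nested hole
        probe = Point(ring[0])
        depth = sum(1 for j, p in enumerate(polys)
                    if j != i and p.contains(probe))
        out.append(Contour(slice_index=slice_index, vertices=ring,
                           label=label, hole=bool(depth % 2)))
    return out


def slice_areas(rois: ROISet, label: str = "WK") -> dict[int, float]:
    """Net contoured area (outer minus holes) per slice, mm^2."""
    areas: dict[int, float] = {}
    for c in rois.contours:
        if c.label != label:
            continue
        a = contour_area(c)
        areas[c.slice_index] = areas.get(c.slice_index, 0.0) + (-a if c.hole else a)
    return {s: max(a, 0.0) for s, a in areas.items()}


def volume_every_slice(rois: ROISet, label: str = "WK") -> float:
    """Volume (ml) with a contour required on every kidney slice."""
    areas = slice_areas(rois, label)
    if not areas:
        raise ValueError("ROISet contains no contours for volumetry")
    lo, hi = min(areas), max(areas)
    for s in range(lo, hi + 1):
        if s not in areas:
            raise ValueError(
                f"every-slice protocol violated: slice {s} has no contour")
    dz = rois.spacing[0]
    return sum(areas.values()) * dz / 1000.0


def volume_alternate_slice(rois: ROISet, label: str = "WK") -> float:
    """Volume (ml) from alternate-slice contours with linear area interpolation.

    Contours must be present on the first and last kidney slices and on every
    alternate slice between them; areas of the single missing slices are
    linearly interpolated from the flanking contoured slices.  Interpolation
    never extrapolates beyond the contoured ends.
    """
    areas = slice_areas(rois, label)
    if not areas:
        raise ValueError("ROISet contains no contours for volumetry")
    contoured = sorted(areas)
    for a, b in zip(contoured, contoured[1:]):
        if b - a > 2:
            raise ValueError(
                f"alternate-slice protocol violated: slices {a + 1}..{b - 1} "
                "leave a gap of more than one missing slice")
    full = np.arange(contoured[0], contoured[-1] + 1)
    interp = np.interp(full, contoured, [areas[s] for s in contoured])
    dz = rois.spacing[0]
    return float(interp.sum()) * dz / 1000.0
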