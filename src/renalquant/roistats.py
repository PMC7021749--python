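"""Six-region ROI taxonomy and per-ROI summary statistics.

The regions mirror a common renal MRI reading protocol on a single analysis
slice: whole kidney (WK, pelvis excluded), whole cortex (Cx), a small
user-placed disc of representative cortex (repCx), cortex restricted to the
superior / inferior poles (supCx / infCx, the top and bottom thirds of the
in-slice kidney bounding box) and a connected region of medulla (Med).

Within-ROI summaries report mean, SD (population n divisor by default,
mirroring typical imaging-software ROI statistics; configurable to n-1),
voxel count and SD as a fraction of the mean — the latter quantifies how
wide a value range a "reproducible" ROI mean is actually drawn from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .phantom import CORTEX, MEDULLA, LabelMap
from .qmap import ParameterMap
from .volumetry import Contour, ROISet, mask_to_contours

__all__ = [
    "ROIKind", "ROISummary", "rasterize_contour", "rasterize_roiset",
    "define_standard_roi_masks", "define_standard_rois", "roi_summary",
    "cortex_medulla_ratio", "sd_fraction_report",
]


class ROIKind(enum.Enum):
    WK = "WK"
    Cx = "Cx"
    repCx = "repCx"
    supCx = "supCx"
    infCx = "infCx"
    Med = "Med"


@dataclass(frozen=True)
class ROISummary:
    """Within-ROI statistics of a parameter map."""

    mean: float
    sd: float
    n_voxels: int
    sd_fraction: float  # sd / mean; NaN when mean == 0
    units: str = ""


def rasterize_contour(contour: Contour, grid_shape: tuple[int, int],
                      spacing: tuple[float, float, float]) -> np.ndarray:
    """Boolean in-plane mask: voxel included iff its centre lies inside the
    polygon (even-odd rule).  Voxel centres sit at (col*dx, row*dy)."""
    ny, nx = grid_shape
    _, dy, dx = spacing
    v = contour.vertices
    if (v[:, 0].min() < -dx / 2 or v[:, 0].max() > (nx - 0.5) * dx
            or v[:, 1].min() < -dy / 2 or v[:, 1].max() > (ny - 0.5) * dy):
        raise ValueError("contour extends outside the voxel grid")
    cols, rows = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy)
    pts = np.column_stack([cols.ravel(), rows.ravel()])
    # closed=True treats the final vertex as the CLOSEPOLY placeholder, so
    # the closing vertex must be appended explicitly
    path = MplPath(np.vstack([v, v[:1]]), closed=True)
    inside = path.contains_points(pts)
    return inside.reshape(ny, nx)


def rasterize_roiset(rois: ROISet, grid_shape: tuple[int, int],
                     slice_index: int, label: str | None = None) -> np.ndarray:
    """Rasterize all contours of one slice; holes subtract from outers."""
    outer = np.zeros(grid_shape, dtype=bool)
    holes = np.zeros(grid_shape, dtype=bool)
    for c in rois.on_slice(slice_index, label):
        m = rasterize_contour(c, grid_shape, rois.spacing)
        if c.hole:
            holes |= m
        else:
            outer |= m
    return outer & ~holes


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def define_standard_roi_masks(
    labelmap: LabelMap,
    slice_index: int | None = None,
    kinds: set[ROIKind] | None = None,
    seed: int = 0,
    repcx_radius_mm: float = 4.0,
) -> dict[ROIKind, np.ndarray]:
    """Build the six standard ROI masks on one analysis slice.

    WK = cortex + medulla (pelvis excluded); Cx = cortex; Med = the largest
    connected medullary region; supCx/infCx = cortex within the top/bottom
    third of the kidney's in-slice bounding box; repCx = a disc of radius
    ``repcx_radius_mm`` placed (deterministically per seed) fully inside the
    cortex.  The default slice is the one of maximal kidney area.
    """
    kinds = set(ROIKind) if kinds is None else set(kinds)
    kid3 = labelmap.kidney_mask()
    if slice_index is None:
        slice_index = int(np.argmax(kid3.sum(axis=(1, 2))))
    kid = kid3[slice_index]
    if not kid.any():
        raise ValueError(f"slice {slice_index} contains no kidney")
    cx = labelmap.labels[slice_index] == CORTEX
    med = labelmap.labels[slice_index] == MEDULLA
    masks: dict[ROIKind, np.ndarray] = {}
    if ROIKind.WK in kinds:
        masks[ROIKind.WK] = kid.copy()
    if ROIKind.Cx in kinds:
        masks[ROIKind.Cx] = cx.copy()
    if ROIKind.Med in kinds:
        masks[ROIKind.Med] = _largest_component(med)
    if ROIKind.supCx in kinds or ROIKind.infCx in kinds:
        rows = np.nonzero(kid.any(axis=1))[0]
        r0, r1 = rows.min(), rows.max()
        third = (r1 - r0 + 1) / 3.0
        sup = np.zeros_like(cx)
        inf = np.zeros_like(cx)
        sup[r0:int(np.floor(r0 + third)) + 1] = True
        inf[int(np.ceil(r1 - third)):r1 + 1] = True
        if ROIKind.supCx in kinds:
            masks[ROIKind.supCx] = cx & sup
        if ROIKind.infCx in kinds:
            masks[ROIKind.infCx] = cx & inf
    if ROIKind.repCx in kinds:
        masks[ROIKind.repCx] = _place_disc(cx, labelmap.spacing,
                                           repcx_radius_mm, seed)
    return masks


def _place_disc(cx: np.ndarray, spacing, radius_mm: float,
                seed: int) -> np.ndarray:
    _, dy, dx = spacing
    dist = ndimage.distance_transform_edt(cx, sampling=(dy, dx))
    candidates = np.argwhere(dist >= radius_mm)
    if len(candidates) == 0:
        raise ValueError(
            f"cortex too thin for a representative-cortex disc of radius "
            f"{radius_mm} mm; use a smaller radius")
    rng = np.random.default_rng(seed)
    r0, c0 = candidates[rng.integers(len(candidates))]
    rows, cols = np.indices(cx.shape)
    disc = ((rows - r0) * dy) ** 2 + ((cols - c0) * dx) ** 2 <= radius_mm ** 2
    return disc & cx


def define_standard_rois(
    labelmap: LabelMap,
    slice_index: int | None = None,
    kinds: set[ROIKind] | None = None,
    seed: int = 0,
    repcx_radius_mm: float = 4.0,
    observer_id: str = "truth",
) -> ROISet:
    """Contour form of :func:`define_standard_roi_masks` (one ROISet whose
    contours are labelled by ROI kind)."""
    kid3 = labelmap.kidney_mask()
    if slice_index is None:
        slice_index = int(np.argmax(kid3.sum(axis=(1, 2))))
    masks = define_standard_roi_masks(labelmap, slice_index, kinds, seed,
                                      repcx_radius_mm)
    contours: list[Contour] = []
    for kind, mask in masks.items():
        contours.extend(mask_to_contours(mask, labelmap.spacing, slice_index,
                                         kind.value))
    return ROISet(contours=contours, spacing=labelmap.spacing,
                  observer_id=observer_id, slice_count=labelmap.shape[0])


def roi_summary(pmap: ParameterMap, mask: np.ndarray, ddof: int = 0) -> ROISummary:
    """Mean / SD / count / SD-fraction of the map values inside ``mask``.

    Uses the population SD (ddof=0) by default; pass ddof=1 for the sample
    convention.  Raises on an empty mask (no finite map voxels inside).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.values.shape:
        raise ValueError("mask shape does not match map")
    sel = mask & pmap.finite_mask()
    vals = pmap.values[sel]
    if vals.size == 0:
        raise ValueError("empty ROI: no finite map voxels inside mask")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    frac = sd / mean if mean != 0 else float("nan")
    return ROISummary(mean=mean, sd=sd, n_voxels=int(vals.size),
                      sd_fraction=frac, units=pmap.units)


def cortex_medulla_ratio(cx: ROISummary, med: ROISummary) -> float:
    """Corticomedullary differentiation: ratio of cortical to medullary mean."""
    if med.mean == 0:
        raise ValueError("medullary mean is zero; ratio undefined")
    return cx.mean / med.mean


def sd_fraction_report(summaries: pd.DataFrame,
                       by: tuple[str, ...] = ("sequence", "roi")) -> pd.DataFrame:
    """Across-subject report of within-ROI spread.

    ``summaries`` is tidy with one row per subject x ROI (columns ``mean``,
    ``sd``, ``units`` plus the ``by`` keys).  Per group: the mean of the
    within-ROI SDs, the mean of the subject means, and the former as a
    percentage of the latter (1 dp).
    """
    required = set(by) | {"mean", "sd", "units"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    rows = []
    for key, grp in summaries.groupby(list(by), sort=True):
        units = grp["units"].unique()
        if len(units) > 1:
            raise ValueError(f"unit mismatch within group {key}: {list(units)}")
        mean_sd = float(grp["sd"].mean())
        mean_val = float(grp["mean"].mean())
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update({
            "roi_sd_mean": mean_sd,
            "mean_value": mean_val,
            "roi_sd_pct_of_mean": round(100.0 * mean_sd / mean_val, 1),
            "n_subjects": int(len(grp)),
            "units": units[0],
        })
        rows.append(row)
    return pd.DataFrame(rows)
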