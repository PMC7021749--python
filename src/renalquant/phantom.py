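"""Synthetic renal phantom: geometry, acquisitions and simulated observers.

The phantom is a single ellipsoidal kidney on a coronal voxel grid with
three labelled compartments — a cortical shell, wedge-shaped medullary
pyramids inside it (separated by cortical columns) and a small central
pelvis.  Each compartment carries ground-truth tissue parameters (T1, ADC,
perfusion, M0) from which inversion-recovery, diffusion-weighted and ASL
label/control/M0 image sets are simulated with the same signal models the
fitting code inverts, plus optional Gaussian noise on the signed data.

Simulated "observers" are produced by displacing contour vertices along the
local outward normal by a systematic bias plus Gaussian jitter, standing in
for the between-reader contouring variability of a two-observer study.

Geometry makes no claim to anatomical realism beyond the cortex-shell /
medulla-core / pelvis topology; see the methods note for what this phantom
does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from .qmap import (ASLConstants, ASLSet, DWISeries, MOLLISeries,
                   forward_asl_signal, DEFAULT_B_VALUES, DEFAULT_TI_MS)
from .volumetry import Contour, ROISet, mask_to_contours, signed_area

__all__ = [
    "BACKGROUND", "CORTEX", "MEDULLA", "PELVIS",
    "LabelMap", "CompartmentParams", "TissueParams", "ObserverModel",
    "make_kidney_labelmap", "ground_truth_map", "simulate_molli_series",
    "simulate_dwi_series", "simulate_asl_set", "perturb_contours",
    "kidney_contours",
]

BACKGROUND, CORTEX, MEDULLA, PELVIS = 0, 1, 2, 3

_MIN_SHAPE = (8, 32, 32)


@dataclass
class LabelMap:
    """Integer compartment labels on a (slice, row, col) voxel grid."""

    labels: np.ndarray  # int8, values {0, 1, 2, 3}
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D (slice, row, col) grid")
        if not np.isin(self.labels, (BACKGROUND, CORTEX, MEDULLA, PELVIS)).all():
            raise ValueError("labels must be in {0 bg, 1 cortex, 2 medulla, 3 pelvis}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def kidney_mask(self, include_pelvis: bool = False) -> np.ndarray:
        m = (self.labels == CORTEX) | (self.labels == MEDULLA)
        return m | (self.labels == PELVIS) if include_pelvis else m

    def kidney_slices(self) -> list[int]:
        return [int(s) for s in
                np.nonzero(self.kidney_mask(include_pelvis=True).any(axis=(1, 2)))[0]]

    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0


@dataclass(frozen=True)
class CompartmentParams:
    """Ground-truth tissue parameters of one compartment."""

    t1_ms: float
    adc_mm2_per_s: float
    perfusion_ml_per_100g_min: float
    m0: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.t1_ms, self.adc_mm2_per_s, self.m0) <= 0:
            raise ValueError("t1, adc and m0 must be positive")
        if self.perfusion_ml_per_100g_min < 0:
            raise ValueError("perfusion must be non-negative")


def _default_cortex() -> CompartmentParams:
    return CompartmentParams(1630.2, 1.6781e-3, 221.0)


def _default_medulla() -> CompartmentParams:
    return CompartmentParams(1975.8, 1.6719e-3, 95.8)


def _default_pelvis() -> CompartmentParams:
    # fluid-like: long T1, free diffusion, negligible tissue perfusion
    return CompartmentParams(2800.0, 2.8e-3, 15.0)


@dataclass(frozen=True)
class TissueParams:
    """Per-compartment ground truth; defaults follow the reference cohort
    means (cortical perfusion above medullary, medullary T1 above cortical)."""

    cortex: CompartmentParams = field(default_factory=_default_cortex)
    medulla: CompartmentParams = field(default_factory=_default_medulla)
    pelvis: CompartmentParams = field(default_factory=_default_pelvis)

    def by_label(self) -> dict[int, CompartmentParams]:
        return {CORTEX: self.cortex, MEDULLA: self.medulla, PELVIS: self.pelvis}


@dataclass(frozen=True)
class ObserverModel:
    """Simulated contour reader: systematic bias plus random jitter (mm)."""

    boundary_jitter_mm: float = 0.5
    bias_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_mm < 0:
            raise ValueError("jitter must be non-negative")


def make_kidney_labelmap(
    shape: tuple[int, int, int] = (26, 46, 46),
    spacing: tuple[float, float, float] = (4.0, 2.5, 2.5),
    seed: int = 0,
    target_volume_ml: float | None = None,
    n_pyramids: int = 5,
) -> LabelMap:
    """Generate an ellipsoid-like kidney label map.

    The kidney is an ellipsoid whose cross-sectional area varies smoothly
    across slices; the cortex is the outer shell, medullary pyramids are
    angular wedges of the core (cortical columns between them) and the
    pelvis a small central region.  At least one slice at each stack end is
    kidney-free so "first and last slices containing renal tissue" is
    well-defined.  Deterministic for a fixed seed; seed also jitters the
    semi-axes and wedge phase so subjects differ.

    ``target_volume_ml`` rescales the semi-axes (within the grid) to an
    approximate total kidney volume.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < m for s, m in zip(shape, _MIN_SHAPE)):
        raise ValueError(f"grid too small: need shape >= {_MIN_SHAPE}, got {shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dz, dy, dx = spacing
    cz = (nz - 1) / 2.0 * dz
    cy = (ny - 1) / 2.0 * dy
    cx = (nx - 1) / 2.0 * dx
    # semi-axes: leave >1 slice margin axially and ~15% in-plane margin
    az_max = ((nz - 1) / 2.0 - 1.1) * dz
    ay_max = 0.42 * (ny - 1) * dy
    ax_max = 0.38 * (nx - 1) * dx
    scale = 0.92 + 0.08 * rng.random(3)
    az, ay, ax = az_max * scale[0], ay_max * scale[1], ax_max * scale[2]
    if target_volume_ml is not None:
        if target_volume_ml <= 0:
            raise ValueError("target_volume_ml must be positive")
        vol = 4.0 / 3.0 * np.pi * az * ay * ax / 1000.0
        s = (target_volume_ml / vol) ** (1.0 / 3.0)
        s = min(s, az_max / az, ay_max / ay, ax_max / ax)
        az, ay, ax = az * s, ay * s, ax * s
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    e = (((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2)
    labels = np.zeros(shape, dtype=np.int8)
    labels[e <= 1.0] = CORTEX
    core = e <= 0.55
    theta = np.arctan2(np.broadcast_to(y - cy, shape),
                       np.broadcast_to(x - cx, shape))
    phase = rng.uniform(0, 2 * np.pi)
    wedges = np.cos(n_pyramids * theta + phase) > -0.15
    labels[core & wedges] = MEDULLA
    labels[e <= 0.10] = PELVIS
    return LabelMap(labels=labels, spacing=spacing)


def ground_truth_map(labelmap: LabelMap, params: TissueParams,
                     which: str) -> np.ndarray:
    """Per-voxel ground-truth map of one tissue parameter (0 in background)."""
    out = np.zeros(labelmap.shape, dtype=float)
    for label, comp in params.by_label().items():
        out[labelmap.labels == label] = getattr(comp, which)
    return out


def simulate_molli_series(
    labelmap: LabelMap, params: TissueParams,
    ti_ms=DEFAULT_TI_MS, noise_sd: float = 0.0, seed: int = 0,
    beta: float = 1.0,
) -> MOLLISeries:
    """Simulate a signed (phase-sensitive) inversion-recovery series.

    Voxel signal S(TI) = A - B exp(-TI/T1*) with A = M0, B = 2 M0 beta and
    T1* chosen so the Look-Locker-corrected T1 = T1*(B/A - 1) equals the
    compartment ground truth; beta = 1 (ideal inversion) makes T1* = T1.
    Gaussian noise of SD ``noise_sd`` is added to the signed signal.
    """
    ti = np.asarray(ti_ms, dtype=float)
    if np.any(ti <= 0) or np.any(np.diff(ti) <= 0):
        raise ValueError("ti_ms must be positive and strictly increasing")
    if beta <= 0.5:
        raise ValueError("inversion efficiency beta must exceed 0.5")
    m0 = ground_truth_map(labelmap, params, "m0")
    t1 = ground_truth_map(labelmap, params, "t1_ms")
    t1_star = np.where(t1 > 0, t1 / (2.0 * beta - 1.0), 1.0)
    a = m0
    b = 2.0 * beta * m0
    frames = a[None] - b[None] * np.exp(-ti[:, None, None, None] / t1_star[None])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return MOLLISeries(frames=frames, ti_ms=tuple(ti), spacing=labelmap.spacing)


def simulate_dwi_series(
    labelmap: LabelMap, params: TissueParams,
    b_values=DEFAULT_B_VALUES, noise_sd: float = 0.0, seed: int = 0,
) -> DWISeries:
    """Simulate mono-exponential diffusion decay S(b) = S0 exp(-b ADC)."""
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if 0.0 not in b:
        raise ValueError("b = 0 must be included (anchors S0)")
    s0 = ground_truth_map(labelmap, params, "m0")
    adc = ground_truth_map(labelmap, params, "adc_mm2_per_s")
    frames = s0[None] * np.exp(-b[:, None, None, None] * adc[None])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return DWISeries(frames=frames, b_s_per_mm2=tuple(b),
                     spacing=labelmap.spacing)


def simulate_asl_set(
    labelmap: LabelMap, params: TissueParams,
    constants: ASLConstants | None = None,
    noise_sd: float = 0.0, seed: int = 0,
) -> ASLSet:
    """Simulate an ASL label/control/M0 triple from ground-truth perfusion.

    control = M0; label = control - dM with dM from the forward pCASL model;
    noise is added independently to label and control.
    """
    c = constants if constants is not None else ASLConstants()
    f = ground_truth_map(labelmap, params, "perfusion_ml_per_100g_min")
    if np.any(f < 0):
        raise ValueError("ground-truth perfusion must be non-negative")
    m0 = ground_truth_map(labelmap, params, "m0")
    control = m0.copy()
    label = control - forward_asl_signal(f, m0, c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        label = label + rng.normal(0.0, noise_sd, label.shape)
        control = control + rng.normal(0.0, noise_sd, control.shape)
    return ASLSet(label_img=label, control_img=control, m0_img=m0,
                  constants=c, spacing=labelmap.spacing)


# ---------------------------------------------------------------------------
# contours and simulated observers

def kidney_contours(labelmap: LabelMap, include_pelvis: bool = False,
                    label: str = "WK", observer_id: str = "truth") -> ROISet:
    """Trace whole-kidney contours (pelvis excluded by default) on every
    slice containing renal tissue."""
    mask3 = labelmap.kidney_mask(include_pelvis=include_pelvis)
    contours: list[Contour] = []
    for s in range(labelmap.shape[0]):
        if mask3[s].any():
            contours.extend(mask_to_contours(mask3[s], labelmap.spacing, s, label))
    return ROISet(contours=contours, spacing=labelmap.spacing,
                  observer_id=observer_id, slice_count=labelmap.shape[0])


def _vertex_normals(vertices: np.ndarray) -> np.ndarray:
    """Unit outward normals at each vertex of a simple polygon."""
    d = np.roll(vertices, -1, axis=0) - np.roll(vertices, 1, axis=0)
    # rotate tangent by -90deg; for a CCW (positive-area) polygon this
    # points outward
    normals = np.column_stack([d[:, 1], -d[:, 0]])
    if signed_area(vertices) < 0:
        normals = -normals
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    return normals / norms[:, None]


def _repair(vertices: np.ndarray) -> np.ndarray:
    poly = Polygon(vertices)
    if poly.is_valid:
        return vertices
    fixed = poly.buffer(0)
    if fixed.geom_type == "MultiPolygon":
        fixed = max(fixed.geoms, key=lambda g: g.area)
    if fixed.is_empty or fixed.geom_type != "Polygon":
        return vertices
    out = np.asarray(fixed.exterior.coords)[:-1]
    return out if len(out) >= 3 else vertices


def perturb_contours(rois: ROISet, model: ObserverModel) -> ROISet:
    """Displace every contour vertex along its outward normal.

    Displacement = bias_mm + N(0, jitter_mm) per vertex; with zero jitter and
    zero bias the input is returned unchanged (exact identity).  Perturbed
    polygons that self-intersect are repaired (largest valid part kept).
    Deterministic for a fixed ``model.seed``.
    """
    if model.boundary_jitter_mm == 0 and model.bias_mm == 0:
        return replace(rois, contours=[replace(c, vertices=c.vertices.copy())
                                       for c in rois.contours])
    rng = np.random.default_rng(model.seed)
    out: list[Contour] = []
    for c in rois.contours:
        normals = _vertex_normals(c.vertices)
        disp = model.bias_mm + rng.normal(0.0, model.boundary_jitter_mm,
                                          len(c.vertices))
        if c.hole:
            # bias grows the ROI, i.e. shrinks its holes
            disp = -disp
        moved = _repair(c.vertices + disp[:, None] * normals)
        out.append(replace(c, vertices=moved))
    return replace(rois, contours=out)
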