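"""Per-voxel quantitative map computation: T1, ADC and ASL perfusion.

Three models are implemented:

* **T1 (inversion recovery)** — the standard three-parameter model for a
  Look-Locker style readout of signed (phase-sensitive) data,
  ``S(TI) = A - B exp(-TI / T1*)``, fitted per voxel by bounded nonlinear
  least squares, followed by the Look-Locker correction
  ``T1 = T1* (B/A - 1)``.
* **ADC (diffusion)** — the mono-exponential decay
  ``S(b) = S0 exp(-b * ADC)`` fitted per voxel across all b-values.
* **pCASL perfusion** — a single-compartment pulsed-labelling model:

  ``dM = f (2 M0 / lambda) T1' alpha exp(-dt/T1blood)
        exp(-(t - tau - dt)/T1') (1 - exp(-tau/T1'))``

  where ``f`` is perfusion (internally ml/g/ms, reported ml/100 g/min),
  ``t`` the label-to-image time, ``tau`` the label duration, ``dt`` the
  arterial transit time, ``alpha`` the labelling efficiency, ``lambda`` the
  blood-tissue water partition coefficient and ``T1blood``/``T1'`` the blood
  and apparent tissue longitudinal relaxation times.  The model is linear in
  both ``f`` and ``M0``, so the perfusion map is its exact algebraic inverse
  applied to ``dM = control - label``.

Note on ``lambda``: the conventional partition coefficient is 0.9 ml/g;
with the perfusion units used here the conversion from ml/100 g/min is a
factor of 1/(100 * 60000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MOLLISeries", "DWISeries", "ASLConstants", "ASLSet", "ParameterMap",
    "fit_t1_map", "fit_adc_map", "forward_asl_signal", "perfusion_map",
    "DEFAULT_TI_MS", "DEFAULT_B_VALUES",
]

#: 14-point inversion-time schedule (ms) of the 11(3)3 acquisition scheme
DEFAULT_TI_MS = (180.0, 260.0, 730.0, 810.0, 1280.0, 1360.0, 1830.0,
                 2380.0, 2930.0, 3480.0, 4030.0, 4580.0, 5130.0, 5680.0)

#: ten diffusion weightings (s/mm^2)
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0,
                    500.0, 750.0, 1000.0)


def _as_frames(frames: np.ndarray, n: int, what: str) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4:
        raise ValueError(f"{what} frames must be 4-D (frame, slice, row, col)")
    if frames.shape[0] != n:
        raise ValueError(
            f"{what}: {frames.shape[0]} frames but {n} schedule entries")
    return frames


@dataclass
class MOLLISeries:
    """Signed inversion-recovery image stack indexed by inversion time."""

    frames: np.ndarray  # (n_ti, slice, row, col)
    ti_ms: tuple[float, ...]
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm

    def __post_init__(self) -> None:
        self.ti_ms = tuple(float(t) for t in self.ti_ms)
        if len(self.ti_ms) < 3:
            raise ValueError("need at least 3 inversion times")
        if any(t <= 0 for t in self.ti_ms) or np.any(np.diff(self.ti_ms) <= 0):
            raise ValueError("ti_ms must be positive and strictly increasing")
        self.frames = _as_frames(self.frames, len(self.ti_ms), "MOLLI")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class DWISeries:
    """Diffusion-weighted image stack indexed by b-value."""

    frames: np.ndarray  # (n_b, slice, row, col)
    b_s_per_mm2: tuple[float, ...]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.b_s_per_mm2 = tuple(float(b) for b in self.b_s_per_mm2)
        if len(self.b_s_per_mm2) < 2:
            raise ValueError("need at least 2 b-values")
        if any(b < 0 for b in self.b_s_per_mm2):
            raise ValueError("b-values must be non-negative")
        if 0.0 not in self.b_s_per_mm2:
            raise ValueError("b = 0 frame is required to anchor S0")
        self.frames = _as_frames(self.frames, len(self.b_s_per_mm2), "DWI")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass(frozen=True)
class ASLConstants:
    """Timing and physiological constants of the pCASL quantification model.

    Defaults: label start-to-image time t = 3000 ms, label duration
    tau = 1500 ms, arterial transit time dt = 750 ms, labelling efficiency
    alpha = 0.98, partition coefficient lambda = 0.9 ml/g and fixed
    T1blood = T1' = 1250 ms.
    """

    t_ms: float = 3000.0
    tau_ms: float = 1500.0
    delta_t_ms: float = 750.0
    alpha: float = 0.98
    lambda_ml_per_g: float = 0.9
    t1_blood_ms: float = 1250.0
    t1_app_ms: float = 1250.0

    def __post_init__(self) -> None:
        vals = (self.t_ms, self.tau_ms, self.delta_t_ms, self.alpha,
                self.lambda_ml_per_g, self.t1_blood_ms, self.t1_app_ms)
        if any(v <= 0 for v in vals):
            raise ValueError("all ASL constants must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("labelling efficiency alpha must be in (0, 1]")
        if self.t_ms < self.tau_ms + self.delta_t_ms:
            raise ValueError("need t >= tau + delta_t (label fully delivered)")


@dataclass
class ASLSet:
    """One label/control/M0 triple with its quantification constants."""

    label_img: np.ndarray
    control_img: np.ndarray
    m0_img: np.ndarray
    constants: ASLConstants = field(default_factory=ASLConstants)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.label_img = np.asarray(self.label_img, dtype=float)
        self.control_img = np.asarray(self.control_img, dtype=float)
        self.m0_img = np.asarray(self.m0_img, dtype=float)
        if not (self.label_img.shape == self.control_img.shape
                == self.m0_img.shape):
            raise ValueError(
                f"label {self.label_img.shape}, control "
                f"{self.control_img.shape} and M0 {self.m0_img.shape} "
                "grids must be congruent")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class ParameterMap:
    """A per-voxel quantitative map with units and fit diagnostics.

    ``values`` is finite inside ``mask`` except where the per-voxel fit
    failed (flagged NaN with ``quality`` set); ``quality`` holds the residual
    norm of the fit (NaN outside the mask), and ``info`` carries map-level
    QC counters.
    """

    values: np.ndarray
    units: str
    mask: np.ndarray
    quality: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def finite_mask(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)


# ---------------------------------------------------------------------------
# T1 fitting

def _t1_model(ti: np.ndarray, a: float, b: float, t1_star: float) -> np.ndarray:
    return a - b * np.exp(-ti / t1_star)


def _t1_initial_guess(ti: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    a0 = max(float(s[-1]), 1e-6)
    b0 = max(a0 - float(s[0]), 1e-6)
    # zero crossing of A - B exp(-TI/T1*) sits at TI = T1* ln(B/A)
    t1s0 = 1000.0
    if b0 > a0:
        sign = np.signbit(s)
        crossings = np.nonzero(sign[:-1] & ~sign[1:])[0]
        if crossings.size:
            i = int(crossings[0])
            # linear interpolation of the crossing time
            t0 = ti[i] + (ti[i + 1] - ti[i]) * s[i] / (s[i] - s[i + 1])
            t1s0 = max(t0 / np.log(b0 / a0), 10.0)
    return a0, b0, t1s0


def _fit_t1_voxel(ti: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Returns (T1 ms, residual norm); (nan, nan) when the fit fails."""
    if not np.any(np.abs(s) > 0):
        return np.nan, np.nan
    p0 = _t1_initial_guess(ti, s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _t1_model, ti, s, p0=p0,
                bounds=([1e-9, 1e-9, 1.0], [np.inf, np.inf, 1e5]),
                ftol=1e-12, xtol=1e-12, maxfev=2000)
    except (RuntimeError, ValueError):
        return np.nan, np.nan
    a, b, t1_star = popt
    resid = float(np.linalg.norm(s - _t1_model(ti, *popt)))
    t1 = t1_star * (b / a - 1.0)
    if not np.isfinite(t1) or t1 <= 0:
        return np.nan, resid
    return float(t1), resid


def _unique_voxel_fit(data: np.ndarray, fit_one) -> tuple[np.ndarray, np.ndarray]:
    """Fit each distinct voxel time-course once (piecewise-constant phantoms
    collapse to a handful of fits)."""
    uniq, inverse = np.unique(data, axis=0, return_inverse=True)
    vals = np.empty(len(uniq))
    quals = np.empty(len(uniq))
    for i, row in enumerate(uniq):
        vals[i], quals[i] = fit_one(row)
    return vals[inverse], quals[inverse]


def fit_t1_map(series: MOLLISeries, mask: np.ndarray | None = None) -> ParameterMap:
    """Fit T1 (ms) per voxel from a signed inversion-recovery series.

    Voxels where the nonlinear fit does not converge (including all-zero
    series) are flagged non-finite rather than raising.
    """
    ti = np.asarray(series.ti_ms)
    shape = series.frames.shape[1:]
    if mask is None:
        mask = np.any(np.abs(series.frames) > 0, axis=0)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image grid")
    data = series.frames.reshape(len(ti), -1).T[mask.ravel()]
    vals, quals = _unique_voxel_fit(data, lambda s: _fit_t1_voxel(ti, s))
    values = np.full(shape, np.nan)
    quality = np.full(shape, np.nan)
    values[mask] = vals
    quality[mask] = quals
    n_failed = int(np.sum(~np.isfinite(vals)))
    return ParameterMap(values=values, units="ms", mask=mask, quality=quality,
                        info={"n_failed": n_failed, "model": "A - B*exp(-TI/T1*)"})


# ---------------------------------------------------------------------------
# ADC fitting

def _adc_model(b: np.ndarray, s0: float, adc: float) -> np.ndarray:
    return s0 * np.exp(-b * adc)


def _fit_adc_voxel(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    if not np.any(s > 0):
        return np.nan, np.nan
    pos = s > 0
    if pos.sum() >= 2:
        # log-linear two-parameter initialisation
        slope, intercept = np.polyfit(b[pos], np.log(s[pos]), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))
    else:
        p0 = (float(s.max()), 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _adc_model, b, s, p0=p0,
                bounds=([1e-12, 0.0], [np.inf, 0.1]),
                ftol=1e-14, xtol=1e-14, maxfev=2000)
    except (RuntimeError, ValueError):
        return np.nan, np.nan
    resid = float(np.linalg.norm(s - _adc_model(b, *popt)))
    adc = float(popt[1])
    if adc < 1e-10:  # snap interior-point dust onto the ADC = 0 bound
        adc = 0.0
    return adc, resid


def fit_adc_map(series: DWISeries, mask: np.ndarray | None = None) -> ParameterMap:
    """Fit the apparent diffusion coefficient (mm^2/s) per voxel.

    ADC is reported in mm^2/s; multiply by 1e6 at the reporting layer for
    the conventional 1e-6 mm^2/s tabulation.  A constant signal across b
    lands on the ADC = 0 bound and is counted in ``info['n_boundary']``.
    """
    b = np.asarray(series.b_s_per_mm2)
    shape = series.frames.shape[1:]
    if mask is None:
        mask = np.any(series.frames > 0, axis=0)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image grid")
    data = series.frames.reshape(len(b), -1).T[mask.ravel()]
    vals, quals = _unique_voxel_fit(data, lambda s: _fit_adc_voxel(b, s))
    values = np.full(shape, np.nan)
    quality = np.full(shape, np.nan)
    values[mask] = vals
    quality[mask] = quals
    return ParameterMap(
        values=values, units="mm^2/s", mask=mask, quality=quality,
        info={"n_failed": int(np.sum(~np.isfinite(vals))),
              "n_boundary": int(np.sum(vals == 0.0)),
              "model": "S0*exp(-b*ADC)"})


# ---------------------------------------------------------------------------
# ASL perfusion

def _asl_kernel(c: ASLConstants) -> float:
    """Model factor k such that dM = (f / (100*60000)) * M0 * k."""
    return (2.0 / c.lambda_ml_per_g) * c.t1_app_ms * c.alpha \
        * np.exp(-c.delta_t_ms / c.t1_blood_ms) \
        * np.exp(-(c.t_ms - c.tau_ms - c.delta_t_ms) / c.t1_app_ms) \
        * (1.0 - np.exp(-c.tau_ms / c.t1_app_ms))


def forward_asl_signal(f, m0, constants: ASLConstants | None = None):
    """Perfusion-weighted signal dM for perfusion f (ml/100 g/min) and M0.

    Evaluates the single-compartment pCASL model; linear in both f and M0.
    ``f`` and ``m0`` may be scalars or broadcastable arrays; f must be
    non-negative (the forward model describes real tissue perfusion).
    """
    c = constants if constants is not None else ASLConstants()
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("perfusion f must be non-negative")
    f_per_ms = f / (100.0 * 60000.0)  # ml/100g/min -> ml/g/ms
    out = f_per_ms * np.asarray(m0, dtype=float) * _asl_kernel(c)
    return out if out.ndim else float(out)


def perfusion_map(asl: ASLSet, mask: np.ndarray | None = None,
                  m0_floor: float = 1e-6) -> ParameterMap:
    """Invert the pCASL model voxelwise: f (ml/100 g/min) from dM and M0.

    dM = control - label.  Noise-induced negative perfusion values are
    preserved in the map (not clipped); their fraction within the mask is
    reported in ``info['negative_fraction']``.  Voxels with M0 at or below
    ``m0_floor`` are flagged out of the mask.
    """
    c = asl.constants
    if mask is None:
        mask = asl.m0_img > m0_floor
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != asl.m0_img.shape:
            raise ValueError("mask shape does not match image grid")
        mask = mask & (asl.m0_img > m0_floor)
    dm = asl.control_img - asl.label_img
    values = np.full(asl.m0_img.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[mask] = dm[mask] / (asl.m0_img[mask] * _asl_kernel(c)) \
            * (100.0 * 60000.0)
    n = int(mask.sum())
    neg = float(np.sum(values[mask] < 0) / n) if n else 0.0
    return ParameterMap(values=values, units="ml/100 g/min", mask=mask,
                        info={"negative_fraction": neg})
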