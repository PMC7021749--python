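"""End-to-end cohort pipeline: phantoms -> maps -> two observers -> reports.

For each simulated subject the pipeline

1. draws tissue parameters and kidney size from the reference-cohort group
   distributions and builds a kidney phantom;
2. simulates the MOLLI, DWI (HV/Tx only) and pCASL acquisitions with noise
   and fits the T1, ADC and perfusion maps on the analysis slice (the slice
   of maximal kidney area), masked to renal tissue;
3. derives the six standard ROIs twice, once per simulated observer — each
   observer perturbs the whole-kidney/cortex/medulla contours with its own
   jitter/bias realisation, re-derives the polar-third cortex regions from
   its own contours, and places its own representative-cortex disc;
4. contours the whole kidney on every slice per observer and computes both
   the every-slice and alternate-slice volumes;
5. assembles tidy tables: per-observer ROI summaries, interobserver
   ICC/CoV/Bland–Altman per sequence x ROI, pairwise group differences of
   the observer-mean values, and within-ROI SD-fraction reports.

All randomness flows from ``StudyConfig.seed`` through per-subject
``numpy.random.SeedSequence`` spawns; a seed manifest is part of the result
bundle and of the CSV output, so a run is exactly repeatable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference_tables as ref
from .config import StudyConfig
from .phantom import (CompartmentParams, LabelMap, ObserverModel,
                      TissueParams, kidney_contours, make_kidney_labelmap,
                      perturb_contours, simulate_asl_set, simulate_dwi_series,
                      simulate_molli_series)
from .qmap import fit_adc_map, fit_t1_map, perfusion_map
from .roistats import (ROIKind, define_standard_roi_masks, rasterize_roiset,
                       roi_summary, sd_fraction_report, _place_disc)
from .reproducibility import group_difference_report, repro_report
from .volumetry import (ROISet, mask_to_contours, volume_alternate_slice,
                        volume_every_slice)

__all__ = ["run_pipeline", "simulate_subject", "PipelineError"]

OBSERVERS = ("A", "B")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and subject."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject


def _draw(rng, mean: float, sd: float, lo: float) -> float:
    return float(max(rng.normal(mean, sd), lo))


def _draw_tissue(rng, group: str) -> TissueParams:
    """Per-subject ground truth from the reference group distributions."""
    adc_group = group if (("ADC", "Cx") in ref._GROUP_STATS
                          and group in ref._GROUP_STATS[("ADC", "Cx")]) else "All"
    cortex = CompartmentParams(
        t1_ms=_draw(rng, ref.group_mean("T1", "Cx", group),
                    ref.group_sd("T1", "Cx", group), 500.0),
        adc_mm2_per_s=_draw(rng, ref.group_mean("ADC", "Cx", adc_group),
                            ref.group_sd("ADC", "Cx", adc_group), 300.0) * 1e-6,
        perfusion_ml_per_100g_min=_draw(
            rng, ref.group_mean("pCASL", "Cx", group),
            ref.group_sd("pCASL", "Cx", group), 20.0))
    medulla = CompartmentParams(
        t1_ms=_draw(rng, ref.group_mean("T1", "Med", group),
                    ref.group_sd("T1", "Med", group), 500.0),
        adc_mm2_per_s=_draw(rng, ref.group_mean("ADC", "Med", adc_group),
                            ref.group_sd("ADC", "Med", adc_group), 300.0) * 1e-6,
        perfusion_ml_per_100g_min=_draw(
            rng, ref.group_mean("pCASL", "Med", group),
            ref.group_sd("pCASL", "Med", group), 5.0))
    return TissueParams(cortex=cortex, medulla=medulla)


def _int_seed(rng) -> int:
    return int(rng.integers(2 ** 31))


def _clip_roiset(rois: ROISet, grid_shape) -> ROISet:
    """Keep perturbed vertices inside the voxel-grid extent."""
    ny, nx = grid_shape
    _, dy, dx = rois.spacing
    eps = 1e-9
    for c in rois.contours:
        c.vertices[:, 0] = np.clip(c.vertices[:, 0], -dx / 2 + eps,
                                   (nx - 0.5) * dx - eps)
        c.vertices[:, 1] = np.clip(c.vertices[:, 1], -dy / 2 + eps,
                                   (ny - 0.5) * dy - eps)
    return rois


def _observer_masks(labelmap: LabelMap, slice_index: int, model: ObserverModel,
                    repcx_seed: int, repcx_radius_mm: float):
    """One observer's six ROI masks on the analysis slice."""
    true_masks = define_standard_roi_masks(
        labelmap, slice_index,
        kinds={ROIKind.WK, ROIKind.Cx, ROIKind.Med})
    shape2d = labelmap.shape[1:]
    masks = {}
    contours = []
    for kind in (ROIKind.WK, ROIKind.Cx, ROIKind.Med):
        contours.extend(mask_to_contours(true_masks[kind], labelmap.spacing,
                                         slice_index, kind.value))
    rois = ROISet(contours=contours, spacing=labelmap.spacing,
                  slice_count=labelmap.shape[0])
    drawn = _clip_roiset(perturb_contours(rois, model), shape2d)
    for kind in (ROIKind.WK, ROIKind.Cx, ROIKind.Med):
        masks[kind] = rasterize_roiset(drawn, shape2d, slice_index, kind.value)
    # polar thirds from this observer's own whole-kidney extent
    rows = np.nonzero(masks[ROIKind.WK].any(axis=1))[0]
    if rows.size == 0:
        raise ValueError("observer whole-kidney mask is empty")
    r0, r1 = rows.min(), rows.max()
    third = (r1 - r0 + 1) / 3.0
    sup = np.zeros(shape2d, dtype=bool)
    inf = np.zeros(shape2d, dtype=bool)
    sup[r0:int(np.floor(r0 + third)) + 1] = True
    inf[int(np.ceil(r1 - third)):r1 + 1] = True
    masks[ROIKind.supCx] = masks[ROIKind.Cx] & sup
    masks[ROIKind.infCx] = masks[ROIKind.Cx] & inf
    masks[ROIKind.repCx] = _place_disc(masks[ROIKind.Cx], labelmap.spacing,
                                       repcx_radius_mm, repcx_seed)
    return masks


def simulate_subject(config: StudyConfig, subject_index: int, group: str):
    """Simulate one subject and return its measurement rows.

    Returns (measurement rows, ground-truth row); measurement rows cover the
    per-observer ROI summaries of all acquired sequences plus both volumetry
    protocols.
    """
    subject = f"S{subject_index:03d}"
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), subject_index]))
    try:
        tissue = _draw_tissue(rng, group)
        target_vol = float(np.clip(
            rng.normal(ref.group_mean("volume", "alternate", group),
                       ref.group_sd("volume", "alternate", group)), 60.0, 380.0))
        labelmap = make_kidney_labelmap(config.shape, config.spacing,
                                        seed=_int_seed(rng),
                                        target_volume_ml=target_vol)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("phantom", subject, exc) from exc

    slice_index = int(np.argmax(labelmap.kidney_mask().sum(axis=(1, 2))))
    fit_mask = np.zeros(labelmap.shape, dtype=bool)
    fit_mask[slice_index] = labelmap.kidney_mask(include_pelvis=True)[slice_index]

    want_dwi = group in config.dwi_groups
    try:
        molli = simulate_molli_series(labelmap, tissue, config.ti_ms,
                                      config.noise_sd_molli, _int_seed(rng))
        asl = simulate_asl_set(labelmap, tissue, config.asl,
                               config.noise_sd_asl, _int_seed(rng))
        dwi = (simulate_dwi_series(labelmap, tissue, config.b_values,
                                   config.noise_sd_dwi, _int_seed(rng))
               if want_dwi else None)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", subject, exc) from exc

    try:
        maps = {"T1": fit_t1_map(molli, fit_mask),
                "pCASL": perfusion_map(asl, fit_mask)}
        if dwi is not None:
            maps["ADC"] = fit_adc_map(dwi, fit_mask)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit_maps", subject, exc) from exc

    rows = []
    wk_all = kidney_contours(labelmap)
    # with zero jitter and zero bias the simulated observers are identical
    # readers by construction (same contours, same repCx placement)
    identical_readers = (config.observer_jitter_mm == 0
                         and config.observer_bias_mm == 0)
    for observer in OBSERVERS:
        obs_entropy = 0 if identical_readers else OBSERVERS.index(observer)
        obs_rng = np.random.default_rng(np.random.SeedSequence(
            [int(config.seed), subject_index, obs_entropy]))
        model = ObserverModel(boundary_jitter_mm=config.observer_jitter_mm,
                              bias_mm=config.observer_bias_mm,
                              seed=_int_seed(obs_rng))
        try:
            masks = _observer_masks(labelmap, slice_index, model,
                                    _int_seed(obs_rng), config.repcx_radius_mm)
            for sequence, pmap in maps.items():
                for kind, mask2d in masks.items():
                    m3 = np.zeros(labelmap.shape, dtype=bool)
                    m3[slice_index] = mask2d
                    s = roi_summary(pmap, m3, ddof=config.sd_ddof)
                    scale = 1e6 if sequence == "ADC" else 1.0
                    rows.append({
                        "subject": subject, "group": group,
                        "sequence": sequence, "roi": kind.value,
                        "observer": observer,
                        "value": s.mean * scale, "sd": s.sd * scale,
                        "n_voxels": s.n_voxels,
                        "sd_fraction": s.sd_fraction,
                        "units": ref.SEQUENCE_UNITS[sequence],
                    })
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("roi_stats", subject, exc) from exc
        try:
            drawn = _clip_roiset(perturb_contours(wk_all, model),
                                 labelmap.shape[1:])
            vol_every = volume_every_slice(drawn)
            slices = drawn.slices("WK")
            keep = set(slices[::2]) | {slices[0], slices[-1]}
            alt = ROISet(contours=[c for c in drawn.contours
                                   if c.slice_index in keep],
                         spacing=drawn.spacing, observer_id=observer,
                         slice_count=drawn.slice_count)
            vol_alt = volume_alternate_slice(alt)
            for mode, vol in (("alternate", vol_alt), ("every", vol_every)):
                rows.append({
                    "subject": subject, "group": group,
                    "sequence": "volume", "roi": mode, "observer": observer,
                    "value": vol, "sd": np.nan, "n_voxels": np.nan,
                    "sd_fraction": np.nan, "units": "ml",
                })
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("volumetry", subject, exc) from exc

    truth = {
        "subject": subject, "group": group,
        "t1_cortex_ms": tissue.cortex.t1_ms,
        "t1_medulla_ms": tissue.medulla.t1_ms,
        "adc_cortex": tissue.cortex.adc_mm2_per_s * 1e6,
        "adc_medulla": tissue.medulla.adc_mm2_per_s * 1e6,
        "perfusion_cortex": tissue.cortex.perfusion_ml_per_100g_min,
        "perfusion_medulla": tissue.medulla.perfusion_ml_per_100g_min,
        "kidney_volume_ml": float(labelmap.kidney_mask(True).sum()
                                  * labelmap.voxel_volume_ml()),
        "analysis_slice": slice_index,
    }
    return rows, truth


def run_pipeline(config: StudyConfig | None = None, out_dir=None) -> dict:
    """Run the full cohort simulation and analysis; optionally write CSVs.

    Returns a bundle with the tidy ``measurements`` table, the
    ``repro`` (interobserver) report, pairwise ``group_differences`` of the
    observer-mean values, the ``sd_fractions`` report, per-subject
    ``ground_truth`` and the ``seed_manifest``.
    """
    config = config if config is not None else StudyConfig()
    rows, truths, manifest = [], [], []
    index = 0
    for group in sorted(config.groups):
        for _ in range(config.groups[group]):
            r, t = simulate_subject(config, index, group)
            rows.extend(r)
            truths.append(t)
            manifest.append({"subject": t["subject"], "group": group,
                             "seed_sequence": [int(config.seed), index]})
            index += 1
    measurements = pd.DataFrame(rows).sort_values(
        ["subject", "sequence", "roi", "observer"]).reset_index(drop=True)
    ground_truth = pd.DataFrame(truths)

    df_a = measurements[measurements.observer == "A"]
    df_b = measurements[measurements.observer == "B"]
    repro = repro_report(df_a, df_b).sort_values(
        ["sequence", "roi"]).reset_index(drop=True)

    obs_mean = (measurements
                .groupby(["subject", "group", "sequence", "roi", "units"],
                         as_index=False)["value"].mean())
    group_diffs = group_difference_report(obs_mean).sort_values(
        ["sequence", "roi", "group_a", "group_b"]).reset_index(drop=True)

    maps_only = measurements[measurements.sequence != "volume"].rename(
        columns={"value": "mean"})
    sd_fracs = sd_fraction_report(maps_only).sort_values(
        ["sequence", "roi"]).reset_index(drop=True)

    bundle = {
        "config": config,
        "measurements": measurements,
        "repro": repro,
        "group_differences": group_diffs,
        "sd_fractions": sd_fracs,
        "ground_truth": ground_truth,
        "seed_manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("measurements", "repro", "group_differences",
                     "sd_fractions", "ground_truth"):
            bundle[name].to_csv(out / f"{name}.csv", index=False,
                                float_format="%.6g")
        config.to_json(out / "config.json")
        (out / "seed_manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle
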