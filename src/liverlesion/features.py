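"""Assembly of the full named feature vector per lesion.

Per lesion the pipeline computes:

* 8 kinetic features on each of the four average contrast curves
  (TIC, CEC, CE lesion/parenchyma ratio, TIC lesion/parenchyma ratio) — 32;
* the within-lesion SD of the 8 features over per-pixel CEC curves and
  per-pixel CE-ratio curves (pixel CEC divided by the average parenchyma
  CEC) — 16;
* 6 gray-level histogram statistics on 7 sources: pre-contrast image, TTP
  image, late arterial enhancement image, T2 image, TTP feature map,
  radial-gradient histogram, ring-enhancement histogram — 42;
* 13 Haralick features on 5 images (pre-contrast, TTP, late enhancement,
  T2, TTP map) plus their variance across the whole DCE series — 78;
* 3 binary risk factors and the lesion area in cm².

That enumeration gives 168 image-derived features. The default
``paper164`` inventory drops the four least well defined heterogeneity
descriptors (the SD of the washout rate and of the time of arrival, for
the CEC and the CE-ratio pixel curves) to yield a 164-feature image
inventory; ``full168`` keeps all. Any feature that is uncomputable on a
degenerate ROI (for instance skewness of a flat histogram) is set to 0 and
logged — tree ensembles tolerate such neutral fill-ins.

Phase-index conventions (configurable): the *late arterial enhancement*
frame is the frame after the aortic peak, and the *portal-venous* frame is
the frame nearest 70 s after the aortic time of arrival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DceSeries, PatientRecord
from .curves import (
    CURVE_FEATURE_NAMES,
    DEFAULT_EPSILON,
    TimeCurve,
    cec_from_tic,
    curve_features,
    per_pixel_feature_sd,
    pixel_tics,
    ratio_curve,
    roi_mean_curve,
)
from .maps import (
    HISTOGRAM_STAT_NAMES,
    histogram_stats,
    radial_gradient_values,
    ring_enhancement_values,
    ttp_image_index,
    ttp_map,
)
from .preprocess import (
    DEFAULT_SIGMA_PROFILE,
    DEFAULT_SIGMA_SPATIAL_MM,
    normalize_intensities,
    tips_filter,
)
from .texture import (
    DEFAULT_N_LEVELS,
    HARALICK_FEATURE_NAMES,
    series_feature_variance,
    texture_features,
)

logger = logging.getLogger(__name__)

CURVE_KINDS: tuple[str, ...] = ("tic", "cec", "ce_ratio", "tic_ratio")
SD_CURVE_KINDS: tuple[str, ...] = ("cec", "ce_ratio")
HIST_SOURCES: tuple[str, ...] = (
    "precontrast",
    "ttp_image",
    "late_enhancement",
    "t2",
    "ttp_map",
    "radial_gradient",
    "ring_enhancement",
)
TEXTURE_SOURCES: tuple[str, ...] = (
    "precontrast",
    "ttp_image",
    "late_enhancement",
    "t2",
    "ttp_map",
)
RISK_NAMES: tuple[str, ...] = ("risk.steatosis", "risk.cirrhosis", "risk.primary_tumor")
AREA_NAME = "area_cm2"

#: SD features dropped by the default 164-feature image inventory.
PAPER164_DROPPED: tuple[str, ...] = (
    "curve.cec.sd.washout_rate",
    "curve.cec.sd.time_of_arrival_s",
    "curve.ce_ratio.sd.washout_rate",
    "curve.ce_ratio.sd.time_of_arrival_s",
)

META_COLUMNS: tuple[str, ...] = ("patient_id", "lesion_id", "label")


@dataclass
class ExtractionConfig:
    """All tunable parameters of the feature-extraction pipeline."""

    inventory: str = "paper164"
    epsilon: float = DEFAULT_EPSILON
    sigma_spatial_mm: float = DEFAULT_SIGMA_SPATIAL_MM
    sigma_profile: float = DEFAULT_SIGMA_PROFILE
    n_levels: int = DEFAULT_N_LEVELS
    n_rays: int = 360
    portal_delay_s: float = 70.0
    late_arterial_index: int | None = None  # override; default aorta-TTP + 1
    portal_venous_index: int | None = None  # override; default nearest arrival + delay

    def __post_init__(self) -> None:
        if self.inventory not in ("paper164", "full168"):
            raise ValueError("inventory must be 'paper164' or 'full168'")


def image_feature_names(mode: str = "paper164") -> list[str]:
    """The ordered image-derived feature inventory (164 or 168 names)."""
    names: list[str] = []
    for kind in CURVE_KINDS:
        names += [f"curve.{kind}.{feat}" for feat in CURVE_FEATURE_NAMES]
    for kind in SD_CURVE_KINDS:
        names += [f"curve.{kind}.sd.{feat}" for feat in CURVE_FEATURE_NAMES]
    for src in HIST_SOURCES:
        names += [f"hist.{src}.{stat}" for stat in HISTOGRAM_STAT_NAMES]
    for src in TEXTURE_SOURCES:
        names += [f"glcm.{src}.{feat}" for feat in HARALICK_FEATURE_NAMES]
    names += [f"glcm.series_variance.{feat}" for feat in HARALICK_FEATURE_NAMES]
    if mode == "paper164":
        names = [n for n in names if n not in PAPER164_DROPPED]
    elif mode != "full168":
        raise ValueError("inventory must be 'paper164' or 'full168'")
    return names


def feature_inventory(mode: str = "paper164") -> list[str]:
    """Full inventory: image features plus the 3 risk factors and the area."""
    return image_feature_names(mode) + list(RISK_NAMES) + [AREA_NAME]


def area_feature(mask: np.ndarray, pixel_spacing_mm: tuple[float, float]) -> float:
    """Lesion area in cm²: pixel count times the pixel area."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    sy, sx = pixel_spacing_mm
    return float(mask.sum()) * sy * sx / 100.0


@dataclass
class PreprocessedPatient:
    """Normalized (and TIPS-filtered) series shared by all lesions of a patient."""

    record: PatientRecord
    normalized: DceSeries
    filtered: DceSeries
    aorta_curve: TimeCurve
    late_arterial_index: int
    portal_venous_index: int


def preprocess_patient(record: PatientRecord, config: ExtractionConfig) -> PreprocessedPatient:
    """Normalize to the aortic peak, TIPS-filter, and resolve the phase indices."""
    normalized = normalize_intensities(record.dce, record.aorta_mask)
    filtered = tips_filter(normalized, config.sigma_spatial_mm, config.sigma_profile)
    aorta_curve = roi_mean_curve(filtered, record.aorta_mask, kind="TIC")
    n_frames = normalized.n_timepoints

    if config.late_arterial_index is not None:
        late_idx = config.late_arterial_index
    else:
        aorta_ttp_idx = int(np.argmax(aorta_curve.values))
        late_idx = min(aorta_ttp_idx + 1, n_frames - 1)
    if config.portal_venous_index is not None:
        portal_idx = config.portal_venous_index
    else:
        arrival = curve_features(aorta_curve).time_of_arrival_s
        portal_idx = int(np.argmin(np.abs(normalized.times_s - (arrival + config.portal_delay_s))))

    return PreprocessedPatient(
        record=record,
        normalized=normalized,
        filtered=filtered,
        aorta_curve=aorta_curve,
        late_arterial_index=late_idx,
        portal_venous_index=portal_idx,
    )


def _safe(compute, names: tuple[str, ...] | list[str], context: str) -> dict[str, float]:
    """Run a feature-block computation; on failure fill the block with zeros."""
    try:
        out = compute()
    except Exception as exc:  # degenerate ROI: neutral fill-in
        logger.warning("feature block %s uncomputable (%s); filled with 0", context, exc)
        return {name: 0.0 for name in names}
    return {
        k: (float(v) if np.isfinite(v) else 0.0) if np.ndim(v) == 0 else v
        for k, v in out.items()
    }


def extract_features(
    prep: PreprocessedPatient,
    lesion_id: str,
    config: ExtractionConfig | None = None,
) -> dict[str, float | str]:
    """Compute the full named feature vector of one lesion.

    Returns a flat dict with ``patient_id``, ``lesion_id``, ``label`` and
    every inventory feature, in inventory order.
    """
    if config is None:
        config = ExtractionConfig()
    record = prep.record
    lesion = record.lesion(lesion_id)
    coords = np.argwhere(lesion.mask)
    if (np.ptp(coords[:, 0]) + 1) < 3 or (np.ptp(coords[:, 1]) + 1) < 3:
        raise ValueError(
            f"lesion {lesion_id} smaller than 3x3 pixels; texture features are unreliable"
        )
    eps = config.epsilon
    filtered = prep.filtered
    normalized = prep.normalized
    spacing = filtered.pixel_spacing_mm

    # --- contrast curves ---------------------------------------------------
    lesion_tics = pixel_tics(filtered, lesion.mask)
    paren_tics = pixel_tics(filtered, record.parenchyma_mask)
    avg_tic = roi_mean_curve(filtered, lesion.mask, kind="TIC")
    avg_paren_tic = roi_mean_curve(filtered, record.parenchyma_mask, kind="TIC")

    pixel_cecs = [cec_from_tic(t, t.values[0], eps) for t in lesion_tics]
    paren_cecs = [cec_from_tic(t, t.values[0], eps) for t in paren_tics]
    avg_cec = TimeCurve(
        np.mean([c.values for c in pixel_cecs], axis=0), filtered.times_s, kind="CEC"
    )
    avg_paren_cec = TimeCurve(
        np.mean([c.values for c in paren_cecs], axis=0), filtered.times_s, kind="CEC"
    )
    ce_ratio = ratio_curve(avg_cec, avg_paren_cec, eps, kind="CE_ratio")
    tic_ratio = ratio_curve(avg_tic, avg_paren_tic, eps, kind="TIC_ratio")

    values: dict[str, float] = {}
    for kind, curve in zip(CURVE_KINDS, (avg_tic, avg_cec, ce_ratio, tic_ratio)):
        feats = curve_features(curve).as_dict()
        values.update({f"curve.{kind}.{k}": v for k, v in feats.items()})

    # per-pixel heterogeneity: CEC pixels, and pixel CEC / average parenchyma CEC
    pixel_ratio = [ratio_curve(c, avg_paren_cec, eps, kind="CE_ratio") for c in pixel_cecs]
    for kind, curveset in zip(SD_CURVE_KINDS, (pixel_cecs, pixel_ratio)):
        sds = per_pixel_feature_sd(curveset)
        values.update({f"curve.{kind}.sd.{k}": v for k, v in sds.items()})

    # --- phase images, maps and histograms --------------------------------
    ttp_idx = ttp_image_index(avg_cec)
    ttp_frame = normalized.frame(ttp_idx)
    pre_frame = normalized.frame(0)
    late_frame = normalized.frame(prep.late_arterial_index)
    portal_frame = normalized.frame(prep.portal_venous_index)
    tmap = ttp_map(filtered, lesion.mask, eps)

    radial = _safe(
        lambda: {"values": radial_gradient_values(late_frame, lesion.mask, spacing)},
        ["values"],
        f"{lesion_id}/radial_gradient",
    )["values"]
    ring = _safe(
        lambda: {"values": ring_enhancement_values(portal_frame, lesion.mask, config.n_rays)},
        ["values"],
        f"{lesion_id}/ring_enhancement",
    )["values"]

    hist_inputs: dict[str, np.ndarray] = {
        "precontrast": pre_frame[lesion.mask],
        "ttp_image": ttp_frame[lesion.mask],
        "late_enhancement": late_frame[lesion.mask],
        "t2": record.t2[lesion.mask],
        "ttp_map": tmap[lesion.mask],
        "radial_gradient": np.asarray(radial, dtype=float),
        "ring_enhancement": np.asarray(ring, dtype=float),
    }
    for src in HIST_SOURCES:
        names = [f"hist.{src}.{s}" for s in HISTOGRAM_STAT_NAMES]
        block = _safe(
            lambda src=src: {
                f"hist.{src}.{k}": v
                for k, v in histogram_stats(hist_inputs[src]).as_dict().items()
            },
            names,
            f"{lesion_id}/hist.{src}",
        )
        values.update(block)

    # --- GLCM texture ------------------------------------------------------
    texture_inputs: dict[str, np.ndarray] = {
        "precontrast": pre_frame,
        "ttp_image": ttp_frame,
        "late_enhancement": late_frame,
        "t2": record.t2,
        "ttp_map": tmap,
    }
    for src in TEXTURE_SOURCES:
        names = [f"glcm.{src}.{f}" for f in HARALICK_FEATURE_NAMES]
        block = _safe(
            lambda src=src: {
                f"glcm.{src}.{k}": v
                for k, v in texture_features(
                    texture_inputs[src], lesion.mask, config.n_levels
                ).items()
            },
            names,
            f"{lesion_id}/glcm.{src}",
        )
        values.update(block)
    var_names = [f"glcm.series_variance.{f}" for f in HARALICK_FEATURE_NAMES]
    block = _safe(
        lambda: {
            f"glcm.series_variance.{k}": v
            for k, v in series_feature_variance(normalized, lesion.mask, config.n_levels).items()
        },
        var_names,
        f"{lesion_id}/glcm.series_variance",
    )
    values.update(block)

    # --- risk factors and area ---------------------------------------------
    values["risk.steatosis"] = float(record.risk_factors.get("steatosis", 0))
    values["risk.cirrhosis"] = float(record.risk_factors.get("cirrhosis", 0))
    values["risk.primary_tumor"] = float(record.risk_factors.get("primary_tumor", 0))
    values[AREA_NAME] = area_feature(lesion.mask, spacing)

    row: dict[str, float | str] = {
        "patient_id": record.patient_id,
        "lesion_id": lesion_id,
        "label": lesion.label,
    }
    for name in feature_inventory(config.inventory):
        row[name] = values[name]
    return row


def extract_patient(
    record: PatientRecord, config: ExtractionConfig | None = None
) -> list[dict[str, float | str]]:
    """Extract every lesion of one patient (preprocessing shared across lesions)."""
    if config is None:
        config = ExtractionConfig()
    prep = preprocess_patient(record, config)
    rows = []
    for lesion in record.lesions:
        try:
            rows.append(extract_features(prep, lesion.lesion_id, config))
        except ValueError as exc:
            logger.warning("lesion %s skipped: %s", lesion.lesion_id, exc)
    return rows


def extract_cohort(
    records: list[PatientRecord], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Feature table for a whole cohort: one row per lesion, inventory order."""
    if config is None:
        config = ExtractionConfig()
    rows = [row for record in records for row in extract_patient(record, config)]
    columns = list(META_COLUMNS) + feature_inventory(config.inventory)
    return pd.DataFrame(rows, columns=columns)
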