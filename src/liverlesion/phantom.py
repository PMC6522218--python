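"""Synthetic multi-phase phantom cohorts with liver-lesion class structure.

No public data set exists for focal-liver-lesion classification on DCE-MRI,
so every downstream stage is exercised on phantoms that encode the
qualitative radiological appearance of the five lesion classes:

* **cyst** — no contrast enhancement, very bright on T2;
* **hemangioma** — slow peripheral fill-in: the rim enhances first, the
  centre peaks late;
* **adenoma** — arterial enhancement without washout, patients may have
  steatosis;
* **HCC** — brisk arterial enhancement followed by washout, strongly
  associated with cirrhosis;
* **metastasis** — portal-venous ring enhancement at the lesion margin,
  associated with a known primary tumor.

A phantom "volume" is a single 2D slice (all features are computed on one
annotated slice); the DCE series is 16 frames over 3 minutes by default.
Each voxel follows a piecewise-linear kinetic template — baseline, linear
rise to the peak, linear decline losing ``washout_fraction`` of the peak by
the end of the series — plus white Gaussian noise. The aorta is rendered to
peak higher than any tissue so intensity normalization is well defined;
liver background follows a portal-phase parenchyma template.

Intensities are in arbitrary scanner units of order 1 for the DCE series
and of order 100-1000 for the T2 image (which the pipeline never
normalizes); ``noise_sd`` applies to the DCE units and is scaled by
``T2_NOISE_SCALE`` for the T2 image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import CLASS_ORDER, DceSeries, Lesion, PatientRecord
from .curves import TimeCurve

#: Acquisition grid defaults: 16 frames, 12 s apart, 64x64 px at 1.5 mm.
DEFAULT_TIMES_S = tuple(float(12 * t) for t in range(16))
DEFAULT_GRID_SIZE = 64
DEFAULT_PIXEL_SPACING_MM = 1.5
DEFAULT_NOISE_SD = 0.02
#: T2 intensities live on a ~400x larger scale than normalized DCE units.
T2_NOISE_SCALE = 400.0
T2_BACKGROUND = 250.0
T2_AORTA = 150.0

#: Interior enhancement relative to the rim for ring-pattern lesions.
RING_INTERIOR_DAMPING = 0.35
#: Delay (s) of the centre peak relative to the rim for fill-in lesions.
FILL_IN_CENTRE_DELAY_S = 60.0

SPATIAL_PATTERNS = ("homogeneous", "ring", "fill_in")


@dataclass(frozen=True)
class KineticTemplate:
    """Per-class enhancement kinetics, spatial pattern, T2 brightness and risk priors."""

    class_label: str
    baseline: float
    peak_amplitude: float
    peak_time_s: float
    washout_fraction: float
    spatial_pattern: str
    t2_intensity: float
    risk_priors: dict[str, float] = field(
        default_factory=lambda: {"steatosis": 0.2, "cirrhosis": 0.05, "primary_tumor": 0.1}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.washout_fraction <= 1.0:
            raise ValueError("washout_fraction must lie in [0, 1]")
        if self.spatial_pattern not in SPATIAL_PATTERNS:
            raise ValueError(f"unknown spatial pattern {self.spatial_pattern!r}")
        for key, prob in self.risk_priors.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"risk prior {key} outside [0, 1]")


def default_templates() -> dict[str, KineticTemplate]:
    """The five lesion-class templates plus 'aorta' and 'parenchyma' backgrounds."""
    return {
        "adenoma": KineticTemplate(
            "adenoma", baseline=0.30, peak_amplitude=0.55, peak_time_s=36.0,
            washout_fraction=0.10, spatial_pattern="homogeneous", t2_intensity=330.0,
            risk_priors={"steatosis": 0.2, "cirrhosis": 0.05, "primary_tumor": 0.1},
        ),
        "cyst": KineticTemplate(
            "cyst", baseline=0.28, peak_amplitude=0.0, peak_time_s=36.0,
            washout_fraction=0.0, spatial_pattern="homogeneous", t2_intensity=950.0,
            risk_priors={"steatosis": 0.2, "cirrhosis": 0.05, "primary_tumor": 0.1},
        ),
        "hemangioma": KineticTemplate(
            "hemangioma", baseline=0.30, peak_amplitude=0.60, peak_time_s=120.0,
            washout_fraction=0.10, spatial_pattern="fill_in", t2_intensity=620.0,
            risk_priors={"steatosis": 0.2, "cirrhosis": 0.05, "primary_tumor": 0.1},
        ),
        "hcc": KineticTemplate(
            "hcc", baseline=0.30, peak_amplitude=0.65, peak_time_s=36.0,
            washout_fraction=0.55, spatial_pattern="homogeneous", t2_intensity=380.0,
            risk_priors={"steatosis": 0.2, "cirrhosis": 0.8, "primary_tumor": 0.1},
        ),
        "metastasis": KineticTemplate(
            "metastasis", baseline=0.30, peak_amplitude=0.55, peak_time_s=72.0,
            washout_fraction=0.15, spatial_pattern="ring", t2_intensity=450.0,
            risk_priors={"steatosis": 0.2, "cirrhosis": 0.05, "primary_tumor": 0.9},
        ),
        # non-lesion tissue templates
        "aorta": KineticTemplate(
            "hcc", baseline=0.25, peak_amplitude=1.35, peak_time_s=24.0,
            washout_fraction=0.35, spatial_pattern="homogeneous", t2_intensity=T2_AORTA,
        ),
        "parenchyma": KineticTemplate(
            "hcc", baseline=0.30, peak_amplitude=0.35, peak_time_s=72.0,
            washout_fraction=0.10, spatial_pattern="homogeneous", t2_intensity=T2_BACKGROUND,
        ),
    }


def scale_separation(
    templates: dict[str, KineticTemplate], factor: float
) -> dict[str, KineticTemplate]:
    """Shrink between-class contrast by pulling lesion templates toward their mean.

    ``factor=1`` returns the templates unchanged; ``factor=0`` collapses all
    five lesion classes onto a common average appearance (kinetics and T2).
    Used to study how classification accuracy depends on class separability.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("factor must lie in [0, 1]")
    if factor == 1.0:
        return dict(templates)
    lesion_keys = [k for k in templates if k in CLASS_ORDER]
    means = {
        attr: float(np.mean([getattr(templates[k], attr) for k in lesion_keys]))
        for attr in ("baseline", "peak_amplitude", "peak_time_s", "washout_fraction", "t2_intensity")
    }
    out = dict(templates)
    for k in lesion_keys:
        t = templates[k]
        out[k] = replace(
            t,
            **{
                attr: means[attr] + factor * (getattr(t, attr) - means[attr])
                for attr in means
            },
        )
    return out


@dataclass
class PhantomConfig:
    """Cohort composition, acquisition grid, noise level and seed."""

    n_patients: int = 50
    lesions_per_patient: tuple[int, int] = (1, 4)
    class_mix: dict[str, float] = field(
        default_factory=lambda: {k: 0.2 for k in CLASS_ORDER}
    )
    grid_size: int = DEFAULT_GRID_SIZE
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    times_s: tuple[float, ...] = DEFAULT_TIMES_S
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_mix:
            raise ValueError("class_mix must not be empty")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix proportions must sum to 1 (got {total:g})")
        if len(self.times_s) < 3:
            raise ValueError("need at least 3 time points")
        if any(b <= a for a, b in zip(self.times_s, self.times_s[1:])):
            raise ValueError("time stamps must be strictly increasing")
        lo, hi = self.lesions_per_patient
        if not 1 <= lo <= hi <= 4:
            raise ValueError("lesions_per_patient must be a range within 1..4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def kinetic_curve(
    template: KineticTemplate,
    times_s: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TimeCurve:
    """Evaluate a kinetic template at the given times, with optional noise.

    Piecewise-linear: baseline at the first time point, linear rise to
    ``baseline + peak_amplitude`` at ``peak_time_s``, then linear decline to
    ``baseline + peak_amplitude * (1 - washout_fraction)`` at the final time.
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    values = _template_values(template, times_s)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return TimeCurve(values, times_s, kind="TIC")


def _template_values(template: KineticTemplate, times_s: np.ndarray) -> np.ndarray:
    t0, t_end = times_s[0], times_s[-1]
    if template.peak_amplitude == 0.0:
        return np.full_like(times_s, template.baseline)
    t_peak = min(max(template.peak_time_s, t0), t_end)
    peak = template.baseline + template.peak_amplitude
    final = template.baseline + template.peak_amplitude * (1.0 - template.washout_fraction)
    values = np.empty_like(times_s)
    rising = times_s <= t_peak
    if t_peak > t0:
        values[rising] = template.baseline + (template.peak_amplitude) * (
            (times_s[rising] - t0) / (t_peak - t0)
        )
    else:
        values[rising] = peak
    if t_end > t_peak:
        values[~rising] = peak + (final - peak) * ((times_s[~rising] - t_peak) / (t_end - t_peak))
    return values


def _disk(grid_size: int, center: tuple[int, int], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:grid_size, :grid_size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _lesion_regions(mask: np.ndarray, pattern: str) -> tuple[np.ndarray, np.ndarray]:
    """Split a lesion mask into (rim, interior) according to its spatial pattern.

    For ``ring`` lesions the enhancing rim straddles the mask boundary and
    extends two pixels beyond it (portal-venous rim enhancement sits at the
    lesion margin); for ``fill_in`` the rim is the outermost ~1.5 px layer
    inside the mask. ``homogeneous`` lesions have an empty rim.
    """
    if pattern == "homogeneous":
        return np.zeros_like(mask), mask
    eroded = ndimage.binary_erosion(mask, iterations=2)
    if pattern == "fill_in":
        rim = mask & ~eroded
        return rim, eroded
    # ring: rim outside the mask (dilation band); the whole mask is interior
    rim = ndimage.binary_dilation(mask, iterations=2) & ~mask
    return rim, mask


def render_patient(
    config: PhantomConfig,
    class_labels: list[str],
    templates: dict[str, KineticTemplate] | None = None,
    rng: np.random.Generator | None = None,
    patient_id: str = "P000",
) -> PatientRecord:
    """Render one patient: DCE series, T2 image, masks, risk flags.

    ``class_labels`` gives the lesion classes to place (one lesion each).
    Lesions are non-overlapping disks of radius 4-7 px in the liver region;
    the aorta and the healthy-parenchyma reference ROI sit at fixed
    locations. All lesion voxels follow their class kinetic template with
    the class's spatial pattern; risk flags are drawn from the class priors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if templates is None:
        templates = default_templates()
    g = config.grid_size
    times = np.asarray(config.times_s, dtype=float)
    spacing = (config.pixel_spacing_mm, config.pixel_spacing_mm)

    aorta_mask = _disk(g, (8, 8), 3.2)
    parenchyma_mask = _disk(g, (12, g - 14), 5.2)

    # place non-overlapping lesion disks away from the aorta/parenchyma ROIs
    occupied = ndimage.binary_dilation(aorta_mask | parenchyma_mask, iterations=4)
    lesions: list[Lesion] = []
    lesion_voxel_curves: list[tuple[np.ndarray, np.ndarray]] = []  # (mask, (T,) curve)
    for idx, label in enumerate(class_labels):
        template = templates[label]
        placed = False
        for attempt in range(400):
            radius = 4.0 if attempt >= 150 else float(rng.integers(4, 8))
            margin = int(radius) + 3
            cy = int(rng.integers(20, g - margin))
            cx = int(rng.integers(margin, g - margin))
            mask = _disk(g, (cy, cx), radius)
            halo = ndimage.binary_dilation(mask, iterations=3)
            if not (halo & occupied).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {idx} on a {g}x{g} grid; reduce lesion count or radius"
            )
        occupied |= halo
        coords = np.argwhere(mask)
        if (np.ptp(coords[:, 0]) + 1) < 3 or (np.ptp(coords[:, 1]) + 1) < 3:
            raise RuntimeError("generated lesion smaller than 3x3 pixels")
        lesions.append(Lesion(mask=mask, label=label, lesion_id=f"{patient_id}_L{idx}"))

        rim, interior = _lesion_regions(mask, template.spatial_pattern)
        rim_curve = _template_values(template, times)
        if template.spatial_pattern == "ring":
            interior_template = replace(
                template, peak_amplitude=template.peak_amplitude * RING_INTERIOR_DAMPING
            )
            interior_curve = _template_values(interior_template, times)
        elif template.spatial_pattern == "fill_in":
            interior_template = replace(
                template,
                peak_time_s=min(template.peak_time_s + FILL_IN_CENTRE_DELAY_S, times[-1]),
            )
            interior_curve = _template_values(interior_template, times)
        else:
            interior_curve = rim_curve
        lesion_voxel_curves.append((interior, interior_curve))
        if rim.any():
            lesion_voxel_curves.append((rim, rim_curve))

    # background tissue, aorta, then lesions painted on top
    data = np.empty((len(times), g, g), dtype=float)
    data[:] = _template_values(templates["parenchyma"], times)[:, None, None]
    data[:, aorta_mask] = _template_values(templates["aorta"], times)[:, None]
    for region, curve in lesion_voxel_curves:
        data[:, region] = curve[:, None]
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)

    t2 = np.full((g, g), T2_BACKGROUND)
    t2[aorta_mask] = T2_AORTA
    for lesion in lesions:
        t2[lesion.mask] = templates[lesion.label].t2_intensity
    if config.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, config.noise_sd * T2_NOISE_SCALE, size=t2.shape)

    # patient-level risk flags: the prior for each flag is the maximum over
    # the patient's lesion classes (a metastasis patient has a primary tumor
    # with high probability regardless of coexisting lesions)
    priors = {
        key: max(templates[lesion.label].risk_priors.get(key, 0.0) for lesion in lesions)
        for key in ("steatosis", "cirrhosis", "primary_tumor")
    }
    risk = {key: int(rng.random() < p) for key, p in priors.items()}

    return PatientRecord(
        patient_id=patient_id,
        dce=DceSeries(data, times, spacing),
        t2=t2,
        lesions=lesions,
        parenchyma_mask=parenchyma_mask,
        aorta_mask=aorta_mask,
        risk_factors=risk,
    )


def _allocate_class_labels(
    n_lesions: int, class_mix: dict[str, float], rng: np.random.Generator
) -> list[str]:
    """Largest-remainder allocation of lesion classes, then a shuffle."""
    classes = [c for c in CLASS_ORDER if class_mix.get(c, 0.0) > 0]
    raw = np.array([class_mix[c] * n_lesions for c in classes])
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder, kind="stable")[: n_lesions - counts.sum()]:
        counts[idx] += 1
    labels = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(labels)
    return labels


def generate_cohort(
    config: PhantomConfig, templates: dict[str, KineticTemplate] | None = None
) -> list[PatientRecord]:
    """Generate ``config.n_patients`` reproducible patient records.

    Lesion counts per patient are uniform over ``lesions_per_patient``;
    class labels across the cohort follow ``class_mix`` up to rounding
    (largest-remainder allocation). Everything is a pure function of
    ``config.seed``.
    """
    if config.n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lesions_per_patient
    lesion_counts = rng.integers(lo, hi + 1, size=config.n_patients)
    labels = _allocate_class_labels(int(lesion_counts.sum()), config.class_mix, rng)
    records = []
    cursor = 0
    for p in range(config.n_patients):
        k = int(lesion_counts[p])
        patient_labels = labels[cursor : cursor + k]
        cursor += k
        child = np.random.default_rng(rng.integers(2**31))
        records.append(
            render_patient(
                config,
                patient_labels,
                templates=templates,
                rng=child,
                patient_id=f"P{p:03d}",
            )
        )
    return records
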