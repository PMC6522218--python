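"""Shared containers, class order and error types.

The five lesion classes are kept in a single fixed order everywhere:
confusion matrices, probability vectors and reports all use
``CLASS_ORDER``. Benign = adenoma/cyst/hemangioma, malignant =
HCC/metastasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_ORDER: tuple[str, ...] = ("adenoma", "cyst", "hemangioma", "hcc", "metastasis")
BENIGN_CLASSES: tuple[str, ...] = ("adenoma", "cyst", "hemangioma")
MALIGNANT_CLASSES: tuple[str, ...] = ("hcc", "metastasis")


class LiverLesionError(Exception):
    """Base class for package errors."""


class DegenerateSeriesError(LiverLesionError):
    """Raised when intensity normalization is impossible (aortic peak <= background)."""


class NoPairsError(LiverLesionError):
    """Raised when a mask admits no co-occurrence pixel pairs."""


class CohortLoadError(LiverLesionError):
    """Raised when a cohort manifest or its referenced files are invalid."""


@dataclass
class DceSeries:
    """A motion-corrected dynamic contrast-enhanced series on a fixed 2D grid.

    Parameters
    ----------
    data
        Array of shape ``(T, H, W)``: one intensity image per acquisition
        time point.
    times_s
        Strictly increasing acquisition times in seconds, length ``T``.
    pixel_spacing_mm
        In-plane pixel spacing ``(row, col)`` in millimetres.
    """

    data: np.ndarray
    times_s: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, H, W) data, got shape {self.data.shape}")
        if self.data.shape[0] != self.times_s.shape[0]:
            raise ValueError("number of frames does not match number of time stamps")
        if self.data.shape[0] < 3:
            raise ValueError("a DCE series needs at least 3 time points")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("acquisition times must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frame(self, index: int) -> np.ndarray:
        return self.data[index]


def validate_mask(mask: np.ndarray, grid_shape: tuple[int, int], *, name: str = "mask") -> np.ndarray:
    """Return ``mask`` as a boolean array after checking bounds and non-emptiness."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(grid_shape):
        raise ValueError(f"{name} shape {mask.shape} does not match grid {grid_shape}")
    if not mask.any():
        raise ValueError(f"{name} is empty")
    return mask


@dataclass
class Lesion:
    """A single annotated lesion: binary mask on the series grid plus its label."""

    mask: np.ndarray
    label: str
    lesion_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass
class PatientRecord:
    """All per-patient inputs the feature pipeline reads.

    ``dce`` holds raw (unnormalized) intensities; ``t2`` keeps its original
    intensity scale by design. Risk factors are patient-level binary flags.
    """

    patient_id: str
    dce: DceSeries
    t2: np.ndarray
    lesions: list[Lesion]
    parenchyma_mask: np.ndarray
    aorta_mask: np.ndarray
    risk_factors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = self.dce.shape
        self.t2 = np.asarray(self.t2, dtype=float)
        if self.t2.shape != grid:
            raise ValueError("T2 image shape does not match DCE grid")
        self.parenchyma_mask = validate_mask(self.parenchyma_mask, grid, name="parenchyma_mask")
        self.aorta_mask = validate_mask(self.aorta_mask, grid, name="aorta_mask")
        for lesion in self.lesions:
            lesion.mask = validate_mask(lesion.mask, grid, name=f"lesion {lesion.lesion_id}")
        for key in ("steatosis", "cirrhosis", "primary_tumor"):
            self.risk_factors.setdefault(key, 0)

    def lesion(self, lesion_id: str) -> Lesion:
        for lesion in self.lesions:
            if lesion.lesion_id == lesion_id:
                return lesion
        raise KeyError(f"no lesion {lesion_id!r} in patient {self.patient_id!r}")
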