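"""Intensity standardization and TIPS bilateral smoothing of DCE series.

Two steps run before any curve is extracted:

1. :func:`normalize_intensities` linearly remaps the whole series so the
   scanner background maps to 0 and the contrast-agent peak of the aortic
   ROI mean curve maps to exactly 1. Values above the aortic peak are left
   above 1 (no clamping).
2. :func:`tips_filter` smooths each voxel's time-intensity profile with a
   bilateral filter whose range term compares whole time profiles (TIPS:
   time-intensity-profile similarity): the weight of a neighbouring voxel
   is a Gaussian in its spatial distance times a Gaussian in the Euclidean
   distance between the two full profiles, so voxels with similar kinetics
   are averaged while enhancing/non-enhancing boundaries are preserved.

T2-weighted images are deliberately passed through unnormalized: their
absolute intensity (e.g. a cyst brighter than spinal fluid) is itself
diagnostic.
"""

from __future__ import annotations

import math

import numpy as np

from .core import DceSeries, DegenerateSeriesError, validate_mask

#: Default spatial bandwidth of the TIPS kernel (mm).
DEFAULT_SIGMA_SPATIAL_MM = 2.0
#: Default profile-distance bandwidth of the TIPS kernel (normalized units).
DEFAULT_SIGMA_PROFILE = 0.15


def normalize_intensities(
    series: DceSeries,
    aorta_mask: np.ndarray,
    *,
    background: float = 0.0,
) -> DceSeries:
    """Remap intensities linearly so background -> 0 and the aortic peak -> 1.

    The aortic peak ``P`` is the maximum over time of the mean intensity
    inside ``aorta_mask``; the output is ``(x - background) / (P - background)``.

    Raises
    ------
    DegenerateSeriesError
        If the aortic peak does not exceed the background level.
    """
    aorta_mask = validate_mask(aorta_mask, series.shape, name="aorta_mask")
    aorta_curve = series.data[:, aorta_mask].mean(axis=1)
    peak = float(aorta_curve.max())
    if peak <= background:
        raise DegenerateSeriesError(
            f"aortic peak ({peak:g}) does not exceed background ({background:g})"
        )
    scaled = (series.data - background) / (peak - background)
    return DceSeries(scaled, series.times_s.copy(), series.pixel_spacing_mm)


def tips_filter(
    series: DceSeries,
    sigma_spatial_mm: float = DEFAULT_SIGMA_SPATIAL_MM,
    sigma_profile: float = DEFAULT_SIGMA_PROFILE,
) -> DceSeries:
    """Smooth a DCE series with the time-intensity-profile-similarity bilateral filter.

    Every voxel's full profile is replaced by a weighted average of the
    profiles in a square window of half-width
    ``ceil(2 * sigma_spatial_mm / min(pixel_spacing_mm))`` pixels; the window
    shrinks at image borders. The weight of neighbour ``q`` relative to
    centre ``p`` is::

        exp(-d_mm(p, q)^2 / (2 sigma_spatial^2))
        * exp(-||I_p - I_q||^2 / (2 sigma_profile^2))

    with ``||I_p - I_q||`` the Euclidean distance between the two whole
    time profiles. Weights are normalized to sum to one per voxel, so a
    spatially constant series is reproduced exactly.
    """
    if sigma_spatial_mm <= 0 or sigma_profile <= 0:
        raise ValueError("TIPS sigmas must be positive")
    data = series.data
    n_t, height, width = data.shape
    sy, sx = series.pixel_spacing_mm
    half_width = int(math.ceil(2.0 * sigma_spatial_mm / min(sy, sx)))

    weighted = np.zeros_like(data)
    weight_sum = np.zeros((height, width))
    inv_2ss = 1.0 / (2.0 * sigma_spatial_mm**2)
    inv_2sp = 1.0 / (2.0 * sigma_profile**2)

    for dy in range(-half_width, half_width + 1):
        y0, y1 = max(0, -dy), height - max(0, dy)
        if y0 >= y1:
            continue
        for dx in range(-half_width, half_width + 1):
            x0, x1 = max(0, -dx), width - max(0, dx)
            if x0 >= x1:
                continue
            centre = data[:, y0:y1, x0:x1]
            neighbour = data[:, y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            profile_d2 = ((centre - neighbour) ** 2).sum(axis=0)
            dist2_mm = (dy * sy) ** 2 + (dx * sx) ** 2
            w = np.exp(-dist2_mm * inv_2ss - profile_d2 * inv_2sp)
            weighted[:, y0:y1, x0:x1] += w * neighbour
            weight_sum[y0:y1, x0:x1] += w

    smoothed = weighted / weight_sum
    return DceSeries(smoothed, series.times_s.copy(), series.pixel_spacing_mm)
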