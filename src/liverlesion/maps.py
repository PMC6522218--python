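"""TTP image selection, TTP feature maps, and the spatial enhancement histograms.

Three spatial descriptors complement the purely temporal curve features:

* the **TTP feature map** — the per-voxel time (seconds) at which the
  voxel's contrast-enhancement curve peaks; peripheral-fill-in lesions
  (hemangiomas) show a rim that peaks earlier than the centre;
* the **radial gradient histogram** — per voxel, the intensity difference
  to the lesion's central voxel multiplied by the distance to that voxel,
  min-max normalized to [0, 1]; it summarizes how spherically the late
  arterial enhancement is organized;
* the **ring enhancement histogram** — per radial direction, the position
  (normalized by the distance to the mask edge) of the strongest intensity
  transition in the portal-venous image, searched out to two pixels beyond
  the mask edge; a mean near 1 signals a bright enhancing rim at the
  lesion boundary (typical for metastases), and a high SD signals
  heterogeneous enhancement.

All three feed the same six gray-level histogram statistics as the image
histograms (mean, SD, skewness, kurtosis, 10th/90th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import DceSeries, validate_mask
from .curves import DEFAULT_EPSILON, TimeCurve

DEFAULT_N_RAYS = 360
#: Ray sampling step, pixels (half-pixel with linear interpolation).
RAY_STEP_PX = 0.5
#: Search margin beyond the mask edge, pixels.
RING_MARGIN_PX = 2.0


@dataclass
class HistogramStats:
    """Six gray-level histogram statistics of a value sample."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    p10: float
    p90: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "p10": self.p10,
            "p90": self.p90,
        }


HISTOGRAM_STAT_NAMES: tuple[str, ...] = ("mean", "sd", "skewness", "kurtosis", "p10", "p90")


def ttp_image_index(avg_cec: TimeCurve) -> int:
    """Index of the frame where the lesion's average CEC peaks (earliest tie)."""
    return int(np.argmax(avg_cec.values))


def ttp_map(
    series: DceSeries, mask: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Per-voxel time to peak (seconds) of the pixel CEC, as a 2D map.

    Returns an (H, W) float array holding the TTP in seconds inside the
    mask and 0 elsewhere. Ties resolve to the earliest time; a constant
    voxel profile therefore maps to ``times[0]``.
    """
    mask = validate_mask(mask, series.shape)
    profiles = series.data[:, mask]  # (T, n)
    pre = np.maximum(profiles[0], epsilon)
    cec = profiles / pre
    peak_times = series.times_s[np.argmax(cec, axis=0)]
    out = np.zeros(series.shape, dtype=float)
    out[mask] = peak_times
    return out


def central_pixel(mask: np.ndarray) -> tuple[int, int]:
    """The masked pixel nearest the mask centroid (the centroid itself may be outside)."""
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    nearest = coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))]
    return int(nearest[0]), int(nearest[1])


def radial_gradient_values(
    image: np.ndarray,
    mask: np.ndarray,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    center: tuple[int, int] | None = None,
) -> np.ndarray:
    """Distance-weighted intensity deviation from the central voxel, min-max scaled.

    For every masked voxel ``v`` the raw value is
    ``(I(v) - I(c)) * dist_mm(v, c)`` with ``c`` the central pixel; the raw
    values are then min-max normalized to [0, 1]. A homogeneous lesion
    yields all zeros.
    """
    image = np.asarray(image, dtype=float)
    mask = validate_mask(mask, image.shape)
    coords = np.argwhere(mask)
    if coords.shape[0] < 2:
        raise ValueError("radial gradient needs a mask with at least 2 pixels")
    cy, cx = center if center is not None else central_pixel(mask)
    sy, sx = pixel_spacing_mm
    dist = np.hypot((coords[:, 0] - cy) * sy, (coords[:, 1] - cx) * sx)
    raw = (image[coords[:, 0], coords[:, 1]] - image[cy, cx]) * dist
    span = raw.max() - raw.min()
    if span == 0:
        return np.zeros_like(raw)
    return (raw - raw.min()) / span


def ring_enhancement_values(
    image: np.ndarray,
    mask: np.ndarray,
    n_rays: int = DEFAULT_N_RAYS,
) -> np.ndarray:
    """Normalized radial position of the strongest intensity transition per direction.

    From the central pixel, ``n_rays`` equally spaced rays are cast. Along
    each ray the image is sampled every half pixel (bilinear interpolation)
    out to the mask edge plus two pixels, truncated at the image border.
    The sample with the maximum absolute first derivative (forward
    difference) marks the enhancement transition; its distance from the
    centre divided by the distance to the mask edge, clipped to [0, 1], is
    that ray's value. Rim enhancement at the lesion boundary therefore
    scores ~1 on every ray.
    """
    image = np.asarray(image, dtype=float)
    mask = validate_mask(mask, image.shape)
    coords = np.argwhere(mask)
    h_span = coords[:, 0].max() - coords[:, 0].min() + 1
    w_span = coords[:, 1].max() - coords[:, 1].min() + 1
    if h_span < 3 or w_span < 3:
        raise ValueError("ring enhancement needs a mask of at least 3x3 pixels")
    height, width = image.shape
    cy, cx = central_pixel(mask)

    max_r = float(np.hypot(height, width))
    dists = np.arange(0.0, max_r + RAY_STEP_PX, RAY_STEP_PX)  # (n_d,)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    dy = np.sin(angles)[:, None] * dists[None, :]
    dx = np.cos(angles)[:, None] * dists[None, :]
    ys = cy + dy  # (n_rays, n_d)
    xs = cx + dx

    # nearest-pixel mask membership; samples outside the grid count as outside
    yi = np.clip(np.rint(ys).astype(int), 0, height - 1)
    xi = np.clip(np.rint(xs).astype(int), 0, width - 1)
    on_grid = (ys >= -0.5) & (ys < height - 0.5) & (xs >= -0.5) & (xs < width - 0.5)
    inside = mask[yi, xi] & on_grid

    # first exit from the mask per ray -> distance to the mask edge
    first_out = np.argmin(inside, axis=1)  # first False (inside[:,0] is True)
    edge_dist = dists[np.maximum(first_out - 1, 1)]
    total_dist = edge_dist + RING_MARGIN_PX

    in_image = (ys >= 0) & (ys <= height - 1) & (xs >= 0) & (xs <= width - 1)
    samples = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")

    deriv = np.abs(np.diff(samples, axis=1))
    # a derivative sample at index i spans dists[i]..dists[i+1]; keep those
    # whose far end lies within the ray (edge + margin) and inside the grid
    valid = (dists[None, 1:] <= total_dist[:, None]) & in_image[:, 1:] & in_image[:, :-1]
    deriv = np.where(valid, deriv, -np.inf)
    best = np.argmax(deriv, axis=1)
    transition_dist = dists[best + 1]  # distance of the pixel reached by the jump
    return np.clip(transition_dist / edge_dist, 0.0, 1.0)


def histogram_stats(values: np.ndarray) -> HistogramStats:
    """Mean, sample SD, skewness, excess kurtosis and 10th/90th percentiles.

    Skewness and kurtosis use the population-moment (biased) estimators;
    both are defined as 0 for a constant sample. Percentiles use linear
    interpolation.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("histogram statistics need at least 2 values")
    sd = float(values.std(ddof=1))
    if values.max() == values.min():
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(values, bias=True))
        kurt = float(stats.kurtosis(values, fisher=True, bias=True))
    p10, p90 = np.percentile(values, [10, 90], method="linear")
    return HistogramStats(
        mean=float(values.mean()),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        p10=float(p10),
        p90=float(p90),
    )
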