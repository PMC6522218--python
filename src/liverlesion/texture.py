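"""Gray-level co-occurrence texture: quantization, summed GLCM, Haralick features.

The GLCM is accumulated over the four principal directions (0°, 45°, 90°,
135°) at an offset of one pixel, symmetrically (each offset and its
negation), restricted to pixel pairs that both lie inside the ROI mask,
then normalized to sum to one. From the normalized matrix the 13 classical
Haralick statistics are computed with logarithms in base 2 and the
convention ``0 * log(0) = 0``.

Notes on the less standardized definitions (documented so tests are exact):

* *sum variance* is the variance of the ``p_{x+y}`` distribution about the
  sum average (the frequently used correction of the original circular
  definition);
* *difference variance* is the variance of the ``p_{x-y}`` distribution
  about its own mean;
* IMC1/IMC2 use the entropies HX, HY, HXY, HXY1, HXY2 in bits, with
  ``IMC2 = sqrt(max(0, 1 - 2^(-2 (HXY2 - HXY))))`` (clamped before the
  square root to absorb rounding);
* correlation is defined as 0 when either marginal is degenerate.

Intensities are quantized into ``n_levels`` equal-width bins over the ROI's
own min-max range (ROI-local, because T2 intensities are deliberately not
normalized); a flat ROI maps entirely to level 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DceSeries, NoPairsError, validate_mask

HARALICK_FEATURE_NAMES: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "entropy",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

DEFAULT_N_LEVELS = 32

# (row, col) offsets for 0, 45, 90 and 135 degrees at distance 1
_DIRECTION_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class Glcm:
    """A normalized, symmetric gray-level co-occurrence matrix."""

    matrix: np.ndarray
    n_levels: int
    normalized: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n_levels, self.n_levels):
            raise ValueError("GLCM shape does not match the level count")


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int = DEFAULT_N_LEVELS) -> np.ndarray:
    """Bin ROI intensities into ``n_levels`` equal-width gray levels.

    Returns an integer label image (0 outside the mask). The top of the
    range is assigned to the highest level; a flat ROI maps to level 0.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    image = np.asarray(image, dtype=float)
    mask = validate_mask(mask, image.shape)
    roi = image[mask]
    lo, hi = roi.min(), roi.max()
    labels = np.zeros(image.shape, dtype=np.intp)
    if hi > lo:
        width = (hi - lo) / n_levels
        labels[mask] = np.minimum(
            ((image[mask] - lo) / width).astype(np.intp), n_levels - 1
        )
    return labels


def glcm_summed(labels: np.ndarray, mask: np.ndarray, n_levels: int = DEFAULT_N_LEVELS) -> Glcm:
    """Sum symmetric co-occurrence counts over the four directions and normalize.

    Only pairs with both pixels inside the mask are counted.

    Raises
    ------
    NoPairsError
        If the mask admits no neighbouring pixel pair in any direction.
    """
    labels = np.asarray(labels)
    mask = validate_mask(mask, labels.shape)
    height, width = labels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for dy, dx in _DIRECTION_OFFSETS:
        y0, y1 = max(0, -dy), height - max(0, dy)
        x0, x1 = max(0, -dx), width - max(0, dx)
        if y0 >= y1 or x0 >= x1:
            continue
        a = labels[y0:y1, x0:x1]
        b = labels[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        pair_ok = mask[y0:y1, x0:x1] & mask[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        np.add.at(counts, (a[pair_ok], b[pair_ok]), 1.0)
    counts = counts + counts.T  # symmetric accumulation (offset and its negation)
    total = counts.sum()
    if total == 0:
        raise NoPairsError("mask admits no co-occurring pixel pairs")
    return Glcm(counts / total, n_levels=n_levels)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick(glcm: Glcm) -> dict[str, float]:
    """The 13 Haralick texture statistics of a normalized GLCM (see module notes)."""
    p = glcm.matrix
    n = glcm.n_levels
    i = np.arange(n)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 0..2n-2  and  p_{x-y}(k), k = 0..n-1
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(2 * n - 1)
    k_diff = np.arange(n)

    asm = float((p**2).sum())
    contrast = float((k_diff**2 * p_diff).sum())
    if sigma_x > 0 and sigma_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sigma_x * sigma_y))
    else:
        correlation = 0.0
    ssq_variance = float((((ii - mu_x) ** 2) * p).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    entropy = _entropy_bits(p.ravel())
    sum_entropy = _entropy_bits(p_sum)
    mu_diff = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - mu_diff) ** 2 * p_diff).sum())
    difference_entropy = _entropy_bits(p_diff)

    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    outer = np.outer(px, py)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    hxy2 = _entropy_bits(outer.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy)))))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares_variance": ssq_variance,
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "entropy": entropy,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def texture_features(
    image: np.ndarray, mask: np.ndarray, n_levels: int = DEFAULT_N_LEVELS
) -> dict[str, float]:
    """Quantize, build the summed GLCM and return the 13 Haralick features."""
    labels = quantize(image, mask, n_levels)
    return haralick(glcm_summed(labels, mask, n_levels))


def series_feature_variance(
    series: DceSeries, mask: np.ndarray, n_levels: int = DEFAULT_N_LEVELS
) -> dict[str, float]:
    """Population variance of each Haralick feature across the DCE frames.

    Each frame is quantized on its own ROI range before its GLCM is built,
    so the variance reflects changing texture, not changing gain.
    """
    if series.n_timepoints < 2:
        raise ValueError("series feature variance needs at least 2 frames")
    per_frame = np.array(
        [
            [texture_features(series.frame(t), mask, n_levels)[name] for name in HARALICK_FEATURE_NAMES]
            for t in range(series.n_timepoints)
        ]
    )
    variances = per_frame.var(axis=0, ddof=0)
    return dict(zip(HARALICK_FEATURE_NAMES, variances.tolist()))
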