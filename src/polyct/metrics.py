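"""Image-quality metrics: MSE, NMSD, region statistics and line profiles.

NMSD is the classical normalized mean square distance,

    NMSD = sqrt( sum (f - g)^2 / sum (g - mean(g))^2 ),

with g the reference image: 0 for identical images, 1 for an image that is
everywhere the reference mean.  Region statistics are taken over label
masks eroded away from the boundaries, where reconstruction edge blur would
otherwise bias the means; line profiles through the phantom are the
standard visual check for cupping (concave profiles) and streaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RegionReport", "mse", "nmsd", "region_stats", "line_profile"]


def _check_shapes(image, reference):
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")
    return image, reference


def mse(image, reference) -> float:
    """Mean squared error over all pixels."""
    image, reference = _check_shapes(image, reference)
    return float(np.mean((image - reference) ** 2))


def nmsd(image, reference) -> float:
    """Normalized mean square distance (reference must be non-constant)."""
    image, reference = _check_shapes(image, reference)
    denom = float(np.sum((reference - reference.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("NMSD undefined for a constant reference image")
    return float(np.sqrt(np.sum((image - reference) ** 2) / denom))


@dataclass(frozen=True)
class RegionReport:
    """Per-label interior statistics of an image.

    ``regions`` maps label -> dict(mean, sd, n); ``erosion_px`` records the
    margin stripped from each label mask before averaging.
    """

    regions: dict
    erosion_px: int

    def mean(self, label: int) -> float:
        return self.regions[label]["mean"]


def region_stats(image, labels, erosion_px: int = 2,
                 include_labels=None) -> RegionReport:
    """Mean/sd/count of an image over eroded per-label masks.

    Each label's mask is binary-eroded ``erosion_px`` times so boundary
    pixels (partial-volume and edge-blur contaminated) are excluded.
    Raises if erosion empties a requested region.
    """
    image = np.asarray(image, float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and labels must have the same shape")
    if include_labels is None:
        include_labels = sorted(np.unique(labels))
    regions = {}
    for lab in include_labels:
        mask = labels == lab
        if erosion_px > 0:
            mask = ndimage.binary_erosion(mask, iterations=erosion_px)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"label {lab}: eroded region is empty")
        vals = image[mask]
        regions[int(lab)] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std()),
            "n": n,
        }
    return RegionReport(regions=regions, erosion_px=erosion_px)


def line_profile(image, index: int | None = None, axis: str = "h") -> np.ndarray:
    """1-D profile through the image: row (axis='h') or column (axis='v').

    Defaults to the central line, the usual cut through a centred phantom.
    """
    image = np.asarray(image, float)
    if index is None:
        index = image.shape[0] // 2 if axis == "h" else image.shape[1] // 2
    if axis == "h":
        return image[index, :].copy()
    if axis == "v":
        return image[:, index].copy()
    raise ValueError("axis must be 'h' or 'v'")
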