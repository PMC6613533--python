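"""Object-level shape features and per-image aggregates from segmented
region-of-interest masks.

Connected components (8-connectivity, small objects despeckled) of a
binary ROI mask are measured for area (px and um^2), contour perimeter,
circularity ``4*pi*area / perimeter^2`` (capped at 1 — digital perimeters
otherwise exceed 1 for small objects), equivalent-ellipse axes from second
central moments, and roundness ``4*area / (pi * major^2)``.  Per-image
summaries add the grayscale-histogram mode of the ROI, an intensity proxy
for staining density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from ._utils import DEFAULT_PIXEL_SCALE_UM, ValidationError, check, to_grayscale_u8

__all__ = [
    "extract_objects",
    "grayscale_mode",
    "ImageSummary",
    "summarize_image",
]

OBJECT_COLUMNS = ("object_id", "area_px", "area_um2", "perimeter_px",
                  "circularity", "ellipse_major_px", "ellipse_minor_px",
                  "roundness")


def _contour_perimeter(region_mask: np.ndarray) -> float:
    """Length of the marching-squares contour polygon of one object.

    The mask is zero-padded so the contour closes; with several contours
    (objects with holes) the longest — the outer boundary — is used.
    """
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    lengths = [np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))
               for c in contours]
    return float(max(lengths))


def extract_objects(binary_mask, pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
                    min_size_px: int = 10) -> pd.DataFrame:
    """Measure all 8-connected components of ``binary_mask``.

    Components smaller than ``min_size_px`` pixels are dropped (despeckle).
    An empty mask yields an empty table, not an error.  Physical areas use
    ``area_um2 = area_px * pixel_scale_um**2``.
    """
    mask = np.asarray(binary_mask).astype(bool)
    check(mask.ndim == 2, "binary mask must be 2-D")
    check(pixel_scale_um > 0, "pixel_scale_um must be > 0")
    labelled = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labelled):
        if region.area < min_size_px:
            continue
        perim = _contour_perimeter(labelled[region.slice] == region.label)
        circ = (4.0 * np.pi * region.area / perim**2) if perim > 0 else 1.0
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        roundness = 4.0 * region.area / (np.pi * major**2) if major > 0 else 1.0
        rows.append({
            "object_id": int(region.label),
            "area_px": int(region.area),
            "area_um2": float(region.area) * pixel_scale_um**2,
            "perimeter_px": perim,
            "circularity": min(1.0, circ),
            "ellipse_major_px": major,
            "ellipse_minor_px": minor,
            "roundness": roundness,
        })
    return pd.DataFrame(rows, columns=list(OBJECT_COLUMNS))


def grayscale_mode(image, roi_mask) -> int:
    """Modal value of the 256-bin 8-bit luma histogram over masked pixels.

    Ties break toward the lowest intensity.  Raises on an empty mask.
    """
    mask = np.asarray(roi_mask).astype(bool)
    gray = to_grayscale_u8(image)
    check(mask.shape == gray.shape, "mask and image must share dimensions")
    if not np.any(mask):
        raise ValidationError("grayscale_mode of an empty ROI is undefined")
    counts = np.bincount(gray[mask].ravel(), minlength=256)
    return int(np.argmax(counts))


@dataclass(frozen=True)
class ImageSummary:
    """Per-image aggregate features of one ROI."""

    time_days: float | None
    group: str | None
    n_objects: int
    mean_area_um2: float      # NaN when no objects
    mean_circularity: float   # NaN when no objects
    gray_mode: int

    def as_dict(self) -> dict:
        return {
            "time_days": self.time_days,
            "group": self.group,
            "n_objects": self.n_objects,
            "mean_area_um2": self.mean_area_um2,
            "mean_circularity": self.mean_circularity,
            "gray_mode": self.gray_mode,
        }


def summarize_image(objects: pd.DataFrame, image, roi_mask,
                    time_days: float | None = None,
                    group: str | None = None) -> ImageSummary:
    """Aggregate an object table into per-image means plus the ROI's
    grayscale mode.  With zero objects the means are reported as NaN."""
    n = len(objects)
    mean_area = float(objects["area_um2"].mean()) if n else float("nan")
    mean_circ = float(objects["circularity"].mean()) if n else float("nan")
    return ImageSummary(
        time_days=time_days, group=group, n_objects=n,
        mean_area_um2=mean_area, mean_circularity=mean_circ,
        gray_mode=grayscale_mode(image, roi_mask))
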