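"""Pectoralis muscle and subcutaneous fat measurement at the T3 level.

The pectoralis is segmented on a user-designated axial slice by HU
thresholding in a skeletal-muscle window (default [-29, +150] HU) followed
by seeded exclusion of the mediastinum: the user clicks a point on
mediastinal soft tissue, the 4-connected component containing that point is
removed, and the remaining components anterior to the seed constitute the
muscle mask.  Muscle area is pixel count x pixel area; attenuation metrics
are plain means over the masks.  Subcutaneous fat is the fat-window
([-120, -60] HU) portion of the body component.

The muscle window is configurable because published threshold methods vary;
the default is the standard skeletal-muscle window.  All connected-component
operations use 4-connectivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import CTVolume

logger = logging.getLogger(__name__)

#: Default skeletal-muscle HU window (inclusive bounds).
MUSCLE_WINDOW_HU = (-29.0, 150.0)
#: Adipose-tissue HU window (inclusive bounds).
FAT_WINDOW_HU = (-120.0, -60.0)
#: Body-mask lower threshold.
BODY_THRESHOLD_HU = -500.0

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class BodyCompResult:
    muscle_area_cm2: float
    muscle_mean_hu: float      # NaN when no muscle pixels
    fat_mean_hu: float         # NaN when no fat pixels
    muscle_pixels: int
    fat_pixels: int


def _slice2d(image: CTVolume, slice_index: int) -> np.ndarray:
    return image.voxels[slice_index]


def segment_pectoralis(slice_image: CTVolume, mediastinum_seed: tuple[int, int],
                       muscle_window: tuple[float, float] = MUSCLE_WINDOW_HU,
                       slice_index: int = 0) -> np.ndarray:
    """Segment the pectoralis compartments with seeded mediastinum exclusion.

    Thresholds the slice by ``muscle_window`` (inclusive), removes the
    4-connected component containing ``mediastinum_seed``, and keeps the
    remaining components whose centroids lie anterior to (above) the seed
    row.  Raises when the seed misses every in-window component; returns an
    empty mask with a warning when the window matches nothing at all.
    """
    img = _slice2d(slice_image, slice_index)
    r0, c0 = mediastinum_seed
    if not (0 <= r0 < img.shape[0] and 0 <= c0 < img.shape[1]):
        raise ValueError(f"seed {mediastinum_seed} outside the {img.shape} grid")
    in_window = (img >= muscle_window[0]) & (img <= muscle_window[1])
    if not in_window.any():
        logger.warning("no pixels in the muscle window %s; empty pectoralis mask",
                       muscle_window)
        return np.zeros_like(in_window)
    labeled, n = ndimage.label(in_window, structure=_STRUCT4)
    seed_label = labeled[r0, c0]
    if seed_label == 0:
        raise ValueError(
            f"seed {mediastinum_seed} does not hit any in-window component; "
            "it must be placed on mediastinal soft tissue")
    mask = np.zeros_like(in_window)
    for lab in range(1, n + 1):
        if lab == seed_label:
            continue
        comp = labeled == lab
        centroid_row = ndimage.center_of_mass(comp)[0]
        if centroid_row <= r0:  # anterior of (or level with) the seed
            mask |= comp
    return mask


def muscle_metrics(slice_image: CTVolume, muscle_mask: np.ndarray,
                   spacing: tuple[float, float] | None = None,
                   slice_index: int = 0) -> tuple[float, float]:
    """Muscle area (cm^2) and mean attenuation (HU) over a mask.

    Area is ``pixels * row_spacing * col_spacing / 100``; an empty mask
    yields area 0 and a NaN mean.
    """
    img = _slice2d(slice_image, slice_index)
    mask = np.asarray(muscle_mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("muscle mask shape does not match the slice")
    sp = spacing or slice_image.pixel_spacing
    n = int(mask.sum())
    area = n * sp[0] * sp[1] / 100.0
    mean = float(img[mask].mean()) if n else math.nan
    return area, mean


def compute_body_mask(slice_image: CTVolume, slice_index: int = 0,
                      body_threshold: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Largest border-free 4-connected component of pixels >= threshold."""
    img = _slice2d(slice_image, slice_index)
    candidate = img >= body_threshold
    labeled, n = ndimage.label(candidate, structure=_STRUCT4)
    if n == 0:
        raise ValueError("no body found (no pixels above the body threshold)")
    border = set(np.unique(labeled[0, :])) | set(np.unique(labeled[-1, :])) \
        | set(np.unique(labeled[:, 0])) | set(np.unique(labeled[:, -1]))
    border.discard(0)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    interior = [(int(sizes[i - 1]), i) for i in range(1, n + 1) if i not in border]
    if not interior:
        raise ValueError("no border-free body component found")
    return labeled == max(interior)[1]


def segment_subcutaneous_fat(slice_image: CTVolume, body_mask: np.ndarray | None = None,
                             fat_window: tuple[float, float] = FAT_WINDOW_HU,
                             slice_index: int = 0) -> np.ndarray:
    """Fat-window pixels of the body component.

    Lung interiors and isolated in-window specks inside the lungs are
    excluded automatically because they do not belong to the largest
    border-free body component; muscle and mediastinum fall outside the
    fat window by construction of the two windows.
    """
    img = _slice2d(slice_image, slice_index)
    if body_mask is None:
        body_mask = compute_body_mask(slice_image, slice_index)
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("empty body mask")
    mask = body_mask & (img >= fat_window[0]) & (img <= fat_window[1])
    if not mask.any():
        logger.warning("no pixels in the fat window %s within the body", fat_window)
    return mask


def fat_attenuation(slice_image: CTVolume, fat_mask: np.ndarray,
                    slice_index: int = 0) -> float:
    """Mean HU over the fat mask; NaN for an empty mask."""
    img = _slice2d(slice_image, slice_index)
    mask = np.asarray(fat_mask, dtype=bool)
    if not mask.any():
        return math.nan
    return float(img[mask].mean())


def measure_body_composition(slice_image: CTVolume, mediastinum_seed: tuple[int, int],
                             muscle_window: tuple[float, float] = MUSCLE_WINDOW_HU,
                             fat_window: tuple[float, float] = FAT_WINDOW_HU,
                             slice_index: int = 0) -> BodyCompResult:
    """Full T3-level body-composition measurement on one slice."""
    muscle = segment_pectoralis(slice_image, mediastinum_seed, muscle_window, slice_index)
    area, muscle_mean = muscle_metrics(slice_image, muscle, slice_index=slice_index)
    fat = segment_subcutaneous_fat(slice_image, None, fat_window, slice_index)
    return BodyCompResult(
        muscle_area_cm2=area,
        muscle_mean_hu=muscle_mean,
        fat_mean_hu=fat_attenuation(slice_image, fat, slice_index),
        muscle_pixels=int(muscle.sum()),
        fat_pixels=int(fat.sum()),
    )
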