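"""Semi-automatic coronary-artery-calcification (CAC) scoring.

The measurement chain mirrors manual workflows on screening chest CT: a
circular region of interest restricts analysis to the heart, a background
normalization anchors exterior air at -1000 HU, pixels above 130 HU inside
the ROI are counted, and the count is mapped to a four-grade severity scale
(0 none, 1 minimal, 2 moderate, 3 severe) through cutpoints calibrated
against reference reader grades by quantile matching.

Grade coding note: severity is coded 0-3 internally with text labels for
I/O; counts at a cutpoint take the higher grade (boundary inclusive
upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import CTVolume

#: HU threshold above which a pixel is considered calcified.
CALCIUM_THRESHOLD_HU = 130.0

GRADE_LABELS = {0: "none", 1: "minimal", 2: "moderate", 3: "severe"}


@dataclass(frozen=True)
class GradeCutpoints:
    """Three increasing pixel-count thresholds separating grades 0|1|2|3."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if not (0 <= self.c1 < self.c2 < self.c3):
            raise ValueError(
                f"cutpoints must satisfy 0 <= c1 < c2 < c3, got "
                f"({self.c1}, {self.c2}, {self.c3})")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c1, self.c2, self.c3)


@dataclass
class CACResult:
    pixel_count: int
    grade: int
    roi_center: tuple[int, int]
    roi_radius: float
    normalization_offset: float = 0.0

    @property
    def grade_label(self) -> str:
        return GRADE_LABELS[self.grade]


def _slice2d(image: CTVolume | np.ndarray, slice_index: int = 0) -> np.ndarray:
    if isinstance(image, CTVolume):
        return image.voxels[slice_index]
    arr = np.asarray(image, dtype=np.float64)
    return arr[slice_index] if arr.ndim == 3 else arr


def normalize_background(slice_image: CTVolume, slice_index: int = 0,
                         air_cutoff: float = -800.0,
                         target_air: float = -1000.0) -> tuple[CTVolume, float]:
    """Anchor the exterior-air level at -1000 HU.

    The background air level is estimated as the median of pixels below
    ``air_cutoff`` (robust as long as exterior air dominates the lungs'
    contribution); the estimate's deviation from ``target_air`` is
    subtracted from every pixel.  Returns the corrected volume and the
    offset that was removed.

    Raises if fewer than 1% of pixels sit below the cutoff, in which case
    the caller must skip normalization explicitly.
    """
    img = slice_image.voxels
    sub = img[img < air_cutoff]
    if sub.size < 0.01 * img.size:
        raise ValueError(
            "no air background found (<1% of pixels below "
            f"{air_cutoff} HU); skip normalization explicitly for this image")
    offset = float(np.median(sub) - target_air)
    corrected = slice_image.with_voxels(img - offset)
    return corrected, offset


def count_calcified_pixels(slice_image: CTVolume | np.ndarray,
                           roi_center: tuple[int, int], roi_radius: float,
                           threshold: float = CALCIUM_THRESHOLD_HU,
                           slice_index: int = 0) -> int:
    """Count pixels strictly above ``threshold`` inside a circular ROI.

    Membership is by pixel center; the ROI must lie fully inside the grid.
    """
    img = _slice2d(slice_image, slice_index)
    r0, c0 = roi_center
    if (r0 - roi_radius < 0 or c0 - roi_radius < 0
            or r0 + roi_radius > img.shape[0] - 1 or c0 + roi_radius > img.shape[1] - 1):
        raise ValueError(
            f"ROI center {roi_center} radius {roi_radius} extends outside the "
            f"{img.shape} grid")
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    roi = (rr - r0) ** 2 + (cc - c0) ** 2 <= roi_radius ** 2
    return int(np.count_nonzero(roi & (img > threshold)))


def calibrate_cutpoints(counts, reference_grades) -> GradeCutpoints:
    """Calibrate grade cutpoints against reference reader grades.

    Quantile matching: for each grade boundary k the cutpoint is placed at
    the count quantile corresponding to the cumulative reference frequency
    of grades below k — concretely, the midpoint between the two sorted
    counts straddling that rank.  Calibrated cutpoints therefore reproduce
    the readers' grade marginal distribution on the calibration set (up to
    ties in the counts).
    """
    counts = np.asarray(counts, dtype=np.float64)
    grades = np.asarray(reference_grades, dtype=int)
    if counts.shape != grades.shape:
        raise ValueError("counts and reference_grades must have equal length")
    if np.any((grades < 0) | (grades > 3)):
        raise ValueError("reference grades must lie in {0, 1, 2, 3}")
    present = set(np.unique(grades).tolist())
    if present != {0, 1, 2, 3}:
        raise ValueError(
            f"reference grades must cover all four grades; got {sorted(present)}")
    s = np.sort(counts)
    cuts = []
    for k in (1, 2, 3):
        m = int(np.count_nonzero(grades < k))
        cuts.append((s[m - 1] + s[m]) / 2.0)
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError(
            f"grade count distributions overlap too much for distinct "
            f"cutpoints: {cuts}")
    return GradeCutpoints(*cuts)


def assign_grade(pixel_count: float, cutpoints: GradeCutpoints) -> int:
    """Map a calcified-pixel count to grade 0-3.

    A count equal to a cutpoint takes the higher grade.
    """
    return int(np.count_nonzero(np.asarray(cutpoints.as_tuple()) <= pixel_count))


def grade_agreement(grades_a, grades_b) -> float:
    """Squared Pearson correlation between two grade vectors."""
    a = np.asarray(grades_a, dtype=np.float64)
    b = np.asarray(grades_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 observations")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("grade agreement undefined for zero-variance vectors")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def score_slice(slice_image: CTVolume, roi_center: tuple[int, int], roi_radius: float,
                cutpoints: GradeCutpoints, normalize: bool = True,
                threshold: float = CALCIUM_THRESHOLD_HU) -> CACResult:
    """Full scoring chain: normalize, count, grade."""
    offset = 0.0
    if normalize:
        slice_image, offset = normalize_background(slice_image)
    count = count_calcified_pixels(slice_image, roi_center, roi_radius, threshold)
    return CACResult(pixel_count=count, grade=assign_grade(count, cutpoints),
                     roi_center=tuple(roi_center), roi_radius=float(roi_radius),
                     normalization_offset=offset)
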