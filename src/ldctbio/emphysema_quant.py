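"""Emphysema quantification: low-attenuation area (LAA) fraction.

Emphysema severity is summarized as the proportion of lung voxels with
attenuation strictly below -950 HU.  Lung segmentation is threshold-based:
sub-threshold voxels are labelled with 4-connectivity in-plane (and
face-connectivity across slices), components touching the in-plane image
border (exterior air) are discarded, and the two largest remaining
components are kept as the lungs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import CTVolume

#: HU threshold below which a lung voxel counts as low-attenuation area.
LAA_THRESHOLD_HU = -950.0
#: HU threshold below which voxels are candidate lung tissue.
LUNG_THRESHOLD_HU = -400.0


@dataclass
class EmphysemaResult:
    laa_fraction: float
    lung_voxels: int
    laa_voxels: int


def _connectivity(ndim: int) -> np.ndarray:
    # face connectivity: 4-neighborhood in-plane, 6-neighborhood in 3-D
    return ndimage.generate_binary_structure(ndim, 1)


def segment_lungs(volume: CTVolume, lung_threshold: float = LUNG_THRESHOLD_HU) -> np.ndarray:
    """Segment the lung fields of an enclosed thorax.

    Keeps the two largest connected components of sub-threshold voxels that
    do not touch the in-plane border (one if only one exists).  Raises when
    no interior sub-threshold component remains.
    """
    vox = volume.voxels
    candidate = vox < lung_threshold
    labeled, n = ndimage.label(candidate, structure=_connectivity(vox.ndim))
    if n == 0:
        raise ValueError("no voxels below the lung threshold; not a chest image?")
    border_labels = set(np.unique(labeled[:, 0, :])) | set(np.unique(labeled[:, -1, :])) \
        | set(np.unique(labeled[:, :, 0])) | set(np.unique(labeled[:, :, -1]))
    border_labels.discard(0)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    interior = [(int(sizes[i - 1]), i) for i in range(1, n + 1) if i not in border_labels]
    if not interior:
        raise ValueError("no interior low-attenuation component found (lungs absent "
                         "or touching the image border)")
    interior.sort(reverse=True)
    keep = [lab for _, lab in interior[:2]]
    return np.isin(labeled, keep)


def compute_laa(volume: CTVolume, lung_mask: np.ndarray,
                threshold: float = LAA_THRESHOLD_HU) -> EmphysemaResult:
    """LAA fraction: voxels strictly below ``threshold`` within the mask."""
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != volume.voxels.shape:
        raise ValueError("lung mask shape does not match the volume")
    n_lung = int(lung_mask.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask")
    n_laa = int(np.count_nonzero(volume.voxels[lung_mask] < threshold))
    return EmphysemaResult(laa_fraction=n_laa / n_lung, lung_voxels=n_lung,
                           laa_voxels=n_laa)


def quantify_emphysema(volume: CTVolume, lung_threshold: float = LUNG_THRESHOLD_HU,
                       laa_threshold: float = LAA_THRESHOLD_HU) -> EmphysemaResult:
    """Segment the lungs and compute the LAA fraction in one call."""
    return compute_laa(volume, segment_lungs(volume, lung_threshold), laa_threshold)
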