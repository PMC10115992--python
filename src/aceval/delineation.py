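"""Tumor delineation: background normalization and TBR-isocontour extraction.

The biological tumor volume (BTV) is the set of brain voxels whose
tumor-to-background ratio (TBR = activity / mean activity in a healthy-brain
background ROI) strictly exceeds a threshold (default 1.6), after skull-strip
masking and removal of physiological high-uptake structures.  Only studies
whose reference BTV strictly exceeds 1 ml enter the PET evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageVolume, Mask, argmax_zyx, voxel_volume_ml

__all__ = [
    "BTVResult",
    "apply_fov_superimposition",
    "compute_background_mean",
    "delineate_btv",
    "btv_inclusion",
]

# 26-connectivity for 3D connected components
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BTVResult:
    """A delineated biological tumor volume.

    ``component_labels`` carries the 26-connected component index (1..n) per
    voxel; the BTV is the union of all suprathreshold components.  The peak is
    the TBR maximum inside the mask, ties resolved by lowest linear index in
    (z, y, x) order.
    """

    mask: Mask
    tbr: ImageVolume
    volume_ml: float
    threshold: float
    background_mean: float
    component_labels: np.ndarray
    component_sizes: list[int]
    peak_index: tuple[int, int, int] | None
    peak_location_mm: tuple[float, float, float] | None
    peak_value: float

    @property
    def is_empty(self) -> bool:
        return self.mask.n_voxels == 0

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    def component_mask(self, label: int) -> Mask:
        return Mask.from_volume(self.mask, self.component_labels == label,
                                label=f"btv_component_{label}")

    def component_peak_mm(self, label: int) -> tuple[float, float, float]:
        """Physical location of the TBR maximum of one component."""
        comp = self.component_labels == label
        if not comp.any():
            raise ValueError(f"no component with label {label}")
        idx = argmax_zyx(self.tbr.data, valid=comp)
        return tuple(self.tbr.index_to_physical(idx))


def apply_fov_superimposition(test_mu: ImageVolume, fallback_mu: ImageVolume,
                              fov: Mask) -> ImageVolume:
    """Replace everything outside the field-of-view mask by the fallback map."""
    if not (test_mu.same_grid(fallback_mu) and test_mu.same_grid(fov)):
        raise ValueError("FOV superimposition requires a single common grid")
    out = np.where(fov.data, test_mu.data, fallback_mu.data)
    return test_mu.with_data(out)


def compute_background_mean(pet: ImageVolume, roi: Mask) -> float:
    """Arithmetic mean activity over the background ROI.

    Computed separately for each attenuation-correction method's PET image, so
    every method is normalized by its own background level.
    """
    if not pet.same_grid(roi):
        raise ValueError("PET and background ROI must share one grid")
    if roi.n_voxels == 0:
        raise ValueError("background ROI is empty")
    return float(np.asarray(pet.data, dtype=float)[roi.data].mean())


def delineate_btv(pet: ImageVolume, background_mean: float, brain: Mask,
                  exclusions: list[Mask] | None = None,
                  threshold: float = 1.6) -> BTVResult:
    """Extract the BTV by TBR isocontouring.

    ``TBR = pet / background_mean``; the mask is ``{TBR > threshold}``
    (strict) intersected with the brain mask and minus every exclusion mask.
    Components use 26-connectivity; the BTV is their union.
    """
    if not background_mean > 0:
        raise ValueError(f"background mean must be positive, got {background_mean}")
    if brain.n_voxels == 0:
        raise ValueError("brain mask is empty")
    if not pet.same_grid(brain):
        raise ValueError("PET and brain mask must share one grid")
    tbr_data = np.asarray(pet.data, dtype=float) / background_mean
    mask = (tbr_data > threshold) & brain.data
    for excl in exclusions or []:
        if not pet.same_grid(excl):
            raise ValueError("exclusion mask grid mismatch")
        mask &= ~excl.data

    labels, n_comp = ndimage.label(mask, structure=CONNECTIVITY_26)
    sizes = [int((labels == i).sum()) for i in range(1, n_comp + 1)]
    tbr = pet.with_data(tbr_data)
    if mask.any():
        peak_index = argmax_zyx(tbr_data, valid=mask)
        peak_mm = tuple(float(v) for v in tbr.index_to_physical(peak_index))
        peak_value = float(tbr_data[peak_index])
    else:
        peak_index, peak_mm, peak_value = None, None, float("nan")
    return BTVResult(
        mask=Mask.from_volume(pet, mask, label="btv"),
        tbr=tbr,
        volume_ml=float(mask.sum()) * voxel_volume_ml(pet),
        threshold=float(threshold),
        background_mean=float(background_mean),
        component_labels=labels,
        component_sizes=sizes,
        peak_index=peak_index,
        peak_location_mm=peak_mm,
        peak_value=peak_value,
    )


def btv_inclusion(btv: BTVResult, min_ml: float = 1.0) -> bool:
    """Whether a study enters the PET evaluation (reference BTV strictly above 1 ml)."""
    return btv.volume_ml > min_ml
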