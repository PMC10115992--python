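"""Agreement metrics between attenuation maps, PET images and tumor contours.

Covers attenuation-class Dice (whole head and in a sphere around each tumor),
MAE/SSIM/PSNR image similarity, contour Dice and Hausdorff distance, a
shape-deviation statistic that discounts one-voxel contour displacement while
flagging focal warps, TBR-peak displacement, and regional mean differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

from .delineation import BTVResult
from .image import ImageVolume, Mask, gaussian_smooth, voxel_volume_ml

__all__ = [
    "MuClassMap",
    "AgreementReport",
    "classify_mu",
    "dice",
    "class_dice",
    "proximity_sphere",
    "mu_similarity",
    "contour_agreement",
    "shape_deviation",
    "peak_distance",
    "pet_similarity",
    "regional_differences",
]

# attenuation class bounds (cm^-1): air < 0.05 <= tissue <= 0.1 < bone.
# Both class boundaries belong to tissue (closed interval).
MU_TISSUE_LOW = 0.05
MU_TISSUE_HIGH = 0.1
CLASS_AIR, CLASS_TISSUE, CLASS_BONE = 0, 1, 2
CLASS_OUTSIDE = -1


@dataclass
class MuClassMap:
    """Per-voxel attenuation class (air/tissue/bone) within an evaluation mask."""

    labels: ImageVolume   # CLASS_* values; CLASS_OUTSIDE beyond the mask
    mask: Mask

    def class_mask(self, cls: int) -> Mask:
        return Mask.from_volume(self.labels, self.labels.data == cls,
                                label=f"mu_class_{cls}")


@dataclass
class AgreementReport:
    """Per-study, per-method agreement bundle."""

    dice_tissue: float = np.nan
    dice_bone: float = np.nan
    dice_tissue_proximal: float = np.nan
    dice_bone_proximal: float = np.nan
    mae_mu: float = np.nan
    ssim_mu: float = np.nan
    contour_dice: float = np.nan
    hausdorff_mm: float = np.nan
    shape_deviation_ml: float = np.nan
    peak_distance_mm: float = np.nan
    peak_within_criterion: bool | None = None
    pet_mae: float = np.nan
    pet_ssim: float = np.nan
    pet_psnr: float = np.nan
    regional_pct: dict[int, float] = field(default_factory=dict)


def classify_mu(mu: ImageVolume, head: Mask, fov: Mask | None = None) -> MuClassMap:
    """Classify a mu-map into air/tissue/bone within the head (and CT FOV)."""
    if not mu.same_grid(head):
        raise ValueError("mu-map and head mask must share one grid")
    region = head.data.copy()
    if fov is not None:
        if not mu.same_grid(fov):
            raise ValueError("FOV mask grid mismatch")
        region &= fov.data
    data = np.asarray(mu.data, dtype=float)
    n_neg = int((data[region] < 0).sum())
    if n_neg:
        raise ValueError(f"{n_neg} negative attenuation values inside the evaluation region")
    labels = np.full(mu.shape[:3], CLASS_OUTSIDE, dtype=np.int16)
    labels[region] = CLASS_TISSUE
    labels[region & (data < MU_TISSUE_LOW)] = CLASS_AIR
    labels[region & (data > MU_TISSUE_HIGH)] = CLASS_BONE
    return MuClassMap(labels=mu.with_data(labels),
                      mask=Mask.from_volume(mu, region, label=head.label))


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    if not a.same_grid(b):
        raise ValueError("Dice requires a single common grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    return 2.0 * float((a.data & b.data).sum()) / (na + nb)


def class_dice(ref: MuClassMap, test: MuClassMap, cls: int,
               within: Mask | None = None) -> float:
    """Dice for one attenuation class, optionally restricted to a mask."""
    a = ref.labels.data == cls
    b = test.labels.data == cls
    if within is not None:
        a, b = a & within.data, b & within.data
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / (na + nb)


def proximity_sphere(btv: BTVResult, radius_mm: float = 50.0) -> Mask:
    """Union of spheres of ``radius_mm`` around each BTV component's TBR peak.

    Emulates restricting map evaluation to within 5 cm of the center-of-max
    of any individual tumor component.
    """
    if btv.is_empty:
        raise ValueError("proximity sphere requires a nonempty BTV")
    vol = btv.mask
    x, y, z = vol.coordinate_grids()
    out = np.zeros(vol.data.shape, dtype=bool)
    for label in range(1, btv.n_components + 1):
        cx, cy, cz = btv.component_peak_mm(label)
        out |= (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm ** 2
    return Mask.from_volume(vol, out, label="btv_proximity")


def _masked_ssim(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                 data_range: float) -> float:
    """Mean SSIM over a mask; Gaussian window sigma 1.5, K1=0.01, K2=0.03."""
    if data_range <= 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    _, smap = structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        data_range=data_range, full=True)
    return float(smap[mask].mean())


def mu_similarity(a: ImageVolume, b: ImageVolume, head: Mask) -> dict[str, float]:
    """MAE (cm^-1) and SSIM between two mu-maps over the head mask."""
    if not (a.same_grid(b) and a.same_grid(head)):
        raise ValueError("mu similarity requires a single common grid")
    if head.n_voxels == 0:
        raise ValueError("head mask is empty")
    da = np.asarray(a.data, dtype=float)
    db = np.asarray(b.data, dtype=float)
    mae = float(np.abs(da - db)[head.data].mean())
    ssim = _masked_ssim(da, db, head.data, data_range=float(da[head.data].max()))
    return {"mae": mae, "ssim": ssim}


def _surface_points_mm(mask: Mask) -> np.ndarray:
    """Physical coordinates of the surface voxels of a mask."""
    m = mask.data
    surface = m & ~ndimage.binary_erosion(m, border_value=0)
    idx = np.argwhere(surface)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


def contour_agreement(ref: Mask, test: Mask, percentile: float | None = None
                      ) -> dict[str, float]:
    """Contour Dice and Hausdorff distance (mm) between two segmentations.

    The Hausdorff distance is the maximum over both directed maximum
    surface-to-surface distances; ``percentile`` (e.g. 95) switches both
    directed distances to that percentile.
    """
    if not ref.same_grid(test):
        raise ValueError("contour agreement requires a single common grid")
    if ref.n_voxels == 0:
        raise ValueError("reference mask is empty")
    if test.n_voxels == 0:
        raise ValueError("test mask is empty; Hausdorff distance is undefined")
    d = dice(ref, test)
    pa = _surface_points_mm(ref)
    pb = _surface_points_mm(test)
    dist_ab, _ = cKDTree(pb).query(pa)
    dist_ba, _ = cKDTree(pa).query(pb)
    if percentile is None:
        hd = max(dist_ab.max(), dist_ba.max())
    else:
        hd = max(np.percentile(dist_ab, percentile), np.percentile(dist_ba, percentile))
    return {"dice": d, "hausdorff_mm": float(hd)}


def shape_deviation(ref_btv: Mask, test_btv: Mask, fwhm_mm: float = 4.0,
                    level: float = 1.0, eps: float = 1e-2) -> float:
    """Volume (ml) of focal shape deviation between two tumor masks.

    The binary symmetric difference is smoothed with a Gaussian (default FWHM
    4 mm) and thresholded where the smoothed image reaches ``level`` (within a
    numerical tolerance ``eps``, since smoothed binary images only approach 1
    asymptotically).  A one-voxel displacement of the whole contour smooths
    well below 1 and scores zero, while a focal blob of a few mm radius keeps
    a core near 1 and is flagged — so the statistic discounts contour jitter
    but catches clinically meaningful warps.
    """
    if not ref_btv.same_grid(test_btv):
        raise ValueError("shape deviation requires a single common grid")
    diff = (ref_btv.data ^ test_btv.data).astype(float)
    smoothed = gaussian_smooth(ref_btv.with_data(diff), fwhm_mm)
    region = smoothed.data >= (level - eps)
    return float(region.sum()) * voxel_volume_ml(ref_btv)


def peak_distance(ref: BTVResult, test: BTVResult,
                  criterion_mm: float = 10.0) -> dict[str, float | bool]:
    """Euclidean distance (mm) between the TBR-peak locations of two BTVs.

    ``within_criterion`` is strict: a displacement of exactly the criterion
    (default 10 mm, the size of an average stereotactic biopsy) fails.
    """
    if ref.peak_location_mm is None or test.peak_location_mm is None:
        raise ValueError("peak distance requires nonempty BTVs on both sides")
    d = float(np.linalg.norm(np.asarray(ref.peak_location_mm) -
                             np.asarray(test.peak_location_mm)))
    return {"distance_mm": d, "within_criterion": d < criterion_mm}


def pet_similarity(ref_pet: ImageVolume, test_pet: ImageVolume, brain: Mask
                   ) -> dict[str, float]:
    """MAE, SSIM and PSNR between two PET images within the brain.

    PSNR = 10 log10(R^2 / MSE) with R the reference maximum over the brain;
    identical images give an infinite PSNR sentinel.
    """
    if not (ref_pet.same_grid(test_pet) and ref_pet.same_grid(brain)):
        raise ValueError("PET similarity requires a single common grid")
    if brain.n_voxels == 0:
        raise ValueError("brain mask is empty")
    a = np.asarray(ref_pet.data, dtype=float)
    b = np.asarray(test_pet.data, dtype=float)
    diff = (a - b)[brain.data]
    mae = float(np.abs(diff).mean())
    mse = float((diff ** 2).mean())
    r = float(a[brain.data].max())
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(r * r / mse)
    ssim = _masked_ssim(a, b, brain.data, data_range=r)
    return {"mae": mae, "ssim": ssim, "psnr": psnr}


def regional_differences(ref_pet: ImageVolume, test_pet: ImageVolume,
                         regions: ImageVolume) -> dict[int, float]:
    """Relative percent difference of mean uptake per region label.

    Returns ``100 * (mean(test) - mean(ref)) / mean(ref)`` for every nonzero
    label; labels whose reference mean is zero are skipped with a warning.
    """
    if not (ref_pet.same_grid(test_pet) and ref_pet.same_grid(regions)):
        raise ValueError("regional differences require a single common grid")
    labels = [int(v) for v in np.unique(regions.data) if v != 0]
    if not labels:
        raise ValueError("region label map is empty")
    a = np.asarray(ref_pet.data, dtype=float)
    b = np.asarray(test_pet.data, dtype=float)
    out: dict[int, float] = {}
    for label in labels:
        sel = regions.data == label
        mr = float(a[sel].mean())
        if mr == 0:
            warnings.warn(f"region {label} has zero reference mean; skipped")
            continue
        out[label] = 100.0 * (float(b[sel].mean()) - mr) / mr
    return out
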