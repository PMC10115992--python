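"""Volume data model, NIfTI I/O and shared geometry utilities.

All volumes live on axis-aligned grids: ``physical = origin + index * spacing``
with 0-based voxel indices, array axes ordered (x, y, z) and all distances in
millimetres.  Multi-volume operations require identical grids; resampling is an
explicit pipeline-entry step, never implicit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "Mask",
    "read_volume",
    "write_volume",
    "voxel_volume_ml",
    "gaussian_smooth",
    "resample_nearest",
    "resample_linear",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class ImageVolume:
    """A 3D (or 4D dynamic) scalar grid with voxel spacing and origin.

    Parameters
    ----------
    data:
        3D array, or 4D with the last axis indexing time frames.  Units are
        contextual: cm^-1 for attenuation (mu) maps, kBq/ml for PET activity,
        {0, 1} for masks.
    spacing:
        Voxel size (dx, dy, dz) in mm, all strictly positive.
    origin:
        Physical coordinate (mm) of voxel (0, 0, 0).
    frame_info:
        For dynamic series only: one ``(start_s, duration_s)`` pair per frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_info: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D/4D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        for axis, s in enumerate(self.spacing):
            if not s > 0:
                raise ValueError(f"spacing must be strictly positive, axis {axis} has {s}")
        if self.frame_info is not None:
            self.frame_info = [(float(a), float(b)) for a, b in self.frame_info]
            if self.data.ndim != 4:
                raise ValueError("frame_info given but data is not 4D")
            if self.data.shape[3] != len(self.frame_info):
                raise ValueError(
                    f"{self.data.shape[3]} frames but {len(self.frame_info)} frame_info entries"
                )
            for start, dur in self.frame_info:
                if dur <= 0:
                    raise ValueError("frame durations must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1

    def index_to_physical(self, index: Sequence[float]) -> np.ndarray:
        """Physical coordinate (mm) of a voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, point_mm: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a physical coordinate (mm)."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical x/y/z coordinates (mm) of every voxel, broadcastable."""
        nx, ny, nz = self.data.shape[:3]
        x = self.origin[0] + np.arange(nx) * self.spacing[0]
        y = self.origin[1] + np.arange(ny) * self.spacing[1]
        z = self.origin[2] + np.arange(nz) * self.spacing[2]
        return x[:, None, None], y[None, :, None], z[None, None, :]

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.data.shape[:3] == other.data.shape[:3]
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray, frame_info: list | None = None) -> "ImageVolume":
        """Copy of the geometry carrying new voxel data."""
        return ImageVolume(data=data, spacing=self.spacing, origin=self.origin,
                           frame_info=frame_info)


def _require_same_grid(*vols: ImageVolume) -> None:
    ref = vols[0]
    for v in vols[1:]:
        if not ref.same_grid(v):
            raise ValueError(
                f"grid mismatch: {ref.data.shape[:3]}/{ref.spacing} vs "
                f"{v.data.shape[:3]}/{v.spacing}"
            )


@dataclass
class Mask(ImageVolume):
    """An :class:`ImageVolume` restricted to {0, 1} with a role label."""

    label: str = "mask"

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask '{self.label}' contains values other than 0/1")
        self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        return self.n_voxels * voxel_volume_ml(self)

    @classmethod
    def from_volume(cls, vol: ImageVolume, data: np.ndarray, label: str = "mask") -> "Mask":
        return cls(data=data, spacing=vol.spacing, origin=vol.origin, label=label)


# -- I/O --------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, frame_info: list | None = None) -> ImageVolume:
    """Read a 3D or 4D NIfTI volume.

    A 4D image becomes a dynamic series; frame timing is taken from
    ``frame_info`` or from a JSON sidecar ``{"frames": [[start_s, dur_s], ...]}``
    next to the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3D/4D image, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()[:3]
    for axis, s in enumerate(zooms):
        if not s > 0:
            raise ValueError(f"non-positive spacing on axis {axis} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if data.ndim == 4:
        if frame_info is None:
            sidecar = _sidecar_path(path)
            if sidecar.exists():
                with open(sidecar) as fh:
                    frame_info = [tuple(f) for f in json.load(fh)["frames"]]
            else:
                raise ValueError(
                    f"4D image {path} needs frame timing (JSON sidecar or frame_info)"
                )
    return ImageVolume(data=data, spacing=tuple(float(z) for z in zooms),
                       origin=origin, frame_info=frame_info)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI; dynamic series also write a timing sidecar."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    if vol.frame_info is not None:
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"frames": [list(f) for f in vol.frame_info]}, fh)
    return path


# -- operations -------------------------------------------------------------

def voxel_volume_ml(vol: ImageVolume) -> float:
    """Volume of one voxel in ml (spacing product / 1000)."""
    dx, dy, dz = vol.spacing
    return dx * dy * dz / 1000.0


def gaussian_smooth(vol: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Isotropic Gaussian smoothing specified by FWHM in mm.

    Per-axis sigma is ``fwhm * FWHM_TO_SIGMA`` converted to voxel units via the
    spacing.  Boundaries are reflective, so constants are preserved and the
    discrete kernel integrates to one.
    """
    if not fwhm_mm > 0:
        raise ValueError(f"fwhm must be positive, got {fwhm_mm}")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.spacing]
    data = np.asarray(vol.data, dtype=float)
    if data.ndim == 4:
        out = np.stack(
            [ndimage.gaussian_filter(data[..., t], sigma_vox, mode="reflect")
             for t in range(data.shape[3])], axis=-1)
    else:
        out = ndimage.gaussian_filter(data, sigma_vox, mode="reflect")
    return vol.with_data(out, frame_info=vol.frame_info)


def _resample(moving: ImageVolume, reference: ImageVolume, order: int) -> np.ndarray:
    # voxel extent of the moving grid: centres +/- half a voxel
    axes = []
    outside_1d = []
    for axis in range(3):
        pos = reference.origin[axis] + np.arange(reference.shape[axis]) * reference.spacing[axis]
        idx = (pos - moving.origin[axis]) / moving.spacing[axis]
        axes.append(idx)
        outside_1d.append((idx < -0.5) | (idx > moving.shape[axis] - 0.5))
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    data = np.asarray(moving.data, dtype=float)
    # interpolate with edge clamping, then zero points beyond the extent
    out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    out = out.reshape(reference.shape[:3])
    outside = (outside_1d[0][:, None, None] | outside_1d[1][None, :, None]
               | outside_1d[2][None, None, :])
    if outside.all():
        warnings.warn("physical extents do not overlap; output is zero-filled")
    out[outside] = 0.0
    return out


def resample_nearest(moving: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Resample onto the reference grid with nearest-neighbour interpolation.

    Use for masks and label maps; continuous images go through
    :func:`resample_linear`.
    """
    if moving.same_grid(reference):
        return replace(moving, data=moving.data.copy())
    out = _resample(moving, reference, order=0)
    if isinstance(moving, Mask):
        return Mask(data=out.astype(bool), spacing=reference.spacing,
                    origin=reference.origin, label=moving.label)
    return ImageVolume(data=out, spacing=reference.spacing, origin=reference.origin)


def resample_linear(moving: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Trilinear variant of :func:`resample_nearest` for continuous images."""
    if moving.same_grid(reference):
        return replace(moving, data=moving.data.copy())
    out = _resample(moving, reference, order=1)
    return ImageVolume(data=out, spacing=reference.spacing, origin=reference.origin)


def argmax_zyx(data: np.ndarray, valid: np.ndarray | None = None) -> tuple[int, int, int]:
    """Index of the maximum; ties resolved by lowest linear index in (z, y, x) order."""
    arr = np.asarray(data, dtype=float)
    if valid is not None:
        arr = np.where(valid, arr, -np.inf)
    flat = np.argmax(arr.transpose(2, 1, 0))
    k, j, i = np.unravel_index(flat, arr.transpose(2, 1, 0).shape)
    return int(i), int(j), int(k)
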