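"""Digital head phantoms for attenuation-correction evaluation.

The generator builds piecewise-constant head attenuation (mu) maps — an
ellipsoidal head with a bony shell, optional air cavities — plus an
amino-acid-PET-like activity image carrying lesions with configurable
tumor-to-background ratio (TBR) and physiological hot foci.  Surgical
attenuation-map artifacts (false bone, metal signal voids, air cavities filled
as water, missing skull flaps, registration shifts) can be injected into a
copy of the mu-map, and a first-order bias model propagates the mu-map error
into the PET image the way an attenuation-corrected reconstruction would:
corrected activity scales with the ratio of attenuation factors, i.e. with
``exp(line integral of delta-mu)`` averaged over lines of response.

The bias model is deliberately not a reconstruction: it averages full-grid
line integrals over K evenly spaced in-plane (axial) angles, which captures
the dominant geometry of a brain PET ring at desk-scale runtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .image import ImageVolume, Mask, voxel_volume_ml

__all__ = [
    "SphereSpec",
    "LesionSpec",
    "ArtifactSpec",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "perturb_mu_map",
    "apply_ac_bias",
    "make_dynamic_frames",
    "FRAME_SCHEME_S",
    "frame_mid_times_min",
]

# default linear attenuation coefficients at 511 keV (cm^-1)
MU_AIR = 0.0
MU_TISSUE = 0.096
MU_BONE = 0.151

LABEL_AIR, LABEL_TISSUE, LABEL_BONE = 0, 1, 2

#: dynamic acquisition: 5 x 1 min, 5 x 3 min, 4 x 5 min = 14 frames over 40 min
FRAME_SCHEME_S: list[tuple[float, float]] = []
_t = 0.0
for _dur in [60.0] * 5 + [180.0] * 5 + [300.0] * 4:
    FRAME_SCHEME_S.append((_t, _dur))
    _t += _dur
del _t, _dur


def frame_mid_times_min(frame_info: Sequence[tuple[float, float]] = FRAME_SCHEME_S) -> np.ndarray:
    """Frame mid-times in minutes."""
    return np.array([(start + dur / 2.0) / 60.0 for start, dur in frame_info])


@dataclass
class SphereSpec:
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class LesionSpec(SphereSpec):
    """A spherical uptake blob with a target tumor-to-background ratio."""

    tbr: float = 2.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.tbr > 0:
            raise ValueError("lesion TBR must be positive")


ArtifactKind = Literal[
    "false_bone_patch", "metal_void", "air_filled_as_water",
    "missing_skull_flap", "registration_shift",
]

ARTIFACT_KINDS = {"false_bone_patch", "metal_void", "air_filled_as_water",
                  "missing_skull_flap", "registration_shift"}


@dataclass
class ArtifactSpec:
    """One attenuation-map defect.

    kind:
        ``false_bone_patch``  — mu set to bone inside a sphere (titanium
        implant read as bone, erroneous bone over pneumocephalus);
        ``metal_void``        — mu set to 0 (metal-induced signal void);
        ``air_filled_as_water`` — air voxels inside the sphere set to tissue
        (a post-surgical air space filled with the attenuation of water);
        ``missing_skull_flap`` — bone inside the sphere set to tissue;
        ``registration_shift`` — whole-map translation by ``shift_mm``.
    """

    kind: str
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size_mm: float = 10.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind: {self.kind!r}")
        if not self.size_mm > 0:
            raise ValueError("artifact size must be positive")


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic head study.

    The grid is centred on the physical origin; all centres are specified in
    mm relative to the head centre.  Defaults approximate an adult head on a
    96^3 grid at 2 mm isotropic spacing with one 12-mm-radius lesion of TBR
    2.5 and 5% Gaussian activity noise.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_semiaxes_mm: tuple[float, float, float] = (70.0, 85.0, 72.0)
    skull_thickness_mm: float = 6.0
    air_cavities: list[SphereSpec] = field(default_factory=list)
    lesions: list[LesionSpec] = field(
        default_factory=lambda: [LesionSpec(center_mm=(28.0, 12.0, 8.0), radius_mm=12.0, tbr=2.5)]
    )
    foci: list[LesionSpec] = field(default_factory=list)
    background_kbq_ml: float = 15.0
    noise_sigma_frac: float = 0.05
    extracerebral_frac: float = 0.25
    mu_tissue: float = MU_TISSUE
    mu_bone: float = MU_BONE
    tbr_threshold: float = 1.6
    background_roi_slab: tuple[float, float] = (0.15, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n < 8 for n in self.shape):
            raise ValueError("invalid grid")
        if not (0.05 <= self.mu_tissue <= 0.1):
            raise ValueError("mu_tissue outside the tissue class bounds (0.05-0.1 cm^-1)")
        if not self.mu_bone > 0.1:
            raise ValueError("mu_bone must exceed the bone class bound (0.1 cm^-1)")


@dataclass
class Phantom:
    """Ground-truth bundle produced by :func:`make_phantom`."""

    spec: PhantomSpec
    labels: ImageVolume            # air=0, tissue=1, bone=2
    mu_map: ImageVolume            # cm^-1
    head_mask: Mask
    brain_mask: Mask
    background_roi: Mask
    region_labels: ImageVolume     # brain octants, 1..8 (0 outside brain)
    activity_true: ImageVolume     # noiseless kBq/ml
    activity: ImageVolume          # with Gaussian noise (seeded)
    lesion_masks: list[Mask]
    true_btv_masks: list[Mask]     # per lesion: voxels with noiseless TBR > threshold

    @property
    def true_btv_mask(self) -> Mask:
        combined = np.zeros(self.labels.shape, dtype=bool)
        for m in self.true_btv_masks:
            combined |= m.data
        return Mask.from_volume(self.labels, combined, label="true_btv")

    def true_btv_ml(self) -> float:
        return float(self.true_btv_mask.data.sum()) * voxel_volume_ml(self.labels)


def _centered_origin(shape, spacing) -> tuple[float, float, float]:
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


def _sphere_mask(vol: ImageVolume, center_mm, radius_mm) -> np.ndarray:
    x, y, z = vol.coordinate_grids()
    cx, cy, cz = center_mm
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm ** 2


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build a deterministic head phantom from its spec.

    Activity model: ``background * TBR`` inside lesions and foci, background
    in normal brain, ``extracerebral_frac * background`` in extracerebral soft
    tissue and bone, zero in air.  Noise is additive Gaussian with sigma equal
    to ``noise_sigma_frac * background``, drawn from ``default_rng(seed)``.
    """
    origin = _centered_origin(spec.shape, spec.spacing)
    geom = ImageVolume(data=np.zeros(spec.shape, dtype=np.int16),
                       spacing=spec.spacing, origin=origin)
    x, y, z = geom.coordinate_grids()
    ax, ay, az = spec.head_semiaxes_mm
    head = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0
    t = spec.skull_thickness_mm
    inner = ((x / (ax - t)) ** 2 + (y / (ay - t)) ** 2 + (z / (az - t)) ** 2) <= 1.0

    labels = np.where(head, LABEL_TISSUE, LABEL_AIR).astype(np.int16)
    labels[head & ~inner] = LABEL_BONE
    for cav in spec.air_cavities:
        labels[_sphere_mask(geom, cav.center_mm, cav.radius_mm) & head] = LABEL_AIR

    mu = np.zeros(spec.shape, dtype=float)
    mu[labels == LABEL_TISSUE] = spec.mu_tissue
    mu[labels == LABEL_BONE] = spec.mu_bone

    brain = inner & (labels == LABEL_TISSUE)

    # validate lesions and paint activity
    activity = np.zeros(spec.shape, dtype=float)
    bg = spec.background_kbq_ml
    activity[labels == LABEL_TISSUE] = spec.extracerebral_frac * bg
    activity[labels == LABEL_BONE] = spec.extracerebral_frac * bg
    activity[brain] = bg

    lesion_masks: list[np.ndarray] = []
    focus_masks: list[np.ndarray] = []
    for blob, sink in [(l, lesion_masks) for l in spec.lesions] + \
                      [(f, focus_masks) for f in spec.foci]:
        m = _sphere_mask(geom, blob.center_mm, blob.radius_mm)
        if not (m <= head).all():
            raise ValueError(f"lesion/focus at {blob.center_mm} extends outside the head")
        activity[m & brain] = blob.tbr * bg
        sink.append(m & brain)

    rng = np.random.default_rng(spec.seed)
    noisy = activity + rng.normal(0.0, spec.noise_sigma_frac * bg, size=spec.shape)

    # background ROI: crescent of normal tissue in the hemisphere contralateral
    # to the first lesion, in an axial slab above the phantom's insula level
    lo, hi = spec.background_roi_slab
    z_arr = z[0, 0, :]
    slab = (z_arr >= lo * az) & (z_arr <= hi * az)
    side = -1.0 if (spec.lesions and spec.lesions[0].center_mm[0] >= 0) else 1.0
    eroded = ndimage.binary_erosion(brain, iterations=3)
    roi = eroded & slab[None, None, :] & (side * x >= 0.15 * ax)
    for m in lesion_masks + focus_masks:
        roi &= ~ndimage.binary_dilation(m, iterations=2)

    # per-lobe octant regions within the brain
    regions = np.zeros(spec.shape, dtype=np.int16)
    octant = (x >= 0).astype(np.int16) * 4 + (y >= 0).astype(np.int16) * 2 + (z >= 0).astype(np.int16)
    regions[brain] = octant[brain] + 1

    tbr_true = np.zeros(spec.shape, dtype=float)
    tbr_true[brain] = activity[brain] / bg
    btv_masks = [m & (tbr_true > spec.tbr_threshold) for m in lesion_masks]

    def mask(data, label):
        return Mask(data=data, spacing=spec.spacing, origin=origin, label=label)

    vol = lambda data: ImageVolume(data=data, spacing=spec.spacing, origin=origin)
    return Phantom(
        spec=spec,
        labels=vol(labels),
        mu_map=vol(mu),
        head_mask=mask(head, "head"),
        brain_mask=mask(brain, "brain"),
        background_roi=mask(roi, "background_roi"),
        region_labels=vol(regions),
        activity_true=vol(activity),
        activity=vol(noisy),
        lesion_masks=[mask(m, f"lesion_{i}") for i, m in enumerate(lesion_masks)],
        true_btv_masks=[mask(m, f"true_btv_{i}") for i, m in enumerate(btv_masks)],
    )


def perturb_mu_map(phantom: Phantom, artifacts: Sequence[ArtifactSpec]) -> ImageVolume:
    """Apply attenuation-map artifacts to a copy of the true mu-map."""
    mu = np.array(phantom.mu_map.data, dtype=float, copy=True)
    spec = phantom.spec
    geom = phantom.mu_map
    head = phantom.head_mask.data
    labels = phantom.labels.data
    for art in artifacts:
        if art.kind == "registration_shift":
            shift_vox = [-d / s for d, s in zip(art.shift_mm, spec.spacing)]
            mu = ndimage.shift(mu, shift_vox, order=1, mode="nearest")
            continue
        sphere = _sphere_mask(geom, art.center_mm, art.size_mm)
        if art.kind == "false_bone_patch":
            mu[sphere & head] = spec.mu_bone
        elif art.kind == "metal_void":
            mu[sphere & head] = 0.0
        elif art.kind == "air_filled_as_water":
            mu[sphere & head & (labels == LABEL_AIR)] = spec.mu_tissue
        elif art.kind == "missing_skull_flap":
            mu[sphere & (labels == LABEL_BONE)] = spec.mu_tissue
        else:  # pragma: no cover - guarded by ArtifactSpec validation
            raise ValueError(f"unknown artifact kind: {art.kind!r}")
    return geom.with_data(mu)


def _in_plane_projections(delta: np.ndarray, geom: ImageVolume, angle: float,
                          step_mm: float):
    """Full-line integrals of ``delta`` (cm^-1) at one in-plane angle.

    Returns the projection table P[s, z] (integral in cm along the line with
    signed perpendicular offset s through each axial slice) together with the
    offset axis.  Sampling is equal-step with trilinear lookup; points outside
    the grid contribute zero, so every line effectively spans the full grid.
    """
    nx, ny, nz = delta.shape
    dx, dy, dz = geom.spacing
    # physical in-plane extent half-diagonal (mm), measured from grid centre
    cx = geom.origin[0] + (nx - 1) / 2.0 * dx
    cy = geom.origin[1] + (ny - 1) / 2.0 * dy
    half_diag = 0.5 * math.hypot(nx * dx, ny * dy)
    u = np.array([math.cos(angle), math.sin(angle)])   # along the line
    v = np.array([-math.sin(angle), math.cos(angle)])  # perpendicular offset
    s_axis = np.arange(-half_diag, half_diag + step_mm, step_mm)
    t_axis = np.arange(-half_diag, half_diag + step_mm, step_mm)
    # sample positions (mm): centre + s*v + t*u, replicated over all slices
    px = cx + s_axis[:, None] * v[0] + t_axis[None, :] * u[0]
    py = cy + s_axis[:, None] * v[1] + t_axis[None, :] * u[1]
    ix = (px - geom.origin[0]) / dx
    iy = (py - geom.origin[1]) / dy
    ns, nt = ix.shape
    iz = np.arange(nz, dtype=float)
    coords = np.empty((3, ns, nt, nz))
    coords[0] = ix[:, :, None]
    coords[1] = iy[:, :, None]
    coords[2] = iz[None, None, :]
    samples = ndimage.map_coordinates(delta, coords.reshape(3, -1), order=1,
                                      mode="constant", cval=0.0).reshape(ns, nt, nz)
    proj = samples.sum(axis=1) * step_mm * 0.1  # mm -> cm
    return proj, s_axis, v, (cx, cy)


def apply_ac_bias(activity: ImageVolume, mu_ref: ImageVolume, mu_alt: ImageVolume,
                  n_angles: int = 8, step_mm: float | None = None) -> ImageVolume:
    """Propagate a mu-map error into an activity image.

    For each voxel x the multiplicative bias is the mean over K evenly spaced
    in-plane angles of ``exp(integral of (mu_alt - mu_ref) along the full line
    through x)`` — the first-order effect of reconstructing with the wrong
    attenuation factors.  Line integrals use equal-step sampling (default step
    = half the minimum spacing) with trilinear lookup.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    for vol in (mu_ref, mu_alt):
        if not activity.same_grid(vol):
            raise ValueError("activity and mu-maps must share one grid")
    delta = np.asarray(mu_alt.data, dtype=float) - np.asarray(mu_ref.data, dtype=float)
    if not np.any(delta):
        bias = np.ones(activity.shape[:3])
    else:
        if step_mm is None:
            step_mm = min(activity.spacing) / 2.0
        nx, ny, nz = delta.shape
        x, y, _ = activity.coordinate_grids()
        bias = np.zeros((nx, ny, nz))
        for k in range(n_angles):
            angle = math.pi * k / n_angles
            proj, s_axis, v, (cx, cy) = _in_plane_projections(delta, activity, angle, step_mm)
            s_vox = (x[:, :, 0] - cx) * v[0] + (y[:, :, 0] - cy) * v[1]
            f = (s_vox - s_axis[0]) / (s_axis[1] - s_axis[0])
            i0 = np.clip(np.floor(f).astype(int), 0, len(s_axis) - 2)
            w = np.clip(f - i0, 0.0, 1.0)
            line_int = proj[i0, :] * (1.0 - w)[:, :, None] + proj[i0 + 1, :] * w[:, :, None]
            bias += np.exp(line_int)
        bias /= n_angles
    data = np.asarray(activity.data, dtype=float)
    if data.ndim == 4:
        out = data * bias[..., None]
    else:
        out = data * bias
    return activity.with_data(out, frame_info=activity.frame_info)


def make_dynamic_frames(phantom: Phantom,
                        pattern: str = "plateau",
                        noise_sigma_frac: float | None = None,
                        ramp_frac: float = 0.2,
                        peak_min: float = 10.0) -> ImageVolume:
    """Synthesize a 14-frame dynamic series from a phantom.

    The frame scheme is 5 x 1 min, 5 x 3 min and 4 x 5 min (40 min total).
    All tissue follows a common early wash-in ramp up to ``peak_min``; after
    the peak, lesion voxels follow the requested pattern: ``increasing`` ramps
    linearly by ``+ramp_frac`` of the peak value at 40 min, ``plateau`` stays
    constant and ``decreasing`` ramps by ``-ramp_frac``.  Non-lesion tissue is
    plateau-shaped.  Frame values are taken at frame mid-times.
    """
    if pattern not in ("increasing", "plateau", "decreasing"):
        raise ValueError(f"unknown TAC pattern: {pattern!r}")
    spec = phantom.spec
    mids = frame_mid_times_min()
    lesion = np.zeros(phantom.labels.shape, dtype=bool)
    for m in phantom.lesion_masks:
        lesion |= m.data
    base = np.asarray(phantom.activity_true.data, dtype=float)
    slope = {"increasing": ramp_frac, "plateau": 0.0, "decreasing": -ramp_frac}[pattern]
    t_end = mids[-1]
    rng = np.random.default_rng(spec.seed + 1)
    sigma = (spec.noise_sigma_frac if noise_sigma_frac is None else noise_sigma_frac)
    frames = np.empty(base.shape + (len(mids),))
    for idx, t in enumerate(mids):
        wash_in = min(t / peak_min, 1.0)
        late = max(t - peak_min, 0.0) / (t_end - peak_min)
        factor = np.where(lesion, wash_in * (1.0 + slope * late), wash_in)
        frame = base * factor
        if sigma > 0:
            frame = frame + rng.normal(0.0, sigma * spec.background_kbq_ml, size=base.shape)
        frames[..., idx] = frame
    return ImageVolume(data=frames, spacing=spec.spacing, origin=phantom.labels.origin,
                       frame_info=list(FRAME_SCHEME_S))
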