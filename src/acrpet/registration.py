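"""Two-stage rigid alignment of design-space templates to PET images.

STAGE I aligns a non-attenuation-corrected (NAC) appearance template to the
NAC PET image, fixing the phantom core.  STAGE II isolates the resolution-rod
insert — located automatically from summed axial profiles via the two
supporting-disc signatures — and registers the rod template to it, starting
from a user-supplied approximate rotation angle (the insert can sit at any
rotation, which a local optimizer cannot discover on its own).

Similarity metric is Mattes mutual information (32 bins) maximized through a
Gaussian pyramid; the optimization backend is SimpleITK with deterministic
metric sampling (full grid at coarse levels, a regular sub-grid with a
gradient-free polish at the final level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .phantom_geometry import VoxelImage

__all__ = [
    "RigidTransform",
    "PyramidSchedule",
    "RegistrationError",
    "RodDetectionError",
    "register_rigid",
    "detect_rod_extent",
    "two_stage_register",
    "resample",
]


class RegistrationError(RuntimeError):
    pass


class RodDetectionError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# rigid transforms
# --------------------------------------------------------------------------

def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    ax, ay, az = (math.radians(a) for a in (rx, ry, rz))
    Rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    Ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    Rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0],
                   [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF transform mapping template (design) space to image space.

    ``p' = R (p - c) + c + t`` with R composed extrinsically as Rz Ry Rx from
    degree angles and the rotation centre ``c`` at the phantom centroid, so
    rotation and translation estimates stay decoupled.
    """

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        R = _rotation_matrix(*self.rotations)
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translations, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c - R @ c + t
        return M

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        M = self.matrix
        return pts @ M[:3, :3].T + M[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: returns T with T(p) = self(other(p))."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix, self.center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), self.center)

    @classmethod
    def from_matrix(cls, M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = np.asarray(M)[:3, :3]
        # Euler extraction for R = Rz(rz) Ry(ry) Rx(rx)
        ry = math.asin(max(-1.0, min(1.0, -R[2, 0])))
        if abs(math.cos(ry)) > 1e-9:
            rx = math.atan2(R[2, 1], R[2, 2])
            rz = math.atan2(R[1, 0], R[0, 0])
        else:                     # gimbal lock; fold everything into rz
            rx = 0.0
            rz = math.atan2(-R[0, 1], R[1, 1])
        c = np.asarray(center, dtype=float)
        t = np.asarray(M)[:3, 3] - c + R @ c
        return cls(tuple(math.degrees(a) for a in (rx, ry, rz)),
                   tuple(float(v) for v in t), tuple(float(v) for v in c))

    def to_dict(self) -> dict:
        return {
            "rotations_deg": list(self.rotations),
            "translations_mm": list(self.translations),
            "center_mm": list(self.center),
            "convention": "p' = Rz Ry Rx (p - c) + c + t",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rotations_deg"]), tuple(d["translations_mm"]),
                   tuple(d["center_mm"]))


@dataclass(frozen=True)
class PyramidSchedule:
    """Gaussian-pyramid schedule: per-level smoothing sigma [mm] and iteration cap."""

    smoothing_sigmas: tuple[float, ...] = (3.0, 1.0, 0.0)
    iterations: tuple[int, ...] = (10000, 1000, 100)
    shrink_factors: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.smoothing_sigmas) != len(self.iterations):
            raise ValueError("sigmas and iterations must have equal length")
        if any(b > a for a, b in zip(self.smoothing_sigmas, self.smoothing_sigmas[1:])):
            raise ValueError("smoothing sigmas must be non-increasing")

    @property
    def levels(self) -> int:
        return len(self.smoothing_sigmas)

    def shrink(self, level: int) -> int:
        if self.shrink_factors is not None:
            return self.shrink_factors[level]
        return 2 ** (self.levels - 1 - level)


# --------------------------------------------------------------------------
# SimpleITK bridge
# --------------------------------------------------------------------------

def _to_sitk(img: VoxelImage) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(img.values, (2, 1, 0)).astype(np.float32))
    out = sitk.GetImageFromArray(arr)
    out.SetSpacing(tuple(float(v) for v in img.voxel_size))
    out.SetOrigin(tuple(float(v) for v in img.origin))
    return out


def _sitk_to_matrix(t: sitk.Transform) -> np.ndarray:
    t = sitk.Euler3DTransform(t)
    M = np.eye(4)
    M[:3, :3] = np.asarray(t.GetMatrix()).reshape(3, 3)
    c = np.asarray(t.GetCenter())
    M[:3, 3] = np.asarray(t.GetTranslation()) + c - M[:3, :3] @ c
    return M


def register_rigid(moving: VoxelImage, fixed: VoxelImage,
                   schedule: PyramidSchedule | None = None,
                   init: RigidTransform | None = None,
                   center: tuple[float, float, float] | None = None) -> RigidTransform:
    """Rigid mutual-information registration of ``moving`` onto ``fixed``.

    Returns the transform mapping moving (template) world coordinates into
    fixed (image) world coordinates.  Deterministic: Mattes MI (32 bins),
    linear interpolation, run level-by-level through the pyramid —
    regular-step gradient descent (scales from physical shift) at coarse
    levels, then a Powell polish at the final level.
    """
    schedule = schedule or PyramidSchedule()
    if float(np.ptp(fixed.values)) == 0.0 or float(np.ptp(moving.values)) == 0.0:
        raise RegistrationError("degenerate (constant) image")
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    c = center or tuple(np.asarray(moving.origin)
                        + (np.asarray(moving.values.shape) - 1) / 2.0
                        * np.asarray(moving.voxel_size))

    # SimpleITK's resampling transform maps fixed physical points to moving
    # space, i.e. the inverse of the template->image transform we report.
    cur = sitk.Euler3DTransform()
    cur.SetCenter(tuple(float(v) for v in c))
    if init is not None:
        Minv = np.linalg.inv(init.matrix)
        cur.SetMatrix(tuple(Minv[:3, :3].ravel()))
        cur.SetTranslation(tuple(Minv[:3, 3] + Minv[:3, :3] @ np.asarray(c)
                                 - np.asarray(c)))

    for level in range(schedule.levels):
        sigma = schedule.smoothing_sigmas[level]
        iters = schedule.iterations[level]
        shrink = schedule.shrink(level)
        final = level == schedule.levels - 1
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetInterpolator(sitk.sitkLinear)
        if final:
            # gradient-free polish: gradient descent stalls in the flat,
            # interpolation-rippled MI landscape at full resolution
            reg.SetMetricSamplingStrategy(reg.REGULAR)
            reg.SetMetricSamplingPercentage(0.25, 1234)
            reg.SetOptimizerAsPowell(
                numberOfIterations=int(min(iters, 20)), maximumLineIterations=15,
                stepLength=0.5, stepTolerance=1e-4, valueTolerance=1e-9)
        else:
            reg.SetMetricSamplingStrategy(reg.NONE)
            reg.SetOptimizerAsRegularStepGradientDescent(
                learningRate=1.0, minStep=1e-4,
                numberOfIterations=int(min(iters, 500)),
                relaxationFactor=0.6, gradientMagnitudeTolerance=1e-7)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([int(shrink)])
        reg.SetSmoothingSigmasPerLevel([float(sigma)])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
        reg.SetInitialTransform(cur, inPlace=True)
        try:
            reg.Execute(f_img, m_img)
        except RuntimeError as e:     # pragma: no cover - backend failure
            raise RegistrationError(str(e)) from e

    M = np.linalg.inv(_sitk_to_matrix(cur))
    return RigidTransform.from_matrix(M, center=c)


# --------------------------------------------------------------------------
# rod extent detection
# --------------------------------------------------------------------------

def detect_rod_extent(image: VoxelImage, low_fraction: float = 0.5,
                      support_fraction: float = 0.05) -> tuple[float, float]:
    """Locate the axial extent of the resolution-rod insert.

    The summed per-slice intensity profile shows two deep minima where the
    acrylic supporting discs displace all activity; the rod region between
    them retains intermediate intensity (warm background minus cold rods).
    Returns the half-open world-z range enclosed by the two disc signatures.
    Scale invariant; raises :class:`RodDetectionError` if no disc pair exists.
    """
    p = image.values.sum(axis=(0, 1)).astype(np.float64)
    if p.max() <= 0:
        raise RodDetectionError("empty image")
    zs = image.axis_coords(2)
    inside = p > support_fraction * p.max()
    if not inside.any():
        raise RodDetectionError("no object found in axial profile")
    ref = float(np.median(p[inside]))
    low = inside & (p < low_fraction * ref)
    # contiguous runs of low slices = candidate disc slabs
    runs: list[tuple[int, int]] = []
    k = 0
    n = len(p)
    while k < n:
        if low[k]:
            j = k
            while j + 1 < n and low[j + 1]:
                j += 1
            runs.append((k, j))
            k = j + 1
        else:
            k += 1
    for (a0, a1), (b0, b1) in zip(runs[:-1], runs[1:]):
        gap = zs[b0] - zs[a1]
        if not (15.0 <= gap <= 130.0):
            continue
        mid = p[a1 + 1: b0]
        if mid.size == 0:
            continue
        frac = float(np.mean(mid)) / ref
        if 0.3 <= frac <= 0.97:   # cold rods depress but do not kill the signal
            dz = image.voxel_size[2]
            return (float(zs[a1] + dz / 2.0), float(zs[b0] - dz / 2.0))
    raise RodDetectionError("no pair of supporting-disc signatures found")


def mask_axial(image: VoxelImage, z_range: tuple[float, float]) -> VoxelImage:
    """Zero all voxels outside the given world-z range (new image)."""
    zs = image.axis_coords(2)
    keep = (zs >= z_range[0]) & (zs < z_range[1])
    vals = image.values.copy()
    vals[:, :, ~keep] = 0
    return VoxelImage(vals, image.voxel_size, image.origin, image.semantics,
                      dict(image.meta))


def two_stage_register(nac_image: VoxelImage, qnt_image: VoxelImage,
                       templates: dict, rod_angle_init: float = 0.0,
                       schedule: PyramidSchedule | None = None
                       ) -> tuple[RigidTransform, RigidTransform]:
    """Full two-stage template-to-image alignment.

    ``templates`` must provide ``nac`` (whole-phantom NAC appearance template)
    and ``rod_qnt`` (rod-component activity template).  STAGE I registers the
    NAC template to the NAC image (phantom core).  STAGE II crops the
    quantitative image to the automatically detected rod extent, zeroes the
    rest, and registers the rod template starting from the core transform
    composed with a rotation of ``rod_angle_init`` about the phantom axis.
    """
    t_core = register_rigid(templates["nac"], nac_image, schedule=schedule)
    z_range = detect_rod_extent(qnt_image)
    fixed2 = mask_axial(qnt_image, z_range)
    rod_t = templates["rod_qnt"]
    c = t_core.center
    init2 = t_core.compose(
        RigidTransform(rotations=(0.0, 0.0, rod_angle_init), center=c))
    t_rods = register_rigid(rod_t, fixed2, schedule=schedule, init=init2, center=c)
    return t_core, t_rods


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def _target_grid(target) -> tuple[tuple[int, int, int], np.ndarray, np.ndarray]:
    if isinstance(target, VoxelImage):
        return target.values.shape, np.asarray(target.voxel_size), np.asarray(target.origin)
    shape, voxel_size, origin = target
    v = np.asarray(voxel_size, dtype=float)
    if v.ndim == 0:
        v = np.repeat(v, 3)
    return tuple(shape), v, np.asarray(origin, dtype=float)


def resample(source: VoxelImage, transform: RigidTransform | None, target,
             mode: str = "trilinear", supersample: int | None = None) -> VoxelImage:
    """Map ``source`` into a target grid under a rigid transform.

    ``target`` is a VoxelImage used as a grid descriptor or a tuple
    ``(shape, voxel_size, origin)``.  Modes: ``trilinear`` point sampling,
    ``nearest`` for label images, ``mean-pool`` for coarsening by >= 2x
    (each target voxel averages a supersampled block, preserving means).
    """
    shape, tvox, torig = _target_grid(target)
    T = transform or RigidTransform()
    Minv = np.linalg.inv(T.matrix)

    axes = [torig[a] + tvox[a] * np.arange(shape[a]) for a in range(3)]
    order = 0 if mode == "nearest" else 1

    if mode == "mean-pool":
        ratio = float(np.max(tvox / np.asarray(source.voxel_size)))
        k = supersample or int(min(4, max(2, round(ratio))))
        offs = [(np.arange(k) + 0.5) / k - 0.5 for _ in range(3)]
    else:
        k = 1
        offs = [np.array([0.0])] * 3

    out = np.zeros(shape, dtype=np.float64)
    svox = np.asarray(source.voxel_size)
    sorig = np.asarray(source.origin)
    n_sub = 0
    for ox in offs[0]:
        for oy in offs[1]:
            for oz in offs[2]:
                X, Y, Z = np.meshgrid(axes[0] + ox * tvox[0],
                                      axes[1] + oy * tvox[1],
                                      axes[2] + oz * tvox[2], indexing="ij")
                pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()])
                wpts = Minv[:3, :3] @ pts + Minv[:3, 3:4]
                idx = (wpts - sorig[:, None]) / svox[:, None]
                vals = map_coordinates(source.values.astype(np.float32), idx,
                                       order=order, mode="constant", cval=0.0)
                out += vals.reshape(shape)
                n_sub += 1
    out /= n_sub

    if not np.any(out) and np.any(source.values):
        raise RegistrationError("resample: empty overlap with target grid")

    dtype = np.int16 if mode == "nearest" and source.semantics == "label" else np.float32
    return VoxelImage(out.astype(dtype), tuple(tvox), tuple(torig),
                      source.semantics, dict(source.meta))
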