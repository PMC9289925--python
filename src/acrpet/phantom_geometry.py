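"""Parametric model of the ACR-approved Jaszczak PET phantom.

The phantom is described as a stack of 2D transaxial sectional profiles,
each a painter's-order list of circular/annular primitives with an attached
material (attenuation at 511 keV plus a relative activity concentration).
Voxelization rasterizes each section once in 2D on the requested grid and
replicates it over the section's axial extent, which reproduces the
high-resolution stacked-profile design the templates are derived from.

Coordinate convention: world millimetres, phantom axis along +z, origin at
the transaxial centre and the axial midpoint of the phantom interior.
Axial extents are half-open ``[z_start, z_end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Material",
    "Primitive",
    "SectionProfile",
    "PhantomSpec",
    "VoxelImage",
    "MATERIALS",
    "REGION_CODES",
    "MU_VALUES",
    "default_acr_spec",
    "voxelize",
    "compartment_volume",
]


# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """A phantom material: linear attenuation at 511 keV and relative activity.

    ``relative_activity`` is 0 for cold compartments, 1 for the warm
    background, and ``None`` for the hot-insert solution (substituted by the
    requested insert-to-background ratio at voxelization time).
    """

    name: str
    mu: float                      # cm^-1 at 511 keV
    relative_activity: float | None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.relative_activity is not None and self.relative_activity < 0:
            raise ValueError("relative_activity must be non-negative")


#: 511 keV linear attenuation coefficients [cm^-1] for the phantom materials.
MU_VALUES = {
    "air": 0.0,
    "water": 0.096,
    "nylon": 0.1036,
    "acrylic": 0.117,
    "teflon": 0.148,
}

MATERIALS: Mapping[str, Material] = {
    "air": Material("air", MU_VALUES["air"], 0.0),
    "water_bg": Material("water_bg", MU_VALUES["water"], 1.0),
    "water_cold": Material("water_cold", MU_VALUES["water"], 0.0),
    "hot_solution": Material("hot_solution", MU_VALUES["water"], None),
    "acrylic": Material("acrylic", MU_VALUES["acrylic"], 0.0),
    "nylon": Material("nylon", MU_VALUES["nylon"], 0.0),
    "teflon": Material("teflon", MU_VALUES["teflon"], 0.0),
}

#: Stable integer region codes for label images.
REGION_CODES = {
    "outside": 0,
    "background": 1,
    "shell": 2,
    "insert_wall": 3,
    "rod_disc": 4,
    "screw": 5,
    "hot_25mm": 10,
    "hot_16mm": 11,
    "hot_12mm": 12,
    "hot_8mm": 13,
    "cold_air": 20,
    "cold_water": 21,
    "teflon": 22,
    # rod sets, largest diameter first
    "rods_1": 30,
    "rods_2": 31,
    "rods_3": 32,
    "rods_4": 33,
    "rods_5": 34,
    "rods_6": 35,
}


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Primitive:
    """A filled circle or annulus in a transaxial section (painter's order)."""

    cx: float
    cy: float
    r_outer: float
    material: Material
    region: int
    r_inner: float = 0.0
    mu_only: bool = False          # painted in mu/label maps but not activity


@dataclass(frozen=True)
class SectionProfile:
    index: int
    z_start: float
    z_end: float
    primitives: tuple[Primitive, ...]

    def __post_init__(self) -> None:
        if self.z_end <= self.z_start:
            raise ValueError("section axial extent must be non-empty")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric + material description of the phantom core and rod insert."""

    core_sections: tuple[SectionProfile, ...]
    rod_sections: tuple[SectionProfile, ...]
    rod_rotation_deg: float
    internal_diameter: float = 210.0
    height: float = 190.0
    wall_thickness: float = 3.2
    insert_diameters_hot: tuple[float, ...] = (25.0, 16.0, 12.0, 8.0)
    cold_insert_diameter: float = 25.0
    insert_wall_thickness: float = 1.5
    rod_diameters: tuple[float, ...] = (12.7, 11.1, 9.5, 7.9, 6.4, 4.8)
    rod_pitch_factor: float = 2.0
    insert_ring_radius: float = 65.0
    insert_centers: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    rod_centers: Mapping[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)
    insert_z: tuple[float, float] = (47.0, 95.0)
    rod_z: tuple[float, float] = (-80.0, -25.0)

    @property
    def z_extent(self) -> tuple[float, float]:
        zs = [s.z_start for s in self.core_sections]
        ze = [s.z_end for s in self.core_sections]
        return (min(zs), max(ze))

    @property
    def outer_radius(self) -> float:
        return self.internal_diameter / 2.0 + self.wall_thickness

    @property
    def insert_midplane(self) -> float:
        return 0.5 * (self.insert_z[0] + self.insert_z[1])

    @property
    def rod_midplane(self) -> float:
        return 0.5 * (self.rod_z[0] + self.rod_z[1])


# --------------------------------------------------------------------------
# voxel image container
# --------------------------------------------------------------------------

@dataclass
class VoxelImage:
    """3D scalar grid with world geometry and value semantics.

    ``values`` is indexed ``[i, j, k]`` along world x, y, z; ``origin`` is
    the world position of the centre of voxel (0, 0, 0); semantics is one of
    ``mu`` [cm^-1], ``activity`` [Bq/mL or relative], ``counts``, ``label``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    semantics: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be 3D")
        if np.isscalar(self.voxel_size):
            v = float(self.voxel_size)
            self.voxel_size = (v, v, v)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.semantics not in {"mu", "activity", "counts", "label"}:
            raise ValueError(f"unknown semantics: {self.semantics}")

    # -- geometry -----------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        A = np.diag(list(self.voxel_size) + [1.0])
        A[:3, 3] = self.origin
        return A

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    # -- I/O ----------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        arr = self.values
        if self.semantics == "label":
            arr = arr.astype(np.int16)
        img = nib.Nifti1Image(arr, self.affine)
        img.header.set_xyzt_units("mm")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path_or_img, semantics: str, meta: dict | None = None) -> "VoxelImage":
        img = path_or_img if isinstance(path_or_img, nib.Nifti1Image) else nib.load(str(path_or_img))
        A = img.affine
        scales = np.linalg.norm(A[:3, :3], axis=0)
        if not np.allclose(A[:3, :3], np.diag(scales), atol=1e-6):
            raise ValueError("only axis-aligned NIfTI grids are supported")
        return cls(
            values=np.asarray(img.dataobj).astype(np.float32 if semantics != "label" else np.int16),
            voxel_size=tuple(scales),
            origin=tuple(A[:3, 3]),
            semantics=semantics,
            meta=meta or {},
        )


# --------------------------------------------------------------------------
# default phantom
# --------------------------------------------------------------------------

def _rot2d(x: float, y: float, deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return (c * x - s * y, s * x + c * y)


def _rod_lattice(diameter: float, sector_deg: float, r_disc: float,
                 pitch_factor: float, rotation_deg: float) -> tuple[tuple[float, float], ...]:
    """Triangular lattice of rod centres filling one 60-degree pie sector.

    Centre-to-centre pitch is ``pitch_factor * diameter`` (standard Jaszczak
    layout).  Rods are kept clear of the sector boundaries, the phantom hub
    and the supporting disc rim.
    """
    p = pitch_factor * diameter
    r = diameter / 2.0
    half = 30.0                   # half sector opening angle
    margin = 1.0                  # clearance from sector edges / rim, mm
    r_min, r_max = 14.0, r_disc - r - 2.0
    n = int(math.ceil(2 * r_disc / p)) + 2
    pts = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            # lattice in sector-local frame, local +x = sector bisector
            x = i * p + (j % 2) * p / 2.0
            y = j * p * math.sqrt(3.0) / 2.0
            rad = math.hypot(x, y)
            if rad < r_min or rad > r_max:
                continue
            ang = math.degrees(math.atan2(y, x))
            # clearance from the two sector boundary lines
            d_edge = rad * math.sin(math.radians(half - abs(ang)))
            if abs(ang) >= half or d_edge < r + margin:
                continue
            pts.append(_rot2d(x, y, sector_deg + rotation_deg))
    return tuple(pts)


def default_acr_spec(rod_rotation_deg: float = 0.0) -> PhantomSpec:
    """Built-in phantom description with the printed dimensions and materials.

    Internal diameter 210 mm, interior height 190 mm; faceplate with four hot
    inserts (diameters 25/16/12/8 mm), cold air and water cylinders and a solid
    Teflon cylinder (all 25 mm; fillable inserts carry a 1.5 mm acrylic wall);
    a uniform middle region; and a separately positioned resolution-rod insert
    with six pie-sector sets of acrylic rods (4.8-12.7 mm diameter).

    ``rod_rotation_deg`` rotates the rod insert about the phantom axis.
    """
    m = MATERIALS
    R_in = 105.0
    wall = 3.2
    R_out = R_in + wall
    iw = 1.5

    def shell_and_bg() -> list[Primitive]:
        return [
            Primitive(0, 0, R_out, m["acrylic"], REGION_CODES["shell"]),
            Primitive(0, 0, R_in, m["water_bg"], REGION_CODES["background"]),
        ]

    # faceplate inserts evenly spread on a ring
    insert_order = [
        ("hot_25mm", 12.5, "hot_solution", True),
        ("hot_16mm", 8.0, "hot_solution", True),
        ("hot_12mm", 6.0, "hot_solution", True),
        ("hot_8mm", 4.0, "hot_solution", True),
        ("cold_air", 12.5, "air", True),
        ("cold_water", 12.5, "water_cold", True),
        ("teflon", 12.5, "teflon", False),      # solid Teflon: no wall
    ]
    centers: dict[str, tuple[float, float]] = {}
    insert_prims: list[Primitive] = []
    for idx, (name, r_int, mat, has_wall) in enumerate(insert_order):
        ang = idx * 360.0 / len(insert_order)
        cx, cy = _rot2d(65.0, 0.0, ang)
        centers[name] = (cx, cy)
        if has_wall:
            insert_prims.append(Primitive(cx, cy, r_int + iw, m["acrylic"],
                                          REGION_CODES["insert_wall"]))
        insert_prims.append(Primitive(cx, cy, r_int, m[mat], REGION_CODES[name]))

    # nylon fixing screws in the top plate (nominal positions; mu-map only)
    screws = [
        Primitive(*_rot2d(85.0, 0.0, a), 2.5, m["nylon"], REGION_CODES["screw"],
                  mu_only=True)
        for a in (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    ]

    core = (
        SectionProfile(1, 95.0, 105.0,
                       tuple([Primitive(0, 0, R_out, m["acrylic"], REGION_CODES["shell"])]
                             + screws)),
        SectionProfile(2, 47.0, 95.0, tuple(shell_and_bg() + insert_prims)),
        SectionProfile(3, -19.0, 47.0, tuple(shell_and_bg())),
        SectionProfile(4, -95.0, -19.0, tuple(shell_and_bg())),
        SectionProfile(5, -105.0, -95.0,
                       (Primitive(0, 0, R_out, m["acrylic"], REGION_CODES["shell"]),)),
    )

    # rod insert: two supporting discs and six pie sectors of rods
    rod_diams = (12.7, 11.1, 9.5, 7.9, 6.4, 4.8)
    r_disc = 104.0
    rod_centers: dict[str, tuple[tuple[float, float], ...]] = {}
    rod_prims: list[Primitive] = [
        Primitive(0, 0, r_disc, m["water_bg"], REGION_CODES["background"]),
    ]
    for si, d in enumerate(rod_diams):
        name = f"rods_{si + 1}"
        pts = _rod_lattice(d, si * 60.0 + 30.0, r_disc, 2.0, rod_rotation_deg)
        rod_centers[name] = pts
        for (cx, cy) in pts:
            rod_prims.append(Primitive(cx, cy, d / 2.0, m["acrylic"], REGION_CODES[name]))
    disc = (Primitive(0, 0, r_disc, m["acrylic"], REGION_CODES["rod_disc"]),)
    rods = (
        SectionProfile(9, -25.0, -19.0, disc),
        SectionProfile(10, -80.0, -25.0, tuple(rod_prims)),
        SectionProfile(11, -86.0, -80.0, disc),
    )

    return PhantomSpec(
        core_sections=core,
        rod_sections=rods,
        rod_rotation_deg=rod_rotation_deg,
        insert_centers=centers,
        rod_centers=rod_centers,
    )


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

def _paint_section(primitives: Sequence[Primitive], xs: np.ndarray, ys: np.ndarray,
                   quantity: str, insert_bg_ratio: float | None) -> np.ndarray:
    """Rasterize one 2D section: voxel centre-in-primitive, painter's order."""
    X = xs[:, None]
    Y = ys[None, :]
    if quantity == "label":
        out = np.zeros((xs.size, ys.size), dtype=np.int16)
    else:
        out = np.zeros((xs.size, ys.size), dtype=np.float32)
    for p in primitives:
        if quantity == "activity" and p.mu_only:
            continue
        d2 = (X - p.cx) ** 2 + (Y - p.cy) ** 2
        mask = d2 <= p.r_outer ** 2
        if p.r_inner > 0:
            mask &= d2 > p.r_inner ** 2
        if quantity == "mu":
            out[mask] = p.material.mu
        elif quantity == "label":
            out[mask] = p.region
        else:
            a = p.material.relative_activity
            out[mask] = insert_bg_ratio if a is None else a
    return out


def voxelize(spec: PhantomSpec, voxel_size: float, quantity: str,
             insert_bg_ratio: float | None = None, component: str = "all",
             axial_range: tuple[float, float] | None = None,
             transaxial_halfwidth: float | None = None) -> VoxelImage:
    """Rasterize the phantom onto an isotropic grid.

    quantity: ``mu`` (cm^-1), ``activity`` (relative; hot inserts take
    ``insert_bg_ratio``, background 1, cold compartments 0) or ``label``
    (stable region codes, see :data:`REGION_CODES`).  ``component`` selects
    ``core``, ``rods`` or ``all`` (rod insert painted over the core).
    ``axial_range`` restricts the grid axially (world mm, half-open).
    """
    if quantity not in {"mu", "activity", "label"}:
        raise ValueError(f"unknown quantity: {quantity}")
    if not (0 < voxel_size <= 5.0):
        raise ValueError("voxel_size must be in (0, 5] mm")
    if quantity == "activity" and insert_bg_ratio is None:
        raise ValueError("insert_bg_ratio required for activity maps")

    if component == "core":
        sections: list[SectionProfile] = list(spec.core_sections)
    elif component == "rods":
        sections = list(spec.rod_sections)
    elif component == "all":
        # painter's order: rod insert overrides the core water compartment
        sections = list(spec.core_sections) + list(spec.rod_sections)
    else:
        raise ValueError(f"unknown component: {component}")

    if axial_range is not None:
        z_lo, z_hi = axial_range
        if z_hi <= z_lo:
            raise ValueError("axial_range must be non-empty")
    else:
        z_lo = min(s.z_start for s in sections)
        z_hi = max(s.z_end for s in sections)

    half = transaxial_halfwidth or (spec.outer_radius + 2.0)
    n_xy = int(round(2 * half / voxel_size))
    xs = -half + voxel_size * (np.arange(n_xy) + 0.5)
    n_z = max(1, int(round((z_hi - z_lo) / voxel_size)))
    zs = z_lo + voxel_size * (np.arange(n_z) + 0.5)

    dtype = np.int16 if quantity == "label" else np.float32
    vol = np.zeros((n_xy, n_xy, n_z), dtype=dtype)

    # group z-slices by the set of sections covering them, rasterize once each
    cache: dict[tuple[int, ...], np.ndarray] = {}
    for k, z in enumerate(zs):
        covering = tuple(i for i, s in enumerate(sections) if s.z_start <= z < s.z_end)
        if not covering:
            continue
        if covering not in cache:
            prims: list[Primitive] = []
            for i in covering:
                prims.extend(sections[i].primitives)
            cache[covering] = _paint_section(prims, xs, xs, quantity, insert_bg_ratio)
        vol[:, :, k] = cache[covering]

    return VoxelImage(
        values=vol,
        voxel_size=(voxel_size,) * 3,
        origin=(xs[0], xs[0], zs[0]),
        semantics="mu" if quantity == "mu" else ("label" if quantity == "label" else "activity"),
        meta={"component": component},
    )


def compartment_volume(label_image: VoxelImage, region: int | str) -> float:
    """Volume [mL] of a labelled compartment: voxel count x voxel volume."""
    if label_image.semantics != "label":
        raise ValueError("compartment_volume requires a label image")
    if isinstance(region, str):
        if region not in REGION_CODES:
            raise KeyError(f"unknown region {region!r}")
        code = REGION_CODES[region]
    else:
        code = int(region)
        if code not in REGION_CODES.values():
            raise KeyError(f"unknown region code {code}")
    n = int(np.count_nonzero(label_image.values == code))
    return n * label_image.voxel_volume_ml
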