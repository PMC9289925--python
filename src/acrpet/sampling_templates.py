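"""Concentric-ring VOI templates and registration templates in design space.

Every sampling pattern is a set of concentric rings (tubes in 3D, axis
parallel to the phantom axis) defined on a fine design grid (0.5 mm by
default).  Ring values are later reduced to per-ring means, giving a finely
sampled radial profile through each insert/rod boundary — the knife-edge
response used for resolution estimation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom_geometry import PhantomSpec, VoxelImage, voxelize

__all__ = [
    "RingTemplate",
    "effective_radius",
    "make_insert_templates",
    "make_rod_templates",
    "make_background_template",
    "make_registration_templates",
    "transaxial_attenuation_factor",
]


def effective_radius(r_in: float, r_out: float) -> float:
    """Area-weighted mean radius of an annulus [r_in, r_out].

    r_eff = (2/3) (r_out^3 - r_in^3) / (r_out^2 - r_in^2); the unbiased
    abscissa for a ring-mean sample of a radial profile.
    """
    return (2.0 / 3.0) * (r_out**3 - r_in**3) / (r_out**2 - r_in**2)


@dataclass
class RingTemplate:
    """Labelled concentric-ring VOI pattern, possibly replicated at many centres.

    ``ring_bounds`` are contiguous (inner radius of ring i+1 equals the outer
    radius of ring i); ``centers`` holds one (x, y) per replica (one for the
    inserts/background, one per rod for a rod set — per-ring values are pooled
    across replicas).  ``exclusions`` are (cx, cy, radius) circles whose
    interior is never sampled (background holes around inserts, neighbouring
    rods).  ``axial_slab`` is the half-open [z_start, z_end) world extent.
    """

    name: str
    centers: tuple[tuple[float, float], ...]
    ring_bounds: tuple[tuple[float, float], ...]
    axial_slab: tuple[float, float]
    grid: float = 0.5
    polarity: str | None = None                  # 'hot' | 'cold' | None
    true_boundary_radius: float | None = None
    edge_radius: float | None = None             # physical knife-edge radius
    wall_annulus: tuple[float, float] | None = None   # cold wall inside a hot edge
    exclusions: tuple[tuple[float, float, float], ...] = ()
    clip_radius: float | None = None             # keep samples within this phantom radius
    _points: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.edge_radius is None:
            self.edge_radius = self.true_boundary_radius
        for (a, b), (c, _d) in zip(self.ring_bounds[:-1], self.ring_bounds[1:]):
            if not math.isclose(b, c):
                raise ValueError("ring bounds must be contiguous")
            if b <= a:
                raise ValueError("ring outer radius must exceed inner radius")

    @property
    def n_rings(self) -> int:
        return len(self.ring_bounds)

    @property
    def effective_radii(self) -> np.ndarray:
        return np.array([effective_radius(a, b) for a, b in self.ring_bounds])

    @property
    def center(self) -> tuple[float, float]:
        return self.centers[0]

    # -- sampling geometry --------------------------------------------------

    def ring_points(self) -> list[np.ndarray]:
        """Per-ring (N, 2) template-space sample points at the design grid.

        Points are voxel centres of the design grid falling inside the ring,
        replicated over all centres, with exclusion zones removed.
        """
        if self._points is not None:
            return self._points
        r_max = self.ring_bounds[-1][1]
        n = int(math.ceil(2 * r_max / self.grid)) + 1
        off = (np.arange(n) - (n - 1) / 2.0) * self.grid
        OX, OY = np.meshgrid(off, off, indexing="ij")
        r2 = OX**2 + OY**2
        pts_per_ring: list[list[np.ndarray]] = [[] for _ in self.ring_bounds]
        for cx, cy in self.centers:
            for i, (a, b) in enumerate(self.ring_bounds):
                m = r2 <= b**2
                if a > 0:
                    m &= r2 > a**2
                p = np.column_stack([OX[m] + cx, OY[m] + cy])
                for ex, ey, er in self.exclusions:
                    if (ex, ey) == (cx, cy):
                        continue
                    p = p[(p[:, 0] - ex) ** 2 + (p[:, 1] - ey) ** 2 > er**2]
                if self.clip_radius is not None:
                    p = p[p[:, 0] ** 2 + p[:, 1] ** 2 <= self.clip_radius**2]
                pts_per_ring[i].append(p)
        out = [np.concatenate(ps, axis=0) if ps else np.empty((0, 2)) for ps in pts_per_ring]
        if any(p.shape[0] == 0 for p in out):
            raise ValueError(f"template {self.name!r}: empty ring at {self.grid} mm grid")
        self._points = out
        return out

    def label_map(self, halfwidth: float | None = None) -> VoxelImage:
        """2D (single-slice) integer label image of the rings, for export/QC."""
        pts = self.ring_points()
        r_max = max(abs(p).max() for p in pts if p.size) + self.grid
        half = halfwidth or r_max
        n = int(math.ceil(2 * half / self.grid))
        arr = np.zeros((n, n, 1), dtype=np.int16)
        origin = -half + self.grid / 2.0
        for i, p in enumerate(pts):
            ix = np.round((p[:, 0] - origin) / self.grid).astype(int)
            iy = np.round((p[:, 1] - origin) / self.grid).astype(int)
            ok = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
            arr[ix[ok], iy[ok], 0] = i + 1
        return VoxelImage(arr, (self.grid, self.grid, self.axial_slab[1] - self.axial_slab[0]),
                          (origin, origin, self.axial_slab[0]), "label",
                          meta={"template": self.name})

    def sidecar(self) -> dict:
        return {
            "name": self.name,
            "centers": [list(c) for c in self.centers],
            "ring_bounds": [list(b) for b in self.ring_bounds],
            "effective_radii": self.effective_radii.tolist(),
            "axial_slab": list(self.axial_slab),
            "grid": self.grid,
            "polarity": self.polarity,
            "true_boundary_radius": self.true_boundary_radius,
            "edge_radius": self.edge_radius,
            "wall_annulus": list(self.wall_annulus) if self.wall_annulus else None,
            "exclusions": [list(e) for e in self.exclusions],
        }

    def save_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)


# --------------------------------------------------------------------------
# ring layouts
# --------------------------------------------------------------------------

def _insert_ring_bounds(r_boundary: float, n_rings: int,
                        wall_step: float = 2.5, step: float = 2.0) -> tuple[tuple[float, float], ...]:
    """Ring boundaries for a faceplate insert.

    Central circle of diameter 4 mm, 2 mm ring spacing, except around the
    insert boundary: one boundary is pinned to the (inner) wall surface so
    sampling aligns with the 1.5 mm insert walls, and the ring just outside
    it is 2.5 mm wide to jump clear of the wall.
    """
    bounds = [0.0]
    while bounds[-1] + step <= r_boundary - step + 1e-9:
        bounds.append(bounds[-1] + step)
    bounds.append(r_boundary)
    bounds.append(r_boundary + wall_step)
    while len(bounds) < n_rings + 1:
        bounds.append(bounds[-1] + step)
    bounds = bounds[: n_rings + 1]
    return tuple(zip(bounds[:-1], bounds[1:]))


def make_insert_templates(spec: PhantomSpec, voxel_size: float = 0.5
                          ) -> Mapping[str, RingTemplate]:
    """Concentric-ring templates for the seven faceplate inserts.

    10 rings per hot insert, 11 per cold insert (cold recovery is harder and
    benefits from deeper background sampling); 10 mm axial slab centred at
    the insert axial midpoint.
    """
    if voxel_size > 0.5:
        raise ValueError("insert templates require a design grid <= 0.5 mm")
    zc = spec.insert_midplane
    slab = (zc - 5.0, zc + 5.0)
    radii = {
        "hot_25mm": 12.5, "hot_16mm": 8.0, "hot_12mm": 6.0, "hot_8mm": 4.0,
        "cold_air": 12.5, "cold_water": 12.5, "teflon": 12.5,
    }
    iw = spec.insert_wall_thickness
    out: dict[str, RingTemplate] = {}
    for name, r in radii.items():
        hot = name.startswith("hot")
        # knife-edge location: hot fillable inserts step to the cold acrylic
        # wall at r; the cold fillable compartments (wall itself is cold) end
        # at r + wall; solid Teflon has no wall.
        if hot:
            edge, wall = r, (r, r + iw)
        elif name == "teflon":
            edge, wall = r, None
        else:
            edge, wall = r + iw, None
        out[name] = RingTemplate(
            name=name,
            centers=(spec.insert_centers[name],),
            ring_bounds=_insert_ring_bounds(r, 10 if hot else 11),
            axial_slab=slab,
            grid=voxel_size,
            polarity="hot" if hot else "cold",
            true_boundary_radius=r,
            edge_radius=edge,
            wall_annulus=wall,
        )
    return out


#: rings per rod set, largest rod diameter first (packing limits the spread)
ROD_RING_COUNTS = (11, 10, 9, 7, 6, 4)


def make_rod_templates(spec: PhantomSpec, voxel_size: float = 0.5
                       ) -> Mapping[str, RingTemplate]:
    """Ring templates for the six resolution-rod sets.

    One identical ring pattern per rod, pooled across all rods of a set:
    central circle of diameter 2.52 mm followed by rings at 2 mm spacing.
    Samples falling inside any *other* rod of the insert (or outside the
    supporting disc) are excluded so the pooled profile sees only the rod of
    interest against the warm background.
    """
    if voxel_size > 0.5:
        raise ValueError("rod templates require a design grid <= 0.5 mm")
    zc = spec.rod_midplane
    slab = (zc - 5.0, zc + 5.0)
    all_rods = [
        (cx, cy, d / 2.0)
        for name, d in zip(sorted(spec.rod_centers), spec.rod_diameters)
        for (cx, cy) in spec.rod_centers[name]
    ]
    out: dict[str, RingTemplate] = {}
    for si, (d, n_rings) in enumerate(zip(spec.rod_diameters, ROD_RING_COUNTS)):
        name = f"rods_{si + 1}"
        bounds = [0.0, 1.26] + [1.26 + 2.0 * i for i in range(1, n_rings)]
        out[name] = RingTemplate(
            name=name,
            centers=spec.rod_centers[name],
            ring_bounds=tuple(zip(bounds[:-1], bounds[1:])),
            axial_slab=slab,
            grid=voxel_size,
            polarity="cold",
            true_boundary_radius=d / 2.0,
            exclusions=tuple(all_rods),
            clip_radius=103.0,
        )
    return out


def make_background_template(spec: PhantomSpec, voxel_size: float = 0.5) -> RingTemplate:
    """18 concentric background rings spanning the phantom interior.

    Outer diameters grow in 12 mm steps (6 mm radial width), the outermost
    ring truncated at the 210 mm internal diameter; holes exclude each insert
    and its vicinity (insert outer radius + 6 mm).
    """
    if voxel_size > 0.5:
        raise ValueError("background template requires a design grid <= 0.5 mm")
    r_int = spec.internal_diameter / 2.0
    bounds = []
    for k in range(18):
        bounds.append((6.0 * k, min(6.0 * (k + 1), r_int)))
    wall = spec.insert_wall_thickness
    outer = {
        "hot_25mm": 12.5 + wall, "hot_16mm": 8.0 + wall, "hot_12mm": 6.0 + wall,
        "hot_8mm": 4.0 + wall, "cold_air": 12.5 + wall, "cold_water": 12.5 + wall,
        "teflon": 12.5,
    }
    excl = tuple(
        (spec.insert_centers[n][0], spec.insert_centers[n][1], r + 6.0)
        for n, r in outer.items()
    )
    zc = spec.insert_midplane
    return RingTemplate(
        name="background",
        centers=((0.0, 0.0),),
        ring_bounds=tuple(bounds),
        axial_slab=(zc - 5.0, zc + 5.0),
        grid=voxel_size,
        polarity=None,
        exclusions=excl,
    )


# --------------------------------------------------------------------------
# registration templates
# --------------------------------------------------------------------------

def transaxial_attenuation_factor(spec: PhantomSpec, xs: np.ndarray, ys: np.ndarray,
                                  n_angles: int = 16, step_mm: float = 2.0) -> np.ndarray:
    """Approximate NAC appearance factor exp(-mean line integral of mu / 2).

    For each transaxial position the attenuation line integral through the
    central (uniform) section of the mu-map is averaged over ``n_angles``
    in-plane directions; the factor suppresses the object centre relative to
    its periphery, mimicking a non-attenuation-corrected reconstruction.
    """
    # rasterize the uniform mid-section mu profile on a coarse working grid
    g = 2.0
    half = spec.outer_radius + 6.0
    n = int(round(2 * half / g))
    wx = -half + g * (np.arange(n) + 0.5)
    mid = [s for s in spec.core_sections if s.z_start <= 0.0 < s.z_end][0]
    from .phantom_geometry import _paint_section
    mu2d = _paint_section(mid.primitives, wx, wx, "mu", None)

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    L = math.hypot(2 * half, 2 * half) / 2.0
    s = np.arange(-L, L + step_mm, step_mm)
    integ = np.zeros(X.shape, dtype=np.float64)
    for a in np.linspace(0.0, math.pi, n_angles, endpoint=False):
        dx, dy = math.cos(a), math.sin(a)
        px = (X[..., None] + s * dx - wx[0]) / g
        py = (Y[..., None] + s * dy - wx[0]) / g
        vals = map_coordinates(mu2d, [px.ravel(), py.ravel()], order=1,
                               mode="constant", cval=0.0)
        integ += vals.reshape(px.shape).sum(axis=-1) * (step_mm / 10.0)
    integ /= n_angles
    return np.exp(-0.5 * integ)


def make_registration_templates(spec: PhantomSpec, grid: float = 0.4,
                                insert_bg_ratio: float = 2.5
                                ) -> tuple[VoxelImage, VoxelImage]:
    """Build the NAC registration template and the rod-insert QNT template.

    The NAC template is the activity map modulated by the transaxial
    attenuation factor (peripheral enhancement); the rod template is the
    activity map of the rod component alone, zero elsewhere.  Both share the
    design space of the mu-map.
    """
    z_extent = spec.z_extent
    nac = voxelize(spec, grid, "activity", insert_bg_ratio, component="all",
                   axial_range=z_extent)
    # attenuation factor varies smoothly: evaluate on a 2 mm grid, interpolate
    half = spec.outer_radius + 6.0
    nc = int(round(2 * half / 2.0))
    cx = -half + 2.0 * (np.arange(nc) + 0.5)
    fac_c = transaxial_attenuation_factor(spec, cx, cx)
    ix = (nac.axis_coords(0) - cx[0]) / 2.0
    iy = (nac.axis_coords(1) - cx[0]) / 2.0
    IX, IY = np.meshgrid(ix, iy, indexing="ij")
    fac = map_coordinates(fac_c, [IX.ravel(), IY.ravel()], order=1,
                          mode="nearest").reshape(IX.shape)
    nac.values = (nac.values * fac[:, :, None]).astype(np.float32)
    nac.meta["kind"] = "nac_template"
    rod = voxelize(spec, grid, "activity", insert_bg_ratio, component="rods",
                   axial_range=z_extent)
    rod.meta["kind"] = "rod_qnt_template"
    return nac, rod
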