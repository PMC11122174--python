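"""CT-like orbital phantoms with closed-form ground truth.

A phantom is a blind cavity (hemisphere, cone or paraboloid of revolution)
filled with soft tissue, enclosed by a thin bone shell and embedded in a
soft-tissue block, opening anteriorly through a planar aperture that is
flush with the anterior face of the block (air lies in front of it).  The
shell can be perforated randomly to mimic the sub-resolution thin walls of
the real orbit, and two failure-mode defects can be injected:

* ``lacrimal_channel`` — a bone-walled soft-tissue channel through the wall
  into a bone-enclosed pocket of known volume, so that downstream
  segmentation overestimates the cavity by the pocket volume;
* ``wall_fracture`` — a contiguous wall patch removed, leaving the cavity
  open to the surrounding soft tissue (a leak the segmentation's guard is
  expected to catch).

All geometry is defined analytically, so every phantom carries exact
volume / surface-area / depth ground truth.

Axis convention: array order (z, y, x); z runs anterior -> posterior; the
aperture plane is perpendicular to z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PhantomGeometryError
from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "inject_defect",
    "SHAPE_FAMILIES",
    "DEFECT_KINDS",
]

SHAPE_FAMILIES = ("hemisphere", "cone", "paraboloid")
DEFECT_KINDS = ("none", "lacrimal_channel", "wall_fracture")

DEFAULT_MATERIAL_HU = {"air": -1000.0, "soft_tissue": 40.0, "bone": 700.0}


@dataclass
class PhantomSpec:
    """Parameters of one phantom orbit.

    ``depth_mm`` is the cavity depth along the z axis from the aperture
    plane to the apex; ``aperture_radius_mm`` the radius of the anterior
    opening.  For a hemisphere the two coincide and ``depth_mm`` must equal
    ``aperture_radius_mm``.
    """

    shape_family: str
    depth_mm: float
    aperture_radius_mm: float
    wall_thickness_mm: float = 1.5
    wall_gap_fraction: float = 0.0
    material_hu: dict = field(default_factory=lambda: dict(DEFAULT_MATERIAL_HU))
    voxel_spacing_mm: tuple = (0.5, 0.5, 0.5)
    side: str = "left"
    defect: str = "none"
    rng_seed: int = 0
    # geometry of the embedding, mm
    soft_tissue_margin_mm: float = 4.0
    air_margin_mm: float = 2.0
    grid_shape: tuple | None = None
    # defect geometry
    defect_pocket_volume_ml: float = 0.6
    defect_channel_radius_mm: float = 2.5
    defect_patch_area_mm2: float = 100.0

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape_family {self.shape_family!r}")
        if self.defect not in DEFECT_KINDS:
            raise ValueError(f"unknown defect {self.defect!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (self.depth_mm > 0 and self.aperture_radius_mm > 0):
            raise ValueError("depth_mm and aperture_radius_mm must be positive")
        if self.shape_family == "hemisphere" and not math.isclose(
            self.depth_mm, self.aperture_radius_mm, rel_tol=1e-9
        ):
            raise ValueError("hemisphere requires depth_mm == aperture_radius_mm")
        if not 0.0 <= self.wall_gap_fraction < 1.0:
            raise ValueError("wall_gap_fraction must be in [0, 1)")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != 3 or min(self.voxel_spacing_mm) <= 0:
            raise ValueError("voxel_spacing_mm must be three positive lengths")
        if self.wall_thickness_mm < min(self.voxel_spacing_mm):
            raise PhantomGeometryError(
                "wall thinner than one voxel: "
                f"{self.wall_thickness_mm} mm < {min(self.voxel_spacing_mm)} mm"
            )
        hu = self.material_hu
        if not (hu["bone"] > hu["soft_tissue"] > hu["air"]):
            raise ValueError("material HUs must satisfy bone > soft_tissue > air")


@dataclass
class PhantomTruth:
    """Closed-form ground truth for a phantom.

    ``area_mm2`` is the total boundary area including the planar aperture
    cap; ``area_lateral_mm2`` excludes it.  ``depth_mm`` is the distance
    from the aperture centroid to the farthest cavity point.  All points
    are physical mm in (z, y, x) order.
    """

    volume_ml: float
    area_mm2: float
    area_lateral_mm2: float
    aperture_area_mm2: float
    depth_mm: float
    aperture_centroid: np.ndarray
    apex_point: np.ndarray
    interior_point: np.ndarray
    defect: str
    spec: PhantomSpec
    defect_extra_volume_ml: float = 0.0
    defect_patch_area_mm2: float = 0.0
    defect_at_risk_volume_ml: float = 0.0

    def interior_voxel(self, volume: ImageVolume) -> tuple[int, int, int]:
        """Voxel index of a point safely inside the cavity (seed point)."""
        return volume.index_of(self.interior_point)


def _closed_forms(spec: PhantomSpec) -> tuple[float, float, float]:
    """(volume mm^3, lateral area mm^2, depth mm) for the named shape."""
    L, R = spec.depth_mm, spec.aperture_radius_mm
    if spec.shape_family == "hemisphere":
        vol = (2.0 / 3.0) * math.pi * R**3
        lat = 2.0 * math.pi * R**2
        depth = R
    elif spec.shape_family == "cone":
        vol = math.pi * R**2 * L / 3.0
        lat = math.pi * R * math.hypot(R, L)
        depth = max(L, R)
    else:  # paraboloid: rho(z) = R * sqrt(1 - z/L)
        vol = math.pi * R**2 * L / 2.0
        lat = (math.pi * R / (6.0 * L**2)) * ((R**2 + 4.0 * L**2) ** 1.5 - R**3)
        depth = max(L, R)
    return vol, lat, depth


def _cavity_mask(spec: PhantomSpec, shape, z0: float, cy: float, cx: float):
    """Boolean mask of voxel centres strictly inside the cavity solid."""
    hz, hy, hx = spec.voxel_spacing_mm
    nz, ny, nx = shape
    zc = (np.arange(nz) + 0.5) * hz - z0
    yc = (np.arange(ny) + 0.5) * hy - cy
    xc = (np.arange(nx) + 0.5) * hx - cx
    zz = zc[:, None, None]
    rho2 = (yc[None, :, None]) ** 2 + (xc[None, None, :]) ** 2
    L, R = spec.depth_mm, spec.aperture_radius_mm
    if spec.shape_family == "hemisphere":
        inside = (zz >= 0) & (zz**2 + rho2 < R**2)
    else:
        with np.errstate(invalid="ignore"):
            if spec.shape_family == "cone":
                rad = R * (1.0 - zz / L)
            else:
                rad = R * np.sqrt(np.clip(1.0 - zz / L, 0.0, None))
        inside = (zz >= 0) & (zz < L) & (rho2 < rad**2)
    return inside


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Voxelize a phantom and return the attenuation volume plus its truth.

    The grid is auto-sized to fit the cavity, wall and soft-tissue margin
    unless ``spec.grid_shape`` is given, in which case a cavity or wall
    exceeding the grid raises :class:`PhantomGeometryError`.
    """
    hz, hy, hx = spec.voxel_spacing_mm
    L, R = spec.depth_mm, spec.aperture_radius_mm
    wall = spec.wall_thickness_mm
    margin = spec.soft_tissue_margin_mm
    pad = 1.0

    # anterior air gap, aligned to a voxel boundary
    z0 = math.ceil(spec.air_margin_mm / hz) * hz

    extra_y_pos = 0.0
    if spec.defect == "lacrimal_channel":
        r_pocket = (3.0 * spec.defect_pocket_volume_ml * 1000.0 / (4 * math.pi)) ** (1 / 3)
        extra_y_pos = 2.0 * r_pocket + 2.0 * wall + 3.0

    half = R + wall + margin + pad
    if spec.grid_shape is not None:
        shape = tuple(int(n) for n in spec.grid_shape)
    else:
        nz = math.ceil((z0 + L + wall + margin + pad) / hz)
        ny = math.ceil((2 * half + extra_y_pos) / hy)
        nx = math.ceil(2 * half / hx)
        shape = (nz, ny, nx)
    cy = half
    cx = shape[2] * hx / 2.0

    cavity = _cavity_mask(spec, shape, z0, cy, cx)
    if cavity.sum() == 0:
        raise PhantomGeometryError("cavity produced no voxels on this grid")
    # the cavity plus its wall must not be clipped by the grid
    zi, yi, xi = np.nonzero(cavity)
    wz, wy, wx = (math.ceil(wall / h) for h in (hz, hy, hx))
    if (
        zi.max() + wz >= shape[0]
        or yi.min() - wy < 0
        or yi.max() + wy >= shape[1]
        or xi.min() - wx < 0
        or xi.max() + wx >= shape[2]
    ):
        raise PhantomGeometryError("cavity exceeds grid bounds (wall clipped)")

    spacing = np.array([hz, hy, hx])
    dist = ndimage.distance_transform_edt(~cavity, sampling=spacing)
    zc = ((np.arange(shape[0]) + 0.5) * hz)[:, None, None]
    behind_plane = np.broadcast_to(zc > z0, shape)
    shell = (dist <= wall + 1e-9) & ~cavity & behind_plane
    soft_block = (dist <= wall + margin) & ~cavity & ~shell & behind_plane

    rng = np.random.default_rng(spec.rng_seed)
    gap_voxels = None
    if spec.wall_gap_fraction > 0:
        idx = np.flatnonzero(shell)
        n_remove = int(round(spec.wall_gap_fraction * idx.size))
        if n_remove:
            gap_voxels = rng.choice(idx, size=n_remove, replace=False)

    hu = spec.material_hu
    values = np.full(shape, hu["air"], dtype=np.float32)
    values[soft_block] = hu["soft_tissue"]
    values[shell] = hu["bone"]
    if gap_voxels is not None:
        values.ravel()[gap_voxels] = hu["soft_tissue"]
    values[cavity] = hu["soft_tissue"]

    vol_mm3, lat_mm2, depth = _closed_forms(spec)
    cap_mm2 = math.pi * R**2
    truth = PhantomTruth(
        volume_ml=vol_mm3 / 1000.0,
        area_mm2=lat_mm2 + cap_mm2,
        area_lateral_mm2=lat_mm2,
        aperture_area_mm2=cap_mm2,
        depth_mm=depth,
        aperture_centroid=np.array([z0, cy, cx]),
        apex_point=np.array([z0 + L, cy, cx]),
        interior_point=np.array([z0 + 0.4 * L, cy, cx]),
        defect="none",
        spec=spec,
    )
    volume = ImageVolume(values=values, spacing=spacing)
    if spec.defect != "none":
        volume, truth = inject_defect(volume, truth, spec.defect)
    return volume, truth


def inject_defect(
    volume: ImageVolume, truth: PhantomTruth, kind: str
) -> tuple[ImageVolume, PhantomTruth]:
    """Inject a segmentation failure mode into an intact phantom.

    ``kind='none'`` is the identity.  Both defects are placed on the +y
    flank of the cavity at 35 % of the depth, where every shape family is
    wide.  Returns new objects; the inputs are not modified.
    """
    if kind == "none":
        return volume, truth
    if kind not in DEFECT_KINDS:
        raise ValueError(f"unknown defect kind {kind!r}")
    spec = truth.spec
    hz, hy, hx = spec.voxel_spacing_mm
    hu = spec.material_hu
    wall = spec.wall_thickness_mm
    values = volume.values.copy()
    shape = values.shape

    z0, cy, cx = truth.aperture_centroid
    L, R = spec.depth_mm, spec.aperture_radius_mm
    z_sel = 0.35 * L
    if spec.shape_family == "hemisphere":
        rho_s = math.sqrt(max(R**2 - z_sel**2, 0.0))
    elif spec.shape_family == "cone":
        rho_s = R * (1 - z_sel / L)
    else:
        rho_s = R * math.sqrt(1 - z_sel / L)

    spacing = volume.spacing
    zc = ((np.arange(shape[0]) + 0.5) * hz)[:, None, None]
    yc = ((np.arange(shape[1]) + 0.5) * hy)[None, :, None]
    xc = ((np.arange(shape[2]) + 0.5) * hx)[None, None, :]
    cavity = _cavity_mask(spec, shape, z0, cy, cx)

    truth = replace(truth, defect=kind)
    if kind == "lacrimal_channel":
        r_pocket = (3.0 * spec.defect_pocket_volume_ml * 1000.0 / (4 * math.pi)) ** (1 / 3)
        pc = np.array([z0 + z_sel, cy + rho_s + wall + 1.0 + r_pocket, cx])
        if pc[1] + r_pocket + wall >= shape[1] * hy:
            raise PhantomGeometryError("pocket does not fit the grid; regenerate "
                                       "the phantom with defect set in the spec")
        d_pocket2 = (zc - pc[0]) ** 2 + (yc - pc[1]) ** 2 + (xc - pc[2]) ** 2
        pocket = d_pocket2 < r_pocket**2
        pocket_shell = (d_pocket2 < (r_pocket + wall) ** 2) & ~pocket & ~cavity

        r_ch = spec.defect_channel_radius_mm
        in_section = ((zc - pc[0]) ** 2 + (xc - pc[2]) ** 2) < r_ch**2
        span = (yc > cy + rho_s - 2.0) & (yc < pc[1])
        channel = np.broadcast_to(in_section, shape) & np.broadcast_to(span, shape)
        sheath_section = ((zc - pc[0]) ** 2 + (xc - pc[2]) ** 2) < (r_ch + wall) ** 2
        sheath = (
            np.broadcast_to(sheath_section, shape)
            & np.broadcast_to(span, shape)
            & ~channel
            & ~cavity
            & ~pocket
        )
        if not np.any(channel & (values == hu["bone"])):
            raise PhantomGeometryError("defect placement does not intersect the wall")
        values[sheath] = hu["bone"]
        values[pocket_shell] = hu["bone"]
        values[pocket] = hu["soft_tissue"]
        values[channel & ~cavity] = hu["soft_tissue"]
        extra = ((pocket | channel) & ~cavity & (values == hu["soft_tissue"])).sum()
        truth = replace(
            truth, defect_extra_volume_ml=float(extra) * float(np.prod(spacing)) / 1000.0
        )
    else:  # wall_fracture
        r_patch = math.sqrt(spec.defect_patch_area_mm2 / math.pi)
        p = np.array([z0 + z_sel, cy + rho_s + wall / 2.0, cx])
        d2 = (zc - p[0]) ** 2 + (yc - p[1]) ** 2 + (xc - p[2]) ** 2
        patch = (d2 < (r_patch + wall) ** 2) & (values == hu["bone"]) & ~cavity
        if not np.any(patch):
            raise PhantomGeometryError("defect placement does not intersect the wall")
        values[patch] = hu["soft_tissue"]
        at_risk = (values == hu["soft_tissue"]).sum() - cavity.sum()
        truth = replace(
            truth,
            defect_patch_area_mm2=spec.defect_patch_area_mm2,
            defect_at_risk_volume_ml=float(at_risk) * float(np.prod(spacing)) / 1000.0,
        )

    out = ImageVolume(values=values, spacing=volume.spacing.copy(),
                      origin=volume.origin.copy(), orientation=volume.orientation)
    return out, truth


def voxelized_cavity_volume_ml(spec: PhantomSpec) -> float:
    """Voxel-count volume of the cavity (oracle for convergence checks)."""
    vol, truth = make_phantom(replace(spec, defect="none"))
    cavity = _cavity_mask(
        spec, vol.shape, truth.aperture_centroid[0],
        truth.aperture_centroid[1], truth.aperture_centroid[2],
    )
    return float(cavity.sum()) * vol.voxel_volume_mm3 / 1000.0
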