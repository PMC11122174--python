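"""Automated orbital cavity segmentation.

Stages, mirroring the automated tool the pipeline emulates:

1. ``select_bone_threshold`` — data-driven bone/soft-tissue HU cut (Otsu on
   the non-air histogram).
2. ``bridge_gaps`` — morphological closing of the bone mask with a physical
   ball radius, sealing sub-resolution dropouts of the thin orbital walls.
3. ``grow_cavity`` — iterative one-voxel front propagation from an interior
   seed, confined to soft-tissue voxels and blocked by the bridged bone,
   with a leak guard that aborts when the front re-accelerates after having
   stabilized (the signature of an escape through a real wall opening).
4. ``refine_cavity`` — optional relaxation of the grown mask back to the
   *unbridged* bone surface, recovering sharp concavities (e.g. a conical
   apex) that ball closing of the wall would otherwise seal off.
5. ``build_closures`` — planar caps over the remaining apertures; the
   largest is the anterior closure, small ones are posterior closures.

Everything is deterministic: identical volume + config give bit-identical
results across runs and processes, which is what makes repeated-measurement
ICCs of 1.0 attainable downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import LeakError, NonTerminationError, SeedError, ThresholdError
from .volume import ImageVolume

__all__ = [
    "SegmentationConfig",
    "CavitySegment",
    "ClosureSurface",
    "select_bone_threshold",
    "bridge_gaps",
    "grow_cavity",
    "refine_cavity",
    "build_closures",
    "segment_orbit",
]

log = logging.getLogger("orbitmorph.segmentation")

#: 6-connected structuring element for front propagation
STRUCT6 = ndimage.generate_binary_structure(3, 1)
STRUCT26 = np.ones((3, 3, 3), dtype=bool)

_FACE_DIRECTIONS = [  # (axis, step)
    (0, -1), (0, +1), (1, -1), (1, +1), (2, -1), (2, +1),
]


@dataclass
class SegmentationConfig:
    """Tunables of the segmentation stage.

    ``hu_threshold`` is the bone cut in HU, or ``"auto"`` for the Otsu
    estimate.  ``air_hu_cutoff`` bounds the growable medium from below:
    the front propagates only through voxels with HU above it (soft
    tissue), so growth stops at air as well as at bone.
    ``leak_guard_factor`` is the front re-acceleration ratio that aborts
    growth with :class:`LeakError`: once the per-iteration growth has
    declined below 70 % of its running peak (the front has met the walls),
    a later iteration adding more than ``leak_guard_factor`` times the
    post-decline trough signals an escape through a wall opening.  On
    intact bone-bounded cavities the growth never re-accelerates beyond a
    fraction of a percent after that decline, while wall-breach leaks
    re-expand the front severalfold, so the default of 2 separates the two
    regimes with a wide margin.
    """

    hu_threshold: float | str = "auto"
    gap_bridge_radius_mm: float = 1.5
    max_iterations: int = 600
    leak_guard_factor: float = 2.0
    posterior_cap_area_max_mm2: float = 150.0
    air_hu_cutoff: float = -200.0
    seed_ball_radius_mm: float = 1.0
    refine_to_bone: bool = True

    def __post_init__(self) -> None:
        if self.gap_bridge_radius_mm < 0:
            raise ValueError("gap_bridge_radius_mm must be >= 0")
        if self.leak_guard_factor <= 1:
            raise ValueError("leak_guard_factor must be > 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class CavitySegment:
    """A segmented orbital cavity: one 6-connected voxel component."""

    mask: np.ndarray
    seed_point: tuple
    spacing: np.ndarray
    origin: np.ndarray
    growth_added: list = field(default_factory=list)
    aperture_labels: np.ndarray | None = None  # per-voxel aperture component id
    boundary_faces: dict | None = None  # filled by build_closures

    @property
    def volume_ml(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing)) / 1000.0


@dataclass
class ClosureSurface:
    """Planar cap over one aperture of the cavity boundary."""

    label: str  # "anterior" | "posterior"
    triangles: np.ndarray  # (n, 3, 3) physical mm
    centroid: np.ndarray  # area-weighted, mm
    area_mm2: float
    normal: np.ndarray
    faces: np.ndarray  # (n_faces, 5): iz, iy, ix, axis, step
    component_id: int = -1  # aperture component in cavity.boundary_faces


def select_bone_threshold(volume: ImageVolume, air_cutoff_hu: float = -200.0) -> float:
    """Data-driven bone threshold: Otsu over the non-air histogram.

    Restricting to voxels above ``air_cutoff_hu`` removes the dominant air
    mode so the cut separates soft tissue from bone.  Deterministic for a
    fixed input; raises :class:`ThresholdError` for (near-)constant images.
    """
    vals = volume.values[volume.values > air_cutoff_hu]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ThresholdError("image has no soft-tissue/bone contrast above air")
    thr = float(threshold_otsu(vals, nbins=512))
    log.debug("bone threshold %.1f HU", thr)
    return thr


def bridge_gaps(bone_mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Morphological closing of the bone mask with a physical ball radius.

    Implemented with two Euclidean distance transforms, which is exact ball
    closing under anisotropic spacing and much faster than an explicit
    structuring element.  ``radius_mm = 0`` is the identity; the output is
    always a superset of the input.
    """
    if radius_mm <= 0 or not bone_mask.any():
        return bone_mask.copy()
    spacing = np.asarray(spacing, dtype=float)
    dilated = ndimage.distance_transform_edt(~bone_mask, sampling=spacing) <= radius_mm
    closed = ndimage.distance_transform_edt(dilated, sampling=spacing) > radius_mm
    return closed | bone_mask


def _seed_ball(shape, seed, radius_mm, spacing) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    r_vox = np.maximum(np.floor(radius_mm / np.asarray(spacing)).astype(int), 0)
    sl = tuple(
        slice(max(s - r, 0), min(s + r + 1, n))
        for s, r, n in zip(seed, r_vox, shape)
    )
    sub = np.zeros([s.stop - s.start for s in sl], dtype=bool)
    centers = [np.arange(s.start, s.stop) - c for s, c in zip(sl, seed)]
    d2 = (
        (centers[0][:, None, None] * spacing[0]) ** 2
        + (centers[1][None, :, None] * spacing[1]) ** 2
        + (centers[2][None, None, :] * spacing[2]) ** 2
    )
    sub[d2 <= radius_mm**2] = True
    out[sl] = sub
    return out


def grow_cavity(
    volume: ImageVolume,
    bone: np.ndarray,
    seed: tuple,
    config: SegmentationConfig | None = None,
) -> CavitySegment:
    """Grow the cavity from an interior seed until it meets the walls.

    A small seed ball is dilated by one voxel (6-connectivity) per
    iteration, restricted to soft-tissue voxels (HU above the air cutoff)
    not in the bridged ``bone`` mask.  Termination: no voxels added.
    The leak guard arms once per-iteration growth has declined below 70 %
    of its running peak; a later iteration adding more than
    ``leak_guard_factor`` times the post-decline trough aborts with
    :class:`LeakError`.

    The returned mask never intersects ``bone``.
    """
    config = config or SegmentationConfig()
    seed = tuple(int(i) for i in seed)
    if bone[seed]:
        raise SeedError(f"seed {seed} lies inside the bone mask")
    allowed = (~bone) & (volume.values > config.air_hu_cutoff)
    if not allowed[seed]:
        raise SeedError(f"seed {seed} is not in a growable (soft tissue) voxel")

    mask = _seed_ball(volume.shape, seed, config.seed_ball_radius_mm, volume.spacing)
    mask &= allowed
    count = int(mask.sum())

    added_log: list[int] = []
    peak = 0
    trough: int | None = None
    shape = volume.shape
    for iteration in range(1, config.max_iterations + 1):
        # restrict the dilation to the active bounding box (+1 voxel)
        nz_idx = np.nonzero(mask.any(axis=(1, 2)))[0]
        ny_idx = np.nonzero(mask.any(axis=(0, 2)))[0]
        nx_idx = np.nonzero(mask.any(axis=(0, 1)))[0]
        sl = tuple(
            slice(max(int(i[0]) - 1, 0), min(int(i[-1]) + 2, n))
            for i, n in zip((nz_idx, ny_idx, nx_idx), shape)
        )
        new = mask.copy()
        new[sl] = ndimage.binary_dilation(mask[sl], structure=STRUCT6) & allowed[sl]
        added = int(new.sum()) - count
        if added == 0:
            mask = new
            break
        added_log.append(added)
        peak = max(peak, added)
        if iteration >= 10 and added < 0.7 * peak:
            trough = added if trough is None else min(trough, added)
        # floor at 1% of peak: end-of-fill trickle through narrow divots
        # can jump by tens of voxels, far below any real breach front
        floor = max(trough if trough is not None else 0, 0.01 * peak, 8.0)
        if trough is not None and added > config.leak_guard_factor * floor:
            raise LeakError(
                f"growth re-accelerated at iteration {iteration} "
                f"({added} voxels vs post-decline trough {trough}): "
                "cavity is leaking through a wall opening"
            )
        mask = new
        count += added
    else:
        raise NonTerminationError(
            f"cavity growth did not converge within {config.max_iterations} iterations"
        )
    log.debug("cavity grown: %d voxels in %d iterations", count, len(added_log))
    return CavitySegment(
        mask=mask,
        seed_point=seed,
        spacing=volume.spacing.copy(),
        origin=volume.origin.copy(),
        growth_added=added_log,
    )


def refine_cavity(
    cavity: CavitySegment,
    volume: ImageVolume,
    bone_unbridged: np.ndarray,
    bridged: np.ndarray,
    config: SegmentationConfig | None = None,
) -> CavitySegment:
    """Relax the grown mask from the bridged to the true bone surface.

    Ball closing of the wall seals sharp concavities of the cavity (the
    closing ball cannot enter them), biasing depth short in conical
    shapes.  This step fills the sealed soft-tissue pockets that are
    adjacent to the cavity and entirely enclosed by bone and cavity —
    i.e. the bridged-but-not-bone voxels whose connected component touches
    neither air nor open (unbridged, non-cavity) soft tissue.  Gap plugs
    in the wall fail the enclosure test, so the wall seal is preserved
    while real concavities are recovered exactly.
    """
    config = config or SegmentationConfig()
    mask = cavity.mask
    soft = (~bone_unbridged) & (volume.values > config.air_hu_cutoff)
    sealed = bridged & soft & ~mask
    if not sealed.any():
        return cavity
    open_soft = soft & ~bridged & ~mask
    air = volume.values <= config.air_hu_cutoff
    labels, n_comp = ndimage.label(sealed, structure=STRUCT6)
    if n_comp == 0:
        return cavity
    outside = ndimage.binary_dilation(open_soft | air, structure=STRUCT6)
    excluded = np.unique(labels[outside & sealed])
    near_cavity = ndimage.binary_dilation(mask, structure=STRUCT6)
    touching = np.unique(labels[near_cavity & sealed])
    good = np.setdiff1d(touching, np.concatenate([[0], excluded]))
    if good.size:
        mask = mask | np.isin(labels, good)
    return CavitySegment(
        mask=mask,
        seed_point=cavity.seed_point,
        spacing=cavity.spacing,
        origin=cavity.origin,
        growth_added=list(cavity.growth_added),
    )


def _boundary_faces(mask: np.ndarray):
    """All exposed voxel faces as (iz, iy, ix, axis, step) int arrays."""
    faces = []
    for axis, step in _FACE_DIRECTIONS:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if step == -1:
            dst[axis] = slice(0, -1)
            src[axis] = slice(1, None)
        else:
            dst[axis] = slice(1, None)
            src[axis] = slice(0, -1)
        shifted = np.zeros_like(mask)
        shifted[tuple(src)] = mask[tuple(dst)]
        exposed = mask & ~shifted
        idx = np.argwhere(exposed)
        if idx.size:
            extra = np.tile([axis, step], (idx.shape[0], 1))
            faces.append(np.hstack([idx, extra]))
    if not faces:
        return np.empty((0, 5), dtype=int)
    return np.vstack(faces)


def _face_corners(faces: np.ndarray, spacing: np.ndarray, origin: np.ndarray):
    """(n, 4, 3) physical corner coordinates of each voxel face.

    Corners are ordered around the face so that consecutive corners share
    an edge; the two triangles (0,1,2) and (0,2,3) tile the square.
    """
    n = faces.shape[0]
    corners = np.empty((n, 4, 3))
    base = faces[:, :3].astype(float)
    axis = faces[:, 3]
    step = faces[:, 4]
    offset = np.zeros((n, 3))
    offset[np.arange(n), axis] = (step + 1) // 2  # 0 for -1 faces, 1 for +1
    others = np.array([[1, 2], [0, 2], [0, 1]])
    quad = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    for c in range(4):
        corner = base + offset
        oa = others[axis]  # (n, 2) the two in-plane axes
        corner[np.arange(n), oa[:, 0]] += quad[c, 0]
        corner[np.arange(n), oa[:, 1]] += quad[c, 1]
        corners[:, c, :] = origin[None, :] + corner * spacing[None, :]
    return corners


def build_closures(
    cavity: CavitySegment,
    bone: np.ndarray,
    config: SegmentationConfig | None = None,
) -> list[ClosureSurface]:
    """Cap the cavity apertures with planar surfaces.

    Aperture faces are exposed cavity faces whose outside neighbour is
    neither cavity nor bone; connected groups of them form apertures.  Each
    aperture is capped by its own voxel faces (two triangles per face) with
    an area-weighted centroid and a least-squares plane normal.  The
    largest cap is labelled ``anterior``; all others are ``posterior`` (a
    warning is issued if one exceeds ``posterior_cap_area_max_mm2``).

    A sealed cavity returns an empty list.  As a side effect the full
    boundary-face classification is stored on ``cavity.boundary_faces`` for
    the mesh builder.
    """
    config = config or SegmentationConfig()
    mask = cavity.mask
    faces = _boundary_faces(mask)
    if faces.shape[0] == 0:
        cavity.boundary_faces = {
            "faces": faces, "kind": np.empty(0, dtype="U12"),
            "component": np.empty(0, dtype=int), "closure_labels": {},
        }
        return []

    nb = faces[:, :3].copy()
    nb[np.arange(len(faces)), faces[:, 3]] += faces[:, 4]
    inside = np.all((nb >= 0) & (nb < np.array(mask.shape)), axis=1)
    is_bone = np.ones(len(faces), dtype=bool)  # out-of-grid treated as bone
    nb_in = nb[inside]
    is_bone[inside] = bone[nb_in[:, 0], nb_in[:, 1], nb_in[:, 2]]

    aperture_faces = faces[~is_bone]
    kind = np.where(is_bone, "bone", "aperture")
    closures: list[ClosureSurface] = []
    face_component = np.full(len(faces), -1, dtype=int)
    if aperture_faces.shape[0]:
        ap_nb = nb[~is_bone]
        ap_vox = np.zeros(mask.shape, dtype=bool)
        ap_vox[ap_nb[:, 0], ap_nb[:, 1], ap_nb[:, 2]] = True
        comp, n_comp = ndimage.label(ap_vox, structure=STRUCT26)
        comp_of_face = comp[ap_nb[:, 0], ap_nb[:, 1], ap_nb[:, 2]]
        face_component[~is_bone] = comp_of_face

        spacing, origin = cavity.spacing, cavity.origin
        caps = []
        for c in range(1, n_comp + 1):
            f = aperture_faces[comp_of_face == c]
            corners = _face_corners(f, spacing, origin)
            tri = np.concatenate(
                [corners[:, [0, 1, 2], :], corners[:, [0, 2, 3], :]], axis=0
            )
            v1 = tri[:, 1] - tri[:, 0]
            v2 = tri[:, 2] - tri[:, 0]
            tri_area = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=1)
            area = float(tri_area.sum())
            tri_centroid = tri.mean(axis=1)
            centroid = (tri_centroid * tri_area[:, None]).sum(axis=0) / tri_area.sum()
            centers = corners.mean(axis=1)
            centered = centers - centers.mean(axis=0)
            _, svals, vt = np.linalg.svd(centered, full_matrices=False)
            normal = vt[-1]
            rms = svals[-1] / np.sqrt(max(len(centers), 1))
            if rms > float(max(spacing)):
                warnings.warn(
                    f"aperture cap deviates from planarity (rms {rms:.2f} mm); "
                    "cap built anyway",
                    stacklevel=2,
                )
            caps.append(
                ClosureSurface(
                    label="posterior", triangles=tri, centroid=centroid,
                    area_mm2=area, normal=normal, faces=f, component_id=c,
                )
            )
        largest = int(np.argmax([c.area_mm2 for c in caps]))
        caps[largest].label = "anterior"
        for i, cap in enumerate(caps):
            if i != largest and cap.area_mm2 > config.posterior_cap_area_max_mm2:
                warnings.warn(
                    f"secondary aperture cap of {cap.area_mm2:.0f} mm^2 exceeds "
                    f"posterior_cap_area_max_mm2; labelled posterior anyway",
                    stacklevel=2,
                )
        closures = caps
    cavity.boundary_faces = {
        "faces": faces,
        "kind": kind,
        "component": face_component,
        "closure_labels": {c.component_id: c.label for c in closures},
    }
    return closures


def segment_orbit(
    volume: ImageVolume,
    seed: tuple,
    config: SegmentationConfig | None = None,
) -> tuple[CavitySegment, list[ClosureSurface]]:
    """Full segmentation: threshold, bridge, grow, refine, cap."""
    config = config or SegmentationConfig()
    if config.hu_threshold == "auto":
        thr = select_bone_threshold(volume, config.air_hu_cutoff)
    else:
        thr = float(config.hu_threshold)
    bone = volume.values > thr
    bridged = bridge_gaps(bone, config.gap_bridge_radius_mm, volume.spacing)
    cavity = grow_cavity(volume, bridged, seed, config)
    if config.refine_to_bone:
        cavity = refine_cavity(cavity, volume, bone, bridged, config)
    closures = build_closures(cavity, bridged | bone, config)
    log.info(
        "segmented orbit: threshold=%.1f HU, %d voxels, %d closure cap(s)",
        thr, int(cavity.mask.sum()), len(closures),
    )
    return cavity, closures
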