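import numpy as np
import pytest

from orbitmorph import PhantomSpec, make_phantom, segment_orbit, tetrahedralize
from orbitmorph.segmentation import CavitySegment, build_closures

#: canonical recovery geometries, one per shape family, 0.5 mm voxels
CANONICAL = {
    "hemisphere": dict(depth_mm=20.0, aperture_radius_mm=20.0),
    "cone": dict(depth_mm=40.0, aperture_radius_mm=20.0),
    "paraboloid": dict(depth_mm=38.0, aperture_radius_mm=21.0),
}


@pytest.fixture(scope="session")
def canonical_phantoms():
    """Segmented + meshed canonical phantom per family (intact walls)."""
    out = {}
    for family, geo in CANONICAL.items():
        spec = PhantomSpec(shape_family=family, **geo)
        volume, truth = make_phantom(spec)
        cavity, closures = segment_orbit(volume, truth.interior_voxel(volume))
        mesh = tetrahedralize(cavity, closures)
        out[family] = dict(
            spec=spec, volume=volume, truth=truth,
            cavity=cavity, closures=closures, mesh=mesh,
        )
    return out


@pytest.fixture(scope="session")
def small_hemisphere():
    """Fast hemisphere (r = 12 mm) through the full segmentation."""
    spec = PhantomSpec("hemisphere", depth_mm=12.0, aperture_radius_mm=12.0)
    volume, truth = make_phantom(spec)
    cavity, closures = segment_orbit(volume, truth.interior_voxel(volume))
    mesh = tetrahedralize(cavity, closures)
    return dict(spec=spec, volume=volume, truth=truth,
                cavity=cavity, closures=closures, mesh=mesh)


def cavity_from_mask(mask: np.ndarray, spacing=(1.0, 1.0, 1.0), bone=None):
    """Wrap a boolean mask as a capped CavitySegment for mesh-level tests.

    With ``bone=None`` the entire boundary is treated as bone (sealed).
    """
    seed = tuple(int(i[0]) for i in np.nonzero(mask))
    cavity = CavitySegment(
        mask=mask, seed_point=seed,
        spacing=np.asarray(spacing, float), origin=np.zeros(3),
    )
    if bone is None:
        bone = np.ones_like(mask)
    closures = build_closures(cavity, bone)
    return cavity, closures
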