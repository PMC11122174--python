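import math

import numpy as np
import pytest
from conftest import cavity_from_mask

from orbitmorph import ImageVolume, PhantomSpec, make_phantom, run_orbit_pipeline
from orbitmorph.errors import DegenerateInputError, NonWatertightError
from orbitmorph.morphometry import (
    DepthAxis,
    depth_axis,
    mesh_area,
    mesh_volume,
    tetrahedralize,
    volume_profile,
)
from orbitmorph.segmentation import segment_orbit


def surface_integral_volume_ml(mesh):
    """Independent divergence-theorem oracle over the labelled boundary."""
    v = mesh.vertices
    tri = mesh.boundary_triangles
    a, b, c = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    flux = np.einsum("ij,ij->i", a, np.cross(b - a, c - a))
    return float(flux.sum() / 6.0) / 1000.0


class TestTetrahedralize:
    def test_single_voxel_six_tets(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        cavity, closures = cavity_from_mask(mask)
        mesh = tetrahedralize(cavity, closures)
        assert mesh.tetrahedra.shape == (6, 4)
        assert mesh_volume(mesh) == pytest.approx(0.001)
        assert mesh_area(mesh, smoothed=False) == pytest.approx(6.0)

    def test_volume_equals_voxel_count_identity(self, small_hemisphere):
        mesh = small_hemisphere["mesh"]
        mask = small_hemisphere["cavity"].mask
        voxvol = float(np.prod(mesh.spacing))
        assert mesh_volume(mesh) == mask.sum() * voxvol / 1000.0

    def test_boundary_watertight_and_spherical(self, small_hemisphere):
        tri = small_hemisphere["mesh"].boundary_triangles
        edges = np.sort(
            np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()
        n_v = np.unique(tri).size
        assert n_v - len(_) + len(tri) == 2  # Euler characteristic of a sphere

    def test_missing_cap_raises(self, small_hemisphere):
        with pytest.raises(NonWatertightError):
            tetrahedralize(small_hemisphere["cavity"], [])

    def test_empty_cavity_raises(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        from orbitmorph.segmentation import CavitySegment

        cavity = CavitySegment(mask=mask, seed_point=(0, 0, 0),
                               spacing=np.ones(3), origin=np.zeros(3))
        with pytest.raises(DegenerateInputError):
            tetrahedralize(cavity, [])


class TestVolumeOracle:
    def test_divergence_theorem_equivalence(self, small_hemisphere):
        mesh = small_hemisphere["mesh"]
        assert abs(mesh_volume(mesh) - surface_integral_volume_ml(mesh)) < 1e-9


class TestArea:
    def test_hemisphere_total_area_within_5pct(self, small_hemisphere):
        area = mesh_area(small_hemisphere["mesh"], include_closures=True)
        truth = small_hemisphere["truth"].area_mm2
        assert abs(area - truth) / truth < 0.05

    def test_hemisphere_lateral_area_without_closures(self, small_hemisphere):
        area = mesh_area(small_hemisphere["mesh"], include_closures=False)
        truth = small_hemisphere["truth"].area_lateral_mm2
        assert abs(area - truth) / truth < 0.05

    def test_raw_voxel_surface_overestimates_smooth_area(self, small_hemisphere):
        # the staircase effect: raw boundary ~1.5x the smooth surface
        raw = mesh_area(small_hemisphere["mesh"], smoothed=False)
        truth = small_hemisphere["truth"].area_mm2
        assert raw > 1.3 * truth


class TestDepthAxis:
    def test_cone_depth_within_voxel_diagonal(self):
        volume, truth = make_phantom(PhantomSpec("cone", 24, 12))
        metrics = run_orbit_pipeline(volume, truth.interior_voxel(volume),
                                     compute_area=False)
        assert abs(metrics.depth_mm - truth.depth_mm) <= \
            np.linalg.norm(volume.spacing)

    def test_hemisphere_depth_within_voxel_diagonal(self, small_hemisphere):
        mesh = small_hemisphere["mesh"]
        anterior = [c for c in small_hemisphere["closures"] if c.label == "anterior"][0]
        axis = depth_axis(mesh, anterior)
        assert abs(axis.length_mm - 12.0) <= np.linalg.norm(mesh.spacing)

    def test_tie_break_deterministic(self, small_hemisphere):
        mesh = small_hemisphere["mesh"]
        anterior = [c for c in small_hemisphere["closures"] if c.label == "anterior"][0]
        a1 = depth_axis(mesh, anterior)
        a2 = depth_axis(mesh, anterior)
        assert np.array_equal(a1.posterior_point, a2.posterior_point)


class TestProfile:
    def test_conservation(self, small_hemisphere):
        mesh = small_hemisphere["mesh"]
        anterior = [c for c in small_hemisphere["closures"] if c.label == "anterior"][0]
        axis = depth_axis(mesh, anterior)
        profile, excluded = volume_profile(mesh, axis)
        assert profile.sum() + excluded == pytest.approx(mesh_volume(mesh), abs=1e-9)

    @pytest.mark.parametrize("n_bins", [1, 5, 10, 17])
    def test_conservation_any_bin_count(self, small_hemisphere, n_bins):
        mesh = small_hemisphere["mesh"]
        anterior = [c for c in small_hemisphere["closures"] if c.label == "anterior"][0]
        axis = depth_axis(mesh, anterior)
        profile, excluded = volume_profile(mesh, axis, n_bins=n_bins)
        assert len(profile) == n_bins
        assert profile.sum() + excluded == pytest.approx(mesh_volume(mesh), abs=1e-9)

    def test_axis_aligned_cylinder_equal_bins(self):
        mask = np.zeros((64, 44, 44), dtype=bool)
        zz = np.arange(64)[:, None, None]
        yy = (np.arange(44) - 21.5)[None, :, None]
        xx = (np.arange(44) - 21.5)[None, None, :]
        mask[(zz >= 2) & (zz < 62) & (yy**2 + xx**2 < 18**2)] = True
        cavity, closures = cavity_from_mask(mask, spacing=(0.5, 0.5, 0.5))
        mesh = tetrahedralize(cavity, closures)
        axis = DepthAxis(
            anterior_point=np.array([1.0, 11.0, 11.0]),
            posterior_point=np.array([31.0, 11.0, 11.0]),
            unit_direction=np.array([1.0, 0.0, 0.0]),
            length_mm=30.0,
        )
        profile, excluded = volume_profile(mesh, axis)
        assert excluded == 0.0
        assert np.ptp(profile) / profile.mean() < 0.01

    def test_cone_cumulative_follows_cubic_law(self):
        volume, truth = make_phantom(PhantomSpec("cone", 30, 14))
        metrics = run_orbit_pipeline(volume, truth.interior_voxel(volume),
                                     compute_area=False)
        cum = np.cumsum(metrics.profile_ml) / metrics.profile_ml.sum()
        assert np.all(np.diff(metrics.profile_ml) > 0)  # increasing toward rim
        k = np.arange(1, 11)
        assert np.abs(cum - (k / 10) ** 3).max() < 0.02
        delta = truth.depth_mm - metrics.depth_mm  # apex truncation, ~1 voxel
        lm = metrics.depth_mm
        corrected = ((delta + k * lm / 10) ** 3 - delta**3) / (
            (delta + lm) ** 3 - delta**3
        )
        assert np.abs(cum - corrected).max() < 0.005


class TestInvariances:
    def test_rigid_translation_invariance(self):
        spec = PhantomSpec("paraboloid", 24, 13)
        volume, truth = make_phantom(spec)
        m1 = run_orbit_pipeline(volume, truth.interior_voxel(volume))
        shifted = ImageVolume(values=volume.values, spacing=volume.spacing,
                              origin=volume.origin + np.array([17.0, -4.5, 3.25]))
        m2 = run_orbit_pipeline(shifted, truth.interior_voxel(volume))
        assert m2.volume_ml == pytest.approx(m1.volume_ml, abs=1e-9)
        assert m2.depth_mm == pytest.approx(m1.depth_mm, abs=1e-6)
        assert m2.area_mm2 == pytest.approx(m1.area_mm2, abs=1e-6)
        assert np.allclose(m2.profile_ml, m1.profile_ml, atol=1e-9)

    def test_mirror_invariance(self):
        spec = PhantomSpec("paraboloid", 24, 13, defect="lacrimal_channel")
        volume, truth = make_phantom(spec)
        m1 = run_orbit_pipeline(volume, truth.interior_voxel(volume))
        flipped = ImageVolume(values=volume.values[:, :, ::-1].copy(),
                              spacing=volume.spacing)
        seed = truth.interior_voxel(volume)
        seed_f = (seed[0], seed[1], volume.shape[2] - 1 - seed[2])
        m2 = run_orbit_pipeline(flipped, seed_f)
        assert m2.volume_ml == pytest.approx(m1.volume_ml, abs=1e-9)
        assert m2.depth_mm == pytest.approx(m1.depth_mm, abs=1e-6)
        assert m2.area_mm2 == pytest.approx(m1.area_mm2, rel=1e-6)
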