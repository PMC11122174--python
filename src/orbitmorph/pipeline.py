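"""End-to-end segmentation + morphometry convenience entry point."""

from __future__ import annotations

from .morphometry import OrbitMetrics, measure_orbit
from .segmentation import SegmentationConfig, segment_orbit
from .volume import ImageVolume

__all__ = ["run_orbit_pipeline"]


def run_orbit_pipeline(
    volume: ImageVolume,
    seed: tuple,
    config: SegmentationConfig | None = None,
    n_bins: int = 10,
    compute_area: bool = True,
    compute_profile: bool = True,
    side: str = "unknown",
) -> OrbitMetrics:
    """Segment one orbit from an attenuation volume and measure it.

    ``seed`` is a voxel index inside the cavity; automatic orbit
    localization is deliberately out of scope, so callers (or phantom
    ground truth) must supply it.
    """
    cavity, closures = segment_orbit(volume, seed, config)
    return measure_orbit(
        cavity,
        closures,
        n_bins=n_bins,
        compute_area=compute_area,
        compute_profile=compute_profile,
        side=side,
    )
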