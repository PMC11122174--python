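"""In-memory container for CT-like attenuation volumes.

The array axis order is (z, y, x) with z the anterior->posterior axis of the
phantoms; ``spacing`` and ``origin`` are stored in the same (z, y, x) order,
in millimetres.  Physical coordinates refer to voxel *centres*:
``p = origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3-D scalar attenuation grid in Hounsfield units.

    Parameters
    ----------
    values
        3-D array of attenuation values (HU), axis order (z, y, x).
    spacing
        Voxel spacing in mm per axis, (z, y, x).
    origin
        Physical position (mm) of the corner of voxel (0, 0, 0); the centre
        of that voxel sits at ``origin + spacing / 2``.
    orientation
        Axis labels, purely informational.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    orientation: tuple[str, str, str] = ("z", "y", "x")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ValueError("spacing must be three positive lengths (mm)")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_center(self, index) -> np.ndarray:
        """Physical coordinates (mm) of the centre of a voxel index."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx + 0.5) * self.spacing

    def index_of(self, point) -> tuple[int, int, int]:
        """Voxel index containing a physical point (mm)."""
        p = np.asarray(point, dtype=float)
        idx = np.floor((p - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError(f"point {p} outside the volume")
        return tuple(int(i) for i in idx)

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            values=self.values.copy(),
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            orientation=self.orientation,
        )
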