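"""Core in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

#: Intensity units a dynamic volume can carry.
UNIT_HU = "HU"
UNIT_CONC = "mgI/mL"


@dataclass
class DynamicVolume:
    """A 4D dynamic perfusion volume (x, y, z, time).

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
    spacing_mm : tuple of 3 floats
        Voxel spacing in mm.
    frame_times_s : ndarray, shape (nt,)
        Acquisition time of each frame in seconds, strictly increasing.
    unit : {"HU", "mgI/mL"}
    kv : int
        Tube voltage the volume was acquired at (70 or 80).
    """

    data: np.ndarray
    spacing_mm: tuple
    frame_times_s: np.ndarray
    unit: str = UNIT_HU
    kv: int = 80

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidInputError(
                f"DynamicVolume requires 4D data, got ndim={self.data.ndim}"
            )
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=np.float64)
        if self.frame_times_s.shape != (self.data.shape[3],):
            raise InvalidInputError("frame_times_s length must match the time axis")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise InvalidInputError("frame_times_s must be strictly increasing")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise InvalidInputError("spacing_mm must be 3 positive floats")
        if self.unit not in (UNIT_HU, UNIT_CONC):
            raise InvalidInputError(f"unknown intensity unit {self.unit!r}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "DynamicVolume":
        """Copy of this volume with replaced voxel data (and optionally unit)."""
        return DynamicVolume(
            data=data,
            spacing_mm=self.spacing_mm,
            frame_times_s=self.frame_times_s.copy(),
            unit=self.unit if unit is None else unit,
            kv=self.kv,
        )
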