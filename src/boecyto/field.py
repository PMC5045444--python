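"""Physically calibrated complex optical fields and focal-plane grids.

A :class:`ComplexField` is a square matrix of complex amplitudes sampled on a
grid of known pitch, centered on the optical axis (sample-centered convention:
the coordinate of sample ``i`` along either axis is ``(i - n/2) * pitch``).
Energy is the pitch²-weighted sum of ``|value|²``, which the scaled discrete
Fourier propagation in :mod:`boecyto.beam_shaping` conserves exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GridError(ValueError):
    """Two fields or a field and a region live on incompatible grids."""


@dataclass(frozen=True)
class GridSpec:
    """A square, axis-centered sampling grid.

    Parameters
    ----------
    n : int
        Samples per side.
    pitch : float
        Physical distance between adjacent samples, in metres.
    """

    n: int
    pitch: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("grid needs at least 2 samples per side")
        if not self.pitch > 0:
            raise ValueError("grid pitch must be positive")

    @property
    def extent(self) -> float:
        """Full physical side length covered by the grid (m)."""
        return self.n * self.pitch

    def coords(self) -> np.ndarray:
        """Sample-center coordinates along one axis (m)."""
        return (np.arange(self.n) - self.n // 2) * self.pitch


@dataclass
class ComplexField:
    """Complex optical amplitude on a calibrated 2D grid.

    ``plane_tag`` records whether the samples live in the aperture (BOE) plane
    or the lens focal plane; operations that mix planes check it.
    """

    values: np.ndarray
    sample_pitch: float
    plane_tag: str = "aperture"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GridError("field matrix must be square")
        if not self.sample_pitch > 0:
            raise GridError("sample pitch must be positive")
        if self.plane_tag not in ("aperture", "focal"):
            raise ValueError("plane_tag must be 'aperture' or 'focal'")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n, self.sample_pitch)

    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def energy(self) -> float:
        """Total energy: sum of |value|² weighted by pitch²."""
        return float(np.sum(self.intensity()) * self.sample_pitch**2)

    def same_grid(self, other: "ComplexField") -> bool:
        return self.n == other.n and np.isclose(
            self.sample_pitch, other.sample_pitch, rtol=1e-12
        )
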