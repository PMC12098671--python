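"""Uniform wavelength grids (the instrument scan axes)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GridError


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly ascending, uniformly spaced wavelength axis in nm.

    Parameters
    ----------
    start, stop : float
        First and last wavelength (inclusive), nm.
    step : float
        Grid spacing, nm; must be positive and divide ``stop - start``.
    """

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise GridError(f"grid step must be > 0, got {self.step}")
        if not (self.stop > self.start):
            raise GridError(
                f"grid stop ({self.stop}) must exceed start ({self.start})"
            )
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise GridError(
                f"step {self.step} does not evenly divide "
                f"[{self.start}, {self.stop}]"
            )

    @property
    def n(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def axis(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n)

    def contains(self, wavelength: float) -> bool:
        return self.start - 1e-9 <= wavelength <= self.stop + 1e-9

    @classmethod
    def from_axis(cls, axis: np.ndarray) -> "WavelengthGrid":
        """Reconstruct a grid from an explicit axis, validating uniformity."""
        axis = np.asarray(axis, dtype=float)
        if axis.ndim != 1 or axis.size < 2:
            raise GridError("axis must be 1-D with at least two points")
        steps = np.diff(axis)
        if np.any(steps <= 0):
            raise GridError("axis must be strictly ascending")
        step = float(np.median(steps))
        if np.max(np.abs(steps - step)) > 1e-6 * max(step, 1.0):
            raise GridError("axis is not uniformly spaced")
        return cls(float(axis[0]), float(axis[-1]), step)


#: Default instrument-like scan axes; they cover both analytes' excitation
#: and emission bands plus every synchronous offset scanned (20-120 nm).
DEFAULT_EX_GRID = WavelengthGrid(220.0, 500.0, 1.0)
DEFAULT_EM_GRID = WavelengthGrid(250.0, 600.0, 1.0)
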