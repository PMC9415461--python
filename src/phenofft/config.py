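"""Acquisition geometry and timing configuration."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging-run geometry and schedule.

    Defaults mirror the study design this pipeline emulates: a
    236 µm × 236 µm field imaged every 3 minutes for 20 h (400 cycles),
    starting with 15–25 cells.

    Parameters
    ----------
    field_side : float
        Side of the square imaging field, µm.
    pixel_size : float
        Pixel pitch of rendered frames, µm/pixel.
    interval : float
        Time between imaging cycles, minutes.
    duration : float
        Total acquisition time, hours.
    initial_cells_min, initial_cells_max : int
        Bounds of the uniform draw for the starting cell count.
    seed : int
        Seed for all randomness downstream of this config.
    """

    field_side: float = 236.0
    pixel_size: float = 0.5
    interval: float = 3.0
    duration: float = 20.0
    initial_cells_min: int = 15
    initial_cells_max: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_side", "pixel_size", "interval", "duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.initial_cells_min < 0:
            raise ConfigurationError("initial_cells_min must be non-negative")
        if self.initial_cells_min > self.initial_cells_max:
            raise ConfigurationError(
                "initial_cells_min must not exceed initial_cells_max "
                f"({self.initial_cells_min} > {self.initial_cells_max})"
            )

    @property
    def n_cycles(self) -> int:
        """Number of imaging cycles: floor(duration·60 / interval)."""
        return int(math.floor(self.duration * 60.0 / self.interval))

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Pixel grid of a rendered frame (rows, cols)."""
        n = int(round(self.field_side / self.pixel_size))
        return (n, n)

    @property
    def field_area(self) -> float:
        """Field area in µm²."""
        return self.field_side ** 2

    def time_hours(self, cycle: int) -> float:
        """Elapsed time at a 1-based cycle index, in hours."""
        return cycle * self.interval / 60.0

    def with_(self, **kwargs) -> "AcquisitionConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
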