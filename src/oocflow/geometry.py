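"""Channel geometry and drive specification.

Coordinate convention (used everywhere in the package): the channel axis is
x, the cross-section spans y in [0, w] (width) and z in [0, h] (height). The
wall z = h is the "membrane" wall — in a vertically stacked organ-on-a-chip
device this is the porous wall the cells grow on, and the surface where wall
shear stress is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidModelError

__all__ = ["ChannelGeometry", "DriveSpec", "WALLS"]

#: Wall naming convention for a rectangular cross-section.
WALLS = ("top", "bottom", "left", "right")


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel: width ``w`` (y), height ``h`` (z), length ``L`` (x), in metres."""

    w: float
    h: float
    L: float = 15e-3

    def __post_init__(self) -> None:
        for name in ("w", "h", "L"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise InvalidModelError(f"geometry dimension {name} must be > 0, got {v}")

    @property
    def area(self) -> float:
        """Cross-section area [m^2]."""
        return self.w * self.h

    @property
    def aspect(self) -> float:
        """Aspect ratio w/h."""
        return self.w / self.h


@dataclass(frozen=True)
class DriveSpec:
    """How the flow is driven: a pressure gradient OR a flow rate, not both.

    ``pressure_gradient`` is the magnitude |delta p| / L [Pa/m] along the
    channel; ``flow_rate`` is Q [m^3/s].
    """

    pressure_gradient: float | None = None
    flow_rate: float | None = None

    def __post_init__(self) -> None:
        set_count = (self.pressure_gradient is not None) + (self.flow_rate is not None)
        if set_count != 1:
            raise InvalidModelError(
                "exactly one of pressure_gradient or flow_rate must be set"
            )
        value = self.pressure_gradient if self.pressure_gradient is not None else self.flow_rate
        if not (value > 0 and math.isfinite(value)):
            raise InvalidModelError(f"drive value must be > 0, got {value}")

    @property
    def is_pressure_driven(self) -> bool:
        return self.pressure_gradient is not None
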