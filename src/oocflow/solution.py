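"""Containers for solved cross-section flow fields and derived shear maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WALLS, ChannelGeometry
from .rheology import PowerLawFluid

__all__ = ["FlowSolution", "ShearField", "WallShearMap"]


@dataclass(frozen=True)
class FlowSolution:
    """Unidirectional velocity field u_x(y, z) on a regular lattice.

    ``u`` is indexed ``u[iz, iy]`` with ``y``/``z`` the node coordinates
    (walls included; u = 0 there). ``pressure_gradient`` is |delta p|/L
    [Pa/m] and ``Q`` the trapezoidal-quadrature flow rate [m^3/s].
    """

    geometry: ChannelGeometry
    fluid: PowerLawFluid
    y: np.ndarray
    z: np.ndarray
    u: np.ndarray
    pressure_gradient: float
    Q: float
    converged: bool
    iterations: int
    residual: float

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def u_max(self) -> float:
        return float(self.u.max())

    @property
    def mean_velocity(self) -> float:
        """Q / A [m/s]."""
        return self.Q / self.geometry.area


@dataclass(frozen=True)
class ShearField:
    """Shear-rate magnitude and shear-stress magnitude on the solution lattice."""

    y: np.ndarray
    z: np.ndarray
    gamma_dot: np.ndarray
    tau: np.ndarray


@dataclass(frozen=True)
class WallShearMap:
    """Shear-stress profile along one wall of the cross-section.

    ``coordinate`` runs along the wall (y for top/bottom, z for left/right);
    ``tau`` >= 0 and vanishes at the wall's corners.
    """

    wall: str
    coordinate: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        if self.wall not in WALLS:
            raise ValueError(f"unknown wall {self.wall!r}; expected one of {WALLS}")

    @property
    def tau_max(self) -> float:
        return float(self.tau.max())

    @property
    def length(self) -> float:
        return float(self.coordinate[-1] - self.coordinate[0])
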