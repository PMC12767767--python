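"""Device flow model and Stokes-Einstein relations.

The analysis rests on two pieces of physics:

* the Stokes-Einstein equation ``D = kB*T / (6*pi*eta*r)`` linking the
  diffusion coefficient of a spherical particle to its hydrodynamic radius
  in a liquid at low Reynolds number, and
* plug flow down the main channel: particles move at the mean carrier speed
  ``v = Q / (h*w)`` (total volumetric flow over the channel cross-section),
  so a measurement point at distance ``s`` from the focusing junction is
  reached after transit time ``t = s / v``.

The width parameter ``c`` of the Gaussian fitted to a cross-channel
fluorescence profile grows as ``c^2 = 4*D*t`` in this package's convention
(the exponent of the fitted Gaussian is ``-((x-b)/c)^2``), so the admissible
variance-time slope for a particle of radius r is ``4*D(r)``.

Canonical internal units: micrometres, seconds, um^2/s for slopes and
diffusion coefficients inside the pipeline; the Stokes-Einstein helpers below
speak SI (metres) and conversions happen at module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

#: Boltzmann constant, J/K (exact, 2019 SI).
BOLTZMANN = 1.380649e-23

#: m^2/s -> um^2/s
M2S_TO_UM2S = 1e12

#: uL/min -> um^3/s  (1 uL = 1e9 um^3)
ULMIN_TO_UM3S = 1e9 / 60.0


@dataclass(frozen=True)
class Conditions:
    """Thermodynamic state of the carrier medium.

    temperature : absolute temperature (K)
    viscosity   : dynamic viscosity (Pa*s)
    """

    temperature: float
    viscosity: float

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise DomainError(f"temperature must be positive, got {self.temperature}")
        if not self.viscosity > 0:
            raise DomainError(f"viscosity must be positive, got {self.viscosity}")


@dataclass(frozen=True)
class DeviceGeometry:
    """Main-channel geometry and measurement-point layout.

    channel_width  : cross-channel width (um)
    channel_height : channel height (um)
    wall_thickness : displayed sidewall line thickness (um)
    positions      : distances of the measurement points from the channel
                     origin at the focusing junction (um), strictly increasing
    """

    channel_width: float
    channel_height: float
    wall_thickness: float
    positions: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("channel_width", "channel_height", "wall_thickness"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", tuple(pos.tolist()))
        if pos.size:
            if np.any(pos < 0):
                raise DomainError("positions must be non-negative")
            if np.any(np.diff(pos) <= 0):
                raise DomainError("positions must be strictly increasing")


@dataclass(frozen=True)
class FlowConfig:
    """Pump rates in uL/min: one analyte stream plus two symmetric buffer streams."""

    analyte_flow: float
    buffer_flow: float

    def __post_init__(self) -> None:
        if self.analyte_flow < 0 or self.buffer_flow < 0:
            raise DomainError("flow rates must be non-negative")
        if not self.total > 0:
            raise DomainError("total flow must be positive")

    @property
    def total(self) -> float:
        """Total volumetric flow through the main channel (uL/min)."""
        return self.analyte_flow + 2.0 * self.buffer_flow


def diffusion_from_radius(r: float, cond: Conditions) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s) of a sphere of radius ``r`` (m)."""
    if not r > 0:
        raise DomainError(f"radius must be positive, got {r}")
    return BOLTZMANN * cond.temperature / (6.0 * math.pi * cond.viscosity * r)


def radius_from_diffusion(D: float, cond: Conditions) -> float:
    """Hydrodynamic radius (m) of a sphere with diffusion coefficient ``D`` (m^2/s)."""
    if not D > 0:
        raise DomainError(f"diffusion coefficient must be positive, got {D}")
    return BOLTZMANN * cond.temperature / (6.0 * math.pi * cond.viscosity * D)


def mean_velocity(flow: FlowConfig, geom: DeviceGeometry) -> float:
    """Mean particle speed (um/s) under plug flow: total flow over the cross-section."""
    q = flow.total * ULMIN_TO_UM3S  # um^3/s
    return q / (geom.channel_height * geom.channel_width)


def transit_times(geom: DeviceGeometry, v: float) -> tuple[np.ndarray, np.ndarray]:
    """Transit times (s) to each measurement point and the inter-point deltas.

    ``t_i = position_i / v``; deltas are the simple differences between
    consecutive times.
    """
    if not v > 0:
        raise DomainError(f"velocity must be positive, got {v}")
    pos = np.asarray(geom.positions, dtype=float)
    t = pos / v
    return t, np.diff(t)


def slope_bounds(r_min: float, r_max: float, cond: Conditions) -> tuple[float, float]:
    """Admissible variance-time slopes (um^2/s) for radii in ``[r_min, r_max]`` (m).

    The slope of the variance-time line is ``4*D``; the fastest admissible
    spreading comes from the smallest particle, so the upper bound is
    ``4*D(r_min)`` and the lower bound ``4*D(r_max)``.
    """
    if not 0 < r_min <= r_max:
        raise DomainError(f"need 0 < r_min <= r_max, got ({r_min}, {r_max})")
    hi = 4.0 * diffusion_from_radius(r_min, cond) * M2S_TO_UM2S
    lo = 4.0 * diffusion_from_radius(r_max, cond) * M2S_TO_UM2S
    return lo, hi
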