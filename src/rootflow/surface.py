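"""Daily weather to surface boundary: ET partition and surface flux.

Daily potential evapotranspiration is split into potential soil evaporation
Ep and potential transpiration Tp with a Beer's-law canopy factor,
``Tp = ET0 (1 - exp(-k_ext * LAI))``.  Potential evaporation is limited to
the exfiltration capacity of the surface block — the Darcy flux toward an
air-dry surface head — and the net of rain minus actual evaporation becomes
the downward-positive surface flux in m/s (1 mm/day = 1/86 400 000 m/s).
Air temperature and relative humidity are read and carried along for file
fidelity but do not enter the default physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MM_DAY_TO_M_S",
    "WeatherRecord",
    "SurfaceForcing",
    "partition_et",
    "evaporation_limit",
    "surface_flux",
]

#: 1 mm/day in m/s
MM_DAY_TO_M_S = 1.0 / 86_400_000.0


@dataclass(frozen=True)
class WeatherRecord:
    """One day of forcing."""

    day: int          # Julian day
    et0: float        # potential evapotranspiration (mm/day)
    tair: float       # air temperature (deg C)
    rain: float       # rainfall (mm/day)
    rh: float         # relative humidity (fraction)
    lai: float        # leaf area index (-)

    def __post_init__(self):
        if self.et0 < 0 or self.rain < 0 or self.lai < 0:
            raise ValueError(f"day {self.day}: et0, rain, lai must be >= 0")
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(f"day {self.day}: rh must be a fraction in [0, 1]")


@dataclass(frozen=True)
class SurfaceForcing:
    """Partitioned daily forcing."""

    potential_evaporation: float   # mm/day
    potential_transpiration: float  # mm/day
    surface_flux: float            # m/s, positive downward


def partition_et(rec: WeatherRecord, k_ext: float = 0.5) -> tuple[float, float]:
    """Split ET0 into (Ep, Tp) by canopy light interception.

    Tp = ET0 (1 - exp(-k_ext LAI)); Ep = ET0 - Tp.
    """
    if k_ext <= 0:
        raise ValueError("canopy extinction coefficient must be positive")
    tp = rec.et0 * (1.0 - np.exp(-k_ext * rec.lai))
    return rec.et0 - tp, tp


def evaporation_limit(
    Ep: float,
    h_surface: float,
    surface_material,
    dz: float,
    h_dry: float = -1000.0,
) -> float:
    """Actual soil evaporation (mm/day): min of demand and supply.

    Supply is the upward Darcy flux the surface block can deliver against
    a prescribed air-dry surface head ``h_dry``, using the block's current
    conductivity across one block spacing:
    ``E_cap = K(h) ((h - h_dry)/dz - 1)`` (never negative).
    """
    if Ep < 0:
        raise ValueError("potential evaporation must be >= 0")
    K = surface_material.K_of_h(h_surface)
    cap_ms = max(0.0, K * ((h_surface - h_dry) / dz - 1.0))
    cap_mmday = cap_ms / MM_DAY_TO_M_S
    return min(Ep, cap_mmday)


def surface_flux(rain: float, actual_evaporation: float) -> float:
    """Net surface flux J(0,t) in m/s, positive downward."""
    return (rain - actual_evaporation) * MM_DAY_TO_M_S
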