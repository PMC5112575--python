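"""Time-loop orchestration: daily forcing, sub-daily flux-update steps,
and water-balance accounting.

Cumulative ledger terms (all mm of water):

WADD
    time-integral of the applied net surface flux (rain minus actual
    evaporation) — the water added at the surface.
BIGI
    infiltration implied by the profile budget: storage change plus
    drainage plus transpiration.  Identical to WADD whenever every trial
    water content was accepted (the mass-balance update telescopes
    exactly); any difference comes from rejection steps.
WBELOW
    drainage through the bottom (unit-gradient) boundary.
C_AEVA / C_ATRA
    cumulative actual soil evaporation / plant transpiration.
PCTDIF
    (BIGI - WADD) / WADD * 100, the percent water-balance closure error
    (reported as 0 while |WADD| is negligible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydraulics import SoilProfile
from .root_uptake import RootUptakeConfig, compute_sink
from .solver import (
    BoundaryCondition,
    Grid,
    SolverError,
    State,
    flux_update_step,
)
from .surface import WeatherRecord, evaporation_limit, partition_et, surface_flux

__all__ = [
    "SimulationOptions",
    "WaterBalanceLedger",
    "SimulationRun",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationOptions:
    """Numerical and surface-physics knobs of the forward run."""

    dt: float = 300.0            # base step (s); halved on numerical failure
    kmean: str = "arithmetic"    # internode conductivity averaging
    k_ext: float = 0.5           # canopy extinction coefficient
    h_dry: float = -1000.0       # air-dry surface head for stage-2 evaporation (m)
    max_halvings: int = 12

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class WaterBalanceLedger:
    """Final cumulative water-balance terms of a run (mm; PCTDIF %)."""

    bigi: float
    wadd: float
    wbelow: float
    c_aeva: float
    c_atra: float
    pctdif: float


@dataclass
class SimulationRun:
    """Daily outputs of one forward simulation."""

    grid: Grid
    days: np.ndarray           # Julian day of each output row
    head: np.ndarray           # (ndays, nz) end-of-day pressure heads (m)
    theta: np.ndarray          # (ndays, nz) end-of-day water contents
    ledger: pd.DataFrame       # daily cumulative terms
    n_rejected: int            # trial-theta rejections over the whole run

    @property
    def final_ledger(self) -> WaterBalanceLedger:
        last = self.ledger.iloc[-1]
        return WaterBalanceLedger(
            bigi=float(last["bigi"]),
            wadd=float(last["wadd"]),
            wbelow=float(last["wbelow"]),
            c_aeva=float(last["c_aeva"]),
            c_atra=float(last["c_atra"]),
            pctdif=float(last["pctdif"]),
        )

    def block_index(self, depth: float) -> int:
        """Index of the block whose centre is nearest to ``depth`` (m)."""
        return int(np.argmin(np.abs(self.grid.z_centers - depth)))

    def theta_at(self, day: int, depth: float) -> float:
        rows = np.flatnonzero(self.days == day)
        if rows.size == 0:
            raise KeyError(f"day {day} not in simulation window")
        return float(self.theta[rows[0], self.block_index(depth)])

    def profile_frame(self) -> pd.DataFrame:
        """Tidy (day, depth, head, theta) table of the daily profiles."""
        zc = self.grid.z_centers
        days = np.repeat(self.days, self.grid.nz)
        depths = np.tile(zc, self.days.size)
        return pd.DataFrame(
            {
                "day": days,
                "depth": depths,
                "head": self.head.ravel(),
                "theta": self.theta.ravel(),
            }
        )


def _storage_mm(theta: np.ndarray, grid: Grid) -> float:
    return float(np.sum(theta) * grid.dz * 1000.0)


def _advance(state, grid, props, bc, sink, dt, kmean, halvings_left):
    """One sub-step with recursive halving on numerical failure.

    Returns a list of (StepResult, dt_used) leaves covering ``dt``.
    """
    try:
        return [(flux_update_step(state, grid, props, bc, sink, dt, kmean), dt)]
    except SolverError:
        if halvings_left <= 0:
            raise
    half = dt / 2.0
    first = _advance(state, grid, props, bc, sink, half, kmean, halvings_left - 1)
    second = _advance(
        first[-1][0].state, grid, props, bc, sink, half, kmean, halvings_left - 1
    )
    return first + second


def run_simulation(
    profile: SoilProfile,
    grid: Grid,
    initial_theta: np.ndarray,
    weather: list[WeatherRecord],
    uptake: RootUptakeConfig,
    options: SimulationOptions | None = None,
) -> SimulationRun:
    """Simulate the weather window day by day with sub-daily steps.

    Daily forcing is held piecewise constant; the surface flux and the sink
    are refreshed every sub-step from the evolving surface state.
    """
    opts = options or SimulationOptions()
    props = profile.bind(grid)
    initial_theta = np.asarray(initial_theta, float)
    if initial_theta.shape != (grid.nz,):
        raise ValueError(f"initial profile length {initial_theta.size} != nz {grid.nz}")
    lo = props.theta_r + 1e-6
    hi = props.theta_s
    theta0 = np.clip(initial_theta, lo, hi)
    state = State(0.0, props.h_of_theta(theta0), theta0.copy())

    storage0 = _storage_mm(state.theta, grid)
    wadd = wbelow = c_aeva = c_atra = 0.0
    n_rejected = 0
    rows = []
    days = []
    heads = []
    thetas = []
    surf_mat = props.surface_material

    day_seconds = 86400.0
    for rec in weather:
        ep, tp = partition_et(rec, opts.k_ext)
        t_in_day = 0.0
        while t_in_day < day_seconds - 1e-6:
            dt = min(opts.dt, day_seconds - t_in_day)
            ae = evaporation_limit(ep, state.h[0], surf_mat, grid.dz, opts.h_dry)
            j0 = surface_flux(rec.rain, ae)
            bc = BoundaryCondition.flux(j0)
            sink = compute_sink(state.h, grid, tp, rec.day, uptake)
            try:
                results = _advance(
                    state, grid, props, bc, sink.S, dt, opts.kmean, opts.max_halvings
                )
            except SolverError as err:
                raise SolverError(
                    f"day {rec.day}, t={t_in_day:.0f}s: {err}"
                ) from err
            state = results[-1][0].state
            n_rejected += sum(r.n_rejected for r, _ in results)
            wadd += j0 * dt * 1000.0
            wbelow += sum(r.fluxes.J[-1] * dt_leaf for r, dt_leaf in results) * 1000.0
            c_aeva += ae * dt / day_seconds
            c_atra += sink.actual_transpiration * dt / day_seconds
            t_in_day += dt

        storage = _storage_mm(state.theta, grid)
        bigi = (storage - storage0) + wbelow + c_atra
        pctdif = (bigi - wadd) / wadd * 100.0 if abs(wadd) > 1e-9 else 0.0
        days.append(rec.day)
        heads.append(state.h.copy())
        thetas.append(state.theta.copy())
        rows.append(
            {
                "day": rec.day,
                "rain": rec.rain,
                "et0": rec.et0,
                "ep": ep,
                "tp": tp,
                "wadd": wadd,
                "bigi": bigi,
                "wbelow": wbelow,
                "c_aeva": c_aeva,
                "c_atra": c_atra,
                "storage": storage,
                "pctdif": pctdif,
            }
        )

    return SimulationRun(
        grid=grid,
        days=np.asarray(days, dtype=int),
        head=np.asarray(heads),
        theta=np.asarray(thetas),
        ledger=pd.DataFrame(rows),
        n_rejected=n_rejected,
    )
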