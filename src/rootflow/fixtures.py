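"""Synthetic scenario generator.

Builds complete, self-consistent inputs — a loam-like soil, a multi-week
weather series with periodic rain pulses, an initial water-content profile,
and "measured" observations produced by a forward truth simulation plus
seeded multiplicative noise — so every part of the package is testable
without external data.  The soil constants below are fixture conventions.

Everything is deterministic given the seed; the same spec written twice
produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .hydraulics import SoilProfile, VanGenuchten
from .io_formats import (
    InputBundle,
    write_init,
    write_soil,
    write_term,
    write_weather,
)
from .root_uptake import RootUptakeConfig
from .simulate import SimulationOptions, SimulationRun, run_simulation
from .solver import Grid
from .surface import WeatherRecord

__all__ = [
    "LOAM",
    "ScenarioSpec",
    "ObservationPlan",
    "make_weather",
    "make_scenario",
    "synthesize_observations",
    "default_spec",
    "reduced_spec",
]

#: loam-like fixture soil (van Genuchten-Mualem)
LOAM = VanGenuchten(
    theta_r=0.05, theta_s=0.45, alpha=2.0, n=1.8, K_s=1e-6, name="loam"
)


@dataclass(frozen=True)
class ObservationPlan:
    """Where and when the synthetic profile is 'measured'."""

    days: tuple
    depths: tuple
    noise_sd: float = 0.0   # sd of multiplicative noise
    seed: int = 0


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic study."""

    depth: float = 2.0
    nz: int = 40
    days: int = 111              # length of the weather window
    start_day: int = 134         # Julian day the window opens
    soil: VanGenuchten = LOAM
    theta0: float = 0.32         # uniform initial water content
    et0_base: float = 4.0        # mm/day, modulated seasonally
    rain_period: int = 8         # days between rain pulses
    rain_depth: float = 16.0     # mm per pulse
    lai_min: float = 0.1
    lai_max: float = 2.5
    beta_true: float = 2.0
    zr_true: float = 1.0
    jthaw: int = 134
    jmatur: int = 180
    icps: int = 1
    ihth: int = 1
    lam: float = 1.0
    l0: float = 0.05
    dt: float = 300.0
    plan: ObservationPlan | None = None

    def grid(self) -> Grid:
        return Grid(nz=self.nz, dz=self.depth / self.nz)

    def uptake(self, beta=None, zr=None) -> RootUptakeConfig:
        from .root_uptake import StressThresholds

        return RootUptakeConfig(
            icps=self.icps,
            beta=self.beta_true if beta is None else beta,
            zr_max=self.zr_true if zr is None else zr,
            jthaw=self.jthaw,
            jmatur=self.jmatur,
            lam=self.lam,
            l0=self.l0,
            thresholds=StressThresholds(ihth=self.ihth),
        )

    def options(self) -> SimulationOptions:
        return SimulationOptions(dt=self.dt)

    def default_plan(self) -> ObservationPlan:
        if self.plan is not None:
            return self.plan
        first = self.start_day + 10
        last = self.start_day + self.days - 1
        days = tuple(range(first, last + 1, 10))
        depths = tuple(
            d for d in (0.1, 0.3, 0.5, 0.7, 0.9, 1.2, 1.5) if d < self.depth
        )
        return ObservationPlan(days=days, depths=depths)


def default_spec(**overrides) -> ScenarioSpec:
    """The standard 111-day synthetic scenario."""
    return replace(ScenarioSpec(), **overrides) if overrides else ScenarioSpec()


def reduced_spec(**overrides) -> ScenarioSpec:
    """Coarse scenario for fast sweeps: 54 days, 20 blocks, 10-min steps.

    Root maturity falls inside the window and the observation plan mimics
    a logging sensor profile (daily records at eight depths): root depth is
    only identifiable from the late-season drydown, and the beta-Zr
    trade-off needs many observations to resolve.
    """
    spec = ScenarioSpec(
        nz=20,
        days=54,
        jmatur=154,
        dt=600.0,
        l0=0.1,
        plan=ObservationPlan(
            days=tuple(range(140, 134 + 54)),
            depths=(0.15, 0.35, 0.55, 0.75, 0.95, 1.15, 1.35, 1.55),
        ),
    )
    return replace(spec, **overrides) if overrides else spec


def make_weather(spec: ScenarioSpec) -> list:
    """Deterministic daily forcing: seasonal ET0, periodic rain pulses,
    LAI ramping from lai_min to lai_max between jthaw and jmatur."""
    recs = []
    for k in range(spec.days):
        day = spec.start_day + k
        et0 = spec.et0_base * (1.0 + 0.15 * np.sin(2.0 * np.pi * k / 30.0))
        rain = spec.rain_depth if k % spec.rain_period == 0 else 0.0
        if day <= spec.jthaw:
            lai = spec.lai_min
        elif day >= spec.jmatur:
            lai = spec.lai_max
        else:
            frac = (day - spec.jthaw) / (spec.jmatur - spec.jthaw)
            lai = spec.lai_min + frac * (spec.lai_max - spec.lai_min)
        recs.append(
            WeatherRecord(day=day, et0=round(et0, 4), tair=20.0,
                          rain=rain, rh=0.6, lai=round(lai, 4))
        )
    return recs


def synthesize_observations(run: SimulationRun, plan: ObservationPlan):
    """(day, depth, theta) triples: simulated values times (1 + eps) with
    eps ~ Normal(0, noise_sd), seeded; exact when noise_sd = 0."""
    for day in plan.days:
        if day not in run.days:
            raise ValueError(f"plan day {day} outside the simulated window")
    rng = np.random.default_rng(plan.seed)
    obs = []
    for day in plan.days:
        for depth in plan.depths:
            th = run.theta_at(day, depth)
            if plan.noise_sd > 0:
                th *= 1.0 + rng.normal(0.0, plan.noise_sd)
            obs.append((int(day), float(depth), float(th)))
    return obs


def make_scenario(spec: ScenarioSpec | None = None, outdir=None):
    """Build the full input bundle plus the hidden truth record.

    Runs the forward truth simulation to synthesize the 'measured'
    observations.  If ``outdir`` is given, writes the four input files
    (soil.dat, initf.dat, termf.dat, wea2.dat) there.

    Returns ``(bundle, truth)`` where truth holds the generating parameters
    and the truth run.
    """
    spec = spec or ScenarioSpec()
    grid = spec.grid()
    profile = SoilProfile.homogeneous(spec.soil, spec.depth)
    theta0 = np.full(grid.nz, spec.theta0)
    weather = make_weather(spec)
    truth_run = run_simulation(
        profile, grid, theta0, weather, spec.uptake(), spec.options()
    )
    plan = spec.default_plan()
    last_day = spec.start_day + spec.days - 1
    in_window = tuple(d for d in plan.days if d <= last_day)
    if not in_window:
        in_window = (last_day,)
    if in_window != plan.days:
        plan = replace(plan, days=in_window)
    obs = synthesize_observations(truth_run, plan)
    bundle = InputBundle(
        grid=grid, profile=profile, initial_theta=theta0,
        weather=weather, observations=obs,
    )
    truth = {
        "beta": spec.beta_true,
        "zr_max": spec.zr_true,
        "run": truth_run,
        "plan": plan,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_soil(outdir / "soil.dat", grid, profile)
        write_init(outdir / "initf.dat", theta0)
        write_term(outdir / "termf.dat", obs)
        write_weather(outdir / "wea2.dat", weather)
    return bundle, truth
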