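"""Model/Results front end for root-parameter estimation.

``RootZoneModel`` binds the forward soil-water model (soil profile, initial
state, weather, uptake configuration) to measured water-content
observations; ``fit()`` sweeps the (beta, Zr) lattice and returns a
``RootZoneResults`` carrying the estimates, the objective surface, the
water-balance grids and a text ``summary()``.

Because the estimator is an exhaustive grid search, uncertainty is
reported as the set of near-optimal lattice points (cells whose ARD is
within a relative tolerance of the minimum), not as standard errors.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .io_formats import InputBundle, read_bundle
from .root_uptake import RootUptakeConfig
from .search import SearchGrid, SearchResult, ard_score, run_search
from .simulate import SimulationOptions, SimulationRun, run_simulation

__all__ = ["RootZoneModel", "RootZoneResults"]


class RootZoneModel:
    """Mechanistic soil-plant water model with grid-search inversion.

    Parameters
    ----------
    observations : iterable of (day, depth_m, theta) triples
        Measured soil water contents (day None means the final weather day).
    bundle : InputBundle
        Soil, grid, initial profile and weather forcing.
    uptake : RootUptakeConfig, optional
        Uptake configuration template; beta and zr_max are overwritten by
        the search.
    search_grid : SearchGrid, optional
        Defaults to the documented 16 x 22 lattice.
    options : SimulationOptions, optional
    """

    def __init__(self, observations, bundle: InputBundle,
                 uptake: RootUptakeConfig | None = None,
                 search_grid: SearchGrid | None = None,
                 options: SimulationOptions | None = None):
        self.observations = list(observations)
        if not self.observations:
            raise ValueError("need at least one observation")
        self.bundle = bundle
        self.uptake = uptake or RootUptakeConfig()
        self.search_grid = search_grid or SearchGrid.default()
        self.options = options or SimulationOptions(kmean=bundle.kmean)

    @classmethod
    def from_files(cls, soil, init, term, weather, **kwargs) -> "RootZoneModel":
        bundle = read_bundle(soil, init, weather, term)
        return cls(bundle.observations, bundle, **kwargs)

    def simulate(self, beta: float | None = None,
                 zr_max: float | None = None) -> SimulationRun:
        """One forward run at the given (or configured) root parameters."""
        cfg = self.uptake
        if beta is not None:
            cfg = replace(cfg, beta=float(beta))
        if zr_max is not None:
            cfg = replace(cfg, zr_max=float(zr_max))
        return run_simulation(
            self.bundle.profile, self.bundle.grid, self.bundle.initial_theta,
            self.bundle.weather, cfg, self.options,
        )

    def fit(self) -> "RootZoneResults":
        res = run_search(
            self.bundle, self.uptake, self.search_grid,
            self.observations, self.options,
        )
        return RootZoneResults(self, res)


class RootZoneResults:
    """Estimates and diagnostics of a fitted :class:`RootZoneModel`."""

    def __init__(self, model: RootZoneModel, search: SearchResult):
        self.model = model
        self.search = search
        beta, zr = search.argmin
        self.params = pd.Series({"beta": beta, "zr_max": zr})
        i, j = search.argmin_index
        self.ard_min = float(search.ard[i, j])

    @property
    def ard(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.search.ard, index=self.search.betas, columns=self.search.zrmaxs
        )

    def near_optimal(self, rtol: float = 0.1) -> pd.DataFrame:
        """Lattice points with ARD within ``(1 + rtol)`` of the minimum."""
        mask = self.search.ard <= self.ard_min * (1.0 + rtol)
        ii, jj = np.nonzero(mask & np.isfinite(self.search.ard))
        return pd.DataFrame(
            {
                "beta": self.search.betas[ii],
                "zr_max": self.search.zrmaxs[jj],
                "ard": self.search.ard[ii, jj],
            }
        ).sort_values("ard", ignore_index=True)

    def best_run(self) -> SimulationRun:
        """Forward run at the fitted parameters."""
        return self.model.simulate(*self.search.argmin)

    def summary(self) -> str:
        s = self.search
        i, j = s.argmin_index
        near = self.near_optimal()
        lines = [
            "Root-zone water model — grid-search fit",
            "=" * 47,
            f"lattice            {len(s.betas)} beta x {len(s.zrmaxs)} zr_max "
            f"({len(s.betas) * len(s.zrmaxs)} simulations)",
            f"observations       {len(self.model.observations)}",
            f"failed cells       {len(s.failures)}",
            "-" * 47,
            f"beta (root shape)  {self.params['beta']:.4g}",
            f"zr_max (m)         {self.params['zr_max']:.4g}",
            f"ARD at optimum     {self.ard_min:.5f}",
            f"near-optimal cells {len(near)} (ARD within 10% of minimum)",
            "-" * 47,
            "water balance at the optimum (mm):",
            f"  infiltration BIGI   {s.bigi[i, j]:.2f}",
            f"  water added  WADD   {s.wadd[i, j]:.2f}",
            f"  evaporation  C_AEVA {s.c_aeva[i, j]:.2f}",
            f"  transpiration C_ATRA {s.c_atra[i, j]:.2f}",
            f"  drainage     WBELOW {s.wbelow[i, j]:.2f}",
            f"  closure      PCTDIF {s.pctdif[i, j]:.4f} %",
        ]
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Filled-contour map of the ARD surface with the optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.search
        cs = ax.contourf(s.zrmaxs, s.betas, s.ard, levels=20)
        ax.plot(self.params["zr_max"], self.params["beta"], "r*", ms=12)
        ax.set_xlabel("maximum rooting depth $Z_r$ (m)")
        ax.set_ylabel(r"root shape factor $\beta$")
        ax.set_title("average relative discrepancy")
        plt.colorbar(cs, ax=ax, label="ARD (-)")
        return ax
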