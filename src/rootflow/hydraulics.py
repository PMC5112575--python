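"""Soil hydraulic property models.

Every layer of the profile supplies four relations to the flow solver:
the retention curve ``theta(h)``, its inverse ``h(theta)``, the unsaturated
conductivity ``K(theta)`` and the soil water capacity ``c(h) = dtheta/dh``.

Two families are provided:

``VanGenuchten``
    Closed-form van Genuchten retention with Mualem conductivity,
    ``m = 1 - 1/n``.  Smooth derivatives, the default for synthetic work.
``TabulatedCurve``
    Piecewise-linear retention and conductivity tables (the workflow of the
    original Fortran lineage, which reads measured curves from file).
    Flat extrapolation beyond the end nodes.

Conventions used throughout the package: pressure head ``h`` in metres of
water (negative when unsaturated, ``h >= 0`` saturated), water content in
m3/m3, conductivity in m/s, depth in metres positive downward with the soil
surface at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HydraulicError",
    "VanGenuchten",
    "TabulatedCurve",
    "SoilProfile",
    "ProfileProperties",
]


class HydraulicError(ValueError):
    """A water content or head outside a layer's admissible range."""


def _as_array(x):
    a = np.asarray(x, dtype=float)
    return a, a.ndim == 0


def _ret(a, scalar):
    return float(a) if scalar else a


@dataclass(frozen=True)
class VanGenuchten:
    """van Genuchten retention with Mualem conductivity for one material.

    Parameters
    ----------
    theta_r, theta_s : residual / saturated water content (m3/m3)
    alpha : inverse air-entry scale (1/m)
    n : pore-size distribution index (> 1); ``m = 1 - 1/n``
    K_s : saturated hydraulic conductivity (m/s)
    ell : Mualem pore-connectivity exponent (default 0.5)
    """

    theta_r: float
    theta_s: float
    alpha: float
    n: float
    K_s: float
    ell: float = 0.5
    name: str = "layer"

    def __post_init__(self):
        if not 0.0 <= self.theta_r < self.theta_s:
            raise ValueError(
                f"{self.name}: need 0 <= theta_r < theta_s, "
                f"got ({self.theta_r}, {self.theta_s})"
            )
        if self.alpha <= 0.0 or self.n <= 1.0 or self.K_s <= 0.0:
            raise ValueError(f"{self.name}: alpha, K_s > 0 and n > 1 required")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n

    def theta_of_h(self, h):
        h, scalar = _as_array(h)
        se = np.ones_like(h)
        neg = h < 0.0
        se[neg] = (1.0 + (self.alpha * np.abs(h[neg])) ** self.n) ** (-self.m)
        return _ret(self.theta_r + (self.theta_s - self.theta_r) * se, scalar)

    def h_of_theta(self, theta, validate: bool = True):
        theta, scalar = _as_array(theta)
        if validate and (
            np.any(theta <= self.theta_r) or np.any(theta > self.theta_s + 1e-12)
        ):
            raise HydraulicError(
                f"{self.name}: theta outside ({self.theta_r}, {self.theta_s}]"
            )
        se = np.minimum((theta - self.theta_r) / (self.theta_s - self.theta_r), 1.0)
        h = np.zeros_like(se)
        uns = se < 1.0
        h[uns] = -((se[uns] ** (-1.0 / self.m) - 1.0) ** (1.0 / self.n)) / self.alpha
        return _ret(h, scalar)

    def K_of_theta(self, theta, validate: bool = True):
        theta, scalar = _as_array(theta)
        if validate and (
            np.any(theta < self.theta_r - 1e-12)
            or np.any(theta > self.theta_s + 1e-12)
        ):
            raise HydraulicError(
                f"{self.name}: theta outside [{self.theta_r}, {self.theta_s}]"
            )
        se = np.clip((theta - self.theta_r) / (self.theta_s - self.theta_r), 0.0, 1.0)
        k = np.zeros_like(se)
        pos = se > 0.0
        sp = se[pos]
        k[pos] = (
            self.K_s
            * sp**self.ell
            * (1.0 - (1.0 - sp ** (1.0 / self.m)) ** self.m) ** 2
        )
        return _ret(k, scalar)

    def K_of_h(self, h):
        return self.K_of_theta(self.theta_of_h(h))

    def capacity(self, h):
        h, scalar = _as_array(h)
        c = np.zeros_like(h)
        neg = h < 0.0
        ah = self.alpha * np.abs(h[neg])
        c[neg] = (
            (self.theta_s - self.theta_r)
            * self.m
            * self.n
            * self.alpha
            * ah ** (self.n - 1.0)
            * (1.0 + ah**self.n) ** (-self.m - 1.0)
        )
        return _ret(c, scalar)


@dataclass(frozen=True)
class TabulatedCurve:
    """Piecewise-linear retention and conductivity curves for one material.

    ``h_nodes`` (m, strictly increasing, last node must be 0) pair with
    ``theta_nodes`` (strictly increasing); ``thetak_nodes`` (strictly
    increasing) pair with ``k_nodes`` (non-decreasing, m/s).  Interpolation
    is linear with flat extrapolation beyond the end nodes.
    """

    h_nodes: tuple
    theta_nodes: tuple
    thetak_nodes: tuple
    k_nodes: tuple
    name: str = "layer"

    def __post_init__(self):
        h = np.asarray(self.h_nodes, float)
        th = np.asarray(self.theta_nodes, float)
        tk = np.asarray(self.thetak_nodes, float)
        k = np.asarray(self.k_nodes, float)
        if h.size != th.size or h.size < 2:
            raise ValueError(f"{self.name}: retention table needs >= 2 (h, theta) pairs")
        if tk.size != k.size or tk.size < 2:
            raise ValueError(f"{self.name}: conductivity table needs >= 2 (theta, K) pairs")
        if np.any(np.diff(h) <= 0) or np.any(np.diff(th) <= 0):
            raise ValueError(f"{self.name}: retention nodes must be strictly increasing")
        if h[-1] != 0.0:
            raise ValueError(f"{self.name}: last retention node must be at h = 0 (saturation)")
        if np.any(np.diff(tk) <= 0) or np.any(np.diff(k) < 0):
            raise ValueError(f"{self.name}: conductivity table must be monotone")

    @property
    def theta_r(self) -> float:
        return float(self.theta_nodes[0])

    @property
    def theta_s(self) -> float:
        return float(self.theta_nodes[-1])

    @property
    def K_s(self) -> float:
        return float(self.k_nodes[-1])

    def theta_of_h(self, h):
        h, scalar = _as_array(h)
        th = np.interp(h, self.h_nodes, self.theta_nodes)
        return _ret(th, scalar)

    def h_of_theta(self, theta, validate: bool = True):
        theta, scalar = _as_array(theta)
        if validate and (
            np.any(theta < self.theta_r - 1e-12)
            or np.any(theta > self.theta_s + 1e-12)
        ):
            raise HydraulicError(
                f"{self.name}: theta outside [{self.theta_r}, {self.theta_s}]"
            )
        h = np.interp(theta, self.theta_nodes, self.h_nodes)
        return _ret(h, scalar)

    def K_of_theta(self, theta, validate: bool = True):
        theta, scalar = _as_array(theta)
        if validate and (
            np.any(theta < self.theta_r - 1e-12)
            or np.any(theta > self.theta_s + 1e-12)
        ):
            raise HydraulicError(
                f"{self.name}: theta outside [{self.theta_r}, {self.theta_s}]"
            )
        return _ret(np.interp(theta, self.thetak_nodes, self.k_nodes), scalar)

    def K_of_h(self, h):
        return self.K_of_theta(self.theta_of_h(h))

    def capacity(self, h):
        h, scalar = _as_array(h)
        hn = np.asarray(self.h_nodes, float)
        tn = np.asarray(self.theta_nodes, float)
        slopes = np.diff(tn) / np.diff(hn)
        # segment index for each h; flat (zero slope) outside the table and at h >= 0
        idx = np.clip(np.searchsorted(hn, h, side="right") - 1, 0, slopes.size - 1)
        c = slopes[idx]
        c = np.where((h < hn[0]) | (h >= 0.0), 0.0, c)
        return _ret(c, scalar)


@dataclass(frozen=True)
class SoilProfile:
    """Ordered soil layers: ``layers[k] = (bottom_depth_m, material)``.

    Depths are positive downward and strictly increasing; the last bottom
    depth is the profile depth ``z_max``.
    """

    layers: tuple

    def __post_init__(self):
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        depths = [d for d, _ in self.layers]
        if any(b <= a for a, b in zip(depths, depths[1:])) or depths[0] <= 0:
            raise ValueError("layer bottom depths must be positive and strictly increasing")

    @property
    def z_max(self) -> float:
        return float(self.layers[-1][0])

    def material_at(self, z: float):
        """Material of the layer containing depth z (m, downward)."""
        for bottom, mat in self.layers:
            if z <= bottom + 1e-12:
                return mat
        raise ValueError(f"depth {z} m below profile bottom {self.z_max} m")

    def bind(self, grid) -> "ProfileProperties":
        return ProfileProperties(self, grid)

    @classmethod
    def homogeneous(cls, material, z_max: float) -> "SoilProfile":
        return cls(((float(z_max), material),))


class ProfileProperties:
    """Per-block hydraulic property evaluation for a profile on a grid.

    Precomputes which contiguous block ranges share a material so the
    solver can evaluate properties on whole arrays.
    """

    def __init__(self, profile: SoilProfile, grid):
        if grid.z_max > profile.z_max + 1e-9:
            raise ValueError(
                f"grid depth {grid.z_max} m exceeds profile depth {profile.z_max} m"
            )
        self.profile = profile
        self.grid = grid
        zc = grid.z_centers
        mats = [profile.material_at(z) for z in zc]
        slices = []
        start = 0
        for i in range(1, len(mats) + 1):
            if i == len(mats) or mats[i] is not mats[start]:
                slices.append((slice(start, i), mats[start]))
                start = i
        self._slices = slices
        self.theta_r = np.array([m.theta_r for m in mats])
        self.theta_s = np.array([m.theta_s for m in mats])
        self.K_s = np.array([m.K_s for m in mats])

    @property
    def surface_material(self):
        return self._slices[0][1]

    def _apply(self, fname, x, **kwargs):
        x = np.asarray(x, float)
        out = np.empty_like(x)
        for sl, mat in self._slices:
            out[sl] = getattr(mat, fname)(x[sl], **kwargs)
        return out

    def theta_of_h(self, h):
        return self._apply("theta_of_h", h)

    def h_of_theta(self, theta, validate: bool = True):
        return self._apply("h_of_theta", theta, validate=validate)

    def K_of_theta(self, theta, validate: bool = True):
        return self._apply("K_of_theta", theta, validate=validate)

    def K_of_h(self, h):
        return self._apply("K_of_h", h)

    def capacity(self, h):
        return self._apply("capacity", h)
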