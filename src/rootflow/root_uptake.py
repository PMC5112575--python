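"""Root water uptake: stress response, dynamic root depth, and three
selectable uptake distribution / compensation models.

The sink term S(z, t) (1/s) removes water from each block at a rate set by
the potential transpiration Tp (mm/day), the vertical root distribution,
and a dimensionless stress reduction factor alpha(h) in [0, 1]:

* ``ICPS = 1`` — power-law root density ``(beta + 1)(1 - z/L)**beta / L``
  applied directly to Tp per block (no compensation).
* ``ICPS = 2`` — compensatory uptake: demand is redistributed toward
  unstressed blocks through ``S_i ∝ alpha_i**2 L_nrd,i**lambda`` normalised
  by ``sum_j alpha_j L_nrd,j**lambda``, with the cubic normalised root
  density ``L_nrd``.  With any uniform alpha = a the total uptake is a*Tp;
  with binary wet/dry stress the total stays at Tp (full compensation).
* ``ICPS = 3`` — cubic normalised root density, proportional allocation of
  Tp, scaled by alpha per block (no compensation).

alpha(h) is the trapezoidal stress function: zero above the anaerobiosis
point h1 and below the wilting point h4, one on the optimal range
[h3, h2], linear in between.  The "ending" head h3 depends linearly on the
transpiration rate between (Tp1 = 1 mm/day, h31) and (Tp2 = 5 mm/day, h32),
with three selectable (h31, h32) option sets (IHTH).

The factor 86 400 000 converts mm/day per metre of soil into 1/s
(86 400 s/day times 1000 mm/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UNIT_FACTOR",
    "StressThresholds",
    "RootUptakeConfig",
    "SinkProfile",
    "NoRootError",
    "alpha",
    "h3_of_Tp",
    "root_depth",
    "sink_prasad",
    "lnrd_wu",
    "sink_wu",
    "sink_li_yadav",
    "compute_sink",
]

#: mm/day per metre of soil -> 1/s  (86400 s/day * 1000 mm/m)
UNIT_FACTOR = 86_400_000.0

#: IHTH option sets: (h31, h32) in metres at (Tp1, Tp2) = (1, 5) mm/day
H3_OPTIONS = {1: (-11.0, -5.0), 2: (-14.0, -8.0), 3: (-16.0, -10.0)}

#: default cubic root-density coefficients (fitted for wheat)
DEFAULT_R_COEFFS = (2.21, -3.72, 3.46, -1.87)


class NoRootError(ValueError):
    """No block carries root density (all uptake weights zero)."""


@dataclass(frozen=True)
class StressThresholds:
    """Pressure-head thresholds (m) of the trapezoidal stress function.

    h1 anaerobiosis point >= h2 >= h3 >= h4 wilting point (all <= 0).
    ``ihth`` selects the (h31, h32) pair used by the transpiration-dependent
    h3 rule; Tp1 = 1 and Tp2 = 5 mm/day are its anchor rates.
    """

    h1: float = -0.1
    h2: float = -0.25
    h3: float = -5.0
    h4: float = -150.0
    ihth: int = 1
    Tp1: float = 1.0
    Tp2: float = 5.0

    def __post_init__(self):
        if self.ihth not in H3_OPTIONS:
            raise ValueError(f"ihth must be one of {sorted(H3_OPTIONS)}")
        if not (self.h1 >= self.h2 >= self.h3 >= self.h4):
            raise ValueError("need h1 >= h2 >= h3 >= h4 (less to more negative)")
        if self.h1 > 0:
            raise ValueError("stress thresholds must be <= 0")

    @property
    def h31(self) -> float:
        return H3_OPTIONS[self.ihth][0]

    @property
    def h32(self) -> float:
        return H3_OPTIONS[self.ihth][1]


@dataclass(frozen=True)
class RootUptakeConfig:
    """All tunables of the uptake sink.

    icps selects the uptake model (1 power-law, 2 compensatory, 3 cubic
    density); beta is the power-law shape factor; zr_max the maximum rooting
    depth (m); jthaw/jmatur the Julian days of growth initiation and
    maturity between which the root front advances linearly from the seed
    depth l0 to zr_max; lam the compensation exponent in [0.01, 2.0];
    r_coeffs the cubic density coefficients.
    """

    icps: int = 1
    beta: float = 2.0
    zr_max: float = 1.0
    jthaw: int = 134
    jmatur: int = 180
    lam: float = 1.0
    r_coeffs: tuple = DEFAULT_R_COEFFS
    l0: float = 0.05
    thresholds: StressThresholds = field(default_factory=StressThresholds)

    def __post_init__(self):
        if self.icps not in (1, 2, 3):
            raise ValueError("icps must be in {1, 2, 3}")
        if not 0.01 <= self.lam <= 2.0:
            raise ValueError("lambda must lie in [0.01, 2.0]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.zr_max <= 0:
            raise ValueError("zr_max must be positive")
        if self.jthaw >= self.jmatur:
            raise ValueError("jthaw must precede jmatur")
        if len(self.r_coeffs) != 4:
            raise ValueError("r_coeffs needs exactly 4 coefficients")
        if self.l0 <= 0:
            raise ValueError("seed depth l0 must be positive")


@dataclass
class SinkProfile:
    """Per-block uptake rates S (1/s) and the mm/day total they extract."""

    S: np.ndarray
    actual_transpiration: float  # mm/day
    fully_stressed: bool = False


def alpha(h, thresholds: StressThresholds):
    """Trapezoidal stress reduction factor in [0, 1] (vectorised)."""
    t = thresholds
    h_arr = np.asarray(h, dtype=float)
    xp = np.array([t.h4, t.h3, t.h2, t.h1])
    fp = np.array([0.0, 1.0, 1.0, 0.0])
    # degenerate corners (equal thresholds) collapse to steps via np.interp
    out = np.interp(h_arr, xp, fp)
    out = np.where(h_arr >= t.h1, 0.0, out)
    out = np.where(h_arr <= t.h4, 0.0, out)
    return float(out) if h_arr.ndim == 0 else out


def h3_of_Tp(Tp: float, thresholds: StressThresholds) -> float:
    """Transpiration-dependent ending head h3 (m).

    Linear between (Tp1, h31) and (Tp2, h32); clamped to the endpoint
    values outside [Tp1, Tp2].
    """
    t = thresholds
    a = (t.h31 - t.h32) / (t.Tp1 - t.Tp2)
    tp = min(max(float(Tp), t.Tp1), t.Tp2)
    return a * tp + t.h31 - a * t.Tp1


def root_depth(t: float, cfg: RootUptakeConfig, z_max: float | None = None) -> float:
    """Root depth L(t) in metres on Julian day t.

    Seed depth l0 up to jthaw, linear growth to zr_max at jmatur, constant
    thereafter; never beyond the profile depth if given.
    """
    if t <= cfg.jthaw:
        L = cfg.l0
    elif t >= cfg.jmatur:
        L = cfg.zr_max
    else:
        frac = (t - cfg.jthaw) / (cfg.jmatur - cfg.jthaw)
        L = cfg.l0 + frac * (cfg.zr_max - cfg.l0)
    if z_max is not None:
        L = min(L, z_max)
    return L


def _alpha_profile(h, thresholds, Tp):
    thr = replace(thresholds, h3=h3_of_Tp(Tp, thresholds))
    return alpha(np.asarray(h, float), thr)


def sink_prasad(h, grid, Tp: float, L: float, cfg: RootUptakeConfig) -> SinkProfile:
    """Power-law root distribution sink (ICPS = 1).

    S_i = alpha(h_i) Tp (beta+1) (1 - z_i/L)**beta / (86400000 L) inside
    the root zone, zero below it.
    """
    if L <= 0:
        raise ValueError("root depth L must be positive")
    zc = grid.z_centers
    a = _alpha_profile(h, cfg.thresholds, Tp)
    S = np.zeros(grid.nz)
    inroot = zc <= L
    S[inroot] = (
        a[inroot]
        * Tp
        * (cfg.beta + 1.0)
        * (1.0 - zc[inroot] / L) ** cfg.beta
        / (UNIT_FACTOR * L)
    )
    total = float(np.sum(S) * grid.dz * UNIT_FACTOR)
    return SinkProfile(S, total)


def lnrd_wu(z_r, r_coeffs=DEFAULT_R_COEFFS):
    """Cubic normalised root density at normalised depth z_r in [0, 1].

    Negative polynomial values (possible for user-supplied coefficients)
    are floored at zero.
    """
    z = np.asarray(z_r, dtype=float)
    if np.any(z < -1e-12) or np.any(z > 1.0 + 1e-12):
        raise ValueError("normalised depth must lie in [0, 1]")
    r1, r2, r3, r4 = r_coeffs
    val = r1 + r2 * z + r3 * z**2 + r4 * z**3
    val = np.maximum(val, 0.0)
    return float(val) if z.ndim == 0 else val


def _wu_weights(grid, L: float, cfg: RootUptakeConfig):
    zc = grid.z_centers
    inroot = zc <= L
    w = np.zeros(grid.nz)
    w[inroot] = lnrd_wu(zc[inroot] / L, cfg.r_coeffs) * grid.dz
    return w, inroot


def sink_wu(h, grid, Tp: float, L: float, cfg: RootUptakeConfig) -> SinkProfile:
    """Cubic-density sink without compensation (ICPS = 3).

    Tp is allocated across in-root blocks in proportion to the discrete
    normalised density, then scaled by alpha per block; total uptake equals
    Tp exactly when alpha = 1 everywhere.
    """
    if L <= 0:
        raise ValueError("root depth L must be positive")
    w, _ = _wu_weights(grid, L, cfg)
    wsum = w.sum()
    if wsum <= 0.0:
        raise NoRootError("all root-density weights are zero")
    a = _alpha_profile(h, cfg.thresholds, Tp)
    S = a * Tp * w / (UNIT_FACTOR * grid.dz * wsum)
    total = float(np.sum(S) * grid.dz * UNIT_FACTOR)
    return SinkProfile(S, total)


def sink_li_yadav(h, grid, Tp: float, L: float, cfg: RootUptakeConfig) -> SinkProfile:
    """Compensatory sink (ICPS = 2) with the cubic normalised density.

    S_i = alpha_i**2 L_nrd,i**lam Tp / (dz sum_j alpha_j L_nrd,j**lam),
    converted to 1/s.  All-stressed profiles (denominator zero) yield a
    zero sink flagged ``fully_stressed`` rather than an error.
    """
    if L <= 0:
        raise ValueError("root depth L must be positive")
    w, inroot = _wu_weights(grid, L, cfg)
    lnrd = w / grid.dz  # density values at block centres (zero outside roots)
    if not np.any(lnrd > 0.0):
        raise NoRootError("all root-density weights are zero")
    a = _alpha_profile(h, cfg.thresholds, Tp)
    num = np.zeros(grid.nz)
    pos = lnrd > 0.0
    num[pos] = a[pos] ** 2 * lnrd[pos] ** cfg.lam
    denom = float(np.sum(a[pos] * lnrd[pos] ** cfg.lam))
    if denom <= 0.0:
        return SinkProfile(np.zeros(grid.nz), 0.0, fully_stressed=True)
    S = num * Tp / (UNIT_FACTOR * grid.dz * denom)
    total = float(np.sum(S) * grid.dz * UNIT_FACTOR)
    return SinkProfile(S, total)


def compute_sink(h, grid, Tp: float, t: float, cfg: RootUptakeConfig) -> SinkProfile:
    """Dispatch on ICPS; refreshes h3 from Tp and the root depth from t.

    Returns an all-zero profile when Tp = 0 or when no block centre lies
    within the current root depth.
    """
    if cfg.icps not in (1, 2, 3):
        raise ValueError("icps must be in {1, 2, 3}")
    if Tp <= 0.0:
        return SinkProfile(np.zeros(grid.nz), 0.0)
    L = root_depth(t, cfg, z_max=grid.z_max)
    if not np.any(grid.z_centers <= L):
        return SinkProfile(np.zeros(grid.nz), 0.0)
    if cfg.icps == 1:
        return sink_prasad(h, grid, Tp, L, cfg)
    if cfg.icps == 2:
        return sink_li_yadav(h, grid, Tp, L, cfg)
    return sink_wu(h, grid, Tp, L, cfg)
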