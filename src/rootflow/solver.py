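"""Implicit block-centered finite-difference solver for 1-D variably
saturated flow with a root-uptake sink.

The vertical axis is positive downward with the surface at z = 0.  The
profile is divided into ``nz`` blocks of thickness ``dz``; pressure head and
water content live at block centres ``z_i = (i - 1/2) dz`` while
conductivities and Darcy fluxes live at block edges (interfaces).

One time step follows a non-iterative flux-update scheme:

1.  Assemble the tridiagonal system with conductivities and capacities
    evaluated at the *old* time.  Under a flux upper boundary the surface
    flux is withheld from this pass.  Solve by the Thomas algorithm for the
    trial heads ``h*``.
2.  Evaluate conductivities anew at ``h*``, form interface Darcy fluxes
    (re-introducing the withheld surface flux), and update water content
    from the divergence of those fluxes plus the sink (exact mass balance).
3.  Accept the trial water content of a block only if the block and its
    immediate neighbours remain unsaturated, in which case the new head
    comes from the retention curve; otherwise keep ``h*`` as the head and
    recompute the water content from the retention curve at ``h*``.

The lower boundary is a unit hydraulic gradient (gravity drainage,
bottom flux equal to the bottom block's conductivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hydraulics import ProfileProperties

__all__ = [
    "Grid",
    "State",
    "BoundaryCondition",
    "TridiagonalSystem",
    "FluxProfile",
    "SolverError",
    "SingularSystemError",
    "internode_conductivity",
    "interface_conductivities",
    "assemble_system",
    "thomas_solve",
    "interface_fluxes",
    "mass_balance_update",
    "flux_update_step",
    "StepResult",
]

#: float-safe saturation test: theta >= theta_s - SAT_EPS counts as saturated
SAT_EPS = 1e-9
#: trial water contents below theta_r + DRY_EPS are treated as overdrawn
DRY_EPS = 1e-7
#: capacity floor (1/m): a tiny specific-storage term that keeps the
#: implicit matrix non-singular when a whole region saturates (c -> 0)
C_MIN = 1e-8


class SolverError(RuntimeError):
    """Numerical failure inside a time step."""


class SingularSystemError(SolverError):
    """Zero pivot during the Thomas elimination."""


@dataclass(frozen=True)
class Grid:
    """Uniform block-centered vertical grid."""

    nz: int
    dz: float

    def __post_init__(self):
        if self.nz < 3:
            raise ValueError("need at least 3 blocks")
        if self.dz <= 0:
            raise ValueError("dz must be positive")

    @property
    def z_max(self) -> float:
        return self.nz * self.dz

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz


@dataclass
class State:
    """Profile state at one instant: time (s), heads (m), water contents."""

    t: float
    h: np.ndarray
    theta: np.ndarray

    def copy(self) -> "State":
        return State(self.t, self.h.copy(), self.theta.copy())


@dataclass(frozen=True)
class BoundaryCondition:
    """Upper boundary: prescribed surface flux (m/s, positive downward) or
    prescribed surface head (m).  The lower boundary is always a unit
    hydraulic gradient."""

    upper: str  # "flux" | "head"
    surface_flux: float = 0.0
    surface_head: float = 0.0

    def __post_init__(self):
        if self.upper not in ("flux", "head"):
            raise ValueError("upper boundary must be 'flux' or 'head'")

    @classmethod
    def flux(cls, j0: float) -> "BoundaryCondition":
        return cls("flux", surface_flux=float(j0))

    @classmethod
    def head(cls, h0: float) -> "BoundaryCondition":
        return cls("head", surface_head=float(h0))


@dataclass
class TridiagonalSystem:
    """A h[i-1] + B h[i] + C h[i+1] = D with A[0] = C[-1] = 0."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def dense(self) -> np.ndarray:
        n = self.B.size
        M = np.zeros((n, n))
        M[np.arange(n), np.arange(n)] = self.B
        M[np.arange(1, n), np.arange(n - 1)] = self.A[1:]
        M[np.arange(n - 1), np.arange(1, n)] = self.C[:-1]
        return M


@dataclass
class FluxProfile:
    """Interface Darcy fluxes, length nz + 1, positive downward.
    ``J[0]`` is the surface flux, ``J[nz]`` the bottom drainage flux."""

    J: np.ndarray


def internode_conductivity(k_upper, k_lower, method: str = "arithmetic"):
    """Conductivity at the interface between two adjacent blocks."""
    if method == "arithmetic":
        return 0.5 * (np.asarray(k_upper, float) + np.asarray(k_lower, float))
    if method == "geometric":
        return np.sqrt(np.asarray(k_upper, float) * np.asarray(k_lower, float))
    raise ValueError(f"unknown internode averaging '{method}'")


def interface_conductivities(
    K_blocks: np.ndarray,
    bc: BoundaryCondition,
    surface_K: float | None = None,
    method: str = "arithmetic",
) -> np.ndarray:
    """Interface conductivity array of length nz + 1.

    Internal interfaces average the two adjacent block values.  The bottom
    interface carries the bottom block's conductivity (unit-gradient
    boundary).  Under a head upper boundary the surface interface averages
    the block value with the conductivity at the prescribed surface head;
    under a flux boundary it simply carries the top block's value (it does
    not enter the matrix there).
    """
    nz = K_blocks.size
    Kh = np.empty(nz + 1)
    Kh[1:nz] = internode_conductivity(K_blocks[:-1], K_blocks[1:], method)
    Kh[nz] = K_blocks[-1]
    if bc.upper == "head":
        if surface_K is None:
            raise ValueError("surface conductivity required for a head boundary")
        Kh[0] = internode_conductivity(surface_K, K_blocks[0], method)
    else:
        Kh[0] = K_blocks[0]
    return Kh


def assemble_system(
    h: np.ndarray,
    c: np.ndarray,
    K_half: np.ndarray,
    sink: np.ndarray,
    dt: float,
    grid: Grid,
    bc: BoundaryCondition,
) -> TridiagonalSystem:
    """Assemble the implicit system with old-time conductivities/capacities.

    ``K_half`` has length nz + 1 (see :func:`interface_conductivities`);
    ``sink`` is the old-time uptake rate per block (1/s).  Under a flux
    upper boundary the surface flux is withheld here (it is applied in the
    mass-balance update of the flux-update scheme).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nz, dz = grid.nz, grid.dz
    if sink.shape != (nz,):
        raise ValueError(f"sink length {sink.shape} != nz {nz}")
    Km = K_half[:nz]       # K_{i-1/2}
    Kp = K_half[1:nz + 1]  # K_{i+1/2}; Kp[-1] is the bottom-block K
    dz2 = dz * dz

    A = -Km / dz2
    C = -Kp / dz2
    B = c / dt + (Km + Kp) / dz2
    D = c * h / dt - (Kp - Km) / dz - sink

    # upper node
    A[0] = 0.0
    if bc.upper == "flux":
        # surface flux withheld: no K_{1/2} coupling, no J(0,t) in D
        B[0] = c[0] / dt + Kp[0] / dz2
        D[0] = c[0] * h[0] / dt + Kp[0] / dz - sink[0]
    else:
        B[0] = c[0] / dt + (Kp[0] + Km[0]) / dz2
        D[0] = (
            c[0] * h[0] / dt
            - (Kp[0] - Km[0]) / dz
            + Km[0] * bc.surface_head / dz2
            - sink[0]
        )

    # lower node: unit-gradient drainage, flux = K_nz independent of h*
    C[-1] = 0.0
    B[-1] = c[-1] / dt + Km[-1] / dz2
    D[-1] = c[-1] * h[-1] / dt - (Kp[-1] - Km[-1]) / dz - sink[-1]

    return TridiagonalSystem(A, B, C, D)


def thomas_solve(sys: TridiagonalSystem) -> np.ndarray:
    """Solve the tridiagonal system by forward elimination / back substitution."""
    a = sys.A.tolist()
    b = sys.B.tolist()
    c = sys.C.tolist()
    d = sys.D.tolist()
    n = len(b)
    cp = [0.0] * n
    dp = [0.0] * n
    beta = b[0]
    if beta == 0.0:
        raise SingularSystemError("zero pivot at row 0")
    cp[0] = c[0] / beta
    dp[0] = d[0] / beta
    for i in range(1, n):
        beta = b[i] - a[i] * cp[i - 1]
        if beta == 0.0:
            raise SingularSystemError(f"zero pivot at row {i}")
        cp[i] = c[i] / beta
        dp[i] = (d[i] - a[i] * dp[i - 1]) / beta
    x = [0.0] * n
    x[-1] = dp[-1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return np.array(x)


def interface_fluxes(
    h_star: np.ndarray,
    grid: Grid,
    K_half: np.ndarray,
    bc: BoundaryCondition,
) -> FluxProfile:
    """Darcy fluxes at the nz + 1 interfaces, positive downward.

    Internal: ``J = -K (h[i+1] - h[i]) / dz + K`` (pressure gradient plus
    gravity with z positive downward).  Bottom: ``J = K`` (unit gradient).
    Top: the applied surface flux under a flux boundary, or the Darcy flux
    from the prescribed surface head across a full dz spacing.
    """
    nz, dz = grid.nz, grid.dz
    J = np.empty(nz + 1)
    Ki = K_half[1:nz]
    J[1:nz] = -Ki * (h_star[1:] - h_star[:-1]) / dz + Ki
    J[nz] = K_half[nz]
    if bc.upper == "flux":
        J[0] = bc.surface_flux
    else:
        J[0] = -K_half[0] * (h_star[0] - bc.surface_head) / dz + K_half[0]
    return FluxProfile(J)


def mass_balance_update(
    theta: np.ndarray,
    fluxes: FluxProfile,
    sink: np.ndarray,
    dt: float,
    grid: Grid,
) -> np.ndarray:
    """theta* = theta - dt (J[i+1/2] - J[i-1/2]) / dz - dt S  (exact budget)."""
    J = fluxes.J
    return theta - dt * (J[1:] - J[:-1]) / grid.dz - dt * sink


@dataclass
class StepResult:
    state: State
    fluxes: FluxProfile
    n_rejected: int


def flux_update_step(
    state: State,
    grid: Grid,
    props: ProfileProperties,
    bc: BoundaryCondition,
    sink: np.ndarray,
    dt: float,
    kmean: str = "arithmetic",
) -> StepResult:
    """Advance the profile one time step of length ``dt`` seconds."""
    h_old = state.h
    theta_old = state.theta

    c = np.maximum(props.capacity(h_old), C_MIN)
    K_old = props.K_of_theta(theta_old, validate=False)
    surf_mat = props.surface_material
    surf_K_old = surf_mat.K_of_h(bc.surface_head) if bc.upper == "head" else None
    K_half = interface_conductivities(K_old, bc, surf_K_old, kmean)

    sys = assemble_system(h_old, c, K_half, sink, dt, grid, bc)
    h_star = thomas_solve(sys)
    if not np.all(np.isfinite(h_star)):
        raise SolverError("non-finite trial heads")

    # conductivities re-evaluated at the trial heads
    theta_ret = props.theta_of_h(h_star)
    K_new = props.K_of_theta(theta_ret, validate=False)
    surf_K_new = surf_mat.K_of_h(bc.surface_head) if bc.upper == "head" else None
    K_half_new = interface_conductivities(K_new, bc, surf_K_new, kmean)

    fluxes = interface_fluxes(h_star, grid, K_half_new, bc)
    theta_trial = mass_balance_update(theta_old, fluxes, sink, dt, grid)
    if not np.all(np.isfinite(theta_trial)):
        raise SolverError("non-finite trial water contents")

    sat = theta_trial >= props.theta_s - SAT_EPS
    nb_sat = sat.copy()
    nb_sat[:-1] |= sat[1:]   # lower neighbour
    nb_sat[1:] |= sat[:-1]   # upper neighbour
    if bc.upper == "head" and bc.surface_head >= 0.0:
        nb_sat[0] = True     # ponded surface counts as a saturated neighbour
    overdraw = theta_trial <= props.theta_r + DRY_EPS
    reject = nb_sat | overdraw

    theta_new = np.where(reject, theta_ret, theta_trial)
    h_new = np.empty_like(h_star)
    accept = ~reject
    if np.any(accept):
        clipped = np.clip(theta_trial, props.theta_r + DRY_EPS, props.theta_s)
        h_from_theta = props.h_of_theta(clipped, validate=False)
        h_new[accept] = h_from_theta[accept]
    h_new[reject] = h_star[reject]

    if np.any(theta_new > props.theta_s + 1e-12) or not np.all(np.isfinite(h_new)):
        raise SolverError("unphysical state after update")

    return StepResult(
        state=State(state.t + dt, h_new, theta_new),
        fluxes=fluxes,
        n_rejected=int(np.count_nonzero(reject)),
    )
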