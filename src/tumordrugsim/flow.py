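"""Steady coupled vascular-interstitial flow.

The vessel is modelled as Poiseuille flow with distributed leakage
(quasi-1D): the lumen Reynolds number is O(1) and the radius-to-length
ratio is 0.01, so inertia and radial pressure variation are negligible
and the axial momentum balance reduces to

    Q(z) = -(pi R_C^4 / 8 mu) dP_v/dz,      dQ/dz = -2 pi R_C J_F(z),

with Dirichlet pressures P_A and P_V at the ends.  The interstitium is a
Darcy medium, div(K grad P_i) = 0, with the Starling filtration velocity
J_F = L_p (P_v - P_i) as a Neumann flux on the vessel wall and the
ambient pressure P_0 on all other boundaries.  The two problems are
coupled through J_F and solved by under-relaxed fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .grid import Grid
from .params import InternalParameters


class FlowSolverError(RuntimeError):
    """Flow fixed point failed to converge or produced unphysical flow."""


@dataclass(frozen=True)
class FlowField:
    """Converged steady flow solution on a :class:`Grid`.

    ``u_r``/``u_z`` are face-normal Darcy velocities, positive in +r/+z;
    ``u_r[0, :]`` equals the filtration velocity J_F.
    """

    P_v: np.ndarray        # (nz,) Pa, lumen cross-section average
    Q_faces: np.ndarray    # (nz+1,) m^3/s, lumen volumetric flow at z faces
    u_v_mean: np.ndarray   # (nz,) m/s, cross-section mean axial velocity
    J_F: np.ndarray        # (nz,) m/s, transmural filtration, + = outward
    P_i: np.ndarray        # (nr, nz) Pa, interstitial pressure
    u_r: np.ndarray        # (nr+1, nz) m/s, radial face velocities
    u_z: np.ndarray        # (nr, nz+1) m/s, axial face velocities
    iterations: int
    residual: float


def starling_flux(P_v_local, P_i_local, L_p: float):
    """Filtration velocity L_p (P_v - P_i); positive = lumen -> tissue.

    The osmotic term of the full Starling relation is dropped: the
    oncotic pressure difference across leaky tumour vessels is
    negligible, so the reflection coefficient never enters the water
    balance here.
    """
    return L_p * (np.asarray(P_v_local) - np.asarray(P_i_local))


def peclet(length: float, speed: float, diffusivity: float) -> float:
    """Peclet number L*u/D, the convection-to-diffusion transport ratio."""
    if diffusivity <= 0:
        raise ValueError(f"diffusivity must be > 0, got {diffusivity}")
    return length * speed / diffusivity


def _lumen_conductances(grid: Grid, ip: InternalParameters):
    """Poiseuille conductances g = pi R_C^4 / (8 mu dz) at z faces."""
    g = np.pi * ip.R_C ** 4 / (8.0 * ip.mu)
    dz = grid.dz
    cond = np.full(grid.nz + 1, g / dz)
    cond[0] = g / (0.5 * dz)   # half-cell to the Dirichlet inlet
    cond[-1] = g / (0.5 * dz)  # half-cell to the Dirichlet outlet
    return cond


def solve_vessel_pressure(grid: Grid, ip: InternalParameters,
                          J_F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-point BVP for P_v given the leakage profile.

    Finite-volume form: net Poiseuille inflow of each lumen cell equals
    its wall leakage, so the discrete water balance Q(0) - Q(L) =
    sum(J_F * wall area) holds exactly.  Returns (P_v, Q_faces).
    """
    nz = grid.nz
    cond = _lumen_conductances(grid, ip)
    leak = J_F * grid.wall_area  # m^3/s out of each cell
    diag = cond[:-1] + cond[1:]
    lower = -cond[1:-1]
    ab = np.zeros((3, nz))
    ab[0, 1:] = lower
    ab[1, :] = diag
    ab[2, :-1] = lower
    rhs = -leak
    rhs[0] += cond[0] * ip.P_A
    rhs[-1] += cond[-1] * ip.P_V
    from scipy.linalg import solve_banded

    P_v = solve_banded((1, 1), ab, rhs)
    Q = np.empty(nz + 1)
    Q[0] = cond[0] * (ip.P_A - P_v[0])
    Q[1:-1] = cond[1:-1] * (P_v[:-1] - P_v[1:])
    Q[-1] = cond[-1] * (P_v[-1] - ip.P_V)
    return P_v, Q


def _build_darcy_matrix(grid: Grid, ip: InternalParameters,
                        end_bc: str) -> tuple[sp.csc_matrix, np.ndarray]:
    """Assemble div(K grad P) = 0; returns (matrix, Dirichlet RHS part).

    Wall faces carry the Neumann flux (added to the RHS by the caller);
    the outer radius and - unless ``end_bc == 'noflux'`` - both end
    annuli are Dirichlet P_0 via half-cell transmissibilities.
    """
    nr, nz = grid.nr, grid.nz
    n = nr * nz
    K = ip.K
    idx = np.arange(n).reshape(nr, nz)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b0 = np.zeros(n)

    def add(i, j, t):
        rows.append(i)
        cols.append(j)
        vals.append(-t)

    # radial interior faces
    dr_c = grid.r_centers[1:] - grid.r_centers[:-1]          # (nr-1,)
    for ir in range(1, nr):
        T = K * grid.area_r[ir, :] / dr_c[ir - 1]            # (nz,)
        a, bidx = idx[ir - 1, :], idx[ir, :]
        for z in range(nz):
            add(a[z], bidx[z], T[z])
            add(bidx[z], a[z], T[z])
        diag[a] += T
        diag[bidx] += T
    # outer radius: Dirichlet P_0
    T_out = K * grid.area_r[nr, :] / (grid.r_faces[-1] - grid.r_centers[-1])
    diag[idx[nr - 1, :]] += T_out
    b0[idx[nr - 1, :]] += T_out * ip.P_0
    # axial interior faces
    T_z = K * grid.area_z / grid.dz                          # (nr,)
    for iz in range(1, nz):
        a, bidx = idx[:, iz - 1], idx[:, iz]
        for r in range(nr):
            add(a[r], bidx[r], T_z[r])
            add(bidx[r], a[r], T_z[r])
        diag[a] += T_z
        diag[bidx] += T_z
    # end annuli
    if end_bc == "dirichlet":
        T_end = K * grid.area_z / (0.5 * grid.dz)
        for iz, col in ((0, idx[:, 0]), (nz - 1, idx[:, -1])):
            diag[col] += T_end
            b0[col] += T_end * ip.P_0
    elif end_bc != "noflux":
        raise ValueError(f"end_bc must be 'dirichlet' or 'noflux', got {end_bc!r}")

    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return A, b0


def solve_interstitial_pressure(grid: Grid, ip: InternalParameters,
                                J_F: np.ndarray,
                                end_bc: str = "dirichlet",
                                _cache: dict | None = None) -> np.ndarray:
    """Darcy pressure field with prescribed wall influx J_F (m/s)."""
    if _cache is not None and "lu" in _cache:
        lu, b0 = _cache["lu"], _cache["b0"]
    else:
        A, b0 = _build_darcy_matrix(grid, ip, end_bc)
        lu = splu(A)
        if _cache is not None:
            _cache["lu"], _cache["b0"] = lu, b0
    b = b0.copy()
    b[: grid.nz] += J_F * grid.wall_area  # wall-adjacent cells are ir = 0
    return lu.solve(b).reshape(grid.nr, grid.nz)


def darcy_velocity(P_i: np.ndarray, K: float, grid: Grid,
                   J_F: np.ndarray | None = None, P_0: float = 0.0,
                   end_bc: str = "dirichlet") -> tuple[np.ndarray, np.ndarray]:
    """Face-normal Darcy velocities u = -K grad P from a pressure field.

    Returns ``(u_r, u_z)`` with shapes (nr+1, nz) and (nr, nz+1).  The
    wall face takes the prescribed J_F (zero if not given); Dirichlet
    edges use half-cell gradients to the ambient pressure.
    """
    nr, nz = grid.nr, grid.nz
    u_r = np.zeros((nr + 1, nz))
    if J_F is not None:
        u_r[0, :] = J_F
    dr_c = (grid.r_centers[1:] - grid.r_centers[:-1])[:, None]
    u_r[1:nr, :] = -K * (P_i[1:, :] - P_i[:-1, :]) / dr_c
    u_r[nr, :] = -K * (P_0 - P_i[-1, :]) / (grid.r_faces[-1] - grid.r_centers[-1])
    u_z = np.zeros((nr, nz + 1))
    u_z[:, 1:nz] = -K * (P_i[:, 1:] - P_i[:, :-1]) / grid.dz
    if end_bc == "dirichlet":
        half = 0.5 * grid.dz
        u_z[:, 0] = -K * (P_i[:, 0] - P_0) / half
        u_z[:, nz] = -K * (P_0 - P_i[:, -1]) / half
    return u_r, u_z


def solve_flow(grid: Grid, ip: InternalParameters, tol: float = 1e-8,
               max_iter: int = 200, relax: float = 0.5,
               end_bc: str = "dirichlet") -> FlowField:
    """Fixed point of the vessel-interstitium water coupling.

    Starting from the uncoupled Starling estimate, alternately solves
    the lumen BVP and the Darcy problem, updating J_F = L_p (P_v - P_i)
    at the wall faces with under-relaxation ``relax`` until the maximum
    relative change in J_F drops below ``tol``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    cache: dict = {}
    # initial guess: linear lumen pressure against ambient tissue
    P_lin = ip.P_A + (ip.P_V - ip.P_A) * grid.z_centers / ip.L
    J_F = starling_flux(P_lin, ip.P_0, ip.L_p)
    # distance from wall face to the first cell center, for the
    # consistent face-pressure extrapolation P_face = P_c + J_F d / K
    d_wall = grid.r_centers[0] - grid.R_C
    residual = np.inf
    P_v = P_lin
    P_i = np.full((grid.nr, grid.nz), ip.P_0)
    for it in range(1, max_iter + 1):
        P_v, Q = solve_vessel_pressure(grid, ip, J_F)
        P_i = solve_interstitial_pressure(grid, ip, J_F, end_bc, cache)
        # J_F consistent with the extrapolated wall-face pressure:
        # J = L_p (P_v - P_i0 - J d / K)  =>  closed form below
        J_new = ip.L_p * (P_v - P_i[0, :]) / (1.0 + ip.L_p * d_wall / ip.K)
        scale = max(np.abs(J_new).max(), 1e-300)
        residual = float(np.abs(J_new - J_F).max() / scale)
        J_F = relax * J_new + (1.0 - relax) * J_F
        if residual < tol:
            break
    else:
        raise FlowSolverError(
            f"flow coupling did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )
    P_v, Q = solve_vessel_pressure(grid, ip, J_F)
    if np.any(Q < 0):
        raise FlowSolverError(
            "negative lumen flow encountered: the leakage exceeds the "
            "perfusion this reduced vessel model can represent"
        )
    u_v_mean = 0.5 * (Q[:-1] + Q[1:]) / grid.lumen_area
    u_r, u_z = darcy_velocity(P_i, ip.K, grid, J_F=J_F, P_0=ip.P_0,
                              end_bc=end_bc)
    return FlowField(
        P_v=P_v, Q_faces=Q, u_v_mean=u_v_mean, J_F=J_F, P_i=P_i,
        u_r=u_r, u_z=u_z, iterations=it, residual=residual,
    )
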