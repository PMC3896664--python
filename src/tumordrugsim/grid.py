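"""Axisymmetric (r, z) finite-volume grid.

The domain is a Krogh cylinder: a straight vessel of radius R_C running
along the axis of a coaxial interstitial annulus R_C <= r <= R_T,
0 <= z <= L.  The vessel lumen is represented by its axial line of
cross-section averages (one 1D cell per z slab); the interstitium is a
2D cell-centered grid, geometrically clustered toward the vessel wall
where the steep drug boundary layer lives.  Coordinates are dimensional
(metres); all transported fields are stored normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InternalParameters


@dataclass(frozen=True)
class Grid:
    """Cell-centered axisymmetric grid.

    Interstitial arrays are indexed ``[ir, iz]`` with ``ir = 0`` adjacent
    to the vessel wall.  Radial faces are shared cylinder surfaces of
    area ``2 pi r_face dz``; axial faces are annuli of area
    ``pi (r_out^2 - r_in^2)``.
    """

    r_faces: np.ndarray      # (nr+1,) m, r_faces[0] = R_C, r_faces[-1] = R_T
    r_centers: np.ndarray    # (nr,) m
    z_faces: np.ndarray      # (nz+1,) m
    z_centers: np.ndarray    # (nz,) m
    cell_volumes: np.ndarray  # (nr, nz) m^3, 2*pi*r*dr*dz annular slabs
    area_r: np.ndarray       # (nr+1, nz) m^2, radial (cylindrical) faces
    area_z: np.ndarray       # (nr,) m^2, axial (annular) faces, z-independent
    lumen_volume: np.ndarray  # (nz,) m^3, pi*R_C^2*dz
    lumen_area: float        # m^2, pi*R_C^2 cross-section
    R_C: float
    R_T: float
    L: float

    @property
    def nr(self) -> int:
        return self.r_centers.size

    @property
    def nz(self) -> int:
        return self.z_centers.size

    @property
    def dz(self) -> float:
        return float(self.z_faces[1] - self.z_faces[0])

    @property
    def wall_area(self) -> np.ndarray:
        """Vessel-wall face area per z slab, 2*pi*R_C*dz (m^2)."""
        return self.area_r[0, :]

    def echo(self) -> str:
        """Text table of radial centers and per-slab volumes (debugging)."""
        lines = ["ir      r_center_m        dr_m         volume_m3"]
        dr = np.diff(self.r_faces)
        for i in range(self.nr):
            lines.append(
                f"{i:<4d} {self.r_centers[i]:.8e} {dr[i]:.6e} "
                f"{self.cell_volumes[i, 0]:.6e}"
            )
        lines.append(f"nz = {self.nz}, dz = {self.dz:.6e} m")
        return "\n".join(lines)


def _clustered_faces(r0: float, r1: float, n: int, refinement: float) -> np.ndarray:
    """Faces of n cells on [r0, r1], widths in geometric progression.

    ``refinement`` is the ratio of the largest (outer) to the smallest
    (wall-adjacent) cell width; 1 gives a uniform grid.
    """
    if refinement == 1.0:
        return np.linspace(r0, r1, n + 1)
    g = refinement ** (1.0 / (n - 1))
    widths = g ** np.arange(n)
    widths *= (r1 - r0) / widths.sum()
    faces = np.empty(n + 1)
    faces[0] = r0
    np.cumsum(widths, out=faces[1:])
    faces[1:] += r0
    faces[-1] = r1  # kill accumulation roundoff
    return faces


def build_grid(ip: InternalParameters, nr_i: int, nz: int,
               refinement: float = 1.0) -> Grid:
    """Build the interstitial annulus grid plus the 1D lumen line.

    Parameters
    ----------
    nr_i, nz : radial / axial cell counts (each >= 2; defaults in the
        driver are 240 x 100).
    refinement : wall-clustering factor, ratio of outermost to innermost
        radial cell width (>= 1).
    """
    if nr_i < 2 or nz < 2:
        raise ValueError(f"need nr_i >= 2 and nz >= 2, got {nr_i}, {nz}")
    if refinement < 1.0:
        raise ValueError(f"refinement must be >= 1, got {refinement}")
    r_faces = _clustered_faces(ip.R_C, ip.R_T, nr_i, refinement)
    z_faces = np.linspace(0.0, ip.L, nz + 1)
    r_centers = 0.5 * (r_faces[:-1] + r_faces[1:])
    z_centers = 0.5 * (z_faces[:-1] + z_faces[1:])
    dz = z_faces[1] - z_faces[0]
    ring = np.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)  # (nr,)
    volumes = np.repeat(ring[:, None] * dz, nz, axis=1)
    area_r = np.repeat((2.0 * np.pi * r_faces * dz)[:, None], nz, axis=1)
    lumen_volume = np.full(nz, np.pi * ip.R_C ** 2 * dz)
    return Grid(
        r_faces=r_faces,
        r_centers=r_centers,
        z_faces=z_faces,
        z_centers=z_centers,
        cell_volumes=volumes,
        area_r=area_r,
        area_z=ring,
        lumen_volume=lumen_volume,
        lumen_area=float(np.pi * ip.R_C ** 2),
        R_C=ip.R_C,
        R_T=ip.R_T,
        L=ip.L,
    )
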