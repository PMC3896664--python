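"""Coarse-grained apoptosis signalling and tumour cell density dynamics.

Two interchangeable switch modules map the intracellular drug level c_I
onto a normalized intermediate species R in [0, 1]:

* **bistable**: a Goldbeter-Koshland-style module with drug-modulated
  positive feedback,
  dR/dt = Vf (1-R)/(Km1 + 1-R) + (p + q c_I) kfb R (1-R) - Vr R/(Km2 + R).
  For low input it has two stable states separated by an unstable one;
  past a saddle-node input level the low state vanishes and R commits
  irreversibly to the high branch.
* **monostable**: a Hill-response relaxation,
  dR/dt = k (c_I^n/(kh + c_I^n) - R), with a single steady state for
  every input; irreversibility is supplied downstream by a permanent
  latch on the trigger.

Downstream, R1 integrates R through
dR1/dt = kf R (1 - R1) - kr R1 and apoptosis is triggered where R1
crosses its threshold.  At the population level the trigger is a hard
gate on the logistic growth rate: dc_t/dt = a1_eff c_t - a2 c_t - b c_t^2
with a1_eff = 0 in triggered cells (re-evaluated every step for the
bistable switch, latched permanently for the monostable one).

All rhs functions take their rate constants from whatever parameter
object is passed (attribute names Vf, Vr, ..., a2, b), so time units
follow that object: tabulated (per hour / per day) for
:class:`~tumordrugsim.params.ModelParameters`, per second for
:class:`~tumordrugsim.params.InternalParameters`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InternalParameters


@dataclass
class CellState:
    """Per-cell signalling state and density.

    ``c_t`` is in 10^5 cells/mm^3 (initial value 10 at the tabulated
    10^6 cells/mm^3); ``triggered`` is the permanent monostable latch.
    """

    R: np.ndarray
    R1: np.ndarray
    triggered: np.ndarray  # bool
    c_t: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.R.copy(), self.R1.copy(),
                         self.triggered.copy(), self.c_t.copy())

    @classmethod
    def uniform(cls, shape: tuple[int, ...], c_t0: float) -> "CellState":
        return cls(
            R=np.zeros(shape),
            R1=np.zeros(shape),
            triggered=np.zeros(shape, dtype=bool),
            c_t=np.full(shape, float(c_t0)),
        )


def bistable_rhs(R, c_I, p):
    """dR/dt of the bistable switch (time unit follows ``p``)."""
    R = np.asarray(R, dtype=float)
    c_I = np.asarray(c_I, dtype=float)
    return (p.Vf * (1.0 - R) / (p.Km1 + 1.0 - R)
            + (p.p + p.q * c_I) * p.kfb * R * (1.0 - R)
            - p.Vr * R / (p.Km2 + R))


def _hill(c_I, p):
    cn = np.asarray(c_I, dtype=float) ** p.n_hill
    if p.hill_denominator == "homogeneous":
        return cn / (p.kh ** p.n_hill + cn)
    return cn / (p.kh + cn)


def monostable_rhs(R, c_I, p):
    """dR/dt of the monostable Hill switch (time unit follows ``p``)."""
    return p.k_mono * (_hill(c_I, p) - np.asarray(R, dtype=float))


def monostable_fixed_point(c_I, p):
    """Closed-form steady state R* = c_I^n / (kh + c_I^n)."""
    return _hill(c_I, p)


def r1_rhs(R1, R, p):
    """dR1/dt = kf R (1 - R1) - kr R1: activation by upstream R,
    saturating in R1, with first-order degradation."""
    R1 = np.asarray(R1, dtype=float)
    return p.kf * np.asarray(R, dtype=float) * (1.0 - R1) - p.kr * R1


def r1_fixed_point(R, p):
    """Steady R1 under sustained upstream R: kf R / (kf R + kr)."""
    return p.kf * R / (p.kf * R + p.kr)


def logistic_rhs(c_t, a1_eff, p):
    """dc_t/dt = a1_eff c_t - a2 c_t - b c_t^2 (units follow ``p``)."""
    c_t = np.asarray(c_t, dtype=float)
    return (a1_eff - p.a2) * c_t - p.b * c_t ** 2


def bistable_steady_states(c_I: float, p, scan_resolution: float = 1e-4
                           ) -> list[tuple[float, bool]]:
    """All roots of the bistable rhs in [0, 1] with stability labels.

    Sign-change scan at ``scan_resolution`` followed by bisection to
    1e-10; a root is stable iff d(rhs)/dR < 0 there.  Raises if the scan
    cannot cleanly separate roots (refine the resolution).
    """
    if c_I < 0:
        raise ValueError(f"c_I must be >= 0, got {c_I}")
    n = int(np.ceil(1.0 / scan_resolution)) + 1
    grid = np.linspace(0.0, 1.0, n)
    vals = bistable_rhs(grid, c_I, p)
    exact = np.flatnonzero(vals == 0.0)
    sign = np.sign(vals)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    roots = [float(grid[i]) for i in exact]
    for i in flips:
        lo, hi = float(grid[i]), float(grid[i + 1])
        flo = float(vals[i])
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fm = float(bistable_rhs(mid, c_I, p))
            if fm == 0.0 or hi - lo < 1e-10:
                break
            if flo * fm < 0:
                hi = mid
            else:
                lo, flo = mid, fm
        roots.append(0.5 * (lo + hi))
    roots = sorted(roots)
    for a, b in zip(roots, roots[1:]):
        if b - a < scan_resolution:
            raise ValueError(
                f"roots {a:.6g} and {b:.6g} closer than the scan "
                f"resolution {scan_resolution}; refine scan_resolution"
            )
    if len(roots) % 2 == 0:
        raise ValueError(
            f"even root count {len(roots)} indicates a near-tangency at "
            f"scan resolution {scan_resolution}; refine scan_resolution"
        )
    h = 1e-7
    out = []
    for r in roots:
        d = (float(bistable_rhs(min(r + h, 1.0), c_I, p))
             - float(bistable_rhs(max(r - h, 0.0), c_I, p))) / (2 * h)
        out.append((r, d < 0))
    return out


def switch_input_threshold(p, c_max: float = 1e3, rel_tol: float = 1e-6,
                           scan_resolution: float = 1e-4) -> float:
    """Saddle-node input level c_I* where the low stable branch vanishes.

    Located by bisection on the root count of the bistable rhs.  Raises
    if the input does not couple in (q = 0) or no bifurcation exists
    below ``c_max``.
    """
    if p.q == 0:
        raise ValueError("q = 0: the switch input is decoupled, no "
                         "bifurcation in c_I exists")
    roots0 = bistable_steady_states(0.0, p, scan_resolution)
    if len(roots0) != 3:
        raise ValueError("no bistability at c_I = 0 for these parameters")
    # the rhs is affine in c_I with a non-negative input coefficient
    # q kfb R (1-R), so the minimum of the rhs over the low-R basin is
    # non-decreasing in c_I: the low root disappears exactly where that
    # minimum crosses zero, and bisection on its sign is exact even at
    # the fold, where a root-count scan cannot separate the merging pair.
    r_high = roots0[2][0]
    R_scan = np.linspace(0.0, 0.9 * r_high, 20001)

    def low_basin_min(c):
        return float(bistable_rhs(R_scan, c, p).min())

    lo = 0.0
    if low_basin_min(lo) >= 0:
        raise ValueError("low steady state already absent at c_I = 0")
    hi = 1.0
    while low_basin_min(hi) < 0:
        hi *= 2.0
        if hi > c_max:
            raise ValueError(f"no saddle-node found below c_I = {c_max}")
    while (hi - lo) > rel_tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if low_basin_min(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def effective_growth(cell_state: CellState, mode: str, a1: float,
                     R1_th: float) -> np.ndarray:
    """Per-cell gated growth rate; updates the monostable latch in place.

    Bistable: the gate follows the instantaneous R1 (reversible at the
    population level).  Monostable: any first crossing of the threshold
    sets ``triggered`` permanently and the gate stays shut.
    """
    if mode == "bistable":
        return np.where(cell_state.R1 >= R1_th, 0.0, a1)
    if mode == "monostable":
        cell_state.triggered |= cell_state.R1 >= R1_th
        return np.where(cell_state.triggered, 0.0, a1)
    raise ValueError(f"unknown switch mode {mode!r}")


class LocalDynamics:
    """Vectorized integrator for the pointwise stiff stage.

    Advances (c_E, c_I, R, R1, c_t) in every interstitial cell over one
    global step with classical RK4 sub-steps.  The growth gate is frozen
    at the start of each sub-step (so the RK4 integrand stays smooth);
    the extracellular sink uses the live cell density, which is the
    bidirectional transport <-> kill coupling.
    """

    def __init__(self, ip: InternalParameters, cell_volumes: np.ndarray,
                 substep_s: float = 1.0, freeze_density: bool = False):
        self.ip = ip
        self.V = cell_volumes
        self.substep_s = substep_s
        # diagnostic switch: consume drug at the initial density even as
        # cells die, to isolate the feedback's contribution
        self.freeze_density = freeze_density

    def _rhs(self, c_E, c_I, R, R1, c_t, a1_eff):
        ip = self.ip
        uptake = ip.V1 * c_E / (c_E + ip.k1)
        efflux = ip.V2 * c_I / (c_I + ip.k2)
        net = uptake - efflux
        sink_density = np.full_like(c_t, ip.c_t0) if self.freeze_density else c_t
        d_cE = -sink_density * net
        d_cI = net
        if ip.switch_kind == "bistable":
            d_R = bistable_rhs(R, c_I, ip)
        else:
            d_R = monostable_rhs(R, c_I, ip)
        d_R1 = r1_rhs(R1, R, ip)
        d_ct = logistic_rhs(c_t, a1_eff, ip)
        return d_cE, d_cI, d_R, d_R1, d_ct

    def step(self, c_E: np.ndarray, c_I: np.ndarray, cells: CellState,
             dt: float) -> tuple[np.ndarray, np.ndarray, dict]:
        """One global step; mutates ``cells``; returns (c_E, c_I, info).

        info carries the stage's mass bookkeeping (normalized mass,
        m^3): drug moved into the intracellular pool, drug lost inside
        dying cells, and any negativity clips.
        """
        ip = self.ip
        n_sub = max(1, int(np.ceil(dt / self.substep_s)))
        h = dt / n_sub
        uptake_mass = 0.0
        dead_loss = 0.0
        clipped = 0.0
        cE0_mass = float((c_E * self.V).sum())
        for _ in range(n_sub):
            a1_eff = effective_growth(cells, ip.switch_kind, ip.a1, ip.R1_th)
            y = (c_E, c_I, cells.R, cells.R1, cells.c_t)
            k1 = self._rhs(*y, a1_eff)
            k2 = self._rhs(*(yi + 0.5 * h * ki for yi, ki in zip(y, k1)), a1_eff)
            k3 = self._rhs(*(yi + 0.5 * h * ki for yi, ki in zip(y, k2)), a1_eff)
            k4 = self._rhs(*(yi + h * ki for yi, ki in zip(y, k3)), a1_eff)
            new = [
                yi + (h / 6.0) * (a + 2 * b + 2 * c + d)
                for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
            ]
            # RK4 quadrature of the drug destroyed inside dying cells
            for w, k, ym in (
                (1.0, k1, y),
                (2.0, k2, tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k1))),
                (2.0, k3, tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k2))),
                (1.0, k4, tuple(yi + h * ki for yi, ki in zip(y, k3))),
            ):
                d_ct = k[4]
                c_I_stage = ym[1]
                # signed: cell death destroys intracellular drug, growth
                # creates it (per-cell concentration bookkeeping)
                dead_loss += (h / 6.0) * w * float(
                    (-(c_I_stage * d_ct) * self.V).sum()
                )
            c_E, c_I, R, R1, c_t = new
            neg = c_E < 0
            if np.any(neg):
                clipped += float(-(c_E[neg] * self.V[neg]).sum())
                c_E = np.where(neg, 0.0, c_E)
            c_I = np.maximum(c_I, 0.0)
            cells.R = np.clip(R, 0.0, 1.0)
            cells.R1 = np.clip(R1, 0.0, 1.0)
            cells.c_t = np.maximum(c_t, 0.0)
            if ip.switch_kind == "monostable":
                cells.triggered |= cells.R1 >= ip.R1_th
        uptake_mass = cE0_mass - float((c_E * self.V).sum()) + clipped
        return c_E, c_I, {
            "uptake": uptake_mass,
            "dead_loss": dead_loss,
            "clipped": clipped,
        }
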