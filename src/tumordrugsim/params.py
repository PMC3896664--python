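"""Parameter registry, unit handling and config parsing.

All model constants live in :class:`ModelParameters`, expressed in the
conventional units of the tumour-transport literature (micrometres, cm,
mmHg, hours, days, ng per 10^5 cells ...).  Before any numerics run they
are converted once into :class:`InternalParameters`, a coherent SI-based
system (m, s, Pa) in which concentrations are carried *normalized* by the
reference scales of :class:`ReferenceScales`:

* vascular / extracellular drug: 0.001 ug/mm^3  (= 1 ug/ml = 1 ng/mm^3)
* intracellular drug:            1 ng per 10^5 cells
* tumour cell density:           10^6 cells/mm^3

Cell density is carried internally in units of 10^5 cells/mm^3 (so the
initial density is 10) because the transmembrane rates V1/V2 and the
logistic saturation constant b are tabulated per 10^5 cells.  With these
scales the extracellular sink of the transport equation and the
intracellular uptake of the exchange equation share one rate constant,
which keeps the cross-compartment bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

MMHG_TO_PA = 133.322

#: config keys (flat, Table-style symbols) -> ModelParameters attribute
_CONFIG_KEYS = {
    "R_C_um": "R_C_um",
    "R_T_um": "R_T_um",
    "L_cm": "L_cm",
    "rho": "rho",
    "mu": "mu",
    "L_p": "L_p",
    "K_tissue": "K_tissue",
    "P_A": "P_A",
    "P_V": "P_V",
    "P_0": "P_0",
    "D_E": "D_E",
    "D_v": "D_v",
    "P_wall": "P_wall",
    "V1": "V1",
    "V2": "V2",
    "k1": "k1",
    "k2": "k2",
    "sigma_f": "sigma_f",
    "c_t0": "c_t0",
    "a1": "a1",
    "a2": "a2",
    "b": "b",
    "Vf": "Vf",
    "Vr": "Vr",
    "Km1": "Km1",
    "Km2": "Km2",
    "kfb": "kfb",
    "p": "p",
    "q": "q",
    "k_mono": "k_mono",
    "kh": "kh",
    "n_hill": "n_hill",
    "kf": "kf",
    "kr": "kr",
    "R1_th": "R1_th",
    "pulse_S": "pulse_S",
    "pulse_T_h": "pulse_T_h",
    "switch_kind": "switch_kind",
    "hill_denominator": "hill_denominator",
}

_NUMERICS_KEYS = {"nr_i", "nz", "dt_s", "t_end_h", "output_every_s",
                  "refinement", "ode_substep_s", "flow_tol", "death_frac"}


class ParameterError(ValueError):
    """A parameter failed validation; the message names the field."""


@dataclass(frozen=True)
class ReferenceScales:
    """Reference values used to nondimensionalize concentrations."""

    c_ref_vE: float = 0.001  # ug/mm^3, vascular & extracellular drug
    c_ref_I: float = 1.0     # ng/(10^5 cells), intracellular drug
    c_ref_t: float = 1.0e6   # cells/mm^3, tumour cell density


@dataclass(frozen=True)
class ModelParameters:
    """Every model constant, in its tabulated unit.

    Geometry / blood flow
    ---------------------
    R_C_um, R_T_um : vessel and interstitium outer radius (um)
    L_cm           : domain length (cm)
    rho, mu        : blood density (kg/m^3) and viscosity (Pa s)
    L_p            : vascular hydraulic conductivity (cm/(mmHg s))
    K_tissue       : tissue hydraulic conductivity (cm^2/(mmHg s))
    P_A, P_V, P_0  : inlet / outlet / ambient pressure (mmHg)

    Drug transport (doxorubicin)
    ----------------------------
    D_E, D_v : interstitial and vascular drug diffusivity (cm^2/s)
    P_wall   : diffusive wall permeability (cm/s)
    V1, V2   : max transmembrane rates (ng/(10^5 cells)/min)
    k1       : Michaelis constant, extracellular side (ug/ml)
    k2       : Michaelis constant, intracellular side (ng/(10^5 cells))
    sigma_f  : osmotic reflection coefficient for the solute (-)

    Cell density
    ------------
    c_t0   : initial cell density (cells/mm^3)
    a1, a2 : growth / natural decay rate (day^-1)
    b      : logistic saturation constant (mm^3/(10^5 cells)/day)

    Apoptosis signalling
    --------------------
    Vf, Vr, Km1, Km2 : bistable Michaelis-Menten constants (rates hr^-1)
    kfb, p, q        : feedback strength (hr^-1), basal level, input gain
    k_mono, kh, n_hill : monostable rate (hr^-1), Hill constant, exponent
    kf, kr           : R1 activation / degradation rate (hr^-1)
    R1_th            : apoptosis threshold on R1 (-)

    Stimulus
    --------
    pulse_S, pulse_T_h : inlet pulse intensity (normalized) and duration (h)
    switch_kind        : "bistable" | "monostable"
    hill_denominator   : "literal" (kh + c^n) | "homogeneous" (kh^n + c^n)
    """

    R_C_um: float = 100.0
    R_T_um: float = 1200.0
    L_cm: float = 1.0
    rho: float = 1000.0
    mu: float = 0.004
    # upper ends of the tabulated ranges: the transmural-velocity and
    # interstitial-Peclet magnitudes are only attained there.
    L_p: float = 2.8e-6
    K_tissue: float = 2.0e-7
    P_A: float = 15.0
    P_V: float = 0.0
    P_0: float = 0.0
    D_E: float = 1.5778e-6
    D_v: float = 1.5778e-6  # not tabulated; taken equal to D_E
    P_wall: float = 2.778e-4
    V1: float = 0.28
    V2: float = 0.28
    k1: float = 0.219
    k2: float = 1.37
    sigma_f: float = 0.0    # free convective filtration by default
    c_t0: float = 1.0e6
    a1: float = 0.5
    a2: float = 0.24
    b: float = 0.02592
    Vf: float = 27.0
    Vr: float = 0.459
    Km1: float = 100.0
    Km2: float = 0.01
    kfb: float = 2.927
    p: float = 0.7
    q: float = 0.3
    k_mono: float = 0.432
    kh: float = 1.0
    n_hill: float = 10.0
    kf: float = 3.6
    kr: float = 0.144
    R1_th: float = 0.9
    pulse_S: float = 1.0
    pulse_T_h: float = 1.5
    switch_kind: str = "bistable"
    hill_denominator: str = "literal"

    def __post_init__(self) -> None:
        validate(self)

    def with_overrides(self, **kwargs: Any) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Numerics:
    """Discretization controls (SI seconds; counts)."""

    nr_i: int = 240
    nz: int = 100
    dt_s: float = 10.0
    t_end_h: float = 10.0
    output_every_s: float = 1800.0
    refinement: float = 3.0      # wall-clustering ratio dr_max/dr_min
    ode_substep_s: float = 1.0   # local stiff-ODE sub-step
    flow_tol: float = 1.0e-8
    death_frac: float = 0.95     # c_t < frac*c_t0 counts as the death region


@dataclass(frozen=True)
class InternalParameters:
    """ModelParameters converted to one coherent system.

    Lengths m, time s, pressure Pa; drug concentrations normalized by
    :class:`ReferenceScales`; cell density in 10^5 cells/mm^3.
    """

    R_C: float
    R_T: float
    L: float
    rho: float
    mu: float
    L_p: float            # m/(Pa s)
    K: float              # m^2/(Pa s)
    P_A: float            # Pa
    P_V: float
    P_0: float
    D_E: float            # m^2/s
    D_v: float
    P_wall: float         # m/s
    V1: float             # normalized c_I / s
    V2: float
    k1: float             # normalized c_E
    k2: float             # normalized c_I
    sigma_f: float
    c_t0: float           # 10^5 cells/mm^3
    a1: float             # s^-1
    a2: float
    b: float              # per (10^5 cells/mm^3) per s
    Vf: float             # s^-1
    Vr: float
    Km1: float
    Km2: float
    kfb: float
    p: float
    q: float              # per normalized c_I
    k_mono: float
    kh: float
    n_hill: float
    kf: float
    kr: float
    R1_th: float
    pulse_S: float
    pulse_T: float        # s
    switch_kind: str
    hill_denominator: str
    scales: ReferenceScales = field(default_factory=ReferenceScales)


def validate(p: ModelParameters) -> None:
    """Raise :class:`ParameterError` naming the first offending field."""
    positive = [
        "R_C_um", "R_T_um", "L_cm", "rho", "mu", "L_p", "K_tissue",
        "D_E", "D_v", "P_wall", "V1", "V2", "k1", "k2", "c_t0",
        "a1", "a2", "b", "Vf", "Vr", "Km1", "Km2", "kfb",
        "k_mono", "kh", "kf", "kr", "pulse_T_h",
    ]
    for name in positive:
        if not getattr(p, name) > 0:
            raise ParameterError(f"{name} must be > 0, got {getattr(p, name)}")
    if p.pulse_S < 0:
        raise ParameterError(f"pulse_S must be >= 0, got {p.pulse_S}")
    if p.R_T_um <= p.R_C_um:
        raise ParameterError(
            f"R_T_um must exceed R_C_um, got R_T_um={p.R_T_um} <= R_C_um={p.R_C_um}"
        )
    if p.P_A <= p.P_V:
        raise ParameterError(f"P_A must exceed P_V, got P_A={p.P_A}, P_V={p.P_V}")
    if not 0.0 <= p.sigma_f <= 1.0:
        raise ParameterError(f"sigma_f must lie in [0, 1], got {p.sigma_f}")
    if not 0.0 < p.R1_th < 1.0:
        raise ParameterError(f"R1_th must lie in (0, 1), got {p.R1_th}")
    if p.n_hill < 1:
        raise ParameterError(f"n_hill must be >= 1, got {p.n_hill}")
    if p.switch_kind not in ("bistable", "monostable"):
        raise ParameterError(
            f"switch_kind must be 'bistable' or 'monostable', got {p.switch_kind!r}"
        )
    if p.hill_denominator not in ("literal", "homogeneous"):
        raise ParameterError(
            f"hill_denominator must be 'literal' or 'homogeneous', "
            f"got {p.hill_denominator!r}"
        )


def to_internal_units(
    p: ModelParameters, scales: ReferenceScales | None = None
) -> InternalParameters:
    """Convert tabulated units to the coherent internal system.

    Conversion table: 1 um = 1e-6 m; 1 cm = 1e-2 m; 1 mmHg = 133.322 Pa;
    1 cm^2/s = 1e-4 m^2/s; 1 day = 86400 s; 1 hr = 3600 s; 1 min = 60 s;
    1 ug/ml = 0.001 ug/mm^3 = 1 ng/mm^3 = 1 normalized vascular /
    extracellular concentration unit.
    """
    scales = scales or ReferenceScales()
    # extracellular reference in ng/mm^3: 0.001 ug/mm^3 -> 1.0
    c_ref_E_ng_mm3 = scales.c_ref_vE * 1000.0
    # k1 is tabulated in ug/ml = ng/mm^3
    k1_norm = p.k1 / c_ref_E_ng_mm3
    k2_norm = p.k2 / scales.c_ref_I
    # V1 in ng/(10^5 cells)/min drives c_I (normalized by c_ref_I) per second
    v1 = p.V1 / 60.0 / scales.c_ref_I
    v2 = p.V2 / 60.0 / scales.c_ref_I
    day = 86400.0
    hr = 3600.0
    return InternalParameters(
        R_C=p.R_C_um * 1e-6,
        R_T=p.R_T_um * 1e-6,
        L=p.L_cm * 1e-2,
        rho=p.rho,
        mu=p.mu,
        L_p=p.L_p * 1e-2 / MMHG_TO_PA,
        K=p.K_tissue * 1e-4 / MMHG_TO_PA,
        P_A=p.P_A * MMHG_TO_PA,
        P_V=p.P_V * MMHG_TO_PA,
        P_0=p.P_0 * MMHG_TO_PA,
        D_E=p.D_E * 1e-4,
        D_v=p.D_v * 1e-4,
        P_wall=p.P_wall * 1e-2,
        V1=v1,
        V2=v2,
        k1=k1_norm,
        k2=k2_norm,
        sigma_f=p.sigma_f,
        c_t0=p.c_t0 / 1e5,
        a1=p.a1 / day,
        a2=p.a2 / day,
        b=p.b / day,
        Vf=p.Vf / hr,
        Vr=p.Vr / hr,
        Km1=p.Km1,
        Km2=p.Km2,
        kfb=p.kfb / hr,
        p=p.p,
        q=p.q,
        k_mono=p.k_mono / hr,
        kh=p.kh,
        n_hill=p.n_hill,
        kf=p.kf / hr,
        kr=p.kr / hr,
        R1_th=p.R1_th,
        pulse_S=p.pulse_S,
        pulse_T=p.pulse_T_h * hr,
        switch_kind=p.switch_kind,
        hill_denominator=p.hill_denominator,
        scales=scales,
    )


def from_internal_units(ip: InternalParameters) -> ModelParameters:
    """Inverse of :func:`to_internal_units` (round-trip identity)."""
    scales = ip.scales
    c_ref_E_ng_mm3 = scales.c_ref_vE * 1000.0
    day = 86400.0
    hr = 3600.0
    return ModelParameters(
        R_C_um=ip.R_C * 1e6,
        R_T_um=ip.R_T * 1e6,
        L_cm=ip.L * 1e2,
        rho=ip.rho,
        mu=ip.mu,
        L_p=ip.L_p * MMHG_TO_PA * 1e2,
        K_tissue=ip.K * MMHG_TO_PA * 1e4,
        P_A=ip.P_A / MMHG_TO_PA,
        P_V=ip.P_V / MMHG_TO_PA,
        P_0=ip.P_0 / MMHG_TO_PA,
        D_E=ip.D_E * 1e4,
        D_v=ip.D_v * 1e4,
        P_wall=ip.P_wall * 1e2,
        V1=ip.V1 * 60.0 * scales.c_ref_I,
        V2=ip.V2 * 60.0 * scales.c_ref_I,
        k1=ip.k1 * c_ref_E_ng_mm3,
        k2=ip.k2 * scales.c_ref_I,
        sigma_f=ip.sigma_f,
        c_t0=ip.c_t0 * 1e5,
        a1=ip.a1 * day,
        a2=ip.a2 * day,
        b=ip.b * day,
        Vf=ip.Vf * hr,
        Vr=ip.Vr * hr,
        Km1=ip.Km1,
        Km2=ip.Km2,
        kfb=ip.kfb * hr,
        p=ip.p,
        q=ip.q,
        k_mono=ip.k_mono * hr,
        kh=ip.kh,
        n_hill=ip.n_hill,
        kf=ip.kf * hr,
        kr=ip.kr * hr,
        R1_th=ip.R1_th,
        pulse_S=ip.pulse_S,
        pulse_T_h=ip.pulse_T / hr,
        switch_kind=ip.switch_kind,
        hill_denominator=ip.hill_denominator,
    )


_COMPARTMENTS = {"vE": "c_ref_vE", "I": "c_ref_I", "t": "c_ref_t"}


def normalize(value: float, compartment: str,
              scales: ReferenceScales | None = None) -> float:
    """Physical concentration -> dimensionless, by compartment tag.

    ``vE``: vascular/extracellular drug in ug/mm^3; ``I``: intracellular
    drug in ng/(10^5 cells); ``t``: cell density in cells/mm^3.
    """
    scales = scales or ReferenceScales()
    try:
        ref = getattr(scales, _COMPARTMENTS[compartment])
    except KeyError:
        raise ParameterError(f"unknown compartment tag {compartment!r}") from None
    return value / ref


def denormalize(value: float, compartment: str,
                scales: ReferenceScales | None = None) -> float:
    """Inverse of :func:`normalize`."""
    scales = scales or ReferenceScales()
    try:
        ref = getattr(scales, _COMPARTMENTS[compartment])
    except KeyError:
        raise ParameterError(f"unknown compartment tag {compartment!r}") from None
    return value * ref


def load_config(path: str | Path) -> tuple[ModelParameters, Numerics]:
    """Read a YAML config; unknown keys are errors, missing keys default.

    Layout: flat ``key: value`` pairs named after the table symbols, plus
    an optional nested ``numerics:`` mapping (nr_i, nz, dt_s, t_end_h,
    output_every_s, refinement, ode_substep_s, flow_tol, death_frac).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: top level must be a mapping")
    num_raw = raw.pop("numerics", {}) or {}
    if not isinstance(num_raw, dict):
        raise ParameterError(f"{path}: 'numerics' must be a mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ParameterError(
            f"{path}: unknown parameter keys {sorted(unknown)}"
        )
    unknown_num = set(num_raw) - _NUMERICS_KEYS
    if unknown_num:
        raise ParameterError(
            f"{path}: unknown numerics keys {sorted(unknown_num)}"
        )
    kwargs = {_CONFIG_KEYS[k]: v for k, v in raw.items()}
    params = ModelParameters(**kwargs)
    num = Numerics(**{k: v for k, v in num_raw.items()})
    if num.nr_i < 2 or num.nz < 2:
        raise ParameterError("numerics nr_i and nz must be >= 2")
    if num.dt_s <= 0 or num.t_end_h <= 0:
        raise ParameterError("numerics dt_s and t_end_h must be > 0")
    if not 0.0 < num.death_frac < 1.0:
        raise ParameterError("numerics death_frac must lie in (0, 1)")
    return params, num


def parameter_table(p: ModelParameters) -> str:
    """Echo the resolved parameter set as an aligned text table."""
    lines = ["parameter            value"]
    for f in fields(p):
        v = getattr(p, f.name)
        if isinstance(v, float):
            lines.append(f"{f.name:<20s} {v:.6g}")
        else:
            lines.append(f"{f.name:<20s} {v}")
    return "\n".join(lines)
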