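"""Result writers: NetCDF field snapshots, CSV profiles and tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .simulate import SimResult


def fields_dataset(result: SimResult) -> xr.Dataset:
    """Pack all snapshots into one structured-grid dataset.

    Coordinates: t (s), r and z (m, interstitial cell centers), z_lumen
    (m).  Variables: c_v(t, z_lumen), c_E/c_I/c_t/R/R1 on (t, r, z).
    """
    g = result.grid
    t = result.times
    stack2 = lambda fld, snaps: np.stack([getattr(s, fld) for s in snaps])
    ds = xr.Dataset(
        {
            "c_v": (("t", "z_lumen"), stack2("c_v", result.drug_snapshots)),
            "c_E": (("t", "r", "z"), stack2("c_E", result.drug_snapshots)),
            "c_I": (("t", "r", "z"), stack2("c_I", result.drug_snapshots)),
            "c_t": (("t", "r", "z"), stack2("c_t", result.cell_snapshots)),
            "R": (("t", "r", "z"), stack2("R", result.cell_snapshots)),
            "R1": (("t", "r", "z"), stack2("R1", result.cell_snapshots)),
        },
        coords={"t": t, "r": g.r_centers, "z": g.z_centers,
                "z_lumen": g.z_centers},
        attrs={"description": "normalized drug/cell fields on the "
                              "axisymmetric Krogh-cylinder grid",
               **{f"prov_{k}": str(v) for k, v in result.provenance.items()}},
    )
    return ds


def write_result(result: SimResult, out_dir: str | Path) -> None:
    """Write fields.nc, profiles_z0.5.csv, metrics.csv and ledger.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fields_dataset(result).to_netcdf(out / "fields.nc", engine="scipy")
    r, c_E = result.mid_profile("c_E")
    _, c_I = result.mid_profile("c_I")
    _, c_t = result.mid_profile("c_t")
    pd.DataFrame({"r_m": r, "c_E": c_E, "c_I": c_I, "c_t": c_t}).to_csv(
        out / "profiles_z0.5.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.ledger.to_csv(out / "ledger.csv", index=False)


def write_flow(result_or_flow, grid, out_dir: str | Path) -> None:
    """Write P_v(z), J_F(z) as CSV and the P_i field as NetCDF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flow = result_or_flow
    pd.DataFrame({"z_m": grid.z_centers, "P_v_Pa": flow.P_v,
                  "J_F_m_per_s": flow.J_F,
                  "u_v_mean_m_per_s": flow.u_v_mean}).to_csv(
        out / "flow_axial.csv", index=False)
    xr.Dataset(
        {"P_i": (("r", "z"), flow.P_i)},
        coords={"r": grid.r_centers, "z": grid.z_centers},
    ).to_netcdf(out / "interstitial_pressure.nc", engine="scipy")
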