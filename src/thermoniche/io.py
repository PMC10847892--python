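"""Trajectory persistence.

Trajectories are stored as netCDF (classic format, written through
xarray's scipy backend) with dims (time, species, box); model parameters
and trait constants ride along as attributes so a saved run can be
re-analyzed without its originating config.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .simulate import ModelParams, Trajectory
from .traits import SpeciesTraits

__all__ = ["trajectory_to_dataset", "dataset_to_trajectory", "save_trajectory", "load_trajectory"]

_PARAM_FIELDS = (
    "gamma", "K_H", "d", "R_0", "dt", "years", "analysis_window_years",
    "initial_P", "initial_R", "save_stride",
)


def trajectory_to_dataset(traj: Trajectory) -> xr.Dataset:
    ds = xr.Dataset(
        data_vars={
            "P": (("time", "species", "box"), traj.P_series),
            "R": (("time", "box"), traj.R_series),
            "T": (("time", "box"), traj.T_series),
            "P_max": (("species", "box"), traj.P_max),
        },
        coords={
            "time": traj.times,
            "species": np.arange(traj.traits.n_species),
            "box": np.arange(traj.latitudes.size),
            "z": ("species", traj.traits.z),
            "T_Fopt": ("species", traj.traits.t_fopt),
            "latitude": ("box", traj.latitudes),
        },
    )
    for name in _PARAM_FIELDS:
        ds.attrs[f"param_{name}"] = getattr(traj.params, name)
    for name in ("w", "a", "b", "k"):
        ds.attrs[f"trait_{name}"] = getattr(traj.traits, name)
    ds.attrs["forcing_mode"] = traj.forcing_mode
    return ds


def dataset_to_trajectory(ds: xr.Dataset) -> Trajectory:
    params = ModelParams(
        **{
            name: (int if name in ("years", "analysis_window_years", "save_stride") else float)(
                ds.attrs[f"param_{name}"]
            )
            for name in _PARAM_FIELDS
        }
    )
    traits = SpeciesTraits(
        z=ds["z"].to_numpy(),
        w=float(ds.attrs["trait_w"]),
        a=float(ds.attrs["trait_a"]),
        b=float(ds.attrs["trait_b"]),
        k=float(ds.attrs["trait_k"]),
    )
    return Trajectory(
        times=ds["time"].to_numpy(),
        P_series=ds["P"].to_numpy(),
        R_series=ds["R"].to_numpy(),
        T_series=ds["T"].to_numpy(),
        P_max=ds["P_max"].to_numpy(),
        params=params,
        traits=traits,
        latitudes=ds["latitude"].to_numpy(),
        forcing_mode=str(ds.attrs["forcing_mode"]),
    )


def save_trajectory(traj: Trajectory, path) -> None:
    trajectory_to_dataset(traj).to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def load_trajectory(path) -> Trajectory:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_trajectory(ds.load())
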