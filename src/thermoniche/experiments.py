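"""Orchestration of the four controlled experiments and parameter sweeps.

The experiment grid crosses two switches — temperature variability
(constant vs. seasonal forcing) and dispersal (K_H = 0 vs. > 0):

    E1  constant, no dispersal      (control: competitive exclusion)
    E2  constant + dispersal        (spatial mass effects only)
    E3  seasonal, no dispersal      (temporal storage effects only)
    E4  seasonal + dispersal        (combined effects)

Each (gamma, K_H) cell is a full model run followed by the niche and
diversity post-processing; cells are collated into long-format tables
keyed by (experiment, gamma, K_H). Everything is deterministic, so
re-running a spec reproduces its tables exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersal import ModelGrid
from .forcing import (
    ClimatologyGrid,
    SyntheticForcingParams,
    load_climatology,
    synthesize_climatology,
    temperature_amplitude,
    to_forcing,
)
from .niche import classify_extant, diversity_profile, estimate_all_niches
from .simulate import ModelParams, run_simulation
from .traits import SpeciesTraits, default_traits

__all__ = ["ExperimentSpec", "SweepSummary", "run_experiment", "collate_figure_tables",
           "EXPERIMENT_DEFAULTS"]

logger = logging.getLogger(__name__)

#: Forcing mode and dispersal range per experiment.
EXPERIMENT_DEFAULTS = {
    "E1": {"mode": "constant", "K_H": [0.0]},
    "E2": {"mode": "constant", "K_H": [1.0, 10.0, 100.0, 1000.0]},
    "E3": {"mode": "seasonal", "K_H": [0.0]},
    "E4": {"mode": "seasonal", "K_H": [1.0, 10.0, 100.0, 1000.0]},
}

GAMMAS = (0.05, 0.1, 0.2)


@dataclass
class ExperimentSpec:
    """One experiment's sweep configuration.

    ``forcing_source`` is ``"synthetic"`` or a path to a climatology file
    (CSV matrix or netCDF). Latitude band, years and dt allow reduced
    configurations; the defaults are the full-scale study conditions.
    """

    experiment: str
    gamma: tuple = GAMMAS
    K_H: tuple | None = None  # None -> experiment default
    forcing_source: str = "synthetic"
    seed: int = 0
    latitude_band: tuple = (-79.0, 79.0)
    years: int = 50
    analysis_window_years: int = 5
    dt: float = 0.125
    output_dir: str | None = None
    save_trajectories: bool = False
    traits: SpeciesTraits | None = None
    kde_min_bandwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_DEFAULTS:
            raise ValueError(f"unknown experiment {self.experiment!r} (expected E1..E4)")
        if self.K_H is None:
            self.K_H = tuple(EXPERIMENT_DEFAULTS[self.experiment]["K_H"])
        if self.experiment in ("E1", "E3") and any(k != 0 for k in self.K_H):
            raise ValueError(f"{self.experiment} runs without dispersal (K_H = 0)")
        if self.traits is None:
            self.traits = default_traits()

    @property
    def mode(self) -> str:
        return EXPERIMENT_DEFAULTS[self.experiment]["mode"]


@dataclass
class SweepSummary:
    """Collated tables for one experiment sweep.

    ``diversity``: one row per (gamma, K_H, box) with S_bar, S_T and the
    box's seasonal amplitude as experienced under the forcing mode.
    ``niches``: one row per (gamma, K_H, extant species); empty for E1,
    where each survivor occupies a single constant-temperature box and a
    realized niche is not defined. ``maxima``: max-over-box diversity per
    cell. ``failed_cells`` lists (gamma, K_H) cells that aborted.
    """

    experiment: str
    diversity: pd.DataFrame
    niches: pd.DataFrame
    maxima: pd.DataFrame
    failed_cells: list = field(default_factory=list)


def _build_forcing(spec: ExperimentSpec):
    lats = np.arange(np.ceil(spec.latitude_band[0]), np.floor(spec.latitude_band[1]) + 0.5)
    if spec.forcing_source == "synthetic":
        clim = synthesize_climatology(SyntheticForcingParams(seed=spec.seed), lats)
    else:
        clim = load_climatology(spec.forcing_source, spec.latitude_band)
    forcing = to_forcing(clim, spec.dt, spec.years, spec.mode)
    return clim, forcing


def run_experiment(spec: ExperimentSpec) -> SweepSummary:
    """Run every (gamma, K_H) cell of an experiment and collate results.

    A cell whose integration fails is logged and skipped; the sweep
    continues and the cell is recorded in ``failed_cells``.
    """
    clim, forcing = _build_forcing(spec)
    grid = ModelGrid(box_center_latitudes=clim.latitudes)
    if spec.mode == "seasonal":
        amplitude = np.array([temperature_amplitude(clim, b) for b in range(clim.n_boxes)])
    else:
        amplitude = np.zeros(clim.n_boxes)

    out_root = Path(spec.output_dir) if spec.output_dir else None
    div_tables, niche_tables, max_rows, failed = [], [], [], []

    for gamma in spec.gamma:
        for K_H in spec.K_H:
            params = ModelParams(
                gamma=gamma, K_H=K_H, dt=spec.dt, years=spec.years,
                analysis_window_years=spec.analysis_window_years,
            )
            try:
                traj = run_simulation(spec.traits, grid, params, forcing)
            except FloatingPointError as err:
                logger.error("cell gamma=%g K_H=%g failed: %s", gamma, K_H, err)
                failed.append((gamma, K_H))
                continue

            div = diversity_profile(traj)
            div.insert(0, "K_H", K_H)
            div.insert(0, "gamma", gamma)
            div.insert(0, "experiment", spec.experiment)
            div["amplitude"] = amplitude

            if spec.experiment == "E1":
                # single survivor per constant-temperature box: no measurable
                # spread of biomass over temperature, niche not applicable
                niches = pd.DataFrame(
                    columns=["species", "z", "T_Fopt", "T_Ropt", "W_R", "delta_W",
                             "delta_Topt", "n_boxes_present", "flag_low_T_Fopt"]
                )
            else:
                report = classify_extant(traj)
                niches = estimate_all_niches(
                    traj, report, min_bandwidth=spec.kde_min_bandwidth
                )
            niches.insert(0, "K_H", K_H)
            niches.insert(0, "gamma", gamma)
            niches.insert(0, "experiment", spec.experiment)

            max_rows.append(
                {
                    "experiment": spec.experiment,
                    "gamma": gamma,
                    "K_H": K_H,
                    "max_S_bar": float(div["S_bar"].max()),
                    "max_S_T": int(div["S_T"].max()),
                }
            )
            div_tables.append(div)
            niche_tables.append(niches)

            if out_root is not None:
                cell = out_root / f"{spec.experiment}_gamma{gamma:g}_KH{K_H:g}"
                cell.mkdir(parents=True, exist_ok=True)
                niches.to_csv(cell / "niches.csv", index=False)
                div.to_csv(cell / "diversity.csv", index=False)
                snap = {k: v for k, v in asdict(params).items()}
                snap.update(experiment=spec.experiment, forcing=spec.forcing_source,
                            mode=spec.mode, seed=spec.seed,
                            latitude_band=list(spec.latitude_band))
                (cell / "params.json").write_text(json.dumps(snap, indent=1))
                if spec.save_trajectories:
                    from .io import save_trajectory

                    save_trajectory(traj, cell / "trajectory.nc")

    empty_div = pd.DataFrame(columns=["experiment", "gamma", "K_H", "box", "latitude",
                                      "S_bar", "S_T", "amplitude"])
    empty_niche = pd.DataFrame(columns=["experiment", "gamma", "K_H", "species", "z",
                                        "T_Fopt", "T_Ropt", "W_R", "delta_W",
                                        "delta_Topt", "n_boxes_present", "flag_low_T_Fopt"])
    nonempty_niches = [n for n in niche_tables if not n.empty]
    summary = SweepSummary(
        experiment=spec.experiment,
        diversity=pd.concat(div_tables, ignore_index=True) if div_tables else empty_div,
        niches=pd.concat(nonempty_niches, ignore_index=True) if nonempty_niches
        else pd.DataFrame(columns=empty_niche.columns),
        maxima=pd.DataFrame(max_rows, columns=["experiment", "gamma", "K_H",
                                               "max_S_bar", "max_S_T"]),
        failed_cells=failed,
    )
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
        summary.diversity.to_csv(out_root / f"{spec.experiment}_diversity.csv", index=False)
        summary.niches.to_csv(out_root / f"{spec.experiment}_niches.csv", index=False)
        summary.maxima.to_csv(out_root / f"{spec.experiment}_maxima.csv", index=False)
    return summary


def collate_figure_tables(summaries) -> dict[str, pd.DataFrame]:
    """Merge experiment summaries into cross-experiment long tables.

    Returns ``diversity`` (experiment x gamma x K_H x box), ``niches``
    (experiment x gamma x K_H x species) and ``maxima`` tables. Missing
    experiments simply contribute no rows; any failed cells are flagged
    in a ``gaps`` table.
    """
    summaries = list(summaries)
    gaps = [
        {"experiment": s.experiment, "gamma": g, "K_H": k}
        for s in summaries
        for (g, k) in s.failed_cells
    ]
    niche_frames = [s.niches for s in summaries if not s.niches.empty]
    return {
        "diversity": pd.concat([s.diversity for s in summaries], ignore_index=True),
        "niches": pd.concat(niche_frames, ignore_index=True)
        if niche_frames else summaries[0].niches.iloc[0:0],
        "maxima": pd.concat([s.maxima for s in summaries], ignore_index=True),
        "gaps": pd.DataFrame(gaps, columns=["experiment", "gamma", "K_H"]),
    }
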