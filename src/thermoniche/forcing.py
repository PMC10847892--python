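"""Per-box temperature forcing.

Each model box is driven by a 365-day climatological sea-surface
temperature cycle, either loaded from an observed zonally averaged
climatology (netCDF grid or pre-tabulated lat x day CSV) or produced by a
synthetic generator that emulates its gross structure: annual means
decreasing poleward, seasonal amplitude peaking at mid-latitudes and
vanishing at the equator and poles, and anti-phased hemispheres. The
climatology is interpolated (periodic linear) onto the model time step for
seasonally forced runs; constant-temperature runs use each box's annual
mean.

The year is 365 days with no leap handling — the climatology is strictly
periodic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClimatologyGrid",
    "SyntheticForcingParams",
    "Forcing",
    "load_climatology",
    "synthesize_climatology",
    "to_forcing",
    "temperature_amplitude",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ClimatologyGrid:
    """Daily SST climatology on the model's 1°-latitude boxes.

    ``temperature`` has shape (n_latitudes, 365); row order matches
    ``latitudes`` (degrees north, one per box centre), columns are
    day-of-year 1..365.
    """

    latitudes: np.ndarray
    temperature: np.ndarray
    day_of_year: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lats = np.asarray(self.latitudes, dtype=float)
        temp = np.asarray(self.temperature, dtype=float)
        days = (
            np.arange(1, DAYS_PER_YEAR + 1)
            if self.day_of_year is None
            else np.asarray(self.day_of_year)
        )
        if temp.shape != (lats.size, days.size):
            raise ValueError(
                f"temperature shape {temp.shape} does not match "
                f"({lats.size} latitudes, {days.size} days)"
            )
        if not np.array_equal(days, np.arange(1, DAYS_PER_YEAR + 1)):
            raise ValueError("day_of_year axis must cover 1..365 with no gaps")
        if not np.all(np.isfinite(temp)):
            bad = np.argwhere(~np.isfinite(temp))
            raise ValueError(
                f"climatology contains {bad.shape[0]} non-finite cells, "
                f"first at (lat={lats[bad[0, 0]]}, day={days[bad[0, 1]]})"
            )
        object.__setattr__(self, "latitudes", lats)
        object.__setattr__(self, "temperature", temp)
        object.__setattr__(self, "day_of_year", days)

    @property
    def n_boxes(self) -> int:
        return self.latitudes.size

    def annual_mean(self) -> np.ndarray:
        """Per-box mean of the daily cycle (°C)."""
        return self.temperature.mean(axis=1)

    def to_csv(self, path) -> None:
        """Write as a lat x day matrix (rows = latitudes, columns 1..365)."""
        df = pd.DataFrame(self.temperature, index=self.latitudes, columns=self.day_of_year)
        df.index.name = "latitude"
        df.to_csv(path)


@dataclass(frozen=True)
class SyntheticForcingParams:
    """Parameters of the synthetic zonal SST climatology.

    Defaults emulate the gross structure of an observed zonal-mean SST
    climatology: ~28 °C annual mean at the equator falling to freezing
    near the poles, an 8 °C seasonal range peaking near 40° latitude, and
    hemispheres half a year out of phase.
    """

    equator_mean: float = 28.0
    pole_mean: float = -1.8
    max_amplitude: float = 8.0
    amplitude_peak_latitude: float = 40.0
    pole_latitude: float = 80.0
    phase_offset_days: float = 120.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_amplitude < 0:
            raise ValueError(f"max_amplitude must be non-negative, got {self.max_amplitude}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")


def _amplitude_profile(lat: np.ndarray, params: SyntheticForcingParams) -> np.ndarray:
    """Half-range seasonal amplitude A(lat): 0 at equator and pole, peak at
    ``amplitude_peak_latitude``. Piecewise quarter-sine, C1 at the peak."""
    x = np.abs(np.asarray(lat, dtype=float))
    pk, pole = params.amplitude_peak_latitude, params.pole_latitude
    a = np.where(
        x <= pk,
        np.sin(0.5 * np.pi * x / pk),
        np.sin(0.5 * np.pi * np.clip(pole - x, 0.0, None) / (pole - pk)),
    )
    return params.max_amplitude * a


def _mean_profile(lat: np.ndarray, params: SyntheticForcingParams) -> np.ndarray:
    """Annual-mean SST: linear in |lat| from equator_mean to pole_mean."""
    x = np.abs(np.asarray(lat, dtype=float)) / params.pole_latitude
    return params.equator_mean + (params.pole_mean - params.equator_mean) * np.clip(x, 0, 1)


def synthesize_climatology(
    params: SyntheticForcingParams, latitudes: np.ndarray
) -> ClimatologyGrid:
    """Generate a smooth anti-phased sinusoidal SST climatology.

        T(lat, d) = mean(lat) + A(lat) * sin(2*pi*(d - phi(lat)) / 365)

    where phi is shifted by half a year in the southern hemisphere. With
    ``noise_sd > 0``, seeded Gaussian noise is added cell-wise (the same
    seed reproduces the grid bit-for-bit).
    """
    lat = np.asarray(latitudes, dtype=float)
    days = np.arange(1, DAYS_PER_YEAR + 1)
    mean = _mean_profile(lat, params)
    amp = _amplitude_profile(lat, params)
    phase = np.where(lat < 0, params.phase_offset_days + DAYS_PER_YEAR / 2.0,
                     params.phase_offset_days)
    T = mean[:, None] + amp[:, None] * np.sin(
        2.0 * np.pi * (days[None, :] - phase[:, None]) / DAYS_PER_YEAR
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        T = T + rng.normal(0.0, params.noise_sd, size=T.shape)
    return ClimatologyGrid(latitudes=lat, temperature=T)


def _expected_band_centres(latitude_band: tuple[float, float]) -> np.ndarray:
    lo, hi = latitude_band
    return np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)


def load_climatology(path, latitude_band: tuple[float, float] = (-79.0, 79.0)) -> ClimatologyGrid:
    """Load a daily SST climatology restricted to the model latitude band.

    Two layouts are accepted:

    * CSV matrix — rows are 1° box-centre latitudes (first column),
      columns day-of-year 1..365 (header row). Read as-is.
    * netCDF — a CF-style gridded SST field with latitude/longitude (and
      optionally time or day-of-year) coordinates. Values are averaged
      across all longitudes and within each 1° latitude band; a datetime
      time axis is collapsed to a day-of-year climatology (day 366
      dropped).

    Raises if any 1° box centre inside ``latitude_band`` is missing from
    the file (the gaps are named) or if any cell is non-finite.
    """
    path = Path(path)
    if path.suffix.lower() in {".nc", ".nc4", ".cdf", ".netcdf"}:
        lats, temp = _read_netcdf(path)
    else:
        df = pd.read_csv(path, index_col=0)
        lats = df.index.to_numpy(dtype=float)
        temp = df.to_numpy(dtype=float)
        if temp.shape[1] != DAYS_PER_YEAR:
            raise ValueError(
                f"CSV climatology must have {DAYS_PER_YEAR} day columns, got {temp.shape[1]}"
            )

    wanted = _expected_band_centres(latitude_band)
    available = {round(float(v), 6): i for i, v in enumerate(lats)}
    missing = [c for c in wanted if round(float(c), 6) not in available]
    if missing:
        raise ValueError(
            "climatology is missing 1° boxes inside the requested band: "
            + ", ".join(f"{m:g}°" for m in missing)
        )
    rows = [available[round(float(c), 6)] for c in wanted]
    return ClimatologyGrid(latitudes=wanted, temperature=temp[rows, :])


def _read_netcdf(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import xarray as xr

    ds = xr.open_dataset(path)
    name = next(
        (v for v in ("sst", "temperature", "tos", "analysed_sst") if v in ds.data_vars),
        list(ds.data_vars)[0],
    )
    da = ds[name]
    lat_dim = next((d for d in da.dims if d.lower() in ("lat", "latitude", "y")), None)
    lon_dim = next((d for d in da.dims if d.lower() in ("lon", "longitude", "x")), None)
    if lat_dim is None:
        raise ValueError(f"no latitude dimension found in {path} (dims {da.dims})")
    if lon_dim is not None:
        da = da.mean(dim=lon_dim)  # zonal average across all longitudes
    time_dim = next(
        (d for d in da.dims if d.lower() in ("time", "day", "dayofyear", "doy")), None
    )
    if time_dim is not None and time_dim.lower() == "time":
        da = da.groupby("time.dayofyear").mean("time")
        da = da.sel(dayofyear=slice(1, DAYS_PER_YEAR))
        time_dim = "dayofyear"
    da = da.transpose(lat_dim, ...)
    cell_lats = da[lat_dim].to_numpy().astype(float)
    values = da.to_numpy().astype(float)
    if values.shape[1] != DAYS_PER_YEAR:
        raise ValueError(
            f"netCDF climatology must resolve {DAYS_PER_YEAR} days, got {values.shape[1]}"
        )
    # average the source cells falling within each 1° band centred on an integer
    centres = np.unique(np.round(cell_lats))
    rows = []
    kept = []
    for c in centres:
        sel = np.abs(cell_lats - c) <= 0.5
        if sel.any():
            kept.append(c)
            with np.errstate(invalid="ignore"):
                rows.append(np.nanmean(values[sel, :], axis=0))
    return np.asarray(kept, dtype=float), np.asarray(rows)


@dataclass(frozen=True)
class Forcing:
    """Per-box temperature as a function of model time.

    The series is stored as one model year of per-step values (shape
    (n_boxes, steps_per_year) in seasonal mode, (n_boxes, 1) in constant
    mode) and tiled periodically over ``years`` — forcing repeats exactly
    with period one model year.
    """

    mode: str  # "seasonal" | "constant"
    dt: float  # days
    years: int
    values: np.ndarray  # (n_boxes, steps_per_year) one-year block

    @property
    def n_boxes(self) -> int:
        return self.values.shape[0]

    @property
    def steps_per_year(self) -> int:
        return int(round(DAYS_PER_YEAR / self.dt))

    @property
    def n_steps(self) -> int:
        return self.steps_per_year * self.years

    def at_step(self, k: int) -> np.ndarray:
        """Temperature in every box at model step ``k`` (time k*dt days)."""
        return self.values[:, k % self.values.shape[1]]

    def times(self) -> np.ndarray:
        """Model time (days) of every step over the whole run."""
        return np.arange(self.n_steps) * self.dt

    def series(self, box: int) -> np.ndarray:
        """Full temperature series for one box over all years."""
        block = self.values[box]
        reps = self.n_steps // block.size + 1
        return np.tile(block, reps)[: self.n_steps]


def to_forcing(grid: ClimatologyGrid, timestep: float, years: int, mode: str) -> Forcing:
    """Interpolate the daily climatology onto the model time grid.

    Seasonal mode uses periodic linear interpolation (day d's value sits
    at time d-1 days into the year; the cycle wraps 365 -> 0). Constant
    mode uses each box's annual mean at every step.
    """
    if mode not in ("seasonal", "constant"):
        raise ValueError(f"mode must be 'seasonal' or 'constant', got {mode!r}")
    spy = DAYS_PER_YEAR / timestep
    if abs(spy - round(spy)) > 1e-9:
        raise ValueError(f"timestep {timestep} d must divide the 365-day year evenly")
    spy = int(round(spy))
    if mode == "constant":
        values = grid.annual_mean()[:, None]
    else:
        t = np.arange(spy) * timestep  # model time within the year (days)
        day_pos = np.arange(DAYS_PER_YEAR + 1, dtype=float)  # 0..365, wrapped
        values = np.empty((grid.n_boxes, spy))
        for j in range(grid.n_boxes):
            daily = grid.temperature[j]
            wrapped = np.append(daily, daily[0])
            values[j] = np.interp(t, day_pos, wrapped)
    return Forcing(mode=mode, dt=float(timestep), years=int(years), values=values)


def temperature_amplitude(grid: ClimatologyGrid, box: int) -> float:
    """Seasonal temperature amplitude of a box: max - min of its daily
    climatology (°C). Twice the half-range for a pure sinusoid."""
    daily = grid.temperature[box]
    return float(daily.max() - daily.min())
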