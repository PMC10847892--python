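"""Species thermal traits and temperature-dependent vital rates.

Each model species carries a Thomas-form thermal performance curve

    mu_i(T) = a * exp(b*T) * [1 - ((T - z_i) / (w/2))**2]

whose exponential envelope (``a*exp(b*T)``, the Eppley curve) skews the
growth maximum warm of the niche-location parameter ``z_i``. Growth is
positive only on (z_i - w/2, z_i + w/2) — the fundamental niche — and
negative outside it. Mortality shares the envelope, scaled by a unitless
factor gamma, so competitive ranking at a fixed temperature reduces to
the growth curve itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesTraits",
    "growth_rate",
    "mortality_rate",
    "fundamental_topt",
    "default_traits",
]

#: Eppley-envelope intercept: growth rate at 0 °C (day^-1).
DEFAULT_A = 0.81
#: Exponential temperature coefficient of the envelope (°C^-1).
DEFAULT_B = 0.0631
#: Fundamental niche width shared by all species (°C).
DEFAULT_W = 10.0
#: Half-saturation constant for nutrient uptake (mmol P m^-3), identical
#: across species so that temperature is the only differentiating trait.
DEFAULT_K = 0.1

#: Temperature grid used to locate each curve's maximum (°C).
TOPT_GRID = np.arange(-4.0, 50.0 + 1e-9, 0.1)


@dataclass(frozen=True)
class SpeciesTraits:
    """Trait table for the model community.

    Attributes
    ----------
    z : ndarray, shape (n_species,)
        Niche-location parameter (°C); growth is zero at ``z ± w/2``.
    w : float
        Niche width (°C), shared by all species.
    a, b : float
        Envelope constants (day^-1 at 0 °C, and °C^-1).
    k : float
        Michaelis–Menten half-saturation (mmol P m^-3), shared.
    t_fopt : ndarray, shape (n_species,)
        Fundamental optimum temperature per species (grid argmax of the
        growth curve), filled in at construction.
    """

    z: np.ndarray
    w: float = DEFAULT_W
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    k: float = DEFAULT_K
    t_fopt: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or z.size == 0:
            raise ValueError("z must be a non-empty 1-D array of niche locations")
        if self.w <= 0:
            raise ValueError(f"niche width w must be positive, got {self.w}")
        object.__setattr__(self, "z", z)
        if self.t_fopt is None:
            object.__setattr__(self, "t_fopt", fundamental_topt(self))

    @property
    def n_species(self) -> int:
        return self.z.size


def default_traits() -> SpeciesTraits:
    """The standard 45-member community: z = -4, -3, ..., 40 °C."""
    return SpeciesTraits(z=np.arange(-4.0, 40.0 + 0.5, 1.0))


def growth_rate(T, traits: SpeciesTraits):
    """Temperature-dependent specific growth rate mu_i(T) (day^-1).

    Broadcasts species against temperature: with scalar ``T`` returns shape
    (n_species,); with ``T`` of shape (n,) returns (n_species, n). Values
    are negative outside the fundamental niche (retained as signed rates).
    """
    T = np.asarray(T, dtype=float)
    z = traits.z.reshape((-1,) + (1,) * T.ndim)
    envelope = traits.a * np.exp(traits.b * T)
    return envelope * (1.0 - ((T - z) / (traits.w / 2.0)) ** 2)


def mortality_rate(T, traits: SpeciesTraits, gamma: float):
    """Temperature-dependent loss rate gamma * a * exp(b*T) (day^-1).

    Identical across species at a given temperature; ``gamma`` scales the
    growth envelope to represent low/intermediate/high loss pressure.
    """
    T = np.asarray(T, dtype=float)
    return gamma * traits.a * np.exp(traits.b * T)


def fundamental_topt(traits: SpeciesTraits, grid: np.ndarray | None = None) -> np.ndarray:
    """Fundamental optimum temperature per species (°C).

    Argmax of the growth curve over a fine temperature grid (default
    -4..50 °C at 0.1 °C, wide enough to bracket every species' niche).
    The exponential envelope places the optimum above ``z_i`` but below
    the warm niche edge ``z_i + w/2``.
    """
    if grid is None:
        grid = TOPT_GRID
    mu = growth_rate(grid, traits)  # (n_species, n_grid)
    return grid[np.argmax(mu, axis=1)]
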