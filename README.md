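# thermoniche

A trait-based metacommunity model for asking how **dispersal** and
**seasonal temperature variability** reshape the *realized* temperature
niches and local diversity of marine phytoplankton, relative to the
*fundamental* niches set by their thermal physiology. It is aimed at
plankton ecologists and metacommunity modellers who want a transparent,
fully deterministic sandbox for spatial mass effects (persistence fed by
immigration) and temporal storage effects (persistence through the
seasonal cycle).

## The model

A latitudinal transect (by default 159 one-degree boxes, 79°S–79°N) of
chemostats, each seeded with the same 45 phytoplankton thermotypes.
Biomass P<sub>i,j</sub> of species *i* in box *j* and the limiting
resource R<sub>j</sub> follow

```
dP_ij/dt = μ_i(T_j) · R_j/(R_j + k) · P_ij  −  γ m(T_j) P_ij  +  netdispersal_ij
dR_j/dt  = d (R0 − R_j)  −  Σ_i μ_i(T_j) · R_j/(R_j + k) · P_ij
```

with a Thomas-form thermal growth curve under an Eppley envelope,

```
μ_i(T) = a e^{bT} [1 − ((T − z_i)/(w/2))²],     a = 0.81 d⁻¹, b = 0.0631 °C⁻¹,
```

niche locations z_i = −4…40 °C (1 °C apart), a common niche width
w = 10 °C, temperature-dependent mortality m(T) = a e^{bT} scaled by
γ ∈ {0.05, 0.1, 0.2}, and a chemostat supply (R0 = 0.8 mmol P m⁻³,
d = 0.864 d⁻¹). Boxes exchange biomass all-to-all at diffusive rates
τ = K_H/Δy² (K_H = 0…10³ m² s⁻¹). Forcing is a repeating daily SST
climatology per box — observed (zonally averaged netCDF/CSV) or a
built-in synthetic emulator — used either seasonally or collapsed to its
annual mean.

After a 50-year integration, a species extant in a box (above 10⁻⁴ of
its population scale, with steady yearly means) contributes
biomass-weighted (T, P) samples to a Gaussian kernel density estimate of
its **realized niche**, summarized by the density argmax T<sub>Ropt</sub>
and 1st–99th percentile span W_R, and contrasted with the fundamental
niche via δW = (W_R − W_F)/W_F and δT<sub>opt</sub> =
(T<sub>Ropt</sub> − T<sub>Fopt</sub>)/T<sub>Fopt</sub>. Per-box diversity
is reported as the mean (S̄) and cumulative (S_T) species counts over the
final five years.

Four controlled experiments cross the two mechanisms:
**E1** constant T, no dispersal (control) · **E2** constant T + dispersal
· **E3** seasonal T, no dispersal · **E4** seasonal T + dispersal.

## Worked example

The numbered drivers under `analysis/` run the study end to end at a
reduced scale by default (60 boxes spanning 0–59°N, 20 years; pass
`--full` for the 159-box, 50-year conditions) and write their tables
under `results/`:

```
$ python analysis/02_control_exclusion.py
E1 (40 years): max S_T per box by gamma -> {0.05: 1, 0.1: 1, 0.2: 1}
competitive exclusion complete: exactly one extant species per box

$ python analysis/03_dispersal_sweep.py
max S_bar over boxes per (gamma, K_H):
K_H    1.0     10.0    100.0   1000.0
gamma
0.05      4.0     7.0    11.0    19.0
0.10      3.0     6.0    10.0    17.0
0.20      3.0     5.0     8.0    15.0
weakest dispersal (K_H=1): delta_W in [-0.92, -0.88] -> all narrower than fundamental: True

$ python analysis/05_combined_effects.py
strongest dispersal, gamma=0.05: median delta_W = +0.094 over 20 species (65% wider than fundamental)
```

Reading: without mass effects every box collapses to its single best
thermotype; dispersal alone raises local diversity with K_H but leaves
realized niches *narrower* than fundamental when dispersal is weak
(δW < 0, since each species effectively samples only its home
temperature); seasonality plus strong dispersal pushes the median
realized niche *wider* than fundamental (δW > 0) — the regime matching
field observations of picophytoplankton whose realized thermal ranges
exceed their laboratory-measured fundamental niches. Driver
`04_seasonal_storage.py` additionally prints the storage-effect
signature: realized optima slightly colder than fundamental
(mean δT<sub>opt</sub> < 0).

A `thermoniche` CLI wraps the same library for single runs and sweeps
(`make-forcing`, `run`, `experiment`, `analyze`, `collate`; every
subcommand takes `--config <yaml>`).

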