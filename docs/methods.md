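# Methods

## Model structure and assumptions

The domain is a one-dimensional chain of 1°-latitude chemostat boxes
(159 boxes with centres at −79…79°N at full scale; the stated 80°S–80°N
span and the 159-box count are off by one degree, and the box count is
taken as authoritative). Each box holds one limiting resource (phosphorus
currency, mmol P m⁻³) supplied from a deep pool R0 = 0.8 mmol P m⁻³ at
dilution rate d = 0.864 day⁻¹, and 45 phytoplankton thermotypes that are
identical in every respect except the location z_i of their thermal
niche. Growth follows a Thomas-form curve under an Eppley exponential
envelope, μ_i(T) = a·e^{bT}·[1 − ((T − z_i)/(w/2))²], positive only on
(z_i − 5, z_i + 5); the envelope skews each species' fundamental optimum
T_Fopt warm of z_i (located by brute-force argmax on a −4…50 °C, 0.1 °C
grid). Mortality is the envelope itself scaled by a unitless γ, so all
species share loss rates at a given temperature; with a common
half-saturation k this makes the competitive (R*) ranking at any fixed
temperature collapse onto the growth curve — the property the control
experiment's exclusion oracle relies on.

Dispersal is all-pairs diffusive exchange, τ[i,j] = K_H·86400/(|i−j|·Δy)²
day⁻¹ with Δy = 111 195 m per degree, closed at both ends (no
wrap-around). Net dispersal is immigration minus emigration and conserves
biomass per species exactly.

Assumptions inherited from the study design: no light limitation, no
explicit grazers or viruses (mortality is their aggregate), a single
trait axis (temperature), equal niche widths, no evolution or
demographic stochasticity, and purely isotropic dispersal. The dynamics
contain no random terms; every run is reproducible bit-for-bit from its
configuration.

## Parameters

| symbol | meaning | default | units | note |
|---|---|---|---|---|
| a | envelope growth at 0 °C | 0.81 | day⁻¹ | empirical Eppley-curve fit |
| b | envelope temperature coefficient | 0.0631 | °C⁻¹ | as above |
| w | fundamental niche width | 10 | °C | equal across species |
| z_i | niche locations | −4…40 step 1 | °C | 45 thermotypes |
| k | half-saturation for uptake | 0.1 | mmol P m⁻³ | see below |
| γ | mortality scaling | 0.05 / 0.1 / 0.2 | – | low/mid/high loss |
| R0, d | deep pool, supply rate | 0.8, 0.864 | mmol P m⁻³, day⁻¹ | chemostat |
| K_H | eddy diffusivity | 0, 10⁰…10³ | m² s⁻¹ | sets τ |
| dt | time step | 0.125 (3 h) | days | 365-day year, no leap days |
| years / window | run length / analysis window | 50 / 5 | years | final window analyzed |
| P(0), R(0) | initial conditions | 10⁻³ | mmol P m⁻³ | identical everywhere |

The half-saturation k is not constrained by the study design beyond
being equal across species; 0.1 mmol P m⁻³ (⅛ of the deep pool) puts
equilibrium resource levels well below supply so competition is
resource-controlled. Diversity maxima are somewhat sensitive to this
choice; it is exposed in the trait configuration.

## Synthetic forcing

The generator emulates the gross structure of a zonally averaged daily
SST climatology: T(lat, d) = mean(lat) + A(lat)·sin(2π(d − φ)/365), with
annual means linear in |lat| from 28 °C (equator) to −1.8 °C (poles), a
half-amplitude A peaking (8 °C, i.e. a 16 °C seasonal range) at 40°
latitude via piecewise quarter-sines vanishing at equator and poles, and
hemispheres anti-phased by half a year. Optional seeded Gaussian noise
(default off) keeps the generator reproducible. It does **not** emulate:
zonal asymmetries, skewed or double-peaked seasonal cycles, sub-seasonal
variability (storms, upwelling), interannual anomalies, or trends.
Results that depend on the detailed shape of the observed climatology —
notably the printed full-scale diversity maxima — are therefore not
reproduced quantitatively by synthetic-forcing runs; the mechanism-level
results (exclusion, signs of δW and δTopt, monotone responses to K_H and
amplitude, cross-experiment dominance) are, and those are what the test
suite asserts. Observed forcing can be supplied as a zonally averaged
lat × day CSV matrix or a CF-style netCDF SST product (zonally averaged
and binned to 1° on load).

Seasonal forcing interpolates the daily cycle onto the 3-h model grid by
periodic linear interpolation (day d's value at time d−1 into the year);
constant forcing uses each box's annual mean. The reported "temperature
amplitude" of a box is the max − min of its daily climatology (twice the
sinusoid half-amplitude); the convention is isolated in
`temperature_amplitude` so a half-range convention can be swapped in.

## Numerical scheme

Biomass is advanced by explicit forward Euler at dt = 3 h with negative
values clipped to zero, as befits rates bounded by ~5 day⁻¹. The
resource equation, however, is stiff: near competitive equilibrium its
relaxation rate is ≈ d·R0/(γ·k) — about 114 day⁻¹ at γ = 0.05 — far
beyond the explicit stability limit 2/dt = 16 day⁻¹, and a fully
explicit update diverges within a few model years. The resource sinks
(dilution and consumption by species with μ > 0) are therefore folded
into a Patankar-type semi-implicit denominator, R⁺ = (R + dt·(d·R0 +
release))/(1 + dt·(d + consumption/R-scale)), which is unconditionally
positive and shares the fixed points of the continuous system; sources
(supply and nutrient release where μ < 0) stay explicit. In the
consumer-free limit the deviation |R − R0| then contracts by exactly
1/(1 + d·dt) per step (rate d to first order). Scheme adequacy is
checked behaviorally: halving dt changes final-year biomass by < 1 % in
the control configuration (asserted in the tests).

Two further numerical guards: the integration aborts with the offending
model time if state goes non-finite, and biomass below 10⁻³⁰⁰ is zeroed
— without this, dispersal sustains subnormal-float populations that are
physically meaningless and slow the FPU by an order of magnitude.
Growth/mortality fields are precomputed for one forcing period (forcing
is strictly year-periodic) and reused across years; daily snapshots of
the final five years are retained for analysis, along with each
species' whole-run biomass maximum per box.

## Extantness and presence conventions

Criterion 1 (abundance): final-year mean biomass in a box must exceed
10⁻⁴ times the species' maximum biomass over the whole run, referenced
**globally** (over all boxes) by default. The per-box reference is
available as a flag but is not the default because a species held at a
vanishing dispersal-fed sink equilibrium trivially passes it (its local
maximum never grew either), which saturates presence at every dispersal
strength and erases the diversity gradients the mass-effect mechanism
produces. Criterion 2 (steadiness): consecutive yearly means over the
final five years must differ by less than 1 % relative. The tolerance
operationalizes "negligible drift at the end of the run": in boxes whose
mean temperature falls nearly halfway between two species' optima,
exclusion is still completing at year 50 — the loser declines a few
percent per year and the winner absorbs its biomass at a few tenths of a
percent per year — and a much tighter tolerance would reject the winner
itself. Extant = both criteria; both knobs are configurable.

Instantaneous presence for the diversity metrics reuses the criterion-1
ratio at snapshot resolution and applies the steadiness criterion as a
per-window gate (it is a property of the window, not of a snapshot), so
transiently decaying remnants of excluded competitors do not count as
diversity. S̄ is the mean presence count over the window's snapshots;
S_T the count of species present at one snapshot or more.

## Realized-niche estimation

Each extant species pools (temperature, biomass) samples over every box
where it is extant and every analysis-window snapshot, and a
biomass-weighted Gaussian KDE is fitted along temperature. Bandwidth is
Silverman's rule on the weighted sample (scipy-compatible: weighted SD
times (3·n_eff/4)^(−1/5), with effective sample size 1/Σw²), floored at
0.1 °C so the point-mass limit (a species occupying one constant
temperature) still yields a defined, kernel-width-limited density; both
the bandwidth and the floor are configurable. The density is evaluated
on the −4…50 °C grid at 0.1 °C; T_Ropt is the grid argmax and W_R the
span between the 0.01 and 0.99 crossings of the density's CDF
(trapezoid-integrated and normalized over the grid) — percentiles of the
continuous estimate, not of the raw weighted sample. Large samples are
pre-binned at 0.02 °C before evaluation (error far below the bandwidth
floor). δW = (W_R − 10)/10 and δTopt = (T_Ropt − T_Fopt)/T_Fopt; the
latter is flagged (and excluded from cross-species means) when
|T_Fopt| < 1 °C, where the ratio blows up for polar species.

In the control experiment realized niches are not reported at all: each
survivor occupies a single constant-temperature box, so there is no
measurable spread of biomass over temperature.

## Problem sizes

The full-scale conditions (159 boxes, 50 years) integrate in ~30 s per
configuration on one core; the acceptance script runs all its cells at
full scale in about two minutes. The test suite and the analysis drivers
default to a reduced configuration — 60 boxes spanning 0–59°N, 20 years
(the control runs 20 boxes × 40 years, since near-tie boxes need the
longer horizon for exclusion to settle) — which reproduces every
qualitative result in about a minute. One reduced-scale caveat is noted
where it arises: the 0–59°N band supports only ~23 viable thermotypes,
and at that ceiling the cumulative count S_T in the combined experiment
is not rank-stable across mortality levels, so the mortality-ordering
check there rests on the mean count S̄.

## Known limitations

Beyond the design simplifications listed above: the synthetic
climatology is an idealization (see "Synthetic forcing") and full-scale
diversity maxima under observed forcing additionally depend on the
unconstrained k and on the KDE/presence conventions; the Euler biomass
update with clipping is first-order and relies on the dt-halving check
rather than error control; δTopt is a relative measure and inflates for
species with small fundamental optima even beyond the |T_Fopt| < 1 °C
flag, so cross-species means of δTopt are best read jointly with the
absolute shift T_Ropt − T_Fopt.
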