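# Methods

## Model and assumptions

The package implements a deliberately minimal transient biofilter model:

- **Gas phase.** Plug flow, no axial dispersion, isothermal, single
  pollutant. The column of height *H* is discretized into *n* well-mixed
  segments (tanks in series); each segment exchanges pollutant with the
  biofilm through an interfacial flux term.
- **Biofilm.** A planar slab of thickness δ with Fickian diffusion
  (effective diffusivity *De*) and first-order degradation. The first-order
  constant k₁ = µm·X/(Y·K) is the low-concentration linearization of Monod
  kinetics, valid for Cl ≪ K; oxygen limitation, substrate inhibition and
  multi-pollutant interaction are outside scope. The gas–biofilm interface
  is at Henry equilibrium (Cl(0) = Cg/H′) and the media support is
  impermeable (zero flux at x = δ). The resulting profile and its
  interfacial gradient −(φCg/H′)·tanh(φδ), φ = √(k₁/De), are closed form.
- **Quasi-steady biofilm.** The biofilm profile is assumed to equilibrate
  instantly to the local gas concentration; only the gas phase carries
  dynamics. This is the standard assumption for thin (tens of µm) films
  whose internal diffusion time δ²/De (~12 s here) is short compared with
  bed-scale transients (1/γ2 ≈ 2 s per segment × n segments, plus start-up
  horizons of minutes).

Each segment then obeys
dCgi/dt = ug/(ε·Δh)·(Cg,i−1 − Cgi) − (De·As·φ·tanh(δφ)/(H′·ε))·Cgi, which
collapses into the two parameters γ1 (per-segment steady attenuation,
dimensionless in (0, 1]) and γ2 (per-segment rate constant, s⁻¹), linked by
γ2 = ug/(γ1·ε·Δh).

## Two solvers and the gap between them

- The **analytic product form** Cge = Cg0·γ1ⁿ·(1 − e^(−γ2 t))ⁿ is exact
  for n = 1 and exact in the t → 0 and t → ∞ limits for any n. At
  intermediate times and n > 1 it slightly *leads* the true cascade
  transient, because it treats every segment as already settled with
  respect to its upstream neighbour. The test suite quantifies this gap
  (it is a few 10⁻⁴ g·m⁻³ for the benzene base case) rather than hiding
  it, and asserts that it closes at both time extremes.
- The **cascade ODE solver** propagates the full linear system exactly:
  within each constant-inlet interval the affine system
  dC/dt = A·C + b·u is advanced with `expm(A·dt)` applied to the deviation
  from the interval's fixed point (Ci = γ1ⁱ·u). There is no time-step
  truncation error; trajectories are exact to round-off for any
  piecewise-constant schedule. An earlier design considered per-segment
  exponential updates with the upstream value frozen over short sub-steps;
  the matrix-exponential route was chosen instead because it removes the
  splitting error entirely at negligible cost (the system matrix is n × n
  bidiagonal, n ≈ 10). The solver is cross-checked against
  `scipy.integrate.solve_ivp` in the tests.

The two printed forms of γ2 in the source material are typographically
ambiguous; dimensional analysis forces γ2 = ug/(γ1·ε·Δh), and equality of
this compact form with the full form is asserted to 10⁻¹² relative.

## Parameters, units, defaults

| Parameter | Meaning | Unit | Benzene default |
|---|---|---|---|
| H′ | dimensionless Henry constant Cg/Cl | – | 0.23 |
| µm | max specific growth rate | s⁻¹ (accepts h⁻¹) | 0.68 h⁻¹ |
| K | Monod half-saturation | g·m⁻³ | 12.22 |
| Y | yield coefficient | – | 0.708 |
| Dw | aqueous diffusivity | m²·s⁻¹ | 1.04·10⁻⁹ |
| Xv | biofilm density | kg·m⁻³ | 100 |
| As | biofilm area per bed volume | m⁻¹ | 40 |
| δ | biofilm thickness | m | 5·10⁻⁵ |
| H | bed height | m | 1.5 |
| n | segment count | – | 10 |
| ε | void fraction | – | 0.35 |
| Cg0 | inlet concentration | g·m⁻³ | 0.13 |

Internal time unit is seconds throughout; µm may be supplied in h⁻¹ and is
converted exactly (÷3600), so both entry routes give bit-identical derived
parameters.

**Unit conventions for the biofilm density.** The diffusivity correlation
consumes X in kg·m⁻³ (its native calibration); the first-order rate
constant consumes biomass in g·m⁻³ (X = 1000·Xv) so units cancel against K.
Only this pairing reproduces the published benzene validation column, which
is how the convention is pinned down.

**Void fraction.** ε is not part of the published parameter table. It
enters only γ2, so every steady-state output is provably independent of it
(asserted numerically in the suite); the default 0.35 is a typical packed
organic-media value and only shifts transient time axes. Published
transient figures can therefore not be reproduced exactly without knowing
ε, and no attempt is made to fit it.

**Diffusivity correlation validity.** De/Dw = 1 − 0.43X^0.92/(11.19 +
0.27X^0.99) is non-monotonic: it reaches a minimum (≈0.052) near
X ≈ 580 kg·m⁻³ and then rises back toward 1, which would mean denser
biofilms diffuse *better* — clearly outside the correlation's calibration.
The package therefore restricts the correlation to its physically sensible
monotone branch and raises a domain error for X > 580.489 kg·m⁻³. The
bracket itself never becomes negative, so a positivity check alone would
never reject any density.

## Numerical choices

- The biofilm profile is evaluated in the grouping
  Cg/[H′(1+e^(−2δφ))]·[e^(φ(x−2δ)) + e^(−φx)]: all exponential arguments
  are ≤ 0 on the slab, so there is no overflow at large δφ.
- tanh is saturated to exactly 1.0 for arguments above 20 (beyond double
  resolution anyway), making the deep-biofilm limit explicit.
- The ODE solver's output grid defaults to t_end/500; breakpoints of the
  inlet schedule are always hit exactly (they are merged into the event
  grid), so step changes are not smeared.
- Initial condition defaults to a clean bed (all segment concentrations
  zero), the condition implied by the analytic form; any non-negative
  state vector may be supplied instead.
- Profile export uses 101 grid points on [0, δ] by default; `repr`-exact
  floats are written so re-reads are lossless.
- Random inlet schedules draw i.i.d. uniform levels on [Cmin, Cmax] at a
  fixed dwell time from `numpy.random.default_rng(seed)`; a seed is
  mandatory, making every run bit-reproducible.

## Validation data and what it shows

The bundled benzene validation compares the model's steady-state outlet
against six published experimental operating points (EBRT 60–186 s, inlet
0.13–0.37 g·m⁻³). Comparisons are made after rounding the model outlet to
two decimals — the precision of the published table — and percent errors
100·(model − exp)/exp are computed from the rounded value to match the
published error convention. One published error cell (EBRT 90 s, −6.2 %) is
inconsistent with its own rounded concentrations (0.14 vs 0.15 gives
−6.7 %); the package asserts the outlet cell and reports, but does not
assert, that error cell. Toluene comparison rows are bundled as data only:
the toluene kinetic parameters are not part of the bundled tables, so the
toluene validation runs only with user-supplied parameters.

Because all inputs are scalar physical constants, there is no synthetic
data generation beyond the seeded random inlet schedules; passing tests
show internal consistency of the solution chain and agreement with the
published benzene column, not that the first-order/quasi-steady
assumptions hold for any particular real biofilter (high inlet loads
violate Cl ≪ K, and oxygen limitation is not modelled).

## Known limitations

- First-order kinetics only; no zero-order or full-Monod biofilm regimes.
- Single pollutant; no oxygen limitation, inhibition or co-substrate
  effects.
- No axial dispersion; the tanks-in-series count n is a resolution knob
  (default 10), not a fitted dispersion surrogate.
- No parameter estimation/calibration machinery; parameters are taken as
  given.
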