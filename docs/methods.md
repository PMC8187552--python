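# Methods

This note documents the models, conventions, parameter choices and
limitations behind `cnpbudget`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Flux model

Diapycnal diffusivity follows the Osborn balance, K_z = Γ ε / N², with the
canonical mixing efficiency Γ = 0.2 (configurable). ε (W kg⁻¹) is an input
from microstructure instruments; N² (s⁻²) is taken from the turbulence
file when supplied (instruments report their own stratification), else
computed from the cast as N² = (g/ρ₀) ∂ρ_θ/∂z with g = 9.81 m s⁻²,
ρ₀ = 1025 kg m⁻³ and depth positive downward, so a statically stable
column gives N² > 0. Potential density comes from the UNESCO EOS-80
one-atmosphere polynomial (Millero & Poisson 1981); at ≤ 200 dbar the
adiabatic correction to in-situ temperature is ≲ 0.02 °C, far below the
0.2 °C mixed-layer criterion, so bottle/CTD temperature is used as
potential temperature directly.

Concentrations are linearly interpolated onto the 5-m K_z grid (no
extrapolation beyond the sampled range) and differentiated with a centred
stencil (one-sided at the ends). Centred differencing is the symmetric
choice on a piecewise-linear interpolant: at a sampling kink it returns
the mean of the adjacent slopes. The flux F_X = K_z ∂X/∂z is reported in
mol m⁻² d⁻¹ (× 86 400 from SI), positive where concentration increases
with depth, i.e. positive = upward supply.

Layer means are unweighted arithmetic means over valid 5-m points with
depth strictly inside (top, bottom]; grid points where N² ≤ 0 are masked
(never produce infinities) and the masked fraction is reported. Negative
layer means are retained — subsurface fluxes are generally but not always
positive. Fluxes above the MLD are computed for inspection but excluded
from budget terms: within the mixed layer they redistribute rather than
import nutrients.

## Per-cast hydrography

* **MLD**: shallowest depth where θ(z) = θ(10 m) − 0.2 °C, scanning
  downward from 10 m with linear θ–z interpolation; if the criterion is
  never met the deepest sample is returned with a flag. Linear (rather
  than nearest-level) interpolation between samples is a documented
  choice; the criterion itself does not specify one.
* **EZD**: shallowest depth where PAR = 1 % of the surface value,
  log-linearly interpolated since PAR decays approximately exponentially;
  on an exactly exponential profile the analytic depth ln(100)/k is
  recovered to numerical precision.
* **Detection substitution**: nanomolar N+N below 5 nM (combined
  nitrate 3 + nitrite 2 nM limits) is set to 5 nM, PO₄ below 3 nM to 3 nM.
  The operation is idempotent and leaves other constituents untouched.
* **Salinity normalisation**: x · S_ref / S with S_ref = 34.91, removing
  evaporation/precipitation dilution before inventories are compared.
* **Inventories**: trapezoidal rule on the piecewise-linear profile, with
  endpoint values interpolated (or constant-extended when an integration
  bound lies outside the sampled range — only relevant for degraded
  casts, since standard casts start at 0 m). Inventories are additive
  over contiguous layers by construction.

## Budget closure

The year is partitioned by monthly SST into four regimes with half-open
bins (−∞, 24), [24, 26), [26, 28), [28, ∞) °C — lower edge inclusive, a
convention the source framework leaves unstated — and days per regime are
months × 365/12 (uniform month length; the regime days always sum to 365).

Per element, Fup is Σ over regimes of (regime-mean daily 100–200 m flux)
× (regime days), with the CI of each term scaling by its day count and
terms combined in quadrature; a regime with days but no flux observations
contributes zero and logs a warning. Fat is: C — Σ regime mean monthly
air–sea CO₂ flux × months (positive into the ocean; individual regimes
may outgas); N — (N₂ fixation + N deposition) × 365; P — deposition × 365.
Lateral fluxes and transport by vertically migrating diatoms are zero by
default with a config override, reflecting the absence of horizontal
surface gradients and consistently low migrating-diatom abundance in the
study region. NCP-Y = Fup_Y + Fat_Y is an exact identity as computed.

Microbial demand uses the community stoichiometric ranges C:N 6–11 and
C:P 107–243: MD-N = [NCP-C/11, NCP-C/6] and MD-P = [NCP-C/243, NCP-C/107].
RF = MD/NCP per element. Full precision is kept internally; the reporting
layer rounds to 2 significant figures, matching the field's convention.

## Uncertainty

Reported quantities are means with 95 % CI half-widths. Sample means use
Student-t intervals by default (regime samples are small, n ≈ 3–25); a
normal-critical-value variant is available since the choice is not
dictated by the framework. Propagation follows quadrature:

* sum/difference: E = √(E₁² + E₂²)
* quotient: E = (M₁/M₂) √((E₁/M₂)² + (E₂/M₂)²)

The quotient rule normalises **both** error terms by the denominator mean
M₂. Standard relative-error propagation would use E₁/M₁ in the first
term; this package defaults to the M₂-normalised form for fidelity to the
established reporting chain, exposes the standard form behind a flag
(`quotient_form="standard"`), and debug-logs when the two differ by more
than 1 %. Note the M₂ form produces very wide CIs on ratios whose
denominator is small relative to the numerator's CI (e.g. NCP-C : NCP-P);
this is a property of the rule as published, not a bug.

Regime comparisons use a tie-corrected Kruskal–Wallis H (scipy) with
chi-square p, followed by Dunn's z post hoc on mean ranks (implemented
here, cross-checked in the tests against an independent re-derivation);
four regimes give six pairwise contrasts judged at 0.05/6 = 0.0083.

## Synthetic scenario

The generator emulates the statistical structure of a 13-cruise, 5-station
time series near 24°N with nine bottle depths (0–200 m). What it emulates:

* **SST**: an annual sinusoid between 20.21 °C (January) and 30.51 °C
  (July), sampled at cruise dates spread evenly over April 2014–May 2019,
  with 0.3 °C cast-to-cast jitter. The default monthly series populates
  all four SST regimes (5/2/2/3 months).
* **Seasonal anomalies**: nutrient and DIC surface anomalies are
  phase-locked to SST through a saturating (logistic) cool-season index
  with midpoint 26 °C and width 0.5 °C, plateauing at 1 in the SST<24
  regime and 0 in the SST>28 regime. The plateau form makes each
  configured amplitude equal, by construction, to the cool-minus-warm
  regime contrast that the inventory-difference operation estimates —
  i.e. the generator's parameters are directly recoverable. A raw
  sinusoidal anomaly would leave regime means partway up the cycle and
  systematically under-recover the configured amplitude.
* **Vertical structure**: constant nanomolar surface nutrients above the
  100-m nutricline (warm floors 5 nM, winter increases +20 nM N+N,
  +15 nM PO₄), rising linearly to micromolar values at 200 m
  (2500 nM N+N, 180 nM PO₄ — chosen so the implied annual upward fluxes
  sit in the observed range for the region); DIC 1.96 mol m⁻³ above
  100 m rising to 1.99 at 200 m, plus a cool-season surface enrichment
  (uniform over 0–100 m, relaxing to zero at 200 m) sized to the
  configured 1.9 mol m⁻² drawdown; DOP declining 120 → 80 nM (small
  negative gradient, near-zero DOP flux); TDP = DOP + PO₄ by
  construction; TPP with a winter increase. Temperature is mixed to a
  seasonal MLD (30 m warm, 95 m cool) then linear to 15 °C at 200 m;
  salinity stays within ~0.1 of 34.91.
* **Turbulence**: ε i.i.d. log-normal per 5-m bin (median 2 × 10⁻⁹
  W kg⁻¹, log-sd 1.0 — typical open-ocean thermocline values), N² from
  the smooth T/S profiles as an instrument would report.
* **Noise**: Gaussian measurement noise with CV 2 % for nanomolar
  nutrients, sd 2 × 10⁻³ mol m⁻³ for DIC (the stated analytical
  precisions), CV 4.3 % for TPP and 5 % for DOP; plus cast-to-cast
  variability (DIC offset sd 5 × 10⁻³ mol m⁻³, log-normal nutrient scale
  sd 0.10) exposed as free parameters because within-regime flux variance
  is not pinned down by the source framework.

What it does **not** emulate: physical circulation, eddies and typhoons
(episodic supply events are absent, so real upward fluxes are likely
undersampled in the same way shipboard observations are), spatial
covariance between stations, seasonal N₂-fixation cycles, or any
covariance between ε and stratification. Tests passing on synthetic data
therefore demonstrate the correctness of the computational chain and
parameter recovery under the assumed statistical structure — not the
oceanographic accuracy of any particular flux value.

Atmospheric forcing defaults: N₂ fixation 2.2 × 10⁻⁴ ± 6.4 × 10⁻⁵,
N deposition 2.7 × 10⁻⁵ ± 5.7 × 10⁻⁶ mol N m⁻² d⁻¹, P deposition
8.4 × 10⁻⁸ ± 5.4 × 10⁻⁸ mol P m⁻² d⁻¹; per-regime monthly CO₂ fluxes
(0.10/0.07/0.045/−0.013 mol C m⁻² mo⁻¹, cool → warm) chosen so the ocean
is a net annual sink with summer outgassing, at a magnitude consistent
with the region's annual carbon uptake.

## Numerical choices and degenerate inputs

* Bins, layers and intervals are half-open with the convention stated at
  each definition; exact threshold hits (θ exactly 0.2 °C down at a
  sample, PAR exactly 1 %) return the sampled depth without a flag.
* N² ≤ 0 masks K_z rather than producing infinities; empty layers return
  a flagged empty result rather than NaN arithmetic.
* Single-sample means carry a flagged (NaN) CI; propagation treats an
  undefined CI as zero-width and the flag travels with the value.
* Means and inventories never clip: negative fluxes and inventory
  differences pass through to the report.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; a fixed seed gives byte-identical CSVs and
  JSON reports.
* Problem sizes: the default scenario (65 casts × 9 depths, 65 × 40-point
  turbulence profiles) runs the full pipeline in about a second; the
  acceptance script averages the drawdown recovery over four replicate
  scenarios, its sampling error being ~5 % of the configured effect at
  that size.

## Known limitations

* The quotient CI rule (M₂-normalised) inflates ratio CIs when the
  denominator is small; use `quotient_form="standard"` for conventional
  relative-error propagation.
* The Friedman paired station comparison used to justify pooling stations
  is out of scope; the pipeline pools stations unconditionally.
* MLD interpolation between bottle levels is linear in θ–z; on coarse
  grids this can differ by a few metres from higher-resolution CTD
  criteria.
* ε spectral processing is out of scope: ε is an input, and instrument
  noise floors or despiking must be handled upstream.
* The pCO₂ diagnostic model behind the air–sea CO₂ fluxes and satellite
  SST retrieval are inputs, not implemented here.
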