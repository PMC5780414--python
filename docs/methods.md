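# Methods

## The rate calculus

`darkcarbon` reduces three shipboard assays to volumetric carbon rates
(µg C m⁻³ d⁻¹) and composes them into a water-column budget.

**Blank subtraction.** Every radiotracer estimate starts from
net DPM = mean(replicates) − mean(killed blanks). Negative nets, routine in
blank-dominated bathypelagic samples, are clamped to zero with a logged
warning: the underlying rates are physical non-negatives, and carrying
negative rates downstream would corrupt integrals and ratios. Replicate
scatter is summarised as the sample standard deviation of the replicate
DPM; because every estimator below is linear in net DPM, the sd propagates
by the same deterministic scaling — the only propagation consistent with a
linear estimator.

**Heterotrophic production (PHP).** For a leucine micro-incubation
(defaults: 1.7 mL, 20 nmol L⁻¹ hot leucine, 144.2 Ci mmol⁻¹, 2.5 h):

    leu incorporated (nmol) = netDPM / (2.22×10⁶ DPM µCi⁻¹) / SA
    PHP = leu / volume / time × CF × 10³        [µg C m⁻³ d⁻¹]

CF is the leucine-to-carbon factor in kg C mol⁻¹: a base 1.5 kg C mol⁻¹
multiplied by the isotope dilution ID of the tracer. The base factor is a
named constant (`leu_to_carbon_base`), inferred from the campaign
calibration CF = 1.92 at ID = 1.28, not a hard-coded literal. The 20
nmol L⁻¹ addition is treated as saturating; no saturation correction is
applied.

**Isotope dilution (kinetic method).** From a series with fixed hot
leucine (5 nmol L⁻¹) and graded cold additions A, the fraction of added
label incorporated f obeys t/f = (A + hot + K_t+S_n)/v_max for saturable
uptake. OLS of t/f on A gives slope 1/v_max and intercept
(K_t+S_n + hot)/v_max, so

    ID = (K_t+S_n + hot) / hot = intercept / (slope × hot).

The published method has variants; this linearisation is the fixed,
documented definition here and is exercised end-to-end through the forward
simulator. A negative fitted K_t+S_n (noise around a zero ambient pool)
clamps ID to 1 with a warning — dilution cannot concentrate. The estimate
is invariant to rescaling all velocities by a positive constant.

**Dark DIC fixation (ABD).** For a bicarbonate incubation (defaults:
40 mL, 0.25 µCi mL⁻¹ added at 56.0 mCi mmol⁻¹, 72 h in the dark):

    f = netDPM / (added activity × volume × 2.22×10⁶)
    ABD = f × DIC × 12 µg µmol⁻¹ / time × 10⁶   [µg C m⁻³ d⁻¹]

The added tracer is only 4.464 µmol L⁻¹ against an ambient DIC of
2.19–2.47 mmol L⁻¹ (a 490–553-fold dilution), which is why the fraction
fixed is scaled by the full ambient pool. DIC is an input, never computed
from pH/alkalinity; a record without DIC raises rather than assuming a
basin default silently. Production of dissolved ¹⁴C-labelled exudates and
viral-lysis losses are not modelled: the estimate is particulate fixation.

**Respiration (PR).** ETS assays measure potential electron flux at the
assay temperature. Conversion:

    PR_O₂ = ETS × exp((E_a/R)(1/T_assay − 1/T_insitu)) × (PR:ETS)
    PR_C  = PR_O₂ × (122/172) × 12                 [µg C m⁻³ d⁻¹]

with E_a = 15.8 kcal mol⁻¹, R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, PR:ETS = 0.68.
The O₂:C ratio is not uniquely standardised in the literature; the default
is the classical 122/172 remineralisation stoichiometry and is
configurable. The Arrhenius correction is its own inverse under
temperature swap, which the simulator exploits. Raw tetrazolium chemistry
(absorbance → O₂ equivalents) is upstream of this contract: inputs are
already O₂-rate units. The assay temperature is campaign metadata and must
be supplied explicitly; no default is assumed.

**Derived metrics.** PCD = PHP + PR; PGE = PHP/(PHP+PR) ∈ [0,1];
cell-specific rates csX = X·10⁹ / (PA·10⁶) fg C cell⁻¹ d⁻¹; ABD:PCD in
percent; generation time bracket = (cell carbon)/csABD for an assumed
10–20 fg C cell⁻¹. Absent ("ND") inputs yield absent outputs everywhere —
never zeros. A reference conversion for a cultured ammonia-oxidising
archaeon turns a protein-normalised fixation rate into fg C cell⁻¹ d⁻¹
via protein per cell = dry mass / cell density × protein fraction.

## Depth integration

Integrals run from the aphotic top (default 200 m) to the seabed:
trapezoids over the usable discrete samples plus a constant extension of
the deepest rate to the bottom depth. No extrapolation is performed above
the shallowest usable sample (on the bundled campaign the shallowest
aphotic sample is always exactly 200 m, so the choice is invisible there,
but it is defined for user data: integration starts at the sample, with a
warning). Samples that are ND or carry a matching exclusion flag are
skipped and recorded on the result.

Uncertainty: each sample's total trapezoid weight w_i is half the span of
its adjacent intervals (plus the bottom extension for the deepest sample);
the integral sd is sqrt(Σ(w_i·sd_i)²), treating depths as independent.
Published column uncertainties for this campaign are not reproducible by
any standard propagation; the bundled table therefore keeps them as
"as-published" metadata while the package reports the delta-method value.

The ST6 3,400 m sample sits at a deep hypersaline anoxic lake (DHAL)
interface, an anomalously active redoxcline: it carries the
`DHAL-influenced` flag and is excluded from column integrals and basin
summaries by default (including it inflates the ST6 column integral by
roughly a quarter, inconsistent with the published 864 mg C m⁻² d⁻¹).
Exclusions are always logged, never silent.

## Basin reporting

The dark:photic comparison divides each station's integrated ABD by the
photic primary production above it. Two literature PhPP columns exist
(in-situ ¹⁴C and a 3-D biogeochemical model); published range statements
mix the denominators, so `regional_summary` reports the full ratio matrix
(both columns × all stations) and lets the reader see which cells
correspond to quoted bounds rather than replicating an asymmetric
selection silently. Range summaries (`summarize_range`) report extrema
with provenance (station, depth) and honour exclusion flags; the Atlantic
reference station ST1 is excluded from "Mediterranean" ranges by
convention (`datasets.MEDITERRANEAN_STATIONS`). Regenerated report tables
round csPCD/csABD to two decimals, the published precision, so table
regeneration is bit-comparable.

Known discrepancies, by design: the published ABD:PCD maximum of 62 %
cannot be derived from any bundled row (the empirical maximum is ≈55 % at
ST6, 500 m); the package reports the computed maximum. Likewise a
published volumetric ABD range of 133–370 µg C m⁻³ d⁻¹ is inconsistent
with the bundled per-depth table (48–411), which is kept authoritative.

## The forward simulator

`make_scenario` draws ground-truth profiles from templates:
`mediterranean-deep` (true values uniform inside the observed envelopes —
ABD 48–411, PR 204–1761, PHP 3.8–125.3 µg C m⁻³ d⁻¹, PA 48–460×10³
cells mL⁻¹, abundance decreasing downward, warm 13.4–14.8 °C water, DIC
2.19–2.47 mmol L⁻¹), `atlantic-cold` (cold bottom water, collapsed deep
fixation) and `uniform` (constant profiles for exact arithmetic).

`simulate_campaign` emits, per depth, incubation records whose *expected*
net DPM is the analytic inverse of the rate estimators at the true rate,
ETS duplicates inverted from true PR, duplicate DAPI counts around true
PA, and one dilution series consistent with a configured true K_t+S_n
(default 1.4 nmol L⁻¹, i.e. ID 1.28). Noise defaults: multiplicative
lognormal with mean 1 and CV 5 % per replicate (chosen because observed
replicate CVs of 3–15 % exceed Poisson expectation at these DPM levels —
pipetting/filtration dominates; a `poisson` counting model is available),
and blanks with a positive mean (100 DPM) so the clamping path of the
blank subtraction is exercised. All randomness flows from one
`numpy.random.default_rng(seed)`: identical scenarios give identical
output.

What passing recovery tests show — and what they do not: the estimators
invert their own forward model exactly (zero noise) and without bias
(~0.3 % at 5 % CV over 200 seeds, ~1 s of compute on the constant-profile
template), and the kinetic ID fit is unbiased though noisy (single-series
spread ≈ 1.0–1.5 at 5 % CV). The simulator does not model pressure
effects on decompressed samples, bottle effects, dissolved-label leakage,
non-saturating substrate additions, or any hydrodynamics or community
dynamics — agreement on synthetic data validates the arithmetic and the
plumbing, not those field-sampling assumptions.

## Numerical and design choices

- Carbon molar mass fixed at 12.0 µg µmol⁻¹ (not 12.011): matches the
  precision of all derived reported values; configurable.
- Depths are metres below surface, positive down; profiles strictly
  ascending; bottom depth bounds the deepest sample.
- Ties/degenerate inputs: a single usable sample integrates as rate ×
  (bottom − depth); a constant time course fits slope 0 with correlation
  reported as 0; a zero-variance dilution series is rejected as
  degenerate.
- Linearity acceptance for time courses uses Pearson |r| ≥ 0.98 by
  caller convention; the fit itself is plain OLS (scipy.stats.linregress).
- Test problem sizes: Monte-Carlo recovery uses 200 seeds of the 3-depth
  uniform template (the bias estimate's MC error is then well under the
  1 % assertion); the dense-grid integration oracle uses ~8k nodes plus
  the knots. Both reflect what the statistics need, and the full suite
  runs in a few seconds.

## Limitations

- PGE, PCD and the cell-specific metrics inherit every conversion-factor
  uncertainty multiplicatively; the package propagates replicate scatter
  only, not calibration uncertainty in CF, PR:ETS or the O₂:C ratio.
- The bottom-extension convention biases integrals high when the deepest
  sample overestimates near-bottom rates; no curvature-aware or spline
  variant is provided.
- No seawater carbonate-system chemistry, no hypothesis testing, no
  partitioning of dark fixation into chemoautotrophic vs anaplerotic
  components.
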