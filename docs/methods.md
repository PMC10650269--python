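# Methods

## Competitive-PCR quantification

### Model

A cPCR reaction co-amplifies the target template (N_t starting copies) with
a known quantity N_c of a shorter competitor sharing both primer sites.
Assuming a shared per-cycle efficiency e over c cycles, both products grow
as N·(1+e)^c, and any late-cycle saturation (reagent exhaustion) suppresses
both proportionally. The molar product ratio therefore equals the starting
template ratio N_t/N_c at every cycle count and plateau level — this ratio
invariance is the entire basis of the method and is asserted as a property
test over randomized inputs.

Across a serial dilution of the competitor, the log intensity ratio is
linear in log competitor input with slope −1. The calibration is an
ordinary least-squares fit of y = log₁₀(I_t/I_c) on x = log₁₀(N_c) over the
usable points (both bands present; zero-intensity lanes are dropped, never
imputed; at least 3 points are required). The equivalence point
N* = 10^(−intercept/slope) is where the line crosses y = 0. A fit with
slope ≥ 0 or |slope| < 0.1 is rejected as having no competition signal. If
the crossing lies outside the sampled dilution range the estimate is still
returned but flagged `extrapolated`.

### Intensity modes

Ethidium fluorescence scales with dsDNA mass, i.e. with copies × length.
Raw band-intensity ratios of unequal-length fragments are therefore biased
by L_t/L_c relative to the molar ratio: 296/196 = 1.51 (0.179 log₁₀) for
the methanogen assay, 360/235 = 1.53 (0.185 log₁₀) for the protozoa assay.
Two modes are provided: `raw` (intensities as densitometry reports them —
what a plain ImageJ workflow yields) and `molar` (each intensity divided by
its fragment length before ratioing), with the bias between them asserted
analytically in the tests. `molar` is the recommended and pipeline-default
mode; the raw-mode equivalence point exceeds the molar one by exactly the
length ratio.

### Copy-number arithmetic and scaling

copies = ng × 6.022×10²³ / (L × 10⁹ × 650), with 650 g/mol/bp the mean
molar mass of a base pair; `mass_from_copies` is the exact inverse
(round-trip to relative 1e−12). Conversion of the per-reaction equivalence
point to copies per mL of culture fluid divides by the template volume and
multiplies through an **explicit** dilution chain (every fold factor
between culture fluid and PCR template). No default chain exists because
extraction/elution volumes vary by protocol; the provenance of every factor
is recorded in the estimate.

## Densitometry

Lanes are 1-D intensity profiles (position strictly increasing, intensities
clamped non-negative). Peaks are detected with a topographic-prominence
threshold, default 2% of the profile maximum — low enough to keep faint
bands near the ends of a titration, comfortably above baseline ripple.
Exactly the two most prominent peaks are taken for a cPCR lane; identity is
assigned by migration order alone (the longer target runs less far), never
by intensity.

Background is removed with a rubber-band baseline: the straight chord
joining the profile values at the integration window's endpoints. The
window is peak ± 4·σ̂, with σ̂ estimated from the detected full width at
half maximum. At ±4σ the chord endpoints sit on true baseline (Gaussian
tail ≈ 10⁻⁴ of peak height) and the clipped tail area is ≈ 0.01%, so
zero-noise round-trips recover injected band areas to well within 2%; a
±3σ window would lose ≈ 3% through chord elevation plus clipped tails,
which is why 4 is the default (`k_sigma` is a parameter). Colliding
windows are truncated at the inter-peak minimum and flagged `overlap`.
Net intensity is clamped at zero with a flag. A grayscale gel image can be
reduced to profiles by summing a rectangular lane ROI across its width;
everything downstream is profile-based.

## Gas kinetics

Blank correction subtracts the per-time mean of the blank syringes (linear
interpolation when grids differ); blank coverage of the substrate time span
is required unless correction is explicitly waived. Slightly negative
early-time values after correction are retained — truncation would bias k
upward.

The no-lag exponential model is fitted by nonlinear least squares
(trust-region reflective) with V ∈ (0, 10·max(y)], k ∈ (0, 2] h⁻¹.
Initialisation: V₀ = 1.05·max(y); k₀ from a through-origin regression of
ln(1 − y/V₀) on t over points with 0 < y < 0.9·V₀ (the exact log-linear
transform of the model). No variance weighting is applied. t = 0 is not an
observation — the model forces y(0) = 0 implicitly and the first reading is
at 2 h. Reported k is in h⁻¹ throughout; T₀.₅ = ln2/k and G₀.₅ = V/2 are
exact functions of the estimates, so y(T₀.₅) = G₀.₅ holds to machine
precision for every converged fit. Tests verify that the NLS solution never
has worse residual sum of squares than a 200×200 brute-force (V, k)
lattice, that the fit is scale-equivariant (volumes ×c scale V and G₀.₅ by
c, leave k and T₀.₅ unchanged), and that noiseless data in the model class
are recovered to relative 1e−6.

## Fermentation bookkeeping

Degradability is (input − residue)/input, serving both dry matter (DDM)
and NDF (NDFD) given the matching masses; it is scale-invariant by
construction. The microbial-protein balance is truly degraded substrate
minus gas × a stoichiometric factor (default 2.2 mg/mL, explicit
configuration), floored at zero with a flag. Group summaries report
mean ± SEM (SEM = sd/√n, n ≥ 2) per factor level and per interaction cell
in declared level order; the mixed-model inference that would normally
follow (random run effect, multiple comparisons) is intentionally left to
dedicated statistical software — the module's tidy table is its input. The
methanogen–protozoa association is the Pearson correlation of paired log₁₀
abundances with the two-sided p from the t transform on n−2 df; zero
variance in either series is an error.

## Synthetic data

The generator emulates the study conditions end to end: competitive
amplification (34 cycles methanogen / 30 protozoa, efficiency 0.9, total
product plateau 10¹² copies ≈ 320 ng per 25 µL reaction), gel lanes with
peak position linear in −log₁₀(length) (the standard agarose mobility
approximation — only ordering and separation matter), band area
proportional to mass × gel gain with unit-mean multiplicative lognormal
noise (densitometry error is scale-dependent; default CV 0.1), a gentle
positive baseline plus white noise, ten-fold competitor dilutions from a
stated stock, gas curves on the 2–120 h 11-point grid with additive
Gaussian noise (default sd 2 mL) and optional blank drift, and a
2 species × 3 treatments × 3 runs factorial culture table with additive
species/treatment/run effects, response magnitudes typical of goat vs
camel batch cultures, and a residual correlation of 0.46 between the two
microbial populations (the protozoa-associated methanogen symbiosis).
Every generator is a pure function of (parameters, seed) and returns its
ground truth.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: primer-annealing kinetics and
cycle-to-cycle efficiency drift, heteroduplex and chimera artifacts between
target and competitor, gel smiling/curvature and detector saturation,
Poisson sampling of low-copy templates, and non-exponential (lagged or
multi-pool) gas dynamics. Estimates on real gels inherit whatever biases
these introduce; the package quantifies the arithmetic faithfully, not the
chemistry.

## Problem sizes and numerical choices

The shipped test suite and acceptance script use 200 simulated dilution
series and 100 gas curves for Monte-Carlo recovery, 100 randomized lanes
for densitometry round-trips and 500 draws for the correlation simulation —
sizes at which the binomial/median acceptance margins are comfortably
resolved while the whole suite runs in seconds. Degenerate inputs are
handled explicitly: zero total template yields zero product, lanes with an
undetectable band become flagged unusable points rather than errors,
all-zero or decreasing gas signals are fitted but flagged, and empty
summary cells are reported with n = 0. Ties in peak prominence are broken
by position order; the calibration's minimum |slope| of 0.1 guards against
fitting noise-flat ratio series.
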