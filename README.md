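# cpcrquant

Quantification toolkit for rumen microbial ecology from two classic
wet-lab readouts:

1. **Competitive PCR (cPCR) enumeration.** An unknown target (here the
   methanogen 16S rRNA gene, 296 bp, or the protozoa 18S rRNA gene, 360 bp)
   is co-amplified with a serially diluted, size-shortened internal
   standard (196 / 235 bp competitor) sharing the same primers. Band
   intensities are read off the agarose gel by densitometry and the
   log intensity ratio is regressed on log competitor input,

   y = log₁₀(I_target / I_competitor) = a + b·log₁₀(N_competitor),

   with slope b ≈ −1 when both templates amplify with equal efficiency.
   The *equivalence point* N* = 10^(−a/b) — where the fitted line crosses
   y = 0 and the two products are equally abundant — equals the target's
   starting copy number, converted to mass via
   copies = ng × N_A / (L × 10⁹ × 650) and scaled to log₁₀ copies per mL
   of culture fluid through an explicit dilution chain.

2. **In vitro gas-production kinetics.** Cumulative gas from buffered
   rumen-fluid incubations (500 mg DM substrate, blanks subtracted,
   readings at 2–120 h) is fitted with the no-lag exponential model
   y(t) = V(1 − e^(−kt)); derived statistics are the half-time
   T₀.₅ = ln2/k and half-time volume G₀.₅ = V/2, plus the CH₄ fraction
   of total gas.

Around these sit fermentation bookkeeping (dry-matter and NDF
degradability from residues, the microbial-protein balance
"truly degraded − 2.2 mg/mL × gas", factorial mean ± SEM summaries, the
methanogen–protozoa Pearson correlation) and a synthetic-data generator
that simulates competitive amplification, gel lanes, gas curves and
factorial culture tables with stored ground truth, so every stage is
verifiable by parameter recovery. It is written for researchers in rumen
microbiology and feed evaluation who want these computations scripted,
tested and reproducible rather than spread across ImageJ sessions and
spreadsheets.

## Worked example

The demo runs the full pipeline on synthetic data shaped like a
two-species (goat, camel) × three-diet × three-run batch-culture study,
with both cPCR assays and an 18-syringe gas experiment:

```bash
cpcrquant demo --out demo_out
```

```
methanogen goat   true 5.30  estimated 5.31  error +0.008 log10
methanogen camel  true 4.60  estimated 4.63  error +0.025 log10
protozoa   goat   true 5.40  estimated 5.40  error +0.005 log10
protozoa   camel  true 4.70  estimated 4.72  error +0.021 log10
gas fits: 18 syringes, median |V error| 1.0%, median |k error| 2.4%
culture: n=54, methanogen~protozoa r=0.84
```

Each population line compares the log₁₀ copies/mL injected by the
generator with the value recovered through gel rendering, densitometry,
calibration and the dilution chain — all four estimates land within
0.03 log₁₀ of truth under 10% densitometry noise. The gas line shows the
median relative error of the fitted asymptotic volume V and rate k over
all syringes; the culture line is the Pearson correlation between the two
populations across the 54 records. `demo_out/` holds every stage artifact
(`dilution_series.csv`, `band_intensities.csv`, `calibration.csv`,
`population_estimate.csv`, `gas_fits.csv`, `summaries.csv`, …) plus
`ground_truth.yaml` and `report.json`; rerunning with the same seed
reproduces them byte for byte.

The `examples/` directory has one short script per capability
(`enumerate_population.py`, `gas_kinetics.py`, `fermentation_summary.py`,
`full_pipeline.py`); the library API (`cpcrquant.build_calibration`,
`fit_exponential`, `group_summaries`, …) is the primary interface and the
CLI (`simulate`, `densito`, `enumerate`, `gasfit`, `summarize`, `run`,
`demo`) is a thin layer over it.

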