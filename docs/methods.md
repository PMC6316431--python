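# Methods

## The processing model

`somaqc` implements the standard quality-control workflow for multiplexed
aptamer-array (SOMAmer-based) proteomics. A run measures ~1300 protein
analytes per well in relative fluorescence units (RFU). Three plasma
dilutions (0.005%, 1%, 40%) bring high-, mid- and low-abundance proteins
into quantification range; every analyte belongs to one dilution bin. Each
plate carries, besides the study specimens, one buffer well (no sample),
two pooled quality-control wells and five pooled calibrator wells, plus
spiked hybridization-control reagents with known expected signals and
negative-control reagents that read assay background.

Observed signal is modelled as multiplicative bias on a latent abundance
plus additive background:

    RFU[i, a] = h_i * m_{i, bin(a)} * g_{p(i), a} * 2^latent[i, a] + bg

* `h_i` — per-sample hybridization/scanner bias, affecting everything in
  well *i* including the hybridization controls;
* `m_{i, d}` — per-sample, per-dilution-bin pipetting/concentration bias
  affecting protein analytes only;
* `g_{p, a}` — per-plate, per-analyte run (batch) effect;
* `bg` — lognormal background (mean ~300 RFU, CV 0.1), the level negative
  controls and buffer wells read.

The normalization cascade inverts these terms in a fixed order, each stage
using the controls designed for it:

1. **Hybridization-control normalization.** Per sample,
   `SF_i = median_c(reference_c / RFU[i, c])` over hybridization controls;
   applied to every analyte of the sample. Estimates `1/h_i`.
2. **Median-signal normalization.** Per plate and dilution bin, a
   reference profile is the per-analyte median over study+qc wells;
   `SF_{i,d} = 1 / median_a(RFU[i, a] / ref_a)` over the bin's protein
   analytes, applied to the sample's analytes in that bin. Calibrator
   wells are normalized against a calibrator-only profile — roles never
   mix. Estimates `1/m_{i,d}` relative to the plate's central sample.
3. **Calibration normalization.** Per plate and protein analyte, the
   median over the plate's calibrator wells is ratioed against a common
   reference (external if supplied, otherwise the cross-plate median of
   plate medians) and applied plate-wide. Estimates `1/g_{p,a}`; a
   single-plate run gets unit factors by construction.

Medians over an even count are the mean of the two central order
statistics; the scale-factor worked examples in the test suite depend on
this convention. All stages record provenance, and the ordering is
enforced: attempting a stage before its prerequisite raises.

## QC criteria

Defaults are the platform's published bands, all intervals closed:

| check | band | scope |
|---|---|---|
| hybridization + median-signal SF | [0.4, 2.5] | per sample (study/qc/calibrator wells) |
| median calibration SF | [0.8, 1.2] | per plate |
| fraction of analytes within plate median ± 0.4 | ≥ 0.95 | per plate |
| calibration SF within plate median ± 0.4 on every plate | — | per analyte |

The analyte-level rule is interpretive: the platform reports analyte pass
counts without printing the per-analyte rule, so the plate-band criterion
is applied analyte-wise. Buffer wells carry no sample; their scale factors
are meaningless by construction and they are excluded from sample QC.

## Downstream statistics

* **Quantile normalization** forces all samples to one empirical
  distribution (per-rank mean of row-sorted values); ties within a row
  receive the mean of the reference values at their occupied ranks.
  Applied to protein analytes of study samples; control analytes are
  excluded from the rank reference.
* **Log transform** base 2 by default (configurable to e/10).
* **Pearson correlation** with the two-sided p from
  `t = r*sqrt(n-2)/sqrt(1-r^2)` on n−2 df.
* **Rank-sum test**: exact p by full enumeration of the Mann–Whitney null
  (count recursion `N(m,n,u) = N(m,n-1,u) + N(m-1,n,u-n)`) when the
  combined n ≤ 14 without ties; otherwise the tie-corrected normal
  approximation with continuity correction. Two-sided
  p = min(1, 2·min(tails)). The cutoff keeps enumeration ≤ C(14,7) = 3432
  arrangements; a 10-vs-11 comparison uses the normal path.
* **Student's t** (pooled variance; Welch available).
* **Median/IQR** by linear interpolation at positions 1+(n−1)q.
* **Plate-effect check**: SVD of the column-centered QN+log2 study
  matrix; Kruskal–Wallis association of the first k=2 PC score vectors
  with plate labels; verdict "plate effect detected" iff any p < 0.01.
* **Reference-assay validation**: platform RFU and immunoassay
  concentration joined by sample, both log2-transformed, Pearson per
  analyte. With `quantile=True` the platform side is quantile-normalized
  first (the same transform sequence the other statistics use); the
  default stays plain log2 so that a noiseless perfectly-shared-epitope
  analyte gives r = 1 exactly.
* **Group comparison** reports per-group median/IQR on the RFU scale and
  tests on log2 values (rank-sum by default).

## The synthetic-data generator

The generator's defaults emulate a two-plate validation run: 11 study
samples per plate (alternating M/F), the full 1317-protein menu, 12
hybridization and 5 negative controls, an even dilution split, `h` log-
uniform on [0.5, 2], the study-well concentration bias log-uniform on
[2/3, 1.5], plate effects with SD 0.05 log2, background 300 RFU at 10% CV,
hybridization-control noise 2% CV, and one designated PSA-like analyte
carrying a +3 log2 male shift (≈8× median separation, in the spirit of the
male/female PSA contrast such a platform should reproduce).

Design choices worth stating:

* **Pipetting bias structure.** `m_{i,d} = c_i · e_{i,d}`: a per-sample
  concentration component shared across bins (the dominant real effect —
  overall protein concentration) times an optional independent per-bin
  prep error (`bin_jitter_range`, off by default). Pooled qc/calibrator
  wells hold one robotically-dispensed material, so their component is
  tight ([0.95, 1.05]). Two observed failure modes motivated this
  structure: wide calibrator-well biases propagate the calibrators'
  pipette-median drift plate-wide through the calibration ratio, and any
  systematic per-bin spread leaves a bin-level rank signature that the
  plate-effect check — which at >1000 analytes resolves consistent
  offsets down to ~σ/√p ≈ 0.004 log2 — flags in every run, branding
  clean runs as batch-affected.
* **Latent abundances.** Per-analyte means log2-uniform on [12, 16]
  (signal well above the ~300 RFU floor, as for quantifiable plasma
  proteins) and SDs uniform on [0.05, 0.25]. The SD range is deliberately
  conservative: the median-of-ratios scale factor carries a sampling
  floor of ≈1.25·σ̄·ln2/√(analytes per bin), and the pipetting-recovery
  tolerance of 3% CV must hold on a 200-analyte menu (~67 per bin).
  Clinical cohorts show larger biological CVs for many proteins; what the
  conservative setting demonstrates is the *technical* recovery of the
  cascade, not population-scale biology.
* **Controls.** Hybridization controls carry only `h` and 2% noise (they
  are spiked after dilution); negative controls and buffer wells carry
  only background. Calibrator wells share one pooled latent profile
  across all plates, so plate-to-plate differences in their medians
  measure `g` directly.
* **Background is added, not multiplied**, so weak analytes saturate at
  the negative-control floor.
* **Immunoassay emulation.** For a chosen analyte, the reference assay
  sees `λ·latent + (1−λ)·z` (z an independent draw with the analyte's
  marginal moments) and multiplicative noise; λ is the shared-epitope
  fraction. λ≈1 reproduces the near-perfect agreement seen for
  well-behaved targets; λ≈0.2 the weak agreement of multi-isoform
  targets. With λ = 0.97 and σ at the top of the default range the
  expected r is ≈0.95; with λ = 0.2, ≈0.23.

What the generator does **not** emulate: saturation/hook effects at the
top of the dynamic range, analyte cross-reactivity, correlated biology
between analytes (latents are independent), missing wells, and clinical
covariate structure. Passing tests therefore demonstrate the pipeline's
algebra and its error control under the stated noise model, not
performance on any clinical cohort.

## Scenario sizes and numerical choices

Simulation-based checks run at sizes that keep the whole suite and the
acceptance script in tens of seconds: recovery scenarios use 2 plates ×
40 study samples × 200 analytes; correlation-regime and sex-contrast
cohorts use n = 21–22 (the scale such validation studies actually use)
with 200 runs for rate estimates; the null-calibration check uses 2000
replicates at n = 10 vs 11. Plate-effect stress scenarios inject
per-analyte run effects (SD 0.5 log2) with per-sample biases disabled, so
each stage's contribution is identified in isolation; the uniform-1.3×
cross-plate scenario likewise runs with other biases off, giving the
predicted pre-calibration gap of log2(1.3) ≈ 0.379.

Numerics: scale factors are validated strictly positive and finite;
nonpositive matrix entries raise with coordinates before any log; the
quantile-normalization reference uses per-rank means with stable sorting,
so its postcondition (identical sorted rows) is exact for tie-free data;
exact rank-sum counts are accumulated in float64 (max C(14,7) ≪ 2^53, so
counts are exact); RFU text serialization uses 17 significant digits and
a correctly-rounded parser, making write→read the identity.

## Known limitations

* The per-bin reference profile uses study+qc wells; plates with fewer
  than 3 such wells are rejected rather than bridged.
* The exact rank-sum path requires tie-free data; ties always route to
  the corrected normal approximation.
* Calibration without an external reference centers plates on their
  cross-plate median, which fixes relative, not absolute, scale.
* With very small per-plate cohorts, median-signal normalization leaves
  plate-level location drift of order 1.25·σ_m/√(wells per plate) that
  quantile normalization removes for rank-based downstream statistics but
  that remains in raw normalized RFUs.
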