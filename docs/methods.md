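# Methods

## Scope and model

`ddscreen` re-implements the computational core of a first-tier quadruplex
ddPCR newborn-screening assay (SMN1, RPP30, SMN2, TREC on channels 1–4)
plus its second-tier decision logic and validation statistics. Everything
upstream of droplet amplitudes (chemistry, droplet generation, optics) and
everything downstream of categorical Sanger outcomes (chromatogram
base-calling) is out of scope; the simulator and a declared outcome table
stand in for them.

### Partitioning and quantification

A well is modelled as `n` droplets of fixed volume `v` (defaults 20,000 ×
0.85 nL — instrument-typical constants, configurable, not assay-published).
For a target at reaction concentration `c`, the number of template
molecules landing in the read droplets is Poisson with mean `c·n·v`;
molecules are assigned to droplets multinomially. Quantification inverts
this: `λ = −ln(n_neg/n_total)`, `c = λ/v`, with a 95% CI from the delta
method on the negative fraction (`Var λ̂ = (e^λ−1)/n`). The estimator is
exactly the inverse of the generator, so recovery bias is pure sampling
noise — the parameter-recovery tests quantify it against the closed-form
Poisson CV, `CV(λ̂) ≈ √(e^λ−1)/(λ√n)`.

Saturation: above ~10 copies/droplet essentially every droplet is positive
and the inversion is undefined; both the generator and
`poisson_concentration` refuse that regime explicitly.

### Fluorescence model and rain

Per channel, negative droplets draw amplitudes from N(1000, 150²) and
positive droplets from N(9000, 300²) (arbitrary units chosen to give
well-separated clusters like real 2D plots). *Rain* — droplets with partial
amplification — affects a fraction (default 1%) of **template-containing**
droplets, whose amplitude is then uniform between the cluster means. Rain
is deliberately restricted to template-containing droplets: physically,
rain is delayed amplification of an occupied droplet, and this choice makes
a true blank produce zero positives (the measured limit of blank is exactly
0), which is how blank chemistry behaves when no false-positive mechanism
is modelled. An independent `false_positive_rate` (default 0) can place
empty droplets in the positive cluster to emulate contamination or
misclassification. Not modelled: droplet-volume dispersion, channel
crosstalk, amplification kinetics.

### Thresholding

The threshold is placed at the minimum of a smoothed amplitude histogram
strictly between the two dominant modes (256 bins, 5-bin moving average,
modes = local maxima ≥ 1% of peak density, ties toward lower amplitude).
Two numerical guards matter in practice:

* **Valley depth.** Histogram noise on a single Gaussian creates spurious
  local maxima; a candidate valley is only accepted if its density falls
  below half the smaller candidate peak. Otherwise the channel is treated
  as single-mode.
* **Single-mode fallback.** If the one mode sits at the negative level, the
  threshold is mode + 7 × robust spread (1.4826·MAD). The MAD (not SD) is
  essential: with a sparse positive cluster (a few dozen droplets, below
  the mode-detection floor) the mixture SD would drag the threshold into
  the positive cluster; the MAD keeps it just above the negative cluster so
  sparse positives are still counted exactly. If the single mode sits at
  the positive level (merged/saturated channel), the threshold falls back
  to the midpoint of the configured cluster means.

With rain and false positives off, the called counts equal the simulator's
per-droplet occupancy labels exactly (tested as an oracle-equivalence
property). Rain droplets follow whichever side of the threshold they land
on; no separate rain class is kept. The threshold is affine-equivariant in
the amplitude axis (tested by property).

### Units and copy number

`copies/µL blood = (copies per 20 µL well / 8 µL input DNA) × (elution µL /
3 µL blood per punch)`. The default elution volume is **50 µL**, which
reproduces the assay's published loading-window anchors (100 copies/µL
reaction ↔ 4167 copies/µL blood; 5000 ↔ ~208,350); a 15 µL elution is
available in configuration for protocols that elute in 15 µL. Copy number
is `2 · c_target/c_RPP30`; reported values round half-up to one decimal and
integer calls take the nearest integer with x.5 rounded up (the
integerization rule for exact mid-values is a package choice; real assays
report no mid-integers at these precisions).

### Screening rules

All cutoff comparisons are strict (`>`), matching the footnoted rules:
RPP30 > 4200 copies/µL blood qualifies; TREC > 57 is negative, else the
specimen is screen-positive and flagged for the re-punch/retest/recall
loop (represented as a flag, not a workflow engine). SMN1 integer copies:
0 → presumptive SMA + second tier; 1 → carrier, flagged for possible
compound-heterozygote follow-up; ≥2 → normal. Unqualified specimens are
never assigned an SMN class. Preterm specimens (< 34 weeks) are classified
against the same TREC cutoff but tagged `trec-cutoff-not-validated-preterm`
because the reference interval covers full-term newborns only.

Second tier: (assay A no amplicon, assay B homozygous c.840T) confirms SMA;
assay A yielding an amplicon with a c.840 variant while assay B is
heterozygous identifies allele dropout (first-tier false positive); any
other combination is contradictory and flagged for review.

### Validation statistics

* CV uses the n−1 SD; at mean 0 the CV is undefined and flagged, with the
  absolute SD as the reportable imprecision.
* LoB is the nonparametric 95th percentile of ≥20 blanks; LoD = LoB +
  1.6 × SD of a low-level series (the 1.6 multiplier is used verbatim as
  the assay defines it, not CLSI's 1.645); LoQ is the lowest level with
  CV < 25%. LoD ≥ LoB by construction.
* Percentiles (LoB, reference interval) use the rank-(n+1)p convention
  with linear interpolation, clamped to the observed range and recorded in
  the result's `method` string. Reference intervals on fewer than 120
  samples are flagged unreliable rather than refused.
* Levey–Jennings evaluation implements the ±2SD acceptance rule, with
  consecutive same-side 2SD violations reported as advisory only; the full
  multirule scheme is out of scope.
* Linearity is OLS of measured on expected with the standard R².

## Synthetic-data defaults as study conditions

The generator's defaults mirror the validation-study designs: 20
within-run replicates (or 5 × 5 across runs, with an optional lognormal
run-loading effect, default off so precision reflects pure Poisson noise);
eight two-fold dilution levels from 2500 down to ≈19.5 copies/µL blood in
five replicates; cohorts drawing SMN copy numbers from the screening-
population frequencies (SMN1 one-copy 2.3%, two-copy 91.4%, …) with TREC
lognormal (median 180 copies/µL blood, log-sd 0.586, putting the 2.5th
percentile near 57) and RPP30 lognormal (median 15,000, log-sd 0.5 —
unpublished; chosen so nearly all specimens qualify), and ~3% preterm.

What the simulator does **not** emulate — extraction efficiency variation,
DNA fragmentation, bench-level inter-run drift, probe-site variants —
means that passing simulated tests demonstrates the *computational*
pipeline (thresholding, Poisson inversion, unit conversion, decision
rules, statistics) is correct, not that bench-measured CVs, the TREC LoD
of a real assay, or a real population's reference cutoff would be
reproduced numerically. Those quantities are covered instead by
formula-level unit tests and distribution-level property tests.

## Problem sizes

Tests and the acceptance script run at the study design sizes (20,000
droplets/well; 20-replicate precision and blank series; 40-well dilution
series; distribution checks at n up to 100,000 on truth records without
droplet synthesis), chosen to match the validation designs while staying
cheap enough to re-run on every change.

## Known limitations

Partial intragenic SMN2 deletions, hybrid SMN1/SMN2 structures, and small
intragenic variants are invisible to this assay design; compound
heterozygotes surface only as the carrier flag. Multidimensional cluster
assignment and crosstalk compensation are not implemented — channels are
thresholded independently. The vendor software's exact smoothing is
proprietary; only cluster-consistent counting, not threshold-value
equality, is claimed.
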