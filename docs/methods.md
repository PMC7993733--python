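# Methods

## Scope and model

`epiage` implements the computational side of a small forensic epigenetic
age assay: a multiplex bisulfite PCR panel of eight age-informative
methylation markers (*ELOVL2*, *MIR29B2CHG*, *KLF14*, *FHL2*, *TRIM59*,
*EDARADD*, *ASPA*, *PDE4C*) covering 44 CpG sites, sequenced as paired-end
amplicon reads. The package covers four stages: panel definition and
validation, synthetic data generation, per-CpG methylation quantification
with QC, and tissue-specific linear age models.

## Panel

Coordinates are 1-based and fully closed (GRCh38); under this convention
every bundled marker's genomic span reproduces its declared amplicon size
(e.g. *ELOVL2* chr6:11044500–11044766 → 267 bp). Amplicon offsets are
0-based in sequencing orientation; for the minus-strand *EDARADD* amplicon
`genomic_pos = end − offset`. CpG labels follow the assay's per-marker
C1…Cn naming even where that order runs against genomic coordinates
(*ELOVL2* C9 lies 5′ of C7); the package never re-sorts them.

The bundled fixture carries real geometry, primers, and the 15 CpG
coordinates that have published positions; the other 29 CpG offsets and all
reference sequences are synthetic stand-ins with the correct lengths and
per-marker CpG counts, flagged `synthetic=1` in the CpG table
(`scripts/make_panel_fixture.py` regenerates them deterministically). Users
can substitute true sequences through the panel TSV.

Bisulfite-collapsed references use the alphabet {A,G,T,Y}: C at a target
CpG becomes Y (reads C if methylated, T if converted), every other C
becomes T. Collapsing a C-free string is the identity, and the Y count
equals the number of designated CpG offsets that carry a C.

## Simulator

The generator's defaults are the package's statement of realistic assay
conditions; they are fixed, not tuning knobs.

* **Age trajectories.** Each CpG has a mean-methylation function of age,
  linear or power-shaped, clamped to [0, 100]%. *ELOVL2* is the non-linear
  (power) marker; *ELOVL2*, *PDE4C*, *FHL2*, *TRIM59*, *KLF14*
  hypermethylate with age, *MIR29B2CHG*, *EDARADD*, *ASPA* hypomethylate.
  Lifespan spans are wide (~50–70%) for *ELOVL2*/*PDE4C*/*MIR29B2CHG* and
  narrowest for *KLF14* (~11%). The true functional forms in tissue are
  unknown at per-CpG resolution; these shapes are qualitative stand-ins
  calibrated to the markers' reported behaviour, and between-individual
  biological noise defaults to sd 2.5%.
* **PCR bias.** Observed = true + b·4p(1−p) percent (p = true/100), so the
  bias vanishes at 0% and 100% and peaks at 50%. Defaults: +3% for
  *MIR29B2CHG* and *EDARADD* (overestimation), −3% for *ELOVL2*
  (underestimation), 0 elsewhere; magnitudes are free parameters.
* **Duplicate noise.** Per-measurement Gaussian noise with sd 1.684%. For
  iid normal noise E|X₁−X₂| = 2σ/√π, so this sd targets a mean absolute
  duplicate difference of 1.9% (verified numerically in the test suite).
* **Template bottleneck.** 300 diploid template molecules per ng input with
  a 60% bisulfite recovery factor; the methylated fraction at each CpG is
  binomially resampled over the surviving molecules before depth sampling.
  This is what makes 1 ng reactions noisy at any sequencing depth.
* **Reads.** Read pairs are primer-anchored, ungapped copies of the
  bisulfite-converted amplicon: R1 the first `read_length` bases, R2 the
  reverse complement of the last. With 2×150 geometry, interiors of the 267
  bp *ELOVL2* and 215 bp *PDE4C* amplicons are covered by one mate only —
  the motivation for the 2×200 kit preset. Conversion failures leave
  unmethylated Cs unconverted at rate 1−conversion_prob (default 0.998);
  sequencing errors substitute bases uniformly at rate `seq_error`
  (default 0.001); base qualities are constant Phred 37.
* **Depth.** Pairs per amplicon are negative-binomial around
  `depth_mean × amplicon_weight` (default mean 2000, dispersion 10); the
  `design1_v2` preset down-weights *PDE4C* to emulate the unbalanced first
  design.

Not modelled: PCR cycle dynamics, chimeras/primer dimers, indels, and
run-to-run batch shifts. Passing tests therefore show the pipeline's
arithmetic and statistical machinery are correct under these artifact
models, not that the simulator reproduces any particular instrument run.

## Quantification

Reads are assigned by end-anchored ungapped matching against the collapsed
references (read T matches ref T or Y, read C matches Y only), trying both
mate/orientation pairings and requiring a unique minimal-mismatch marker.
The mismatch-fraction threshold (default 5%, applied per mate) plus the
unique-best-hit rule is the package's proxy for a mapping-quality ≥ 30
filter; base quality ≥ 30 is required at tallied positions. Matching is
numpy-vectorized (reads as byte matrices against per-position allowed-byte
tables), which keeps 10⁵-pair runs in seconds.

Beta = 100·C/(C+T) at each CpG; other bases are excluded from the
denominator but define the misincorporation rate (other/depth, a choice the
package makes since no standard definition of the denominator exists).
Depth pass/fail uses total depth (C+T+other) against the 1000-read
threshold and is a flag, never a suppression, so QC stays auditable. Both
mates of an overlapping pair are counted ("paired reads" units) with a
fragment-level option. Conversion efficiency is 100 × mean of T/(C+T) over
all covered non-CpG cytosine reference positions. Normalized read depth
divides each amplicon's depth at a representative CpG (default C1,
configurable) by the total coverage; under perfect balance every marker is
at 1/8 = 0.125.

## Age models

Modelling follows the statsmodels shape: `AgeRegression` holds the training
data, `fit`/`fit_stepwise` return an `AgeRegressionResults` with estimates,
standard errors, standardized β, adjusted R² and a `summary()` table.

* **Curve estimation.** Per CpG, linear-fit R² of age against raw beta is
  compared with beta**k over a grid k ∈ 0.5–3.0 step 0.1; ties favor the
  identity, and sites touching 0% keep the identity (the power form is
  undefined there). The grid is a stand-in since no canonical exponent
  exists.
* **Screening.** Univariate standardized β equals the Pearson correlation;
  p-values from the t distribution; zero-variance predictors are flagged
  and excluded.
* **Stepwise selection.** Probability-of-F entry/removal with p_enter =
  0.05, p_remove = 0.10 (the usual statistics-package defaults;
  p_enter ≤ p_remove guarantees termination). For single-coefficient entry
  the partial F equals the squared t statistic, so coefficient t-tests
  drive both steps. An all-null candidate set yields an explicit
  empty-model result (intercept = mean age), distinct from an error.
* **Evaluation.** MAE overall and in four age categories (1–20, 21–40,
  41–60, >60 years; the first two are the natural 20-year bins preceding
  the conventional upper two and are overridable), plus Pearson correlation
  of |error| with age. Category MAEs weighted by their n reproduce the
  overall MAE exactly. Predictions are not clamped to a plausible range.
* **Assay equivalence.** Per marker, assay B is regressed on assay A and
  the joint hypothesis (intercept, slope) = (0, 1) is F-tested
  (RSS-comparison form, robust to perfect fits); p-values are
  Bonferroni-adjusted.
* **Splitting.** Train/test splits stratify on age quartile × sex with
  largest-remainder rounding, so stratum proportions hold within ±1 sample.
* **Serialization.** Model JSON records predictors, transforms,
  coefficients, standardized β, adjusted R², training n and a panel
  checksum; prediction refuses a mismatched panel.

A note on "recovering the informative CpGs": under the default generative
functions every panel CpG is age-informative and strongly collinear within
markers, so no subset selector can (or should) return all 44. The
parameter-recovery checks therefore use cohorts where a known CpG subset
drives age and the remainder are noise — the only setting in which the
recovery target is well-defined.

## Problem sizes and numerical choices

The test suite and acceptance script run the conversion-efficiency
simulation at 10⁵ read pairs (≈1.7 million non-CpG cytosine observations,
Monte-Carlo sd ≈ 0.003%), quantification fidelity at depth 10⁵ per CpG
(binomial 3σ < 0.5%), dilution curves at 50 replicates × 3 input levels,
stepwise oracle comparisons on 20 datasets of n = 150 with 8 candidates,
and parameter recovery on 50 cohorts of n = 112 — sizes chosen so the
statistical assertions have comfortable margins while the whole suite runs
in well under a minute of compute per module. All randomness flows through
seeded `numpy.random.default_rng` streams; reruns are bit-identical.

## Known limitations

Real cohort data for the assay are not publicly deposited, so the shipped
trajectories and noise levels cannot be validated against measured
training sets, and the package makes no claim to reproduce published model
coefficients or error rates. The matcher is deliberately not a general
bisulfite aligner: no gaps, no genome-scale search, no SNP awareness.
Postmortem/cartilage/muscle tissue behaviour is available only as
attenuated-slope simulator settings.
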