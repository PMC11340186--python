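# Methods

## Problem setting

Plasma cell-free DNA (cfDNA) of a colorectal-cancer (CRC) patient is a
mixture: a dominant background shed by normal (mostly hematopoietic) cells
and a minority tumor-derived component whose weight is the *tumor fraction*
(tf), typically well below 10% in early-stage disease. Every genomic signal
a liquid-biopsy assay measures is attenuated by tf, so single-analyte tests
lose sensitivity exactly where screening matters most. `cfomics` implements
a multiomics alternative: four independent feature channels measured from
one cfDNA library — targeted DNA methylation, 5' fragment-end motifs,
arm-level copy number, and driver-gene mutations — combined by a stacked
logistic classifier.

## Feature channels

**Methylation.** For a targeted marker with `m` methylated and `u`
unmethylated molecules the methylation level (beta) is `m / (m + u)`.
Sites with total coverage below `min_molecules` (default 10 molecules; a
ratio of fewer molecules is too unstable to interpret) are treated as
missing and imputed with the training-cohort per-marker median; the medians
are frozen in the model bundle and reused on validation data so no
validation information leaks into preprocessing. Markers with no coverage
anywhere are dropped with a warning. The study design this emulates reads
methylation through a methylation-sensitive restriction-enzyme protocol;
that chemistry is upstream of this package, which starts from molecule
counts.

**5' end motifs.** Each fragment record carries the k-mer at its 5' end
(k = 4, giving 256 features, the convention of the end-motif literature;
k is configurable and the vector length is 4^k). One record contributes
exactly one motif — counting both physical ends of a duplex fragment
requires two records, which keeps the counting rule unambiguous and the
record format strand-explicit. Motifs containing N are excluded from both
numerator and denominator; the frequency vector sums to 1 over usable
fragments.

**Arm-level copy number.** Bin counts from shallow WGS are GC-corrected by
dividing each bin by the smoothed (rolling-median over GC deciles, linearly
interpolated) median count of its GC stratum — this is scale-free, so
library size cancels. Corrected values are expressed as log2 ratios to a
panel of normals (per-bin median over training controls), median-centred
per sample, and averaged per chromosome arm with bin-length weights. This
is a deliberately transparent surrogate for HMM-based CNV callers: the
downstream model only consumes arm-level dosage features, and tumor-fraction
estimation is out of scope. Median centring assumes less than half the
genome is altered. Acrocentric short arms (13p, 14p, 15p, 21p, 22p) carry
no assayable sequence and are excluded from the default arm table; arms
with fewer than `min_bins` (default 10) usable bins are dropped.

**Mutations.** Candidate calls pass a stringent eligibility filter: panel
gene (APC, TP53, KRAS, PIK3CA, FBXW7, BRAF, ACVR2A by default), damaging
effect class (missense/nonsense/frameshift/splice), recurrence (hotspot OR
COSMIC count ≥ 3, with hotspot additionally required for missense), VAF ≥
0.001 and ≥ 3 supporting reads. Exact thresholds are configuration; the
defaults are typical stringent values for cfDNA driver panels. Rejected
calls carry the first failing criterion in a fixed evaluation order (gene
panel, mutation type, hotspot/COSMIC, VAF, alt reads) so diagnostics are
deterministic. A sample's *mutation score* is 1 iff at least one call
survives. The filter is monotone: relaxing any threshold never removes an
eligible call.

## Marker selection

Selection sees training data only. Each omics matrix is filtered by a
two-sided Wilcoxon rank-sum test per feature with Benjamini–Hochberg
adjustment (keep at adjusted p < 0.05); the nonparametric test suits
bounded betas and compositional motif frequencies. Constant features get
p = 1 by convention. Methylation and end-motif survivors are then ranked by
random-forest mean-decrease-in-impurity importance (impurity rather than
permutation importance for speed; 500 trees, fixed seed, rows canonically
ordered by sample id so selection is invariant to input order, ties broken
lexicographically) and the top 23 / 14 are retained; CNV keeps up to 34
arms by the univariate ranking alone. These targets mirror the assay design
the package emulates; on synthetic cohorts they are targets, not
guarantees — when fewer features reach significance, fewer are kept. When
*nothing* reaches significance (a signal-free cohort), selection falls back
to the smallest raw p-values with a warning so the downstream model stays
defined; on null data this yields chance-level classifiers, which is the
correct behaviour for calibration experiments.

## Models

Each omics block feeds a logistic regression on z-standardized selected
features (standardization statistics frozen from the training fit). A small
ridge penalty with strength λ = 1e-4·n keeps the maximum-likelihood fit
defined under complete separation; λ is configurable and 0 is allowed. Fits
use Newton/IRLS iterations to tolerance 1e-12, and a unit test pins the
coefficients to an independent IRLS implementation at 1e-6.

Training-cohort probabilities come from stratified tenfold cross-validation
(per-fold class counts within 1 of proportionality, seed recorded):
standardization and coefficients are re-fit per fold and each sample gets
exactly one out-of-fold probability. Marker selection is performed once on
the full training cohort, mirroring the select-then-model sequence of the
assay design; this carries a known optimistic bias for the *training* CV
estimate, so a fully nested mode (`nested_selection=True`) re-runs
selection inside every fold. Validation metrics are unaffected either way.

The integrated model is a logistic regression over exactly four inputs:
the three sub-model probabilities and the binary mutation score. It is fit
on *out-of-fold* sub-model probabilities — never in-fold fits, which a
regression test shows inflate apparent performance on null data — and its
own training-cohort score is again cross-validated on the same partition.

Decision cutoffs default to the Youden-index maximizer (sensitivity +
specificity − 1) over the observed out-of-fold scores, ties resolved to the
smallest cutoff; a `specificity_floor` alternative takes the smallest
cutoff reaching a target specificity. With perfectly separated scores the
Youden rule returns the smallest observed case score.

## Evaluation

AUC is the Mann–Whitney concordance (ties counted ½; a test pins it to
brute-force pair counting at 1e-12). Its 95% CI uses the analytic DeLong
variance by default, with a stratified percentile bootstrap (2000
resamples, seeded) as the alternative; a degenerate variance (perfect
separation) falls back to [AUC, 1.0] with a warning. Proportions carry
exact Clopper–Pearson intervals (Wilson selectable) and are rendered to one
decimal percent with half-up rounding. Per-stage sensitivity is computed
over case samples only. `single_marker_eval` thresholds a continuous
biomarker (e.g. a CEA-like protein marker at 5 ng/ml) and evaluates it with
the same machinery for baseline comparisons.

## Synthetic cohorts

The real cohorts behind this design are controlled-access; the package
therefore ships a generator that reproduces the *statistical structure* the
classifier assumes, not sequencing reads (no FASTQ/BAM emission, no
digestion chemistry).

* Stage mix: multinomial over stages I–IV with proportions renormalized
  from 17.2 / 39.8 / 38.7 / 2.2%.
* Tumor fraction: log-normal per stage; default medians 0.8%, 1.8%, 3.5%,
  8% for stages I–IV with log-sd 0.8 — plausible magnitudes for CRC cfDNA,
  chosen once (no per-sample tf values exist to fit against).
* Methylation: per site, total molecules ~ Poisson(depth 300), methylated ~
  Binomial(total, clamp(baseline + tf·effect, 0, 1)); 30 of 50 panel
  markers informative with effects uniform on [0.25, 0.85] over low
  baselines [0.005, 0.06].
* End motifs: fragments draw motifs multinomially from
  (1−tf)·control + tf·tumor over 256 motifs (30,000 fragments/sample); the
  tumor profile is a genome-wide log-normal perturbation of the healthy
  profile (per-motif log-ratio sd 1.0), reflecting that cancer shifts the
  whole motif spectrum rather than a few motifs.
* Copy number: expected bin depth ∝ (1 + tf·(copies/2 − 1)) · gc_bias(gc),
  negative-binomial noise (size 80); cases share a clonal CRC-typical
  alteration set (8q+, 8p−, 20q+, 17p−, 13q+, 18q−, 7p+, 18p−, 7q+).
* Mutations: cases are mutation-positive with probability 1 − exp(−tf/τ),
  τ = 0.0453 calibrated so the default tf mix gives ≈ 41.9% case
  positivity; controls carry CHIP-like eligible false positives at rate
  0.094; both arms receive filter-failing decoys (wrong effect class,
  non-recurrent missense, sub-threshold VAF). Eligible variants get
  VAF ≈ tf/2 with log-normal noise.
* A CEA-like protein marker (log-normal, tf-coupled) is calibrated to
  ≈ 53% sensitivity / 83% specificity at 5 ng/ml — the modest performance
  expected of a single protein marker.

Effect magnitudes were fixed once so that the default cohort reproduces the
qualitative structure of the assay: sub-model AUCs ordered methylation >
end motif > CNV, an integrated model that at least matches the best single
channel, and mutation positivity near the calibration constants. Randomness
uses one root seed; every sample owns a stream keyed by a stable hash of
its sample id, so enlarging a cohort never perturbs existing samples, and
training/validation cohorts share a `panel_seed` so they describe one
underlying biology sampled twice.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: batch and extraction effects, age/sex
confounding, fragment-length structure, correlated noise between channels,
subclonal copy-number heterogeneity, and CHIP that shifts CNV (not just
mutation) background. Absolute performance numbers on synthetic cohorts are
properties of these modelling choices; only the qualitative contracts
(ordering, stacking dominance, null calibration, closed-form recoveries)
are meaningful checks.

## Numerical choices and degenerate inputs

* Logistic solver: Newton-Cholesky, tol 1e-12, max 500 iterations;
  non-convergence raises with diagnostics rather than returning silently.
* Zero-variance features are dropped at fit time with a relative floor
  (sd > 1e-9·max(1, |mean|)) so float round-off does not resurrect
  constants.
* GC correction refuses all-zero counts and fewer than 5 distinct GC
  values; single-stratum input degrades to global-median division.
* Cutoff choice on identical scores returns that score with a warning.
* All TSV/JSON artifacts are written with stable ordering; two runs with
  the same config and seed are byte-identical, and a manifest records the
  config hash and a SHA-256 per artifact.

## Problem sizes

Default cohorts match the emulated study (training 93 + 96, validation
89 + 95) at 30,000 fragments and ~2,900 1-Mb bins per sample. The
calibration suites run 20 seeds of the full pipeline (default scale for the
stacking checks; 100 + 100 per cohort for the null-calibration checks), and
the reduced-scale configuration used in smoke/determinism tests (25 + 25
samples, 10-Mb bins, 4,000 fragments) exercises every stage in a few
seconds. These sizes were chosen to make the full suite comfortably
repeatable on a laptop-class single core.

## Known limitations

* The CNV channel is a log-ratio summary, not a segmentation/HMM caller;
  focal events inside an arm are diluted.
* Marker selection on the full training cohort inflates training CV AUC
  slightly (validation estimates are unbiased); the nested mode is slower
  but honest for both.
* The printed retained-marker counts (23 / 14 / 34) are reproduced on
  synthetic data only to the extent the simulated effects reach
  significance; the CNV channel typically retains fewer than 34 arms.
* DeLong intervals undercover near AUC = 1; the bootstrap alternative is
  preferable there.
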