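# Methods

This note documents the models, conventions and numerical choices behind
`cystmir`, and what its synthetic-data tests do and do not establish about
real specimens.

## Count model and differential abundance

Counts for miRNA unit *g* (a merged mature, cistron cluster or sequence
family) in sample *i* are modeled as negative binomial,

    y_gi ~ NB(μ_gi, φ),   Var = μ + φ μ²,
    log μ_gi = log N_i + x_iᵀ β_g,

where *N_i* is the sample's total miRNA reads (so coefficients act on the
CPM scale; no TMM-style factor is applied, keeping normalization pure CPM —
a compositional choice: a very large true shift in one abundant unit
depresses the apparent CPM of everything else), and the design holds an
intercept, a disease-group indicator and optionally a sex indicator. The
sex column is included only when both sexes occur in both groups; otherwise
it is dropped with a warning, since it would be confounded with the group
or constant.

**Dispersion.** φ reflects biological variation between samples of the same
group. The common φ maximizes the summed Cox–Reid adjusted profile
likelihood, APL_g(φ) = ℓ_g(β̂_g(φ), φ) − ½ log det(XᵀWX), with working
weights W = μ/(1+φμ); the adjustment penalizes the profile likelihood by
the Fisher information of the mean parameters, removing the downward bias
of plain profiling. The optimizer is a bounded scalar search on log φ over
[1e−6, 20]; a solution at the lower bound is reported as φ = 0 (effectively
Poisson). Per-unit ("tagwise") estimates maximize
APL_g(φ) + w·mean_g'(APL_g'(φ)) on a 21-point log-spaced grid spanning
32-fold either side of the common value. The prior weight *w* (default 10)
acts as that many pseudo-units of shared evidence — a fixed-weight
shrinkage toward the common value in place of trend-based schemes, adequate
for the few-hundred-unit matrices of miRNA profiling.

**Filtering.** Units averaging below 1 CPM are removed before dispersion
estimation (config value `min_cpm`): near-zero units contribute almost no
likelihood curvature and destabilize the APL grid. Units that are all-zero
after filtering are reported with p = 1 and an undefined log₂FC.

**Testing.** Group effects are tested unit-wise by likelihood ratio:
2(ℓ_full − ℓ_reduced) against χ²(1) (the quasi-likelihood F variant is out
of scope). BH step-up FDR is applied with monotonicity enforcement, and a
unit is called significant when p < 0.05 **and** FDR < 0.2 jointly.
`fold_report` renders log₂FC as round(2^|log₂FC|, 1) plus a direction, the
convention used when quoting linear folds in prose.

**GLM numerics.** All units are fitted simultaneously by vectorized IRLS
(working response z = η − offset + (y−μ)/μ, weights μ/(1+φμ)); the linear
predictor is clipped to |η| ≤ 60 to keep exp finite, iteration stops when
every unit's log-likelihood changes by < 1e−10 relative, and a singular
normal-equations batch falls back to least squares. At φ = 0 the likelihood
reduces exactly to Poisson; tests verify the LRT then matches an
independent Poisson-GLM oracle to 1e−6.

**Calibration (what the simulations show).** Under a 2000-unit null at
φ = 0.2, n = 10+10, the empirical type-I error at p < 0.05 stays within
[0.035, 0.065]; a log₂FC of 3.2 planted on a 500-CPM unit is recovered with
|bias| < 0.15 and flagged significant in ≥95% of 200 replicate studies.
These establish calibration of the engine, not of any particular patient
dataset.

## Unit systems and aggregation

Matures with identical sequence at several loci are merged (`name(N)`);
merged-mature counts are the substrate for aggregation into cistron
clusters and sequence families, so identical sequences are never counted
twice. Aggregation is a pure sum, hence per-sample totals are invariant
across the three unit systems — a tested conservation law. Cistron and
family membership are input annotations, not inferred from genomic
distance. Cellular specimens are analyzed on cistron units (co-transcribed
members are correlated); biofluid/exosome specimens on merged matures,
since secretion and extracellular stability decouple cluster members. The
unit system is an explicit parameter everywhere.

## Absolute quantification

Calibrator oligoribonucleotides spiked at known femtomole amounts give a
linear reads→moles conversion: miRNA fmol = miRNA reads × (Σ calibrator
fmol / Σ calibrator reads); divided by input RNA (µg) this yields fmol/µg,
and multiplied by the specimen's RNA yield (ng RNA per ml urine, numerically
µg per liter) a molar urine concentration. The estimator is depth
scale-invariant; samples with zero calibrator reads are flagged
unquantifiable rather than reported as zero.

## Read annotation

Demultiplexing is exact-prefix only — barcodes are short and mismatch
rescue risks cross-sample bleed. Adapter trimming removes the suffix at the
leftmost exact match of the adapter's first k nt (k from the full adapter
length down to a 6-nt minimum overlap); inserts outside 16–30 nt are
discarded. Annotation priority is calibrator (exact) → mature miRNA →
genome-matching unannotated → discarded. The mature tolerance records
isomiR variants: ≤1 internal substitution (equal length), end trims up to
2 nt per end (shorter), or ≤3 untemplated 3' additions (longer, exact
prefix). Templated end *extensions* beyond the mature are not considered —
they would require genomic context around each precursor, which the toy
genome does not model. Ties between distinct matures at equal edit cost are
broken toward the mature with the higher global exact-match tally (computed
in a first pass), then by name; annotation is therefore deterministic and
independent of read order. Genome matching for the unannotated class is
exact substring search on both strands; no spliced or gapped alignment.

## Variant screening and composite score

Variant frequencies are variant reads over all reads of that miRNA;
(miRNA, sample) cells with fewer than 20 reads (`min_mirna_reads`) are
missing, not zero, because a frequency from a handful of reads is counting
noise. Screening is a two-sided Mann–Whitney U per variant at α = 0.1 with
pairwise deletion of missing cells; variants observed in fewer than 3
samples per group are skipped. The composite score uses each selected
variant's median frequency across *all* samples in the comparison
(per-group medians would be circular): +1 above, −1 below, 0 at ties. The
literal rule is the default; a direction-aware mode that sign-flips
variants lower in the case group is provided, since reported analyses are often ambiguous on that point. Selecting and scoring on the same samples
reproduces the classical in-sample (optimistically biased) procedure;
`CompositeVariantScorer.transform` on held-out samples gives the honest
cross-validated counterpart. The ROC AUC is computed by exhaustive pair
counting (ties count ½) — verified to equal trapezoidal ROC integration —
with a tie- and continuity-corrected normal-approximation Mann–Whitney p.

## Mining

Candidates are unannotated genome-matching sequences of 21–23 nt, collapsed
by exact identity; abundance is reads per million miRNA reads, computed
per sample, and a candidate is flagged when its per-sample maximum strictly
exceeds 200 RPM ("exceeded" is read as a strict inequality, and per-sample
maximum is the stricter reading of the screen).

## Synthetic-data generator

The generator is the package's study-condition statement. Defaults: two
groups of 8–20 samples; library-size factors log-uniform within 2-fold of
5×10⁵ miRNA reads (yields vary between libraries but no distribution is
published, so log-uniform is a convention); baseline relative abundances
log-normal (σ = 2), optionally pinned to stated CPM values; a single NB
dispersion φ = 0.2 shared across units (per-unit φ is a config extension);
planted log₂ fold changes on named units; reads of 50 nt with a fixed 3'
adapter and Q40 qualities (no sequencing-error or ligation-bias modeling);
3 equimolar calibrators at 0.5 fmol anchored to a planted miRNA content of
5.8 fmol/µg at 5 µg input; decoy sequences planted at stated RPM and
embedded in a toy genome, kept outside the annotation tolerance of every
mature so they provably survive as unannotated.

Variant-frequency tables emulate a profiled variant catalogue: 138 variants,
9 carrying a true group shift, baselines uniform on [0.02, 0.30] with
Gaussian noise at 25% CV. Shifts are upward in the case group, sized in
noise-SD multiples — 3×SD for the primary-culture-like arm and 1×SD for the
urine-like arm, reflecting the strong cell-culture signal versus attenuated
patient-level signal. Disease-associated variants are broadly observed
(75–100% of samples) while null variants sit near the depth floor (5–50%
observed); that sparsity is what makes an uncorrected α = 0.1 screen over
~138 variants return on the order of ten selections, as in the profiled
study — on a dense exchangeable table the same screen would admit ~13 false
selections by construction.

**What passing tests do not show.** The generator draws independent units;
real miRNA counts are compositionally coupled and correlated within
cistrons. It has no sequencing errors, GC/ligation bias, batch effects or
cell-type mixtures. Round-trip exactness therefore validates the
bookkeeping and the estimators' statistical behavior under the stated
model, not robustness to those artifacts.

## Reproducibility

All randomness derives from one root seed through named substreams (one per
stage), so every stage is byte-reproducible; the pipeline writes a manifest
with the config hash and SHA-256 checksums of all outputs, and TSV floats
are formatted at 6 significant digits so checksums are platform-stable.
Problem sizes in the test suite and acceptance script (e.g. 2000 null
units; 50–200 replicate studies; 3000–20000-read synthetic lanes) are
chosen to exercise each property at Monte-Carlo error well inside the
asserted tolerances while keeping a full run in the order of a minute.

## Known limitations

- The annotation edit tolerances follow the established small-RNA
  convention; catalogue-specific definitions may differ.
- The spike-in estimator assumes equal capture efficiency for calibrators
  and endogenous miRNA.
- Pure-CPM offsets make strong effects in dominant units bleed into other
  units' apparent fold changes (no median-ratio correction by default).
- The variant screen is uncorrected for multiplicity by design (α = 0.1,
  matching the published procedure); its in-sample AUC is optimistic.
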