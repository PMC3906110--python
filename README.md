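# cystmir

Small-RNA sequencing analysis of miRNA profiles in polycystic kidney disease
specimens — urine sediment cells, urine microvesicle (exosome) fractions and
primary cultures of kidney tubule epithelium — built as a tested, fully
synthetic-data-driven pipeline.

Autosomal dominant polycystic kidney disease (ADPKD) lacks biomarkers of
progression. Deep sequencing of multiplexed small-RNA cDNA libraries lets one
profile miRNA abundance from nanograms of urine RNA and compare ADPKD against
other chronic kidney disease (CKD) patients, and cyst-derived against normal
tubule epithelial cultures. `cystmir` implements the complete analysis chain
for such studies, for researchers who want the method itself — reproducible,
unit-tested, and exercised end to end on generated data with known ground
truth.

## What the pipeline does

1. **Library processing** — demultiplex barcoded reads by exact 5'-prefix
   match, trim the 3' adapter, and annotate inserts against a miRNA
   catalogue (exact match, ≤1 internal substitution, end trims within ±2 nt,
   ≤3 untemplated 3' additions), spike-in calibrators and a genome sequence.
2. **Profiles** — aggregate merged-mature counts into cistron clusters
   (co-transcribed miRNAs, `cluster-…(N)`) or sequence families
   (`seqfam-…(N)`), normalize to counts per million miRNA counts (CPM), and
   convert read counts to femtomoles via calibrator oligoribonucleotides
   spiked at known amounts:
   `miRNA fmol = miRNA reads × (Σ calibrator fmol / Σ calibrator reads)`.
3. **Differential abundance** — per-unit negative binomial GLMs with log
   link and `log(total)` offset: `log μ_gi = log N_i + x_iᵀ β_g`, variance
   `μ + φμ²`. Dispersion φ is estimated by maximizing the Cox–Reid adjusted
   profile likelihood (common, then per-unit values shrunk toward the common
   estimate); the group effect is tested by likelihood-ratio tests against
   χ²(1), with Benjamini–Hochberg FDR. A unit is significant when p < 0.05
   and FDR < 0.2. `fold_report` converts log₂ fold changes to the linear
   folds used in prose (e.g. log₂FC 3.2 → 9.2-fold).
4. **Sequence variants** — tabulate isomiR/variant frequencies (variant
   reads / all reads of that miRNA; cells under 20 reads are missing, not
   zero), screen them between groups by two-sided Mann–Whitney at α = 0.1,
   and score each sample by +1/−1 per selected variant above/below its
   across-sample median frequency. Group discrimination is summarized by a
   pair-counting ROC AUC with a Mann–Whitney p-value.
5. **Mining** — flag unannotated genome-matching 21–23 nt sequences whose
   abundance exceeds 200 reads per million miRNA reads (0.02% of miRNA) in
   any sample: the abundance floor below which a novel miRNA could not
   compete for Argonaute occupancy.
6. **Synthetic data** — a first-class generator producing every input above
   (reference with multicopy/cistron/family structure, NB counts with
   planted log₂ fold changes, barcoded FASTQ reads, calibrators, planted
   variants and genome decoys) so each stage is testable by exact round-trip
   conservation and parameter recovery.

## Worked example

```python
from cystmir import SimulationConfig, make_reference, simulate_counts
from cystmir.diffexpr import NBGLMDifferentialExpression, fold_report
from cystmir.profiles import aggregate

cfg = SimulationConfig(
    seed=1, n_samples_per_group=10, n_mirna=30, n_clusters=12,
    planted_log2fc={"miR-s07": 3.2, "miR-s08": 3.2, "miR-s09": 3.2},
    baseline_cpm={"miR-s07": 300.0, "miR-s08": 500.0, "miR-s09": 200.0},
)
ref = make_reference(cfg)
counts, samples, truth = simulate_counts(cfg, ref)
cistron = aggregate(counts, ref, "cistron")
model = NBGLMDifferentialExpression().fit(cistron, samples["group"])
print(model.results_.head(3).round(4))
fold, direction = fold_report(model.results_.iloc[0]["log2_fc"])
print(f"top unit: {model.results_.index[0]}  fold change = {fold} ({direction})")
```

prints

```
                    log10_cpm  log2_fc  p_value     fdr  significant  dispersion
cluster-mir-s07(3)     3.6819   3.2012   0.0000  0.0000         True      0.1647
cluster-mir-s19(2)     4.4826   0.5640   0.0318  0.1910         True      0.1647
cluster-mir-s23(2)     4.3071   0.3546   0.1764  0.5643        False      0.1647
top unit: cluster-mir-s07(3)  fold change = 9.2 (up)
```

A cistron whose three co-transcribed members were planted at log₂FC 3.2 on a
1000-CPM baseline is recovered at log₂FC 3.20 — a 9.2-fold elevation in the
case group — and flagged significant under the joint p/FDR rule; unplanted
clusters sit near zero.

The same machinery is scriptable from the shell:

```sh
cystmir run-all --config run.yaml     # simulate → process → … → mine
cystmir de --counts counts.tsv --meta samples.tsv --unit cistron --out de.tsv
```

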