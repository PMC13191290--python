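# kre — Kit response element discovery, prediction and scoring

Growth-factor signalling reshapes chromatin within minutes: stimulating the
Kit receptor tyrosine kinase with its ligand SCF opens some accessible
*cis*-regulatory elements and closes others in erythroid precursor cells.
`kre` is a pipeline for finding these **Kit response elements (KREs)** from
condition-contrast ATAC-style signals, tying them to signal-regulated
transcripts, predicting responsiveness from transcription-factor occupancy,
and ranking each element with a composite activity score. It is written
for regulatory genomicists who have condition-wise accessibility peaks and
signals, differential-expression tables, promoter-capture contacts, and a
catalog of ChIP peak sets — and who want a tested, reproducible path from
those inputs to a ranked list of signal-responsive enhancers.

## Method at a glance

1. **Differential accessibility.** Stimulated vs control signals are
   normalized on the M-A plane (M = log2 x_a/x_b, A = ½ log2 x_a·x_b; OLS
   fit over common elements, iterated to |α|,|β| < 1e-8) and elements are
   called activated / repressed / insensitive at fold change ≥ 1.5 with a
   BH-adjusted two-sided rate test. With a second, EGR1-perturbed genotype,
   responsive elements are further split into EGR1-sensitive
   (|Δlog2FC| ≥ log2 1.5, Fisher p < .05) and -insensitive.
2. **Linking.** Elements link to genes within 15 kb of the TSS or through
   contact pairs whose bait covers the promoter window (TSS ± 2 kb).
   Elements linked to regulated transcripts are positives; elements linked
   only to insensitive transcripts are the negative-control set.
3. **Occupancy features.** Many ChIP peak sets (replicates merged per
   factor, QC-filtered) intersect the elements (≥ 1 bp) into a binary
   elements × factors matrix.
4. **Classification.** An XGBoost ensemble (L1/L2 regularized, SMOTE
   rebalancing fitted inside each of 5 stratified CV folds) predicts
   responsiveness; features are attributed by exact TreeSHAP and ranked by
   the log-odds ratio of occupancy, ln(ad/bc) with Haldane-Anscombe
   correction, gated on stimulation footprints and ≥ 10% occupancy.
5. **Scoring.** Each element's activity score sums its selected-feature
   log-odds weights with fixed components: +2 early-stage accessibility,
   −1 late-stage, −1 no Kit-positive-context accessibility, ±1 ABC
   activity, ±1 H3K27ac, +1 conservation (PhyloP-style summary > 1).
   The fixed components span exactly [−4, +5]; totals ≥ 4 flag the
   high-activity set.
6. **Transfer.** Elements are partitioned by accessibility and enhancer
   status in a second cell type; the unique set is exported as a
   retraining control group.

A synthetic cohort generator (`kre.simulate`) emits the complete study —
elements, four-condition signals, DE contrasts, ChIP BEDs, contacts,
annotations — with planted classes, fold changes and feature odds ratios,
so every stage is testable against known truth.

## Worked example

The numbered drivers under `analysis/` run the stages on the default
synthetic cohort (3000 elements, 600 genes, 286 occupancy features, 20%
responsive at 1:4 imbalance, 12 features planted at 0.60 vs 0.16
prevalence), writing all tables under `results/pipeline/`:

```
$ python analysis/01_simulate_cohort.py
simulated 3000 elements into .../results/pipeline/cohort
$ python analysis/02_call_differential_accessibility.py
response-call counts: {'insensitive': 2400, 'activated': 360, 'repressed': 240}
elements tested for EGR1 sensitivity: 600
$ python analysis/03_link_elements_to_transcripts.py
linked 3000 elements: 600 positive, 2400 negative, 0 unlinked
$ python analysis/04_build_occupancy_matrix.py
290 factors in, 286 retained; matrix 3000 x 286
$ python analysis/05_train_and_rank_features.py
kit model: accuracy 0.968 (SD 0.009), AUROC 0.994, AUPR 0.979, 59 selected features
egr1 model: accuracy 0.967 (SD 0.018), AUROC 0.994, AUPR 0.997, 53 selected features
$ python analysis/06_score_and_transfer.py
scored 600 elements: 600 high, range [10.10, 38.26], conserved fraction of high set 0.29
transfer: 316/600 (52.7%) accessible in the other cell type; 183/600 (30.5%) enhancer-annotated
```

Reading the output: the caller recovers the planted 600 responsive
elements (360 opened, 240 closed by stimulation) exactly at this noise
level; QC drops the four decoy ChIP datasets leaving 286 factors; held-out
cross-validated accuracy/AUROC reflect the planted odds ratio of ≈ 8 per
feature; all 12 planted features are among the selected predictors (the
remainder pass the gates by chance at background occupancy); and the
transfer fractions match the configured 55% / 31.4% overlaps. Scored
responsive elements sit far above the fixed-component floor of −4 because
each carries several planted features whose log-odds weights add ≈ 2 each.

The same stages are available as a CLI (`kre simulate|diffacc|annotate|
features|train|score|transfer|demo --config FILE [--seed N] [--out DIR]`)
driven by a single YAML config with per-stage checksummed manifests;
`kre demo` runs the whole chain and writes a JSON report.

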