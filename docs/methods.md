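# Methods

## Problem and model

The task is binary classification of short peptides (3–30 residues over the
20 canonical amino acids) into A-cell epitopes — peptides that activate
antigen presenting cells via innate immune receptors, hence candidate
vaccine adjuvants — and non-immunomodulatory peptides. Two signal families
drive the discrimination and are modelled explicitly:

1. **Compositional bias.** Epitopes are relatively enriched in R, I, V and W;
   serum-like negatives in E, G, P and L. Variable-length sequences are
   mapped to fixed-length percentage vectors: amino-acid composition
   (AAC, 20 values, 100·count/L), overlapping dipeptide composition
   (DPC, 400 values, denominator L−1) and tripeptide composition
   (TPC, 8000 values, denominator L−2; analysis only). Terminal variants
   restrict the window to the first/last k residues (N_k, C_k, or both),
   and positional one-hot "binary profiles" encode each terminal position
   as a 20-slot block. The overlapping-window denominators are the
   standard composition convention; all composition vectors are in percent
   and sum to 100.
2. **Class-exclusive motifs.** Literal ungapped substrings (default length
   3–8) contained in at least `min_support` sequences of one class and in
   zero sequences of the contrast class. Exclusivity is the defining
   property and is certifiable after the fact by re-scanning the contrast
   class. Redundant motifs — those with a proper substring that is also
   exclusive with identical support — are pruned, keeping the shortest
   informative form. `min_support` defaults to max(3, 1% of the positive
   set): small enough to catch rare conserved patterns, large enough to
   exclude singletons.

The classifier is a support vector machine with an RBF kernel,
parameterized by `g` (kernel width), `c` (error/margin trade-off) and `j`
(a cost factor multiplying the error weight of positive training
examples — useful when classes are imbalanced). Features enter on their
natural percent (or 0/1) scale without standardization; the `g` grid is
chosen for that scale. A peptide is labelled an epitope iff its decision
score is ≥ a stored threshold; ties at the threshold go to the positive
class. **Hybrid** models add a motif term to the raw SVM score: +w if the
sequence contains any positive-exclusive motif, −w for any
negative-exclusive motif (default w = 0.5, roughly a third of the typical
decision-score range, so motif evidence can flip borderline calls but not
overturn confident ones); matching both cancels.

## Evaluation protocol

* **Split.** Stratified 80/20 internal/external partition per class;
  the external class size is round((1−f)·n), half-up, sampled uniformly
  without replacement. A 304/385 dataset therefore splits into 243/308
  and 61/77.
* **Internal validation.** Stratified fivefold cross-validation on the
  internal part. Every sequence is held out exactly once; the held-out
  decision scores are pooled and the metrics computed once at the
  configured threshold. Pooling keeps sensitivity and specificity well
  defined even when per-fold class counts are small.
* **Metrics.** Sensitivity, specificity and accuracy as percentages; MCC
  from the confusion counts with the zero-marginal convention (MCC = 0
  when any row or column of the confusion matrix is empty); AUROC as the
  rank (Mann–Whitney) statistic with ties counted half.
* **Threshold selection.** Grid −1.5 … +1.5 in steps of 0.1, maximizing
  MCC; ties prefer the smallest |Sn − Sp| gap, then the smallest
  threshold.
* **Repeated splits ("bagging").** The split is repeated 10 times; each
  round reports internal (pooled CV) and external (train on the whole
  internal part, score the external part) metrics; the summary is the
  mean ± sample SD (ddof = 1) over rounds. Round seeds are derived
  deterministically from one master seed via `numpy.random.SeedSequence`,
  kept below 2³¹; a report is bitwise reproducible from the master seed.
* **Hyperparameters.** `tune_hyperparameters` searches a small grid
  (g ∈ 1e−5…0.5, c ∈ 1…9, j ∈ 1…4) by internal fivefold MCC and is kept
  out of the evaluation loop: one parameter set per feature space.

### Motif protocols in hybrid evaluation

Two variants are implemented because they answer different questions:

* **Shared catalogue** (`motifs=`): the exclusive-motif catalogue is mined
  once on the whole dataset and reused by every round and both splits.
  This mirrors the classic workflow in which motif tables are a published
  artifact of the full dataset. It is *optimistic*: evaluated sequences
  contributed to the catalogue, so both internal and external estimates
  share an upward bias (they remain mutually consistent, which is what
  the internal-vs-external comparison probes).
* **Leakage-free** (`motif_config=`): motifs are re-mined per round on the
  internal split only, and per training fold inside the internal CV, so
  no evaluated sequence ever contributed to the motifs scoring it. This
  gives unbiased generalization estimates and is the recommended protocol
  for honest performance claims.

On the default synthetic conditions the shared-catalogue hybrid reports
internal ≈ 91.4%, external ≈ 90.4%; the leakage-free variant ≈ 84% for
both — close to the generator's Bayes ceiling (an exclusive-motif rule
plus the exact log-likelihood ratio of the generating residue
distributions reaches ≈ 86% balanced accuracy), which quantifies exactly
how much of the shared-catalogue figure is catalogue reuse rather than
generalization.

## Dataset handling

Sequences are validated strictly against the 20-letter alphabet
(ambiguity codes are errors, not skips, because every encoder assumes the
canonical alphabet), upper-cased, length-filtered inclusively (default
3–30) and deduplicated within each class (first occurrence kept). A
sequence occurring in both classes is kept in both with a warning
(`strict=True` turns this into an error); within-class deduplication only
is the default because cross-class collisions are a data-curation signal
the user should see, not silently resolve.

Peptides shorter than a terminal window k cannot be encoded under
terminal feature specs; they are excluded from training with a warning
and rejected at prediction time with an explicit error — padding would
fabricate residues. For N_kC_k windows with k ≤ L < 2k the two windows
overlap in the middle; both are valid individually. The N5C5 DPC encoder
averages the two segment vectors rather than encoding the concatenation,
because the N-to-C junction dipeptide does not exist in the molecule
(`nc_dpc="concat"` provides the alternative).

## Statistical analyses

* **Composition comparison.** Per-peptide percent composition first, then
  the class mean (so short and long peptides weigh equally); Welch's
  unequal-variance t-test per feature (class variances differ materially
  in this data); Benjamini–Hochberg adjustment across the feature family
  (20/400/8000 tests; Bonferroni available). Features with zero variance
  in both classes report p = 1.
* **Terminal preference.** Per terminal position (1..k, counted inward)
  and residue: class frequencies, difference (positive = enriched in
  epitopes), and a two-proportion z-test. Degenerate cells (residue absent
  from both classes, or present in every sequence of both) report p = 1.
* **Rare n-mer bins.** Background n-mers (n = 3..6) are sorted by
  ascending occurrence (ties lexicographic) and split into 8 near-equal
  rank bins, bin 1 rarest. Each dataset's percentage per bin is its n-mer
  occurrence mass falling in that bin over its total occurrences; dataset
  n-mers absent from the background go to a separate "unseen" row, so
  every dataset's bins + unseen sum to 100. Occurrences (not distinct
  types) are used as the denominator so that the statistic reflects how
  much of a dataset is built from rare background vocabulary.

## Synthetic data generator

`simulate_dataset` draws lengths uniformly on 3–30 and residues i.i.d.
from a tilted distribution: uniform weights, multiplied by the enrichment
factor (default 2) on the enriched set (R/I/V/W for positives, E/G/P/L
for negatives), renormalized. Planted motifs (default "RIV" and "KWR",
each with probability 0.4 per positive) overwrite a random window so the
length distribution is preserved; negatives containing a planted pattern
by chance are resampled, making planted motifs class-exclusive by
construction. Sequences are unique within each class.

The generator reproduces the *statistical contrasts* a composition+motif
classifier exploits — enrichment direction, exclusive motifs, the length
range — and deliberately nothing else: no phylogenetic or positional
correlation structure, no physico-chemical coherence, no curation noise,
and residues outside the enriched sets are exchangeable. Passing tests on
synthetic data therefore validate the machinery (encoders, discovery,
protocol, arithmetic), not real-data performance; absolute accuracies on
curated data will differ.

## Problem sizes and numerical choices

Tests and the acceptance script run at the generator's default scale
(300 peptides per class; 10 bagging rounds; fivefold CV), the package's
reference study condition. Composition sums are checked to 1e−6 (exact
arithmetic up to float rounding); metric comparisons against oracles are
exact to machine precision; MCC/|Sn−Sp| ties in threshold selection are
rounded at 1e−12 before comparison to avoid float-ordering artifacts.

## Limitations

* Exclusive-motif support counts sequence containment, not occurrence
  multiplicity; highly repetitive peptides do not inflate support.
* The hybrid score is a post-hoc adjustment, not a learned feature; its
  weight is a fixed hyperparameter (`--motif-as-feature`-style appended
  match-count features are intentionally not the default, keeping the SVM
  feature space fixed across plain and hybrid models).
* Model bundles are serialized with joblib and are not portable across
  major scikit-learn versions; the loader checks a format version and the
  feature dimensionality, not cross-version estimator compatibility.
* No physico-chemical property encodings, post-translational
  modifications, or gapped/residue-class motifs.
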