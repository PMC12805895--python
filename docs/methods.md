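# Methods

This note documents the models, conventions and numerical choices behind
`lncboost`, and what the synthetic-data generator does and does not emulate.

## Coordinates and annotation handling

All internal coordinates are 0-based half-open on a named chromosome with a
strand in {+, −, unstranded}. GTF I/O converts from/to the 1-based closed
convention at the boundary; BED and bedGraph are native. The GTF reader
groups exon rows by `transcript_id`, captures the Cuffcompare-style
provenance attributes (`ref_gene_id`, `class_code`), per-sample
`FPKM_<sample>` attributes and the `gene_biotype`, ignores unknown
attributes, raises on malformed lines naming the line number, and logs and
drops transcripts with no exon rows. Round-tripping through
`write_annotation` is lossless for everything the model stores.

A transcript is **novel** iff its gene ID (or, as a fallback, transcript ID
— annotation merges differ in which ID carries the generated prefix) starts
with the assembler prefix (default `MSTRG.`) *and* it has no `ref_gene_id`
link. Novel candidates receive a positional subclass: an explicit class
code takes precedence (u → lincRNA, i → intronic, x → antisense); otherwise
geometry decides — *intronic* if the span lies fully inside an intron of a
reference transcript on either strand, *antisense* if any exon overlaps a
reference exon on the opposite strand, *lincRNA* if nothing overlaps, and
*other* for remaining (same-strand or partial) overlaps. Ties resolve
intronic > antisense > lincRNA, most specific first. Transcripts with class
codes outside {u, i, x} are retained as *other* rather than dropped.

Training labels follow the annotation: after removing tRNA/rRNA/sRNA
records (case-insensitive), label 1 ⇔ biotype `ncRNA`, else 0. Soft-masked
genome bases are uppercased before any sequence computation.

## Feature schema

The evidence matrix has a fixed, countable column order: 23 quantitative
track statistics, one Boolean column per ReMap regulator (sorted), one per
JASPAR motif (sorted), one k-mer SVD component per k (ascending), then
`ss_mfe` and `length` — `25 + |V_remap| + |V_jaspar| + |k_range|` columns
in total, which is 730 at the published configuration (549, 146, k=3..12).

Conventions the sources leave open, fixed here and configurable:

- **cov** is the fraction of span bases with nonzero signal (signal tracks)
  or covered by the interval union (interval tracks); it is unit-free.
- Track-derived features are computed over the candidate's *genomic span*
  (gene start→end); GC, k-mer, MFE and length over the *spliced sequence*.
- Signal statistics are moments of the per-base value vector across the
  span with uncovered bases reading 0 (so max/min include 0 whenever part
  of the span is uncovered). They are computed by interval arithmetic; the
  per-base expansion is the semantics and the test oracle. The variance is
  accumulated about the mean to avoid cancellation on near-constant signal.
- Minus-strand CAGE signal is stored signed-negative (unsigned input can be
  negated on load), which is why the schema takes its minimum and the plus
  strand's maximum.
- The promoter-coverage feature uses a strand-aware upstream window,
  default 500 bp, clipped at chromosome ends.
- `max_tfbs` is the maximum per-base stacking depth of binding-site
  intervals within the span (the natural "maximum" for an unvalued
  interval track). A single `cov_remap` feature is implemented; the
  source's feature table lists two names for that one-feature row.
- Missing track data imputes 0 — the classifier never sees missing values.
- Conservation is two generic signal tracks (`pcons27`, `phylocons124`
  column names); which genome-wide scores back them is configuration.

### k-mer embedding

Per k: binary presence of each corpus-observed k-mer per sequence, IDF
weights with the smoothed convention `ln((1+N)/(1+df)) + 1`, L2 row
normalisation, then the first right-singular vector of the weighted matrix
(dense SVD; corpora here are modest and determinism matters more than
speed). The sign is fixed by making the largest-magnitude loading positive,
so components reproduce across platforms. The projector is fitted on the
training corpus only and frozen — inference always projects onto the
training-time basis (no leakage), and it persists to JSON bit-exactly.
Sequences shorter than k, or sharing no k-mer with the corpus, project
to 0.

### Structure MFE

The built-in folding engine is a unit-energy Nussinov dynamic program:
Watson–Crick plus GU wobble pairs, hairpin loops of at least 3 unpaired
bases, energy −1 per pair, giving a score ≤ 0 (0 when nothing can pair).
It is a deliberate structural stand-in — it ranks pairing potential, not
thermodynamics — with a plug-in hook (`mfe(seq, engine=...)`) accepting any
`str -> float` thermodynamic folder. Because the DP is O(n³), matrix
assembly folds a configurable 5′ window (default 160 nt) of each
transcript; the `mfe()` operator itself folds whatever it is given, and the
test oracle is exhaustive structure enumeration on sequences ≤ 12 nt.

## Classifier

An explainable-boosting-machine-style GAM, authored here:

- Each feature is discretised into up to 256 quantile (default) or uniform
  bins fitted on the training data.
- Training is cyclic gradient boosting on the logistic loss: every round
  fits, per feature, one depth-one Newton stump over that feature's bins —
  the split maximises the usual gain `G²_L/(H_L+λ) + G²_R/(H_R+λ)` with
  both leaves holding at least `min_samples_leaf` rows and a small ridge
  λ = 10⁻³ — and adds the damped (learning-rate-scaled) leaf values to the
  feature's shape function.
- Early stopping monitors log-loss on a stratified 15% inner split with
  patience 30 rounds. Inner-split membership is decided by hashing
  (seed, bag, row label), so the fit is invariant to row order and exactly
  reproducible. Datasets under 40 rows skip the inner split.
- Outer bagging (default 8 bags, each with its own inner split) averages
  the resulting shape functions; averaging piecewise-constant stumps is
  what stabilises the boundary behaviour of small datasets.
- Optional pairwise interaction terms (`interaction_depth` of them) are
  selected among the top-ranked main effects and boosted on the residual
  of the averaged mains, with the same early stopping and bagging.
- After fitting, every term is centred over the training distribution and
  the means are folded into the intercept, so `logit p = intercept + Σ
  terms` exactly, contributions are mean-zero and comparable, and the
  global importance of a term is the mean |shape| over training rows
  (zero for constant features).

No resampling of any kind is applied to the training set: the class
imbalance of annotation-derived corpora is part of the problem, and
synthetic augmentation was reported to cost precision on it. Resampling is
therefore not even an option of `train()`; anyone reproducing that
comparison applies it upstream of the dataset.

Hyperparameter search (`tune`) is a seeded sweep over a declared space
(learning rate 10⁻³–0.5 log-uniform, rounds 100–5000, interactions 0–10,
min leaf 2–50, binning {quantile, uniform}) or an explicit configuration
list, maximising **precision** on a disjoint evaluation slice — false
positives are the expensive mistake when triaging candidates. A trial
predicting zero positives scores precision 0 (rewarding degenerate
all-negative models would otherwise win ties). The full trial ledger
persists as JSON lines. `retrain_final` refits on train+test and refuses
overlapping row IDs. The decision threshold defaults to 0.5 (call = 1 iff
p ≥ threshold) and is exposed everywhere.

Model bundles persist to a single JSON file (bins, shapes, pair grids,
intercept, contributions, schema fingerprint, hyperparameters, optionally
the k-mer projector); reloaded bundles reproduce predictions bit-exactly.

## Evaluation protocol

Stratified 70/15/15 partition with per-class largest-remainder rounding
(deviation from target fractions at most one instance per class per set;
classes so small that a 15% share rounds to zero still get one instance
each, at the cost of that bound). Stratified k-fold assigns each shuffled
class round-robin, so per-fold class counts differ by at most one.
Metrics follow the standard confusion-count formulas with the
zero-denominator convention precision = recall = 0 (warned). ROC and PR
points come from the threshold sweep over distinct scores
(scikit-learn curves); both AUCs are the package's own trapezoid over
threshold-ordered points, which for ROC equals the pairwise rank statistic
with ties at ½ — the property the tests check against an O(n²) oracle.
Cross-validation reports per-fold metrics, mean ± sd, and pooled
out-of-fold scores.

qPCR arithmetic: relative expression `2^(−ΔCt)`, fold enrichment as a
ratio of relative expressions, and a strict Ct-threshold expression call
(`expressed` iff Ct < threshold, default 37.9 — the negative-control
amplification cycle; at exactly the threshold the call is negative).
Differential expression itself is out of scope: the metadata CSV is parsed
and its conditions are attached to the FPKM column names of the results
file for downstream tools.

## Demultiplexer

A read belongs to a cluster iff its header contains any whitelist barcode
as a substring — matching the upstream tool's stated behaviour — with an
optional strict mode that matches only whole colon/whitespace-delimited
header tokens. Reads matching several sets are written to each (disjoint
whitelists make this moot in practice); a read matching two barcodes of the
same set is emitted once. Output records are byte-identical copies in input
order. Gzip inputs are detected by magic bytes, not extension. Paired-end
folders are processed file-by-file. Barcode lists are deduplicated with a
logged count; mixed lengths are an error; a flag strips `-N` well suffixes.

## Synthetic-data generator

Every generator is a pure function of (config, seed) — byte-identical
outputs across runs. The genomic path emulates the statistical structure
the classifier assumes: protein-coding genes carry higher GC (+0.10 by
default), stronger Pol II / H3K4me3 / CAGE signal (multiplicative effects
2.0 / 2.0 / 1.5), higher conservation (+0.30), denser regulator binding
(+0.35 hit probability) and likelier promoters (+0.5), each behind an
explicit effect knob; `null_effects()` zeroes all of them, making the class
distributions identical by construction. Critically, gene *architecture*
(exon count, lengths, strand, placement) is drawn from one shared
distribution for coding and noncoding genes, so geometry cannot leak class
signal — only the knobs do. Small-RNA genes are single short exons. The
assembled-transcriptome generator re-emits the reference under generated
IDs with `ref_gene_id` links plus `n_novel` unlinked candidates placed to
honour a known subclass truth (cycling lincRNA/intronic/antisense), with
log-normal per-sample FPKM attributes. The read generator embeds each
read's cell barcode as a colon-delimited header token and records
per-cluster truth counts; a configurable fraction of reads carries decoy
barcodes. A fast path (`make_labeled_dataset`) simulates the feature space
directly — standard-normal noise with mean-shifted informative features —
for model tests that need thousands of rows in milliseconds.

What the generator does *not* emulate: sequencing error, coverage
variability, assembly artifacts (fragmented or merged transcripts), codon
structure or ORFs, realistic k-mer composition beyond GC, genuine
thermodynamic folding energies, UMIs, or barcode sequencing errors.
Passing tests therefore demonstrate that the machinery recovers planted
structure under its own assumptions — not field performance on real
genomes, which depends on the quality of the real tracks and annotation.

## Problem sizes and simulation choices

Chosen as the package's own defaults: end-to-end recovery runs use ~300
genes on 4 chromosomes of 160 kb (strong effects; validation ROC AUC is
checked against 0.95), while the null-effect check uses ~1 200 genes and
pools stratified five-fold out-of-fold scores — pooling uses every
simulated row once, giving a chance-level AUC estimate with sampling sd
≈ 0.02, tight enough that the [0.45, 0.55] band is meaningful rather than
a lucky draw. Oracle property suites run ≥ 1 000 random cases per kernel
(per-base signal expansion, pairwise-rank AUC, exhaustive folding
enumeration at ≤ 12 nt, dense-SVD k-mer projection, all-pairs interval
overlap).

## Known limitations

- The unit-energy folding score correlates with, but is not, a free
  energy; plug in a thermodynamic folder for real energies.
- Boolean fingerprints are stored densely in the assembled matrix; at the
  full 730-column, genome-scale configuration a sparse container would be
  the next step.
- The stump booster's shape functions are piecewise-constant; very smooth
  dose-response features are approximated in steps.
- Pipeline training (when no model bundle is supplied) uses fixed, modest
  hyperparameters; serious use should `tune` on the target corpus and pass
  the resulting bundle.
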