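# Methods

## The problem and the model

Somatic-mutation datasets attach labels to *samples* (a tumour's
microsatellite status, its tissue of origin) while the measurements are
individual *mutations*. `mutmil` treats this as multiple-instance
learning (MIL): a sample is a bag, a mutation is an instance, and a
single end-to-end model encodes instances, weights them by trainable
attention and aggregates them into a sample vector for classification.
Because the aggregation is a segment-wise reduction over an unordered
set, predictions are permutation invariant by construction.

The pipeline is

1. **Variant IO** (`mutmil.variant_io`) — MAF-dialect parsing, FILTER-set
   retention (a record is kept iff its flags are a subset of the allowed
   set, so combinations of allowed flags pass), optional multi-caller
   thresholding, BED-interval intersection (full reference span must lie
   inside the covered union; insertions test their one-base anchor), and
   merging of consecutive single-base substitutions.
2. **Concepts** (`mutmil.concepts`) — featurizers for local sequence
   context (fixed-width padded flank/allele arrays in forward and
   reverse-complement orientation), the SBS96 trinucleotide category
   with a 97th outgroup, genomic position bins over the concatenated
   genome, gene identity through a sorted vocabulary with an OTHER
   bucket, and reading frame (strand + CDS position mod 3; zero vector
   for noncoding).
3. **Model** (`mutmil.mil`) — statsmodels-style `MILClassifier` /
   `MILResults` objects over a small reverse-mode autodiff core
   (`mutmil.autodiff`), with per-concept encoders, multi-headed
   adaptive-sigmoid attention and three aggregation modes.
4. **Training** (`mutmil.training`) — MIL instance dropout, inverse
   frequency class weights, stratified folds/batches, early stopping.
5. **Interpretation** (`mutmil.interpret`) — attention z-scores,
   top-attention extraction, K-means instance clustering ordered by
   median attention, sequence-logo probability matrices and information
   content.

## Adaptive activations

All nonlinearities derive from the adaptive square root
`ASR(x, a) = sqrt(exp(a) + x^2)`:

* `ARU(x, a) = 0.5 (x + ASR(x, a))` — a smooth rectifier, strictly
  positive for finite x, tending to ReLU as `a -> -inf`;
* `ASU(x, a_lo, a_hi) = (x + ASR(x, a_lo)) / (ASR(x, a_lo) + ASR(x, a_hi))`
  — a sigmoid bounded by (0, 1).

The input appears only squared, never as `exp(x)`, so aggregation over
large bags cannot overflow. Curvatures are trainable per unit. Default
initializations are derived, not tuned: `ARU_ALPHA0 = 2 ln(2 ln 2)`
matches softplus at x = 0 exactly; `ASU_ALPHA0 = 2 ln 2` matches the
logistic sigmoid's value (1/2) and slope (1/4) at x = 0.

## Attention and aggregation

Attention is a linear map from instance features to one scalar per head,
passed through ASU, so every weight lies strictly in (0, 1). With one
head per class the heads act as class-specific attention (the multiclass
default); binary models use a single head. An L1 activity penalty
(`attention_l1 x mean attention`) sharpens the separation between key
and background instances; more L1 gives clearer separation at some cost
in accuracy.

Aggregation modes:

* **mean** — per-head attention-weighted average (weights normalized to
  sum 1). Scale-invariant in the attention, which makes it robust to the
  L1 penalty.
* **sum** — per-head attention-weighted sum followed by elementwise
  `log1p`. Instance features are non-negative (ARU/ReLU-activated), so
  the raw sum grows with bag size and the log keeps it bounded;
  `log1p(0) = 0` keeps absent features neutral. Sum mode is the right
  choice when the *number* of key instances carries the label.
* **dynamic** — a first attention + weighted mean produces a sample
  vector, which is broadcast back and concatenated onto each instance's
  features; a second attention is computed from this context and a
  second aggregation (mean or log-sum) produces the output. This lets an
  instance's weight depend on its bag. The second aggregation reduces
  the original instance features; the broadcast vector only steers the
  second attention.

Ragged bags are batched as one instance-major matrix plus per-bag row
counts; every reduction is segment-wise (`numpy.add.reduceat`), and no
bag is padded.

## Training

The loss is class-weighted cross-entropy (weights proportional to
inverse class frequency, normalized to mean sample weight 1 — so a
calibrated uniform predictor scores ln C regardless of imbalance) plus
the attention L1 and any L2 kernel penalties, minimized with Adam.
Batches are stratified: each class's samples are spread evenly through
the epoch order, so every minibatch has near-proportional class
representation. MIL instance dropout keeps a fresh uniform subset of
`ceil((1 - rate) n)` instances (never fewer than one) per bag per
gradient update; evaluation always uses all instances. Early stopping
monitors validation weighted cross-entropy and restores the best
parameters. With fixed seeds the whole loop is bit-reproducible on CPU.

Numerical choices: float64 throughout; softmax is max-shifted; binary
heads use a single logit through ASU, whose output is strictly inside
(0, 1) so log-likelihoods are always finite. The final linear layer uses
a small random init — with an exactly zero init no gradient reaches the
attention or encoders during early steps, and in sum mode the attention
L1 can collapse all weights to zero before any classification signal
arrives (we observed exactly this failure). Divergence (non-finite
loss) aborts with a diagnostic rather than continuing.

## Sequence encoder

The sequence concept is four components (5' flank, 3' flank, ref, alt),
each W wide, in both orientations, one-hot with PAD as the all-zero row.
Two encoder modes:

* `conv` — per-component banks of `n_kernels` convolution filters
  (width `kernel_size`), ARU activation, shared between orientations,
  max-pooled over positions, fused by a ReLU dense layer. Suits
  position-free motifs such as homopolymer runs.
* `dense` — flatten and apply one ARU dense layer. Position-sensitive;
  suits tasks where the variant-adjacent alignment matters (codon frame).

`msi_reference_config()` ships the reference binary architecture for
microsatellite status: 8 kernels per sequence component with ARU, fusion
to 128 with ReLU and 0.01 L2, 0.5 feature dropout, single-head ASU
attention with 0.05 L1, instance dropout 0.4, then 256/0.5-dropout/128/
0.5-dropout to one logit. Aggregation is the attention-weighted mean:
the sources describing this architecture do not name its aggregation
function, and the mean's scale-invariance keeps training stable under
the attention L1 at small sample sizes (log-weighted-sum variants
collapsed their attention at desk scale). Note this architecture is
sized for cohorts of hundreds of samples with thousands of instances
each; on the bundled synthetic tasks (hundreds of bags, tens of
instances) its 0.5 dropouts underfit, so the test suite and the
acceptance script exercise a desk-scaled variant of the same topology
(fusion 64, one 32-unit head layer, dropouts off).

## Synthetic tasks

The generators in `mutmil.simulate` are pure functions of a `TaskSpec`
(bit-reproducible given the seed) and probe the axes that matter for MIL
on mutation data; they are analogs of the corresponding real-data
settings, not replications.

* **presence** — the classic witness-rate benchmark: positive bags carry
  key instances at the witness rate (at least one), negative bags none.
  Defaults: 500 bags of 50-100 instances, witness rate 0.05.
* **count** — label = (number of key instances > 5), with the key count
  drawn uniformly on 0..12 *independently* of bag size (10-150), so the
  key fraction overlaps between classes and only an aggregation that
  preserves absolute counts (sum) can separate cleanly. A brute-force
  recount of key codes reproduces the labels exactly.
* **fraction** — the complement: label depends on the key fraction.
* **context** — label = key AND marker instances co-occur (disjoint
  slots). With a *linear* post-aggregation head this is not separable
  from mean-pooled code fractions (an AND over two coordinates), while
  dynamic attention can gate the key's second-round weight on the
  marker's presence in the sample vector; the comparison uses linear
  heads in both arms to isolate the aggregation mechanism.
* **repeat_indel** — a microsatellite-instability analog: positive bags
  are enriched for 1-bp deletions inside planted mononucleotide runs of
  length 5-15, rendered as W=20 sequence concepts; background instances
  are random SBSs and non-repeat deletions (rejection-sampled so no run
  of 5+ spans the deleted base). Per-instance key flags are retained for
  attention-separation and logo checks.
* **consequence** — a toy contig (~9 kb) with ~12 non-overlapping ORFs
  planted on both strands; variants are labelled by an independent
  translation oracle (Biopython codon table) over frameshift/in-frame
  indels, missense, nonsense, silent and noncoding, drawn to class
  balance. Variants in stop codons that would lose the stop are
  resampled. This is a per-instance task (bags of size one with frozen
  attention), used to show the sequence encoder separates
  missense/nonsense/silent only when given the reading-frame feature.

What the generators do *not* emulate: realistic trinucleotide signature
mixtures, caller noise, coverage bias, or correlated mutation processes.
Passing these tasks shows the machinery (encoders, attention,
aggregation, training) does what it claims on planted structure; it does
not certify accuracy on real cohorts.

## Problem sizes

Desk-scale defaults keep every experiment on one CPU core: presence
500 + 200 bags x 50-100 instances; count 300 + 150 bags x 10-150;
repeat-indel 150 + 80 bags x 20-50 at witness rate 0.3 (the enrichment
of repeat indels in mismatch-repair-deficient tumours is high, so 0.3 is
a realistic witness rate for that analog); consequence 8,000 instances
(6,500 train). These sizes were chosen as the smallest at which the
phenomena of interest are stable across seeds.

## Interpretation

Attention z-scores make heads and folds comparable: within each head,
attention over features is z-scored; heads are averaged, then folds.
Zero-variance heads carry no ranking signal and contribute 0 (with a
warning). Top-attention extraction takes the `ceil(frac x n)` highest
instances of a head with ties broken by input order. K-means clusters
(unit-variance scaling by default; `scale=False` for raw) are relabelled
so cluster 0 has the highest median attention. Logo matrices are
column-stochastic over the 5' | allele | 3' layout with PAD excluded
from denominators, computed separately per variant class; information
content is `2 - H` bits per column, with no small-sample correction, and
carries the caveat that pooled logos lower-bound the information a head
uses (one head may attend to several motifs).

## Known limitations

* No GPU path and no minibatch parallelism; the autodiff core is plain
  numpy and sized for desk-scale experiments, not TCGA-scale training.
* VCF input is not parsed (MAF dialects only); GFF3 transcript models
  are not consumed — gene/strand/CDS-position annotation is expected as
  columns of the variant table.
* The consequence oracle labels partially-overlapping indels at ORF
  boundaries as noncoding and resamples stop-loss variants rather than
  modelling them.
* The merge rule's "percentage difference" and "VAF deviation" admit
  several readings; both are implemented (`pct_mode`, `vaf_mode`) with
  the defaults documented in `merge_consecutive_snvs`.
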