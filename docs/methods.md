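# Methods

## Labeling model

Matched FF/FFPE pairs from one tumor, processed through one pipeline,
define the supervision signal. A call in the FFPE PASS set is labeled a
**true variant** when its full variant key (chrom, 1-based pos, ref,
alt) occurs in the FF PASS set, otherwise an **FFPE artifact**. Matching
is exact: no left-alignment, no `chr`-prefix normalization, and a
different alt at the same site is a different variant. This assumes both
call sets share an allele representation, which holds when the same
caller and reference are used for both samples. The known caveat is
inherited deliberately: a real subclonal variant missed in the FF sample
(regional heterogeneity, sampling) is labeled an artifact; the labeler
makes no attempt to rescue such calls.

Train/validation partitioning is per source file: each sample's calls
are shuffled and split independently at a 7:3 ratio (train gets
round-half-up(0.7·n)), with a dedicated RNG stream per sample derived
from the split seed (default 42) so that adding or removing one sample
does not reshuffle the others. Because technical replicates may be used
as separate samples, validation calls whose key occurred *anywhere* in
training are excluded before evaluation.

## Feature vector (schema `v1`, 41 entries)

22 raw MuTect2 annotations (DP, AD_ref, AD_alt, AF, F1R2_ref, F1R2_alt,
F2R1_ref, F2R1_alt, MBQ_ref/alt, MFRL_ref/alt, MMQ_ref/alt, MPOS, TLOD,
ECNT, POPAF, GERMQ, SEQQ, STRANDQ, ROQ), 4 derived entries, a 3-way
variant-class one-hot and a 12-way substitution-type one-hot. The
derived entries:

* `SOB = |F1R2_alt − F2R1_alt| / (F1R2_alt + F2R1_alt)` ∈ [0, 1];
  0 means balanced pair orientations, 1 means fully one-orientation
  support, the signature of orientation-specific formalin damage.
  Undefined (missing) when the alt allele has no orientation-resolved
  support.
* orientation cosine: cosine similarity between the ref and alt
  (F1R2, F2R1) count vectors; near 1 for real variants whose alt reads
  mirror the reference orientation profile. Undefined when either
  vector is all-zero.
* ref and alt allele lengths.

The variant class (SNV/INS/DEL) is assigned by allele-length comparison,
so the block always sums to exactly 1; multi-nucleotide substitutions
count as SNV-class but keep all twelve substitution flags at zero, since
the per-type spectrum is only defined for single-base changes. The
12 substitution types are strand-specific (C>T and G>A are separate
entries) because deamination damage is orientation-specific.

Missing annotations are carried as NaN with a per-entry flag — never as
zero — and imputed with the **training-set median** inside the scaler,
which then z-scores numeric entries with training mean/sd (constant
features map to 0, one-hot entries pass through untouched). The scaler
is fit on the training split only, so no validation information leaks
into preprocessing.

## Classifier

Three linear layers, 41 → 32 → 16 → 2, ReLU on the two hidden layers,
one batch-normalization layer after each hidden activation (ε = 1e-5,
running-statistics momentum 0.1), softmax output. The positive output
node is the probability of being a true variant; the loss is cross
entropy on that probability (binary cross entropy). Total trainable
parameters: 1344 + 64 + 528 + 32 + 34 = 2002.

Training uses Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Defaults, pinned
for reproducibility and overridable via the estimator parameters:
learning rate 1e-3, batch size 256, 100 epochs, no class weighting.
Weight initialization (He-scaled normals) and per-epoch shuffling come
from a single `numpy` Generator seeded with `random_state`, so two fits
with the same seed produce bit-identical weights. After training the
batch-norm layers freeze their running statistics; inference is a pure
function of (weights, input) and never updates state.

Decision rule: probability ≥ threshold ⇒ true variant. The boundary is
inclusive by convention (a call scoring exactly at the cutoff is kept),
which makes thresholding monotone: lowering the threshold can only add
kept calls. The default threshold 0.5 travels with the saved model
bundle (a `.npz` archive holding weights, batch-norm statistics, scaler
statistics, schema names and fingerprint, threshold and seed).

## Metrics and reports

With true variant as the positive class:
accuracy = (TP+TN)/(TP+TN+FP+FN), specificity = TN/(TN+FP),
sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
F1 = 2/(sensitivity⁻¹ + precision⁻¹). Zero-denominator cases return
0.0 with an explicit `undefined` flag; F1 is 0.0 whenever either
component is 0. Rounding for report comparison is decimal half-up at
3 decimals.

The threshold sweep evaluates F1 at 0, at every midpoint between
consecutive distinct probabilities, and at 1 — this covers every
achievable prediction set — and breaks ties toward the lowest
threshold, which maximizes sensitivity among the optima. Stratified
reports cover: overall; per cancer type; the deamination transition
group C:G>T:A = {C>T, G>A} and the oxidation transversion group
G:C>T:A = {G>T, C>A}; and the low-MAF bin, the *open* interval
1% < MAF < 5%. Empty strata are emitted as flagged rows, not errors.

## Synthetic matched-pair generator

The generator draws call-level annotations directly (no reads). Per
call: depth ~ NegativeBinomial(mean 80, dispersion 10) floored at 10;
alt support ~ Binomial(depth, MAF) conditioned ≥ 1; orientation counts
~ Binomial splits with the class bias for alt reads and 0.5 for ref
reads, so `F1R2_alt + F2R1_alt = AD_alt` holds exactly. Class-specific
defaults:

| parameter | true variants | artifacts | basis |
|---|---|---|---|
| MAF | Beta(2.5, 7.0), median ≈ 0.25 | Beta(1.8, 14.0), median ≈ 0.10 | documented MAF separation |
| orientation bias | 0.5 | 0.9 | artifact SOB median ≈ 0.66 |
| substitution weights | uniform over 12 | 0.35 C>T, 0.35 G>A, 0.03 each other | deamination spectrum |
| median position in read (MPOS) | N(25, 7) | N(12, 7) | damage near fragment ends |
| indel fraction | 0.08 | 0 | deamination artifacts are substitutions |
| fragment length mean | 221 bp (FF sample) | 147 bp (FFPE sample) | observed insert medians |

Fragment length is a property of the *sample*, not the class: all FFPE
calls draw MFRL around 147 bp and all FF calls around 221 bp, so it
carries no label signal within one FFPE file. Base/mapping qualities
and the site-level Phred annotations (GERMQ, SEQQ, STRANDQ, ROQ) are
drawn from identical distributions for both classes — the learnable
signal is confined to MAF, orientation bias, substitution type, read
position and the indel excess, mirroring what the labeler can actually
see in real data. Positions are unique (chrom, pos) slots on an
abstract 22-chromosome genome; no reference FASTA is needed.

What the generator does **not** emulate: sequence context
(trinucleotide signatures), regional tumor heterogeneity, sample-to-
sample quality variation, multi-allelic sites, and correlated
annotation noise. Passing the synthetic benchmark therefore shows that
the pipeline recovers the encoded class structure end to end, not that
real-data performance is attained; real validation requires matched
FF/FFPE pairs.

## Problem sizes and numerical choices

The default benchmark uses 2,000 true variants + 2,000 artifacts
(2,800 train / 1,200 held-out after the 7:3 split), which gives the
held-out metrics a standard error of about 1 point; the no-signal
control uses 5,000 + 5,000 so that its accuracy estimate is tight
enough to confirm chance-level behavior within ±3 points. The
no-signal control sets both classes to the true-variant distributions
(equal MAF Beta, bias 0.5, uniform spectra, equal MPOS, no indels) and
must land at the class-proportion baseline.

Ties and degenerate inputs: duplicate variant keys within one call set
are rejected as ambiguous; an AD sum exceeding DP is recorded verbatim
and flagged, never clamped; empty FFPE inputs label to an empty set;
metric computation on an empty confusion matrix is an error, while an
empty report stratum is a flagged row. VCF records with symbolic or
non-ACGT alt alleles are skipped by the reader, as the classifier is
defined only for sequence-resolved alleles.

## Known limitations

* Labels inherit the FF-presence definition, so true subclonal variants
  absent from FF are trained on as artifacts.
* The 41-entry schema is a versioned reconstruction spanning all named
  discriminative properties using only MuTect2 outputs; alternative
  layouts of the same width can be swapped in via `FeatureSchema`, and
  the model bundle's schema fingerprint guards against mixing layouts.
* Hidden-layer widths aside, the training hyperparameters (learning
  rate, batch size, epochs) are pinned package defaults, not tuned
  values; they train the default benchmark to convergence in seconds.
* The insert-length QC operates on alignment records (properly paired,
  not duplicate/secondary/supplementary, MQ > 20, one count per
  template via the positive-TLEN mate) and is reported separately; it
  is not a classifier feature beyond the caller's own MFRL.
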