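# Methods

## Problem

Orthologous-group (OG) assignment places a protein sequence into one of the
groups of an orthology database. Alignment-based tools (profile HMM search,
fast protein aligners) are accurate but slow at database scale. `ognet`
implements an alignment-free alternative: a convolutional classifier that maps
a raw residue string directly to a probability distribution over groups, plus
a confidence threshold that leaves sequences from unknown groups unassigned
instead of forcing a wrong label.

## Model

### Embedding network (`variant="deepnog"`)

1. **Encoding.** Sequences use the 26-letter extended IUPAC protein alphabet
   (20 standard residues plus B, J, O, U, X, Z), indexed 1..26 in alphabetical
   order; index 0 is reserved for padding. The ordering is persisted inside
   every model archive so encodings remain stable.
2. **Embedding.** Each code is embedded into R^D (default D = 10), trained
   jointly with the classifier. Unlike one-hot encoding, the embedding can
   place biochemically similar residues near each other. The padding row is
   pinned to the zero vector and excluded from updates.
3. **Convolution.** For each filter size K in {8, 12, 16, 20, 24, 28, 32, 36},
   F filters (default F = 150) slide over the embedded sequence with stride 1
   and no implicit padding, producing L − K + 1 activations per filter. The
   activation is SELU (λ ≈ 1.0507, α ≈ 1.6733), making the feature extractor
   self-normalizing: no batch-normalization layers are needed.
4. **Masked adaptive max-pooling.** Each filter keeps the maximum activation
   over the sequence's *valid* windows only: positions 1..max(L − K + 1, 1).
   Sequences shorter than the largest filter are zero-padded to 36 so every
   filter sees at least one window. Because windows lying entirely in trailing
   padding are excluded, a sequence's output is mathematically independent of
   how far its row is padded and of its batch companions — the property the
   tests call padding invariance. (Pooling over the full padded row would emit
   SELU(bias) for pure-padding windows and silently couple outputs to batch
   composition; the masked form is therefore the only choice under which the
   "arbitrary input length" contract is exactly testable.)
5. **Classification.** The |K|·F pooled features (1200 by default) go through
   dropout (P = 0.3, training only) straight into an affine softmax layer —
   no hidden layer — so the classifier stage is multinomial logistic
   regression on motif-occurrence strengths. Argmax ties break to the lowest
   output index.

### Fixed-length baseline (`variant="deepfam"`)

The comparison architecture encodes sequences as pseudo one-hot matrices of a
fixed length (default 1000; longer sequences are rejected): 20 standard
residues plus X are one-hot in 21 dimensions, and the ambiguity codes
interpolate (B = ½D + ½N, J = ½I + ½L, Z = ½E + ½Q; O and U fold into X).
Convolutions use the same filter sizes, followed by batch normalization
(ε = 1e-5, running-statistics momentum 0.1 for inference) and ReLU, full-row
1-max-pooling over exactly fixed_length − K + 1 units, a hidden ReLU layer
(best 2000 units with 250 filters/size; light 1500 with 150), dropout, and
the softmax output. The hidden activation is ReLU — a choice, since the
baseline's hidden nonlinearity is not pinned down here.

### Parameter counts

`count_parameters` gives the closed form; for the embedding network
(A+1)·D + Σᵢ F·(KᵢD + 1) + |K|·F·C + C, with A = 26 and C the group count.
The frozen padding row is counted because it is allocated. The form is tested
against brute-force enumeration of the allocated arrays for random
configurations.

## Training

* **Filtering.** Groups below a minimum population (thresholds of 100 or 500
  are typical at database scale; any value ≥ 3 works) are dropped entirely —
  singletons cannot be split.
* **Splits.** Per-group stratified 81 / 9 / 10 train/validation/test with
  largest-remainder rounding and an at-least-one-member floor per partition;
  members are shuffled under the run seed. A group of exactly 100 splits
  81/9/10; a group of 3 splits 1/1/1.
* **Initialization.** Convolution and affine weights ~ N(0, 1/fan_in), biases
  zero, embedding rows standard normal — the regime in which SELU propagates
  approximately zero-mean/unit-variance signals, which the tests verify
  empirically at initialization (mean within ±0.3, variance within [0.5, 1.5];
  the bands are this package's acceptance tolerances for the qualitative
  property).
* **Optimization.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on the softmax
  cross-entropy (the natural loss for a softmax classifier; row 0 of the
  embedding receives no gradient). Learning rate 0.01 decayed by 25% after
  each epoch, batch size 64, per-epoch seeded shuffling, default 15 epochs
  with the best-on-validation-accuracy epoch's weights returned (ties to the
  earliest epoch). The ReLU/batch-norm baseline is trained at Adam's
  conventional rate of 0.001 — its original training procedure — because the
  0.01 schedule is tailored to the self-normalizing network and sits at the
  edge of stability for the baseline.
* **Implementation.** Forward and backward passes are written directly in
  numpy (im2col convolutions on BLAS matrix products; the pooling argmax makes
  most gradients sparse). Analytic gradients are verified against central
  finite differences in the test suite. Training is deterministic given the
  data, initialization and shuffle seeds on fixed hardware arithmetic.

## Inference and open-set rejection

`assign` computes softmax probabilities per sequence and reports the rank-1
group when its probability reaches the confidence threshold, default **0.99**
— a strict setting that trades a few missed in-model sequences for very few
false assignments of out-model sequences. Below the threshold the sequence is
"unassigned" but keeps its rank-1 probability, so results can be
re-thresholded without re-running the network. Confidence histograms use 100
bins of width 0.01, half-open except the last (closed at 1.0). Results are
independent of batch size by the padding-invariance property. Under the
fixed-length baseline, sequences longer than the model's input length cannot
be scored and come back unassigned with confidence 0.

## Metrics

Accuracy is the fraction of correct assignments among all inputs ("unassigned"
counts as incorrect). Because accuracy is dominated by large groups,
macro-averaged precision and recall are reported alongside: per-group values
averaged unweighted over the groups present in the truth. A group never
predicted gets precision 0 (pessimistic but well-defined); groups only ever
predicted, never true, contribute false positives but no row of their own.
`score` is tested against an independently written brute-force confusion
matrix and against scikit-learn's macro metrics where the conventions
coincide.

## Synthetic data generator

The generator emulates the two features of orthology databases that matter
for this classifier: group-specific sequence motifs (what the filters learn)
and imbalanced populations (rank r gets round(base·r^(−e)) members, floored at
1, so e > 0 produces a singleton tail). Sequences are i.i.d. uniform over the
20 standard residues; each family's motifs (consensus length 6–12) are
implanted at fixed relative positions, with each site redrawn uniformly over
the 20 residues with the per-site mutation probability (so retention is
(1 − m) + m/20 — a closed-form oracle tested by simulation). Out-model
families for the confidence analysis come from the same process with a fresh
seed and disjoint group ids.

What the generator does **not** emulate: indels, phylogenetic correlation
among family members, natural residue composition, domain architecture,
homology between families. Passing the scaled benchmark therefore shows the
implementation learns implanted motif structure under noise and imbalance —
it does not certify accuracy on real orthology databases, where remote
homology and shared domains make the task much harder.

## Scaled benchmark (`ognet.experiments`)

The standard study conditions, fixed once: 20 in-model families × 200
sequences (3 motifs each, 5% per-site motif mutation, lengths uniform
80–300), stratified 81/9/10 split; the embedding network with F = 16 filters
per size and the baseline with F = 16, 128 hidden units and fixed length 300
(covering the generator's length law), both trained 5 epochs; 10 extra
out-model families × 100 sequences for the rejection analysis at threshold
0.99. The reduced filter count and epoch budget keep a full run to a few
minutes on one CPU; at these settings the embedding network reaches ≳99% test
accuracy and the baseline ≳90%, and the in-/out-model confidence
distributions separate cleanly (median in-model confidence near 1, out-model
far below; the fraction of out-model sequences above the threshold is near
zero).

## Numerical choices and degenerate inputs

* Softmax is computed in float64 with max-subtraction; weights and forward
  passes are float32.
* Padding invariance is exact in the masked-pool arithmetic; BLAS blocking
  across different matrix shapes leaves relative differences ~1e-6, and the
  documented contract is ≤1e-5 relative.
* A single-residue sequence is padded to 36 and yields one valid window per
  filter — finite logits, no special case.
* Sanitation: one trailing `*` is stripped (warning); internal `*` and any
  character outside the alphabet become X (warning); a sequence empty after
  sanitation is an error naming the record.
* Empty FASTA input yields an empty result with a warning, not an error.

## Known limitations

* CPU-only by construction; throughput is adequate for desk-scale databases,
  not for multi-million-group ones.
* Single-label classification only; multi-domain proteins that belong to
  several groups get at most one.
* The baseline's hidden-layer nonlinearity and the exact split rounding rule
  are underdetermined by the published descriptions; the choices here (ReLU;
  per-group largest remainder with a one-member floor) are documented above.
* Alpha-dropout is not implemented; plain dropout performed better in the
  published exploration and is the only variant exposed.
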