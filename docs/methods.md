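# Methods

## Problem setting

For one RNA-binding protein (RBP), the observed data are variable-length
sequence fragments on circular RNAs where cross-linking experiments place
binding sites. The task is binary: does a fragment carry the RBP's
sequence preference? Negatives are not random genomic background but
dinucleotide-preserving shuffles of the positives themselves, so a
classifier cannot win on composition statistics (GC or CpG content); it
must learn order-dependent sequence features, i.e. motifs.

## Dataset construction

- **Deduplication.** Exact-duplicate positive sequences are collapsed
  (first identifier wins). CLIP-derived site collections are heavily
  redundant; with only sequences (no genomic coordinates) exact identity is
  the reproducible criterion. When coordinates are available, an overlap
  filter is the natural extension; none is applied by default because no
  principled cutoff exists without calibration data.
- **Length threshold.** Fragments vary in length, but the network takes a
  fixed `L`. The threshold is the Tukey boxplot upper fence
  `Q3 + 1.5·IQR` of the site-length distribution with linear-interpolation
  quartiles, rounded to the nearest integer. Sites above it are treated as
  outliers and discarded; this loses a small fraction of data instead of
  truncating sites (which would bias toward the centre of long sites).
- **Centring and padding.** Shorter sites are centred in the `L`-window
  and padded with `N`; when the deficit is odd, the extra `N` goes to the
  3′ side (an arbitrary but fixed convention — symmetric alternatives are
  equivalent up to a 1-nt shift). `N` encodes as an all-zero row, so
  padding contributes nothing to any convolution sum; padding with flanking
  transcript sequence would instead inject sequence the cross-linking
  experiment never implicated.
- **Negatives.** One per positive, by the Euler-path (Altschul–Erikson)
  dinucleotide shuffle: the sequence is a walk on the base-transition
  multigraph, and a random Eulerian walk with the same start and end
  vertices has exactly the same 16 dinucleotide counts and terminal bases.
  Low-complexity sequences can admit a unique walk; if the shuffle returns
  the input, it is retried up to 10 times and then accepted.

## Architecture and numerical choices

One convolution layer (`K` filters, width `h`, ReLU), global max pooling,
primary capsules of dimension 8, one learned 16×8 affine matrix per
(input, output) capsule pair, dynamic routing, two 16-dimensional digit
capsules. Defaults: `K = 128` (so 16 primary capsules), `h = 9` for
fragments under 100 nt and `h = 11` above, routing rounds `T = 2`.

- **Squash.** `v ↦ (‖v‖²/(1+‖v‖²)) · v/‖v‖` with `ε = 1e-8` added inside
  the norm's square root, so the zero vector maps to zero and gradients
  stay finite.
- **Routing softmax axis.** The couplings normalise over the *n input
  capsules*, independently per output capsule. The convention in the
  original capsule-network literature normalises over output capsules
  instead; both are implemented (`routing_softmax="inputs" | "outputs"`),
  with "inputs" the default. With logits initialised to zero, `T = 1`
  reduces to `squash(mean(u))` under either reading.
- **Separate affine matrices per output capsule.** With a single shared
  matrix the two digit capsules would receive identical inputs and could
  only differ through routing; per-pair matrices let the two classes learn
  distinct projections.
- **No reconstruction decoder.** The classifier keeps max pooling and
  drops the reconstruction branch of the original capsule network; pooling
  both regularises and makes the per-filter argmax available for motif
  discovery.
- **Pooling ablation.** `maxpool=False` feeds the full feature maps to the
  capsule layer (the `K·(L−h+1)` activations regroup into 8-dim capsules),
  for the on/off comparison. The flattened size must divide by 8.
- **Margin loss.** `m⁺ = 0.9`, `m⁻ = 0.1`, `λ = 0.5`; summed over the two
  classes, averaged over the batch. It is zero exactly when the true-class
  norm reaches 0.9 and the other stays at or below 0.1.
- **Initialisation.** Weights ~ N(0, 0.1²), biases zero, seeded through
  `numpy.random.default_rng`; training, fold splitting and shuffling all
  derive from explicit seeds, so runs are bit-reproducible on a platform.
- **Gradients.** A minimal reverse-mode autodiff engine
  (`circrb.autodiff`) backpropagates through the unrolled routing loop,
  the max-pool argmax (leftmost tie-break) and the loss; every operator's
  gradient is tested against central finite differences. Optimisation is
  Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch 64, switching to 512 above
  100 000 instances (a config default; the switch point is not principled,
  only a throughput convenience).

## Training and evaluation protocol

Each fit holds out a stratified 10% of its training data; after every
epoch the validation margin loss is measured and the best-so-far weights
are kept (patience 5, max 30 epochs), so the returned checkpoint never has
a higher validation loss than any earlier epoch. Assessment is stratified
5-fold cross-validation (each fold 20% test), reporting the ROC AUC per
fold; AUC uses the rank statistic with ties counted ½.

## Motif discovery

For each detector and each positive test fragment, if the detector's
maximum activation is strictly positive, the `h`-window under the leftmost
argmax is extracted. Windows stack into a position frequency matrix; `N`
characters are excluded from their column's counts. Probabilities add a
pseudocount of 0.25 per base (all-`N` columns become uniform); information
content per column is `2 + Σ p log₂ p` bits. Detectors contributing fewer
than 10 windows are dropped by default (a config knob; below that the PFM
is mostly sampling noise). Export formats: MEME minimal (for Tomtom-style
comparison against reference motif collections — running such comparisons
is outside this package), tab-delimited counts, and logos (drawn with
matplotlib glyphs, `U` shown for RNA).

## circRNA scanning

The trained fragment length `W` slides along the full circRNA at stride 1.
Circular mode (default) treats every position as a window start, reading
junction-crossing windows from the sequence virtually concatenated with its
first `W−1` bases; a wrapped hit keeps its start coordinate on the original
sequence and sets a flag rather than reporting `end > L`. Coordinates are
1-based inclusive. Hits rank by score, ties by start; `report_top_hits`
greedily takes non-overlapping hits (overlap is wrap-aware). Whether real
binding sites cross the junction is an open biological question; the linear
mode exists for the comparison.

## Synthetic benchmark

The generator emulates the statistical structure the classifier assumes:
positives are i.i.d. background (uniform by default; a GC-rich preset
exists to confirm composition alone cannot separate the classes) with one
motif occurrence planted at a uniformly random offset; negatives are
dinucleotide shuffles of those positives. The benchmark conditions are
2000 positives, 50-nt fragments, consensus `ACTAAC` (the DNA form of the
canonical QKI motif) — chosen because QKI is the clearest biological
anchor for circRNA-RBP motif work. The benchmark network uses 64 filters
(8×8 capsules): the planted-motif task is easier than real CLIP data, and
64 detectors keep the three-seed protocol comfortably inside a desk-scale
CPU budget while leaving the default `K = 128` for real data. The pooling
ablation runs at a further reduced size (300 positives, 10 epochs, 32
filters) because it checks the alternative wiring end to end, not final
accuracy.

What passing the benchmark does **not** show: real binding sites have
positional and structural context, degenerate multi-motif grammars,
CLIP-specific noise and length variation that the generator deliberately
omits (fragments are fixed-length here; the padding path is exercised by
unit tests and real-FASTA workflows instead). Benchmark AUCs therefore say
the machinery works, not how the model performs on any particular RBP
corpus.

## Known limitations

- CPU-only; the autodiff engine favours clarity and testability over
  speed. Corpus-scale datasets (10⁵–10⁶ fragments) train, but slowly.
- Redundancy removal without coordinates is exact-match only.
- The routing-softmax convention is a genuine fork in the literature; both
  options are exposed, only the default is benchmarked.
- Binding scores are capsule norms in `[0, 1)`; they are calibrated only
  in rank, not as probabilities.
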