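# circrb

Capsule-network classification of the sequence specificities of
circRNA-binding proteins.

Circular RNAs (circRNAs) are covalently closed transcripts that interact
with RNA-binding proteins (RBPs); where an RBP binds on a circRNA is
governed by short sequence preferences (motifs). Given CLIP-derived
binding-site fragments for one RBP, this package learns a classifier that
separates true binding sites from dinucleotide-shuffled background, exposes
the learned motifs, and scans full-length circRNAs — including across the
back-splice junction — for candidate binding positions. It is aimed at
computational biologists studying circRNA–RBP regulation who want a
self-contained, CPU-friendly reimplementation of the capsule-network
approach with testable synthetic benchmarks.

## Model

A binding-site fragment `s = s_1 … s_L` over `{A, C, G, U/T, N}` is encoded
as an `L × 4` one-hot matrix `M` with column order **A, T, C, G** and
all-zero rows for `N` (so N-padding is inert under convolution). The
network is:

1. **Convolution motif detectors.** `K` filters of width `h` produce
   feature maps `conf_i = ReLU(Σ_{j=1}^{h} w_j · x_j + b)` of length
   `L − h + 1`.
2. **Global max pooling.** One scalar per filter (argmax positions kept for
   motif discovery).
3. **Primary capsules.** The `K` pooled responses regroup into
   `n = K / 8` capsules of dimension 8, squashed by
   `v_out = (‖v‖² / (1 + ‖v‖²)) · v / ‖v‖` so each norm lies in `[0, 1)`.
4. **Affine transform.** Per (input capsule `i`, output capsule `j`) a
   learned `16 × 8` matrix `W^{ij}` gives prediction vectors
   `u^{ij} = W^{ij} v_out^i`.
5. **Dynamic routing** (`T` rounds, default 2): couplings
   `c = softmax(b)`, aggregate `a = Σ_i c_i u^i`, output `v = squash(a)`,
   logit update `b_i ← b_i + v · u^i`.
6. **Digit capsules.** Two 16-dimensional output capsules (bound / not
   bound); `‖v_c‖` is the class confidence and the positive capsule's norm
   is the binding score.

Training minimises the margin loss
`L_c = T_c max(0, m⁺ − ‖v_c‖)² + λ (1 − T_c) max(0, ‖v_c‖ − m⁻)²`
(`m⁺ = 0.9`, `m⁻ = 0.1`, `λ = 0.5`, summed over both classes) with Adam,
early-stopped on a held-out validation split.

Dataset construction mirrors CLIP practice: exact-duplicate fragments are
removed, a fragment-length threshold is set by the Tukey boxplot upper
fence `Q3 + 1.5·IQR` (longer sites discarded as outliers), shorter sites
are centred and N-padded, and one negative per positive is generated by a
dinucleotide-preserving (Euler-path) shuffle, so class balance and exact
dinucleotide composition are maintained.

The package has no GPU dependency: forward and backward passes run on a
small, finite-difference-verified reverse-mode autodiff engine over numpy.

## Worked example

```python
from circrb import SimConfig, simulate_dataset, simulate_full_circrna, CircRBModel, TrainConfig
from circrb.benchmark import top_motif_consensus

# synthetic study: 500 positives of 50 nt, one planted ACTAAC each,
# negatives by dinucleotide shuffling
cfg = SimConfig(n_pos=500, seed=7)
ds, truth = simulate_dataset(cfg)

model = CircRBModel(ds, n_filters=32)
res = model.fit(TrainConfig(seed=7))
print(res.summary())
```

```
circRB capsule-network results
============================================
fragment length (nt)    50
conv filters x window   32 x 9
primary capsules        4 x 8d
digit capsules          2 x 16d
routing rounds          2
global max pooling      True
trainable parameters    2208
instances (train/test)  800/200
epochs run (best)       30 (29)
final train loss        0.2102
best validation loss    0.2105
held-out test AUC       0.8969
```

The held-out AUC of 0.90 says the network ranks true (motif-bearing)
fragments above their dinucleotide-shuffled twins; pure composition cannot
achieve this, so the signal is the planted motif. The detectors recover it:

```python
print(top_motif_consensus(res))          # -> TTACTAACA  (contains ACTAAC)

seq, circ_truth = simulate_full_circrna(cfg, L_circ=400, n_sites=1, seed=99)
print(circ_truth[["start", "end", "wrapped"]].iloc[0].tolist())   # [283, 288, False]
print(res.top_binding_sites(seq, k=1)[0])
# ScanHit(start=279, end=328, wrapped=False, score=0.637)
```

The top-scoring 50-nt scan window (positions 279–328, 1-based inclusive)
covers the planted site at 283–288. At larger training sizes
(2000 positives, the package's benchmark) 5-fold cross-validated AUC
exceeds 0.95 on every fold.

The same pipeline runs from the shell:

```bash
circrb simulate --outdir sim --n-pos 500 --n-circrna 2 --seed 7
circrb train sim/positives.fa --out model.npz --filters 32 --seed 7
circrb motifs model.npz sim/positives.fa --meme motifs.meme
circrb scan model.npz sim/circrnas.fa --out hits.tsv
```

## Layout

- `circrb.encoding`, `circrb.shuffle`, `circrb.datasets` — fragment
  encoding, dinucleotide shuffling, dataset construction.
- `circrb.capsnet`, `circrb.autodiff`, `circrb.training` — the network,
  its gradient engine, and Adam/CV/AUC machinery.
- `circrb.model` — the `CircRBModel` / `CircRBResults` user surface.
- `circrb.motifs`, `circrb.scan` — PFM/MEME/logo export and circRNA
  scanning.
- `circrb.synthetic`, `circrb.benchmark` — the planted-motif generator and
  the fixed benchmark protocol.
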