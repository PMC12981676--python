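# Methods

## Problem and model

The package predicts drug–target affinity (DTA): a real-valued binding
strength (pK_d, a KIBA score, or synthetic units) for a pair of a small
molecule and a protein. The model combines four representations of each
pair:

1. **Protein graph.** Each residue is a node; node features are the
   residue-level embeddings a protein language model produces for the
   sequence (width 1152 for the standard provider). Edges connect residue
   pairs whose contact probability `M_ij` strictly exceeds 0.5; the edge
   weight is the probability itself. Providers that emit start/end special
   tokens have those rows trimmed so node count equals residue count; a
   token-indexed contact matrix gets the same window cut from both axes.
   Asymmetric contact predictions are symmetrized as `(M + Mᵀ)/2` before
   thresholding, and the diagonal is excluded (the graph convolution adds
   its own unit self-loops during normalization).
2. **Protein sequence.** The raw token embeddings pass through a learned
   projection, learned positional embeddings, and a 3-layer, 8-head
   pre-norm transformer with a padding mask.
3. **Drug graph.** RDKit parses the SMILES; each heavy atom carries an
   88-dimensional feature vector (one-hot blocks: 43 elements + OTHER,
   degree 0–10, formal charge −5…+5, hybridization, total H 0–8, plus
   aromaticity, ring membership and R/S chirality). Bonds contribute both
   directed arcs weighted by bond order (aromatic = 1.5; Kekulé orders
   available behind a flag).
4. **Drug sequence.** Chemical-language-model token embeddings (width 384
   for the standard provider) through an identical transformer encoder.

Both graphs share one encoder architecture: a weighted GCN layer with
symmetric degree normalization (unit self-loops added), five single-head
GAT layers (attention over in-neighborhood ∪ self; LeakyReLU slope 0.2;
edge weights are *not* consumed by attention), batch normalization + ReLU
after every graph layer, global add pooling, dropout, and a two-layer MLP
to the output width.

The four streams are fused as:

- `A_g = σ(W_g[H_d;H_p]) ⊙ H_d + (1−σ(·)) ⊙ H_p` — a learned elementwise
  convex combination of the two graph-level vectors;
- `A_d`, `A_t` — additive (tanh-scorer) attention pooling of the drug and
  protein token sequences;
- `A_dt` — the pair `[A_d, A_t]` treated as a 2-token sequence and pooled
  by the same operator with its own parameters;
- `Z = [A_g, A_d, A_t, A_dt]` in that fixed order.

`Z` enters a Kolmogorov–Arnold network (KAN) head: stacked layers whose
edges carry learned cubic B-spline functions (uniform grid of 5 intervals
on [−1,1], Cox–de Boor evaluation with analytic input derivatives) plus a
SiLU base path. Before each KAN layer, features are normalized to the grid
domain by running per-feature min–max statistics that only expand during
training and freeze at evaluation; out-of-range values are clamped so the
compactly supported splines never receive dead input. An MLP head with the
same widths implements the no-KAN ablation behind the same interface.

## Design choices where the design was open

- **"Linear attention"** is realized as additive attention pooling: each
  use site consumes a token sequence and must emit a fixed-width vector
  that is concatenated with the graph vectors, which forces a pooling
  (not token-to-token) operator.
- **Cross-modal input** `[A_d, A_t]` is read as a 2-token sequence rather
  than a 256-wide concatenation, so a single operator serves all three
  attention sites.
- **Fusion widths.** The gated block works at the graph-encoder output
  width and the attention pools at the transformer width; both are 128 in
  the full-scale configuration but are tracked separately so desk-scale
  configurations stay consistent.
- **GAT details** (head count, negative slope, attention self-loop) are
  one head, slope 0.2, self-loop included; no residual connections and no
  dropout between GAT layers — only the dropout before the post-pooling
  MLP.
- **Threshold strictness** is `>` 0.5, never `≥`.
- **Ablation semantics.** Without the graph branch, `A_g` is dropped;
  without the sequence branch, all three attention outputs are dropped;
  without gated fusion, `A_g` is replaced by a linear reduction of
  `[H_d;H_p]`; without linear attention, `A_d`/`A_t` become masked means
  and the cross block disappears (plain concatenation); without
  language-model node features, protein nodes carry 21-dim residue
  one-hots.
- **r₀² convention.** The through-origin coefficient of determination
  `1 − Σ(y−kp)²/Σ(y−ȳ)²` with `k = Σyp/Σp²`; the radicand `r²−r₀²` is
  clamped at 0 before the square root so numerical edge cases cannot
  produce NaN.
- **Warm split** is pair-level disjoint: a (drug, protein) pair never
  appears in two subsets, while individual entities may. The all-unseen
  split partitions drug ids and protein ids independently and discards
  mixed-bucket pairs; the discard count is reported.
- **Label-tie handling in CI.** Pairs with tied labels contribute nothing
  to the normalizer; tied predictions on strictly ordered labels credit
  0.5.

## Numerical implementation

All neural components run on a small reverse-mode automatic
differentiation engine over NumPy arrays written for this package
(`kanpm._autodiff`). Model arithmetic is float32; analysis helpers (raw
B-spline evaluation, metrics) use float64. Softmaxes (dense, masked and
per-graph-segment) are fused single-node primitives with the standard
Jacobian backward; graph message passing uses scatter-add/gather segment
operations, and batches of graphs are processed block-diagonally. Batch
normalization uses batch statistics (momentum 0.1 running estimates)
during training and the frozen running estimates at evaluation, so
eval-mode forwards are deterministic and independent of batch composition.

Training minimizes MSE with Adam. Full-scale defaults follow the published
configuration (learning rate 1e-4, batch 16, at most 200 epochs, early
stopping when validation MSE fails to improve for more than 20 consecutive
epochs, best-validation weights restored). Everything is seeded: parameter
initialization, dropout streams, batch shuffling and the synthetic
generator, so a fixed seed reproduces a bit-identical training history on
one machine.

## Synthetic data: what it emulates and what it does not

The generator fabricates provider outputs so the full pipeline runs with
no downloads and no GPU:

- residue embeddings `(L+2) × 1152` (start/end tokens included, flag set)
  from per-entity hash-seeded standard normals scaled by `1/√dim`;
- symmetric contact maps with unit diagonal, a near-diagonal band
  (`|i−j| ≤ 3` by default) guaranteed above the 0.5 threshold — so the
  chain subgraph is always connected — plus sparse long-range contacts
  (probability 0.02 per off-band entry by default);
- drug records drawn from a packaged library of ~50 valid drug-like
  SMILES filtered to the requested heavy-atom count (±2), with an
  alkane/alcohol chain fallback; token embeddings are one per SMILES
  character, width 384;
- affinities from a planted latent-factor model
  `y(d,p) = u_p·v_d + b + ε`, `ε ~ N(0, noise_sd²)`, with the ground-truth
  factors returned for recovery tests.

Seeding is per-entity via a SHA-256 hash of `(entity id, global seed)`,
so datasets are byte-identical across platforms and adding entities never
perturbs existing ones.

The embeddings are unstructured Gaussians: they identify entities but
encode no biochemistry, and the planted affinity is independent of
molecular structure. Passing tests therefore demonstrate that the
*mechanism* works — graph construction, gradient flow, fusion, ranking
recovery of a learnable signal — and say nothing about accuracy on real
binding data, which requires the real pretrained embedders and benchmark
datasets.

Default study conditions for the recovery experiment: 40 proteins × 40
drugs, 1200 sampled pairs, latent dimension 4, noise sd 0.1. Protein
lengths are drawn from 40–120 residues and drug sizes from 10–30 heavy
atoms — desk-scale choices (real kinase domains are typically several
hundred residues) that keep a full CPU training run in minutes while
leaving every architectural path exercised.

## Desk-scale training preset

`ModelConfig.tiny()` keeps the architecture (1 GCN + 5 GAT, 3 transformer
layers, 8 heads, full fusion, KAN head) but shrinks widths (transformer
and graph widths 32, KAN hidden widths 64/16) and adapts the optimization
to CPU-scale NumPy execution: batch size 128 with per-batch entity
deduplication (each unique protein/drug is encoded once per step),
learning rate 1e-3, at most 150 epochs with patience 25. On the planted
dataset this run reaches test concordance ≈ 0.9 while test MSE falls well
below the label variance; the training trajectory is reproduced by
`scripts/acceptance.py`.

## Known limitations

- No adapters ship for real pretrained checkpoints; the provider
  interface accepts any `(tokens × width)` matrices plus a special-token
  flag, and the synthetic provider is the only bundled implementation.
- The 88-dimensional atom feature layout is this package's own
  composition of the standard property families (the upstream list is not
  public); it is versioned in `AtomFeatureScheme` so an alternative layout
  can be swapped without touching encoders.
- Training cannot resume mid-run from a checkpoint: checkpoints carry
  model weights and configuration (exact for inference and evaluation),
  not optimizer moments or shuffle-RNG state.
- The kernelized token-to-token linear-attention variant is not
  implemented; only the additive pooling form is.
- Batch normalization with very small node batches (single-node graphs)
  degenerates to the learned shift; this is exercised in tests but such
  graphs carry little signal.
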