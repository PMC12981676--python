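# kanpm-dta

Drug–target affinity (DTA) prediction from paired protein and small-molecule
representations: contact-map-derived residue graphs with language-model node
features, molecular graphs with 88-dimensional atom features, transformer
sequence encoders over pretrained-style token embeddings, gated multimodal
fusion with additive ("linear") attention, and a Kolmogorov–Arnold network
(KAN) regression head.

The package is aimed at method developers who want a fully testable,
CPU-runnable implementation of this architecture family: every stage — data
I/O, featurization, encoders, fusion, training, cold-start evaluation — runs
on synthetic stand-ins for the pretrained embedders, so no checkpoint
downloads or GPUs are required to exercise and validate the mechanism.

## Model

For a drug *d* (SMILES) and protein *t* (sequence):

- **Protein graph** `G_p = (V_p, E_p, W_p)`: nodes are residues with
  language-model embeddings as features (width 1152), edges
  `E_p = {(i,j) : M_ij > 0.5}` from the contact-probability matrix `M`,
  weights `W_ij = M_ij`. Start/end special tokens are trimmed so embedding
  rows align with residues.
- **Drug graph** `G_d`: one node per heavy atom (88-d one-hot feature
  blocks), arcs in both directions per bond, weight = bond order
  (aromatic 1.5).
- A shared **graph encoder** (weighted GCN → five GAT layers with batch
  norm → global add pooling → dropout → MLP) produces `H_p` and `H_d`;
  two 3-layer, 8-head **transformer encoders** produce token features
  `F_t`, `F_s` from the protein/drug token embeddings.
- **Fusion**: `A_g = σ(W_g[H_d;H_p]) ⊙ H_d + (1−σ(·)) ⊙ H_p`;
  `A_d = attnpool(F_s)`, `A_t = attnpool(F_t)`,
  `A_dt = attnpool([A_d, A_t])`; `Z = [A_g, A_d, A_t, A_dt]`.
- **Head**: `ŷ = KAN(Z)` — stacked layers of learned cubic B-spline edge
  functions plus a SiLU base path (an MLP head implements the no-KAN
  ablation).

Evaluation uses MSE, the concordance index
`CI = (1/Z) Σ_{y_i>y_j} h(p_i−p_j)` with step credits 1/0.5/0, and
`r_m² = r²(1 − √(r²−r₀²))` with `r₀²` from the through-origin fit. Splits
cover the warm setting and three cold-start protocols (unseen drug, unseen
protein, all unseen). Details, design decisions and limitations:
[docs/methods.md](docs/methods.md).

All neural components run on a small NumPy reverse-mode autodiff engine
bundled with the package, so the only heavyweight dependencies are NumPy,
pandas, RDKit and Biopython.

## Worked example

Simulate a small planted-signal dataset, split it, train a desk-scale
model and evaluate:

```bash
kanpm simulate --out demo --seed 5 --config demo.yaml
kanpm split --data demo --mode warm --seed 1 --out demo/split.csv
kanpm train --data demo --split demo/split.csv --out demo/run \
            --config model.yaml --seed 3
kanpm eval --checkpoint demo/run/checkpoint.npz --data demo \
           --split demo/split.csv --subset test
```

with `demo.yaml` shrinking the universe (8 proteins × 8 drugs, 56 pairs,
embedding widths 12/8, one latent factor, no noise) and `model.yaml`
selecting the tiny preset with matching provider widths and 200 epochs.
The run prints:

```
wrote 8 proteins, 8 drugs, 56 interactions to demo
split sizes train/val/test = 46/5/5
best val MSE 0.0042 at epoch 119; artifacts in demo/run
{
  "mse": 0.06005426112855468,
  "ci": 0.8,
  "rm2": 0.8738145383611651,
  "n": 5,
  "subset": "test",
  "version": "0.1.0",
  "config_hash": "41fead236c9fbe3a"
}
```

Labels here are draws from a rank-1 latent-factor model with variance
≈ 1.6, so a test MSE of ≈ 0.06 means the model has recovered nearly all of
the planted signal from 46 training pairs; CI = 0.8 says 4 of the 5 ordered
held-out pair comparisons rank correctly, and `rm2` is the
external-validation coefficient on the same 5 pairs.

`kanpm predict --checkpoint … --data … --out ranked.csv --top 12` scores
every drug × protein pair and writes the 12 highest-affinity predictions,
ties broken by drug id — the screening workflow, at synthetic scale.

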