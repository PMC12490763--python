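# rlalign

Joint embedding of protein sequences and structures by **residue-level
alignment (RLA)**: a contrastive objective that places the per-residue
embeddings of a sequence encoder and a structure encoder into one shared
latent space, plus the screening analytics built on top of it — a
sequence–structure similarity score, docking-decoy discrimination,
unsupervised contact probing, greedy structural clustering of designed
binders, and a two-stage screening filter.

The package is aimed at method developers and binder-design practitioners
who want a fast, sequence-optional compatibility score between a protein
sequence and a backbone structure, exercisable end-to-end at desk scale
with small trainable encoders and a synthetic-data generator (no external
datasets or pretrained weights required).

## The model

Given a protein with `T` residues, a transformer sequence encoder produces
per-residue embeddings `U ∈ R^{T×d}` from the amino-acid tokens (chains
joined by a chain-break token; whole chains may be replaced by mask
tokens), and a message-passing network over the k-NN backbone graph
(Cα distances, `k = 30`) produces structure embeddings `V ∈ R^{T×d}` from
rigid-invariant dihedral and orientation/distance features. The alignment
score of residues `i, j` is the cosine similarity

    r(i, j) = U_i · V_j / (‖U_i‖ ‖V_j‖)

Training minimizes a symmetric softmax cross-entropy (InfoNCE) over one
protein's `T×T` similarity matrix: each residue's matched partner must
beat every other residue of the same protein in both directions, with
temperature τ (default 0.1). Negatives come only from within the protein,
so no large batches are needed. The structure encoder carries no absolute
positional information, and chain order is shuffled independently per view
during training, so the diagonal cannot be predicted from position alone.

The complex-level similarity score is the per-chain average of diagonal
alignment scores, averaged over chains:

    S_RLA = (1/|C|) Σ_c (1/T_c) Σ_i r(U_{c,i}, V_{c,i})

For docking applications only interface residues are averaged (a residue
is interfacial when its 30 nearest residues across the whole complex
include one from another chain), and the binder chain's sequence can be
masked entirely — scoring a backbone-only design candidate.

## Worked example

Train the desk-scale model on an identity-coupled synthetic corpus (the
generator couples each residue's amino acid to its quantized backbone
dihedrals, making alignment learnable by construction) and score held-out
proteins:

```python
from rlalign import encoders, geometry, rla_core, synthdata

corpus = synthdata.gen_corpus(synthdata.GeneratorSpec(num_proteins=80, seed=11))
cfg = rla_core.TrainingConfig(epochs=4, peak_epoch=1, seed=0)
result = rla_core.train(cfg, corpus[:60], *encoders.synthetic_profile())
print(f"loss: {result.loss_trace[0]:.2f} -> {result.loss_trace[-1]:.2f}")

held = corpus[60:]
acc = rla_core.retrieval_top1(result.seq_encoder, result.struct_encoder, held)
print(f"held-out top-1 retrieval: {acc:.2f}")

s = held[0]
res = rla_core.score_structure(result.seq_encoder, result.struct_encoder, s)
print(f"S_RLA({s.source_id}) = {res.s_rla:.3f}")
noisy = geometry.add_structure_noise(s, 1.0, seed=5)
res_n = rla_core.score_structure(result.seq_encoder, result.struct_encoder, noisy)
print(f"S_RLA(+1.0 A noise) = {res_n.s_rla:.3f}")
```

Output:

```
loss: 7.66 -> 6.28
held-out top-1 retrieval: 1.00
S_RLA(synth-identity-0060) = 0.398
S_RLA(+1.0 A noise) = 0.275
```

The contrastive loss falls from its uniform-similarity ceiling (2·ln T ≈
7.5 for these lengths), the trained model retrieves each held-out
sequence's matched structure among 20 candidates, and corrupting a
structure with 1 Å of coordinate noise lowers its similarity score — the
misalignment the score is designed to detect.

A command-line interface wraps the same library:

```
rlalign gen out/data --seed 3
rlalign train out/data out/model.npz
rlalign score out/model.npz out/data --out out/scores.tsv
rlalign rank scores.tsv --out report.json       # AUROC vs DockQ labels
rlalign cluster binders/ labels.tsv --out clusters.tsv
rlalign perturb out/model.npz complex.pdb --noise 0.1,0.5,1.0 --out report.tsv
rlalign filter candidates.tsv --out filtered.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the main computation from scratch —
corpus generation, contrastive training, held-out retrieval, interface
scoring of graded docking decoys with AUROC aggregation, binder-library
clustering and two-stage filtering — and writes its result JSON to the
path given by `--out`:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Progress and summary statistics are printed to stderr.

## Layout

- `rlalign.structio` — PDB/FASTA/score-table I/O, backbone-only structures
- `rlalign.geometry` — dihedrals, k-NN graphs, interfaces, binding sites,
  Kabsch superposition, TM-score, structural noise
- `rlalign.encoders` — the two trainable encoders and checkpoints
- `rlalign.rla_core` — similarity matrix, loss, S_RLA, training loop
- `rlalign.analysis` — decoy ranking, contact probing, mutation scans,
  greedy clustering, joint filtering
- `rlalign.synthdata` — the synthetic world generator
- `rlalign.cli` — the `rlalign` command
- `docs/methods.md` — modelling assumptions, parameter choices, limits
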