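# Methods

This note records the modelling choices behind `rlalign`: the objective
and score, the encoder architectures, the synthetic world the tests train
on, and the numerical conventions. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The objective

For one protein with residue embeddings `U, V ∈ R^{T×d}` the loss is a
symmetric softmax cross-entropy over the cosine-similarity matrix
`r[i][j] = cos(U_i, V_j)`:

    L = (1/T) Σ_i [ −log softmax_j(r[i][j]/τ)_i ]
      + (1/T) Σ_j [ −log softmax_i(r[i][j]/τ)_j ]

Two readings of a residue-level contrastive objective are possible — a
literal ratio of similarities or a softmax cross-entropy over similarity
logits. Only the cross-entropy reading is well defined on cosine values
in [−1, 1] (a raw ratio can divide by a negative sum), so that is what is
implemented, with a temperature τ (default **0.1**) to give useful
gradient scale on bounded logits. Useful identities follow and are
tested: a constant matrix gives exactly `2·ln T`, and raising the
diagonal strictly lowers the loss.

Negatives are drawn **within the protein only** — the softmax runs over
the protein's own residues, never across a batch — so batch size controls
only gradient averaging (mean of per-protein losses). Residues with
repeated amino acids in one chain are genuinely ambiguous for the
sequence-side softmax; this bounds the achievable loss above zero and is
expected.

## Scoring

`S_RLA` is the mean over chains of each chain's mean diagonal cosine.
Chains are weighted equally regardless of length (a 2-residue chain and a
200-residue chain each contribute one term); chains with no admitted
residues under the active mode are excluded from the outer mean with a
warning rather than contributing zero. Interface mode admits residues
whose 30 nearest residues by Cα distance over the whole complex (own
chain included) contain a residue of another chain. Masked-binder scoring
replaces one chain's tokens with mask tokens upstream; the structure
encoder is unaffected.

## Encoders

*Sequence*: a pre-LN transformer over a 24-token vocabulary (20 amino
acids, unknown, mask, pad, chain-break), learned positional embeddings,
per-layer multi-head attention with maps exposed for contact probing, and
a learned linear head to the shared dimension d. Positional information
is legitimate here; chain shuffling during training prevents exploiting
chain order.

*Structure*: a message-passing network over the directed k-NN residue
graph. Node features are (cos, sin) of phi/psi/omega (undefined terminal
angles encode as (0, 0)); edge features are the relative sequence offset
clipped to ±32 (one-hot, with a cross-chain flag), the quaternion of the
relative rotation between Gram-Schmidt backbone frames plus the unit
inter-Cα vector in the source frame, and all 16 backbone atom-pair
distances through 16 Gaussian radial basis functions (centers 0–20 Å,
width 1.25 Å). No absolute positional encodings enter the network, so
its output is invariant to rigid motion and equivariant to residue
relabeling — both tested. Quaternions are sign-canonicalized (largest
component positive) because q and −q encode one rotation.

The default configuration is deliberately small (sequence: 4 layers,
4 heads, hidden 128; structure: 3 message-passing rounds, hidden 128;
shared d = 320). The `synthetic_profile()` used throughout the tests is
smaller still (2 layers/rounds, hidden 64, d = 32, k = 16) so that full
training runs finish in about a minute on one CPU. The contract — two
per-residue encoders meeting in one space — is the point; capacity is
configurable. Both encoders run on an in-repo reverse-mode autodiff over
numpy arrays, gradient-checked against central finite differences.

Training uses Adam (lr 0.001, L2 weight decay 0.001), batch size 10
proteins, 10 epochs, and a cosine learning-rate schedule with linear
warmup peaking at epoch 2. Long proteins are cropped once to a contiguous
window per chain (default cap 512 residues). All randomness flows from a
single seed; training is deterministic under it.

## The synthetic world

The generator builds ideal-geometry backbones (canonical bond lengths and
angles, trans peptide bonds) from per-segment (phi, psi) targets — helix
(−57°, −47°), strand (−139°, 135°), coil sampled broadly — with ±2°
jitter, a 2.5 Å Cα self-clash filter with regeneration, and a small
coordinate noise floor (0.02 Å). Default corpus: 200 single chains of
30–50 residues.

**Coupling.** Under the default `identity` coupling each residue's amino
acid is a deterministic function of its quantized (phi, psi) bin (4 × 5
bins → 20 letters), so sequence–structure alignment is learnable by
construction and retrieval accuracy gives a sharp acceptance surface.
The 20 letters are assigned to bins along a greedy BLOSUM62 similarity
chain over a serpentine path of the bin grid, so conservative
(BLOSUM62-positive) substitutions correspond to small local-geometry
changes — emulating the real tendency of conservative substitutions to
be structurally conservative, which is what the mutation-scan analysis
probes. `local-window` adds neighbor-bin substitution noise;
`none` draws letters independently (negative control, verified by a χ²
independence test).

**Decoys.** Docking decoys displace and rotate the second chain along a
severity ladder with added internal noise; each decoy carries the
fraction of native inter-chain Cα contacts (8 Å) it retains, a proxy
quality that is monotone in severity and stands in for DockQ wherever a
quality label is consumed. **Binder libraries** plant scaffold and
cluster structure (two conformations per scaffold, mutual TM < 0.8;
members perturbed at 0.15 Å RMS, mutual TM > 0.8), labels whose rates are
elevated in designated clusters while preserving the marginal planted
rate, and a label-correlated screening-score stand-in.

What a green test does **not** establish: the generator has no side
chains, no packing energetics, no evolutionary covariation, and its
sequence–structure code is far sharper than nature's; results quantify
the machinery, not biological performance. Published benchmark numbers
that require a fine-tuned 150M-parameter language model and external
datasets are out of desk scope by design; a pluggable adapter with the
same encode signature accepts such a model where available.

## Numerical conventions

- Torsions use the standard IUPAC sign convention, range (−180°, 180°];
  collinear triples raise rather than return arbitrary values.
- k-NN neighbor ties break toward the lower residue index (stable sort).
- TM-score: `d0 = max(0.5, 1.24·(L−15)^{1/3} − 1.8)`; iterative
  refinement re-fits on residues with aligned distance < d0 (≥ 3
  required), caps at 20 iterations, and reports the best score seen, so
  it never falls below the single global-fit score. Equal-length traces
  only — the shared-scaffold use case.
- Kabsch superposition enforces det(R) = +1 and raises on collinear
  point sets.
- Structural noise of "x Å" means expected per-atom displacement RMS
  (per-axis σ = x/√3).
- Binding sites use strict `< 8 Å` on Cα distances; overlap is Jaccard,
  with the empty/empty case defined as 0 (warned).
- The clustering skip rule compares |T(i,k) − T(j,k)| (absolute value)
  over reference binders k for which both values were actually computed;
  binders are iterated in input order; TM values are cached and never
  recomputed. Binders captured by no cluster become singletons.
- "Top 25th percentile" keeps candidates with score ≥ the 75th-percentile
  value, ties included, so exactly 25 of 100 distinct scores survive.
- Success rates are percentages rounded half-up to 2 decimals — the
  convention consistent with all six published design-count rows.
- BLOSUM62 zero-scored substitutions belong to neither mutation group;
  identity substitutions are excluded. The scan mutates one interface
  residue at a time by default (an all-at-once option exists, since the
  protocol wording is ambiguous).
- AUROC uses the Mann–Whitney mean-rank tie convention; per-target values
  aggregate as mean ± SEM.

## Known limitations

- The autodiff engine is float64 and single-threaded; the package trades
  throughput for having zero deep-learning-framework dependencies.
- TM-score for unequal lengths (fragment-seeded alignment) is not
  implemented; clustering therefore requires equal-length traces within
  a scaffold, which the design-library use case guarantees.
- PDB parsing is backbone-only (N, CA, C, O); mmCIF, HETATM ligands and
  assembly expansion are out of scope.
- The drop rule for residues missing backbone atoms is a package choice;
  upstream handling in the original training data is unknown.
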