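"""Residue-level alignment: similarity matrix, contrastive loss, the
chain-averaged similarity score S_RLA, and the training loop.

The training objective is a symmetric softmax cross-entropy (InfoNCE) over
the matrix of cosine similarities between per-residue sequence embeddings
U and structure embeddings V of one protein: each residue's matched
embedding must beat every other residue of the same protein, in both the
sequence→structure and structure→sequence directions.  Negatives are drawn
only within the protein, never across the batch, so the objective does not
require large batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import geometry
from .autodiff import Adam, Tensor, gather_rows
from .encoders import (
    EmbeddingPair,
    SequenceEncoder,
    SequenceEncoderConfig,
    StructureEncoder,
    StructureEncoderConfig,
    encode_sequence,
    encode_structure,
    pair_embeddings,
)
from .structio import Chain, ProteinStructure


@dataclass
class SimilarityMatrix:
    """r[i, j] = cosine similarity between U_i and V_j; entries in [−1, 1]."""

    r: np.ndarray
    residue_keys: list[tuple[str, int]]

    @property
    def T(self) -> int:
        return self.r.shape[0]


@dataclass
class RLAResult:
    """Per-residue alignment scores and their chain-averaged summary S_RLA."""

    per_residue: np.ndarray
    residue_keys: list[tuple[str, int]]
    per_chain_mean: dict[str, float]
    s_rla: float
    mode: str
    masked_chains: frozenset = frozenset()


@dataclass
class TrainingConfig:
    """Training hyperparameters (defaults follow the published recipe)."""

    batch_size: int = 10
    epochs: int = 10
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    peak_epoch: int = 2
    temperature: float = 0.1
    max_residues_per_protein: int = 512
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.learning_rate, self.temperature,
               self.max_residues_per_protein) <= 0:
            raise ValueError("all positive hyperparameters required")
        if self.epochs < 0 or self.weight_decay < 0:
            raise ValueError("epochs and weight_decay must be non-negative")
        if self.epochs > 0 and self.peak_epoch >= self.epochs:
            raise ValueError("peak_epoch must be < epochs")


# ---------------------------------------------------------------------------
# similarity and loss
# ---------------------------------------------------------------------------

def similarity_matrix(pair: EmbeddingPair) -> SimilarityMatrix:
    """All-pairs cosine similarity between sequence and structure rows."""
    un = np.linalg.norm(pair.U, axis=1)
    vn = np.linalg.norm(pair.V, axis=1)
    for name, norms in (("U", un), ("V", vn)):
        zero = np.where(norms == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-norm {name} embedding at residue {pair.residue_keys[zero[0]]}"
            )
    r = (pair.U / un[:, None]) @ (pair.V / vn[:, None]).T
    return SimilarityMatrix(r=r, residue_keys=list(pair.residue_keys))


def rla_loss(r: SimilarityMatrix | np.ndarray, temperature: float = 0.1) -> float:
    """Symmetric InfoNCE over similarity logits r/τ; uniform r gives 2·ln T."""
    mat = r.r if isinstance(r, SimilarityMatrix) else np.asarray(r, dtype=float)
    T = mat.shape[0]
    if T < 2:
        raise ValueError("loss needs T >= 2 residues (no negatives otherwise)")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = mat / temperature
    diag = np.diag(logits)
    row_ce = logsumexp(logits, axis=1) - diag
    col_ce = logsumexp(logits, axis=0) - diag
    return float(row_ce.mean() + col_ce.mean())


def rla_loss_tensor(U: Tensor, V: Tensor, temperature: float) -> Tensor:
    """Differentiable counterpart of `rla_loss` built from raw embeddings."""
    T = U.shape[0]
    idx = np.arange(T)
    Un = U / (((U * U).sum(axis=1, keepdims=True)) ** 0.5)
    Vn = V / (((V * V).sum(axis=1, keepdims=True)) ** 0.5)
    logits = (Un @ Vn.T) * (1.0 / temperature)
    diag = logits[idx, idx]
    row = logits.logsumexp(axis=1) - diag
    col = logits.T.logsumexp(axis=1) - diag
    return row.mean() + col.mean()


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_complex(pair: EmbeddingPair, structure: ProteinStructure,
                  mode: str = "all",
                  masked_chains: frozenset = frozenset()) -> RLAResult:
    """Chain-averaged similarity S_RLA from matched embeddings.

    S_RLA is the mean over chains of each chain's mean diagonal cosine
    similarity; in "interface" mode only interface residues (30-NN rule)
    are averaged.  Chains with no admitted residues are excluded from the
    outer mean with a warning.
    """
    if mode not in ("all", "interface"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    sim = similarity_matrix(pair)
    diag = np.diag(sim.r).copy()
    admitted: dict[str, frozenset | None]
    if mode == "interface":
        iface = geometry.interface_residues(structure)  # raises on 1 chain
        admitted = {cid: iface.by_chain.get(cid, frozenset())
                    for cid in structure.chain_ids}
    else:
        admitted = {cid: None for cid in structure.chain_ids}

    per_chain: dict[str, float] = {}
    for cid in structure.chain_ids:
        vals = [
            diag[row]
            for row, (kcid, local) in enumerate(pair.residue_keys)
            if kcid == cid and (admitted[cid] is None or local in admitted[cid])
        ]
        if not vals:
            warnings.warn(
                f"chain {cid} has no residues admitted by mode {mode!r}; "
                "excluded from S_RLA", stacklevel=2,
            )
            continue
        per_chain[cid] = float(np.mean(vals))
    if not per_chain:
        raise ValueError("no chain has admitted residues")
    label = mode
    if mode == "interface" and masked_chains:
        label = "interface_masked"
    return RLAResult(
        per_residue=diag,
        residue_keys=list(pair.residue_keys),
        per_chain_mean=per_chain,
        s_rla=float(np.mean(list(per_chain.values()))),
        mode=label,
        masked_chains=frozenset(masked_chains),
    )


def score_structure(seq_encoder: SequenceEncoder,
                    struct_encoder: StructureEncoder,
                    structure: ProteinStructure, mode: str = "all",
                    masked_chains: frozenset = frozenset()) -> RLAResult:
    """End-to-end S_RLA for a structure: encode both modalities, then score."""
    for cid in masked_chains:
        structure.chain(cid)  # raises KeyError naming an absent chain
    chains = [(c.chain_id, c.sequence) for c in structure.chains]
    U, keys_u, _ = encode_sequence(
        seq_encoder, chains, masked_chains=set(masked_chains),
        collect_attention=False,
    )
    graph = geometry.knn_graph(structure, k=struct_encoder.config.k)
    V, keys_v = encode_structure(struct_encoder, graph)
    pair = pair_embeddings(U, V, keys_u, keys_v)
    return score_complex(pair, structure, mode=mode, masked_chains=masked_chains)


# ---------------------------------------------------------------------------
# chain shuffling
# ---------------------------------------------------------------------------

@dataclass
class ShuffledExample:
    """One training example with independently shuffled chain orders.

    The sequence and structure encoders each see their own uniformly random
    chain order; residue keys let the loss align rows back to a canonical
    order so the contrastive diagonal stays correct.
    """

    seq_chains: list[tuple[str, str]]
    struct_view: ProteinStructure
    seq_order: tuple[int, ...]
    struct_order: tuple[int, ...]
    canonical_keys: list[tuple[str, int]]


def shuffle_chains(structure: ProteinStructure,
                   rng: np.random.Generator) -> ShuffledExample:
    """Draw independent uniform chain orders for the two encoder views."""
    n = len(structure.chains)
    seq_order = tuple(rng.permutation(n).tolist())
    struct_order = tuple(rng.permutation(n).tolist())
    seq_chains = [
        (structure.chains[i].chain_id, structure.chains[i].sequence)
        for i in seq_order
    ]
    struct_view = ProteinStructure(
        chains=[structure.chains[i] for i in struct_order],
        source_id=structure.source_id,
    )
    return ShuffledExample(
        seq_chains=seq_chains,
        struct_view=struct_view,
        seq_order=seq_order,
        struct_order=struct_order,
        canonical_keys=structure.residue_keys,
    )


def _crop_structure(structure: ProteinStructure, max_residues: int,
                    rng: np.random.Generator) -> ProteinStructure:
    """Random contiguous per-chain crop keeping total length ≤ max_residues."""
    if structure.total_residues <= max_residues:
        return structure
    budget = max(5, max_residues // len(structure.chains))
    chains = []
    for c in structure.chains:
        if len(c) <= budget:
            chains.append(c)
            continue
        start = int(rng.integers(0, len(c) - budget + 1))
        chains.append(Chain(
            chain_id=c.chain_id,
            sequence=c.sequence[start:start + budget],
            backbone=c.backbone[start:start + budget],
        ))
    return ProteinStructure(chains=chains, source_id=structure.source_id)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    seq_encoder: SequenceEncoder
    struct_encoder: StructureEncoder
    loss_trace: list[float] = field(default_factory=list)


def lr_schedule(config: TrainingConfig, fractional_epoch: float) -> float:
    """Linear warmup to `peak_epoch`, then cosine decay to 0 at `epochs`."""
    peak, total, lr = config.peak_epoch, config.epochs, config.learning_rate
    if fractional_epoch < peak:
        return lr * fractional_epoch / peak
    return lr * 0.5 * (1.0 + np.cos(np.pi * (fractional_epoch - peak) / (total - peak)))


def _protein_loss(seq_enc: SequenceEncoder, struct_enc: StructureEncoder,
                  example: ShuffledExample, temperature: float,
                  graph_cache: dict | None = None) -> Tensor:
    U, keys_u, _ = seq_enc.encode_tensor(example.seq_chains)
    cache_key = (id(example.struct_view), example.struct_order)
    graph = None
    if graph_cache is not None:
        graph = graph_cache.get(cache_key)
    if graph is None:
        graph = geometry.knn_graph(example.struct_view, k=struct_enc.config.k)
        if graph_cache is not None:
            graph_cache[cache_key] = graph
    V = struct_enc.forward(graph)
    keys_v = graph.residue_keys
    # permute both views into canonical key order so the diagonal pairs up
    pos_u = {k: i for i, k in enumerate(keys_u)}
    pos_v = {k: i for i, k in enumerate(keys_v)}
    order_u = np.array([pos_u[k] for k in example.canonical_keys])
    order_v = np.array([pos_v[k] for k in example.canonical_keys])
    return rla_loss_tensor(gather_rows(U, order_u), gather_rows(V, order_v),
                           temperature)


def train(config: TrainingConfig, corpus: list[ProteinStructure],
          seq_cfg: SequenceEncoderConfig | None = None,
          struct_cfg: StructureEncoderConfig | None = None,
          progress: bool = False) -> TrainResult:
    """Train both encoders with the contrastive objective.

    Adam with L2 weight decay, cosine schedule with linear warmup, batch
    loss = mean of per-protein losses.  Deterministic under `config.seed`.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    seq_cfg = seq_cfg or SequenceEncoderConfig()
    struct_cfg = struct_cfg or StructureEncoderConfig()
    if seq_cfg.output_dim != struct_cfg.output_dim:
        raise ValueError(
            f"encoder output dims differ: {seq_cfg.output_dim} vs "
            f"{struct_cfg.output_dim}"
        )
    rng = np.random.default_rng(config.seed)
    seq_enc = SequenceEncoder(seq_cfg, seed=int(rng.integers(2**31)))
    struct_enc = StructureEncoder(struct_cfg, seed=int(rng.integers(2**31)))
    params = {f"seq::{k}": p for k, p in seq_enc.params.items()}
    params.update({f"struct::{k}": p for k, p in struct_enc.params.items()})
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.weight_decay)

    n = len(corpus)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    trace: list[float] = []
    graph_cache: dict = {}
    # crop once up-front (lengths here are small; re-cropping each epoch
    # would defeat graph caching for no benefit at desk scale)
    cropped = [
        _crop_structure(s, config.max_residues_per_protein, rng) for s in corpus
    ]
    shuffled_cache: dict = {}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for b, lo in enumerate(range(0, n, config.batch_size)):
            batch = order[lo:lo + config.batch_size]
            frac = epoch + b / steps_per_epoch
            lr = lr_schedule(config, frac)
            grads: dict[str, np.ndarray] | None = None
            batch_loss = 0.0
            for idx in batch:
                structure = cropped[idx]
                if len(structure.chains) == 1:
                    ex = shuffled_cache.get(idx)
                    if ex is None:
                        ex = shuffle_chains(structure, rng)
                        shuffled_cache[idx] = ex
                else:
                    ex = shuffle_chains(structure, rng)
                seq_enc.zero_grad()
                struct_enc.zero_grad()
                loss = _protein_loss(seq_enc, struct_enc, ex,
                                     config.temperature, graph_cache)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}, "
                        f"protein {structure.source_id!r}"
                    )
                loss.backward()
                batch_loss += float(loss.data)
                g = {f"seq::{k}": v for k, v in seq_enc.grads().items()}
                g.update({f"struct::{k}": v for k, v in struct_enc.grads().items()})
                if grads is None:
                    grads = g
                else:
                    for k in grads:
                        grads[k] += g[k]
            scale = 1.0 / len(batch)
            grads = {k: v * scale for k, v in grads.items()}
            opt.step(grads, lr=lr)
            epoch_losses.append(batch_loss * scale)
        trace.append(float(np.mean(epoch_losses)))
        if progress:
            print(f"epoch {epoch + 1}/{config.epochs}: loss {trace[-1]:.4f}")
    return TrainResult(seq_encoder=seq_enc, struct_encoder=struct_enc,
                       loss_trace=trace)


def retrieval_top1(seq_encoder: SequenceEncoder,
                   struct_encoder: StructureEncoder,
                   structures: list[ProteinStructure]) -> float:
    """Matched sequence–structure retrieval accuracy among candidates.

    For each protein's sequence, every candidate structure is scored by its
    mean rRLA against that sequence (diagonal mean for equal lengths, mean
    over all residue pairs otherwise) and the argmax must be the matched
    structure.  Returns the top-1 accuracy.
    """
    Us, Vs = [], []
    for s in structures:
        chains = [(c.chain_id, c.sequence) for c in s.chains]
        U, _, _ = encode_sequence(seq_encoder, chains, collect_attention=False)
        graph = geometry.knn_graph(s, k=struct_encoder.config.k)
        V, _ = encode_structure(struct_encoder, graph)
        Us.append(U / np.linalg.norm(U, axis=1, keepdims=True))
        Vs.append(V / np.linalg.norm(V, axis=1, keepdims=True))
    hits = 0
    for i, U in enumerate(Us):
        scores = []
        for V in Vs:
            r = U @ V.T
            scores.append(float(np.diag(r).mean()) if U.shape[0] == V.shape[0]
                          else float(r.mean()))
        hits += int(np.argmax(scores) == i)
    return hits / len(Us)


def save_loss_trace(trace: list[float], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tloss\n")
        for i, v in enumerate(trace):
            fh.write(f"{i}\t{v:.6f}\n")
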