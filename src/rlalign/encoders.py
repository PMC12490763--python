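"""Per-residue sequence and structure encoders sharing one latent space.

The sequence encoder is a small pre-LN transformer over amino-acid tokens
(chains joined by a chain-break token, masked chains replaced by a mask
token) that exposes its per-layer, per-head attention maps for contact
probing.  The structure encoder is a message-passing network over the k-NN
backbone graph that alternates edge updates and node updates; it receives
no absolute positional information — only the rigid-invariant dihedral node
features and orientation/distance/relative-offset edge features.

Both encoders project their final hidden states to a shared dimension d
through a learned linear head, so a residue's sequence embedding U_i and
structure embedding V_i can be compared by cosine similarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, scatter_sum
from .geometry import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, ResidueGraph
from .structio import AMINO_ACIDS

TOKENS = list(AMINO_ACIDS) + ["X", "<mask>", "<pad>", "<cb>"]
TOKEN_TO_ID = {t: i for i, t in enumerate(TOKENS)}
MASK_ID = TOKEN_TO_ID["<mask>"]
PAD_ID = TOKEN_TO_ID["<pad>"]
CHAIN_BREAK_ID = TOKEN_TO_ID["<cb>"]
VOCAB_SIZE = len(TOKENS)


@dataclass
class SequenceEncoderConfig:
    num_layers: int = 4
    num_heads: int = 4
    hidden_dim: int = 128
    output_dim: int = 320
    dropout: float = 0.0
    max_len: int = 1024

    def __post_init__(self):
        if self.hidden_dim % self.num_heads:
            raise ValueError("hidden_dim must be divisible by num_heads")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


@dataclass
class StructureEncoderConfig:
    num_mp_rounds: int = 3
    hidden_dim: int = 128
    output_dim: int = 320
    k: int = 30

    def __post_init__(self):
        if self.num_mp_rounds < 1:
            raise ValueError("num_mp_rounds must be >= 1")


@dataclass
class AttentionStack:
    """Per-layer (num_heads, T, T) attention maps over residue positions."""

    maps: list[np.ndarray]

    @property
    def num_layers(self) -> int:
        return len(self.maps)

    def stacked(self) -> np.ndarray:
        """(num_layers * num_heads, T, T) feature stack for contact probing."""
        return np.concatenate(self.maps, axis=0)


@dataclass
class EmbeddingPair:
    """Matched per-residue sequence (U) and structure (V) embeddings."""

    U: np.ndarray
    V: np.ndarray
    residue_keys: list[tuple[str, int]]

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.shape != self.V.shape:
            raise ValueError(
                f"U shape {self.U.shape} does not match V shape {self.V.shape}"
            )
        if self.U.shape[0] != len(self.residue_keys):
            raise ValueError("residue_keys length does not match embeddings")
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.V))):
            raise ValueError("embeddings contain non-finite entries")

    @property
    def T(self) -> int:
        return self.U.shape[0]


def pair_embeddings(U, V, keys_u, keys_v) -> EmbeddingPair:
    """Validate and pair matched sequence/structure embeddings."""
    keys_u, keys_v = list(keys_u), list(keys_v)
    if len(keys_u) != len(keys_v):
        raise ValueError(
            f"embedding row counts differ: {len(keys_u)} vs {len(keys_v)}"
        )
    for a, b in zip(keys_u, keys_v):
        if a != b:
            raise ValueError(f"residue key mismatch: {a} (sequence) vs {b} (structure)")
    return EmbeddingPair(U=np.asarray(U), V=np.asarray(V), residue_keys=keys_u)


# ---------------------------------------------------------------------------
# parameter plumbing
# ---------------------------------------------------------------------------

def _init(rng: np.random.Generator, *shape, scale=None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape))


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape))


def _ones(*shape) -> Tensor:
    return Tensor(np.ones(shape))


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gain + bias


class _Model:
    """Tiny base: a flat name → Tensor parameter dict plus grad collection."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, tensor: Tensor) -> Tensor:
        self.params[name] = tensor
        return tensor

    def grads(self) -> dict[str, np.ndarray]:
        return {
            k: (p.grad if p.grad is not None else np.zeros_like(p.data))
            for k, p in self.params.items()
        }

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(values[k], dtype=np.float64)


# ---------------------------------------------------------------------------
# sequence encoder
# ---------------------------------------------------------------------------

class SequenceEncoder(_Model):
    """Small transformer mapping tokenized chains to per-residue d-vectors."""

    def __init__(self, config: SequenceEncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        h, d = config.hidden_dim, config.output_dim
        self._add("tok_emb", _init(rng, VOCAB_SIZE, h, scale=0.02))
        self._add("pos_emb", _init(rng, config.max_len, h, scale=0.02))
        for layer in range(config.num_layers):
            p = f"layer{layer}."
            for name in ("Wq", "Wk", "Wv", "Wo"):
                self._add(p + name, _init(rng, h, h))
                self._add(p + name + "_b", _zeros(h))
            self._add(p + "ln1_g", _ones(h))
            self._add(p + "ln1_b", _zeros(h))
            self._add(p + "ln2_g", _ones(h))
            self._add(p + "ln2_b", _zeros(h))
            self._add(p + "W1", _init(rng, h, 4 * h))
            self._add(p + "b1", _zeros(4 * h))
            self._add(p + "W2", _init(rng, 4 * h, h))
            self._add(p + "b2", _zeros(h))
        self._add("lnf_g", _ones(h))
        self._add("lnf_b", _zeros(h))
        self._add("proj_W", _init(rng, h, d))
        self._add("proj_b", _zeros(d))

    # -- tokenization --------------------------------------------------------
    def tokenize(self, chains: list[tuple[str, str]],
                 masked_chains: set[str] | None = None):
        """Concatenate chains with break tokens; apply per-chain masking.

        Returns (token_ids, residue_positions, residue_keys).
        """
        masked_chains = masked_chains or set()
        ids, positions, keys = [], [], []
        for n, (cid, seq) in enumerate(chains):
            if n > 0:
                ids.append(CHAIN_BREAK_ID)
            for i, letter in enumerate(seq):
                if cid in masked_chains:
                    tok = MASK_ID
                elif letter in TOKEN_TO_ID and letter != "X":
                    tok = TOKEN_TO_ID[letter]
                else:
                    if letter not in TOKEN_TO_ID:
                        warnings.warn(
                            f"unknown residue character {letter!r} mapped to "
                            "the unknown token", stacklevel=3,
                        )
                    tok = TOKEN_TO_ID["X"]
                positions.append(len(ids))
                keys.append((cid, i))
                ids.append(tok)
        if len(ids) > self.config.max_len:
            raise ValueError(
                f"token sequence length {len(ids)} exceeds max_len "
                f"{self.config.max_len}"
            )
        return np.array(ids), np.array(positions), keys

    # -- forward -------------------------------------------------------------
    def forward(self, token_ids: np.ndarray, collect_attention: bool = False):
        """Run the transformer; returns (Tensor (L, d), attention list)."""
        cfg = self.config
        L = len(token_ids)
        H, h = cfg.num_heads, cfg.hidden_dim
        dh = h // H
        P = self.params
        x = gather_rows(P["tok_emb"], token_ids) + P["pos_emb"][np.arange(L)]
        attentions: list[np.ndarray] = []
        for layer in range(cfg.num_layers):
            p = f"layer{layer}."
            xn = _layer_norm(x, P[p + "ln1_g"], P[p + "ln1_b"])
            q = (xn @ P[p + "Wq"] + P[p + "Wq_b"]).reshape(L, H, dh).transpose(1, 0, 2)
            kk = (xn @ P[p + "Wk"] + P[p + "Wk_b"]).reshape(L, H, dh).transpose(1, 0, 2)
            v = (xn @ P[p + "Wv"] + P[p + "Wv_b"]).reshape(L, H, dh).transpose(1, 0, 2)
            scores = (q @ kk.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
            attn = scores.softmax(axis=-1)  # (H, L, L)
            if collect_attention:
                attentions.append(attn.data.copy())
            ctx = (attn @ v).transpose(1, 0, 2).reshape(L, h)
            x = x + (ctx @ P[p + "Wo"] + P[p + "Wo_b"])
            xn2 = _layer_norm(x, P[p + "ln2_g"], P[p + "ln2_b"])
            x = x + ((xn2 @ P[p + "W1"] + P[p + "b1"]).relu() @ P[p + "W2"] + P[p + "b2"])
        x = _layer_norm(x, P["lnf_g"], P["lnf_b"])
        out = x @ P["proj_W"] + P["proj_b"]
        return out, attentions

    def encode_tensor(self, chains, masked_chains=None, collect_attention=False):
        """Differentiable encode: (U Tensor (T, d), keys, AttentionStack|None)."""
        token_ids, positions, keys = self.tokenize(chains, masked_chains)
        out, attentions = self.forward(token_ids, collect_attention)
        U = gather_rows(out, positions)
        stack = None
        if collect_attention:
            maps = []
            for full in attentions:
                sub = full[:, positions][:, :, positions]
                sub = sub / sub.sum(axis=-1, keepdims=True)
                maps.append(sub)
            stack = AttentionStack(maps=maps)
        return U, keys, stack


def encode_sequence(encoder: SequenceEncoder, chains: list[tuple[str, str]],
                    masked_chains: set[str] | None = None,
                    collect_attention: bool = True):
    """Evaluation-mode encoding: (U array (T, d), residue keys, AttentionStack)."""
    U, keys, stack = encoder.encode_tensor(
        chains, masked_chains, collect_attention=collect_attention
    )
    return U.data.copy(), keys, stack


# ---------------------------------------------------------------------------
# structure encoder
# ---------------------------------------------------------------------------

class StructureEncoder(_Model):
    """Message-passing network over the k-NN backbone residue graph.

    Alternates edge updates (from the edge feature and the two incident node
    features) with node updates (from each neighbor's node feature and the
    updated connecting edge, aggregated by mean).  Carries no absolute
    positional encodings.
    """

    def __init__(self, config: StructureEncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        h, d = config.hidden_dim, config.output_dim
        self._add("node_in_W", _init(rng, NODE_FEATURE_DIM, h))
        self._add("node_in_b", _zeros(h))
        self._add("edge_in_W", _init(rng, EDGE_FEATURE_DIM, h))
        self._add("edge_in_b", _zeros(h))
        for r in range(config.num_mp_rounds):
            p = f"round{r}."
            self._add(p + "We1", _init(rng, 3 * h, h))
            self._add(p + "be1", _zeros(h))
            self._add(p + "We2", _init(rng, h, h))
            self._add(p + "be2", _zeros(h))
            self._add(p + "ln_e_g", _ones(h))
            self._add(p + "ln_e_b", _zeros(h))
            self._add(p + "Wm", _init(rng, 2 * h, h))
            self._add(p + "bm", _zeros(h))
            self._add(p + "Wu", _init(rng, h, h))
            self._add(p + "bu", _zeros(h))
            self._add(p + "ln_n_g", _ones(h))
            self._add(p + "ln_n_b", _zeros(h))
        self._add("proj_W", _init(rng, h, d))
        self._add("proj_b", _zeros(d))

    def forward(self, graph: ResidueGraph) -> Tensor:
        cfg = self.config
        if graph.k != cfg.k:
            warnings.warn(
                f"graph built with k={graph.k} but encoder configured for "
                f"k={cfg.k}", stacklevel=2,
            )
        P = self.params
        src = graph.edge_index[:, 0]
        dst = graph.edge_index[:, 1]
        T = graph.num_nodes
        degree = np.bincount(src, minlength=T).astype(float)[:, None]
        hN = Tensor(graph.node_features) @ P["node_in_W"] + P["node_in_b"]
        e = Tensor(graph.edge_features) @ P["edge_in_W"] + P["edge_in_b"]
        for r in range(cfg.num_mp_rounds):
            p = f"round{r}."
            h_i = gather_rows(hN, src)
            h_j = gather_rows(hN, dst)
            e_up = (concat([e, h_i, h_j], axis=1) @ P[p + "We1"] + P[p + "be1"]).relu()
            e_up = e_up @ P[p + "We2"] + P[p + "be2"]
            e = _layer_norm(e + e_up, P[p + "ln_e_g"], P[p + "ln_e_b"])
            msg = (concat([gather_rows(hN, dst), e], axis=1) @ P[p + "Wm"]
                   + P[p + "bm"]).relu()
            agg = scatter_sum(msg, src, T) * Tensor(1.0 / np.maximum(degree, 1.0))
            hN = _layer_norm(hN + agg @ P[p + "Wu"] + P[p + "bu"],
                             P[p + "ln_n_g"], P[p + "ln_n_b"])
        return hN @ P["proj_W"] + P["proj_b"]


def encode_structure(encoder: StructureEncoder, graph: ResidueGraph):
    """Evaluation-mode encoding: (V array (T, d), residue keys)."""
    V = encoder.forward(graph)
    return V.data.copy(), list(graph.residue_keys)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, seq_encoder: SequenceEncoder,
                    struct_encoder: StructureEncoder,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: both encoders' weights + embedded JSON config."""
    config = {
        "sequence": asdict(seq_encoder.config),
        "structure": asdict(struct_encoder.config),
        "extra": extra or {},
    }
    arrays = {f"seq::{k}": p.data for k, p in seq_encoder.params.items()}
    arrays.update({f"struct::{k}": p.data for k, p in struct_encoder.params.items()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint -> (SequenceEncoder, StructureEncoder, extra dict)."""
    data = np.load(path)
    config = json.loads(bytes(data["config_json"]).decode())
    seq = SequenceEncoder(SequenceEncoderConfig(**config["sequence"]))
    struct = StructureEncoder(StructureEncoderConfig(**config["structure"]))
    seq.set_params({k[len("seq::"):]: data[k] for k in data.files
                    if k.startswith("seq::")})
    struct.set_params({k[len("struct::"):]: data[k] for k in data.files
                       if k.startswith("struct::")})
    return seq, struct, config.get("extra", {})


def synthetic_profile(d: int = 32, k: int = 16):
    """Desk-scale encoder configs used for synthetic-corpus experiments."""
    seq = SequenceEncoderConfig(num_layers=2, num_heads=4, hidden_dim=64,
                                output_dim=d, max_len=512)
    struct = StructureEncoderConfig(num_mp_rounds=2, hidden_dim=64,
                                    output_dim=d, k=k)
    return seq, struct
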