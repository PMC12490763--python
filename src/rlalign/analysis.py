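"""Downstream screening analytics: decoy discrimination, contact-prediction
probing, mutation scans, greedy structural clustering of designed binders,
and the two-stage Joint Prediction filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from . import geometry
from .structio import AMINO_ACIDS, ProteinStructure, ScoreTable

DOCKQ_ACCEPTABLE = 0.23
CONTACT_CUTOFF = 8.0  # Å between Cα atoms
TM_CLUSTER_THRESHOLD = 0.8
TM_SKIP_MARGIN = 0.25


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class ContactSpec:
    """Cα contact definition with sequence-separation range classes.

    Pairs with |i−j| ≤ 6 belong to no range; short is 6<|i−j|≤12, medium
    12<|i−j|≤24, long |i−j|>24.
    """

    contact_cutoff: float = CONTACT_CUTOFF
    short: tuple[int, int] = (6, 12)
    medium: tuple[int, int] = (12, 24)
    long_min: int = 24

    def range_of(self, separation: int) -> str | None:
        s = abs(separation)
        if self.short[0] < s <= self.short[1]:
            return "short"
        if self.medium[0] < s <= self.medium[1]:
            return "medium"
        if s > self.long_min:
            return "long"
        return None


@dataclass
class BinderRecord:
    """A designed binder: Cα trace, sequence, experimental label and score."""

    binder_id: str
    scaffold_id: str
    ca: np.ndarray
    sequence: str
    label: str | None = None  # "binder" / "nonbinder" (kD ≤ 4 μM rule)
    score: float | None = None
    planted_cluster: str | None = None  # ground truth in synthetic libraries


@dataclass
class BinderCluster:
    """A structurally coherent group of binders sharing one scaffold."""

    cluster_id: str
    scaffold_id: str
    member_ids: list[str]
    mean_score: float | None = None
    success_rate: float | None = None
    label: str | None = None


@dataclass
class DiscriminationReport:
    """Per-target AUROC / rank-correlation summary for decoy ranking."""

    per_target: pd.DataFrame
    mean_auroc: float
    sem_auroc: float
    mean_spearman: float
    sem_spearman: float
    n_dropped: int = 0


@dataclass
class FilterResult:
    """Outcome of the two-stage Joint Prediction filter."""

    stage1_ids: list
    stage2_ids: list
    cutoff: float
    counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# BLOSUM62
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def blosum62_matrix(path: str | None = None):
    """The standard BLOSUM62 substitution matrix (NCBI values).

    Loads biopython's bundled copy, or an NCBI-format text file if `path`
    is given.
    """
    from Bio.Align import substitution_matrices

    if path is None:
        return substitution_matrices.load("BLOSUM62")
    return substitution_matrices.read(path)


def blosum62_score(a: str, b: str) -> int:
    return int(blosum62_matrix()[a, b])


# ---------------------------------------------------------------------------
# contacts and attention probing
# ---------------------------------------------------------------------------

def contact_map(structure: ProteinStructure,
                spec: ContactSpec | None = None):
    """Boolean Cα contact map of a monomer plus per-pair range labels.

    Returns (contacts (T, T) bool, ranges (T, T) object array of
    'short'/'medium'/'long'/None).
    """
    spec = spec or ContactSpec()
    if len(structure.chains) != 1:
        raise ValueError("contact protocol operates on single chains")
    ca = structure.chains[0].ca
    d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
    contacts = d < spec.contact_cutoff
    np.fill_diagonal(contacts, False)
    T = len(ca)
    sep = np.abs(np.arange(T)[:, None] - np.arange(T)[None, :])
    ranges = np.empty((T, T), dtype=object)
    ranges[(sep > spec.short[0]) & (sep <= spec.short[1])] = "short"
    ranges[(sep > spec.medium[0]) & (sep <= spec.medium[1])] = "medium"
    ranges[sep > spec.long_min] = "long"
    return contacts, ranges


def apc(f: np.ndarray) -> np.ndarray:
    """Average product correction of a coupling/attention matrix.

    The matrix is symmetrized first; the row-mean × column-mean / grand-mean
    background product is subtracted elementwise.
    """
    f = np.asarray(f, dtype=float)
    f = 0.5 * (f + f.T)
    total = f.sum()
    if total <= 0:
        raise ValueError("APC undefined for a matrix with non-positive sum")
    row = f.sum(axis=1, keepdims=True)
    col = f.sum(axis=0, keepdims=True)
    return f - row @ col / total


def contact_probe_dataset(structures: list[ProteinStructure], seq_encoder,
                          spec: ContactSpec | None = None):
    """APC-corrected attention features and contact labels for |i−j| > 6 pairs.

    Returns (X (n_pairs, layers*heads), y bool, ranges str array).
    """
    from .encoders import encode_sequence

    spec = spec or ContactSpec()
    feats, labels, rngs = [], [], []
    for s in structures:
        chains = [(c.chain_id, c.sequence) for c in s.chains]
        _, _, stack = encode_sequence(seq_encoder, chains,
                                      collect_attention=True)
        heads = stack.stacked()  # (L*H, T, T)
        corrected = np.stack([apc(h) for h in heads])
        contacts, ranges = contact_map(s, spec)
        T = contacts.shape[0]
        iu, ju = np.triu_indices(T, k=spec.short[0] + 1)
        keep = np.array([ranges[i, j] is not None for i, j in zip(iu, ju)])
        iu, ju = iu[keep], ju[keep]
        feats.append(corrected[:, iu, ju].T)
        labels.append(contacts[iu, ju])
        rngs.append(np.array([ranges[i, j] for i, j in zip(iu, ju)]))
    return (np.concatenate(feats), np.concatenate(labels),
            np.concatenate(rngs))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    total = tp + fn + tn + fp
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "tnr": tn / (tn + fp) if (tn + fp) else float("nan"),
        "tpr": tp / (tp + fn) if (tp + fn) else float("nan"),
    }


@dataclass
class ContactProbeReport:
    probe: LogisticRegression
    regularization: float
    metrics: dict[str, dict[str, float]]  # overall + per range


def train_contact_probe(X: np.ndarray, y: np.ndarray, ranges: np.ndarray,
                        split=(0.6, 0.2, 0.2), seed: int = 0,
                        c_grid=(0.01, 0.1, 1.0, 10.0)) -> ContactProbeReport:
    """Fit an L2 logistic probe on attention features; report per-range metrics.

    Regularization strength is chosen by validation accuracy over `c_grid`.
    """
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("contact labels are single-class; cannot fit probe")
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_tr = int(split[0] * n)
    n_va = int(split[1] * n)
    tr, va, te = order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:]

    best_c, best_acc, best_model = None, -1.0, None
    for c in c_grid:
        model = LogisticRegression(C=c, max_iter=2000)
        model.fit(X[tr], y[tr])
        acc = float((model.predict(X[va]) == y[va]).mean()) if len(va) else 1.0
        if acc > best_acc:
            best_c, best_acc, best_model = c, acc, model

    pred = best_model.predict(X[te])
    metrics: dict[str, dict[str, float]] = {}
    for name in ("all", "short", "medium", "long"):
        mask = np.ones(len(te), dtype=bool) if name == "all" else (
            ranges[te] == name)
        if not mask.any():
            continue
        yt, yp = y[te][mask], pred[mask]
        tp = int((yt & yp).sum())
        fn = int((yt & ~yp).sum())
        tn = int((~yt & ~yp).sum())
        fp = int((~yt & yp).sum())
        metrics[name] = confusion_metrics(tp, fn, tn, fp)
    return ContactProbeReport(probe=best_model, regularization=best_c,
                              metrics=metrics)


# ---------------------------------------------------------------------------
# decoy discrimination
# ---------------------------------------------------------------------------

def rank_decoys(scores: ScoreTable, score_col: str = "rla",
                label_col: str = "dockq",
                threshold: float = DOCKQ_ACCEPTABLE) -> DiscriminationReport:
    """Per-target AUROC (acceptable = label ≥ threshold) and Spearman rank
    correlation of score vs label, aggregated as mean ± SEM over targets."""
    frame = scores.frame
    usable = frame.dropna(subset=[score_col, label_col])
    n_dropped = len(frame) - len(usable)
    rows = []
    for target, grp in usable.groupby("complex_id", sort=True):
        y = (grp[label_col] >= threshold).to_numpy()
        x = grp[score_col].to_numpy(dtype=float)
        auroc = (roc_auc_score(y, x)
                 if 0 < y.sum() < len(y) and len(y) >= 2 else np.nan)
        lab = grp[label_col].to_numpy(dtype=float)
        rho = (spearmanr(x, lab).statistic
               if len(y) >= 2 and np.ptp(x) > 0 and np.ptp(lab) > 0
               else np.nan)
        rows.append({"complex_id": target, "auroc": auroc, "spearman": rho,
                     "n_candidates": len(y), "n_acceptable": int(y.sum())})
    per_target = pd.DataFrame(rows)

    def _agg(col):
        vals = per_target[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            return float("nan"), float("nan")
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        return float(vals.mean()), float(sem)

    mean_a, sem_a = _agg("auroc")
    mean_s, sem_s = _agg("spearman")
    return DiscriminationReport(per_target=per_target, mean_auroc=mean_a,
                                sem_auroc=sem_a, mean_spearman=mean_s,
                                sem_spearman=sem_s, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# mutation scan
# ---------------------------------------------------------------------------

def mutation_scan(structure: ProteinStructure, seq_encoder, struct_encoder,
                  max_mutations: int | None = None, seed: int = 0,
                  all_at_once: bool = False,
                  balanced: bool = False) -> pd.DataFrame:
    """Per-mutation change in interface S_RLA, grouped by BLOSUM62 sign.

    Every interface residue is mutated (one at a time by default) to every
    amino acid with a strictly positive or strictly negative BLOSUM62 score
    against the wild type (zero-scored pairs and identity excluded); the
    structure is left unchanged and only the sequence is re-encoded.
    """
    from .encoders import encode_sequence, encode_structure, pair_embeddings
    from .rla_core import score_complex

    if len(structure.chains) < 2:
        raise ValueError("mutation scan requires a complex (≥ 2 chains)")
    mat = blosum62_matrix()
    iface = geometry.interface_residues(structure)
    graph = geometry.knn_graph(structure, k=struct_encoder.config.k)
    V, keys_v = encode_structure(struct_encoder, graph)
    wt_chains = [(c.chain_id, c.sequence) for c in structure.chains]

    def s_rla_of(chains) -> float:
        U, keys_u, _ = encode_sequence(seq_encoder, chains,
                                       collect_attention=False)
        pair = pair_embeddings(U, V, keys_u, keys_v)
        return score_complex(pair, structure, mode="interface").s_rla

    s_wt = s_rla_of(wt_chains)
    candidates = []
    for cid, residues in iface.by_chain.items():
        seq = structure.chain(cid).sequence
        for idx in sorted(residues):
            wt = seq[idx]
            if wt not in AMINO_ACIDS:
                continue
            for mut in AMINO_ACIDS:
                if mut == wt:
                    continue
                b = int(mat[wt, mut])
                if b == 0:
                    continue
                candidates.append((cid, idx, wt, mut, b))
    if max_mutations is not None and len(candidates) > max_mutations:
        rng = np.random.default_rng(seed)
        if balanced:
            # equal draws from the adverse and benign groups where possible
            adverse = [c for c in candidates if c[4] < 0]
            benign = [c for c in candidates if c[4] > 0]
            half = max_mutations // 2
            picked = []
            for pool in (adverse, benign):
                if len(pool) > half:
                    pick = rng.choice(len(pool), size=half, replace=False)
                    picked.extend(pool[i] for i in sorted(pick))
                else:
                    picked.extend(pool)
            candidates = picked
        else:
            pick = rng.choice(len(candidates), size=max_mutations, replace=False)
            candidates = [candidates[i] for i in sorted(pick)]

    rows = []
    if all_at_once:
        # one mutated complex per drawn mutation set is not meaningful;
        # mutate every interface residue simultaneously with a random
        # admissible substitution per residue, once per sign group
        rng = np.random.default_rng(seed)
        for group, sign in (("benign", 1), ("adverse", -1)):
            seqs = {cid: list(structure.chain(cid).sequence)
                    for cid in structure.chain_ids}
            for cid, residues in iface.by_chain.items():
                for idx in sorted(residues):
                    wt = seqs[cid][idx]
                    opts = [aa for aa in AMINO_ACIDS if aa != wt
                            and np.sign(int(mat[wt, aa])) == sign]
                    if opts:
                        seqs[cid][idx] = opts[int(rng.integers(len(opts)))]
            chains = [(cid, "".join(seqs[cid])) for cid in structure.chain_ids]
            rows.append({"chain": "*", "index": -1, "wt": "*", "mut": "*",
                         "blosum": sign, "group": group,
                         "delta_s": s_rla_of(chains) - s_wt})
        return pd.DataFrame(rows)

    for cid, idx, wt, mut, b in candidates:
        chains = [
            (c.chain_id,
             c.sequence[:idx] + mut + c.sequence[idx + 1:]
             if c.chain_id == cid else c.sequence)
            for c in structure.chains
        ]
        rows.append({"chain": cid, "index": idx, "wt": wt, "mut": mut,
                     "blosum": b, "group": "benign" if b > 0 else "adverse",
                     "delta_s": s_rla_of(chains) - s_wt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# greedy structural clustering
# ---------------------------------------------------------------------------

def greedy_cluster(binders: list[BinderRecord],
                   tm_threshold: float = TM_CLUSTER_THRESHOLD,
                   skip_margin: float = TM_SKIP_MARGIN,
                   tm_func=None) -> list[BinderCluster]:
    """Greedy TM-score clustering of binders within each scaffold.

    Iterates binders in input order.  An unclustered binder i seeds a new
    cluster; the TM-score T(i, j) to an unclustered j is computed only when
    no previously scored binder k separates them (min over shared k of
    |T(i,k) − T(j,k)| < `skip_margin`, or no shared k exists), and the
    cluster collects every j with T(i, j) > `tm_threshold`.  TM values are
    cached, never recomputed.  The result partitions the input and never
    spans scaffolds.
    """
    tm_func = tm_func or geometry.tm_score
    clusters: list[BinderCluster] = []
    by_scaffold: dict[str, list[int]] = {}
    for n, rec in enumerate(binders):
        by_scaffold.setdefault(rec.scaffold_id, []).append(n)

    for scaffold_id, members in by_scaffold.items():
        lengths = {binders[n].ca.shape[0] for n in members}
        if len(lengths) > 1:
            raise ValueError(
                f"scaffold {scaffold_id!r} mixes Cα trace lengths {lengths}"
            )
        cache: dict[tuple[int, int], float] = {}

        def tm(a: int, b: int) -> float:
            key = (a, b) if a <= b else (b, a)
            if key not in cache:
                cache[key] = 1.0 if a == b else float(
                    tm_func(binders[a].ca, binders[b].ca))
            return cache[key]

        def known(a: int, b: int) -> float | None:
            key = (a, b) if a <= b else (b, a)
            return cache.get(key)

        clustered: set[int] = set()
        for pos, i in enumerate(members):
            if i in clustered:
                continue
            group = [i]
            for j in members:
                if j == i or j in clustered:
                    continue
                shared = []
                for k in members[:pos]:
                    tik, tjk = known(i, k), known(j, k)
                    if tik is not None and tjk is not None:
                        shared.append(abs(tik - tjk))
                if shared and min(shared) >= skip_margin:
                    continue  # i and j already differ from some k differently
                if tm(i, j) > tm_threshold:
                    group.append(j)
            clustered.update(group)
            clusters.append(BinderCluster(
                cluster_id=f"{scaffold_id}/c{len(clusters)}",
                scaffold_id=scaffold_id,
                member_ids=[binders[n].binder_id for n in group],
            ))
    return clusters


def label_clusters(clusters: list[BinderCluster],
                   records: list[BinderRecord]) -> list[BinderCluster]:
    """Attach success rates, binder/nonbinder labels and mean scores.

    A cluster is labeled "binder" iff its success rate strictly exceeds the
    overall success rate of its scaffold class; the cluster score is the
    mean of its members' scores.
    """
    by_id = {r.binder_id: r for r in records}
    scaffold_rate: dict[str, float] = {}
    for scaffold_id in {r.scaffold_id for r in records}:
        labels = [r.label for r in records if r.scaffold_id == scaffold_id]
        if any(l is None for l in labels):
            raise ValueError(f"missing labels in scaffold {scaffold_id!r}")
        scaffold_rate[scaffold_id] = float(
            np.mean([l == "binder" for l in labels]))
    for cluster in clusters:
        assert cluster.member_ids, "empty cluster is impossible by construction"
        members = [by_id[m] for m in cluster.member_ids]
        cluster.success_rate = float(
            np.mean([m.label == "binder" for m in members]))
        cluster.mean_score = float(np.mean([m.score for m in members]))
        cluster.label = ("binder"
                         if cluster.success_rate > scaffold_rate[cluster.scaffold_id]
                         else "nonbinder")
    return clusters


def clusters_to_frame(clusters: list[BinderCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for m in c.member_ids:
            rows.append({"binder_id": m, "scaffold_id": c.scaffold_id,
                         "cluster_id": c.cluster_id, "label": c.label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-stage filtering and success rates
# ---------------------------------------------------------------------------

def joint_filter(candidates: pd.DataFrame | ScoreTable, second_stage=None,
                 percentile: float = 25.0, score_col: str = "rla",
                 id_col: str = "candidate_id") -> FilterResult:
    """Two-stage screen: keep the top `percentile` % by score (ties at the
    cutoff included), then apply the second-stage scorer's pass rule.

    `second_stage` is a callable mapping the surviving sub-DataFrame to a
    boolean mask (default: accept all; the slow scorer is pluggable and is
    never computed here).
    """
    frame = candidates.frame if isinstance(candidates, ScoreTable) else candidates
    if len(frame) == 0:
        raise ValueError("empty candidate set")
    scores = frame[score_col].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError(f"missing values in score column {score_col!r}")
    cutoff = float(np.quantile(scores, 1.0 - percentile / 100.0))
    survivors = frame[scores >= cutoff]
    if second_stage is None:
        passed = survivors
    else:
        mask = np.asarray(second_stage(survivors), dtype=bool)
        passed = survivors[mask]
    return FilterResult(
        stage1_ids=survivors[id_col].tolist(),
        stage2_ids=passed[id_col].tolist(),
        cutoff=cutoff,
        counts={"input": len(frame), "stage1": len(survivors),
                "stage2": len(passed)},
    )


def success_rate(num_designs: int, num_successes: int) -> float:
    """Percentage of successful designs, half-up rounded to 2 decimals."""
    if num_designs <= 0:
        raise ValueError("num_designs must be positive")
    if not 0 <= num_successes <= num_designs:
        raise ValueError("num_successes must be in [0, num_designs]")
    pct = Decimal(100 * num_successes) / Decimal(num_designs)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
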