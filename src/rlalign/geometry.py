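"""Coordinate mathematics: dihedrals, k-NN residue graphs, interfaces,
binding sites, superposition, TM-score and structural noise.

All residue–residue distances (k-NN graphs, interface detection, binding
sites, contacts) are taken between Cα atoms.  Every feature produced here
is invariant under rigid-body motion of the input coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import BACKBONE_ATOMS, Chain, ProteinStructure

# Ingraham-style radial basis expansion of backbone atom-pair distances.
RBF_CENTERS = np.linspace(0.0, 20.0, 16)
RBF_WIDTH = 1.25
MAX_SEQ_OFFSET = 32  # relative-offset edge feature is clipped to ±32

NODE_FEATURE_DIM = 6  # (cos, sin) of phi, psi, omega
# one-hot offset (65) + cross-chain flag + quaternion (4) + unit vector (3)
# + 16 atom pairs × 16 RBFs
EDGE_FEATURE_DIM = (2 * MAX_SEQ_OFFSET + 1) + 1 + 4 + 3 + 16 * len(RBF_CENTERS)


class DihedralUndefinedError(ValueError):
    """Raised when a torsion angle is requested for degenerate geometry."""


class InterfaceError(ValueError):
    """Raised for interface operations on single-chain structures."""


@dataclass
class ResidueGraph:
    """k-NN graph over residues with rigid-invariant node/edge features."""

    num_nodes: int
    node_features: np.ndarray  # (T, NODE_FEATURE_DIM)
    edge_index: np.ndarray  # (E, 2) directed (i, j), j in kNN(i)
    edge_features: np.ndarray  # (E, EDGE_FEATURE_DIM)
    k: int
    residue_keys: list[tuple[str, int]]


@dataclass(frozen=True)
class BindingSite:
    """Target residues whose Cα lies strictly within `cutoff` of the binder."""

    target_id: str
    residue_keys: frozenset


@dataclass
class InterfaceSet:
    """Per-chain residue indices at a binding interface."""

    by_chain: dict[str, frozenset]

    def total(self) -> int:
        return sum(len(v) for v in self.by_chain.values())


# ---------------------------------------------------------------------------
# dihedrals and frames
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DihedralUndefinedError("collinear points: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def backbone_dihedrals(chain: Chain) -> np.ndarray:
    """Per-residue (phi, psi, omega) in degrees; undefined angles are NaN.

    phi_i  : C(i−1)–N(i)–CA(i)–C(i)
    psi_i  : N(i)–CA(i)–C(i)–N(i+1)
    omega_i: CA(i−1)–C(i−1)–N(i)–CA(i)
    Chain-terminal angles (and degenerate geometry) are NaN; downstream
    feature encoding maps NaN to (cos, sin) = (0, 0).
    """
    T = len(chain)
    out = np.full((T, 3), np.nan)
    bb = chain.backbone  # (T, 4, 3): N, CA, C, O
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]
    for i in range(T):
        if i > 0:
            try:
                out[i, 0] = dihedral(C[i - 1], N[i], CA[i], C[i])
            except DihedralUndefinedError:
                pass
            try:
                out[i, 2] = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
            except DihedralUndefinedError:
                pass
        if i < T - 1:
            try:
                out[i, 1] = dihedral(N[i], CA[i], C[i], N[i + 1])
            except DihedralUndefinedError:
                pass
    return out


def dihedral_features(chain: Chain) -> np.ndarray:
    """(cos, sin) encoding of (phi, psi, omega); NaN angles become (0, 0)."""
    ang = np.radians(backbone_dihedrals(chain))
    feats = np.empty((len(chain), 6))
    feats[:, 0::2] = np.cos(ang)
    feats[:, 1::2] = np.sin(ang)
    feats[np.isnan(feats)] = 0.0
    return feats


def residue_frames(backbone: np.ndarray) -> np.ndarray:
    """Per-residue orthonormal frames (T, 3, 3) from N, CA, C by Gram-Schmidt.

    Columns are e1 = unit(CA−N), e2 = unit(C−CA ⊥ e1), e3 = e1 × e2.
    """
    N, CA, C = backbone[:, 0], backbone[:, 1], backbone[:, 2]
    u = CA - N
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    v = C - CA
    v = v - (v * u).sum(axis=1, keepdims=True) * u
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    w = np.cross(u, v)
    return np.stack([u, v, w], axis=2)


def _quaternion_from_rotation(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) with the largest-|component| sign positive."""
    w = 0.5 * np.sqrt(max(0.0, 1.0 + R[0, 0] + R[1, 1] + R[2, 2]))
    x = 0.5 * np.sqrt(max(0.0, 1.0 + R[0, 0] - R[1, 1] - R[2, 2]))
    y = 0.5 * np.sqrt(max(0.0, 1.0 - R[0, 0] + R[1, 1] - R[2, 2]))
    z = 0.5 * np.sqrt(max(0.0, 1.0 - R[0, 0] - R[1, 1] + R[2, 2]))
    x = np.copysign(x, R[2, 1] - R[1, 2])
    y = np.copysign(y, R[0, 2] - R[2, 0])
    z = np.copysign(z, R[1, 0] - R[0, 1])
    q = np.array([w, x, y, z])
    n = np.linalg.norm(q)
    if n < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    q /= n
    if q[np.argmax(np.abs(q))] < 0:
        q = -q
    return q


def rbf_expand(d: np.ndarray) -> np.ndarray:
    """Gaussian radial-basis expansion of distances (…,) → (…, 16)."""
    return np.exp(-(((d[..., None] - RBF_CENTERS) / RBF_WIDTH) ** 2))


# ---------------------------------------------------------------------------
# graphs and interfaces
# ---------------------------------------------------------------------------

def _knn_indices(ca: np.ndarray, k: int) -> np.ndarray:
    """Ascending-distance neighbor lists (T, min(k, T−1)); ties by lower index."""
    T = ca.shape[0]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    kk = min(k, T - 1)
    order = np.argsort(d, axis=1, kind="stable")  # stable: ties → lower index
    return order[:, :kk]


def knn_graph(structure: ProteinStructure, k: int = 30) -> ResidueGraph:
    """Directed k-NN residue graph (Cα distances) with invariant features."""
    T = structure.total_residues
    if T < 2:
        raise ValueError("k-NN graph requires at least 2 residues")
    ca = structure.all_ca()
    bb = structure.all_backbone()
    chain_idx = structure.chain_index()
    keys = structure.residue_keys
    local_idx = np.array([key[1] for key in keys])

    nbrs = _knn_indices(ca, k)
    kk = nbrs.shape[1]
    src = np.repeat(np.arange(T), kk)
    dst = nbrs.reshape(-1)
    edge_index = np.stack([src, dst], axis=1)

    frames = residue_frames(bb)
    E = edge_index.shape[0]
    feats = np.zeros((E, EDGE_FEATURE_DIM))

    # relative sequence offset (one-hot, clipped) + cross-chain flag
    n_off = 2 * MAX_SEQ_OFFSET + 1
    same_chain = chain_idx[src] == chain_idx[dst]
    offset = np.clip(local_idx[dst] - local_idx[src], -MAX_SEQ_OFFSET, MAX_SEQ_OFFSET)
    rows = np.where(same_chain)[0]
    feats[rows, offset[rows] + MAX_SEQ_OFFSET] = 1.0
    feats[~same_chain, n_off] = 1.0
    col = n_off + 1

    # relative orientation: quaternion of R_i^T R_j and unit CA_i→CA_j in frame i
    for e in range(E):
        i, j = src[e], dst[e]
        R_rel = frames[i].T @ frames[j]
        feats[e, col:col + 4] = _quaternion_from_rotation(R_rel)
        vec = ca[j] - ca[i]
        feats[e, col + 4:col + 7] = frames[i].T @ (vec / np.linalg.norm(vec))
    col += 7

    # all 16 backbone atom-pair distances through RBFs
    pair_d = np.linalg.norm(
        bb[src][:, :, None, :] - bb[dst][:, None, :, :], axis=3
    ).reshape(E, 16)
    feats[:, col:] = rbf_expand(pair_d).reshape(E, -1)

    node_feats = np.concatenate(
        [dihedral_features(c) for c in structure.chains], axis=0
    )
    return ResidueGraph(
        num_nodes=T,
        node_features=node_feats,
        edge_index=edge_index,
        edge_features=feats,
        k=k,
        residue_keys=keys,
    )


def interface_residues(structure: ProteinStructure, k: int = 30) -> InterfaceSet:
    """Residues whose k nearest residues (whole complex) include another chain.

    Matches the docking-interface definition: a residue is interfacial iff a
    residue from an opposing chain appears among its 30 nearest neighbors.
    """
    if len(structure.chains) < 2:
        raise InterfaceError(
            "interface detection needs ≥ 2 chains; use all-residue scoring "
            "mode for single-chain structures"
        )
    ca = structure.all_ca()
    chain_idx = structure.chain_index()
    nbrs = _knn_indices(ca, k)
    is_iface = (chain_idx[nbrs] != chain_idx[:, None]).any(axis=1)
    by_chain: dict[str, set] = {c.chain_id: set() for c in structure.chains}
    for (cid, local), flag in zip(structure.residue_keys, is_iface):
        if flag:
            by_chain[cid].add(local)
    return InterfaceSet(by_chain={c: frozenset(v) for c, v in by_chain.items()})


# ---------------------------------------------------------------------------
# binding sites
# ---------------------------------------------------------------------------

def binding_site(target_ca: np.ndarray, binder_ca: np.ndarray,
                 cutoff: float = 8.0, target_id: str = "target") -> BindingSite:
    """Target residues with Cα strictly within `cutoff` Å of any binder Cα."""
    target_ca = np.asarray(target_ca, dtype=float)
    binder_ca = np.asarray(binder_ca, dtype=float)
    if target_ca.size == 0 or binder_ca.size == 0:
        raise ValueError("both coordinate sets must be non-empty")
    tree = cKDTree(binder_ca)
    dmin, _ = tree.query(target_ca, k=1)
    keys = frozenset(int(i) for i in np.where(dmin < cutoff)[0])
    return BindingSite(target_id=target_id, residue_keys=keys)


def binding_site_overlap(s1: BindingSite, s2: BindingSite) -> float:
    """Jaccard overlap of two binding sites on the same target."""
    if s1.target_id != s2.target_id:
        raise ValueError(
            f"binding sites on different targets: {s1.target_id!r} vs {s2.target_id!r}"
        )
    union = s1.residue_keys | s2.residue_keys
    if not union:
        warnings.warn("both binding sites empty; overlap defined as 0", stacklevel=2)
        return 0.0
    return len(s1.residue_keys & s2.residue_keys) / len(union)


def average_binding_site_overlap(sites: list[BindingSite]) -> float:
    """Mean pairwise Jaccard overlap, O_T = 2/(n(n−1)) Σ_{i<j} L_ij."""
    n = len(sites)
    if n < 2:
        raise ValueError("need at least 2 binding sites")
    total = sum(
        binding_site_overlap(sites[i], sites[j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    return 2.0 * total / (n * (n - 1))


# ---------------------------------------------------------------------------
# superposition and TM-score
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, fixed: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `fixed`.

    Returns (R, t, rmsd) with R a proper rotation (det +1) such that
    mobile @ R.T + t least-squares matches fixed.
    """
    mobile = np.asarray(mobile, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if mobile.shape != fixed.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mc, fc = mobile.mean(axis=0), fixed.mean(axis=0)
    A, B = mobile - mc, fixed - fc
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(A), np.linalg.norm(B))
    if scale == 0 or S[1] < 1e-9 * scale**2 / n:
        # identical point clouds give a full-rank covariance except when the
        # points themselves are (near-)collinear, which is genuinely ambiguous
        if not np.allclose(A, B, atol=1e-12):
            raise ValueError("rank-deficient (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    diff = (A @ R.T) - B
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def tm_d0(length: int) -> float:
    """Length-dependent TM-score normalization distance (floored at 0.5 Å)."""
    return max(0.5, 1.24 * np.cbrt(length - 15.0) - 1.8)


def tm_score_from_distances(d: np.ndarray, ref_length: int) -> float:
    """TM = (1/L_ref) Σ 1/(1 + (d_i/d0)²) for already-superposed distances."""
    d0 = tm_d0(ref_length)
    return float(np.sum(1.0 / (1.0 + (np.asarray(d) / d0) ** 2)) / ref_length)


def tm_score(model: np.ndarray, reference: np.ndarray, max_iter: int = 20) -> float:
    """TM-score between equal-length Cα traces.

    Starts from the all-residue Kabsch fit, then alternately re-fits on the
    residue subset with d_i < d0 and re-scores, keeping the best score seen.
    Iteration stops when the included set is stable (cap `max_iter`).
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError("TM-score here requires equal-length Cα traces")
    L = reference.shape[0]
    d0 = tm_d0(L)

    def aligned_distances(subset: np.ndarray) -> np.ndarray:
        R, t, _ = kabsch_superpose(model[subset], reference[subset])
        return np.linalg.norm(model @ R.T + t - reference, axis=1)

    subset = np.arange(L)
    d = aligned_distances(subset)
    best = tm_score_from_distances(d, L)
    prev: frozenset | None = None
    for _ in range(max_iter):
        include = np.where(d < d0)[0]
        if len(include) < 3:
            break
        cur = frozenset(include.tolist())
        if cur == prev:
            break
        prev = cur
        try:
            d = aligned_distances(include)
        except ValueError:  # degenerate subset
            break
        best = max(best, tm_score_from_distances(d, L))
    return best


# ---------------------------------------------------------------------------
# structural noise
# ---------------------------------------------------------------------------

def add_structure_noise(structure: ProteinStructure, target_rms: float,
                        seed: int) -> ProteinStructure:
    """Gaussian coordinate noise with expected per-atom displacement RMS
    equal to `target_rms` (per-axis σ = target_rms/√3); deterministic in seed."""
    if target_rms < 0:
        raise ValueError("target_rms must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = target_rms / np.sqrt(3.0)
    chains = []
    for c in structure.chains:
        noise = rng.normal(0.0, sigma, size=c.backbone.shape) if sigma > 0 else 0.0
        chains.append(
            Chain(
                chain_id=c.chain_id,
                sequence=c.sequence,
                backbone=c.backbone + noise,
                author_numbering=c.author_numbering,
            )
        )
    return ProteinStructure(chains=chains, source_id=structure.source_id)
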