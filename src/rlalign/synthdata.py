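"""Synthetic sequence–structure corpora, docking decoys and binder libraries.

The generator builds ideal-geometry backbones from canonical bond lengths
and angles with per-segment (phi, psi) targets, and couples sequence to
local structure by mapping each residue's quantized (phi, psi) bin to an
amino acid.  Under the default "identity" coupling the sequence is a
deterministic function of local backbone geometry, so sequence–structure
alignment is learnable by construction — a sharp, fully synthetic stand-in
for training on real structure databases.

Amino acids are assigned to dihedral bins along a greedy BLOSUM62
similarity chain, so conservative (BLOSUM62-positive) substitutions
correspond to small changes in local geometry, emulating the real-world
tendency the mutation-scan analyses probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .analysis import BinderRecord, blosum62_matrix
from .geometry import add_structure_noise
from .structio import AMINO_ACIDS, Chain, ProteinStructure

# canonical backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

CLASH_CUTOFF = 2.5  # Å, non-consecutive Cα pairs
MAX_REGEN = 50

N_PHI_BINS = 4
N_PSI_BINS = 5  # 4 × 5 = 20 bins, one amino acid each


@dataclass
class GeneratorSpec:
    """Stated world for the synthetic corpus."""

    num_proteins: int = 200
    chain_length_range: tuple[int, int] = (30, 50)
    num_chains_range: tuple[int, int] = (1, 1)
    coupling_mode: str = "identity"  # identity | local-window | none
    secondary_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # helix/strand/coil
    noise_floor: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.secondary_mix) - 1.0) > 1e-9:
            raise ValueError("secondary_mix proportions must sum to 1")
        if self.chain_length_range[0] < 5:
            raise ValueError("chain lengths must be >= 5")
        if self.coupling_mode not in ("identity", "local-window", "none"):
            raise ValueError(f"unknown coupling mode {self.coupling_mode!r}")


@dataclass
class DecoySpec:
    """Perturbation ladder for docking-pose decoys, mildest tier first."""

    decoys_per_tier: int = 2
    # (rigid displacement Å, internal noise Å) per tier beyond the native
    ladder: tuple[tuple[float, float], ...] = (
        (1.5, 0.1), (4.0, 0.3), (10.0, 0.6), (25.0, 1.0),
    )

    def __post_init__(self):
        sev = [d + 10 * s for d, s in self.ladder]
        if any(b <= a for a, b in zip(sev, sev[1:])):
            raise ValueError("ladder must be strictly increasing in severity")


@dataclass
class DecoyRecord:
    structure: ProteinStructure
    tier: int
    quality: float  # native-contact recovery fraction, stands in for DockQ


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension-reference-frame placement of atom d after a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion),
         -np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone (T, 4, 3) from per-residue (phi, psi); omega fixed trans."""
    T = len(phi)
    bb = np.zeros((T, 4, 3))
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    bb[0, 2] = bb[0, 1] + BOND_CA_C * np.array([np.cos(np.pi - ang),
                                                np.sin(np.pi - ang), 0.0])
    for i in range(1, T):
        bb[i, 0] = _place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                               BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        bb[i, 1] = _place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                               BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        bb[i, 2] = _place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                               BOND_CA_C, ANGLE_N_CA_C, phi[i])
    for i in range(T):
        bb[i, 3] = _place_atom(bb[i, 0], bb[i, 1], bb[i, 2],
                               BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    return bb


def _sample_targets(length: int, secondary_mix, rng: np.random.Generator,
                    jitter: float = 2.0):
    """Per-residue (phi, psi) targets from random secondary-structure segments."""
    phi = np.empty(length)
    psi = np.empty(length)
    i = 0
    while i < length:
        seg = int(rng.integers(6, 13))
        kind = rng.choice(3, p=list(secondary_mix))
        hi = min(length, i + seg)
        if kind == 0:
            p, s = HELIX_PHI_PSI
            phi[i:hi], psi[i:hi] = p, s
        elif kind == 1:
            p, s = STRAND_PHI_PSI
            phi[i:hi], psi[i:hi] = p, s
        else:
            phi[i:hi] = rng.uniform(-160.0, -50.0, hi - i)
            psi[i:hi] = rng.uniform(-180.0, 180.0, hi - i)
        i = hi
    phi += rng.normal(0.0, jitter, length)
    psi += rng.normal(0.0, jitter, length)
    return phi, psi


def _has_self_clash(ca: np.ndarray, cutoff: float = CLASH_CUTOFF) -> bool:
    d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
    T = len(ca)
    mask = np.abs(np.arange(T)[:, None] - np.arange(T)[None, :]) >= 2
    return bool((d[mask] < cutoff).any())


def gen_backbone(length: int, secondary_mix=(0.5, 0.25, 0.25),
                 seed: int | np.random.Generator = 0,
                 pure: str | None = None) -> np.ndarray:
    """Generate one self-avoiding ideal-geometry backbone (length, 4, 3).

    `pure` forces a single secondary structure ("helix" or "strand");
    regenerates on self-clash up to 50 times.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    for _ in range(MAX_REGEN):
        if pure == "helix":
            phi = np.full(length, HELIX_PHI_PSI[0])
            psi = np.full(length, HELIX_PHI_PSI[1])
        elif pure == "strand":
            phi = np.full(length, STRAND_PHI_PSI[0])
            psi = np.full(length, STRAND_PHI_PSI[1])
        else:
            phi, psi = _sample_targets(length, secondary_mix, rng)
        bb = _build_backbone(phi, psi)
        if not _has_self_clash(bb[:, 1]):
            return bb
        if pure is not None:  # deterministic targets cannot clash differently
            return bb
    raise RuntimeError(f"could not build a clash-free backbone of length {length}")


# ---------------------------------------------------------------------------
# sequence coupling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def coupled_letter_order() -> str:
    """The 20 amino acids ordered along a greedy BLOSUM62 similarity chain.

    Consecutive letters are mutually high-scoring, so assigning them to
    adjacent dihedral bins makes conservative substitutions structurally
    conservative too.
    """
    mat = blosum62_matrix()
    letters = list(AMINO_ACIDS)
    order = ["A"]
    remaining = [aa for aa in letters if aa != "A"]
    while remaining:
        cur = order[-1]
        best = max(remaining, key=lambda aa: (mat[cur, aa], -ord(aa)))
        order.append(best)
        remaining.remove(best)
    return "".join(order)


def dihedral_bin(phi: float, psi: float) -> int:
    """Quantize (phi, psi) in degrees to one of 20 bins (NaN treated as 0°)."""
    if np.isnan(phi):
        phi = 0.0
    if np.isnan(psi):
        psi = 0.0
    pb = min(N_PHI_BINS - 1, int((phi + 180.0) / (360.0 / N_PHI_BINS)))
    sb = min(N_PSI_BINS - 1, int((psi + 180.0) / (360.0 / N_PSI_BINS)))
    # serpentine path so path-adjacent bins are grid-adjacent
    sb_path = sb if pb % 2 == 0 else N_PSI_BINS - 1 - sb
    return pb * N_PSI_BINS + sb_path


def sequence_from_backbone(chain_bb: np.ndarray,
                           coupling_mode: str = "identity",
                           rng: np.random.Generator | None = None,
                           substitution_rate: float = 0.2) -> str:
    """Derive a sequence from backbone dihedrals under the coupling model."""
    from .geometry import backbone_dihedrals

    order = coupled_letter_order()
    T = chain_bb.shape[0]
    if coupling_mode == "none":
        if rng is None:
            raise ValueError("coupling 'none' requires an rng")
        return "".join(rng.choice(list(AMINO_ACIDS), size=T))
    tmp = Chain(chain_id="?", sequence="X" * T, backbone=chain_bb)
    ang = backbone_dihedrals(tmp)
    letters = []
    for i in range(T):
        b = dihedral_bin(ang[i, 0], ang[i, 1])
        if coupling_mode == "local-window" and rng is not None \
                and rng.random() < substitution_rate:
            b = int(np.clip(b + rng.choice([-1, 1]), 0, 19))
        letters.append(order[b])
    return "".join(letters)


# ---------------------------------------------------------------------------
# paired examples / corpora
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def place_chain_near(fixed_ca: np.ndarray, mobile_bb: np.ndarray,
                     rng: np.random.Generator, contact_gap: float = 4.5,
                     clash: float = 3.2, site_point: np.ndarray | None = None
                     ) -> np.ndarray:
    """Rigidly place a chain so its closest Cα approach to `fixed_ca` is
    ~`contact_gap` Å (never below `clash`), approaching toward `site_point`."""
    bb = mobile_bb.copy()
    center = bb[:, 1].mean(axis=0)
    R = _random_rotation(rng)
    bb = (bb - center) @ R.T
    anchor = (site_point if site_point is not None
              else fixed_ca[rng.integers(len(fixed_ca))])
    direction = anchor - fixed_ca.mean(axis=0)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    r_mobile = np.linalg.norm(bb[:, 1], axis=1).max()
    pos = bb + anchor + direction * (r_mobile + 12.0)
    for t in np.arange(r_mobile + 12.0, -0.1, -0.5):
        cand = bb + anchor + direction * t
        dmin = np.min(np.linalg.norm(
            fixed_ca[:, None] - cand[None, :, 1], axis=2))
        if dmin < clash:
            break
        pos = cand
        if dmin <= contact_gap:
            break
    return pos


def gen_paired_example(spec: GeneratorSpec,
                       seed: int | np.random.Generator | None = None):
    """One multi-chain structure plus its coupled per-chain sequences."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(spec.seed if seed is None else seed))
    n_chains = int(rng.integers(spec.num_chains_range[0],
                                spec.num_chains_range[1] + 1))
    chains = []
    placed_ca = None
    for m in range(n_chains):
        length = int(rng.integers(spec.chain_length_range[0],
                                  spec.chain_length_range[1] + 1))
        bb = gen_backbone(length, spec.secondary_mix, rng)
        if placed_ca is not None:
            bb = place_chain_near(placed_ca, bb, rng)
        seq = sequence_from_backbone(bb, spec.coupling_mode, rng)
        chains.append(Chain(chain_id=chr(ord("A") + m), sequence=seq,
                            backbone=bb))
        placed_ca = np.concatenate(
            [c.ca for c in chains], axis=0
        )
    structure = ProteinStructure(chains=chains, source_id=f"synth-{rng.integers(1 << 30)}")
    if spec.noise_floor > 0:
        structure = add_structure_noise(
            structure, spec.noise_floor, seed=int(rng.integers(2**31))
        )
        # noise changes coordinates but the sequence stays coupled to the
        # noise-free targets; re-derive so coupling reflects realized geometry
        structure = ProteinStructure(
            chains=[
                Chain(chain_id=c.chain_id,
                      sequence=sequence_from_backbone(
                          c.backbone, spec.coupling_mode, rng),
                      backbone=c.backbone)
                for c in structure.chains
            ],
            source_id=structure.source_id,
        )
    sequences = [(c.chain_id, c.sequence) for c in structure.chains]
    return structure, sequences


def gen_corpus(spec: GeneratorSpec) -> list[ProteinStructure]:
    """A reproducible corpus of paired examples."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.num_proteins):
        s, _ = gen_paired_example(spec, rng)
        s.source_id = f"synth-{spec.coupling_mode}-{i:04d}"
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# docking decoys
# ---------------------------------------------------------------------------

def _interchain_contacts(structure: ProteinStructure, cutoff: float = 8.0):
    a, b = structure.chains[0].ca, structure.chains[1].ca
    d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
    return set(zip(*np.where(d < cutoff)))


def gen_docking_decoys(native: ProteinStructure, spec: DecoySpec,
                       seed: int = 0) -> list[DecoyRecord]:
    """Graded docking-pose decoys of a two-chain native complex.

    Tier 0 is the native itself; higher tiers rigidly displace (and rotate)
    chain 2 with added internal noise.  Each decoy carries a proxy quality:
    the fraction of native inter-chain Cα contacts (8 Å) it retains —
    a monotone stand-in for DockQ.
    """
    if len(native.chains) != 2:
        raise ValueError("decoy generation requires exactly 2 chains")
    rng = np.random.default_rng(seed)
    native_contacts = _interchain_contacts(native)
    records = [DecoyRecord(structure=native, tier=0, quality=1.0)]
    fixed = native.chains[0]
    for tier, (disp, noise) in enumerate(spec.ladder, start=1):
        for _ in range(spec.decoys_per_tier):
            for _attempt in range(20):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                mobile_bb = native.chains[1].backbone.copy()
                center = mobile_bb[:, 1].mean(axis=0)
                angle = np.radians(min(90.0, 4.0 * disp)) * rng.random()
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
                mobile_bb = (mobile_bb - center) @ R.T + center
                mobile_bb = mobile_bb + direction * disp
                if noise > 0:
                    mobile_bb = mobile_bb + rng.normal(
                        0.0, noise / np.sqrt(3.0), size=mobile_bb.shape)
                dmin = np.min(np.linalg.norm(
                    fixed.ca[:, None] - mobile_bb[None, :, 1], axis=2))
                if dmin >= 2.5:
                    break
            decoy = ProteinStructure(
                chains=[
                    fixed,
                    Chain(chain_id=native.chains[1].chain_id,
                          sequence=native.chains[1].sequence,
                          backbone=mobile_bb),
                ],
                source_id=f"{native.source_id}-t{tier}",
            )
            found = _interchain_contacts(decoy)
            quality = (len(native_contacts & found) / len(native_contacts)
                       if native_contacts else 0.0)
            records.append(DecoyRecord(structure=decoy, tier=tier,
                                       quality=quality))
    return records


# ---------------------------------------------------------------------------
# binder libraries
# ---------------------------------------------------------------------------

def gen_binder_library(target: ProteinStructure, num_scaffolds: int = 4,
                       binders_per_scaffold: int = 20,
                       planted_rate: float = 0.1, seed: int = 0,
                       clusters_per_scaffold: int = 2,
                       intra_cluster_noise: float = 0.15,
                       conformation_noise: float = 2.5,
                       binder_length: int = 30,
                       score_effect: float = 2.0) -> list[BinderRecord]:
    """Binder library with planted scaffold/cluster structure and labels.

    Each scaffold gets `clusters_per_scaffold` distinct conformations
    (mutual TM < 0.8 at the default noise); members of a conformation are
    small perturbations of it (mutual TM > 0.8).  Half of the clusters are
    designated "good" (1.8× the planted rate), the rest "poor" (0.2×), so
    the marginal success rate stays `planted_rate`.  Each record carries a
    screening-score stand-in correlated with its label (label effect
    `score_effect` over unit noise).
    """
    if not 0.0 < planted_rate < 1.0:
        raise ValueError("planted_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    target_ca = target.all_ca()
    records = []
    for s in range(num_scaffolds):
        scaffold_bb = gen_backbone(binder_length, (0.7, 0.1, 0.2), rng)
        site_anchor = target_ca[rng.integers(len(target_ca))]
        for c in range(clusters_per_scaffold):
            conf_bb = scaffold_bb + rng.normal(
                0.0, conformation_noise / np.sqrt(3.0), size=scaffold_bb.shape)
            good = (s * clusters_per_scaffold + c) % 2 == 0
            rate = planted_rate * (1.8 if good else 0.2)
            placed = place_chain_near(target_ca, conf_bb, rng,
                                      site_point=site_anchor)
            for m in range(binders_per_scaffold // clusters_per_scaffold):
                bb = placed + rng.normal(
                    0.0, intra_cluster_noise / np.sqrt(3.0), size=placed.shape)
                label = "binder" if rng.random() < rate else "nonbinder"
                score = rng.normal() + (score_effect if label == "binder" else 0.0)
                records.append(BinderRecord(
                    binder_id=f"s{s}c{c}m{m}",
                    scaffold_id=f"scaffold{s}",
                    ca=bb[:, 1].copy(),
                    sequence=sequence_from_backbone(bb, "identity", rng),
                    label=label,
                    score=float(score),
                    planted_cluster=f"s{s}c{c}",
                ))
    return records
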