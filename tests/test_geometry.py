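"""Coordinate math: oracles and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rlalign import geometry, synthdata
from rlalign.geometry import (
    BindingSite,
    DihedralUndefinedError,
    InterfaceError,
    add_structure_noise,
    average_binding_site_overlap,
    backbone_dihedrals,
    binding_site,
    binding_site_overlap,
    dihedral,
    interface_residues,
    kabsch_superpose,
    knn_graph,
    tm_d0,
    tm_score,
    tm_score_from_distances,
)
from rlalign.structio import Chain, ProteinStructure

from conftest import random_structure


def rigid_copy(structure, seed=0):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    chains = [
        Chain(c.chain_id, c.sequence, c.backbone @ R.T + t)
        for c in structure.chains
    ]
    return ProteinStructure(chains=chains, source_id=structure.source_id)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def test_dihedral_planar_cases():
    assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)
    assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)


def test_dihedral_matches_independent_construction(rng):
    """Signed angle between plane normals, sign from the triple product."""
    for _ in range(20):
        p = rng.normal(size=(4, 3)) * 3.0
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-6:
            continue
        cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        if np.dot(np.cross(n1, n2), b2) > 0:
            ang = -ang
        got = dihedral(*p)
        assert got == pytest.approx(ang if ang != -180.0 else 180.0, abs=1e-8)


def test_dihedral_collinear_errors():
    with pytest.raises(DihedralUndefinedError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_backbone_dihedrals_single_residue():
    bb = synthdata.gen_backbone(2, pure="helix")[:1]
    assert np.isnan(backbone_dihedrals(Chain("A", "A", bb))).all()


def test_backbone_dihedrals_helix(helix_chain):
    ang = backbone_dihedrals(helix_chain)
    interior = ang[1:-1]
    assert np.abs(interior[:, 0] + 57.0).max() < 1.0
    assert np.abs(interior[:, 1] + 47.0).max() < 1.0


def test_backbone_dihedrals_rotation_invariant(small_structure):
    a = backbone_dihedrals(small_structure.chains[0])
    b = backbone_dihedrals(rigid_copy(small_structure, 3).chains[0])
    assert np.nanmax(np.abs(a - b)) < 1e-9


# ---------------------------------------------------------------------------
# k-NN graph
# ---------------------------------------------------------------------------

def test_knn_out_degree_small_structure():
    bb = synthdata.gen_backbone(3, pure="helix")
    s = ProteinStructure([Chain("A", "ACD", bb)])
    g = knn_graph(s, k=30)
    out_deg = np.bincount(g.edge_index[:, 0], minlength=3)
    assert (out_deg == 2).all()
    assert (g.edge_index[:, 0] != g.edge_index[:, 1]).all()


@pytest.mark.parametrize("seed", range(20))
def test_knn_matches_brute_force(seed):
    s = random_structure(seed, length_range=(8, 12))
    k = 4
    g = knn_graph(s, k=k)
    ca = s.all_ca()
    T = len(ca)
    for i in range(T):
        d = np.linalg.norm(ca - ca[i], axis=1)
        d[i] = np.inf
        expected = set(np.argsort(d, kind="stable")[:k])
        got = set(g.edge_index[g.edge_index[:, 0] == i, 1])
        assert got == expected


def test_knn_rigid_invariance(small_structure):
    g1 = knn_graph(small_structure, k=8)
    translated = ProteinStructure(
        chains=[Chain(c.chain_id, c.sequence, c.backbone + np.array([5.0, 5.0, 5.0]))
                for c in small_structure.chains]
    )
    g2 = knn_graph(translated, k=8)
    assert (g1.edge_index == g2.edge_index).all()
    assert np.abs(g1.edge_features - g2.edge_features).max() < 1e-9
    g3 = knn_graph(rigid_copy(small_structure, 7), k=8)
    assert (g1.edge_index == g3.edge_index).all()
    assert np.abs(g1.edge_features - g3.edge_features).max() < 1e-6
    assert np.abs(g1.node_features - g3.node_features).max() < 1e-6


# ---------------------------------------------------------------------------
# interfaces and binding sites
# ---------------------------------------------------------------------------

def test_interface_all_residues_when_small(two_chain_structure):
    s = two_chain_structure
    iface = interface_residues(s, k=s.total_residues + 1)
    assert iface.total() == s.total_residues


@pytest.mark.parametrize("seed", range(10))
def test_interface_matches_brute_force(seed):
    s = random_structure(seed, length_range=(10, 20), chains=2)
    k = 30
    iface = interface_residues(s, k=k)
    ca = s.all_ca()
    cidx = s.chain_index()
    keys = s.residue_keys
    expected = {c.chain_id: set() for c in s.chains}
    for i in range(len(ca)):
        d = np.linalg.norm(ca - ca[i], axis=1)
        d[i] = np.inf
        nbrs = np.argsort(d, kind="stable")[: min(k, len(ca) - 1)]
        if (cidx[nbrs] != cidx[i]).any():
            expected[keys[i][0]].add(keys[i][1])
    assert {c: set(v) for c, v in iface.by_chain.items()} == expected


def test_interface_symmetry_on_generator(two_chain_structure):
    iface = interface_residues(two_chain_structure)
    sizes = [len(v) for v in iface.by_chain.values()]
    assert all(s > 0 for s in sizes) or all(s == 0 for s in sizes)


def test_interface_single_chain_errors(small_structure):
    with pytest.raises(InterfaceError, match="all-residue"):
        interface_residues(small_structure)


def test_binding_site_trivial_cases(rng):
    target = rng.normal(size=(10, 3))
    far = target + 100.0
    assert binding_site(target, far).residue_keys == frozenset()
    coincident = target[5:6].copy()
    assert 5 in binding_site(target, coincident).residue_keys


@pytest.mark.parametrize("seed", range(20))
def test_binding_site_matches_double_loop(seed):
    rng = np.random.default_rng(seed)
    target = rng.uniform(0, 25, size=(20, 3))
    binder = rng.uniform(0, 25, size=(8, 3))
    site = binding_site(target, binder)
    expected = {
        i for i in range(20)
        if any(np.linalg.norm(target[i] - b) < 8.0 for b in binder)
    }
    assert set(site.residue_keys) == expected


def test_binding_site_overlap_values():
    mk = lambda keys: BindingSite("t", frozenset(keys))
    assert binding_site_overlap(mk({1, 2}), mk({1, 2})) == 1.0
    assert binding_site_overlap(mk({1}), mk({2})) == 0.0
    assert binding_site_overlap(mk({1, 2, 3}), mk({2, 3, 4})) == 0.5
    with pytest.warns(UserWarning):
        assert binding_site_overlap(mk(set()), mk(set())) == 0.0
    with pytest.raises(ValueError, match="different targets"):
        binding_site_overlap(mk({1}), BindingSite("other", frozenset({1})))


def test_average_binding_site_overlap(rng):
    mk = lambda keys: BindingSite("t", frozenset(keys))
    sites = [mk({1, 2}), mk({1, 2}), mk({3})]
    # pairwise overlaps: 1.0, 0.0, 0.0
    assert average_binding_site_overlap(sites) == pytest.approx(1.0 / 3)
    assert average_binding_site_overlap([mk({1}), mk({1})]) == 1.0
    random_sites = [mk(set(rng.integers(0, 10, size=4).tolist())) for _ in range(5)]
    brute = np.mean([
        binding_site_overlap(random_sites[i], random_sites[j])
        for i in range(5) for j in range(i + 1, 5)
    ])
    assert average_binding_site_overlap(random_sites) == pytest.approx(brute)
    with pytest.raises(ValueError):
        average_binding_site_overlap(sites[:1])


# ---------------------------------------------------------------------------
# superposition and TM-score
# ---------------------------------------------------------------------------

def test_kabsch_identity_and_recovery(rng):
    pts = rng.normal(size=(10, 3)) * 5.0
    _, _, rmsd = kabsch_superpose(pts, pts)
    assert rmsd < 1e-12
    R_true = Rotation.random(random_state=1).as_matrix()
    t_true = np.array([3.0, -2.0, 7.0])
    moved = pts @ R_true.T + t_true
    R, t, rmsd = kabsch_superpose(pts, moved)
    assert rmsd < 1e-9
    assert np.abs(R - R_true).max() < 1e-8
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_kabsch_beats_random_placements(rng):
    pts = rng.normal(size=(12, 3)) * 4.0
    target = pts + rng.normal(scale=0.8, size=pts.shape)
    _, _, best = kabsch_superpose(pts, target)
    for i in range(100):
        R = Rotation.random(random_state=i).as_matrix()
        t = rng.normal(scale=3.0, size=3)
        rmsd = np.sqrt(((pts @ R.T + t - target) ** 2).sum(axis=1).mean())
        assert best <= rmsd + 1e-12


def test_kabsch_degenerate_errors(rng):
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
    other = np.random.default_rng(0).normal(size=(5, 3))
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, other)


@pytest.mark.parametrize("seed", range(10))
def test_tm_score_self_identity(seed):
    ca = random_structure(seed, length_range=(16, 30)).all_ca()
    assert tm_score(ca, ca) == pytest.approx(1.0)


def test_tm_score_uniform_displacement_half():
    """If every aligned distance equals d0, each term is 1/2."""
    L = 40
    d0 = tm_d0(L)
    d = np.full(L, d0)
    assert tm_score_from_distances(d, L) == pytest.approx(0.5)


def test_tm_score_symmetric_and_beats_global_fit(rng):
    for seed in range(5):
        a = random_structure(seed, length_range=(20, 25)).all_ca()
        b = a + np.random.default_rng(seed).normal(scale=2.0, size=a.shape)
        s_ab, s_ba = tm_score(a, b), tm_score(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-6)
        _, _, _ = kabsch_superpose(a, b)
        R, t, _ = kabsch_superpose(a, b)
        d = np.linalg.norm(a @ R.T + t - b, axis=1)
        assert s_ab >= tm_score_from_distances(d, len(a)) - 1e-12


def test_tm_score_unequal_lengths_error(rng):
    with pytest.raises(ValueError):
        tm_score(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


# ---------------------------------------------------------------------------
# structural noise
# ---------------------------------------------------------------------------

def test_noise_zero_identity(small_structure):
    noisy = add_structure_noise(small_structure, 0.0, seed=1)
    assert np.array_equal(noisy.all_backbone(), small_structure.all_backbone())


def test_noise_rms_calibration():
    s = random_structure(0, length_range=(250, 250))
    noisy = add_structure_noise(s, 1.0, seed=2)
    disp = noisy.all_backbone() - s.all_backbone()
    rms = np.sqrt((disp**2).sum(axis=-1).mean())
    assert 0.95 < rms < 1.05


def test_noise_deterministic(small_structure):
    a = add_structure_noise(small_structure, 0.5, seed=9)
    b = add_structure_noise(small_structure, 0.5, seed=9)
    assert np.array_equal(a.all_backbone(), b.all_backbone())
    with pytest.raises(ValueError):
        add_structure_noise(small_structure, -0.1, seed=0)
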