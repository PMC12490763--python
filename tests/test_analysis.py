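"""Screening analytics: contacts, APC, probes, ranking, clustering, filters."""

import numpy as np
import pandas as pd
import pytest

from rlalign import analysis, synthdata
from rlalign.analysis import (
    BinderCluster,
    BinderRecord,
    ContactSpec,
    apc,
    blosum62_score,
    confusion_metrics,
    contact_map,
    greedy_cluster,
    joint_filter,
    label_clusters,
    rank_decoys,
    success_rate,
    train_contact_probe,
)
from rlalign.structio import Chain, ProteinStructure, ScoreTable

from conftest import random_structure


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def test_contact_range_boundaries():
    spec = ContactSpec()
    assert spec.range_of(12) == "short"
    assert spec.range_of(7) == "short"
    assert spec.range_of(6) is None
    assert spec.range_of(13) == "medium"
    assert spec.range_of(24) == "medium"
    assert spec.range_of(25) == "long"


def test_extended_chain_has_no_remote_contacts():
    bb = synthdata.gen_backbone(30, pure="strand")
    s = ProteinStructure([Chain("A", "A" * 30, bb)])
    contacts, ranges = contact_map(s)
    T = 30
    sep = np.abs(np.arange(T)[:, None] - np.arange(T)[None, :])
    assert not contacts[sep >= 3].any()
    assert (ranges[sep == 12] == "short").all()


@pytest.mark.parametrize("seed", range(5))
def test_contact_map_matches_brute_force(seed):
    s = random_structure(seed, length_range=(15, 25))
    contacts, _ = contact_map(s)
    ca = s.chains[0].ca
    for i in range(len(ca)):
        for j in range(len(ca)):
            expected = i != j and np.linalg.norm(ca[i] - ca[j]) < 8.0
            assert contacts[i, j] == expected


def test_contact_map_rejects_complexes(two_chain_structure):
    with pytest.raises(ValueError):
        contact_map(two_chain_structure)


# ---------------------------------------------------------------------------
# APC
# ---------------------------------------------------------------------------

def test_apc_constant_and_rank_one_vanish(rng):
    assert np.abs(apc(np.full((5, 5), 3.0))).max() < 1e-12
    a = rng.uniform(0.1, 1.0, size=6)
    outer = np.outer(a, a)  # symmetric rank-1
    assert np.abs(apc(outer)).max() < 1e-10


@pytest.mark.parametrize("seed", range(20))
def test_apc_matches_elementwise_oracle(seed):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 1.0, size=(4, 4))
    got = apc(f)
    sym = 0.5 * (f + f.T)
    total = sym.sum()
    for i in range(4):
        for j in range(4):
            expected = sym[i, j] - sym[i].sum() * sym[:, j].sum() / total
            assert got[i, j] == pytest.approx(expected, abs=1e-6)


def test_apc_preserves_symmetry_and_errors_on_zero(rng):
    f = rng.uniform(0, 1, size=(5, 5))
    out = apc(f)
    assert np.abs(out - out.T).max() < 1e-12
    with pytest.raises(ValueError):
        apc(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# contact probe
# ---------------------------------------------------------------------------

def test_probe_separable_features(rng):
    n = 400
    y = rng.random(n) < 0.5
    X = np.where(y[:, None], 1.0, -1.0) + rng.normal(0, 0.05, size=(n, 3))
    ranges = np.where(rng.random(n) < 0.5, "short", "long")
    report = train_contact_probe(X, y, ranges, seed=1)
    assert report.metrics["all"]["accuracy"] == 1.0


def test_probe_random_labels_near_chance(rng):
    n = 2000
    y = rng.random(n) < 0.5
    X = rng.normal(size=(n, 4))
    ranges = np.full(n, "long")
    report = train_contact_probe(X, y, ranges, seed=2)
    assert abs(report.metrics["all"]["accuracy"] - 0.5) < 0.08


def test_probe_single_class_errors(rng):
    with pytest.raises(ValueError):
        train_contact_probe(rng.normal(size=(10, 2)), np.ones(10, dtype=bool),
                            np.full(10, "long"))


def test_confusion_metric_definitions():
    m = confusion_metrics(tp=3, fn=1, tn=4, fp=2)
    assert m["tpr"] == pytest.approx(0.75)
    assert m["tnr"] == pytest.approx(2 / 3, abs=1e-3)
    assert m["accuracy"] == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# decoy ranking
# ---------------------------------------------------------------------------

def mk_table(rows):
    return ScoreTable(frame=pd.DataFrame(rows))


def test_rank_perfect_ordering():
    rows = [{"complex_id": "t", "candidate_id": f"d{i}",
             "rla": i / 10, "dockq": 0.1 if i < 5 else 0.5}
            for i in range(10)]
    report = rank_decoys(mk_table(rows))
    assert report.mean_auroc == 1.0


def test_rank_all_tied_scores():
    rows = [{"complex_id": "t", "candidate_id": f"d{i}",
             "rla": 0.3, "dockq": 0.1 if i % 2 else 0.5} for i in range(8)]
    assert rank_decoys(mk_table(rows)).mean_auroc == pytest.approx(0.5)


def brute_force_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_rank_hand_example_matches_pair_counting():
    scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.1]
    dockq = [0.5, 0.1, 0.5, 0.5, 0.1, 0.1]
    rows = [{"complex_id": "t", "candidate_id": f"d{i}", "rla": s, "dockq": d}
            for i, (s, d) in enumerate(zip(scores, dockq))]
    expected = brute_force_auroc(scores, [d >= 0.23 for d in dockq])
    assert rank_decoys(mk_table(rows)).mean_auroc == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(20))
def test_rank_matches_brute_force_random(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 50))
    scores = rng.normal(size=n).round(1)  # rounding forces some ties
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    rows = [{"complex_id": "t", "candidate_id": f"d{i}", "rla": s,
             "dockq": 0.5 if l else 0.1}
            for i, (s, l) in enumerate(zip(scores, labels))]
    report = rank_decoys(mk_table(rows))
    assert report.mean_auroc == pytest.approx(
        brute_force_auroc(scores, labels), abs=1e-6)


def test_rank_missing_labels_dropped_and_sem():
    rows = [{"complex_id": c, "candidate_id": f"d{i}",
             "rla": i + (0 if c == "a" else 3),
             "dockq": 0.5 if i % 2 else 0.1}
            for c in ("a", "b") for i in range(6)]
    rows.append({"complex_id": "a", "candidate_id": "dx", "rla": 0.2,
                 "dockq": None})
    report = rank_decoys(mk_table(rows))
    assert report.n_dropped == 1
    assert len(report.per_target) == 2
    assert report.sem_auroc >= 0.0


# ---------------------------------------------------------------------------
# mutation grouping
# ---------------------------------------------------------------------------

def test_blosum_sign_examples():
    assert blosum62_score("W", "P") < 0
    assert blosum62_score("A", "S") > 0
    assert blosum62_score("A", "A") > 0


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def fake_records(n, scaffold="s0"):
    return [
        BinderRecord(binder_id=f"b{i}", scaffold_id=scaffold,
                     ca=np.zeros((5, 3)), sequence="AAAAA")
        for i in range(n)
    ]


def tm_from_matrix(mat, records):
    index = {id(r.ca): i for i, r in enumerate(records)}

    def tm(a, b):
        return mat[index[id(a)], index[id(b)]]

    return tm


def test_cluster_all_similar_single_cluster():
    recs = fake_records(4)
    clusters = greedy_cluster(recs, tm_func=lambda a, b: 1.0)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == [f"b{i}" for i in range(4)]


def test_cluster_all_dissimilar_singletons():
    recs = fake_records(4)
    clusters = greedy_cluster(recs, tm_func=lambda a, b: 0.0)
    assert len(clusters) == 4
    assert all(len(c.member_ids) == 1 for c in clusters)


def test_cluster_hand_traced_two_groups():
    """Two tight groups {0,1,2} and {3,4}: TM 0.9 inside, 0.1 across.

    Hand trace: binder 0 seeds {0,1,2}; binder 3 is unclustered, binder 4
    shares computed references (T(3,0)=T(4,0)=0.1 differ by 0 < 0.25) so
    T(3,4)=0.9 is computed and {3,4} forms.
    """
    mat = np.array([
        [1.0, 0.9, 0.9, 0.1, 0.1],
        [0.9, 1.0, 0.9, 0.1, 0.1],
        [0.9, 0.9, 1.0, 0.1, 0.1],
        [0.1, 0.1, 0.1, 1.0, 0.9],
        [0.1, 0.1, 0.1, 0.9, 1.0],
    ])
    recs = fake_records(5)
    clusters = greedy_cluster(recs, tm_func=tm_from_matrix(mat, recs))
    groups = sorted(sorted(c.member_ids) for c in clusters)
    assert groups == [["b0", "b1", "b2"], ["b3", "b4"]]


def test_cluster_skip_rule_blocks_tm_computation():
    """If references separate i and j by ≥ 0.25, T(i,j) is never computed."""
    mat = np.array([
        [1.0, 0.9, 0.1, 0.5],
        [0.9, 1.0, 0.1, 0.5],
        [0.1, 0.1, 1.0, 0.85],
        [0.5, 0.5, 0.85, 1.0],
    ])
    calls = []
    recs = fake_records(4)
    base = tm_from_matrix(mat, recs)

    def spy(a, b):
        calls.append((id(a), id(b)))
        return base(a, b)

    clusters = greedy_cluster(recs, tm_func=spy)
    # binder 2: |T(2,0) - T(3,0)| = 0.4 >= 0.25, so T(2,3) is skipped and
    # binder 3 later seeds its own singleton
    groups = sorted(sorted(c.member_ids) for c in clusters)
    assert groups == [["b0", "b1"], ["b2"], ["b3"]]
    index = {id(r.ca): i for i, r in enumerate(recs)}
    assert (2, 3) not in {tuple(sorted((index[a], index[b]))) for a, b in calls}


def test_cluster_partitions_and_respects_scaffolds(rng):
    recs = fake_records(6, "s0") + fake_records(5, "s1")
    for i, r in enumerate(recs[6:]):
        r.binder_id = f"c{i}"
    clusters = greedy_cluster(
        recs, tm_func=lambda a, b: float(rng.random()))
    seen = [m for c in clusters for m in c.member_ids]
    assert sorted(seen) == sorted(r.binder_id for r in recs)
    for c in clusters:
        assert len({next(r.scaffold_id for r in recs if r.binder_id == m)
                    for m in c.member_ids}) == 1


def test_cluster_mixed_lengths_error():
    recs = fake_records(2)
    recs[1].ca = np.zeros((6, 3))
    with pytest.raises(ValueError, match="lengths"):
        greedy_cluster(recs)


def test_label_clusters_rules():
    recs = []
    for i in range(10):
        recs.append(BinderRecord(
            binder_id=f"b{i}", scaffold_id="s0", ca=np.zeros((3, 3)),
            sequence="AAA", label="binder" if i < 1 else "nonbinder",
            score=0.2 if i % 2 else 0.4))
    # scaffold rate 0.1; cluster {b0, b1} has rate 0.5 -> binder
    clusters = [
        BinderCluster("c0", "s0", ["b0", "b1"]),
        BinderCluster("c1", "s0", [f"b{i}" for i in range(2, 10)]),
    ]
    labeled = label_clusters(clusters, recs)
    assert labeled[0].label == "binder"
    assert labeled[1].label == "nonbinder"  # 0.0 < 0.1
    assert labeled[0].mean_score == pytest.approx((0.4 + 0.2) / 2)
    # equality is nonbinder under the strict rule
    even = [BinderCluster("c0", "s0", [f"b{i}" for i in range(10)])]
    assert label_clusters(even, recs)[0].label == "nonbinder"
    assert label_clusters(even, recs)[0].mean_score == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# joint filter and success rates
# ---------------------------------------------------------------------------

def test_filter_keeps_exactly_top_quartile():
    df = pd.DataFrame({"candidate_id": [f"d{i}" for i in range(100)],
                       "rla": np.arange(100) / 100.0})
    res = joint_filter(df)
    assert res.counts["stage1"] == 25
    assert set(res.stage1_ids) == {f"d{i}" for i in range(75, 100)}
    assert res.stage2_ids == res.stage1_ids


def test_filter_tie_inclusive():
    df = pd.DataFrame({"candidate_id": [f"d{i}" for i in range(8)],
                       "rla": [1, 2, 3, 4, 5, 5, 5, 5]})
    res = joint_filter(df)
    assert res.counts["stage1"] == 4
    assert set(res.stage1_ids) == {"d4", "d5", "d6", "d7"}


def test_filter_monotone_in_score():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=40)
    df = pd.DataFrame({"candidate_id": [f"d{i}" for i in range(40)],
                       "rla": scores})
    survivors = set(joint_filter(df).stage1_ids)
    lifted = df.copy()
    target = next(iter(survivors))
    lifted.loc[lifted.candidate_id == target, "rla"] += 5.0
    assert target in set(joint_filter(lifted).stage1_ids)


def test_filter_second_stage_rule():
    df = pd.DataFrame({"candidate_id": [f"d{i}" for i in range(20)],
                       "rla": np.arange(20.0),
                       "af2": [1.0 if i % 2 else -1.0 for i in range(20)]})
    res = joint_filter(df, second_stage=lambda d: d["af2"].to_numpy() > 0)
    assert res.counts["stage1"] == 5
    assert all(int(c[1:]) % 2 for c in res.stage2_ids)


def test_filter_empty_errors():
    with pytest.raises(ValueError):
        joint_filter(pd.DataFrame({"candidate_id": [], "rla": []}))


@pytest.mark.parametrize("designs,successes,expected", [
    (59361, 592, 1.00),
    (14921, 22, 0.15),
    (58772, 244, 0.42),
    (99211, 283, 0.29),
    (99393, 18, 0.02),
    (9955, 65, 0.65),
    (100, 0, 0.00),
])
def test_success_rate_half_up(designs, successes, expected):
    assert success_rate(designs, successes) == expected


def test_success_rate_validation():
    with pytest.raises(ValueError):
        success_rate(0, 0)
    with pytest.raises(ValueError):
        success_rate(5, 6)
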