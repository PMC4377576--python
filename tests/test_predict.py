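"""Concordance scoring: closed forms, the worked toy, and brute-force oracles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet.core_io import CompoundRecord, ReferenceDrug
from herbnet.predict import (
    KernelSpec,
    chem_similarity_vector,
    concordance_score,
    functional_similarity_vector,
    herb_profile,
    overlap_with_drug_targets,
    common_targets,
    profile_overlap_matrix,
    proximity,
    rank_targets,
    score_matrix,
    tanimoto,
    HerbProfile,
)
from herbnet.synth import PRESETS, generate_bundle

from conftest import make_network
from oracles import brute_rank_targets


# ---------------------------------------------------------------------------
# tanimoto
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2, 3}, {2, 3, 4}, 0.5),
        ({1, 2}, {3, 4}, 0.0),
        (set(), set(), 0.0),
    ],
)
def test_tanimoto_examples(a, b, expected):
    assert tanimoto(a, b) == expected


@settings(derandomize=True, max_examples=50)
@given(
    a=st.frozensets(st.integers(0, 31), max_size=16),
    b=st.frozensets(st.integers(0, 31), max_size=16),
)
def test_tanimoto_symmetric_and_bounded(a, b):
    s = tanimoto(a, b)
    assert 0.0 <= s <= 1.0
    assert s == tanimoto(b, a)


# ---------------------------------------------------------------------------
# similarity vectors and proximity
# ---------------------------------------------------------------------------


def test_chem_vector_alignment_and_permutation(path4):
    _, panel, query = path4
    vec = chem_similarity_vector(query, panel)
    assert vec.panel_order == ("D1", "D2")
    assert vec.values.tolist() == [1.0, 0.0]
    rev = chem_similarity_vector(query, panel[::-1])
    assert rev.values.tolist() == [0.0, 1.0]
    with pytest.raises(ValueError):
        chem_similarity_vector(query, [])


def test_proximity_closed_forms(path4):
    net, panel, _ = path4
    d1 = panel[0]  # sole target A
    assert proximity("A", d1, net) == pytest.approx(1.0)
    assert proximity("B", d1, net) == pytest.approx(math.exp(-1))
    assert proximity("C", d1, net) == pytest.approx(math.exp(-4))
    with pytest.raises(KeyError):
        proximity("ZZ", d1, net)


def test_proximity_unreachable_target_contributes_zero():
    net = make_network([("a", "b")], nodes=["c"])
    drug = ReferenceDrug("D", frozenset({0}), 8, frozenset({"C"}))
    assert proximity("a", drug, net) == 0.0


def test_functional_vector_matches_proximity(path4):
    net, panel, _ = path4
    vec = functional_similarity_vector("B", panel, net)
    assert vec.values == pytest.approx([math.exp(-1), math.exp(-4)])
    assert (vec.values >= 0).all()


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 1, 1], [1, 2, 3], None),
    ],
)
def test_concordance_examples(x, y, expected):
    score = concordance_score(np.array(x, float), np.array(y, float))
    if expected is None:
        assert score is None
    else:
        assert score == pytest.approx(expected)


def test_concordance_rejects_short_vectors():
    with pytest.raises(ValueError):
        concordance_score(np.array([1.0]), np.array([2.0]))


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def test_rank_targets_worked_toy(path4):
    """Path A-B-C-D, panel {D1→A, D2→D}, query = D1's fingerprint.

    Proximity vectors are a=(1,e⁻⁹), b=(e⁻¹,e⁻⁴), c=(e⁻⁴,e⁻¹), d=(e⁻⁹,1);
    with chem vector (1,0) the two-point Pearson is the slope sign, so
    a=b=+1, c=d=−1, ranked A,B,C,D by the symbol tie-break.
    """
    net, panel, query = path4
    preds = rank_targets(query, panel, net)
    assert [p.protein for p in preds] == ["A", "B", "C", "D"]
    assert [p.rank for p in preds] == [1, 2, 3, 4]
    scores = {p.protein: p.score for p in preds}
    assert scores["A"] == pytest.approx(1.0) and scores["B"] == pytest.approx(1.0)
    assert scores["C"] == pytest.approx(-1.0) and scores["D"] == pytest.approx(-1.0)


def test_rank_targets_panel_order_invariant(path4):
    net, panel, query = path4
    fwd = {p.protein: p.score for p in rank_targets(query, panel, net)}
    rev = {p.protein: p.score for p in rank_targets(query, panel[::-1], net)}
    for prot in fwd:
        assert fwd[prot] == pytest.approx(rev[prot])


def test_rank_targets_undefined_scores_rank_last():
    # isolated node -> constant (all-zero) functional vector -> undefined
    net = make_network([("a", "b"), ("b", "c"), ("c", "d")], nodes=["z"])
    panel = [
        ReferenceDrug("D1", frozenset({0}), 8, frozenset({"A"})),
        ReferenceDrug("D2", frozenset({1}), 8, frozenset({"D"})),
    ]
    query = CompoundRecord("q", "h", frozenset({0}), 8)
    preds = rank_targets(query, panel, net)
    assert preds[-1].protein == "Z" and preds[-1].score is None
    assert all(p.score is not None for p in preds[:-1])


def test_rank_targets_matches_brute_force_oracle():
    """Full ranking equals an independent brute-force implementation on
    random networks of ≤8 nodes with panels of ≤3 drugs."""
    rng = np.random.default_rng(11)
    from conftest import random_network

    for _ in range(30):
        net = random_network(rng)
        nodes = sorted(net.nodes)
        n_drugs = int(rng.integers(2, 4))
        panel = []
        for j in range(n_drugs):
            fp = frozenset(int(b) for b in rng.choice(16, size=4, replace=False))
            tgts = frozenset(
                nodes[int(i)] for i in rng.choice(len(nodes), size=min(2, len(nodes)), replace=False)
            )
            panel.append(ReferenceDrug(f"D{j}", fp, 16, tgts))
        query = CompoundRecord(
            "q", "h", frozenset(int(b) for b in rng.choice(16, size=4, replace=False)), 16
        )
        preds = rank_targets(query, panel, net)
        edges = [tuple(sorted(e)) for e in net.edges]
        expected = brute_rank_targets(
            query.fingerprint,
            [(set(d.fingerprint), set(d.targets)) for d in panel],
            nodes,
            edges,
            lambda d: math.exp(-(d**2)),
        )
        assert [p.protein for p in preds] == [prot for prot, _ in expected]
        for p, (_, sc) in zip(preds, expected):
            if sc is None:
                assert p.score is None
            else:
                assert p.score == pytest.approx(sc, abs=1e-9)


def test_kernel_choice_preserves_toy_ranking(path4):
    """Any strictly decreasing kernel gives the same sign structure on the toy."""
    net, panel, query = path4
    for kind in ("gaussian-of-distance", "exponential-of-distance"):
        preds = rank_targets(query, panel, net, KernelSpec(kind=kind))
        assert [p.protein for p in preds] == ["A", "B", "C", "D"]


# ---------------------------------------------------------------------------
# herb profiles and overlaps
# ---------------------------------------------------------------------------


def test_herb_profile_max_aggregation_and_topk():
    nodes = ["P1", "P2", "P3"]
    c1 = CompoundRecord("c1", "h", frozenset({0}), 8)
    c2 = CompoundRecord("c2", "h", frozenset({1}), 8)
    scores = {"c1": np.array([0.2, 0.5, np.nan]), "c2": np.array([0.9, 0.1, np.nan])}
    prof = herb_profile("h", [c1, c2], nodes, scores, k=10)
    assert prof.entries == [("P1", 0.9), ("P2", 0.5)]  # max rule; all-NaN excluded
    prof1 = herb_profile("h", [c1, c2], nodes, scores, k=1)
    assert prof1.entries == [("P1", 0.9)]
    with pytest.raises(ValueError):
        herb_profile("missing", [c1], nodes, scores)


def test_profile_overlaps_and_common_targets():
    a = HerbProfile("A", [("G1", 1.0), ("G2", 0.5)])
    b = HerbProfile("B", [("G2", 0.9), ("G3", 0.4)])
    mat = profile_overlap_matrix([a, b])
    assert mat.loc["A", "B"] == 1 and mat.loc["B", "A"] == 1
    assert mat.loc["A", "A"] == 2
    assert common_targets([a, b]) == {"G2"}
    twin = HerbProfile("B", [("G1", 0.8), ("G2", 0.7)])  # same symbols as A
    ident = profile_overlap_matrix([a, twin])
    assert ident.loc["A", "B"] == 2  # identical profiles: off-diagonal = size


def test_overlap_percentage_matches_reported_rounding():
    """101 shared of 1746 putative is 5.78% at two decimals."""
    putative = {f"G{i}" for i in range(1746)}
    reference = {f"G{i}" for i in range(101)}
    rep = overlap_with_drug_targets(putative, reference)
    assert rep.n_overlap == 101 and rep.percentage == 5.78


def test_planted_targets_rank_above_median_without_noise():
    """With bit_flip_rate 0 a compound is its parent drug; the planted
    targets all land above the median rank."""
    cfg = dataclasses.replace(PRESETS["toy"], seed=7, bit_flip_rate=0.0)
    b = generate_bundle(cfg)
    nodes, scores = score_matrix(b.compounds, b.panel, b.network)
    by_id = {d.drug_id: d for d in b.panel}
    idx = {n: i for i, n in enumerate(nodes)}
    for comp in b.compounds[:6]:
        parent = by_id[b.truth.compound_parent[comp.compound_id]]
        vec = scores[comp.compound_id]
        key = np.where(np.isnan(vec), -np.inf, vec)
        ranks = np.empty(len(nodes))
        ranks[np.argsort(-key, kind="stable")] = np.arange(1, len(nodes) + 1)
        for t in parent.targets:
            assert ranks[idx[t]] <= len(nodes) / 2
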