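"""Placement: query threading, pruning likelihoods, edge search, bootstrap."""

import dendropy
import numpy as np
import pytest

from amfplace._seq import MISSING, encode
from amfplace.placement import (
    PENDANT_MAX,
    PENDANT_MIN,
    PlacementEngine,
    align_query,
    place_queries,
)
from amfplace.reference import ReferenceSet, delineate_family_clades
from amfplace.substmodel import SubstModel
from conftest import make_ref
from oracles import grafted_tree, grid_place, prune_loglik


# -- align_query -----------------------------------------------------------


def test_align_identical_to_reference_reproduces_row(small_sim):
    _, ref, _, _ = small_sim
    name = sorted(ref.alignment)[0]
    aq = align_query(ref, "copy", ref.alignment[name])
    assert aq.nearest_reference == name
    np.testing.assert_array_equal(aq.codes, encode(ref.alignment[name]))
    assert not aq.low_confidence


def test_align_truncated_query_leaves_leading_columns_missing(small_sim):
    _, ref, _, _ = small_sim
    name = sorted(ref.alignment)[0]
    aq = align_query(ref, "trunc", ref.alignment[name][10:])
    assert np.all(aq.codes[:10] == MISSING)
    np.testing.assert_array_equal(aq.codes[10:], encode(ref.alignment[name])[10:])


def test_align_threading_preserves_base_order(small_sim):
    _, ref, _, queries = small_sim
    for qid, seq in list(queries.items())[:4]:
        aq = align_query(ref, qid, seq)
        threaded = "".join("ACGT"[c] for c in aq.codes if c >= 0)
        # threaded bases appear in the query in the same order (subsequence)
        it = iter(seq)
        assert all(ch in it for ch in threaded)


def test_align_empty_query_rejected(small_sim):
    _, ref, _, _ = small_sim
    with pytest.raises(ValueError, match="empty"):
        align_query(ref, "bad", "----")


# -- likelihood ------------------------------------------------------------


def _two_leaf_ref(seq: str) -> ReferenceSet:
    return make_ref(
        "(x:0.0,y:0.0);",
        {"x": seq, "y": seq},
        {"x": "outgroup", "y": "outgroup"},
    )


def test_jc_pairwise_likelihood_closed_form():
    """Identical query attached at distance t to a single effective leaf:
    per-site lnL = ln(1/4) + ln(1/4 + 3/4 exp(-4t/3))."""
    seq = "ACGT" * 50
    ref = _two_leaf_ref(seq)
    eng = PlacementEngine(ref, SubstModel.jc69(rate_variation=False))
    aq = align_query(ref, "q", seq)
    L = len(seq)
    for t in (0.01, 0.2, 0.7):
        expected = L * (np.log(0.25) + np.log(0.25 + 0.75 * np.exp(-4 * t / 3)))
        assert eng.edge_loglik(aq, 0, t) == pytest.approx(expected, abs=1e-8)


def test_saturation_limit_reaches_stationary():
    seq = "ACGT" * 50
    ref = _two_leaf_ref(seq)
    eng = PlacementEngine(ref, SubstModel.jc69(rate_variation=False))
    aq = align_query(ref, "q", seq)
    ll = eng.edge_loglik(aq, 0, 50.0)
    # per-site likelihood factorizes: stationary 1/4 for the query
    expected = len(seq) * 2 * np.log(0.25)
    assert ll == pytest.approx(expected, abs=1e-6 * len(seq))


def test_engine_matches_independent_pruning_oracle(small_sim):
    _, ref, _, queries = small_sim
    model = SubstModel(
        pi=(0.3, 0.2, 0.3, 0.2),
        exchangeabilities=(1, 2, 1, 1, 2, 1),
        gamma_shape=0.7,
        n_categories=4,
    )
    eng = PlacementEngine(ref, model)
    qid, seq = next(iter(queries.items()))
    aq = align_query(ref, qid, seq)
    seqs = {n: encode(s) for n, s in ref.alignment.items()}
    seqs["QUERY"] = aq.codes
    for edge in (0, 5, ref.n_edges - 1):
        for pendant in (1e-6, 0.05, 0.4):
            mine = eng.edge_loglik(aq, edge, pendant)
            oracle = prune_loglik(grafted_tree(ref, edge, pendant), seqs, model)
            assert mine == pytest.approx(oracle, abs=1e-7)


def test_likelihood_invariant_to_edge_subdivision():
    """Attaching with pendant 0 at the midpoint of an edge equals the
    likelihood of the unmodified tree, wherever the edge is split."""
    seq1, seq2, seq3 = "ACGTACGTAC", "ACGAACGTAC", "TCGAACTTAC"
    ref = make_ref(
        "((x:0.1,y:0.1):0.05,z:0.2);",
        {"x": seq1, "y": seq2, "z": seq3},
        {"x": "F1", "y": "F1", "z": "outgroup"},
    )
    model = SubstModel.jc69(rate_variation=False)
    eng = PlacementEngine(ref, model)
    aq = align_query(ref, "q", seq1)
    # likelihood at pendant ~0 is the same on both halves of a split edge:
    # compare attaching at midpoints of the two edges created by splitting
    # edge 0 against attaching at the original midpoint
    base = eng.edge_loglik(aq, 0, PENDANT_MIN)
    # subdivide edge 0 with a zero-offset node marked by an all-missing leaf
    # (an all-gap row contributes nothing); the surviving 0.05 stretch keeps
    # its midpoint at the same absolute position on both variants
    variants = [
        "((w:0.0,(x:0.1,y:0.1):0.05):0.0,z:0.2);",  # split at the top
        "(((x:0.1,y:0.1):0.0,w:0.0):0.05,z:0.2);",  # split at the bottom
    ]
    for nwk in variants:
        eng2 = PlacementEngine(
            make_ref(
                nwk,
                {"x": seq1, "y": seq2, "z": seq3, "w": "-" * 10},
                {"x": "F1", "y": "F1", "z": "outgroup", "w": "outgroup"},
            ),
            model,
        )
        aq2 = align_query(eng2.ref, "q", seq1)
        target = None
        for e in range(eng2.ref.n_edges):
            child = eng2.ref.index.edge_child(e)
            leaves = {
                eng2.ref.index.leaf_name[n]
                for n in eng2.ref.index.leaves_under(child)
            }
            if leaves == {"x", "y"} and eng2.ref.index.branch_length[child] > 0:
                target = e
            if leaves == {"x", "y", "w"} and eng2.ref.index.branch_length[child] > 0:
                target = e
        val = eng2.edge_loglik(aq2, target, PENDANT_MIN)
        assert val == pytest.approx(base, abs=1e-6)


def test_unimodality_of_pendant_likelihood(small_engine, small_sim):
    _, ref, _, queries = small_sim
    qid, seq = next(iter(queries.items()))
    aq = align_query(ref, qid, seq)
    grid = np.geomspace(1e-6, 2.0, 60)
    for edge in (0, ref.n_edges // 2):
        vals = np.array([small_engine.edge_loglik(aq, edge, p) for p in grid])
        peak = int(np.argmax(vals))
        assert np.all(np.diff(vals[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(vals[peak:]) <= 1e-9)


# -- place -----------------------------------------------------------------


def test_identity_query_placed_on_its_pendant_edge(small_engine, small_sim):
    _, ref, _, _ = small_sim
    for name in list(ref.alignment)[:4]:
        aq = align_query(ref, "copy", ref.alignment[name])
        pl = small_engine.place(aq)
        assert pl.best_edge == ref.index.node_of_leaf[name] - 1
        assert pl.pendant_length <= 1e-3


def test_place_agrees_with_grid_oracle():
    """Best edge equals the exhaustive pendant-grid oracle on small random
    backbones (more fixtures run in the acceptance suite)."""
    from amfplace.simulate import SimConfig, simulate_backbone, simulate_queries

    agree = 0
    n = 8
    for seed in range(n):
        cfg = SimConfig(
            seed=seed, n_families=2, leaves_per_family=2, n_outgroups=2,
            seq_length=80, novel_clades=(), in_family_queries_per_family=1,
            n_non_amf_queries=0,
        )
        ref, truth = simulate_backbone(cfg)
        queries, truth = simulate_queries(ref, cfg, truth)
        qid, seq = next(iter(queries.items()))
        model = SubstModel.jc69(rate_variation=False)
        eng = PlacementEngine(ref, model)
        aq = align_query(ref, qid, seq)
        pl = eng.place(aq)
        _, _, oracle_ll = grid_place(ref, aq.codes, model)
        agree += oracle_ll[pl.best_edge] >= oracle_ll.max() - 1e-6
    assert agree == n


def test_tiebreak_prefers_smallest_edge_id():
    """A perfectly symmetric fixture: query equidistant from both cherries
    resolves deterministically to the smallest edge id."""
    seq = "ACGT" * 10
    ref = make_ref(
        "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);",
        {"a": seq, "b": seq, "c": seq, "d": seq},
        {"a": "F1", "b": "F1", "c": "F2", "d": "outgroup"},
    )
    eng = PlacementEngine(ref, SubstModel.jc69(rate_variation=False))
    aq = align_query(ref, "q", seq)
    pl = eng.place(aq, keep_edge_table=True)
    ll = pl.edge_log_likelihoods
    ties = np.flatnonzero(ll == ll.max())
    assert len(ties) > 1  # the fixture is genuinely symmetric
    assert pl.best_edge == ties[0]


def test_all_missing_query_is_unplaceable(small_engine, small_sim):
    _, ref, _, _ = small_sim
    from amfplace.placement import AlignedQuery

    aq = AlignedQuery(
        asv_id="void",
        codes=np.full(ref.length, MISSING, dtype=np.int8),
        nearest_reference="?",
        score=0.0,
    )
    with pytest.raises(ValueError, match="unplaceable"):
        small_engine.place(aq)


def test_placement_invariant_to_batch_order(small_engine, small_sim):
    _, ref, _, queries = small_sim
    fwd = place_queries(small_engine, queries)[1]
    rev = place_queries(small_engine, dict(reversed(list(queries.items()))))[1]
    for qid in queries:
        assert fwd[qid].best_edge == rev[qid].best_edge
        assert fwd[qid].pendant_length == rev[qid].pendant_length


def test_pendant_length_within_bounds(small_engine, small_sim):
    _, ref, _, queries = small_sim
    for qid, seq in queries.items():
        pl = small_engine.place(align_query(ref, qid, seq))
        assert PENDANT_MIN <= pl.pendant_length <= PENDANT_MAX


# -- bootstrap -------------------------------------------------------------


def test_bootstrap_support_bounds_and_b1(small_engine, small_sim):
    _, ref, _, queries = small_sim
    clades = delineate_family_clades(ref)
    qid, seq = next(iter(queries.items()))
    aq = align_query(ref, qid, seq)
    es, cs = small_engine.bootstrap_support(aq, clades, B=1, seed=0)
    assert es in (0.0, 1.0) and cs in (0.0, 1.0)
    es, cs = small_engine.bootstrap_support(aq, clades, B=10, seed=0)
    assert 0.0 <= es <= 1.0 and 0.0 <= cs <= 1.0
    with pytest.raises(ValueError):
        small_engine.bootstrap_support(aq, clades, B=0)


def test_bootstrap_high_category_support_without_conflict(small_engine, small_sim):
    """A query equal to a reference carries no conflicting signal, so its
    category support is high."""
    _, ref, _, _ = small_sim
    clades = delineate_family_clades(ref)
    name = [n for n, f in ref.labels.items() if f not in ("outgroup",)][0]
    aq = align_query(ref, "copy", ref.alignment[name])
    _, cs = small_engine.bootstrap_support(aq, clades, B=40, seed=1)
    assert cs >= 0.95
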