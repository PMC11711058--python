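"""Shared fixtures: small hand-built references and cached simulations."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from amfplace.placement import PlacementEngine
from amfplace.reference import ReferenceSet, delineate_family_clades
from amfplace.simulate import CommunityDesign, SimConfig, simulate_backbone, simulate_queries
from amfplace.substmodel import SubstModel


def make_ref(newick: str, alignment: dict[str, str], labels: dict[str, str]) -> ReferenceSet:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
    )
    return ReferenceSet(tree=tree, alignment=alignment, labels=labels)


@pytest.fixture(scope="session")
def four_leaf_ref() -> ReferenceSet:
    """((a,b),(c,d)) with two families of two leaves plus implicit rooting.

    a/b are family F1, c is F2, d is the outgroup.
    """
    return make_ref(
        "((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1);",
        {
            "a": "ACGTACGTACGTACGTACGT",
            "b": "ACGTACGTACGTACGTACGA",
            "c": "ACGTACGAACGTTCGTACGT",
            "d": "TCGTACGAACGTTCTTACGT",
        },
        {"a": "F1", "b": "F1", "c": "F2", "d": "outgroup"},
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated backbone (4 families x 3 leaves, short sequences)."""
    cfg = SimConfig(
        seed=11,
        n_families=4,
        leaves_per_family=3,
        n_outgroups=2,
        seq_length=300,
        novel_clades=(),
        in_family_queries_per_family=1,
        n_non_amf_queries=1,
        community=CommunityDesign(sites_per_cell=1, replicates_per_site=1),
    )
    ref, truth = simulate_backbone(cfg)
    queries, truth = simulate_queries(ref, cfg, truth)
    return cfg, ref, truth, queries


@pytest.fixture(scope="session")
def small_engine(small_sim):
    _, ref, _, _ = small_sim
    return PlacementEngine(ref)


@pytest.fixture(scope="session")
def default_study():
    """One full default-configuration study, shared across tests."""
    from amfplace.pipeline import run_study

    return run_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def jc_model() -> SubstModel:
    return SubstModel.jc69(rate_variation=False)
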