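"""End-to-end convenience driver for a synthetic study.

Simulates a backbone and queries, places them, classifies them by both
methods, detects novel clades and assembles the pieces most analyses start
from.  Thin orchestration only — every step is an ordinary public function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import Assignment, ConcordanceReport, classify_tree, concordance, tophit_assign
from .novel import NovelCladeReport, find_novel_clades, graft_all, zone_composition
from .placement import AlignedQuery, Placement, PlacementEngine, place_queries
from .reference import FamilyCladeMap, ReferenceSet, delineate_family_clades
from .simulate import (
    SimConfig,
    TruthSet,
    corrupt_labels,
    simulate_backbone,
    simulate_community,
    simulate_queries,
)
from ._seq import ungap


@dataclass
class StudyResult:
    config: SimConfig
    ref: ReferenceSet
    truth: TruthSet
    queries: dict[str, str]
    counts: pd.DataFrame
    meta: pd.DataFrame
    clades: FamilyCladeMap
    engine: PlacementEngine = field(repr=False, default=None)
    aligned: dict[str, AlignedQuery] = field(default_factory=dict, repr=False)
    placements: dict[str, Placement] = field(default_factory=dict)
    tree_assignments: dict[str, Assignment] = field(default_factory=dict)
    tophit_assignments: dict[str, Assignment] = field(default_factory=dict)
    corrupted_labels: dict[str, str] = field(default_factory=dict)
    concordance: ConcordanceReport | None = None
    novel_clades: list[NovelCladeReport] = field(default_factory=list)

    @property
    def tree_categories(self) -> dict[str, str]:
        return {a: v.category for a, v in self.tree_assignments.items()}


def run_study(
    cfg: SimConfig,
    run_tophit: bool = True,
    run_novel: bool = True,
    min_clade_size: int = 2,
) -> StudyResult:
    """Simulate one study and run the core pipeline on it."""
    ref, truth = simulate_backbone(cfg)
    queries, truth = simulate_queries(ref, cfg, truth)
    counts, meta = simulate_community(truth, cfg, queries)
    clades = delineate_family_clades(ref)
    engine = PlacementEngine(ref)
    aligned, placements = place_queries(engine, queries)
    tree_assignments = {
        qid: classify_tree(pl, clades) for qid, pl in placements.items()
    }
    result = StudyResult(
        config=cfg,
        ref=ref,
        truth=truth,
        queries=queries,
        counts=counts,
        meta=meta,
        clades=clades,
        engine=engine,
        aligned=aligned,
        placements=placements,
        tree_assignments=tree_assignments,
    )
    if run_tophit:
        corrupted, original = corrupt_labels(
            ref, cfg.unlabeled_fraction, cfg.mislabeled_fraction, cfg.seed
        )
        truth.original_labels = original
        db = {name: ungap(seq) for name, seq in ref.alignment.items()}
        result.corrupted_labels = corrupted
        result.tophit_assignments = {
            qid: tophit_assign(qid, seq, db, corrupted)
            for qid, seq in queries.items()
        }
        result.concordance = concordance(
            tree_assignments, result.tophit_assignments
        )
    if run_novel:
        unknown = {
            qid: placements[qid]
            for qid, a in tree_assignments.items()
            if a.category == "unknown_amf"
        }
        if unknown:
            ext = graft_all(ref, unknown)
            reports = find_novel_clades(ext, min_size=min_clade_size)
            result.novel_clades = [
                zone_composition(r, counts, meta) for r in reports
            ]
    return result
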