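"""Read preparation: pair merging, expected-error filtering, exact
dereplication into ASVs, and an alignment-free homology prescreen.

Exact dereplication stands in for denoising: the analysis unit is the exact
amplicon sequence variant, and simulated error rates keep inflation
controlled.  The k-mer containment prescreen plays the role of a fast
pre-search against the reference database, removing sequences with no
resemblance to any reference before the expensive placement stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import kmer_set, revcomp
from .reference import ReferenceSet


@dataclass
class MergeOutcome:
    read_id: str
    merged: str | None
    overlap: int
    mismatch_rate: float
    accepted: bool


@dataclass
class ASVTable:
    sequences: dict[str, str]  # asv id -> sequence
    counts: pd.DataFrame  # samples x asvs
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        seqs = list(self.sequences.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("ASV sequences must be unique")
        missing = set(self.counts.columns) - set(self.sequences)
        if missing:
            raise ValueError(f"count columns without sequences: {sorted(missing)}")


def _phred_error_probs(qual: str) -> np.ndarray:
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    if np.any(q < 0) or np.any(q > 93):
        raise ValueError("malformed quality string")
    return 10.0 ** (-q / 10.0)


def merge_pairs(
    r1: list[tuple[str, str, str]],
    r2: list[tuple[str, str, str]],
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> list[MergeOutcome]:
    """Merge mate pairs by their best ungapped overlap.

    R2 is reverse-complemented; overlaps of at least ``min_overlap`` bases
    are scanned and the one with the fewest mismatches (ties: longest) wins.
    The pair is merged when the winning overlap's mismatch rate is at most
    ``max_mismatch_rate`` (inclusive); overlap disagreements resolve to the
    base with the higher quality (ties to R1).
    """
    if len(r1) != len(r2):
        raise ValueError(f"mate count mismatch: {len(r1)} vs {len(r2)}")
    out = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
        s2rc = revcomp(s2)
        q2rc = q2[::-1]
        best = None  # (mismatches, -overlap, merged, rate)
        max_ov = min(len(s1), len(s2rc))
        for ov in range(min_overlap, max_ov + 1):
            a = s1[-ov:]
            b = s2rc[:ov]
            mm = sum(1 for x, y in zip(a, b) if x != y)
            key = (mm, -ov)
            if best is None or key < best[0]:
                best = (key, ov, mm)
        if best is None:
            out.append(MergeOutcome(id1, None, 0, 1.0, False))
            continue
        _, ov, mm = best
        rate = mm / ov
        if rate > max_mismatch_rate:
            out.append(MergeOutcome(id1, None, ov, rate, False))
            continue
        e1 = _phred_error_probs(q1)
        e2 = _phred_error_probs(q2rc)
        head = s1[:-ov]
        overlap_bases = []
        for i in range(ov):
            c1, c2 = s1[len(s1) - ov + i], s2rc[i]
            if c1 == c2:
                overlap_bases.append(c1)
            else:
                p1, p2 = e1[len(s1) - ov + i], e2[i]
                overlap_bases.append(c1 if p1 <= p2 else c2)
        tail = s2rc[ov:]
        merged = head + "".join(overlap_bases) + tail
        out.append(MergeOutcome(id1, merged, ov, rate, True))
    return out


def quality_filter(
    records: list[tuple[str, str, str]], max_expected_errors: float = 1.0
) -> tuple[list[tuple[str, str, str]], int]:
    """Keep reads whose summed per-base error probability (from Phred) is at
    most ``max_expected_errors``.  Returns (kept records, n rejected)."""
    kept, rejected = [], 0
    for rid, seq, qual in records:
        if len(qual) != len(seq):
            raise ValueError(f"malformed quality string for read {rid!r}")
        ee = float(_phred_error_probs(qual).sum())
        if ee <= max_expected_errors:
            kept.append((rid, seq, qual))
        else:
            rejected += 1
    return kept, rejected


def dereplicate(
    records: list[tuple[str, str]] | list[tuple[str, str, str]],
    sample_of_read: dict[str, str] | None = None,
) -> ASVTable:
    """Exact-sequence dereplication into an ASV table.

    ``records`` are (read id, sequence[, quality]); the sample of a read is
    ``sample_of_read[read_id]`` or, by default, the prefix of the read id up
    to the first ``|``.  ASV ids are ordered by descending total count, then
    lexicographic sequence.
    """
    per_sample: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for rec in records:
        rid, seq = rec[0], rec[1]
        sample = (
            sample_of_read[rid]
            if sample_of_read is not None
            else rid.split("|", 1)[0]
        )
        per_sample.setdefault(sample, {})
        per_sample[sample][seq] = per_sample[sample].get(seq, 0) + 1
        totals[seq] = totals.get(seq, 0) + 1
    ordered = sorted(totals, key=lambda s: (-totals[s], s))
    ids = {seq: f"ASV_{i + 1}" for i, seq in enumerate(ordered)}
    samples = sorted(per_sample)
    counts = pd.DataFrame(
        0, index=samples, columns=[ids[s] for s in ordered], dtype=int
    )
    for sample, seqs in per_sample.items():
        for seq, n in seqs.items():
            counts.loc[sample, ids[seq]] = n
    counts.index.name = "sample_id"
    return ASVTable(
        sequences={ids[s]: s for s in ordered},
        counts=counts,
        provenance={"reads_dereplicated": len(records)},
    )


def homology_prescreen(
    asvs: ASVTable,
    ref: ReferenceSet,
    k: int = 8,
    min_containment: float = 0.10,
) -> tuple[ASVTable, list[str]]:
    """Drop ASVs with no k-mer resemblance to any reference sequence.

    An ASV is retained iff max over references of (shared k-mers / ASV
    k-mers) >= ``min_containment``.  Returns (retained table, removed ids).
    """
    shortest = min(len(s) for s in asvs.sequences.values())
    if k > shortest:
        raise ValueError(f"k={k} longer than the shortest ASV ({shortest})")
    ref_kmers = [kmer_set(s, k) for s in ref.alignment.values()]
    keep, removed = [], []
    for asv_id, seq in asvs.sequences.items():
        qk = kmer_set(seq, k)
        best = max((len(qk & rk) / len(qk)) for rk in ref_kmers) if qk else 0.0
        (keep if best >= min_containment else removed).append(asv_id)
    table = ASVTable(
        sequences={a: asvs.sequences[a] for a in keep},
        counts=asvs.counts[keep].copy(),
        provenance={**asvs.provenance, "asvs_removed_by_prescreen": len(removed)},
    )
    return table, removed
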