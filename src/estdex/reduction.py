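"""Redundancy reduction and homology trimming of the EST set.

De novo 454 assemblies carry heavy redundancy: many contigs/singletons match
the same reference gene, often with variable 5'/3' ends that may be isoforms
or assembly artifacts. The reducer keeps exactly one "representative" EST per
reference gene — the best trade-off between alignment length and percent
identity — and trims it to its homology-supported span, yielding a
non-redundant, conservative EST set.

Selection rule, per tier:
  * tiers with an identity cutoff (the Aedes tiers): among members at or
    above the cutoff, the longest alignment wins (ties: higher identity,
    then est id); when no member reaches the cutoff, the highest identity
    wins.
  * tiers without a cutoff (distant references): the highest identity wins
    among alignments of at least 50 bp (ties: longer alignment, then est id).

Hits on the genomic-DNA tier are used only when the majority (>50%) of the
aligned span falls within an annotated mRNA. The trimmed product must be at
least 50 bp or the gene is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import Assignment, HitRecord, TierConfig, DEFAULT_TIERS
from .qc import compute_n50

__all__ = [
    "GeneGroup",
    "TrimmedEst",
    "ReductionSummary",
    "group_by_gene",
    "select_representative",
    "genomic_overlap_filter",
    "trim_to_alignment",
    "reduce_est_set",
    "read_gff3_mrna_intervals",
]

MIN_TRIMMED_LENGTH = 50


@dataclass
class GeneGroup:
    """All ESTs assigned to one reference gene (all on the same tier)."""

    gene_id: str
    members: list[Assignment]
    tier: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("GeneGroup must have at least one member")
        bad = [m for m in self.members if m.gene_id != self.gene_id]
        if bad:
            raise ValueError(f"members assigned to other genes: {bad}")


@dataclass(frozen=True)
class TrimmedEst:
    est_id: str           # source id suffixed "_trimmed"
    source_est_id: str
    gene_id: str
    sequence: str
    trim_span: tuple[int, int]  # 1-based inclusive on the source EST
    bp_trimmed: int


@dataclass
class ReductionSummary:
    n_groups: int = 0
    n_kept: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # gene -> reason
    group_sizes: list[int] = field(default_factory=list)
    mean_bp_trimmed: float = float("nan")
    n50_before: int = 0
    n50_after: int = 0


def group_by_gene(assignments: Sequence[Assignment]) -> list[GeneGroup]:
    """Partition assignments by reference gene; group order follows first
    appearance, member order follows input order."""
    by_gene: dict[str, list[Assignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)
    return [
        GeneGroup(gene_id=g, members=members, tier=members[0].tier)
        for g, members in by_gene.items()
    ]


def select_representative(group: GeneGroup, tier: TierConfig) -> Assignment:
    """Pick the group's representative EST under the tier's selection rule."""
    members = group.members
    cutoff = tier.min_pct_identity_for_selection
    if cutoff > 0:
        qualifying = [m for m in members if m.hit.pct_identity >= cutoff]
        if qualifying:
            return min(
                qualifying,
                key=lambda m: (-m.hit.aln_length, -m.hit.pct_identity, m.est_id),
            )
        return min(members, key=lambda m: (-m.hit.pct_identity, m.est_id))
    long_enough = [m for m in members if m.hit.aln_length >= MIN_TRIMMED_LENGTH]
    pool = long_enough or members
    return min(pool, key=lambda m: (-m.hit.pct_identity, -m.hit.aln_length, m.est_id))


def read_gff3_mrna_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """mRNA intervals per scaffold from a GFF3 file (1-based inclusive)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(str(path)) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5 or cols[2] != "mRNA":
                continue
            start, end = int(cols[3]), int(cols[4])
            if end < start:
                raise ValueError(f"malformed interval {start}..{end} in {path}")
            intervals.setdefault(cols[0], []).append((start, end))
    return intervals


def genomic_overlap_filter(
    hit: HitRecord,
    annotations: Mapping[str, Sequence[tuple[int, int]]],
) -> bool:
    """True iff strictly more than half the EST's aligned genomic span lies
    within annotated mRNA. Overlap is computed on subject (genome)
    coordinates against the union of mRNA intervals on the hit's scaffold."""
    lo, hi = sorted((hit.sstart, hit.send))
    span = hi - lo + 1
    merged: list[list[int]] = []
    for s, e in sorted(annotations.get(hit.subject_id, ())):
        if e < s:
            raise ValueError(f"malformed mRNA interval {s}..{e}")
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = sum(
        max(0, min(hi, e) - max(lo, s) + 1) for s, e in merged
    )
    return covered / span > 0.5


def trim_to_alignment(est_sequence: str, hit: HitRecord) -> TrimmedEst:
    """Trim an EST to its alignment's query start/stop coordinates.

    Coordinates are 1-based inclusive; reversed pairs (as produced by
    translated searches on the minus frame) are min/max-normalized. The
    product is always an exact contiguous substring of the source on the
    forward strand — no reverse complementing, so the output stays a
    nucleotide EST in source orientation.
    """
    lo, hi = sorted((hit.qstart, hit.qend))
    if lo < 1 or hi > len(est_sequence):
        raise ValueError(
            f"alignment span {lo}..{hi} outside EST of length {len(est_sequence)}"
        )
    sub = est_sequence[lo - 1 : hi]
    return TrimmedEst(
        est_id=f"{hit.query_id}_trimmed",
        source_est_id=hit.query_id,
        gene_id=hit.subject_id,
        sequence=sub,
        trim_span=(lo, hi),
        bp_trimmed=len(est_sequence) - len(sub),
    )


def reduce_est_set(
    assignments: Sequence[Assignment],
    sequences: Mapping[str, str],
    tiers: Sequence[TierConfig] = DEFAULT_TIERS,
    gff: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> tuple[list[TrimmedEst], ReductionSummary]:
    """Collapse each gene group to one trimmed representative EST.

    Genomic-tier assignments failing the mRNA-containment rule are discarded
    before grouping; winners whose trimmed product is shorter than 50 bp are
    dropped with a logged reason.
    """
    tier_by_name = {t.name: t for t in tiers}
    usable = []
    summary = ReductionSummary()
    for a in assignments:
        tier = tier_by_name[a.tier]
        if tier.genomic:
            if gff is None or not genomic_overlap_filter(a.hit, gff):
                summary.dropped.setdefault(a.gene_id, "genomic_overlap")
                continue
        usable.append(a)

    groups = group_by_gene(usable)
    summary.n_groups = len(groups)
    summary.group_sizes = [len(g.members) for g in groups]

    kept: list[TrimmedEst] = []
    for g in groups:
        rep = select_representative(g, tier_by_name[g.tier])
        if rep.est_id not in sequences:
            raise KeyError(f"no sequence for EST {rep.est_id}")
        trimmed = trim_to_alignment(sequences[rep.est_id], rep.hit)
        if len(trimmed.sequence) < MIN_TRIMMED_LENGTH:
            summary.dropped[g.gene_id] = "trimmed_below_50bp"
            continue
        summary.dropped.pop(g.gene_id, None)
        kept.append(trimmed)

    summary.n_kept = len(kept)
    if kept:
        before = [len(sequences[t.source_est_id]) for t in kept]
        after = [len(t.sequence) for t in kept]
        summary.mean_bp_trimmed = float(np.mean([t.bp_trimmed for t in kept]))
        summary.n50_before = compute_n50(before)
        summary.n50_after = compute_n50(after)
    return kept, summary
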