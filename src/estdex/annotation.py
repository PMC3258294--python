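"""Tiered homology annotation of ESTs.

Each EST (contig or singleton) is assigned to a putative homolog by walking an
ordered cascade of reference databases — conspecific mRNA first, then close
relatives, out to Swiss-Prot — with e-value cutoffs that relax as taxonomic
distance grows. Within the first tier holding a qualifying hit, the single
best hit wins: lowest e-value, ties broken by highest bitscore, residual ties
by subject id (so assignment is deterministic). E-values from nucleotide and
translated searches against different databases are not comparable, which is
why the cascade is walked tier by tier rather than pooled.

Also provides the bootstrapped gene-accumulation curve used to judge
sequencing depth: the read order is permuted many times and the mean
cumulative number of distinct reference genes discovered per additional read
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitRecord",
    "TierConfig",
    "Assignment",
    "DEFAULT_TIERS",
    "read_hit_table",
    "hits_from_frame",
    "best_hit",
    "cascade_assign",
    "assign_all",
    "accumulation_curve",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One alignment row (BLAST tabular outfmt 6) tagged with its tier."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    tier: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class TierConfig:
    """One reference database of the cascade with its search cutoffs.

    ``min_pct_identity_for_selection`` is used later, when choosing the
    representative EST per gene; 0 means identity alone decides. ``genomic``
    marks the genomic-DNA tier whose hits must additionally fall mostly
    within an annotated mRNA.
    """

    name: str
    algorithm: str  # "nucleotide" (BLASTN) or "translated" (BLASTX)
    max_evalue: float
    min_pct_identity_for_selection: float
    priority: int
    genomic: bool = False


#: The default cascade: conspecific mRNA, congeneric transcripts / genome /
#: peptides, then increasingly distant dipteran and metazoan references,
#: Swiss-Prot last. E-value ceilings relax with taxonomic distance.
DEFAULT_TIERS: tuple[TierConfig, ...] = (
    TierConfig("aalb_mrna", "nucleotide", 1e-10, 85.0, 1),
    TierConfig("aaeg_transcripts", "nucleotide", 1e-10, 85.0, 2),
    TierConfig("aaeg_genomic", "nucleotide", 1e-10, 85.0, 3, genomic=True),
    TierConfig("aaeg_peptides", "translated", 1e-10, 70.0, 4),
    TierConfig("cquinq_peptides", "translated", 1e-5, 0.0, 5),
    TierConfig("agamb_peptides", "translated", 1e-5, 0.0, 6),
    TierConfig("dmel_peptides", "translated", 1e-5, 0.0, 7),
    TierConfig("celeg_peptides", "translated", 1e-4, 0.0, 8),
    TierConfig("swissprot", "translated", 1e-3, 0.0, 9),
)


@dataclass(frozen=True)
class Assignment:
    est_id: str
    gene_id: str
    tier: str
    hit: HitRecord


def read_hit_table(path, tier: str = "") -> list[HitRecord]:
    """Parse a BLAST outfmt 6 / m8 TSV into HitRecords."""
    frame = pd.read_csv(str(path), sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return hits_from_frame(frame, tier)


def hits_from_frame(frame: pd.DataFrame, tier: str = "") -> list[HitRecord]:
    return [
        HitRecord(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            pct_identity=float(row.pident),
            aln_length=int(row.length),
            qstart=int(row.qstart),
            qend=int(row.qend),
            sstart=int(row.sstart),
            send=int(row.send),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
            tier=tier,
        )
        for row in frame.itertuples(index=False)
    ]


def best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    """The hit with the lowest e-value; equal e-values fall back to the
    highest bitscore, then lexicographically smallest subject id."""
    if not hits:
        raise ValueError("best_hit of an empty hit list")
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def cascade_assign(
    est_id: str,
    hits_by_tier: Mapping[str, Sequence[HitRecord]],
    tiers: Sequence[TierConfig] = DEFAULT_TIERS,
) -> Optional[Assignment]:
    """Walk tiers in priority order; the first tier holding at least one hit
    within its e-value ceiling yields the assignment (its best hit). Returns
    None when no tier qualifies — the EST joins the no-hit class."""
    for tier in sorted(tiers, key=lambda t: t.priority):
        candidates = [
            h for h in hits_by_tier.get(tier.name, ()) if h.evalue <= tier.max_evalue
        ]
        if candidates:
            win = best_hit(candidates)
            return Assignment(est_id=est_id, gene_id=win.subject_id, tier=tier.name, hit=win)
    return None


def assign_all(
    hits: Sequence[HitRecord],
    tiers: Sequence[TierConfig] = DEFAULT_TIERS,
    est_ids: Optional[Sequence[str]] = None,
) -> tuple[list[Assignment], list[str]]:
    """Assign every EST appearing in ``hits`` (plus any extra ids in
    ``est_ids``). Returns (assignments, no-hit est ids)."""
    by_est: dict[str, dict[str, list[HitRecord]]] = {}
    for h in hits:
        by_est.setdefault(h.query_id, {}).setdefault(h.tier, []).append(h)
    universe = list(by_est)
    if est_ids is not None:
        seen = set(universe)
        universe += [e for e in est_ids if e not in seen]
    assignments, no_hit = [], []
    for est in universe:
        a = cascade_assign(est, by_est.get(est, {}), tiers)
        if a is None:
            no_hit.append(est)
        else:
            assignments.append(a)
    return assignments, no_hit


def accumulation_curve(
    read_hits: Sequence[tuple[str, Optional[str]]],
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrapped gene-accumulation curve.

    ``read_hits`` pairs each read with the reference gene it matched (or None
    for no match). The order is permuted ``n_boot`` times; for each
    permutation the cumulative count of newly seen genes per read rank is
    taken, and the per-rank mean over permutations is returned.

    The curve is monotone non-decreasing, and its endpoint equals the number
    of distinct genes regardless of permutation or seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    genes = [g for _, g in read_hits]
    n = len(genes)
    if n == 0:
        return np.zeros(0)
    # integer-encode gene ids; -1 = no hit
    uniq = sorted({g for g in genes if g is not None})
    code = {g: i for i, g in enumerate(uniq)}
    coded = np.array([code[g] if g is not None else -1 for g in genes], dtype=np.int64)
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(n_boot):
        perm = coded[rng.permutation(n)]
        # a rank contributes iff it is the first occurrence of a real gene
        first = ~pd.Series(perm).duplicated().to_numpy() & (perm >= 0)
        total += np.cumsum(first)
    return total / n_boot
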