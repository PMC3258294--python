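"""Read cleaning for pooled 454-style EST libraries.

Implements the four quality filters (ambiguous bases, artificial duplicates,
mean Phred quality, contaminant homology), poly-A/T tail trimming, and the
50 bp length floor, applied in a fixed order with per-step removal tallies.
All filters are stable: retained reads keep their input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "QcConfig",
    "QcReport",
    "filter_ambiguous",
    "remove_duplicates",
    "filter_mean_quality",
    "screen_contaminants",
    "trim_polyAT",
    "enforce_min_length",
    "compute_n50",
    "run_qc",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class Read:
    """One sequencing read with per-base Phred qualities and a library label."""

    id: str
    sequence: str
    qualities: tuple[int, ...]
    library: str = "DI"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcConfig:
    min_mean_quality: float = 25.0
    contaminant_evalue: float = 1e-25
    polyat_min_run: int = 10
    polyat_mismatch_allowance: int = 1
    min_length: int = 50


@dataclass
class QcReport:
    """Per-step removal tallies plus summary statistics of the surviving reads.

    Invariant: ``remaining + sum(removed.values()) == input_count``.
    """

    input_count: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    reads_trimmed: int = 0
    bases_trimmed: int = 0
    remaining: int = 0
    mean_length: float = float("nan")
    median_length: float = float("nan")
    n50: int = 0
    mean_gc: float = float("nan")

    def check_conservation(self) -> bool:
        return self.remaining + sum(self.removed.values()) == self.input_count

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed": dict(self.removed),
            "reads_trimmed": self.reads_trimmed,
            "bases_trimmed": self.bases_trimmed,
            "remaining": self.remaining,
            "mean_length": self.mean_length,
            "median_length": self.median_length,
            "n50": self.n50,
            "mean_gc": self.mean_gc,
        }


def filter_ambiguous(reads: Sequence[Read]) -> list[Read]:
    """Drop every read containing at least one ambiguous base (N)."""
    return [r for r in reads if "N" not in r.sequence]


def remove_duplicates(reads: Sequence[Read]) -> list[Read]:
    """Drop exact-sequence duplicates, keeping the first occurrence.

    454 libraries contain artificial duplicates; exact full-length sequence
    identity is the (conservative, deterministic) criterion used here.
    """
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    return out


def filter_mean_quality(reads: Sequence[Read], min_mean: float = 25.0) -> list[Read]:
    """Drop reads whose arithmetic mean Phred score is below ``min_mean``.

    The boundary is inclusive: a read at exactly the threshold survives.
    """
    out = []
    for r in reads:
        if len(r.qualities) == 0:
            raise ValueError(f"read {r.id} has no quality scores")
        if float(np.mean(r.qualities)) >= min_mean:
            out.append(r)
    return out


def screen_contaminants(
    reads: Sequence[Read],
    hit_table,
    evalue_cutoff: float = 1e-25,
) -> list[Read]:
    """Drop reads with a significant homology hit to a contaminant database.

    ``hit_table`` is a DataFrame with at least ``qseqid`` and ``evalue``
    columns (BLAST outfmt 6 against e.g. rRNA / endosymbiont sequences).
    A read is removed when any of its hits has e-value <= ``evalue_cutoff``;
    significant matches have small e-values. Hits naming unknown read ids
    raise a warning and are ignored.
    """
    if hit_table is None or len(hit_table) == 0:
        return list(reads)
    known = {r.id for r in reads}
    sig = hit_table[hit_table["evalue"] <= evalue_cutoff]
    unknown = set(sig["qseqid"]) - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} contaminant hit(s) reference unknown read ids; ignored",
            stacklevel=2,
        )
    flagged = set(sig["qseqid"]) & known
    return [r for r in reads if r.id not in flagged]


def _terminal_run(seq: str, base: str, end: str, min_run: int, allowance: int) -> int:
    """Length of the maximal terminal run of ``base`` at ``end`` ('5p'/'3p'),
    permitting up to ``allowance`` interior non-matching bases. Returns 0 if
    the best qualifying run is shorter than ``min_run``."""
    n = len(seq)
    idx = range(n - 1, -1, -1) if end == "3p" else range(n)
    best = 0
    mismatches = 0
    length = 0
    for i in idx:
        length += 1
        if seq[i] == base:
            if mismatches <= allowance:
                best = length
        else:
            mismatches += 1
            if mismatches > allowance:
                break
    return best if best >= min_run else 0


def trim_polyAT(read: Read, min_run: int = 10, mismatch_allowance: int = 1) -> Read:
    """Trim a terminal poly-A run from the 3' end and poly-T from the 5' end.

    A run qualifies when it is at least ``min_run`` bases long counting at
    most ``mismatch_allowance`` interior non-matching bases. Qualities are
    trimmed in register with the sequence.
    """
    seq = read.sequence
    a_run = _terminal_run(seq, "A", "3p", min_run, mismatch_allowance)
    seq = seq[: len(seq) - a_run] if a_run else seq
    t_run = _terminal_run(seq, "T", "5p", min_run, mismatch_allowance)
    start = t_run
    stop = len(read.sequence) - a_run
    if start == 0 and stop == len(read.sequence):
        return read
    return replace(
        read,
        sequence=read.sequence[start:stop],
        qualities=read.qualities[start:stop],
    )


def enforce_min_length(reads: Sequence[Read], floor: int = 50) -> list[Read]:
    """Drop reads strictly shorter than ``floor`` bp."""
    return [r for r in reads if len(r) >= floor]


def compute_n50(lengths: Iterable[int]) -> int:
    """N50: smallest length L such that sequences >= L hold >= half the bases."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("N50 of an empty length set is undefined")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2.0)])


def _gc_percent(seq: str) -> float:
    if not seq:
        return float("nan")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def run_qc(
    reads: Sequence[Read],
    config: QcConfig | None = None,
    contaminant_hits=None,
) -> tuple[list[Read], QcReport]:
    """Full cleaning pass in the fixed order:

    ambiguous -> duplicates -> mean quality -> contaminants -> poly-A/T trim
    -> length floor.

    The order is part of the contract: per-step tallies depend on it. The pass
    is idempotent — a second application removes nothing.
    """
    cfg = config or QcConfig()
    report = QcReport(input_count=len(reads))
    cur = list(reads)

    step = filter_ambiguous(cur)
    report.removed["ambiguous"] = len(cur) - len(step)
    cur = step

    step = remove_duplicates(cur)
    report.removed["duplicate"] = len(cur) - len(step)
    cur = step

    step = filter_mean_quality(cur, cfg.min_mean_quality)
    report.removed["low_quality"] = len(cur) - len(step)
    cur = step

    step = screen_contaminants(cur, contaminant_hits, cfg.contaminant_evalue)
    report.removed["contaminant"] = len(cur) - len(step)
    cur = step

    trimmed = []
    for r in cur:
        t = trim_polyAT(r, cfg.polyat_min_run, cfg.polyat_mismatch_allowance)
        if len(t) < len(r):
            report.reads_trimmed += 1
            report.bases_trimmed += len(r) - len(t)
        trimmed.append(t)
    cur = trimmed

    step = enforce_min_length(cur, cfg.min_length)
    report.removed["short"] = len(cur) - len(step)
    cur = step

    report.remaining = len(cur)
    if cur:
        lengths = [len(r) for r in cur]
        report.mean_length = float(np.mean(lengths))
        report.median_length = float(np.median(lengths))
        report.n50 = compute_n50(lengths)
        report.mean_gc = float(np.mean([_gc_percent(r.sequence) for r in cur]))
    return cur, report


def read_fastq(path) -> list[Read]:
    """Load Phred+33 FASTQ. Library label is taken from an ``lib=XX`` token in
    the description when present, else defaults to DI."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        lib = "DI"
        for token in rec.description.split():
            if token.startswith("lib="):
                lib = token[4:]
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
                library=lib,
            )
        )
    return reads


def write_fastq(reads: Sequence[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description=f"lib={r.library}")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
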