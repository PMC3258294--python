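"""Synthetic inputs for every pipeline stage, with a ground-truth manifest.

The generators emulate the statistical structure of a pooled two-library
454 EST study of photoperiod-driven diapause induction: a reference gene set
(standing in for the congeneric transcript database), redundant contig
groups per homolog with variable 5'/3' ends and sequencing errors, two
read-count libraries with size skew and known differentially expressed
genes (including genes present in only one library), reads carrying
injected QC defects, and replicated qPCR Ct measurements anchored to three
stable reference genes.

Homology hit tables are constructed directly from known provenance rather
than by running an aligner: the pipeline consumes tabular hits, so the
e-value is modeled as a deterministic decreasing function of alignment
length x identity and the bitscore rises with alignment quality. Every
emitted record is traceable through the manifest. All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import OUTFMT6_COLUMNS
from .de import CountMatrix
from .qc import Read

__all__ = [
    "GroundTruth",
    "simulate_reference",
    "simulate_redundant_contigs",
    "simulate_counts",
    "simulate_qc_reads",
    "simulate_qpcr",
    "write_fasta",
    "write_gff3",
]

BASES = np.array(list("ACGT"))
REFERENCE_GENES = ("RpL34", "HistoneH3", "NAP")


@dataclass
class GroundTruth:
    """Manifest tying every synthetic record to its origin.

    ``true_log2_fc`` is the DI-vs-NDI log2 fold-change (0 for non-DE genes);
    ``qpcr_true_abundance`` holds per-gene, per-treatment relative abundance
    on the same scale the qPCR stage estimates. ``contig_provenance`` and
    ``library_sizes`` are filled in by the contig and count generators.
    """

    gene_ids: list[str]
    gene_lengths: dict[str, int]
    true_log2_fc: dict[str, float]
    de_flags: dict[str, bool]
    expression: dict[str, float]
    sequences: dict[str, str]
    scaffold: dict[str, tuple[str, int, int]]  # gene -> (scaffold, start, end)
    library_sizes: dict[str, float] = field(default_factory=dict)
    contig_provenance: dict[str, tuple[str, tuple[int, int]]] = field(
        default_factory=dict
    )
    qpcr_true_abundance: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for g, L in self.gene_lengths.items():
            if L < 100:
                raise ValueError(f"gene {g} shorter than 100 bp")
        for g, flag in self.de_flags.items():
            if not flag and self.true_log2_fc[g] != 0.0:
                raise ValueError(f"non-DE gene {g} has nonzero true fold-change")

    def manifest_json(self) -> str:
        payload = {
            "gene_ids": self.gene_ids,
            "gene_lengths": self.gene_lengths,
            "true_log2_fc": self.true_log2_fc,
            "de_flags": self.de_flags,
            "expression": self.expression,
            "library_sizes": self.library_sizes,
            "contig_provenance": {
                c: [g, list(span)] for c, (g, span) in self.contig_provenance.items()
            },
            "qpcr_true_abundance": self.qpcr_true_abundance,
        }
        return json.dumps(payload, indent=1)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _sample_lengths(rng: np.random.Generator, n: int, params: Mapping) -> np.ndarray:
    kind = params.get("kind", "lognormal")
    if kind == "fixed":
        lengths = np.full(n, int(params["length"]))
    elif kind == "lognormal":
        # median ~ exp(mu); defaults give a few-hundred-bp transcript-fragment scale
        mu = float(params.get("mean_log", np.log(600.0)))
        sigma = float(params.get("sigma_log", 0.5))
        lengths = rng.lognormal(mu, sigma, size=n).astype(int)
    else:
        raise ValueError(f"unknown length distribution {kind!r}")
    return np.maximum(lengths, int(params.get("min_length", 100)))


def simulate_reference(
    n_genes: int,
    length_params: Optional[Mapping] = None,
    seed: int = 0,
    n_de: int = 0,
    de_log2fc: float = 2.0,
    expression_sigma: float = 0.6,
    de_min_expression: float = 2.0,
) -> GroundTruth:
    """Reference gene set: sequences, scaffold placement, expression levels,
    and the true DE structure.

    ``n_de`` genes receive a true |log2 fold-change| of ``de_log2fc``
    (alternating direction); all others are exactly null. Per-gene baseline
    expression is lognormal with ``expression_sigma`` on the log scale; DE
    genes are floored at ``de_min_expression`` so the planted signal sits in
    the well-measured part of the dynamic range, as qPCR-verified candidates
    do in practice.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    lengths = _sample_lengths(rng, n_genes, length_params or {})
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]

    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    fc = {g: 0.0 for g in gene_ids}
    flags = {g: False for g in gene_ids}
    for k, i in enumerate(sorted(de_idx)):
        fc[gene_ids[i]] = de_log2fc if k % 2 == 0 else -de_log2fc
        flags[gene_ids[i]] = True

    expression = {
        g: float(rng.lognormal(0.0, expression_sigma)) for g in gene_ids
    }
    for g in gene_ids:
        if flags[g]:
            expression[g] = max(expression[g], de_min_expression)
    sequences = {}
    scaffold = {}
    pos = 1
    for g, L in zip(gene_ids, lengths):
        sequences[g] = _random_seq(rng, int(L))
        scaffold[g] = ("scaffold_1", pos, pos + int(L) - 1)
        pos += int(L) + 200  # intergenic gap

    qpcr = {
        g: {
            "DI": expression[g] * 2.0 ** (fc[g] / 2.0),
            "NDI": expression[g] * 2.0 ** (-fc[g] / 2.0),
        }
        for g in gene_ids
    }
    truth = GroundTruth(
        gene_ids=gene_ids,
        gene_lengths={g: int(L) for g, L in zip(gene_ids, lengths)},
        true_log2_fc=fc,
        de_flags=flags,
        expression=expression,
        sequences=sequences,
        scaffold=scaffold,
        qpcr_true_abundance=qpcr,
    )
    truth.validate()
    return truth


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(str(path), "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(truth: GroundTruth, path) -> None:
    """One mRNA feature per gene on its synthetic scaffold."""
    with open(str(path), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.gene_ids:
            scaf, start, end = truth.scaffold[g]
            fh.write(
                f"{scaf}\testdex_sim\tmRNA\t{start}\t{end}\t.\t+\t.\tID={g}\n"
            )


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    """Substitute bases at ``error_rate``; returns (sequence, n_substituted)."""
    if error_rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), len(hits)


def _hit_row(
    contig_id: str,
    subject_id: str,
    qstart: int,
    qend: int,
    sstart: int,
    send: int,
    n_mismatch: int,
) -> dict:
    """Construct one outfmt 6 row from known provenance. The bitscore grows
    with alignment length x identity and the e-value decays with the
    bitscore, so both are monotone in alignment quality."""
    aln = qend - qstart + 1
    pident = 100.0 * (aln - n_mismatch) / aln
    bitscore = round(1.85 * aln * pident / 100.0, 1)
    evalue = max(10.0 ** (-bitscore / 3.4), 1e-180)
    return {
        "qseqid": contig_id,
        "sseqid": subject_id,
        "pident": round(pident, 2),
        "length": aln,
        "mismatch": n_mismatch,
        "gapopen": 0,
        "qstart": qstart,
        "qend": qend,
        "sstart": sstart,
        "send": send,
        "evalue": float(f"{evalue:.2e}"),
        "bitscore": bitscore,
    }


def simulate_redundant_contigs(
    truth: GroundTruth,
    redundancy_params: Optional[Mapping] = None,
    end_variability: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    tier_fractions: Optional[Mapping[str, float]] = None,
    n_no_hit: int = 0,
    n_chimeric: int = 0,
) -> tuple[dict[str, str], dict[str, pd.DataFrame]]:
    """Redundant contigs per reference gene plus constructed per-tier hit
    tables.

    Per gene, the number of ESTs is 1 + Poisson(mean - 1) (default mean
    8.86, matching the redundancy the pooled assembly showed); each EST
    covers a sub-span of its gene with uniformly jittered 5'/3' ends and
    additionally carries random non-homologous flanks (up to
    ``end_variability`` bp per end) — the "variable ends" that homology
    trimming later removes. Substitution errors hit the homologous segment
    at ``error_rate``; the constructed hit row covers exactly that segment.
    ``tier_fractions`` splits genes across cascade tiers (default: all on
    the congeneric transcript tier). ``n_no_hit`` extra contigs get no hit
    rows at all; ``n_chimeric`` contigs splice two genes, each half hitting
    its own gene and neither hit covering more than 60% of the contig.
    Updates ``truth.contig_provenance`` (span = hit coordinates on the
    contig).
    """
    params = dict(redundancy_params or {})
    rng = np.random.default_rng(seed)
    mean_red = float(params.get("mean", 8.86))
    fixed = params.get("fixed")
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must be in [0, 1]")
    if mean_red < 1:
        raise ValueError("mean redundancy must be >= 1")

    fractions = dict(tier_fractions or {"aaeg_transcripts": 1.0})
    genes = list(truth.gene_ids)
    order = rng.permutation(len(genes))
    tier_of: dict[str, str] = {}
    start = 0
    items = list(fractions.items())
    for j, (tier, frac) in enumerate(items):
        take = len(genes) - start if j == len(items) - 1 else int(round(frac * len(genes)))
        for i in order[start : start + take]:
            tier_of[genes[i]] = tier
        start += take

    contigs: dict[str, str] = {}
    rows: dict[str, list[dict]] = {t: [] for t in fractions}
    c_idx = 0
    for g in genes:
        L = truth.gene_lengths[g]
        k = int(fixed) if fixed else 1 + int(rng.poisson(mean_red - 1.0))
        tier = tier_of[g]
        for _ in range(k):
            jitter5 = int(rng.integers(0, end_variability // 2 + 1))
            jitter3 = int(rng.integers(0, end_variability // 2 + 1))
            s = min(jitter5, max(0, L - 60))
            e = max(s + 50, L - jitter3)
            e = min(e, L)
            segment, n_sub = _mutate(rng, truth.sequences[g][s:e], error_rate)
            flank5 = _random_seq(rng, int(rng.integers(0, end_variability + 1)))
            flank3 = _random_seq(rng, int(rng.integers(0, end_variability + 1)))
            cid = f"contig{c_idx:06d}"
            c_idx += 1
            contigs[cid] = flank5 + segment + flank3
            qstart = len(flank5) + 1
            qend = len(flank5) + len(segment)
            if tier == "aaeg_genomic":
                scaf, g_start, _ = truth.scaffold[g]
                subject, sstart, send = scaf, g_start + s, g_start + e - 1
            else:
                subject, sstart, send = g, s + 1, e
            rows[tier].append(
                _hit_row(cid, subject, qstart, qend, sstart, send, n_sub)
            )
            truth.contig_provenance[cid] = (g, (qstart, qend))

    for _ in range(n_no_hit):
        g = genes[int(rng.integers(0, len(genes)))]
        cid = f"contig{c_idx:06d}"
        c_idx += 1
        length = int(rng.integers(100, 400))
        contigs[cid] = _random_seq(rng, length)
        truth.contig_provenance[cid] = (g, (0, 0))  # designed to miss every tier

    de_free = [g for g in genes if len(truth.sequences[g]) >= 200]
    for _ in range(n_chimeric):
        g1, g2 = (
            de_free[int(rng.integers(0, len(de_free)))],
            de_free[int(rng.integers(0, len(de_free)))],
        )
        if g1 == g2:
            g2 = de_free[(de_free.index(g1) + 1) % len(de_free)]
        half1 = truth.sequences[g1][:150]
        half2 = truth.sequences[g2][:150]
        cid = f"contig{c_idx:06d}"
        c_idx += 1
        contigs[cid] = half1 + half2
        clen = len(contigs[cid])
        t1, t2 = tier_of[g1], tier_of[g2]
        rows[t1].append(_hit_row(cid, g1, 1, 150, 1, 150, 0))
        rows[t2].append(_hit_row(cid, g2, 151, 300, 1, 150, 0))
        truth.contig_provenance[cid] = (g1, (1, 150))

    tables = {
        t: pd.DataFrame(r, columns=OUTFMT6_COLUMNS) for t, r in rows.items()
    }
    return contigs, tables


def simulate_counts(
    truth: GroundTruth,
    dispersion: float = 0.0,
    skew: float = 1.1,
    n_unique: int = 0,
    seed: int = 0,
    total_reads: int = 600_000,
    lengths: Optional[Mapping[str, int]] = None,
) -> CountMatrix:
    """Gene x library counts from a negative-binomial model.

    Per-gene means are proportional to gene length x expression x library
    depth, split between treatments by the true fold-change; ``skew`` is the
    DI:NDI library-size ratio and ``dispersion`` the NB overdispersion.
    The default is Poisson (dispersion 0): with a single pooled RNA sample
    sequenced once per treatment, between-library variation is sampling
    variation, which is the regime the exact binomial test assumes;
    overdispersion is exposed for robustness experiments. When ``n_unique``
    is positive, exactly that many genes are forced to zero in one library
    (alternating sides, the other side floored at 1) and any incidental zero
    elsewhere is floored at 1, emulating treatment-unique transcripts.
    Library sizes recorded in the truth manifest are the realized column
    sums.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if skew <= 0:
        raise ValueError("skew must be > 0")
    if n_unique > len(truth.gene_ids):
        raise ValueError("n_unique exceeds gene count")
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_ids)
    L = np.array([
        (lengths or truth.gene_lengths)[g] for g in genes
    ], dtype=float)
    expr = np.array([truth.expression[g] for g in genes])
    fc = np.array([truth.true_log2_fc[g] for g in genes])

    depth = np.array([skew / (1.0 + skew), 1.0 / (1.0 + skew)]) * total_reads
    base = L * expr
    weights = np.stack([base * 2.0 ** (fc / 2.0), base * 2.0 ** (-fc / 2.0)], axis=1)
    mu = weights / weights.sum(axis=0, keepdims=True) * depth[None, :]

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)

    if n_unique:
        uniq_genes = rng.choice(len(genes), size=n_unique, replace=False)
        counts = np.maximum(counts, 1)
        for k, i in enumerate(sorted(uniq_genes)):
            zero_col = k % 2  # alternate which library loses the gene
            counts[i, zero_col] = 0

    matrix = CountMatrix(
        gene_ids=genes,
        lengths=L,
        counts=counts.astype(np.int64),
        library_sizes=counts.sum(axis=0).astype(float),
    )
    truth.library_sizes = {
        "DI": float(matrix.library_sizes[0]),
        "NDI": float(matrix.library_sizes[1]),
    }
    return matrix


DEFECTS = ("ambiguous", "duplicate", "low_quality", "contaminant", "polyat", "short")


def simulate_qc_reads(
    truth: GroundTruth,
    defect_rates: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    n_reads: int = 1000,
    read_length_mean: int = 350,
    read_length_sd: int = 80,
    read_error_rate: float = 0.01,
) -> tuple[list[Read], pd.DataFrame, dict[str, list[str]]]:
    """Reads drawn from the reference genes with QC defects injected at the
    requested rates, each read carrying at most one defect so per-step QC
    tallies match the manifest exactly.

    Every read receives substitution errors at ``read_error_rate`` (454-like
    base miscalls), which also keeps independent reads from colliding into
    accidental exact duplicates; the injected-duplicate class copies a donor
    read verbatim. Returns (reads, contaminant hit table, manifest). The
    manifest maps each defect to the ids of reads carrying it; contaminant
    reads also appear in the hit table with e-value well below the screening
    cutoff.
    """
    rates = {d: 0.0 for d in DEFECTS}
    rates.update(defect_rates or {})
    unknown = set(rates) - set(DEFECTS)
    if unknown:
        raise ValueError(f"unknown defect kinds: {sorted(unknown)}")
    for d, r in rates.items():
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"rate for {d} must be in [0, 1]")
    if sum(rates.values()) > 1.0:
        raise ValueError("defect rates sum above 1; defects are exclusive")

    rng = np.random.default_rng(seed)
    genes = list(truth.gene_ids)
    seen_seqs: set[str] = set()

    def unique_seq(seq: str) -> str:
        # force sequence uniqueness so only the injected-duplicate class
        # produces exact duplicates and QC tallies match the manifest
        while seq in seen_seqs:
            pos = int(rng.integers(0, len(seq)))
            alt = [b for b in "ACGT" if b != seq[pos]]
            seq = seq[:pos] + alt[rng.integers(0, len(alt))] + seq[pos + 1 :]
        seen_seqs.add(seq)
        return seq

    def clean_read(idx: int, lib: str) -> Read:
        g = genes[int(rng.integers(0, len(genes)))]
        seq = truth.sequences[g]
        length = int(np.clip(rng.normal(read_length_mean, read_length_sd), 60, len(seq)))
        start = int(rng.integers(0, len(seq) - length + 1))
        frag, _ = _mutate(rng, seq[start : start + length], read_error_rate)
        quals = tuple(int(q) for q in rng.integers(30, 41, size=length))
        return Read(f"{lib}_read{idx:06d}", unique_seq(frag), quals, lib)

    counts = {d: int(round(rates[d] * n_reads)) for d in DEFECTS}
    n_clean = n_reads - sum(counts.values())
    reads: list[Read] = []
    manifest: dict[str, list[str]] = {d: [] for d in DEFECTS}
    contaminant_rows: list[dict] = []
    idx = 0

    for _ in range(n_clean):
        lib = "DI" if idx % 2 == 0 else "NDI"
        reads.append(clean_read(idx, lib))
        idx += 1

    for d in DEFECTS:
        for _ in range(counts[d]):
            lib = "DI" if idx % 2 == 0 else "NDI"
            r = clean_read(idx, lib)
            if d == "ambiguous":
                pos = int(rng.integers(0, len(r)))
                r = Read(r.id, r.sequence[:pos] + "N" + r.sequence[pos + 1 :],
                         r.qualities, lib)
            elif d == "duplicate":
                donor = reads[int(rng.integers(0, n_clean))] if n_clean else r
                r = Read(r.id, donor.sequence, donor.qualities, lib)
            elif d == "low_quality":
                quals = tuple(int(q) for q in rng.integers(10, 23, size=len(r)))
                r = Read(r.id, r.sequence, quals, lib)
            elif d == "contaminant":
                contaminant_rows.append(
                    _hit_row(r.id, "contaminant_rRNA", 1, min(80, len(r)),
                             1, min(80, len(r)), 0)
                )
            elif d == "polyat":
                tail = "A" * int(rng.integers(12, 21))
                r = Read(r.id, r.sequence + tail,
                         r.qualities + tuple([35] * len(tail)), lib)
            elif d == "short":
                cut = int(rng.integers(20, 50))
                r = Read(r.id, r.sequence[:cut], r.qualities[:cut], lib)
            manifest[d].append(r.id)
            reads.append(r)
            idx += 1

    hit_table = pd.DataFrame(contaminant_rows, columns=OUTFMT6_COLUMNS)
    return reads, hit_table, manifest


def simulate_qpcr(
    truth: GroundTruth,
    n_bio: int = 5,
    n_tech: int = 3,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    target_genes: Optional[Sequence[str]] = None,
    base_ct: float = 25.0,
) -> pd.DataFrame:
    """Replicated Ct table: three reference genes with treatment-independent
    expected Ct near ``base_ct``, and target Ct = reference level -
    log2(true relative abundance) + Gaussian noise per measurement.
    """
    if n_bio < 2:
        raise ValueError("need >= 2 biological replicates")
    if n_tech < 1:
        raise ValueError("need >= 1 technical replicate")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    targets = list(target_genes) if target_genes is not None else list(truth.gene_ids)

    # multiplicative offsets keep the geometric mean of the three reference
    # Cts exactly at base_ct, so noiseless recovery is an identity
    ref_levels = {
        g: base_ct * r for g, r in zip(REFERENCE_GENES, (1 / 1.02, 1.0, 1.02))
    }
    rows = []
    for trt in ("DI", "NDI"):
        for b in range(1, n_bio + 1):
            for g, level in ref_levels.items():
                for t in range(1, n_tech + 1):
                    ct = level + rng.normal(0.0, ct_noise_sd)
                    rows.append((g, "reference", trt, b, t, ct))
            for g in targets:
                ab = truth.qpcr_true_abundance[g][trt]
                expect = base_ct - np.log2(ab)
                for t in range(1, n_tech + 1):
                    ct = expect + rng.normal(0.0, ct_noise_sd)
                    rows.append((g, "target", trt, b, t, ct))
    return pd.DataFrame(
        rows, columns=["gene_id", "role", "treatment", "bio_rep", "tech_rep", "ct"]
    )
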