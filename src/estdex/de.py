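"""Two-library differential expression from read counts.

The design has one sequencing library per photoperiod treatment (DI =
diapause-inducing short days, NDI = non-diapause-inducing long days), so
significance comes from an exact binomial test on the two counts of each
gene, conditional on the pair's total — the classic SAGE-style comparison —
with the treatment split under the null given by the ratio of (effective)
library sizes. Two normalizations set those effective sizes:

* TMM (trimmed mean of M values): a between-library scaling factor estimated
  from doubly trimmed per-gene log ratios of count proportions, robust to
  library-size skew and to an asymmetric burden of expressed genes. The
  estimator is implemented here from first principles.
* RPKM: reads per kilobase of transcript per million mapped reads, using the
  trimmed EST length as transcript length; RPKM values are rescaled by one
  global constant so their grand sum equals the original two-library read
  total, making binomial p-values comparable between the two methods.

Fold-change uses a 0.1 pseudocount so genes observed in only one library
(which would otherwise have undefined log ratios) stay in the analysis:
M = log2((x_DI + 0.1)/N_DI) - log2((x_NDI + 0.1)/N_NDI). The pseudocount
affects fold-change only, never the significance test. Raw p-values get
Benjamini-Hochberg correction; genes with adjusted p below alpha (default
0.001) are called DE, direction given by the sign of M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DeResult",
    "NormalizationFactors",
    "unique_mapping_filter",
    "tmm_factors",
    "rpkm",
    "scale_rpkm_to_counts",
    "binom_exact_test",
    "bh_adjust",
    "fold_change",
    "call_de",
]

LIBRARIES = ("DI", "NDI")
PSEUDOCOUNT = 0.1


@dataclass
class CountMatrix:
    """Gene-by-library read counts with trimmed-EST lengths and library sizes."""

    gene_ids: list[str]
    lengths: np.ndarray          # bp, > 0
    counts: np.ndarray           # shape (n_genes, 2), columns (DI, NDI)
    library_sizes: np.ndarray    # total mapped reads per library, shape (2,)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        n = len(self.gene_ids)
        if self.counts.shape != (n, 2):
            raise ValueError(f"counts must be (n_genes, 2), got {self.counts.shape}")
        if np.any(self.lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        col = self.counts.sum(axis=0)
        if np.any(self.library_sizes + 1e-9 < col):
            raise ValueError("library sizes smaller than column sums")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        """Read a TSV with columns gene_id, length, count_DI, count_NDI and an
        optional '#library_sizes DI NDI' header comment (defaults to column
        sums)."""
        sizes = None
        with open(str(path)) as fh:
            first = fh.readline()
        if first.startswith("#library_sizes"):
            sizes = np.array([float(x) for x in first.split()[1:3]])
        frame = pd.read_csv(str(path), sep="\t", comment="#")
        counts = frame[["count_DI", "count_NDI"]].to_numpy()
        if sizes is None:
            sizes = counts.sum(axis=0).astype(float)
        return cls(
            gene_ids=[str(g) for g in frame["gene_id"]],
            lengths=frame["length"].to_numpy(float),
            counts=counts,
            library_sizes=sizes,
        )

    def to_tsv(self, path) -> None:
        with open(str(path), "w") as fh:
            fh.write(
                f"#library_sizes {self.library_sizes[0]:.0f} {self.library_sizes[1]:.0f}\n"
            )
            pd.DataFrame(
                {
                    "gene_id": self.gene_ids,
                    "length": self.lengths.astype(int),
                    "count_DI": self.counts[:, 0],
                    "count_NDI": self.counts[:, 1],
                }
            ).to_csv(fh, sep="\t", index=False)


@dataclass
class NormalizationFactors:
    method: str                       # "TMM" or "RPKM"
    factors: np.ndarray               # per-library factor (TMM) or ones
    effective_sizes: np.ndarray       # N(DI), N(NDI)


@dataclass
class DeResult:
    gene_id: str
    count_di: float
    count_ndi: float
    M: float
    A: float
    p_raw: float
    p_adj: float = float("nan")
    call: str = "ns"                  # "DI-up" | "NDI-up" | "ns"
    unique_to: str = "none"           # "DI" | "NDI" | "none"


def unique_mapping_filter(
    mapping: pd.DataFrame,
    lengths: dict[str, float],
    min_identity: float = 95.0,
) -> tuple[CountMatrix, dict[str, int]]:
    """Turn read-to-EST mapping rows into a count matrix.

    ``mapping`` columns: read_id, est_id, pct_identity, library. Rows below
    ``min_identity`` are dropped first; any read still mapping to more than
    one EST (or more than one location) is then discarded entirely and
    tallied. Surviving unique assignments are counted per library.
    """
    tally = {"low_identity": 0, "multi_mapped": 0, "counted": 0}
    ok = mapping[mapping["pct_identity"] >= min_identity]
    tally["low_identity"] = int(
        mapping["read_id"].nunique() - ok["read_id"].nunique()
    )
    per_read = ok.groupby("read_id").size()
    multi = set(per_read[per_read > 1].index)
    tally["multi_mapped"] = len(multi)
    uniq = ok[~ok["read_id"].isin(multi)]
    tally["counted"] = len(uniq)

    gene_ids = sorted(lengths)
    idx = {g: i for i, g in enumerate(gene_ids)}
    counts = np.zeros((len(gene_ids), 2), dtype=np.int64)
    for lib_i, lib in enumerate(LIBRARIES):
        sub = uniq[uniq["library"] == lib]
        for est, c in sub.groupby("est_id").size().items():
            counts[idx[str(est)], lib_i] = c
    matrix = CountMatrix(
        gene_ids=gene_ids,
        lengths=np.array([lengths[g] for g in gene_ids], dtype=float),
        counts=counts,
        library_sizes=counts.sum(axis=0).astype(float),
    )
    return matrix, tally


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors, from first principles.

    For each library against the reference library (the one whose upper
    quartile of count proportions is closest to the mean upper quartile):
    per-gene M = log2 ratio of count proportions and A = mean log2 abundance
    are computed over genes positive in both libraries; genes in the upper
    and lower ``trim_m`` tails of M and ``trim_a`` tails of A are discarded;
    the factor is 2 to the precision-weighted mean of the surviving M values,
    with inverse asymptotic (delta-method binomial) variances as weights.
    Factors are rescaled to multiply to 1; effective library size = raw size
    x factor.
    """
    counts = matrix.counts.astype(float)
    sizes = matrix.library_sizes
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("each library needs at least one positive count")
    props = counts / sizes

    q75 = np.array([np.quantile(counts[:, j], 0.75) / sizes[j] for j in range(2)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(2)
    for j in range(2):
        if j == ref:
            continue
        pos = (counts[:, j] > 0) & (counts[:, ref] > 0)
        x, xr = counts[pos, j], counts[pos, ref]
        n, nr = sizes[j], sizes[ref]
        m = np.log2((x / n) / (xr / nr))
        a = 0.5 * np.log2((x / n) * (xr / nr))
        w = (n - x) / (n * x) + (nr - xr) / (nr * xr)
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            continue
        k = m.size
        lo_m, hi_m = np.floor(k * trim_m) + 1, k + 1 - (np.floor(k * trim_m) + 1)
        lo_a, hi_a = np.floor(k * trim_a) + 1, k + 1 - (np.floor(k * trim_a) + 1)
        rm, ra = _rank(m), _rank(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not np.any(keep):
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if np.isfinite(f):
            factors[j] = 2.0 ** f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        method="TMM", factors=factors, effective_sizes=sizes * factors
    )


def rpkm(matrix: CountMatrix) -> np.ndarray:
    """Reads per kilobase of transcript per million mapped reads:
    count x 1e9 / (length_bp x library_size), per gene and library."""
    if np.any(matrix.library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    return matrix.counts * 1e9 / (
        matrix.lengths[:, None] * matrix.library_sizes[None, :]
    )


def scale_rpkm_to_counts(rpkm_values: np.ndarray, total_reads: float) -> np.ndarray:
    """Rescale RPKM values by one global constant so the grand sum equals the
    original both-library read total (count conservation)."""
    s = float(np.sum(rpkm_values))
    if s <= 0:
        raise ValueError("cannot scale an all-zero RPKM matrix")
    return rpkm_values * (total_reads / s)


def binom_exact_test(x1: int, x2: int, n1: float, n2: float) -> float:
    """Exact binomial test of the two-library split of a gene's reads.

    Conditional on the total k = x1 + x2, x1 ~ Binomial(k, n1/(n1+n2)) under
    the null of equal (normalized) expression. Two-sided p sums every point
    probability not exceeding the observed one (minimum-likelihood
    convention, as in SAGE-style count tests). x1 = x2 = 0 is undefined and
    returns 1 with a warning.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x1 == 0 and x2 == 0:
        warnings.warn("binomial test undefined for a zero-zero pair", stacklevel=2)
        return 1.0
    p0 = n1 / (n1 + n2)
    return float(stats.binomtest(int(x1), int(x1 + x2), p0).pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    x_di: float,
    x_ndi: float,
    n_di: float,
    n_ndi: float,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """M = log2((x_DI + c)/N_DI) - log2((x_NDI + c)/N_NDI), c = 0.1.

    Defined even when one count is zero, so genes unique to a treatment keep
    a finite fold-change.
    """
    if n_di <= 0 or n_ndi <= 0:
        raise ValueError("normalized library sizes must be positive")
    return float(
        np.log2((x_di + pseudocount) / n_di) - np.log2((x_ndi + pseudocount) / n_ndi)
    )


def call_de(
    matrix: CountMatrix,
    method: str = "TMM",
    alpha: float = 0.001,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> list[DeResult]:
    """Per-gene DE pipeline for one normalization method.

    TMM: the exact binomial test runs on raw counts with effective library
    sizes = raw sizes x TMM factors. RPKM: per-gene RPKM values are rescaled
    to conserve the two-library read total, rounded to integers (the exact
    test needs integer outcomes), and tested with the rounded per-library
    sums as sizes. Genes with a zero raw count in one library are flagged
    ``unique_to`` that treatment.
    """
    method = method.upper()
    raw = matrix.counts.astype(float)
    total = float(matrix.library_sizes.sum())
    if method == "TMM":
        norm = tmm_factors(matrix, trim_m=trim_m, trim_a=trim_a)
        test_counts = raw
        eff = norm.effective_sizes
    elif method == "RPKM":
        scaled = scale_rpkm_to_counts(rpkm(matrix), total)
        test_counts = np.rint(scaled)
        eff = test_counts.sum(axis=0)
        if np.any(eff <= 0):
            raise ValueError("a library's scaled counts sum to zero")
    else:
        raise ValueError(f"unknown method {method!r}; use 'TMM' or 'RPKM'")

    results: list[DeResult] = []
    pseudo = PSEUDOCOUNT
    for i, gene in enumerate(matrix.gene_ids):
        x1, x2 = test_counts[i]
        p = 1.0 if (x1 == 0 and x2 == 0) else binom_exact_test(x1, x2, eff[0], eff[1])
        m = fold_change(x1, x2, eff[0], eff[1])
        a = 0.5 * (np.log2((x1 + pseudo) / eff[0]) + np.log2((x2 + pseudo) / eff[1]))
        unique = "none"
        if raw[i, 0] == 0 and raw[i, 1] > 0:
            unique = "NDI"
        elif raw[i, 1] == 0 and raw[i, 0] > 0:
            unique = "DI"
        results.append(
            DeResult(
                gene_id=gene,
                count_di=float(raw[i, 0]),
                count_ndi=float(raw[i, 1]),
                M=m,
                A=float(a),
                p_raw=p,
                unique_to=unique,
            )
        )

    adj = bh_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        if pa < alpha and r.M > 0:
            r.call = "DI-up"
        elif pa < alpha and r.M < 0:
            r.call = "NDI-up"
    return results


def de_table(results: Sequence[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "count_DI": [r.count_di for r in results],
            "count_NDI": [r.count_ndi for r in results],
            "M": [r.M for r in results],
            "A": [r.A for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "call": [r.call for r in results],
            "unique_to": [r.unique_to for r in results],
        }
    )
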