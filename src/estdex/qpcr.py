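"""qPCR quantification and cross-platform concordance.

Relative mRNA abundance follows a modified 2^-ddCt scheme: technical
replicates are averaged arithmetically per biological replicate, the
geometric mean Ct of three stably expressed reference genes is subtracted
from each target gene's mean Ct (dCt), and abundance is 2^-dCt. Fold-change
is log2 of the ratio of mean DI to mean NDI abundance. Significance is a
pooled-variance two-sample Student's t-test on the per-replicate abundances,
with Benjamini-Hochberg correction across genes.

Concordance judges the sequencing platform's DE calls against qPCR as the
benchmark: a sequencing positive is a true positive when qPCR confirms
significant DE in the same direction, a false positive when qPCR is not
significant or significant in the opposite direction; a sequencing negative
is a true negative when qPCR is also non-significant, and a false negative
when qPCR finds significance. Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP). Directional consistency is the fraction of a gene category whose
qPCR mean fold-change sign matches the sequencing prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "QpcrResult",
    "ConfusionSummary",
    "load_ct_table",
    "delta_ct",
    "qpcr_fold_change",
    "qpcr_significance",
    "analyze_qpcr",
    "cv_comparison",
    "expression_correlation",
    "concordance",
]

TREATMENTS = ("DI", "NDI")


@dataclass
class QpcrResult:
    gene_id: str
    rel_abundance: dict[str, np.ndarray]   # per-bio-rep 2^-dCt per treatment
    mean_abundance: dict[str, float]
    log2_fc: float
    cv: dict[str, float]
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    degenerate: bool = False


@dataclass
class ConfusionSummary:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def TPR(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else float("nan")

    @property
    def TNR(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else float("nan")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "TPR": self.TPR, "TNR": self.TNR,
        }


def load_ct_table(path) -> pd.DataFrame:
    """Ct CSV with columns gene_id, role (target|reference), treatment
    (DI|NDI), bio_rep, tech_rep, ct."""
    frame = pd.read_csv(str(path))
    required = {"gene_id", "role", "treatment", "bio_rep", "tech_rep", "ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (frame["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return frame


def _mean_ct_per_biorep(sub: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of technical replicates per biological replicate."""
    return sub.groupby("bio_rep")["ct"].mean()


def delta_ct(
    target_ct: pd.DataFrame,
    reference_ct: pd.DataFrame,
    n_references: int = 3,
) -> tuple[pd.Series, pd.Series]:
    """Per-biological-replicate dCt and 2^-dCt for one gene in one treatment.

    ``target_ct`` holds the target gene's rows, ``reference_ct`` the rows of
    all reference genes (same treatment). Technical replicates are averaged
    first; dCt = mean target Ct - geometric mean of the per-reference mean
    Cts.
    """
    refs = reference_ct["gene_id"].unique()
    if len(refs) < n_references:
        raise ValueError(
            f"need {n_references} reference genes, found {len(refs)}: {sorted(refs)}"
        )
    t_mean = _mean_ct_per_biorep(target_ct)
    ref_means = reference_ct.groupby(["gene_id", "bio_rep"])["ct"].mean().unstack(0)
    geo = np.exp(np.log(ref_means).mean(axis=1))
    dct = t_mean - geo.loc[t_mean.index]
    return dct, 2.0 ** (-dct)


def qpcr_fold_change(abundance: Mapping[str, Sequence[float]]) -> float:
    """log2(mean DI abundance / mean NDI abundance)."""
    mean_di = float(np.mean(abundance["DI"]))
    mean_ndi = float(np.mean(abundance["NDI"]))
    if mean_di <= 0 or mean_ndi <= 0:
        raise ValueError("mean abundances must be positive")
    return float(np.log2(mean_di / mean_ndi))


def qpcr_significance(
    abundance: Mapping[str, Sequence[float]], equal_var: bool = True
) -> tuple[float, bool]:
    """Two-sample Student's t-test (pooled variance) on per-replicate
    abundances, DI vs NDI. Returns (p, degenerate): zero within-group
    variance with equal means is degenerate and yields p = 1."""
    a = np.asarray(abundance["DI"], dtype=float)
    b = np.asarray(abundance["NDI"], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 biological replicates per treatment")
    if np.var(a) == 0 and np.var(b) == 0:
        return (1.0, True) if np.mean(a) == np.mean(b) else (0.0, True)
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue), False


def analyze_qpcr(
    ct: pd.DataFrame,
    reference_genes: Optional[Sequence[str]] = None,
    equal_var: bool = True,
) -> list[QpcrResult]:
    """Full qPCR analysis: dCt -> abundance -> fold-change, CV, t-test, BH."""
    if reference_genes is None:
        reference_genes = sorted(ct.loc[ct["role"] == "reference", "gene_id"].unique())
    targets = sorted(
        set(ct.loc[ct["role"] == "target", "gene_id"].unique()) - set(reference_genes)
    )
    results = []
    for gene in targets:
        rel, mean_ab, cv = {}, {}, {}
        for trt in TREATMENTS:
            sub = ct[(ct["treatment"] == trt)]
            tgt = sub[sub["gene_id"] == gene]
            ref = sub[sub["gene_id"].isin(reference_genes)]
            _, ab = delta_ct(tgt, ref, n_references=len(reference_genes))
            vals = ab.to_numpy()
            rel[trt] = vals
            mean_ab[trt] = float(np.mean(vals))
            cv[trt] = float(np.std(vals, ddof=1) / np.mean(vals)) if len(vals) > 1 else 0.0
        p, degen = qpcr_significance(rel, equal_var=equal_var)
        results.append(
            QpcrResult(
                gene_id=gene,
                rel_abundance=rel,
                mean_abundance=mean_ab,
                log2_fc=qpcr_fold_change(rel),
                cv=cv,
                p_raw=p,
                degenerate=degen,
            )
        )
    adj = bh_adjust([r.p_raw for r in results]) if results else []
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    return results


def cv_comparison(results: Sequence[QpcrResult]) -> dict:
    """Paired Student's t-test on per-gene coefficients of variation between
    treatments, with per-treatment medians. CV uses the n-1 sample standard
    deviation and is scale-invariant."""
    if len(results) < 2:
        raise ValueError("need >= 2 genes for a paired CV comparison")
    cv_di = np.array([r.cv["DI"] for r in results])
    cv_ndi = np.array([r.cv["NDI"] for r in results])
    if np.allclose(cv_di, cv_ndi):
        p, degen = 1.0, True
    else:
        p, degen = float(stats.ttest_rel(cv_di, cv_ndi).pvalue), False
    return {
        "median_cv_DI": float(np.median(cv_di)),
        "median_cv_NDI": float(np.median(cv_ndi)),
        "p_paired": p,
        "degenerate": degen,
        "n_genes": len(results),
    }


def expression_correlation(
    platform_expression: Mapping[str, float],
    qpcr_results: Sequence[QpcrResult],
    treatment: str = "DI",
    exclude: Sequence[str] = (),
) -> dict:
    """r^2 of an ordinary least-squares fit of qPCR mean abundance on the
    sequencing platform's expression measure, one treatment at a time.
    ``exclude`` drops named genes (e.g. a paralog-confounded outlier) before
    fitting."""
    pairs = [
        (platform_expression[r.gene_id], r.mean_abundance[treatment])
        for r in qpcr_results
        if r.gene_id not in set(exclude) and r.gene_id in platform_expression
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 genes for a correlation fit")
    x, y = map(np.asarray, zip(*pairs))
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the variables")
    fit = stats.linregress(x, y)
    return {
        "treatment": treatment,
        "r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n_genes": len(pairs),
    }


def concordance(
    de_calls: Mapping[str, int],
    qpcr_results: Sequence[QpcrResult],
    alpha: float = 0.05,
) -> dict:
    """Confusion summary of sequencing DE calls against qPCR.

    ``de_calls`` maps gene -> sign: +1 (DI-up), -1 (NDI-up), 0 (not
    significant); the qPCR side is significant when p_adj < ``alpha``, with
    direction from the sign of its log2 fold-change. Gene universes must
    match.
    """
    qpcr_by_gene = {r.gene_id: r for r in qpcr_results}
    if set(de_calls) != set(qpcr_by_gene):
        raise ValueError("DE and qPCR gene sets differ")
    tp = tn = fp = fn = 0
    consistent: dict[str, list[bool]] = {"DI-up": [], "NDI-up": []}
    for gene, sign in de_calls.items():
        q = qpcr_by_gene[gene]
        q_sig = q.p_adj < alpha
        q_sign = int(np.sign(q.log2_fc))
        if sign != 0:
            if q_sig and q_sign == sign:
                tp += 1
            else:
                fp += 1
            consistent["DI-up" if sign > 0 else "NDI-up"].append(q_sign == sign)
        else:
            if q_sig:
                fn += 1
            else:
                tn += 1
    summary = ConfusionSummary(TP=tp, TN=tn, FP=fp, FN=fn)
    out = summary.to_dict()
    out["directional_consistency"] = {
        cat: (float(np.mean(v)) if v else float("nan")) for cat, v in consistent.items()
    }
    return out
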