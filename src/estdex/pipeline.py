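"""End-to-end orchestration: fixture generation and the full analysis flow.

``make_fixture`` writes a self-contained input directory (reference FASTA +
GFF3, contig FASTA, per-tier hit tables, FASTQ reads with a contaminant hit
table, a count matrix, a Ct table, and the ground-truth manifest).
``run_all`` consumes such a directory and executes
qc -> annotate -> accumulate -> reduce -> de (both normalizations) -> qpcr
-> concordance, emitting one report per stage plus a run-level JSON report.
Every random stage is seeded from the run seed, so a config + seed pair
fully determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation, de, qc, qpcr, reduction, synthetic

__all__ = ["make_fixture", "run_all", "PRESETS"]

PRESETS = {
    # completes in seconds; shapes small enough to eyeball
    "tiny": dict(
        n_genes=40, n_de=6, redundancy_mean=3.0, end_variability=80,
        error_rate=0.01, n_reads=800, total_reads=40_000, skew=1.1,
        n_unique=2, n_no_hit=4, n_chimeric=2, n_qpcr_targets=10,
        defect_rates={"ambiguous": 0.03, "duplicate": 0.03, "low_quality": 0.03,
                      "contaminant": 0.02, "polyat": 0.03, "short": 0.02},
    ),
    # mirrors the study's shape (two libraries, redundancy mean ~8.86,
    # ~10% library skew, a minority of DE genes) at roughly 1/1000 scale
    "paper-like": dict(
        n_genes=300, n_de=30, redundancy_mean=8.86, end_variability=150,
        error_rate=0.02, n_reads=5000, total_reads=150_000, skew=1.1,
        n_unique=5, n_no_hit=20, n_chimeric=5, n_qpcr_targets=30,
        defect_rates={"ambiguous": 0.04, "duplicate": 0.05, "low_quality": 0.04,
                      "contaminant": 0.02, "polyat": 0.05, "short": 0.02},
    ),
}


def _subseed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_fixture(preset: str = "tiny", seed: int = 0, out_dir="fixture") -> Path:
    """Generate a complete synthetic input directory for ``run_all``."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = synthetic.simulate_reference(
        n_genes=p["n_genes"], seed=_subseed(seed, "reference"), n_de=p["n_de"]
    )
    synthetic.write_fasta(truth.sequences, out / "reference.fa")
    synthetic.write_gff3(truth, out / "reference.gff3")

    contigs, tables = synthetic.simulate_redundant_contigs(
        truth,
        redundancy_params={"mean": p["redundancy_mean"]},
        end_variability=p["end_variability"],
        error_rate=p["error_rate"],
        seed=_subseed(seed, "contigs"),
        n_no_hit=p["n_no_hit"],
        n_chimeric=p["n_chimeric"],
    )
    synthetic.write_fasta(contigs, out / "contigs.fa")
    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    for tier, frame in tables.items():
        frame.to_csv(hits_dir / f"{tier}.tsv", sep="\t", header=False, index=False)

    reads, contaminant_hits, manifest = synthetic.simulate_qc_reads(
        truth, defect_rates=p["defect_rates"], seed=_subseed(seed, "reads"),
        n_reads=p["n_reads"],
    )
    qc.write_fastq(reads, out / "reads.fastq")
    contaminant_hits.to_csv(
        out / "contaminant_hits.tsv", sep="\t", header=False, index=False
    )
    (out / "qc_manifest.json").write_text(json.dumps(manifest, indent=1))

    matrix = synthetic.simulate_counts(
        truth, skew=p["skew"], n_unique=p["n_unique"],
        seed=_subseed(seed, "counts"), total_reads=p["total_reads"],
    )
    matrix.to_tsv(out / "counts.tsv")

    rng = np.random.default_rng(_subseed(seed, "qpcr_targets"))
    de_genes = [g for g in truth.gene_ids if truth.de_flags[g]]
    null_genes = [g for g in truth.gene_ids if not truth.de_flags[g]]
    n_null = max(0, p["n_qpcr_targets"] - len(de_genes))
    targets = de_genes[: p["n_qpcr_targets"]] + [
        null_genes[i] for i in sorted(rng.choice(len(null_genes), n_null, replace=False))
    ]
    ct = synthetic.simulate_qpcr(
        truth, seed=_subseed(seed, "qpcr"), target_genes=targets
    )
    ct.to_csv(out / "ct.csv", index=False)

    (out / "manifest.json").write_text(truth.manifest_json())
    (out / "fixture.json").write_text(
        json.dumps({"preset": preset, "seed": seed}, indent=1)
    )
    return out


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_all(
    in_dir,
    out_dir,
    seed: int = 0,
    alpha: float = 0.001,
    skip_qc: bool = False,
    tiers=annotation.DEFAULT_TIERS,
) -> dict:
    """Run every stage on a fixture directory; returns the run report."""
    ind, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "stages": {}}

    # --- QC -------------------------------------------------------------
    if not skip_qc:
        reads = qc.read_fastq(ind / "reads.fastq")
        contam_path = ind / "contaminant_hits.tsv"
        contam = (
            pd.read_csv(contam_path, sep="\t", names=annotation.OUTFMT6_COLUMNS)
            if contam_path.exists() and contam_path.stat().st_size
            else None
        )
        clean, qc_report = qc.run_qc(reads, contaminant_hits=contam)
        qc.write_fastq(clean, out / "clean.fastq")
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=1))
        report["stages"]["qc"] = qc_report.to_dict()

    # --- annotation -----------------------------------------------------
    hits = []
    for tier in tiers:
        path = ind / "hits" / f"{tier.name}.tsv"
        if path.exists() and path.stat().st_size:
            hits.extend(annotation.read_hit_table(path, tier=tier.name))
    contigs = _read_fasta(ind / "contigs.fa")
    assignments, no_hit = annotation.assign_all(hits, tiers, est_ids=sorted(contigs))
    assign_frame = pd.DataFrame(
        {
            "est_id": [a.est_id for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "tier": [a.tier for a in assignments],
            "pident": [a.hit.pct_identity for a in assignments],
            "evalue": [a.hit.evalue for a in assignments],
            "bitscore": [a.hit.bitscore for a in assignments],
            "qstart": [a.hit.qstart for a in assignments],
            "qend": [a.hit.qend for a in assignments],
        }
    )
    assign_frame.to_csv(out / "assignments.tsv", sep="\t", index=False)
    per_tier = assign_frame["tier"].value_counts().to_dict()
    report["stages"]["annotation"] = {
        "assigned": len(assignments),
        "no_hit": len(no_hit),
        "per_tier": per_tier,
    }

    # --- accumulation curve --------------------------------------------
    by_query: dict[str, Optional[str]] = {}
    for a in assignments:
        by_query[a.est_id] = a.gene_id
    read_hits = [(e, by_query.get(e)) for e in sorted(contigs)]
    curve = annotation.accumulation_curve(
        read_hits, n_boot=200, seed=_subseed(seed, "curve")
    )
    pd.DataFrame(
        {"rank": np.arange(1, len(curve) + 1), "mean_cumulative_genes": curve}
    ).to_csv(out / "accumulation.tsv", sep="\t", index=False)
    report["stages"]["accumulation"] = {
        "endpoint": float(curve[-1]) if len(curve) else 0.0
    }

    # --- reduction ------------------------------------------------------
    gff = reduction.read_gff3_mrna_intervals(ind / "reference.gff3")
    trimmed, summary = reduction.reduce_est_set(assignments, contigs, tiers, gff)
    synthetic.write_fasta({t.est_id: t.sequence for t in trimmed}, out / "final.fa")
    report["stages"]["reduction"] = {
        "n_groups": summary.n_groups,
        "n_kept": summary.n_kept,
        "mean_bp_trimmed": summary.mean_bp_trimmed,
        "n50_before": summary.n50_before,
        "n50_after": summary.n50_after,
    }

    # --- differential expression ---------------------------------------
    matrix = de.CountMatrix.from_tsv(ind / "counts.tsv")
    de_results = {}
    for method in ("TMM", "RPKM"):
        results = de.call_de(matrix, method=method, alpha=alpha)
        de.de_table(results).to_csv(out / f"de_{method.lower()}.tsv", sep="\t",
                                    index=False)
        de_results[method] = results
        report["stages"][f"de_{method.lower()}"] = {
            "DI_up": sum(r.call == "DI-up" for r in results),
            "NDI_up": sum(r.call == "NDI-up" for r in results),
            "unique_DI": sum(r.unique_to == "DI" for r in results),
            "unique_NDI": sum(r.unique_to == "NDI" for r in results),
        }

    # --- qPCR and concordance ------------------------------------------
    ct_path = ind / "ct.csv"
    if ct_path.exists():
        ct = qpcr.load_ct_table(ct_path)
        q_results = qpcr.analyze_qpcr(ct)
        pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in q_results],
                "mean_DI": [r.mean_abundance["DI"] for r in q_results],
                "mean_NDI": [r.mean_abundance["NDI"] for r in q_results],
                "log2_fc": [r.log2_fc for r in q_results],
                "cv_DI": [r.cv["DI"] for r in q_results],
                "cv_NDI": [r.cv["NDI"] for r in q_results],
                "p_raw": [r.p_raw for r in q_results],
                "p_adj": [r.p_adj for r in q_results],
            }
        ).to_csv(out / "qpcr.tsv", sep="\t", index=False)
        concord = {}
        target_set = {r.gene_id for r in q_results}
        for method, results in de_results.items():
            calls = {
                r.gene_id: (1 if r.call == "DI-up" else -1 if r.call == "NDI-up" else 0)
                for r in results
                if r.gene_id in target_set
            }
            subset = [r for r in q_results if r.gene_id in calls]
            concord[method] = qpcr.concordance(calls, subset)
        (out / "concordance.json").write_text(json.dumps(concord, indent=1))
        report["stages"]["qpcr"] = {
            "n_targets": len(q_results),
            "cv_comparison": qpcr.cv_comparison(q_results),
        }
        report["stages"]["concordance"] = concord

    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def de_benchmark(seed: int = 0, n_genes: int = 2000, n_de: int = 20,
                 de_log2fc: float = 2.0, skew: float = 1.1,
                 n_qpcr_null: int = 10) -> dict:
    """Parameter-recovery benchmark for the two DE paths and the qPCR stage.

    Generates a seeded dataset (``n_genes`` genes, ``n_de`` planted DE genes
    at |log2FC| = ``de_log2fc`` in the well-measured count range, ~10%
    library-size skew), runs both normalization paths at adjusted p < 0.001,
    and scores recall and false-discovery proportion against the planted
    truth. The qPCR stage runs on the DE genes plus ``n_qpcr_null`` null
    genes; recovery is scored as the absolute z of the estimated vs true
    log2 fold-change, with the standard error taken from the per-replicate
    spread of log2 abundances.
    """
    truth = synthetic.simulate_reference(
        n_genes, seed=_subseed(seed, "bench-ref"), n_de=n_de, de_log2fc=de_log2fc
    )
    matrix = synthetic.simulate_counts(
        truth, skew=skew, seed=_subseed(seed, "bench-counts")
    )
    de_genes = {g for g in truth.gene_ids if truth.de_flags[g]}
    out: dict = {"n_genes": n_genes, "n_de": n_de}
    mean_counts = dict(zip(truth.gene_ids, matrix.counts.mean(axis=1)))
    out["min_de_mean_count"] = float(min(mean_counts[g] for g in de_genes))
    for method in ("TMM", "RPKM"):
        results = de.call_de(matrix, method=method, alpha=0.001)
        called = {r.gene_id for r in results if r.call != "ns"}
        correct_dir = {
            r.gene_id
            for r in results
            if r.call != "ns"
            and r.gene_id in de_genes
            and np.sign(r.M) == np.sign(truth.true_log2_fc[r.gene_id])
        }
        out[method] = {
            "n_called": len(called),
            "recall": len(correct_dir) / n_de,
            "fdp": (len(called) - len(called & de_genes)) / max(len(called), 1),
        }

    rng = np.random.default_rng(_subseed(seed, "bench-qpcr-targets"))
    nulls = [g for g in truth.gene_ids if not truth.de_flags[g]]
    targets = sorted(de_genes) + [
        nulls[i] for i in sorted(rng.choice(len(nulls), n_qpcr_null, replace=False))
    ]
    ct = synthetic.simulate_qpcr(
        truth, seed=_subseed(seed, "bench-qpcr"), target_genes=targets
    )
    q_results = qpcr.analyze_qpcr(ct)
    zs = []
    for r in q_results:
        log_di = np.log2(r.rel_abundance["DI"])
        log_ndi = np.log2(r.rel_abundance["NDI"])
        se = float(
            np.sqrt(np.var(log_di, ddof=1) / len(log_di)
                    + np.var(log_ndi, ddof=1) / len(log_ndi))
        )
        zs.append(abs(r.log2_fc - truth.true_log2_fc[r.gene_id]) / se)
    zs = np.asarray(zs)
    out["qpcr"] = {
        "n_targets": len(q_results),
        "max_abs_z": float(zs.max()),
        "mean_abs_z": float(zs.mean()),
        "frac_within_3se": float(np.mean(zs <= 3.0)),
    }
    return out
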