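"""Representative-EST selection, genomic overlap rule, and homology trimming."""

import numpy as np
import pytest

from estdex import annotation, reduction, synthetic
from estdex.annotation import Assignment, HitRecord, TierConfig
from estdex.qc import compute_n50
from estdex.reduction import (
    GeneGroup,
    genomic_overlap_filter,
    group_by_gene,
    select_representative,
    trim_to_alignment,
)

AEDES_TIER = TierConfig("aaeg_transcripts", "nucleotide", 1e-10, 85.0, 2)
DISTANT_TIER = TierConfig("swissprot", "translated", 1e-3, 0.0, 9)


def member(est, pid, length, gene="g1", tier="aaeg_transcripts"):
    h = HitRecord(est, gene, pid, length, 1, length, 1, length, 1e-30, 100.0, tier)
    return Assignment(est_id=est, gene_id=gene, tier=tier, hit=h)


class TestGrouping:
    def test_partition(self):
        ms = [member("e1", 90, 100), member("e2", 91, 100),
              member("e3", 92, 100, gene="g2")]
        groups = group_by_gene(ms)
        assert sorted(len(g.members) for g in groups) == [1, 2]
        assert sum(len(g.members) for g in groups) == 3

    def test_all_distinct_and_empty(self):
        ms = [member(f"e{i}", 90, 100, gene=f"g{i}") for i in range(4)]
        assert all(len(g.members) == 1 for g in group_by_gene(ms))
        assert group_by_gene([]) == []


class TestSelectRepresentative:
    def test_longest_within_identity_subset(self):
        g = GeneGroup("g1", [member("e1", 90, 300), member("e2", 86, 500),
                            member("e3", 95, 200)], "aaeg_transcripts")
        assert select_representative(g, AEDES_TIER).est_id == "e2"

    def test_fallback_to_highest_identity(self):
        g = GeneGroup("g1", [member("e1", 80, 400), member("e2", 84, 100)],
                      "aaeg_transcripts")
        assert select_representative(g, AEDES_TIER).est_id == "e2"

    def test_singleton(self):
        g = GeneGroup("g1", [member("only", 50, 60)], "aaeg_transcripts")
        assert select_representative(g, AEDES_TIER).est_id == "only"

    def test_no_cutoff_tier_uses_identity(self):
        g = GeneGroup("g1", [member("e1", 70, 400, tier="swissprot"),
                            member("e2", 90, 80, tier="swissprot")], "swissprot")
        assert select_representative(g, DISTANT_TIER).est_id == "e2"

    def test_no_cutoff_tier_length_floor(self):
        # a 40-residue match loses to a longer one despite higher identity
        g = GeneGroup("g1", [member("e1", 95, 40, tier="swissprot"),
                            member("e2", 80, 120, tier="swissprot")], "swissprot")
        assert select_representative(g, DISTANT_TIER).est_id == "e2"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GeneGroup("g1", [], "aaeg_transcripts")

    def test_oracle_equivalence_on_random_groups(self):
        """Exhaustive rule evaluation agrees with the implementation."""
        rng = np.random.default_rng(17)

        def oracle(group, tier):
            cutoff = tier.min_pct_identity_for_selection
            ms = group.members
            if cutoff > 0:
                subset = [m for m in ms if m.hit.pct_identity >= cutoff]
                pool = subset if subset else ms
                best = None
                for m in pool:
                    if subset:
                        key = (m.hit.aln_length, m.hit.pct_identity)
                    else:
                        key = (m.hit.pct_identity,)
                    if best is None or key > best_key or (
                        key == best_key and m.est_id < best.est_id
                    ):
                        best, best_key = m, key
                return best
            pool = [m for m in ms if m.hit.aln_length >= 50] or ms
            best = None
            for m in pool:
                key = (m.hit.pct_identity, m.hit.aln_length)
                if best is None or key > best_key or (
                    key == best_key and m.est_id < best.est_id
                ):
                    best, best_key = m, key
            return best

        for trial in range(500):
            tier = AEDES_TIER if trial % 2 == 0 else DISTANT_TIER
            n = int(rng.integers(1, 9))
            ms = [
                member(
                    f"e{j}",
                    float(rng.integers(60, 101)),
                    int(rng.integers(30, 600)),
                    tier=tier.name,
                )
                for j in range(n)
            ]
            g = GeneGroup("g1", ms, tier.name)
            assert select_representative(g, tier).est_id == oracle(g, tier).est_id


class TestGenomicOverlap:
    def hit_span(self, sstart, send, scaf="scaffold_1"):
        return HitRecord("e1", scaf, 95.0, send - sstart + 1, 1, send - sstart + 1,
                         sstart, send, 1e-30, 100.0, "aaeg_genomic")

    def test_majority_inside(self):
        ann = {"scaffold_1": [(1, 600)]}
        assert genomic_overlap_filter(self.hit_span(1, 1000), ann)

    def test_exact_half_fails(self):
        ann = {"scaffold_1": [(1, 500)]}
        assert not genomic_overlap_filter(self.hit_span(1, 1000), ann)

    def test_fully_inside(self):
        ann = {"scaffold_1": [(100, 5000)]}
        assert genomic_overlap_filter(self.hit_span(200, 300), ann)

    def test_union_of_intervals(self):
        # two mRNAs jointly covering 60% pass even though neither alone does
        ann = {"scaffold_1": [(1, 300), (701, 1000)]}
        assert genomic_overlap_filter(self.hit_span(1, 1000), ann)

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            genomic_overlap_filter(self.hit_span(1, 100), {"scaffold_1": [(50, 10)]})


class TestTrim:
    def test_substring(self):
        h = HitRecord("e1", "g1", 95.0, 50, 11, 60, 1, 50, 1e-30, 90.0, "t")
        seq = "A" * 10 + "C" * 50 + "G" * 40
        t = trim_to_alignment(seq, h)
        assert t.sequence == "C" * 50
        assert t.bp_trimmed == 50
        assert t.trim_span == (11, 60)
        assert t.est_id == "e1_trimmed"

    def test_identity_trim(self):
        h = HitRecord("e1", "g1", 95.0, 100, 1, 100, 1, 100, 1e-30, 90.0, "t")
        t = trim_to_alignment("A" * 100, h)
        assert t.bp_trimmed == 0 and len(t.sequence) == 100

    def test_reversed_coordinates(self):
        fwd = HitRecord("e1", "g1", 95.0, 50, 11, 60, 1, 50, 1e-30, 90.0, "t")
        rev = HitRecord("e1", "g1", 95.0, 50, 60, 11, 50, 1, 1e-30, 90.0, "t")
        seq = "A" * 10 + "C" * 50 + "G" * 40
        assert trim_to_alignment(seq, fwd).sequence == trim_to_alignment(seq, rev).sequence

    def test_out_of_range(self):
        h = HitRecord("e1", "g1", 95.0, 50, 11, 60, 1, 50, 1e-30, 90.0, "t")
        with pytest.raises(ValueError):
            trim_to_alignment("ACGT", h)


class TestReduce:
    def test_one_trimmed_est_per_gene(self, truth30):
        contigs, tables = synthetic.simulate_redundant_contigs(
            truth30, {"mean": 4.0}, end_variability=60, error_rate=0.0, seed=33
        )
        hits = []
        for tier, frame in tables.items():
            hits.extend(annotation.hits_from_frame(frame, tier))
        assignments, _ = annotation.assign_all(hits)
        trimmed, summary = reduction.reduce_est_set(assignments, contigs)
        genes = [t.gene_id for t in trimmed]
        assert len(genes) == len(set(genes)) == summary.n_kept
        for t in trimmed:
            assert t.sequence in contigs[t.source_est_id]
            assert len(t.sequence) >= 50

    def test_redundancy_one_round_trip(self, truth30):
        contigs, tables = synthetic.simulate_redundant_contigs(
            truth30, {"fixed": 1}, end_variability=0, error_rate=0.0, seed=34
        )
        hits = []
        for tier, frame in tables.items():
            hits.extend(annotation.hits_from_frame(frame, tier))
        assignments, _ = annotation.assign_all(hits)
        trimmed, _ = reduction.reduce_est_set(assignments, contigs)
        assert len(trimmed) == len(truth30.gene_ids)
        # with no end variability the trimmed EST is the full gene sequence
        for t in trimmed:
            assert t.sequence == truth30.sequences[t.gene_id]

    def test_n50_cross_module(self, truth30):
        contigs, tables = synthetic.simulate_redundant_contigs(
            truth30, {"mean": 3.0}, end_variability=40, error_rate=0.0, seed=35
        )
        hits = []
        for tier, frame in tables.items():
            hits.extend(annotation.hits_from_frame(frame, tier))
        assignments, _ = annotation.assign_all(hits)
        trimmed, summary = reduction.reduce_est_set(assignments, contigs)
        assert summary.n50_after == compute_n50([len(t.sequence) for t in trimmed])

    def test_short_trimmed_product_dropped(self):
        ms = [member("e1", 99.0, 40)]
        ms[0] = Assignment(
            "e1", "g1", "aaeg_transcripts",
            HitRecord("e1", "g1", 99.0, 40, 1, 40, 1, 40, 1e-30, 70.0,
                      "aaeg_transcripts"),
        )
        trimmed, summary = reduction.reduce_est_set(ms, {"e1": "A" * 120})
        assert trimmed == [] and summary.dropped["g1"] == "trimmed_below_50bp"
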