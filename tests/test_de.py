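"""Normalization, the exact binomial test, BH correction, and DE calling."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from estdex import de, synthetic
from estdex.de import CountMatrix


def matrix_from(counts, lengths=None, sizes=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n)],
        lengths=np.full(n, 500.0) if lengths is None else np.asarray(lengths, float),
        counts=counts,
        library_sizes=counts.sum(axis=0).astype(float) if sizes is None else np.asarray(sizes, float),
    )


class TestUniqueMappingFilter:
    def make_mapping(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "est_id", "pct_identity", "library"])

    def test_multimapper_discarded(self):
        mapping = self.make_mapping(
            [("r1", "e1", 99.0, "DI"), ("r1", "e2", 99.0, "DI"),
             ("r2", "e1", 96.0, "DI")]
        )
        matrix, tally = de.unique_mapping_filter(mapping, {"e1": 100, "e2": 100})
        assert tally["multi_mapped"] == 1
        assert matrix.counts[0, 0] == 1  # only r2 counted

    def test_low_identity_resolves_multimapper(self):
        # the 90% row fails the identity filter first, leaving a unique target
        mapping = self.make_mapping(
            [("r1", "e1", 90.0, "NDI"), ("r1", "e2", 98.0, "NDI")]
        )
        matrix, tally = de.unique_mapping_filter(mapping, {"e1": 100, "e2": 100})
        assert tally["multi_mapped"] == 0
        assert matrix.counts[1, 1] == 1

    def test_all_below_identity(self):
        mapping = self.make_mapping([("r1", "e1", 80.0, "DI")])
        matrix, tally = de.unique_mapping_filter(mapping, {"e1": 100})
        assert tally["low_identity"] == 1 and matrix.counts.sum() == 0


class TestTmm:
    def test_identical_libraries(self):
        counts = np.tile(np.arange(1, 51)[:, None], (1, 2))
        norm = de.tmm_factors(matrix_from(counts))
        assert np.allclose(norm.factors, 1.0)

    def test_pure_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(4)
        c1 = rng.integers(5, 500, size=100)
        counts = np.stack([c1, 2 * c1], axis=1)
        norm = de.tmm_factors(matrix_from(counts))
        # proportions are identical, so the factors stay at 1
        assert np.allclose(norm.factors, 1.0, atol=1e-12)
        assert np.allclose(
            norm.effective_sizes / norm.effective_sizes.sum(),
            counts.sum(0) / counts.sum(),
        )

    def test_one_sided_de_recentered(self):
        """With 20% one-sided DE, non-DE normalized ratios center on 1."""
        rng = np.random.default_rng(12)
        base = rng.integers(50, 400, size=500).astype(float)
        counts = np.stack([base, base], axis=1).astype(np.int64)
        counts[:100, 0] *= 8  # DE genes inflate the DI library only
        norm = de.tmm_factors(matrix_from(counts))
        eff = norm.effective_sizes
        ratios = (counts[100:, 0] / eff[0]) / (counts[100:, 1] / eff[1])
        assert abs(np.median(ratios) - 1.0) < 0.05

    def test_all_zero_library_rejected(self):
        counts = np.stack([np.arange(1, 11), np.zeros(10, int)], axis=1)
        with pytest.raises(ValueError):
            de.tmm_factors(matrix_from(counts, sizes=[55, 1]))

    def test_matches_edger_reference(self, tmp_path):
        """Independent cross-check against the canonical R implementation."""
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(5, 0.01, size=(200, 2)).astype(np.int64)
        counts[:20, 0] *= 4
        norm = de.tmm_factors(matrix_from(counts))
        path = tmp_path / "counts.txt"
        np.savetxt(path, counts, fmt="%d")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(edgeR))
            x <- matrix(scan("{path}", quiet=TRUE), ncol=2, byrow=TRUE)
            f <- calcNormFactors(x, method="TMM")
            cat(sprintf("%.12f %.12f", f[1], f[2]))
            """
        )
        try:
            res = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
            )
        except FileNotFoundError:
            pytest.skip("Rscript unavailable")
        assert res.returncode == 0, res.stderr
        expected = np.array([float(x) for x in res.stdout.split()])
        assert np.allclose(norm.factors, expected, atol=1e-8)


class TestRpkm:
    def test_unit_cases(self):
        m = matrix_from([[10, 0]], lengths=[1000], sizes=[1_000_000, 1_000_000])
        vals = de.rpkm(m)
        assert vals[0, 0] == pytest.approx(10.0)
        assert vals[0, 1] == 0.0

    def test_formula(self):
        m = matrix_from([[7, 7]], lengths=[350], sizes=[2_000_000, 2_000_000])
        assert de.rpkm(m)[0, 0] == pytest.approx(10.0)

    def test_scaling_conservation(self):
        rng = np.random.default_rng(6)
        vals = rng.gamma(2.0, 50.0, size=(300, 2))
        scaled = de.scale_rpkm_to_counts(vals, 123_456.0)
        assert abs(scaled.sum() - 123_456.0) / 123_456.0 < 1e-12

    def test_scaling_examples(self):
        vals = np.array([[200.0, 300.0]])
        assert np.allclose(de.scale_rpkm_to_counts(vals, 1000.0), [[400.0, 600.0]])
        assert np.allclose(de.scale_rpkm_to_counts(vals, 500.0), vals)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            de.scale_rpkm_to_counts(np.zeros((3, 2)), 100.0)


class TestBinomExact:
    def test_modal_outcome(self):
        assert de.binom_exact_test(3, 3, 1e6, 1e6) == pytest.approx(1.0)

    def test_five_zero_enumeration(self):
        # pmf of Binomial(5, 1/2): only j=0 and j=5 are as extreme -> 2/32
        assert de.binom_exact_test(5, 0, 1e6, 1e6) == pytest.approx(0.0625)

    def test_zero_zero_flagged(self):
        with pytest.warns(UserWarning):
            assert de.binom_exact_test(0, 0, 1e6, 1e6) == 1.0

    @given(
        st.integers(0, 30),
        st.integers(0, 30),
        st.floats(0.2, 5.0),
    )
    def test_symmetry(self, x1, x2, ratio):
        if x1 == 0 and x2 == 0:
            return
        n2 = 1e6
        n1 = ratio * n2
        assert de.binom_exact_test(x1, x2, n1, n2) == pytest.approx(
            de.binom_exact_test(x2, x1, n2, n1), rel=1e-9
        )


class TestBhAdjust:
    def test_single(self):
        assert de.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_hand_computed(self):
        # step-up: min over j>=i of p_(j) * m / j -> all 0.04
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_hand_computed_mixed(self):
        got = de.bh_adjust([0.005, 0.04, 0.03, 0.9])
        assert np.allclose(got, [0.02, 0.0533333333, 0.0533333333, 0.9])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40))
    def test_monotone_in_raw_order(self, ps):
        adj = de.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFoldChange:
    def test_equal_is_zero(self):
        assert de.fold_change(10, 10, 1e6, 1e6) == 0.0

    def test_unique_gene_value(self):
        assert de.fold_change(10, 0, 1e6, 1e6) == pytest.approx(np.log2(101.0))

    @given(st.integers(0, 1000), st.integers(0, 1000),
           st.floats(1e4, 1e7), st.floats(1e4, 1e7))
    def test_antisymmetry(self, x1, x2, n1, n2):
        assert de.fold_change(x1, x2, n1, n2) == pytest.approx(
            -de.fold_change(x2, x1, n2, n1), abs=1e-9
        )


class TestCallDe:
    def test_all_equal_no_calls(self):
        counts = np.tile(np.arange(10, 110)[:, None], (1, 2))
        for method in ("TMM", "RPKM"):
            results = de.call_de(matrix_from(counts), method=method)
            assert all(r.call == "ns" for r in results)

    def test_null_calibration(self):
        """Raw p-values under the null are conservative-to-uniform."""
        truth = synthetic.simulate_reference(800, seed=51)
        matrix = synthetic.simulate_counts(truth, skew=1.2, seed=52,
                                           total_reads=200_000)
        results = de.call_de(matrix, method="TMM")
        frac = np.mean([r.p_raw < 0.05 for r in results])
        # exact-test conservatism keeps the rate at or below nominal + noise
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(results))
        assert all(r.call == "ns" for r in results)

    def test_recovery_and_direction(self):
        truth = synthetic.simulate_reference(600, seed=61, n_de=12)
        matrix = synthetic.simulate_counts(truth, skew=1.1, seed=62,
                                           total_reads=300_000)
        de_genes = {g for g in truth.gene_ids if truth.de_flags[g]}
        for method in ("TMM", "RPKM"):
            results = de.call_de(matrix, method=method)
            called = {r.gene_id: r for r in results if r.call != "ns"}
            recalled = de_genes & set(called)
            assert len(recalled) / len(de_genes) >= 0.8
            for g in recalled:
                want = "DI-up" if truth.true_log2_fc[g] > 0 else "NDI-up"
                assert called[g].call == want

    def test_sign_matches_call(self):
        rng = np.random.default_rng(71)
        counts = rng.integers(0, 500, size=(200, 2))
        counts[0] = [400, 3]
        for r in de.call_de(matrix_from(counts), method="TMM"):
            if r.call == "DI-up":
                assert r.M > 0
            elif r.call == "NDI-up":
                assert r.M < 0

    def test_unique_flags(self):
        counts = np.array([[50, 0], [0, 50], [20, 20]])
        results = de.call_de(matrix_from(counts), method="TMM")
        assert [r.unique_to for r in results] == ["DI", "NDI", "none"]

    def test_matrix_tsv_round_trip(self, tmp_path):
        m = matrix_from([[5, 8], [100, 90]], lengths=[200, 900], sizes=[400, 500])
        path = tmp_path / "counts.tsv"
        m.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        assert back.gene_ids == m.gene_ids
        assert np.array_equal(back.counts, m.counts)
        assert np.allclose(back.library_sizes, m.library_sizes)
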