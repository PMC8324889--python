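"""Shuffle nulls, Fisher enrichment, and length-stratified fold-change bins."""

import numpy as np
import pytest
from scipy import stats

from milseq.enrich import (
    geneset_host_enrichment,
    length_stratified_foldchange,
    rbp_overlap_enrichment,
    shuffle_intervals,
)
from milseq.synth import TruthParams, gen_annotation, gen_rbp_peaks
from milseq.types import GenomicInterval

from test_mil import fisher_two_sided_brute


def iv(start, end, chrom="chr1", strand="+", name=""):
    return GenomicInterval(chrom, start, end, strand, name)


class TestShuffleIntervals:
    def test_no_freedom_reproduces_query(self):
        q = [iv(100, 300, name="q")]
        assert shuffle_intervals(q, [iv(100, 300)], rng=5) == q

    def test_lengths_and_chromosomes_preserved(self):
        rng = np.random.default_rng(0)
        query = []
        for i in range(50):
            chrom = "chr1" if i % 2 else "chr2"
            s = int(rng.integers(0, 5000))
            query.append(iv(s, s + int(rng.integers(10, 400)), chrom, "+", f"q{i}"))
        universe = [iv(0, 10_000, "chr1"), iv(0, 10_000, "chr2")]
        for seed in range(20):
            shuffled = shuffle_intervals(query, universe, rng=seed)
            for a, b in zip(query, shuffled):
                assert len(a) == len(b)
                assert a.chrom == b.chrom
                assert a.strand == b.strand

    def test_oversized_query_rejected(self):
        with pytest.raises(ValueError, match="fits no universe"):
            shuffle_intervals([iv(0, 5000)], [iv(0, 100)], rng=0)

    def test_uniform_placement_chi_square(self):
        """Start positions over a single 10 kb universe pass uniformity at alpha=0.01."""
        universe = [iv(0, 10_000)]
        q = [iv(0, 100, name="q")]
        rng = np.random.default_rng(123)
        starts = [shuffle_intervals(q, universe, rng)[0].start for _ in range(3000)]
        counts, _ = np.histogram(starts, bins=10, range=(0, 10_000 - 100 + 1))
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestRbpOverlapEnrichment:
    def _l1_world(self, seed, q_meth, q_bg):
        params = TruthParams(seed=seed)
        genes, l1s, truth = gen_annotation(params)
        rbp = gen_rbp_peaks(
            l1s, truth, q_meth=q_meth, q_bg=q_bg, n_bg_peaks=100, genes=genes,
            seed=seed,
        )
        meth = truth[truth.is_methylated]
        m6a_peaks = [
            iv(int(r.start), int(r.end), r.chrom, r.strand, r.l1_id)
            for r in meth.itertuples()
        ]
        universe = [g.body for g in genes]
        return m6a_peaks, rbp, universe

    def test_enrichment_detected_in_most_seeds(self):
        """At the scale the test is used (hundreds of peaks), q_meth = 0.8 vs
        q_bg = 0.05 is significant at alpha = 1e-4 in >= 95% of seeds."""
        import pandas as pd

        from milseq.types import GeneModel, L1Element

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            body = iv(0, 5_000_000, name="host")
            gene = GeneModel("host", GenomicInterval("chr1", 0, 5_000_000, "+", "host"))
            l1s = [
                L1Element(iv(20_000 * i, 20_000 * i + 1000, name=f"L1_{i:04d}"), "L1HS", 1.0)
                for i in range(200)
            ]
            truth = pd.DataFrame(
                {"l1_id": [x.name for x in l1s], "is_methylated": True}
            )
            rbp = gen_rbp_peaks(
                l1s, truth, q_meth=0.8, q_bg=0.05, n_bg_peaks=100, genes=[gene],
                seed=seed,
            )
            query = [x.interval for x in l1s]
            res = rbp_overlap_enrichment(query, rbp, [body], n_shuffles=50, seed=seed)
            hits += res.p_value < 1e-4
        assert hits >= int(0.95 * n_seeds)

    def test_null_not_significant_in_most_seeds(self):
        clean = total = 0
        for seed in range(20):
            m6a, rbp, universe = self._l1_world(seed, q_meth=0.05, q_bg=0.05)
            if len(m6a) < 3:
                continue
            res = rbp_overlap_enrichment(m6a, rbp, universe, n_shuffles=50, seed=seed)
            total += 1
            clean += res.p_permutation > 0.05
        assert clean / total >= 0.9

    def test_fisher_table_matches_oracle(self):
        # constructed so observed=80 of 100 while shuffles expect ~20
        rng = np.random.default_rng(3)
        universe = [iv(0, 1_000_000)]
        query = []
        for i in range(100):
            if i < 80:
                s = int(rng.integers(0, 180_000))  # inside the RBP-covered 20%
            else:
                s = int(rng.integers(200_000, 980_000))
            query.append(iv(s, s + 100, name=f"q{i}"))
        rbp = [iv(0, 200_000, name="rbp")]
        res = rbp_overlap_enrichment(query, rbp, universe, n_shuffles=200, seed=0)
        assert res.observed_overlap == 80
        exp = int(round(res.expected_overlap))
        assert res.p_value == pytest.approx(
            fisher_two_sided_brute(80, 20, exp, 100 - exp), rel=1e-8
        )
        assert res.odds_ratio > 10

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            rbp_overlap_enrichment([], [iv(0, 10)], [iv(0, 100)])


class TestGenesetEnrichment:
    def test_expected_and_oracle_p(self):
        bg = [f"g{i}" for i in range(1000)]
        hosts = bg[:100]
        gene_set = bg[80:130]  # overlap with hosts = 20
        res = geneset_host_enrichment(hosts, gene_set, bg)
        assert res.observed_overlap == 20
        assert res.expected_overlap == pytest.approx(50 * 100 / 1000)
        assert res.p_value == pytest.approx(
            fisher_two_sided_brute(20, 80, 30, 870), rel=1e-8
        )

    def test_overlap_at_expected_rate_is_null(self):
        bg = [f"g{i}" for i in range(1000)]
        hosts = bg[:100]
        gene_set = bg[90:190]  # 10 of 100 hosts, matching the 10% base rate
        res = geneset_host_enrichment(hosts, gene_set, bg)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.15)
        assert res.p_value > 0.5

    def test_disjoint_set_zero_odds(self):
        bg = [f"g{i}" for i in range(500)]
        res = geneset_host_enrichment(bg[:100], bg[200:300], bg)
        assert res.observed_overlap == 0
        assert res.odds_ratio == 0.0
        assert res.p_value == pytest.approx(
            fisher_two_sided_brute(0, 100, 100, 300), rel=1e-8
        )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            geneset_host_enrichment(["a"], ["a"], [])


class TestLengthStratifiedFoldchange:
    def test_bin_sizes_differ_by_at_most_one(self):
        for n in (5, 7, 23, 104):
            rng = np.random.default_rng(n)
            bins, _ = length_stratified_foldchange(
                rng.uniform(1e3, 1e6, n), rng.normal(size=n), n_groups=5
            )
            assert bins.n.sum() == n
            assert bins.n.max() - bins.n.min() <= 1
            # remainder goes to the longest bins
            assert bins.n.is_monotonic_increasing

    def test_zero_foldchange_everywhere(self):
        bins, reg = length_stratified_foldchange(
            np.linspace(1e3, 1e5, 50), np.zeros(50)
        )
        assert np.allclose(bins.mean_log2fc, 0)
        assert reg["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_signal_recovers_slope(self):
        """fc = -standardized log10(length): OLS slope equals -1/sd(log10 L)."""
        rng = np.random.default_rng(1)
        lengths = rng.uniform(1e3, 1e6, 200)
        x = np.log10(lengths)
        fc = -(x - x.mean()) / x.std()
        _, reg = length_stratified_foldchange(lengths, fc)
        assert reg["slope"] == pytest.approx(-1 / x.std(), rel=1e-9)
        # closed-form OLS oracle
        beta = np.sum((x - x.mean()) * (fc - fc.mean())) / np.sum((x - x.mean()) ** 2)
        assert reg["slope"] == pytest.approx(beta, rel=1e-9)

    def test_length_scaled_suppression_gives_monotone_bins(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lengths = 10 ** rng.uniform(4, 6, 150)
            fc = -0.8 * (np.log10(lengths) - 4) + rng.normal(0, 0.3, 150)
            bins, _ = length_stratified_foldchange(lengths, fc)
            hits += bins.mean_log2fc.is_monotonic_decreasing
        assert hits >= 9

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            length_stratified_foldchange([1e3, 1e4], [0.0, 0.1], n_groups=5)
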