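"""MIL classification, orientation bias, Super-MIL ranking, host assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from milseq.mil import (
    assign_host_genes,
    call_mils,
    orientation_bias_test,
    rank_super_mils,
    super_cutoff,
)
from milseq.quant import compute_fpkm
from milseq.synth import TruthParams, gen_annotation
from milseq.types import (
    GeneModel,
    GenomicInterval,
    L1Element,
    MILRecord,
    Peak,
    QuantRow,
)

from conftest import make_track

# ---------------------------------------------------------------------------
# Fisher oracle


def fisher_two_sided_brute(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over one margin."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logpmf(k):
        return (
            math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1) - math.lgamma(r2 - c1 + k + 1)
            + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(logpmf(a))
    total = 0.0
    for k in range(lo, hi + 1):
        pk = math.exp(logpmf(k))
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestFisherOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_scipy_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 250, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_brute(a, b, c, d), rel=1e-8)


# ---------------------------------------------------------------------------
# orientation bias


def mk_orient(n_sense, n_anti):
    return ["sense"] * n_sense + ["antisense"] * n_anti


class TestOrientationBias:
    def test_odds_ratio_worked_example(self):
        res = orientation_bias_test(mk_orient(90, 10), mk_orient(90 + 1000, 10 + 2000))
        assert res.odds_ratio == pytest.approx(18.0)
        assert res.p_value == pytest.approx(
            fisher_two_sided_brute(90, 10, 1000, 2000), rel=1e-8
        )

    def test_identical_proportions_null(self):
        res = orientation_bias_test(mk_orient(10, 20), mk_orient(40, 80))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_expected_counts_use_background_fraction(self):
        res = orientation_bias_test(mk_orient(30, 0), mk_orient(40, 80))
        assert res.expected_sense == pytest.approx(30 * (40 / 120))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            orientation_bias_test([], mk_orient(1, 1))

    def test_power_on_synthetic_truth(self):
        """Methylation drawn only among sense L1s drives a strong orientation
        bias: significant at alpha = 0.01 in >= 95% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            _, _, truth = gen_annotation(TruthParams(seed=seed))
            mils = list(truth.orientation[truth.is_methylated])
            bg = list(truth.orientation)
            res = orientation_bias_test(mils, bg)
            hits += res.p_value < 0.01
        assert hits >= math.ceil(0.95 * n_seeds)


# ---------------------------------------------------------------------------
# Super-MIL ranking


def supermil_oracle(levels, window=5):
    """Exhaustive scan: slope at every index, min |slope-1|, tie -> highest rank;
    Super = elements strictly above the cutoff point."""
    lv = sorted(levels)
    n = len(lv)
    span = lv[-1] - lv[0]
    if span <= 0:
        return n - 1, []
    x = [i / (n - 1) for i in range(n)]
    y = [(v - lv[0]) / span for v in lv]
    h = max(window // 2, 1)
    best_i, best_d = None, None
    for i in range(n):
        lo, hi = max(i - h, 0), min(i + h, n - 1)
        slope = (y[hi] - y[lo]) / (x[hi] - x[lo])
        d = abs(slope - 1.0)
        if best_d is None or d <= best_d:  # ties break toward the highest rank
            best_i, best_d = i, d
    return best_i, [v for v in lv if v > lv[best_i]]


def mk_mils(levels):
    out = []
    for i, lv in enumerate(levels):
        iv = GenomicInterval("chr1", 1000 * i + 10, 1000 * i + 510, "+", f"L1_{i}")
        out.append(
            MILRecord(
                L1Element(iv, "L1HS", 1.0),
                "gene0",
                "sense",
                tt_fpkm=1.0,
                meth_level=float(lv),
                n_peaks=1,
                mil_class="typical",
            )
        )
    return out


class TestSuperMils:
    def test_single_outlier_is_sole_super(self):
        ranked, cutoff, supers = rank_super_mils(mk_mils([1, 1, 1, 1, 1, 100]))
        assert [m.meth_level for m in supers] == [100]
        assert supers[0].mil_class == "super"

    def test_linear_ramp_yields_empty_super_set(self):
        ranked, cutoff, supers = rank_super_mils(mk_mils(list(np.linspace(1, 2, 50))))
        assert supers == []

    def test_constant_levels_empty_super(self):
        ranked, cutoff, supers = rank_super_mils(mk_mils([2.0] * 10))
        assert supers == []

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False, width=32), min_size=3, max_size=200)
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_exhaustive_oracle(self, levels):
        mils = mk_mils(levels)
        ranked, cutoff, supers = rank_super_mils(mils)
        o_cut, o_supers = supermil_oracle(levels)
        assert cutoff == o_cut
        assert [m.meth_level for m in supers] == pytest.approx(o_supers)

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_super_set_is_suffix_of_ranking(self, levels):
        ranked, cutoff, supers = rank_super_mils(mk_mils(levels))
        k = len(supers)
        assert supers == ranked[len(ranked) - k :] if k else supers == []

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            rank_super_mils(mk_mils([1, 2]))


# ---------------------------------------------------------------------------
# call_mils filters and partition


def _scenario():
    body = GenomicInterval("chr1", 0, 50_000, "+", "geneA")
    exons = [
        GenomicInterval("chr1", 0, 300, "+"),
        GenomicInterval("chr1", 49_700, 50_000, "+"),
    ]
    gene = GeneModel("geneA", body, exons)

    def l1(name, start, length, strand="+"):
        return L1Element(
            GenomicInterval("chr1", start, start + length, strand, name), "L1HS", 1.0
        )

    l1s = [
        l1("short", 1000, 150),        # fails length filter
        l1("weak", 3000, 1000),        # fails expression filter (see coverage)
        l1("hit", 10_000, 2000),       # MIL
        l1("quiet", 20_000, 2000),     # control: no peak
        l1("exonic", 49_600, 300),     # straddles an exon: not intronic
    ]
    segs = [(300, 2000, 1.0), (4000, 49_700, 1.0)]  # hole over "weak"
    tt = make_track("TT", "+", "chr1", segs, 1e6)
    mint = make_track("MINT", "+", "chr1", segs, 1e6)
    peaks = [Peak(GenomicInterval("chr1", 10_500, 10_700, "+", "pk"), 5, 1e-9, 1e-6)]
    return gene, l1s, tt, mint, peaks


class TestCallMils:
    def test_filters_and_classes(self):
        gene, l1s, tt, mint, peaks = _scenario()
        tt_rows = compute_fpkm(tt, l1s)
        mint_rows = compute_fpkm(mint, l1s)
        recs = call_mils(l1s, [gene], tt_rows, mint_rows, peaks)
        by_id = {r.l1_id: r for r in recs}
        assert set(by_id) == {"hit", "quiet"}
        assert by_id["hit"].mil_class == "typical" and by_id["hit"].n_peaks == 1
        assert by_id["quiet"].mil_class == "control"

    def test_peak_on_other_strand_ignored(self):
        gene, l1s, tt, mint, peaks = _scenario()
        flipped = [Peak(GenomicInterval("chr1", 10_500, 10_700, "-", "pk"), 5, 1e-9, 1e-6)]
        recs = call_mils(l1s, [gene], compute_fpkm(tt, l1s), compute_fpkm(mint, l1s), flipped)
        assert all(r.mil_class == "control" for r in recs)

    def test_partition_on_synthetic_dataset(self, mil_results, dataset):
        mils, _ = mil_results
        classes = {m.mil_class for m in mils}
        assert classes <= {"super", "typical", "control"}
        mil_ids = {m.l1_id for m in mils if m.mil_class != "control"}
        ctl_ids = {m.l1_id for m in mils if m.mil_class == "control"}
        assert not (mil_ids & ctl_ids)


class TestAssignHostGenes:
    def test_mil_host_excluded_from_control_hosts(self):
        gene, l1s, tt, mint, peaks = _scenario()
        recs = call_mils(l1s, [gene], compute_fpkm(tt, l1s), compute_fpkm(mint, l1s), peaks)
        host_map, control_hosts = assign_host_genes(recs, [gene])
        assert host_map["hit"] == ["geneA"]
        assert control_hosts == []  # geneA hosts a MIL, so it cannot be a control host

    def test_control_only_gene_is_control_host(self):
        gene, l1s, tt, mint, _ = _scenario()
        recs = call_mils(l1s, [gene], compute_fpkm(tt, l1s), compute_fpkm(mint, l1s), [])
        _, control_hosts = assign_host_genes(recs, [gene])
        assert control_hosts == ["geneA"]

    def test_nested_genes_both_listed_as_hosts(self):
        outer = GeneModel(
            "outer",
            GenomicInterval("chr1", 0, 30_000, "+", "outer"),
            [GenomicInterval("chr1", 0, 200, "+"), GenomicInterval("chr1", 29_800, 30_000, "+")],
        )
        inner = GeneModel(
            "inner",
            GenomicInterval("chr1", 5_000, 20_000, "+", "inner"),
            [GenomicInterval("chr1", 5_000, 5_200, "+"), GenomicInterval("chr1", 19_800, 20_000, "+")],
        )
        l1 = L1Element(GenomicInterval("chr1", 10_000, 11_000, "+", "L1x"), "L1HS", 1.0)
        tt = make_track("TT", "+", "chr1", [(0, 30_000, 1.0)], 1e6)
        recs = call_mils([l1], [outer, inner], compute_fpkm(tt, [l1]), compute_fpkm(tt, [l1]), [])
        assert sorted(r.host_gene_id for r in recs) == ["inner", "outer"]
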