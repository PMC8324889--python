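"""Shuffle-based overlap enrichment, gene-set host enrichment, and
length-stratified fold-change summaries.

The shuffle null keeps each query interval's chromosome and length and
re-places it uniformly at random within the universe (by default the
transcribed regions, so the null respects where signal can exist at all).
Enrichment is tested two ways: a Fisher's exact test of observed vs the
rounded expected count — mirroring the observed-vs-expected construction of
the original analysis — and an empirical permutation p from the shuffles
themselves, which is the statistically cleaner companion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import as_interval, interval_overlap
from .types import GenomicInterval


@dataclass
class EnrichmentResult:
    observed_overlap: int
    expected_overlap: float
    odds_ratio: float
    p_value: float
    n_shuffles: int = 0
    p_permutation: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")
        if self.expected_overlap < 0:
            raise ValueError("expected_overlap must be >= 0")


def shuffle_intervals(
    query: Sequence,
    universe: Sequence,
    rng: Union[int, np.random.Generator] = 0,
) -> List[GenomicInterval]:
    """Re-place each query interval uniformly inside the universe.

    Placement is uniform over every valid start position across the universe
    intervals of the query's chromosome; lengths, chromosomes, names and
    strands are preserved, and self-overlap among shuffled intervals is not
    prevented. Raises when a query is longer than every universe interval on
    its chromosome.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for u in universe:
        iv = as_interval(u)
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for qrec in query:
        q = as_interval(qrec)
        qlen = len(q)
        slots = [
            (u.start, len(u) - qlen + 1)
            for u in by_chrom.get(q.chrom, [])
            if len(u) >= qlen
        ]
        if not slots:
            raise ValueError(
                f"query {q.name or q.chrom} ({qlen} bp) fits no universe "
                f"interval on {q.chrom}"
            )
        totals = np.array([n for _, n in slots])
        cums = np.cumsum(totals)
        pick = int(rng.integers(0, cums[-1]))
        idx = int(np.searchsorted(cums, pick, side="right"))
        offset = pick - (int(cums[idx]) - int(totals[idx]))
        start = slots[idx][0] + offset
        out.append(GenomicInterval(q.chrom, start, start + qlen, q.strand, q.name))
    return out


def _n_overlapping(query: Sequence, targets: Sequence, same_strand: bool) -> int:
    hits = interval_overlap(list(query), list(targets), same_strand=same_strand)
    return len({id(x) for x, _, _ in hits})


def rbp_overlap_enrichment(
    query_peaks: Sequence,
    rbp_peaks: Sequence,
    universe: Sequence,
    n_shuffles: int = 100,
    seed: int = 0,
    same_strand: bool = False,
) -> EnrichmentResult:
    """Observed vs shuffle-expected count of query peaks hit by >= 1 RBP peak.

    The Fisher 2x2 compares [observed hit, observed miss] against
    [round(expected), N - round(expected)]; ``p_permutation`` is the fraction
    of shuffles reaching the observed count (add-one corrected).
    """
    if not query_peaks or not rbp_peaks:
        raise ValueError("query and RBP peak lists must be non-empty")
    if not universe:
        raise ValueError("universe must be non-empty")
    n = len(query_peaks)
    observed = _n_overlapping(query_peaks, rbp_peaks, same_strand)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        shuffled = shuffle_intervals(query_peaks, universe, rng)
        null_counts[i] = _n_overlapping(shuffled, rbp_peaks, same_strand)
    expected = float(null_counts.mean())
    exp_int = int(round(expected))
    table = np.array([[observed, n - observed], [exp_int, n - exp_int]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    p_perm = (1 + int((null_counts >= observed).sum())) / (n_shuffles + 1)
    return EnrichmentResult(
        observed_overlap=observed,
        expected_overlap=expected,
        odds_ratio=float(odds),
        p_value=float(p),
        n_shuffles=n_shuffles,
        p_permutation=p_perm,
    )


def geneset_host_enrichment(
    host_genes: Sequence[str],
    gene_set: Sequence[str],
    background: Sequence[str],
) -> EnrichmentResult:
    """Fisher's exact test of gene-set membership among host genes.

    All sets are intersected with the expressed-gene background first; the
    expected overlap assumes every background gene is equally likely to be a
    host: |set ∩ bg| x |hosts| / |bg|.
    """
    bg: Set[str] = set(background)
    if not bg:
        raise ValueError("background gene list must be non-empty")
    hosts = set(host_genes) & bg
    gset = set(gene_set) & bg
    a = len(hosts & gset)
    b = len(hosts - gset)
    c = len(gset - hosts)
    d = len(bg) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    expected = len(gset) * len(hosts) / len(bg)
    return EnrichmentResult(
        observed_overlap=a,
        expected_overlap=expected,
        odds_ratio=float(odds),
        p_value=float(p),
    )


def length_stratified_foldchange(
    gene_lengths: Sequence[float],
    log2fc: Sequence[float],
    n_groups: int = 5,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Equal-count length bins of fold changes plus an OLS trend on log10(length).

    Genes are sorted by length and split into ``n_groups`` equal-count bins
    (remainders go to the longest bins, so sizes differ by at most 1); each
    bin reports its mean log2 fold change with a t-based 95% CI. The
    regression fits log2fc on log10(length) and returns the slope with its
    95% CI.
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    fc = np.asarray(log2fc, dtype=float)
    keep = np.isfinite(lengths) & np.isfinite(fc)
    lengths, fc = lengths[keep], fc[keep]
    n = len(lengths)
    if n < n_groups:
        raise ValueError(f"need >= {n_groups} genes with finite values, got {n}")
    order = np.argsort(lengths, kind="stable")
    lengths, fc = lengths[order], fc[order]
    base, rem = divmod(n, n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    rows = []
    pos = 0
    for i, size in enumerate(sizes):
        grp = fc[pos : pos + size]
        glen = lengths[pos : pos + size]
        pos += size
        mean = float(grp.mean())
        if size > 1 and grp.std(ddof=1) > 0:
            lo, hi = stats.t.interval(
                0.95, df=size - 1, loc=mean, scale=stats.sem(grp)
            )
        else:
            lo = hi = mean
        rows.append(
            {
                "bin": i + 1,
                "n": size,
                "median_length": float(np.median(glen)),
                "mean_log2fc": mean,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    x = np.log10(lengths)
    res = stats.linregress(x, fc)
    # two-sided 95% CI on the slope from the standard error
    tcrit = stats.t.ppf(0.975, df=n - 2) if n > 2 else np.nan
    regression = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_ci_low": float(res.slope - tcrit * res.stderr) if n > 2 else np.nan,
        "slope_ci_high": float(res.slope + tcrit * res.stderr) if n > 2 else np.nan,
        "r_value": float(res.rvalue),
        "p_value": float(res.pvalue),
    }
    return pd.DataFrame(rows), regression
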