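"""Synthetic data with recorded ground truth.

Generates a toy two-chromosome genome carrying genes with intronic LINE-1s, the
matching TT-Seq / MINT-Seq / RNA-Seq coverage, dual spike-in count tables, RBP
peak sets and L1-like sequences. Every stochastic choice is a pure function of
(params, seed), and a truth table records per-L1 methylation, orientation,
blocking and stability so downstream callers can be scored against it.

The generative model mirrors what the analysis assumes about real nascent-RNA
data rather than the data itself: TT-Seq coverage is flat across a gene body
(stepping down by a blocking factor downstream of blocking L1s), MINT-Seq is
the TT rate multiplied by an enrichment factor inside methylated L1s, and
RNA-Seq keeps exons while decaying introns except where methylated L1 RNA is
stabilised. Counts are Poisson by default; a negative-binomial toggle adds
overdispersion for robustness checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CoverageTrack, GeneModel, GenomicInterval, L1Element

logger = logging.getLogger(__name__)

YOUNG_SUBFAMILIES = ("L1HS", "L1PA2", "L1PA3")
OLD_SUBFAMILIES = ("L1PA4", "L1PA7", "L1PB1", "L1MA4", "L1MB7")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


@dataclass
class TruthParams:
    """Study conditions for the synthetic genome.

    ``sense_fraction`` defaults to 1/3, matching the roughly 1:2
    sense:antisense orientation ratio of intronic L1s; methylation, blocking
    and stabilisation are drawn only for sense L1s.
    """

    n_genes: int = 30
    gene_length_bounds: Tuple[int, int] = (30_000, 300_000)  # log-uniform, bp
    exon_fraction: float = 0.08
    l1_per_gene_mean: float = 2.0
    l1_length_bounds: Tuple[int, int] = (500, 6_000)
    sense_fraction: float = 1.0 / 3.0
    meth_fraction: float = 0.5
    enrichment_e: float = 8.0     # MINT/TT rate multiplier inside methylated L1s
    blocking_b: float = 0.5       # downstream coverage multiplier per blocking L1
    stability_s: float = 3.0      # RNA/TT multiplier inside methylated L1s
    intron_decay: float = 0.05    # RNA-Seq intron rate relative to the gene rate
    depth: float = 2_000_000      # fragments per assay
    rate_bounds: Tuple[float, float] = (0.2, 5.0)  # log-uniform per-gene rates
    capture_p: float = 0.9        # IP capture prob. of a methylated spike molecule
    background_p: float = 0.05    # IP capture prob. of a non-methylated molecule
    spike_depth: float = 100_000  # input fragments per spike-in group
    spike_ip_scale: float = 1.0   # global IP library scale applied to all spikes
    dispersion: Optional[float] = None  # NB overdispersion; None = Poisson
    bin_nt: int = 50
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 8_000_000}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.blocking_b <= 1):
            raise ValueError("blocking_b must be in (0, 1]")
        if self.enrichment_e < 1:
            raise ValueError("enrichment_e must be >= 1")
        for name in ("sense_fraction", "meth_fraction", "exon_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.capture_p <= self.background_p:
            raise ValueError("capture_p must exceed background_p")
        if sum(self.chrom_sizes.values()) > 20_000_000:
            raise ValueError("toy genome limited to 20 Mb")


PRESETS: Dict[str, dict] = {
    "small": {"n_genes": 8, "depth": 300_000, "gene_length_bounds": (20_000, 100_000)},
    "medium": {},
}


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    params: TruthParams,
) -> Tuple[List[GeneModel], List[L1Element], pd.DataFrame]:
    """Place non-overlapping genes and fully-intronic L1s; return them with the truth table."""
    rng = _rng(params.seed, 1)
    lo, hi = params.gene_length_bounds
    chroms = list(params.chrom_sizes)
    cursors = {c: 10_000 for c in chroms}

    genes: List[GeneModel] = []
    for i in range(params.n_genes):
        length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        gap = int(rng.integers(5_000, 50_000))
        placed = False
        for c in sorted(chroms, key=lambda c: cursors[c]):
            start = cursors[c] + gap
            if start + length + 10_000 <= params.chrom_sizes[c]:
                strand = "+" if rng.random() < 0.5 else "-"
                body = GenomicInterval(c, start, start + length, strand, f"gene{i:03d}")
                genes.append(_build_gene(body, params))
                cursors[c] = start + length
                placed = True
                break
        if not placed:
            logger.warning("genome full after %d genes", len(genes))
            break

    l1s: List[L1Element] = []
    rows = []
    counter = 0
    for gene in genes:
        n_l1 = int(rng.poisson(params.l1_per_gene_mean))
        occupied: List[Tuple[int, int]] = []
        for _ in range(n_l1):
            l1_len = int(rng.uniform(*params.l1_length_bounds))
            spot = _place_in_intron(gene, l1_len, occupied, rng)
            if spot is None:
                logger.info("gene %s too crowded for a %d bp L1", gene.gene_id, l1_len)
                continue
            occupied.append(spot)
            start, end = spot
            sense = rng.random() < params.sense_fraction
            strand = gene.strand if sense else ("-" if gene.strand == "+" else "+")
            is_meth = bool(sense and rng.random() < params.meth_fraction)
            if is_meth:
                subfam = str(rng.choice(YOUNG_SUBFAMILIES))
                diverg = float(rng.uniform(0.2, 3.0))
            else:
                subfam = str(rng.choice(OLD_SUBFAMILIES))
                diverg = float(rng.uniform(5.0, 25.0))
            l1_id = f"L1_{counter:04d}"
            counter += 1
            iv = GenomicInterval(gene.body.chrom, start, end, strand, l1_id)
            l1s.append(L1Element(iv, subfam, diverg, is_full_length=l1_len >= 5_500))
            rows.append(
                {
                    "l1_id": l1_id,
                    "chrom": iv.chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "host_gene": gene.gene_id,
                    "orientation": "sense" if sense else "antisense",
                    "is_methylated": is_meth,
                    "enrichment_e": params.enrichment_e if is_meth else 1.0,
                    "blocking_b": params.blocking_b if is_meth else 1.0,
                    "stability_s": params.stability_s if is_meth else 1.0,
                    "subfamily": subfam,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "l1_id", "chrom", "start", "end", "strand", "host_gene", "orientation",
            "is_methylated", "enrichment_e", "blocking_b", "stability_s", "subfamily",
        ],
    )
    return genes, l1s, truth


def _build_gene(body: GenomicInterval, params: TruthParams) -> GeneModel:
    """Terminal 300 bp exons plus at most 8 evenly spaced internal exons.

    Capping the internal exon count keeps introns tens of kb long, as in the
    long genes that host intronic L1s, while the total exonic share still
    tracks ``exon_fraction``.
    """
    L = len(body)
    terminal = min(300, L // 4)
    target_internal = max(0.0, params.exon_fraction * L - 2 * terminal)
    n_internal = min(8, int(round(target_internal / 150)))
    exons = [GenomicInterval(body.chrom, body.start, body.start + terminal, body.strand)]
    if n_internal > 0:
        exon_len = max(150, int(target_internal / n_internal))
        inner_lo = body.start + terminal
        inner_hi = body.end - terminal
        anchors = np.linspace(inner_lo, inner_hi, n_internal + 2)[1:-1]
        for a in anchors:
            s = int(a)
            exons.append(
                GenomicInterval(body.chrom, s, min(s + exon_len, inner_hi), body.strand)
            )
    exons.append(GenomicInterval(body.chrom, body.end - terminal, body.end, body.strand))
    return GeneModel(gene_id=body.name, body=body, exons=exons)


def _place_in_intron(gene, l1_len, occupied, rng, margin=100, tries=10):
    introns = [i for i in gene.introns if len(i) >= l1_len + 2 * margin]
    if not introns:
        return None
    weights = np.array([len(i) for i in introns], dtype=float)
    for _ in range(tries):
        intr = introns[rng.choice(len(introns), p=weights / weights.sum())]
        start = int(rng.integers(intr.start + margin, intr.end - margin - l1_len + 1))
        end = start + l1_len
        if all(end <= s or start >= e for s, e in occupied):
            return (start, end)
    return None


# ---------------------------------------------------------------------------
# coverage


def expected_rate_segments(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    params: TruthParams,
    assay: str,
) -> Dict[Tuple[str, str], List[Tuple[int, int, float]]]:
    """Unnormalised expected per-base rates as (start, end, rate) segments.

    Keyed by (chrom, strand). This is the closed-form expectation downstream
    rate checks compare simulated coverage against; rates are relative and are
    rescaled to the assay depth at sampling time.
    """
    rng = _rng(params.seed, 2)
    r_lo, r_hi = params.rate_bounds
    gene_rate = {
        g.gene_id: float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi)))) for g in genes
    }
    out: Dict[Tuple[str, str], List[Tuple[int, int, float]]] = {}
    for gene in genes:
        t = truth[truth.host_gene == gene.gene_id] if len(truth) else truth
        meth = t[t.is_methylated] if len(t) else t
        cuts = {gene.body.start, gene.body.end}
        if len(meth):
            if gene.strand == "+":
                cuts.update(int(x) for x in meth.end[meth.blocking_b < 1.0])
            else:
                cuts.update(int(x) for x in meth.start[meth.blocking_b < 1.0])
            cuts.update(int(x) for x in meth.start)
            cuts.update(int(x) for x in meth.end)
        if assay == "RNA":
            for ex in gene.exons:
                cuts.update((ex.start, ex.end))
        edges = sorted(cuts)
        segs = out.setdefault((gene.body.chrom, gene.strand), [])
        for a, b in zip(edges[:-1], edges[1:]):
            mid = (a + b) / 2
            rate = gene_rate[gene.gene_id]
            if assay in ("TT", "MINT"):
                if len(meth):
                    for _, m in meth.iterrows():
                        three_prime_passed = (
                            mid >= m.end if gene.strand == "+" else mid < m.start
                        )
                        if m.blocking_b < 1.0 and three_prime_passed:
                            rate *= m.blocking_b
                        if assay == "MINT" and m.start <= mid < m.end:
                            rate *= m.enrichment_e
            else:  # RNA
                exonic = any(ex.start <= mid < ex.end for ex in gene.exons)
                if not exonic:
                    rate *= params.intron_decay
                    if len(meth):
                        for _, m in meth.iterrows():
                            if m.start <= mid < m.end:
                                rate *= m.stability_s
            segs.append((a, b, rate))
    return out


def _sample_counts(rng, mean: np.ndarray, dispersion: Optional[float]) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    return rng.negative_binomial(n, p)


def gen_coverage_tracks(
    genes: Sequence[GeneModel],
    l1s: Sequence[L1Element],
    truth: pd.DataFrame,
    params: TruthParams,
) -> Dict[str, Tuple[CoverageTrack, CoverageTrack]]:
    """Sample stranded TT/MINT/RNA coverage; returns {assay: (plus, minus)}."""
    if params.depth <= 0:
        raise ValueError("depth must be > 0")
    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]] = {}
    for k, assay in enumerate(("TT", "MINT", "RNA")):
        rng = _rng(params.seed, 10 + k)
        rate_segs = expected_rate_segments(genes, truth, params, assay)
        total_expected = sum(
            (b - a) * r for segs in rate_segs.values() for a, b, r in segs
        )
        if total_expected <= 0:
            raise ValueError("no transcribed sequence to cover")
        scale = params.depth / total_expected
        by_strand: Dict[str, Dict[str, list]] = {"+": {}, "-": {}}
        total_reads = 0.0
        for (chrom, strand), segs in sorted(rate_segs.items()):
            store = by_strand[strand].setdefault(chrom, [])
            for a, b, r in segs:
                edges = np.arange(a, b, params.bin_nt)
                starts = edges
                ends = np.minimum(edges + params.bin_nt, b)
                widths = ends - starts
                counts = _sample_counts(rng, scale * r * widths, params.dispersion)
                total_reads += counts.sum()
                nz = counts > 0
                store.extend(zip(starts[nz], ends[nz], counts[nz] / widths[nz]))
        lib = max(total_reads, 1.0)
        pair = []
        for strand in ("+", "-"):
            segs = {
                c: tuple(np.array(x) for x in zip(*rows))
                for c, rows in by_strand[strand].items()
                if rows
            }
            pair.append(
                CoverageTrack(assay, strand, segs, lib, chroms=params.chrom_sizes)
            )
        tracks[assay] = (pair[0], pair[1])
    return tracks


# ---------------------------------------------------------------------------
# spike-ins

SPIKE_GROUP_LEVELS = {1: 0.0, 2: 25.0, 3: 50.0, 4: 75.0, 5: 100.0}


def gen_spikein_counts(
    params: TruthParams, n_species_per_group: int = 4, n_ercc: int = 92
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the dual spike-in count tables.

    m6A spike-ins: five groups mixed non-methylated:methylated at
    1:0, 3:1, 1:1, 1:3 and 0:1 (0/25/50/75/100% methylated); the IP read
    expectation per species is abundance x per-molecule capture probability
    ``frac * capture_p + (1 - frac) * background_p`` x the IP library scale.
    ERCC species are present identically in both libraries up to that same
    global scale.
    """
    rng = _rng(params.seed, 3)
    rows = []
    for g, level in SPIKE_GROUP_LEVELS.items():
        frac = level / 100.0
        p_mol = frac * params.capture_p + (1 - frac) * params.background_p
        for j in range(n_species_per_group):
            abundance = (
                params.spike_depth / n_species_per_group * rng.lognormal(0.0, 0.2)
            )
            rows.append(
                {
                    "species": f"MS{(g - 1) * n_species_per_group + j + 1:02d}",
                    "group": g,
                    "expected_level": level,
                    "input_reads": int(rng.poisson(abundance)),
                    "ip_reads": int(
                        rng.poisson(abundance * p_mol * params.spike_ip_scale)
                    ),
                }
            )
    m6a = pd.DataFrame(rows)
    ab = np.exp(rng.uniform(np.log(100.0), np.log(30_000.0), size=n_ercc))
    ercc = pd.DataFrame(
        {
            "species": [f"ERCC-{i + 1:05d}" for i in range(n_ercc)],
            "input_reads": rng.poisson(ab),
            "ip_reads": rng.poisson(ab * params.spike_ip_scale),
        }
    )
    return m6a, ercc


# ---------------------------------------------------------------------------
# RBP peaks


def gen_rbp_peaks(
    l1s: Sequence[L1Element],
    truth: pd.DataFrame,
    q_meth: float = 0.8,
    q_bg: float = 0.05,
    n_bg_peaks: int = 200,
    genes: Optional[Sequence[GeneModel]] = None,
    peak_width: int = 200,
    seed: int = 0,
) -> List[GenomicInterval]:
    """RBP binding peaks hitting methylated L1s with probability ``q_meth``.

    Non-methylated L1s are hit with probability ``q_bg``; ``n_bg_peaks``
    further background peaks fall uniformly over transcribed gene bodies.
    """
    if q_meth < q_bg:
        raise ValueError("q_meth must be >= q_bg")
    rng = _rng(seed, 4)
    meth_ids = set(truth.l1_id[truth.is_methylated]) if len(truth) else set()
    peaks: List[GenomicInterval] = []
    k = 0
    for l1 in l1s:
        p = q_meth if l1.name in meth_ids else q_bg
        if rng.random() < p:
            iv = l1.interval
            w = min(peak_width, len(iv))
            start = int(rng.integers(iv.start, iv.end - w + 1))
            peaks.append(
                GenomicInterval(iv.chrom, start, start + w, iv.strand, f"rbp{k:04d}")
            )
            k += 1
    if n_bg_peaks and genes:
        lens = np.array([g.length_bp for g in genes], dtype=float)
        for _ in range(n_bg_peaks):
            g = genes[int(rng.choice(len(genes), p=lens / lens.sum()))]
            w = min(peak_width, g.length_bp)
            start = int(rng.integers(g.body.start, g.body.end - w + 1))
            peaks.append(
                GenomicInterval(g.body.chrom, start, start + w, g.strand, f"rbp{k:04d}")
            )
            k += 1
    return peaks


# ---------------------------------------------------------------------------
# sequences


def gen_l1_sequences(
    n: int,
    length: int,
    rrach_per_100nt: float,
    seed: int = 0,
    background_alphabet: str = "ACGT",
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Random sequences with RRACH motifs planted at spaced positions.

    Returns (sequences, true counts); the true count is recomputed by an
    exhaustive scan, so accidental background matches are included.
    """
    from .motif import count_rrach  # local import: motif depends on nothing here

    n_plant = int(round(rrach_per_100nt * length / 100.0))
    slots = length // 5
    if n_plant > slots:
        raise ValueError(
            f"cannot place {n_plant} non-overlapping motifs in {length} nt"
        )
    rng = _rng(seed, 5)
    seqs: Dict[str, str] = {}
    counts: Dict[str, int] = {}
    bg = np.array(list(background_alphabet))
    for i in range(n):
        arr = rng.choice(bg, size=length)
        if n_plant:
            chosen = rng.choice(slots, size=n_plant, replace=False)
            for slot in chosen:
                pos = slot * 5
                motif = [
                    rng.choice(["A", "G"]),
                    rng.choice(["A", "G"]),
                    "A",
                    "C",
                    rng.choice(["A", "C", "T"]),
                ]
                arr[pos : pos + 5] = motif
        name = f"seq{i:03d}"
        seq = "".join(arr)
        seqs[name] = seq
        counts[name] = count_rrach(seq).total_count
    return seqs, counts


# ---------------------------------------------------------------------------
# single-gene construction (used by index-recovery experiments)


def single_gene_annotation(
    gene_length: int = 100_000,
    l1_length: int = 6_000,
    strand: str = "+",
    chrom: str = "chr1",
    offset: int = 10_000,
    l1_center: Optional[int] = None,
    is_methylated: bool = True,
    params: Optional[TruthParams] = None,
) -> Tuple[List[GeneModel], List[L1Element], pd.DataFrame]:
    """One gene hosting one centred sense intronic L1, with a matching truth table."""
    params = params or TruthParams()
    body = GenomicInterval(chrom, offset, offset + gene_length, strand, "gene000")
    exons = [
        GenomicInterval(chrom, body.start, body.start + 300, strand),
        GenomicInterval(chrom, body.end - 300, body.end, strand),
    ]
    gene = GeneModel("gene000", body, exons)
    center = l1_center if l1_center is not None else offset + gene_length // 2
    start = center - l1_length // 2
    iv = GenomicInterval(chrom, start, start + l1_length, strand, "L1_0000")
    l1 = L1Element(iv, "L1HS", 0.5, is_full_length=l1_length >= 5_500)
    truth = pd.DataFrame(
        [
            {
                "l1_id": "L1_0000",
                "chrom": chrom,
                "start": start,
                "end": start + l1_length,
                "strand": strand,
                "host_gene": "gene000",
                "orientation": "sense",
                "is_methylated": is_methylated,
                "enrichment_e": params.enrichment_e if is_methylated else 1.0,
                "blocking_b": params.blocking_b if is_methylated else 1.0,
                "stability_s": params.stability_s if is_methylated else 1.0,
                "subfamily": "L1HS",
            }
        ]
    )
    return [gene], [l1], truth
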