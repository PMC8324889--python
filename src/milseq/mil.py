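"""MIL calling, orientation-bias testing, Super-MIL ranking, and host-gene maps.

A MIL (m6A-methylated intronic L1) is a transcribed intronic L1
(TT FPKM > 0.1, length > 200 bp, fully contained in an intron) that overlaps
at least one m6A peak on its own strand. Expressed intronic L1s passing the
same filters but with no peak become Control L1s. Super-MILs are the high
tail of the ranked methylation-level curve, cut where the min-max-scaled
curve's slope is closest to 1 — the ranking strategy used for
super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import interval_overlap, is_intronic, orientation_to
from .quant import RatioConfig, methylation_level
from .types import GeneModel, L1Element, MILRecord, Peak, QuantRow

logger = logging.getLogger(__name__)


def call_mils(
    l1s: Sequence[L1Element],
    genes: Sequence[GeneModel],
    tt_quant: Mapping[str, QuantRow],
    mint_quant: Mapping[str, QuantRow],
    peaks: Sequence[Peak],
    fpkm_min: float = 0.1,
    len_min: int = 200,
    min_overlap_bp: int = 1,
    cfg: Optional[RatioConfig] = None,
) -> List[MILRecord]:
    """Classify expressed intronic L1s into MILs (typical) and Control L1s.

    One record is emitted per (L1, host gene) pair; L1s failing the intronic,
    length or expression filters are excluded entirely. Peak overlap is
    same-strand, >= ``min_overlap_bp`` bases. Super-MILs are assigned
    afterwards by :func:`rank_super_mils`.
    """
    cfg = cfg or RatioConfig()
    peak_hits = {
        id(x): 0 for x in l1s
    }
    for x, _, _ in interval_overlap(
        list(l1s), list(peaks), same_strand=True, min_bp=min_overlap_bp
    ):
        peak_hits[id(x)] += 1
    out: List[MILRecord] = []
    for l1 in l1s:
        if len(l1.interval) <= len_min:
            continue
        tt = tt_quant.get(l1.name)
        mint = mint_quant.get(l1.name)
        if tt is None or mint is None or tt.fpkm <= fpkm_min:
            continue
        hosts = [g for g in genes if is_intronic(l1, g)]
        if not hosts:
            continue
        n_peaks = peak_hits[id(l1)]
        level = methylation_level(mint, tt, cfg)
        for gene in hosts:
            out.append(
                MILRecord(
                    l1=l1,
                    host_gene_id=gene.gene_id,
                    orientation=orientation_to(l1, gene),
                    tt_fpkm=tt.fpkm,
                    meth_level=level,
                    n_peaks=n_peaks,
                    mil_class="typical" if n_peaks >= 1 else "control",
                )
            )
    return out


@dataclass
class OrientationBias:
    mil_sense: int
    mil_antisense: int
    background_sense: int
    background_antisense: int
    expected_sense: float
    expected_antisense: float
    odds_ratio: float
    p_value: float


def _orientation(x) -> str:
    if isinstance(x, str):
        return x
    return x.orientation


def orientation_bias_test(
    mils: Sequence, all_intronic: Sequence
) -> OrientationBias:
    """Fisher's exact test of MIL orientation against all intronic L1s.

    The 2x2 table is [MIL sense, MIL antisense; non-MIL sense, non-MIL
    antisense]; expected counts scale the MIL total by the background sense
    fraction. Accepts records bearing an ``orientation`` attribute or plain
    "sense"/"antisense" strings.
    """
    if not mils or not all_intronic:
        raise ValueError("both MIL and background lists must be non-empty")
    mil_s = sum(1 for x in mils if _orientation(x) == "sense")
    mil_a = len(mils) - mil_s
    bg_s = sum(1 for x in all_intronic if _orientation(x) == "sense")
    bg_a = len(all_intronic) - bg_s
    non_s = max(bg_s - mil_s, 0)
    non_a = max(bg_a - mil_a, 0)
    table = np.array([[mil_s, mil_a], [non_s, non_a]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("orientation table has an empty margin; p undefined")
        odds, p = float("nan"), float("nan")
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    frac_sense = bg_s / (bg_s + bg_a)
    return OrientationBias(
        mil_s, mil_a, bg_s, bg_a,
        expected_sense=len(mils) * frac_sense,
        expected_antisense=len(mils) * (1 - frac_sense),
        odds_ratio=float(odds),
        p_value=float(p),
    )


def super_cutoff(levels: np.ndarray, window: int = 5) -> Tuple[int, np.ndarray]:
    """Cutoff index on ascending ``levels`` where the scaled curve's slope is nearest 1.

    Both axes are min-max scaled to [0, 1]; the discrete slope at rank i is a
    central difference over a ``window``-rank smoothing span. Ties on
    |slope - 1| break toward the highest rank. Returns (cutoff_index, slopes).
    """
    n = len(levels)
    if n < 3:
        raise ValueError("need >= 3 levels to locate a cutoff")
    span = levels[-1] - levels[0]
    if span <= 0:
        return n - 1, np.full(n, np.nan)
    x = np.arange(n) / (n - 1)
    y = (levels - levels[0]) / span
    h = max(window // 2, 1)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h, n - 1)
    slopes = (y[hi] - y[lo]) / (x[hi] - x[lo])
    dist = np.abs(slopes - 1.0)
    # argmin of |slope-1| with ties broken toward the highest rank
    cutoff = int(n - 1 - np.argmin(dist[::-1]))
    return cutoff, slopes


def rank_super_mils(
    mils: Sequence[MILRecord], window: int = 5
) -> Tuple[List[MILRecord], int, List[MILRecord]]:
    """Rank MILs by methylation level and promote the high tail to Super-MILs.

    Only peak-overlapping records (class != control) enter the ranking.
    Returns (ranked ascending, cutoff index, super list); records strictly
    above the cutoff point — higher rank and methylation level strictly
    greater than the cutoff's — get ``mil_class = "super"``, so the Super set
    is always a suffix of the ranking. A constant curve yields an empty
    Super set.
    """
    cands = [m for m in mils if m.mil_class != "control" and np.isfinite(m.meth_level)]
    if len(cands) < 3:
        raise ValueError("need >= 3 MILs with finite levels")
    ranked = sorted(cands, key=lambda m: m.meth_level)
    levels = np.array([m.meth_level for m in ranked])
    if levels[-1] - levels[0] <= 0:
        logger.warning("constant methylation levels; Super-MIL set empty")
        return ranked, len(ranked) - 1, []
    cutoff, _ = super_cutoff(levels, window=window)
    supers = [m for m in ranked[cutoff + 1 :] if m.meth_level > levels[cutoff]]
    for m in supers:
        m.mil_class = "super"
    return ranked, cutoff, supers


def assign_host_genes(
    mils: Sequence[MILRecord], genes: Sequence[GeneModel]
) -> Tuple[Dict[str, List[str]], List[str]]:
    """Host map (l1_id -> gene ids) and the Control-L1 host gene list.

    A gene qualifies as a Control-L1 host only if it hosts at least one
    Control L1 and no MIL: MIL-hosting genes are excluded even when they also
    contain Control L1s.
    """
    host_map: Dict[str, List[str]] = {}
    mil_hosts = set()
    control_hosts = set()
    for rec in mils:
        host_map.setdefault(rec.l1_id, []).append(rec.host_gene_id)
        if rec.mil_class in ("super", "typical"):
            mil_hosts.add(rec.host_gene_id)
        elif rec.mil_class == "control":
            control_hosts.add(rec.host_gene_id)
    return host_map, sorted(control_hosts - mil_hosts)
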