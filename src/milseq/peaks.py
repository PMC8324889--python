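"""Window-based IP-vs-input peak calling and the observed/expected peak-class table.

This caller is a deliberately simple, documented stand-in for a full MACS-style
model: sliding windows, a one-sided Poisson upper-tail test of the IP count
against the library-scaled input count (floored at ``lambda_min``), BH
correction across all windows of a strand, and merging of significant windows.
Externally produced peak BEDs are accepted interchangeably everywhere peaks
are consumed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import as_interval, interval_overlap
from .types import CoverageTrack, GenomicInterval, Peak


def call_peaks_window(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    window: int = 100,
    step: int = 50,
    q_max: float = 0.01,
    merge_gap: int = 100,
    min_len: int = 100,
    lambda_min: float = 1.0,
    local_lambda_nt: int = 1000,
) -> List[Peak]:
    """Call IP-enriched peaks on one strand.

    Per window, the expected IP count is the input count scaled by the ratio
    of library sizes; to damp the Poisson noise of the input itself, the
    input rate is also estimated over a ``local_lambda_nt`` window centred on
    the test window and the larger of the two estimates is used, floored at
    ``lambda_min``. The p-value is the Poisson upper tail P(X >= observed).
    Windows with q <= ``q_max`` (BH across all windows of the strand) are
    merged when separated by at most ``merge_gap`` bases, and merged peaks
    shorter than ``min_len`` are dropped. The fold enrichment of a merged
    peak is total observed / total expected.
    """
    if ip.strand != input_track.strand:
        raise ValueError(
            f"strand mismatch: IP is {ip.strand}, input is {input_track.strand}"
        )
    lib_ratio = ip.library_size / input_track.library_size
    chroms = sorted(set(ip.covered_chroms()) | set(input_track.covered_chroms()))
    recs = []
    for chrom in chroms:
        extents = []
        for t in (ip, input_track):
            if chrom in t.covered_chroms():
                extents.append(t.extent(chrom))
        lo = min(e[0] for e in extents)
        hi = max(e[1] for e in extents)
        starts = np.arange(lo, hi, step, dtype=np.int64)
        ends = np.minimum(starts + window, hi)
        obs = np.round(ip.query_many(chrom, starts, ends))
        lam_win = input_track.query_many(chrom, starts, ends)
        pad = max((local_lambda_nt - window) // 2, 0)
        lam_local = input_track.query_many(chrom, starts - pad, ends + pad) * (
            (ends - starts) / (ends - starts + 2 * pad)
        )
        lam = np.maximum(np.maximum(lam_win, lam_local) * lib_ratio, lambda_min)
        p = stats.poisson.sf(obs - 1, lam)  # P(X >= obs); obs = 0 -> p = 1
        recs.append((chrom, starts, ends, obs, lam, p))
    if not recs:
        return []
    all_p = np.concatenate([r[5] for r in recs])
    _, all_q, _, _ = multipletests(all_p, method="fdr_bh")
    peaks: List[Peak] = []
    offset = 0
    for chrom, starts, ends, obs, lam, p in recs:
        q = all_q[offset : offset + len(p)]
        offset += len(p)
        sig = q <= q_max
        peaks.extend(
            _merge_windows(
                chrom, ip.strand, starts[sig], ends[sig], obs[sig], lam[sig],
                p[sig], q[sig], merge_gap, min_len,
            )
        )
    return peaks


def _merge_windows(chrom, strand, starts, ends, obs, lam, p, q, merge_gap, min_len):
    out: List[Peak] = []
    if len(starts) == 0:
        return out
    order = np.argsort(starts)
    starts, ends, obs, lam, p, q = (a[order] for a in (starts, ends, obs, lam, p, q))
    i = 0
    k = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and starts[j + 1] - ends[j] <= merge_gap:
            j += 1
        s, e = int(starts[i]), int(max(ends[i : j + 1]))
        if e - s >= min_len:
            tot_obs = float(obs[i : j + 1].sum())
            tot_lam = float(lam[i : j + 1].sum())
            out.append(
                Peak(
                    GenomicInterval(chrom, s, e, strand, f"peak_{chrom}_{strand}{k}"),
                    fold_enrichment=tot_obs / tot_lam if tot_lam > 0 else 0.0,
                    p_value=float(p[i : j + 1].min()),
                    q_value=float(q[i : j + 1].min()),
                )
            )
            k += 1
        i = j + 1
    return out


def expected_peak_distribution(
    peaks: Sequence[Peak],
    classes: Dict[str, Sequence[GenomicInterval]],
    priority: Sequence[str],
    tt_tracks: Sequence[CoverageTrack],
) -> pd.DataFrame:
    """Observed vs expected peak counts per region class.

    Under the null that any transcribed region has an equal chance of holding
    a peak, the expected count of class c is
    ``N_peaks x (TT reads in c / total TT reads over all classes)``.
    Peaks overlapping several classes are assigned to the first class in
    ``priority`` order.
    """
    missing = set(classes) - set(priority)
    if missing:
        raise ValueError(f"classes missing from priority order: {missing}")
    observed = {c: 0 for c in priority}
    assigned = set()
    for cls in priority:
        hits = interval_overlap(list(peaks), list(classes[cls]))
        for x, _, _ in hits:
            key = id(x)
            if key not in assigned:
                assigned.add(key)
                observed[cls] += 1
    reads = {}
    for cls in priority:
        total = 0.0
        for iv in classes[cls]:
            for t in tt_tracks:
                total += t.query(iv.chrom, iv.start, iv.end)
        reads[cls] = total
    grand = sum(reads.values())
    if grand <= 0:
        raise ValueError("no TT reads in any class")
    n = len(peaks)
    return pd.DataFrame(
        {
            "class": list(priority),
            "observed": [observed[c] for c in priority],
            "expected": [n * reads[c] / grand for c in priority],
            "tt_reads": [reads[c] for c in priority],
        }
    )
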