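"""The Transcription Blocking Index (TBI) and its differential statistics.

For a sense-oriented intronic L1, the upstream flank runs from the host
gene's TSS-side boundary to the L1 end nearest the TSS and the downstream
flank from the L1 end nearest the TES to the TES, both in the transcription
direction (for minus-strand genes "upstream" is the higher-coordinate flank).
TBI = downstream-flank TT-Seq FPKM / upstream-flank TT-Seq FPKM: a value near
1 means elongation passes the L1 unimpeded, values below 1 mean the L1
blocks transcription. Records are invalid (no value) when a flank is shorter
than ``min_flank`` or the upstream FPKM falls below an expression floor —
both validity guards of this implementation.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import as_interval, is_intronic
from .types import CoverageTrack, GeneModel, L1Element, MILRecord, TBIRecord

logger = logging.getLogger(__name__)


def _flank_fpkm(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    reads = track.query(chrom, start, end)
    return reads / ((end - start) / 1000.0 * track.library_size_millions)


def compute_tbi(
    l1: Union[L1Element, MILRecord],
    gene: GeneModel,
    tt: CoverageTrack,
    min_flank: int = 500,
    floor_fpkm: float = 0.1,
    tes_override: Optional[int] = None,
) -> TBIRecord:
    """TBI of one sense intronic L1 within its host gene.

    ``tt`` must be the TT-Seq track on the gene's strand. ``tes_override``
    replaces the annotated TES-side boundary (exclusive end for + genes,
    start for - genes) for genes whose annotation mixes isoforms.
    """
    if isinstance(l1, MILRecord):
        element = l1.l1
    else:
        element = l1
    iv = element.interval
    if iv.strand != gene.strand:
        raise ValueError(
            f"L1 {iv.name!r} is antisense to {gene.gene_id}; TBI is defined "
            "only for sense-oriented intronic L1s"
        )
    if not is_intronic(element, gene):
        raise ValueError(f"L1 {iv.name!r} is not intronic in {gene.gene_id}")
    if tt.strand != gene.strand:
        raise ValueError("TT track strand must match the gene strand")
    body = gene.body
    if gene.strand == "+":
        tes_bound = tes_override if tes_override is not None else body.end
        up = (body.start, iv.start)     # TSS .. L1 5' end
        down = (iv.end, tes_bound)      # L1 3' end .. TES
    else:
        tes_bound = tes_override if tes_override is not None else body.start
        up = (iv.end, body.end)         # L1 5' end .. TSS (higher coordinates)
        down = (tes_bound, iv.start)    # TES .. L1 3' end
    up_len = up[1] - up[0]
    down_len = down[1] - down[0]
    up_fpkm = _flank_fpkm(tt, body.chrom, *up) if up_len > 0 else 0.0
    down_fpkm = _flank_fpkm(tt, body.chrom, *down) if down_len > 0 else 0.0
    valid = (
        up_len >= min_flank and down_len >= min_flank and up_fpkm >= floor_fpkm
    )
    tbi = down_fpkm / up_fpkm if valid else float("nan")
    return TBIRecord(iv.name, gene.gene_id, up_fpkm, down_fpkm, tbi, valid)


def compute_tbi_table(
    l1s: Sequence[Union[L1Element, MILRecord]],
    genes: Dict[str, GeneModel],
    host_of: Dict[str, str],
    tt_tracks: Dict[str, CoverageTrack],
    min_flank: int = 500,
    floor_fpkm: float = 0.1,
    tes_overrides: Optional[Dict[str, int]] = None,
) -> List[TBIRecord]:
    """TBI for every sense intronic L1 with a known host; antisense L1s are skipped."""
    out = []
    for l1 in l1s:
        element = l1.l1 if isinstance(l1, MILRecord) else l1
        gene = genes.get(host_of.get(element.interval.name, ""))
        if gene is None or element.interval.strand != gene.strand:
            continue
        override = (tes_overrides or {}).get(gene.gene_id)
        out.append(
            compute_tbi(element, gene, tt_tracks[gene.strand], min_flank,
                        floor_fpkm, tes_override=override)
        )
    return out


def delta_tbi(
    tbi_condition: Sequence[TBIRecord], tbi_control: Sequence[TBIRecord]
) -> pd.DataFrame:
    """Per-L1 ΔTBI = condition − control, ranked ascending (strongest release first).

    Pairs invalid in either condition are dropped (count logged); an empty
    intersection raises.
    """
    cond = {(r.l1_id, r.gene_id): r for r in tbi_condition if r.valid}
    ctl = {(r.l1_id, r.gene_id): r for r in tbi_control if r.valid}
    keys = sorted(set(cond) & set(ctl))
    n_dropped = len(set(c.l1_id for c in tbi_condition) | set(c.l1_id for c in tbi_control)) - len(keys)
    if not keys:
        raise ValueError("no (L1, gene) pair valid in both conditions")
    if n_dropped:
        logger.info("delta_tbi: dropped %d pairs invalid in one condition", n_dropped)
    df = pd.DataFrame(
        {
            "l1_id": [k[0] for k in keys],
            "gene_id": [k[1] for k in keys],
            "tbi_control": [ctl[k].tbi for k in keys],
            "tbi_condition": [cond[k].tbi for k in keys],
        }
    )
    df["delta_tbi"] = df["tbi_condition"] - df["tbi_control"]
    return df.sort_values("delta_tbi", ignore_index=True)


def fraction_blocked(
    delta_table: pd.DataFrame, threshold: float = 0.1
) -> Tuple[float, int, int]:
    """Fraction of L1s whose TBI decreased by more than ``threshold``.

    Returns (fraction, n_below, n_total) over ΔTBI < −threshold.
    """
    if len(delta_table) == 0:
        raise ValueError("empty delta table")
    n_total = len(delta_table)
    n_below = int((delta_table["delta_tbi"] < -threshold).sum())
    return n_below / n_total, n_below, n_total
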