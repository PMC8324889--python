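"""Interval arithmetic shared across the pipeline."""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

from intervaltree import IntervalTree

from .types import CoverageTrack, GeneModel, GenomicInterval, L1Element


def as_interval(rec) -> GenomicInterval:
    """Extract the :class:`GenomicInterval` from a typed record or pass one through."""
    if isinstance(rec, GenomicInterval):
        return rec
    iv = getattr(rec, "interval", None)
    if isinstance(iv, GenomicInterval):
        return iv
    body = getattr(rec, "body", None)
    if isinstance(body, GenomicInterval):
        return body
    raise TypeError(f"no genomic interval on {type(rec).__name__}")


def interval_overlap(
    a: Sequence,
    b: Sequence,
    same_strand: bool = False,
    min_bp: int = 1,
) -> List[Tuple[object, object, int]]:
    """All pairs (x in a, y in b) overlapping by >= ``min_bp`` bases.

    Intervals are half-open, so touching intervals do not overlap. With
    ``same_strand`` the pair is reported only when strands are equal.
    Returns (record_a, record_b, overlap_bp) triples, in order of ``a``.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees: dict = {}
    for y in b:
        iv = as_interval(y)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, y)
    out = []
    for x in a:
        ix = as_interval(x)
        tree = trees.get(ix.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(ix.start, ix.end), key=lambda h: (h.begin, h.end))
        for h in hits:
            y = h.data
            iy = as_interval(y)
            if same_strand and ix.strand != iy.strand:
                continue
            ov = ix.overlap_bp(iy)
            if ov >= min_bp:
                out.append((x, y, ov))
    return out


def query_coverage(track: CoverageTrack, iv: GenomicInterval) -> float:
    """Total reads over ``iv`` (sum of per-base values); unknown chromosome raises."""
    return track.query(iv.chrom, iv.start, iv.end)


def hosting_introns(l1: L1Element, gene: GeneModel) -> List[GenomicInterval]:
    """Introns of ``gene`` that fully contain the L1 (orientation-agnostic)."""
    return [intr for intr in gene.introns if intr.contains(l1.interval)]


def is_intronic(l1: L1Element, gene: GeneModel) -> bool:
    return bool(hosting_introns(l1, gene))


def orientation_to(l1: L1Element, gene: GeneModel) -> str:
    """"sense" if the L1 points with the host gene's transcription, else "antisense"."""
    if l1.interval.strand not in ("+", "-"):
        raise ValueError(f"L1 {l1.name!r} is unstranded")
    return "sense" if l1.interval.strand == gene.strand else "antisense"
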