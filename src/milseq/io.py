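"""Readers and writers for the interval, coverage and sequence formats the pipeline touches.

BED dialects
------------
* generic: BED3/BED6 -> :class:`GenomicInterval`
* gene:    BED6 (single-exon) or BED12 with exon blocks -> :class:`GeneModel`
* l1:      BED6 + subfamily (col 7) + divergence (col 8) [+ full_length flag col 9]
           -> :class:`L1Element`
* peak:    chrom, start, end, name, fold, strand, p, q -> :class:`Peak`

Coverage is read from one bedGraph file per strand; the library size is always
supplied by the caller (header lines ``track`` / ``#`` are skipped).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CoverageTrack, GeneModel, GenomicInterval, L1Element, Peak

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed input line, reported with its file and line number."""


def _parse_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _int(fields, idx, path, lineno):
    try:
        return int(fields[idx])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:{lineno}: bad integer in column {idx + 1}") from exc


def _float(fields, idx, path, lineno):
    try:
        return float(fields[idx])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:{lineno}: bad number in column {idx + 1}") from exc


def read_intervals(path: PathLike, kind: str = "generic"):
    """Read a BED-dialect file into typed records (see module docstring for dialects)."""
    if kind not in ("generic", "gene", "l1", "peak"):
        raise ValueError(f"unknown kind {kind!r}")
    out: list = []
    for lineno, f in _parse_lines(path):
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
        chrom = f[0]
        start = _int(f, 1, path, lineno)
        end = _int(f, 2, path, lineno)
        name = f[3] if len(f) > 3 else ""
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        try:
            iv = GenomicInterval(chrom, start, end, strand, name)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if kind == "generic":
            out.append(iv)
        elif kind == "l1":
            subfamily = f[6] if len(f) > 6 else "L1"
            divergence = _float(f, 7, path, lineno) if len(f) > 7 else 0.0
            full = len(f) > 8 and f[8] in ("1", "True", "true")
            try:
                out.append(L1Element(iv, subfamily, divergence, full))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
        elif kind == "peak":
            fold = _float(f, 4, path, lineno) if len(f) > 4 else 0.0
            p = _float(f, 6, path, lineno) if len(f) > 6 else 1.0
            q = _float(f, 7, path, lineno) if len(f) > 7 else 1.0
            out.append(Peak(iv, fold, p, q))
        else:  # gene
            out.append(_parse_gene(f, iv, path, lineno))
    return out


def _parse_gene(f, iv: GenomicInterval, path, lineno) -> GeneModel:
    if iv.strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: gene records require a strand column")
    exons: List[GenomicInterval] = []
    if len(f) >= 12:
        n = _int(f, 9, path, lineno)
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n or len(offsets) != n:
            raise FormatError(f"{path}:{lineno}: exon block count mismatch")
        for sz, off in zip(sizes, offsets):
            exons.append(
                GenomicInterval(iv.chrom, iv.start + off, iv.start + off + sz, iv.strand)
            )
    try:
        return GeneModel(gene_id=iv.name or f"{iv.chrom}:{iv.start}", body=iv, exons=exons)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_intervals(records: Iterable, path: PathLike) -> None:
    """Write typed records back to their BED dialect (inverse of :func:`read_intervals`)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name or '.'}\t0\t{rec.strand}\n"
                )
            elif isinstance(rec, L1Element):
                iv = rec.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
                    f"\t{rec.subfamily}\t{rec.divergence:g}\t{int(rec.is_full_length)}\n"
                )
            elif isinstance(rec, Peak):
                iv = rec.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{rec.fold_enrichment:g}\t{iv.strand}"
                    f"\t{rec.p_value:g}\t{rec.q_value:g}\n"
                )
            elif isinstance(rec, GeneModel):
                iv = rec.body
                sizes = ",".join(str(len(e)) for e in rec.exons)
                offs = ",".join(str(e.start - iv.start) for e in rec.exons)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.gene_id}\t0\t{iv.strand}"
                    f"\t{iv.start}\t{iv.end}\t0\t{len(rec.exons)}\t{sizes}\t{offs}\n"
                )
            else:
                raise TypeError(f"cannot write record of type {type(rec).__name__}")


def _read_bedgraph(path: PathLike) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    by_chrom: Dict[str, list] = {}
    for lineno, f in _parse_lines(path):
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom = f[0]
        start = _int(f, 1, path, lineno)
        end = _int(f, 2, path, lineno)
        value = _float(f, 3, path, lineno)
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative coverage value")
        if end <= start:
            raise FormatError(f"{path}:{lineno}: empty bedGraph record")
        by_chrom.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        s, e, v = (np.array(x) for x in zip(*rows))
        out[chrom] = (s, e, v)
    return out


def read_coverage(
    path_plus: PathLike,
    path_minus: PathLike,
    library_size: float,
    assay: str = "other",
    chroms: Optional[Sequence[str]] = None,
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Read one bedGraph per strand into a (+, -) pair of :class:`CoverageTrack`.

    ``library_size`` is the total mapped reads of the library, supplied by the
    caller (it is not inferable from the tracks). Overlapping records raise.
    """
    plus = CoverageTrack(assay, "+", _read_bedgraph(path_plus), library_size, chroms)
    minus = CoverageTrack(assay, "-", _read_bedgraph(path_minus), library_size, chroms)
    return plus, minus


def write_coverage(track: CoverageTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in track.covered_chroms():
            s, e, v = track.segments(chrom)
            for a, b, val in zip(s, e, v):
                if val != 0:
                    fh.write(f"{chrom}\t{a}\t{b}\t{val:g}\n")


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Dict[str, str], path: PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )
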