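"""Core domain types.

All coordinates are 0-based, half-open (BED convention), everywhere in the
package. Strands are "+", "-" or "." (unstranded). Coverage is stored
piecewise-constant per chromosome, which keeps multi-megabase toy genomes
cheap to hold in memory while still answering exact base-resolution queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A gene body with an exon chain; introns are the complement within the body."""

    gene_id: str
    body: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: body must be stranded")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if not self.body.contains(ex):
                raise ValueError(f"gene {self.gene_id}: exon outside body")
            if ex.strand not in (".", self.body.strand):
                raise ValueError(f"gene {self.gene_id}: exon strand mismatch")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end
        if not self.exons:
            # single-exon view: the whole body is exonic, no introns
            self.exons = [self.body]

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tes(self) -> int:
        return self.body.end - 1 if self.strand == "+" else self.body.start

    @property
    def length_bp(self) -> int:
        return len(self.body)

    @property
    def introns(self) -> List[GenomicInterval]:
        out = []
        for a, b in zip(self.exons[:-1], self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(
                        self.body.chrom, a.end, b.start, self.strand,
                        name=f"{self.gene_id}_intron",
                    )
                )
        return out


@dataclass
class L1Element:
    """A LINE-1 copy: interval plus subfamily label and % divergence from consensus."""

    interval: GenomicInterval
    subfamily: str = "L1"
    divergence: float = 0.0
    is_full_length: bool = False

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")

    @property
    def name(self) -> str:
        return self.interval.name


class CoverageTrack:
    """Stranded per-base coverage held as sorted non-overlapping constant segments.

    ``query(chrom, start, end)`` returns the sum of per-base values over the
    half-open interval, i.e. the read count attributed to that region.
    ``library_size`` is the total mapped reads of the library the track came
    from; it is supplied, never inferred, because it generally exceeds the
    signal present in the track.
    """

    def __init__(
        self,
        assay: str,
        strand: str,
        segments: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: float,
        chroms: Optional[Iterable[str]] = None,
    ) -> None:
        if strand not in ("+", "-"):
            raise ValueError("coverage tracks must be stranded")
        if library_size <= 0:
            raise ValueError("library_size must be > 0")
        self.assay = assay
        self.strand = strand
        self.library_size = float(library_size)
        self._segs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: Dict[str, np.ndarray] = {}
        for chrom, (s, e, v) in segments.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(v < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            if np.any(e <= s):
                raise ValueError(f"empty coverage segment on {chrom}")
            if len(s) > 1 and np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping coverage segments on {chrom}")
            self._segs[chrom] = (s, e, v)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])
        # the set of chromosomes the track knows about; None = open world
        self.chroms: Optional[set] = set(chroms) if chroms is not None else None
        if self.chroms is not None:
            missing = set(self._segs) - self.chroms
            if missing:
                raise ValueError(f"segments on undeclared chromosomes: {missing}")

    @property
    def library_size_millions(self) -> float:
        return self.library_size / 1e6

    def total_signal(self) -> float:
        return float(sum(c[-1] for c in self._cum.values()))

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Cumulative signal from the chromosome start up to each position."""
        s, e, v = self._segs[chrom]
        cum = self._cum[chrom]
        i = np.searchsorted(s, pos, side="right") - 1
        i_safe = np.clip(i, 0, len(s) - 1)
        inside = np.clip(pos - s[i_safe], 0, e[i_safe] - s[i_safe])
        out = cum[i_safe] + v[i_safe] * inside
        return np.where(i < 0, 0.0, out)

    def query(self, chrom: str, start: int, end: int) -> float:
        if self.chroms is not None and chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r} for {self.assay} track")
        if chrom not in self._segs:
            return 0.0
        lo, hi = self._integral(chrom, np.array([start, end], dtype=np.int64))
        return float(hi - lo)

    def query_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised window sums over one chromosome."""
        if self.chroms is not None and chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r} for {self.assay} track")
        if chrom not in self._segs:
            return np.zeros(len(starts))
        return self._integral(chrom, np.asarray(ends)) - self._integral(
            chrom, np.asarray(starts)
        )

    def covered_chroms(self) -> List[str]:
        return sorted(self._segs)

    def extent(self, chrom: str) -> Tuple[int, int]:
        s, e, _ = self._segs[chrom]
        return int(s[0]), int(e[-1])

    def segments(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._segs[chrom]


@dataclass
class QuantRow:
    """Read count and FPKM for one feature in one assay."""

    feature_id: str
    assay: str
    reads: float
    fpkm: float
    mappability: float = 1.0

    def __post_init__(self) -> None:
        if self.reads < 0 or self.fpkm < 0:
            raise ValueError(f"{self.feature_id}: negative reads/fpkm")
        if not (0 < self.mappability <= 1):
            raise ValueError(f"{self.feature_id}: mappability must be in (0, 1]")


@dataclass
class Peak:
    """A called enrichment peak (IP over input)."""

    interval: GenomicInterval
    fold_enrichment: float = 0.0
    p_value: float = 1.0
    q_value: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value outside [0, 1]")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


@dataclass
class MILRecord:
    """An intronic L1 scored for m6A, relative to one host gene."""

    l1: L1Element
    host_gene_id: str
    orientation: str  # "sense" | "antisense"
    tt_fpkm: float
    meth_level: float
    n_peaks: int
    mil_class: str = "none"  # "super" | "typical" | "control" | "none"

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.mil_class == "control" and self.n_peaks != 0:
            raise ValueError("control L1 cannot overlap peaks")
        if self.mil_class in ("super", "typical") and self.n_peaks < 1:
            raise ValueError("MIL must overlap at least one peak")
        if self.meth_level < 0:
            raise ValueError("meth_level must be >= 0")

    @property
    def l1_id(self) -> str:
        return self.l1.name


@dataclass
class TBIRecord:
    """Transcription Blocking Index of one sense intronic L1 inside its host gene.

    ``tbi`` = downstream-flank FPKM / upstream-flank FPKM in the transcription
    direction; values below 1 indicate that elongation drops after the L1.
    """

    l1_id: str
    gene_id: str
    upstream_fpkm: float
    downstream_fpkm: float
    tbi: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and not (self.tbi >= 0):
            raise ValueError("valid TBI must be >= 0")
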