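"""Feature-level FPKM and the two ratio statistics built on it.

The methylation level of a feature is
``(MINT FPKM + pc) / (TT FPKM + pc)`` and its relative stability is
``(RNA FPKM + pc) / (TT FPKM + pc)``; the pseudo-count ``pc`` bounds the
ratios for weakly covered features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

from .intervals import as_interval
from .types import CoverageTrack, GenomicInterval, QuantRow


@dataclass
class RatioConfig:
    pseudo_count: float = 1.0
    mappability_adjust: bool = False

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be > 0")


TrackLike = Union[CoverageTrack, Tuple[CoverageTrack, CoverageTrack]]


def _by_strand(track: TrackLike) -> Dict[str, CoverageTrack]:
    if isinstance(track, CoverageTrack):
        return {track.strand: track}
    return {t.strand: t for t in track}


def compute_fpkm(
    track: TrackLike,
    features: Sequence,
    mappability: Optional[Mapping[str, float]] = None,
    cfg: Optional[RatioConfig] = None,
) -> Dict[str, QuantRow]:
    """FPKM per feature: reads / (length_kb x library_size_millions).

    ``track`` is a single stranded track or a (+, -) pair; stranded features
    are counted on their own strand, unstranded features on both. With
    ``cfg.mappability_adjust`` the FPKM is divided by the feature's
    mappability weight in (0, 1].
    """
    cfg = cfg or RatioConfig()
    tracks = _by_strand(track)
    assay = next(iter(tracks.values())).assay
    lib_m = next(iter(tracks.values())).library_size_millions
    out: Dict[str, QuantRow] = {}
    for feat in features:
        iv = as_interval(feat)
        if len(iv) <= 0:
            raise ValueError(f"zero-length feature {iv.name!r}")
        strands = [iv.strand] if iv.strand in ("+", "-") else ["+", "-"]
        reads = sum(
            tracks[s].query(iv.chrom, iv.start, iv.end) for s in strands if s in tracks
        )
        fpkm = reads / (len(iv) / 1000.0 * lib_m)
        m = 1.0
        if cfg.mappability_adjust and mappability is not None:
            m = float(mappability.get(iv.name, 1.0))
            fpkm /= m
        key = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        out[key] = QuantRow(key, assay, float(reads), fpkm, m)
    return out


def _ratio(num: QuantRow, den: QuantRow, cfg: RatioConfig) -> float:
    if num.feature_id != den.feature_id:
        raise ValueError(
            f"feature mismatch: {num.feature_id!r} vs {den.feature_id!r}"
        )
    pc = cfg.pseudo_count
    return (num.fpkm + pc) / (den.fpkm + pc)


def methylation_level(
    mint: QuantRow, tt: QuantRow, cfg: Optional[RatioConfig] = None
) -> float:
    """m6A level = (MINT FPKM + pc) / (TT FPKM + pc) for the same feature."""
    return _ratio(mint, tt, cfg or RatioConfig())


def stability_ratio(
    rna: QuantRow, tt: QuantRow, cfg: Optional[RatioConfig] = None
) -> float:
    """Relative RNA stability = (RNA FPKM + pc) / (TT FPKM + pc)."""
    return _ratio(rna, tt, cfg or RatioConfig())
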