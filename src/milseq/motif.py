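"""RRACH motif accounting and the subfamily m6A-vs-age correlation.

RRACH is the m6A consensus 5-mer (R = A/G, H = A/C/U) with the methylated A
at position 3. Scanning is single-strand on the RNA sense, U is read as T,
N never matches, and every matching offset is counted (overlapping
occurrences included); a greedy non-overlapping mode is available for
sensitivity checks.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

# lookahead so overlapping occurrences are all reported
RRACH_RE = re.compile(r"(?=[AG][AG]AC[ACT])")
RRACH_PLAIN = re.compile(r"[AG][AG]AC[ACT]")


@dataclass
class MotifProfile:
    sequence_id: str
    length: int
    total_count: int
    density_per_100nt: float
    bin_counts: np.ndarray
    bin_nt: int

    def __post_init__(self) -> None:
        if self.total_count != int(self.bin_counts.sum()):
            raise ValueError("bin counts do not sum to the total")


@dataclass
class SubfamilyLevel:
    """m6A level (MINT/TT FPKM ratio) and estimated age of one L1 subfamily."""

    subfamily: str
    mint_fpkm: float
    tt_fpkm: float
    level: float
    age_myr: float

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("level must be >= 0")
        if self.age_myr <= 0:
            raise ValueError("age_myr must be > 0")


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def rrach_positions(seq: str, overlapping: bool = True) -> List[int]:
    """Start offsets of RRACH matches; overlapping offsets all counted by default."""
    s = _normalise(seq)
    if overlapping:
        return [m.start() for m in RRACH_RE.finditer(s)]
    out, pos = [], 0
    while True:
        m = RRACH_PLAIN.search(s, pos)
        if not m:
            return out
        out.append(m.start())
        pos = m.start() + 5


def count_rrach(
    seq: str,
    bin_nt: int = 500,
    sequence_id: str = "",
    overlapping: bool = True,
) -> MotifProfile:
    """Scan a sequence for RRACH; motifs are binned by their first base."""
    if not seq:
        raise ValueError("empty sequence")
    positions = rrach_positions(seq, overlapping=overlapping)
    n_bins = (len(seq) + bin_nt - 1) // bin_nt
    bins = np.bincount(
        np.asarray(positions, dtype=int) // bin_nt, minlength=n_bins
    ) if positions else np.zeros(n_bins, dtype=int)
    total = len(positions)
    return MotifProfile(
        sequence_id=sequence_id,
        length=len(seq),
        total_count=total,
        density_per_100nt=100.0 * total / len(seq),
        bin_counts=bins,
        bin_nt=bin_nt,
    )


def compare_rrach_mutant(
    consensus_seq: str,
    mutant_seq: str,
    bin_nt: int = 500,
    overlapping: bool = True,
) -> Dict[str, object]:
    """Motif bookkeeping between an original sequence and its aligned mutant.

    Returns counts on both sequences, the number of disrupted motifs, the
    positions lost, the nucleotide (Hamming) distance, and a per-bin table.
    The sequences must already be aligned base-for-base; no alignment is done.
    """
    if len(consensus_seq) != len(mutant_seq):
        raise ValueError(
            f"length mismatch ({len(consensus_seq)} vs {len(mutant_seq)}); "
            "sequences must be pre-aligned"
        )
    prof_c = count_rrach(consensus_seq, bin_nt, "consensus", overlapping)
    prof_m = count_rrach(mutant_seq, bin_nt, "mutant", overlapping)
    pos_c = set(rrach_positions(consensus_seq, overlapping))
    pos_m = set(rrach_positions(mutant_seq, overlapping))
    a, b = _normalise(consensus_seq), _normalise(mutant_seq)
    hamming = sum(1 for x, y in zip(a, b) if x != y)
    table = pd.DataFrame(
        {
            "bin_start": np.arange(len(prof_c.bin_counts)) * bin_nt,
            "bin_end": np.minimum(
                (np.arange(len(prof_c.bin_counts)) + 1) * bin_nt, prof_c.length
            ),
            "count_consensus": prof_c.bin_counts,
            "count_mutant": prof_m.bin_counts,
        }
    )
    return {
        "count_consensus": prof_c.total_count,
        "count_mutant": prof_m.total_count,
        "n_disrupted": prof_c.total_count - prof_m.total_count,
        "positions_lost": sorted(pos_c - pos_m),
        "n_nt_changed": hamming,
        "bins": table,
    }


def _would_create_motif(seq: List[str], i: int) -> bool:
    """Would substituting C at position i create a new RRACH one frame left?

    The new C can only serve as the C (position 4) of a motif starting at
    i - 3, which requires an A/G three bases upstream, an A directly
    upstream, and an H following.
    """
    return (
        i >= 3
        and seq[i - 3] in "AG"
        and seq[i - 2] in "AG"
        and seq[i - 1] == "A"
        and i + 1 < len(seq)
        and seq[i + 1] in "ACT"
    )


def design_rrach_mutant(
    seq: str, fraction: float = 0.35, seed: int = 0
) -> Tuple[str, Dict[str, object]]:
    """Disrupt a sampled fraction of RRACH motifs at their central A.

    ``floor(fraction x count)`` motif instances (at least one) are sampled
    uniformly and processed left to right; the central A is substituted by C,
    or by T in the rare context where a C would itself complete a new RRACH
    one frame to the left, so a re-scan never finds new instances. A
    substitution inside overlapping motifs can disrupt more than one
    instance; the report carries the exact bookkeeping.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    s = _normalise(seq)
    positions = rrach_positions(s)
    if not positions:
        raise ValueError("sequence contains no RRACH motif")
    n_target = max(1, int(np.floor(fraction * len(positions))))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(positions), size=n_target, replace=False))
    arr = list(s)
    mutated_at: List[int] = []
    for idx in chosen:
        center = positions[idx] + 2
        if arr[center] != "A":
            continue  # already destroyed by an earlier overlapping substitution
        arr[center] = "T" if _would_create_motif(arr, center) else "C"
        mutated_at.append(center)
    mutant = "".join(arr)
    report = compare_rrach_mutant(s, mutant)
    report["n_substitutions"] = len(mutated_at)
    report["substituted_positions"] = mutated_at
    return mutant, report


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho via full enumeration."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float((rx_c[list(perm)] * ry_c).sum() / denom)
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def subfamily_age_correlation(
    levels: Sequence[SubfamilyLevel], exact_max_n: int = 10
) -> Tuple[float, float]:
    """Spearman correlation between subfamily m6A levels and evolutionary ages.

    Two-sided p is computed by exact permutation enumeration for
    n <= ``exact_max_n`` subfamilies and by the t-approximation otherwise.
    """
    if len(levels) < 4:
        raise ValueError("need >= 4 subfamilies")
    lv = np.array([s.level for s in levels], dtype=float)
    age = np.array([s.age_myr for s in levels], dtype=float)
    if np.allclose(lv, lv[0]) or np.allclose(age, age[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p_t = stats.spearmanr(lv, age)
    if len(levels) <= exact_max_n:
        p = _exact_spearman_p(lv, age, rho)
    else:
        p = float(p_t)
    return float(rho), p
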