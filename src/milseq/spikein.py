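"""Dual spike-in QC: ERCC normalization, observed m6A levels, and calibration.

Two spike-in sets enter every MINT/TT library pair: 20 in-vitro transcripts in
five groups mixed non-methylated:methylated at 1:0, 3:1, 1:1, 1:3 and 0:1
(0/25/50/75/100% methylated), and 92 ERCC-like species added identically to
both libraries. The ERCC species give a zero-intercept regression slope
(IP reads on input reads) that normalizes away the library-scale difference;
each m6A species' observed level is its raw IP/input ratio divided by that
factor. The QC statistic is the Spearman correlation of observed group levels
against the designed levels; in addition, a linear calibration anchored at the
0% and 100% groups converts observed ratios into estimated percent methylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LEVELS = {1: 0.0, 2: 25.0, 3: 50.0, 4: 75.0, 5: 100.0}
GROUP_RATIOS = {1: "1:0", 2: "3:1", 3: "1:1", 4: "1:3", 5: "0:1"}


@dataclass
class SpikeDesign:
    """Mapping of spike species to groups and designed methylation levels (%)."""

    table: pd.DataFrame = field(default_factory=lambda: default_design())

    def __post_init__(self) -> None:
        need = {"species", "group", "expected_level"}
        if not need <= set(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(need)}")
        by_group = self.table.groupby("group")["expected_level"].nunique()
        if (by_group != 1).any():
            raise ValueError("inconsistent expected_level within a group")

    def expected_levels(self) -> pd.Series:
        return self.table.groupby("group")["expected_level"].first()


def default_design(n_per_group: int = 4) -> pd.DataFrame:
    rows = []
    for g, level in GROUP_LEVELS.items():
        for j in range(n_per_group):
            rows.append(
                {
                    "species": f"MS{(g - 1) * n_per_group + j + 1:02d}",
                    "group": g,
                    "expected_level": level,
                    "mix_ratio": GROUP_RATIOS[g],
                }
            )
    return pd.DataFrame(rows)


def ercc_norm_factor(ercc: pd.DataFrame) -> float:
    """Zero-intercept least-squares slope of IP reads on input reads over ERCC species.

    f = sum(x*y) / sum(x^2); the regression is forced through the origin
    because the ERCC mix is added identically to both libraries, so their
    relation is a pure scale.
    """
    x = ercc["input_reads"].to_numpy(dtype=float)
    y = ercc["ip_reads"].to_numpy(dtype=float)
    pos = x > 0
    if pos.sum() == 0:
        raise ValueError("all ERCC input reads are zero")
    if pos.sum() < 3:
        warnings.warn("fewer than 3 ERCC species with reads; factor is unstable")
    sxx = float((x**2).sum())
    return float((x * y).sum() / sxx)


def observed_spike_level(ip_reads: float, input_reads: float, f: float) -> float:
    """(IP/input) / f for one species; undefined (NaN, warned) when input is 0."""
    if input_reads <= 0:
        warnings.warn("observed_spike_level undefined for zero input reads")
        return float("nan")
    return (ip_reads / input_reads) / f


def group_ratios(
    counts: pd.DataFrame, f: float, pooled: bool = False
) -> pd.Series:
    """Per-group normalized IP/input ratio r_g.

    Default is the mean of per-species ratios (robust to unequal species
    abundances); ``pooled`` sums counts across the group's species first.
    """
    if pooled:
        g = counts.groupby("group")[["ip_reads", "input_reads"]].sum()
        return g["ip_reads"] / g["input_reads"] / f
    ratios = counts.apply(
        lambda r: observed_spike_level(r["ip_reads"], r["input_reads"], f), axis=1
    )
    return ratios.groupby(counts["group"]).mean()


def calibrate_levels(design: SpikeDesign, observed: pd.Series) -> pd.Series:
    """Estimated % methylation per group, anchored at the 0% and 100% groups.

    estimate_g = 100 * (r_g - r_0) / (r_100 - r_0). Exactly affine-invariant
    in the observed ratios; the anchor groups map to exactly 0 and 100.
    """
    levels = design.expected_levels()
    anchors_lo = levels.index[levels == 0.0]
    anchors_hi = levels.index[levels == 100.0]
    if len(anchors_lo) == 0 or len(anchors_hi) == 0:
        raise ValueError("calibration needs both a 0% and a 100% group")
    r0 = float(observed.loc[anchors_lo].mean())
    r100 = float(observed.loc[anchors_hi].mean())
    if r100 <= r0:
        raise ValueError(
            f"no dynamic range: r_100={r100:.4g} <= r_0={r0:.4g}"
        )
    return 100.0 * (observed - r0) / (r100 - r0)


def spike_qc_spearman(observed: pd.Series, expected: pd.Series) -> float:
    """Spearman rank correlation of observed vs designed group levels (ties mid-ranked)."""
    common = observed.index.intersection(expected.index)
    if len(common) < 3:
        raise ValueError("need >= 3 groups for the rank correlation")
    o = observed.loc[common].to_numpy(dtype=float)
    e = expected.loc[common].to_numpy(dtype=float)
    if np.allclose(o, o[0]) or np.allclose(e, e[0]):
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(o, e)
    return float(rho)


def run_spike_qc(
    m6a_counts: pd.DataFrame,
    ercc_counts: pd.DataFrame,
    design: Optional[SpikeDesign] = None,
    pooled: bool = False,
) -> Dict[str, object]:
    """Full QC: normalization factor, per-group ratios, calibrated estimates, Spearman rho."""
    design = design or SpikeDesign()
    f = ercc_norm_factor(ercc_counts)
    r = group_ratios(m6a_counts, f, pooled=pooled)
    estimates = calibrate_levels(design, r)
    expected = design.expected_levels()
    rho = spike_qc_spearman(r, expected)
    table = pd.DataFrame(
        {
            "expected_level": expected,
            "observed_ratio": r,
            "estimated_level": estimates,
        }
    )
    return {"norm_factor": f, "table": table, "spearman_rho": rho}
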