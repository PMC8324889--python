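"""End-to-end orchestration: simulate -> quant -> callpeaks -> mil -> tbi.

Thin compositions of the module-level operations, shared by the CLI and by
experiment scripts so the same code path is exercised everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .intervals import is_intronic
from .mil import call_mils, rank_super_mils
from .peaks import call_peaks_window
from .quant import RatioConfig, compute_fpkm
from .synth import TruthParams, gen_annotation, gen_coverage_tracks, gen_rbp_peaks, gen_spikein_counts
from .tbi import compute_tbi
from .types import CoverageTrack, GeneModel, L1Element, MILRecord, Peak, TBIRecord


def simulate_dataset(params: TruthParams) -> Dict[str, object]:
    """Generate the full synthetic dataset for one seed."""
    genes, l1s, truth = gen_annotation(params)
    tracks = gen_coverage_tracks(genes, l1s, truth, params)
    m6a, ercc = gen_spikein_counts(params)
    rbp = gen_rbp_peaks(l1s, truth, genes=genes, seed=params.seed)
    return {
        "genes": genes,
        "l1s": l1s,
        "truth": truth,
        "tracks": tracks,
        "spike_m6a": m6a,
        "spike_ercc": ercc,
        "rbp_peaks": rbp,
    }


def write_dataset(data: Dict[str, object], outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_intervals(data["genes"], outdir / "genes.bed")
    mio.write_intervals(data["l1s"], outdir / "l1s.bed")
    data["truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = []
    for assay, (plus, minus) in data["tracks"].items():
        for track in (plus, minus):
            tag = "plus" if track.strand == "+" else "minus"
            path = outdir / f"{assay.lower()}_{tag}.bedgraph"
            mio.write_coverage(track, path)
            manifest.append(
                {
                    "assay": assay,
                    "strand": track.strand,
                    "path": path.name,
                    "library_size": track.library_size,
                }
            )
    pd.DataFrame(manifest).to_csv(outdir / "tracks.tsv", sep="\t", index=False)
    data["spike_m6a"].to_csv(outdir / "spike_m6a.tsv", sep="\t", index=False)
    data["spike_ercc"].to_csv(outdir / "spike_ercc.tsv", sep="\t", index=False)
    mio.write_intervals(data["rbp_peaks"], outdir / "rbp_peaks.bed")


def read_tracks(manifest_path: Path) -> Dict[str, Tuple[CoverageTrack, CoverageTrack]]:
    """Load coverage tracks listed in a tracks.tsv manifest."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    out: Dict[str, Tuple[CoverageTrack, CoverageTrack]] = {}
    for assay, grp in manifest.groupby("assay"):
        by_strand = {}
        for _, row in grp.iterrows():
            by_strand[row["strand"]] = CoverageTrack(
                assay,
                row["strand"],
                mio._read_bedgraph(base / row["path"]),
                row["library_size"],
            )
        out[assay] = (by_strand["+"], by_strand["-"])
    return out


def call_mint_peaks(
    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]],
    q_max: float = 0.01,
    **kwargs,
) -> List[Peak]:
    """MINT-vs-TT peak calling on both strands."""
    peaks: List[Peak] = []
    for i in (0, 1):
        peaks.extend(
            call_peaks_window(tracks["MINT"][i], tracks["TT"][i], q_max=q_max, **kwargs)
        )
    return peaks


def mil_pipeline(
    genes: Sequence[GeneModel],
    l1s: Sequence[L1Element],
    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]],
    peaks: Optional[Sequence[Peak]] = None,
    fpkm_min: float = 0.1,
    len_min: int = 200,
    cfg: Optional[RatioConfig] = None,
) -> Tuple[List[MILRecord], List[Peak]]:
    """Quantify L1s, call MINT peaks if none supplied, and classify MILs."""
    if peaks is None:
        peaks = call_mint_peaks(tracks)
    tt_rows = compute_fpkm(tracks["TT"], l1s, cfg=cfg)
    mint_rows = compute_fpkm(tracks["MINT"], l1s, cfg=cfg)
    mils = call_mils(
        l1s, genes, tt_rows, mint_rows, peaks,
        fpkm_min=fpkm_min, len_min=len_min, cfg=cfg,
    )
    if sum(1 for m in mils if m.mil_class != "control") >= 3:
        rank_super_mils(mils)
    return mils, list(peaks)


def sense_hosts(
    l1s: Sequence[L1Element], genes: Sequence[GeneModel]
) -> Dict[str, str]:
    """Map each L1 to the first gene hosting it in an intron on the same strand."""
    out: Dict[str, str] = {}
    for l1 in l1s:
        for g in genes:
            if g.strand == l1.interval.strand and is_intronic(l1, g):
                out[l1.name] = g.gene_id
                break
    return out


def tbi_pipeline(
    l1s: Sequence[L1Element],
    genes: Sequence[GeneModel],
    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]],
    min_flank: int = 500,
    floor_fpkm: float = 0.1,
) -> List[TBIRecord]:
    """TBI for every sense intronic L1 against the TT track of its gene's strand."""
    gene_by_id = {g.gene_id: g for g in genes}
    hosts = sense_hosts(l1s, genes)
    by_strand = {t.strand: t for t in tracks["TT"]}
    out = []
    for l1 in l1s:
        gid = hosts.get(l1.name)
        if gid is None:
            continue
        gene = gene_by_id[gid]
        out.append(
            compute_tbi(l1, gene, by_strand[gene.strand], min_flank, floor_fpkm)
        )
    return out


def mils_to_frame(mils: Sequence[MILRecord]) -> pd.DataFrame:
    rows = []
    for m in mils:
        iv = m.l1.interval
        rows.append(
            {
                "l1_id": m.l1_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "subfamily": m.l1.subfamily,
                "divergence": m.l1.divergence,
                "host_gene": m.host_gene_id,
                "orientation": m.orientation,
                "tt_fpkm": m.tt_fpkm,
                "meth_level": m.meth_level,
                "n_peaks": m.n_peaks,
                "class": m.mil_class,
            }
        )
    return pd.DataFrame(rows)


def tbi_to_frame(records: Sequence[TBIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "l1_id": [r.l1_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "upstream_fpkm": [r.upstream_fpkm for r in records],
            "downstream_fpkm": [r.downstream_fpkm for r in records],
            "tbi": [r.tbi for r in records],
            "valid": [r.valid for r in records],
        }
    )
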