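"""Genome tiling and regional methylation.

Builds the two kinds of regions the analysis runs on — a genome-wide
grid of fixed-width tiles (default 1 kb) and SNP-centred windows of the
same width — and computes the coverage-weighted mean methylation of each
region from a symmetric-merged CpG site table.

Tile collections are DataFrames with columns chrom, start, end, tile_id,
origin ("grid" | "snp_centred"), source_snp (None for grid tiles).
Regional methylation adds mean_meth (NaN when no covered CpG falls in
the tile), n_cpgs_covered, and total_reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TILE_COLUMNS = ["chrom", "start", "end", "tile_id", "origin", "source_snp"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sizes shared across the pipeline.

    Attributes
    ----------
    tile_width
        Region width in bp (1 kb: methylation correlates across this scale).
    dmr_threshold
        Absolute methylation difference above which a region is called a
        DMR (strict inequality).
    logfc_threshold
        |log2 FC| above which a gene counts as highly differentially
        expressed (strict inequality, the "single log-fold" split).
    n_resample_draws
        Number of random background samples in the depletion test.
    rng_seed
        Seed for every stochastic step (resampling, tie-breaks).
    """

    tile_width: int = 1000
    dmr_threshold: float = 0.2
    logfc_threshold: float = 1.0
    n_resample_draws: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_width <= 0:
            raise ValueError("tile_width must be positive")
        if not 0 < self.dmr_threshold < 1:
            raise ValueError("dmr_threshold must be in (0, 1)")
        if self.n_resample_draws < 1:
            raise ValueError("n_resample_draws must be >= 1")


def make_grid_tiles(chrom_sizes: dict[str, int], config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Tile each chromosome with fixed-width windows [0,w), [w,2w), ...

    The final tile per chromosome is truncated at the chromosome end, so
    each chromosome yields ceil(length / w) tiles.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    config = config or AnalysisConfig()
    w = config.tile_width
    frames = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        starts = np.arange(0, length, w, dtype=np.int64)
        ends = np.minimum(starts + w, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "tile_id": [f"{chrom}:{s}-{e}" for s, e in zip(starts, ends)],
                    "origin": "grid",
                    "source_snp": None,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TILE_COLUMNS]


def make_snp_tiles(
    snps: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """One width-w window centred on each SNP: [p - w/2, p + w/2).

    For even w the centre base is the first base of the right half.
    Windows are clipped at 0 and at the chromosome end.  Overlapping or
    duplicate-position windows are all retained — each locus is its own
    unit of analysis.

    Parameters
    ----------
    snps
        DataFrame with columns chrom, pos and optionally id.
    """
    config = config or AnalysisConfig()
    w = config.tile_width
    snps = snps.reset_index(drop=True)
    if (snps["pos"] < 0).any():
        raise ValueError("SNP positions must be >= 0")
    missing = set(snps["chrom"]) - set(chrom_sizes)
    if missing:
        bad = snps[snps["chrom"].isin(missing)].iloc[0]
        raise ValueError(
            f"SNP {bad.get('id', '?')} on chromosome {bad['chrom']} absent from chrom_sizes"
        )
    ids = snps["id"] if "id" in snps.columns else pd.Series(
        [f"snp{i}" for i in range(len(snps))]
    )
    lengths = snps["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    pos = snps["pos"].to_numpy(dtype=np.int64)
    starts = np.clip(pos - w // 2, 0, None)
    ends = np.minimum(pos + (w - w // 2), lengths)
    out = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "start": starts,
            "end": ends,
            "tile_id": [f"{sid}@{c}:{s}-{e}" for sid, c, s, e in zip(ids, snps["chrom"], starts, ends)],
            "origin": "snp_centred",
            "source_snp": ids.to_numpy(),
        }
    )
    if (out["start"] >= out["end"]).any():
        raise ValueError("SNP window collapsed to zero width after clipping")
    return out[TILE_COLUMNS]


def region_methylation(
    tiles: pd.DataFrame, sites: pd.DataFrame, *, weighted: bool = True
) -> pd.DataFrame:
    """Coverage-weighted mean methylation per region.

    For each tile, averages the methylation of covered CpGs whose anchor
    position lies in [start, end): mean = sum(meth_i * cov_i) /
    sum(cov_i) (the proportion of methylated reads over total reads,
    roimethstat-style).  With ``weighted=False`` an unweighted per-CpG
    mean is computed instead.  Tiles with no covered CpG are reported
    with NaN methylation rather than dropped.

    ``sites`` must be sorted by (chrom, pos) (as the readers and mergers
    emit); an unsorted table raises.
    """
    pos_all = sites["pos"].to_numpy()
    if len(sites) > 1:
        chrom_change = sites["chrom"].to_numpy()[:-1] != sites["chrom"].to_numpy()[1:]
        pos_noninc = np.diff(pos_all) < 0
        if np.any(pos_noninc & ~chrom_change):
            raise ValueError("sites must be sorted by (chrom, pos)")

    covered = sites[sites["cov"] > 0]
    by_chrom = {
        chrom: (
            grp["pos"].to_numpy(dtype=np.int64),
            grp["meth"].to_numpy(dtype=np.float64),
            grp["cov"].to_numpy(dtype=np.float64),
        )
        for chrom, grp in covered.groupby("chrom", sort=False)
    }

    n = len(tiles)
    mean_meth = np.full(n, np.nan)
    n_cpgs = np.zeros(n, dtype=np.int64)
    total_reads = np.zeros(n, dtype=np.int64)
    chroms = tiles["chrom"].to_numpy()
    starts = tiles["start"].to_numpy()
    ends = tiles["end"].to_numpy()
    for i in range(n):
        entry = by_chrom.get(chroms[i])
        if entry is None:
            continue
        pos, meth, cov = entry
        lo = np.searchsorted(pos, starts[i], side="left")
        hi = np.searchsorted(pos, ends[i], side="left")
        if hi <= lo:
            continue
        m, c = meth[lo:hi], cov[lo:hi]
        n_cpgs[i] = hi - lo
        total_reads[i] = int(c.sum())
        mean_meth[i] = float((m * c).sum() / c.sum()) if weighted else float(m.mean())

    out = tiles.copy()
    out["mean_meth"] = mean_meth
    out["n_cpgs_covered"] = n_cpgs
    out["total_reads"] = total_reads
    return out


def tiles_to_bed(tiles: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a tile collection (tile_id in the name column)."""
    return pd.DataFrame(
        {
            "chrom": tiles["chrom"],
            "start": tiles["start"],
            "end": tiles["end"],
            "name": tiles["tile_id"],
            "score": 0,
            "strand": ".",
        }
    )
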