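"""Genomic annotation assignment, closest-gene lookup, and distribution tests.

Each locus (a SNP position, or a tile represented by its midpoint) is
assigned to exactly one annotation class — promoter, exon, intron, or
intergenic — with intergenic the implicit complement of the other
three.  Where classes overlap, a fixed precedence decides (default
promoter > exon > intron: promoters are the regulatory class of
interest).  Intervals within a class are coordinate-merged before any
assignment, so input interval order can never change a result.

Closest-gene lookup mirrors bedtools closest: distance is the interval
gap in bp, 0 for overlap, upstream/downstream not distinguished; exact
ties are broken by a seeded uniform choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

CLASSES = ("promoter", "exon", "intron", "intergenic")
DEFAULT_PRECEDENCE = ("promoter", "exon", "intron")


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Coordinate-sort and merge overlapping/adjacent intervals per chrom."""
    if intervals.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = intervals.sort_values(["chrom", "start", "end"], ignore_index=True)
    out_rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out_rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end"])


class _IntervalIndex:
    """Sorted merged intervals per chromosome with O(log n) membership."""

    def __init__(self, merged: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            chrom: (
                grp["start"].to_numpy(dtype=np.int64),
                grp["end"].to_numpy(dtype=np.int64),
            )
            for chrom, grp in merged.groupby("chrom", sort=False)
        }

    def contains(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        for chrom in pd.unique(chroms):
            entry = self._by_chrom.get(chrom)
            if entry is None:
                continue
            starts, ends = entry
            mask = chroms == chrom
            p = pos[mask]
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(p), dtype=bool)
            hit[ok] = p[ok] < ends[idx[ok]]
            out[mask] = hit
        return out


@dataclass
class AnnotationTrack:
    """Promoter/exon/intron interval sets (merged within each class)."""

    promoters: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame

    def __post_init__(self) -> None:
        self.promoters = merge_intervals(self.promoters)
        self.exons = merge_intervals(self.exons)
        self.introns = merge_intervals(self.introns)
        self._indices = {
            "promoter": _IntervalIndex(self.promoters),
            "exon": _IntervalIndex(self.exons),
            "intron": _IntervalIndex(self.introns),
        }

    def index(self, klass: str) -> _IntervalIndex:
        return self._indices[klass]


def assign_annotation(
    loci: pd.DataFrame,
    track: AnnotationTrack,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Assign each locus position to exactly one annotation class.

    ``loci`` needs columns chrom and pos (use :func:`tile_midpoints` to
    turn tiles into loci first).  A locus inside several classes gets
    the earliest class in ``precedence``; a locus inside none is
    intergenic.  The returned frame is ``loci`` plus a ``klass`` column.
    """
    chroms = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy(dtype=np.int64)
    klass = np.full(len(loci), "intergenic", dtype=object)
    unassigned = np.ones(len(loci), dtype=bool)
    for cls in precedence:
        hit = track.index(cls).contains(chroms, pos) & unassigned
        klass[hit] = cls
        unassigned &= ~hit
    out = loci.copy()
    out["klass"] = klass
    return out


def tile_midpoints(tiles: pd.DataFrame) -> pd.DataFrame:
    """Loci at tile midpoints (start + width//2), carrying tile_id."""
    out = pd.DataFrame(
        {
            "chrom": tiles["chrom"],
            "pos": tiles["start"] + (tiles["end"] - tiles["start"]) // 2,
        }
    )
    if "tile_id" in tiles.columns:
        out["tile_id"] = tiles["tile_id"].to_numpy()
    return out


def class_counts(assignments: pd.DataFrame) -> pd.Series:
    """Locus count per annotation class, in canonical class order."""
    counts = assignments["klass"].value_counts()
    return pd.Series({cls: int(counts.get(cls, 0)) for cls in CLASSES})


def closest_gene(
    chrom: str,
    start: int,
    end: int | None,
    genes: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> str | None:
    """Label of the gene nearest a locus or interval (bedtools-closest style).

    ``genes`` needs columns chrom, start, end, name.  Distance is the bp
    gap between intervals (0 when they overlap).  Exact ties are broken
    by a seeded uniform random choice, so results are reproducible under
    a fixed seed.  Returns None when the chromosome has no gene.
    """
    if end is None:
        end = start + 1
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    g = genes[genes["chrom"] == chrom]
    if g.empty:
        return None
    gs = g["start"].to_numpy(dtype=np.int64)
    ge = g["end"].to_numpy(dtype=np.int64)
    # gap distance: 0 if [start,end) and [gs,ge) overlap, else bp between them
    # (+1 so that bookended intervals are at distance 1, as bedtools reports)
    dist = np.where((gs < end) & (start < ge), 0, np.maximum(gs - end, start - ge) + 1)
    best = np.flatnonzero(dist == dist.min())
    pick = best[0] if len(best) == 1 else rng.choice(best)
    return str(g["name"].to_numpy()[pick])


def closest_genes(
    loci: pd.DataFrame, genes: pd.DataFrame, seed: int = 0
) -> pd.Series:
    """Vectorised closest-gene lookup over many loci (one shared RNG so
    tie-breaks depend only on the seed and locus order)."""
    rng = np.random.default_rng(seed)
    start = loci["start"] if "start" in loci.columns else loci["pos"]
    end = loci["end"] if "end" in loci.columns else loci["pos"] + 1
    return pd.Series(
        [
            closest_gene(c, s, e, genes, rng)
            for c, s, e in zip(loci["chrom"], start, end)
        ],
        index=loci.index,
    )


@dataclass(frozen=True)
class ContingencyResult:
    """Contingency-table comparison of two class-count vectors."""

    table: np.ndarray
    statistic: float | None
    df: int | None
    p: float
    method: str


def annotation_distribution_test(
    counts_a,
    counts_b,
    method: str = "chi_square",
    *,
    n_mc_tables: int = 100_000,
    seed: int = 0,
) -> ContingencyResult:
    """Compare two annotation class-count vectors as a 2 x k table.

    ``chi_square``: Pearson statistic sum((O-E)^2 / E) with df = k - 1,
    no continuity correction.  ``fisher_mc``: Monte-Carlo Fisher exact
    test — samples ``n_mc_tables`` tables with the observed margins held
    fixed and reports the add-one fraction whose probability under the
    margins-fixed null is at most the observed table's.
    """
    table = np.asarray([np.asarray(counts_a, dtype=np.int64),
                        np.asarray(counts_b, dtype=np.int64)])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total; drop empty classes first")
    if method == "chi_square":
        expected = np.outer(row, col) / table.sum()
        statistic = float(((table - expected) ** 2 / expected).sum())
        df = (table.shape[0] - 1) * (table.shape[1] - 1)
        p = float(stats.chi2.sf(statistic, df))
        return ContingencyResult(table, statistic, df, p, "chi_square")
    if method == "fisher_mc":
        rng = np.random.default_rng(seed)
        dist = stats.random_table(row, col)
        samples = dist.rvs(n_mc_tables, random_state=rng)
        logp_obs = dist.logpmf(table)
        logp_samples = dist.logpmf(samples)
        k = int(np.sum(logp_samples <= logp_obs + 1e-10))
        p = (1 + k) / (1 + n_mc_tables)
        return ContingencyResult(table, None, None, float(p), "fisher_mc")
    raise ValueError(f"unknown method {method!r}")


def annotation_methylation_profile(
    assignments: pd.DataFrame,
    meth_by_condition: dict[str, pd.DataFrame],
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-class, per-condition methylation summaries (+ DMR fraction).

    ``assignments`` maps tile_id -> klass; each condition's frame is a
    region-methylation table sharing those tile_ids.  When ``calls`` is
    given, the per-class DMR fraction (of tiles called in that class) is
    added, identical across conditions.  Classes with no data yield no
    row.
    """
    rows = []
    dmr_frac: dict[str, float] = {}
    if calls is not None:
        joined = assignments.merge(calls[["tile_id", "is_dmr"]], on="tile_id")
        for cls, grp in joined.groupby("klass"):
            if len(grp):
                dmr_frac[cls] = float(grp["is_dmr"].mean())
    for cond, meth in meth_by_condition.items():
        joined = assignments.merge(
            meth[["tile_id", "mean_meth"]], on="tile_id"
        ).dropna(subset=["mean_meth"])
        for cls, grp in joined.groupby("klass"):
            vals = grp["mean_meth"].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "klass": cls,
                    "condition": cond,
                    "n": len(vals),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "dmr_fraction": dmr_frac.get(cls, np.nan),
                }
            )
    return pd.DataFrame(rows)
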