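"""Reading, validation, and strand/replicate merging of CpG methylation calls.

In-memory conventions
---------------------
CpG site collections are pandas DataFrames with columns

    chrom : str       chromosome name (no normalisation applied by default)
    pos   : int64     0-based position of the cytosine
    strand: str       "+" or "-" ("." after symmetric merging)
    meth  : float64   methylation fraction in [0, 1]; NaN when cov == 0
    cov   : int64     read coverage (>= 0)

sorted by (chrom, pos).  Coordinates are 0-based half-open throughout the
package, matching methcounts and BED.  Sites with cov == 0 are retained by
the readers — they mark assayed-but-uncovered CpGs — but carry zero weight
in every downstream average; their methylation value is stored as NaN,
never as 0.

Interval collections are DataFrames with columns chrom, start, end
(+ optional name, score, strand), 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "strand", "meth", "cov"]

#: Sex, mitochondrial, and haploid chromosomes excluded from all analyses.
DEFAULT_EXCLUDED_CHROMS = frozenset({"chrX", "chrY", "chrM"})


class MethcountsParseError(ValueError):
    """A methcounts-dialect row could not be parsed; names the line number."""


class DuplicateSiteError(ValueError):
    """Two sites share (chrom, pos, strand), which merging cannot resolve."""


@dataclass(frozen=True)
class ChromFilter:
    """Set of chromosome names to drop from sites and intervals.

    Membership is exact string match.  When ``harmonize_chr_prefix`` is
    True a leading "chr" is stripped from both sides before comparison;
    the default is off because silent renaming causes cross-file
    mismatches.
    """

    excluded: frozenset[str] = field(default=DEFAULT_EXCLUDED_CHROMS)
    harmonize_chr_prefix: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded", frozenset(self.excluded))

    def _norm(self, name: str) -> str:
        if self.harmonize_chr_prefix and name.startswith("chr"):
            return name[3:]
        return name

    def is_excluded(self, chrom: str) -> bool:
        if self.harmonize_chr_prefix:
            return self._norm(chrom) in {self._norm(c) for c in self.excluded}
        return chrom in self.excluded


def _finish_sites(df: pd.DataFrame) -> pd.DataFrame:
    # strand in the key makes output order canonical when a merged "." site
    # and an unpaired site share a position
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort", ignore_index=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["cov"] = df["cov"].astype(np.int64)
    df["meth"] = df["meth"].astype(np.float64)
    df.loc[df["cov"] == 0, "meth"] = np.nan
    return df[SITE_COLUMNS]


def read_methcounts(path: str | Path, *, drop_uncovered: bool = False) -> pd.DataFrame:
    """Read a methcounts-dialect text file into a CpG site table.

    Expected columns per row (whitespace separated):
    chrom, pos, strand, context, meth, cov.  Rows whose context is not a
    CpG variant (methcounts writes e.g. CpG, CpGx; CHH/CHG/CXG rows are
    non-CpG) are dropped and the dropped count is logged.

    Parameters
    ----------
    path
        File to read.
    drop_uncovered
        If True, rows with cov == 0 are dropped instead of being kept
        with NaN methylation.

    Raises
    ------
    MethcountsParseError
        On a malformed row (wrong field count, non-numeric pos/meth/cov,
        or meth outside [0, 1] with cov > 0), naming the line number.
    """
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    meths: list[float] = []
    covs: list[int] = []
    n_dropped_context = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise MethcountsParseError(
                    f"{path}:{lineno}: expected >=6 fields, got {len(fields)}"
                )
            chrom, pos_s, strand, context, meth_s, cov_s = fields[:6]
            try:
                pos = int(pos_s)
                meth = float(meth_s)
                cov = int(cov_s)
            except ValueError as exc:
                raise MethcountsParseError(
                    f"{path}:{lineno}: non-numeric pos/meth/cov: {exc}"
                ) from None
            if pos < 0:
                raise MethcountsParseError(f"{path}:{lineno}: negative position {pos}")
            if cov < 0:
                raise MethcountsParseError(f"{path}:{lineno}: negative coverage {cov}")
            if cov > 0 and not (0.0 <= meth <= 1.0):
                raise MethcountsParseError(
                    f"{path}:{lineno}: methylation {meth} outside [0, 1] with cov > 0"
                )
            if not context.startswith("CpG"):
                n_dropped_context += 1
                continue
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            meths.append(meth)
            covs.append(cov)
    if n_dropped_context:
        logger.info(
            "%s: dropped %d non-CpG-context rows", path.name, n_dropped_context
        )
    df = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "strand": strands, "meth": meths, "cov": covs}
    )
    if df.empty:
        df = pd.DataFrame(columns=SITE_COLUMNS)
    df = _finish_sites(df)
    if drop_uncovered:
        df = df[df["cov"] > 0].reset_index(drop=True)
    return df


def write_methcounts(sites: pd.DataFrame, path: str | Path, *, context: str = "CpG") -> None:
    """Write a site table in methcounts dialect (6 columns, tab separated).

    NaN methylation (cov == 0 sites) is written as 0, methcounts'
    convention for uncovered cytosines; reading back restores NaN.
    """
    out = sites.copy()
    out["context"] = context
    out["meth"] = out["meth"].fillna(0.0)
    out = out[["chrom", "pos", "strand", "context", "meth", "cov"]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def merge_symmetric(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each symmetric CpG dyad.

    A "+" site at position p pairs with a "-" site at p + 1 on the same
    chromosome (the C of the reverse-complement CpG).  The merged site is
    anchored at p with cov = cov+ + cov- and the coverage-weighted mean
    methylation.  Unpaired sites pass through unchanged.  Total read
    count is conserved.  Idempotent: already-merged sites (strand ".")
    are never re-paired.

    Raises
    ------
    DuplicateSiteError
        If two sites share (chrom, pos, strand).
    """
    if sites.empty:
        return sites.copy()
    if sites.duplicated(subset=["chrom", "pos", "strand"]).any():
        dup = sites[sites.duplicated(subset=["chrom", "pos", "strand"], keep=False)]
        raise DuplicateSiteError(
            f"duplicate sites at e.g. {dup.iloc[0]['chrom']}:{dup.iloc[0]['pos']}"
        )
    plus = sites[sites["strand"] == "+"]
    minus = sites[sites["strand"] == "-"]
    other = sites[~sites["strand"].isin(["+", "-"])]

    # pair (+ at p) with (- at p+1); anything further away never merges
    key_minus = minus.assign(_anchor=minus["pos"] - 1)
    merged = plus.merge(
        key_minus,
        left_on=["chrom", "pos"],
        right_on=["chrom", "_anchor"],
        how="outer",
        suffixes=("_p", "_m"),
        indicator=True,
    )

    both = merged[merged["_merge"] == "both"]
    cov_p = both["cov_p"].to_numpy(dtype=np.float64)
    cov_m = both["cov_m"].to_numpy(dtype=np.float64)
    meth_p = np.nan_to_num(both["meth_p"].to_numpy(dtype=np.float64))
    meth_m = np.nan_to_num(both["meth_m"].to_numpy(dtype=np.float64))
    tot = cov_p + cov_m
    with np.errstate(invalid="ignore", divide="ignore"):
        meth = np.where(tot > 0, (meth_p * cov_p + meth_m * cov_m) / np.where(tot > 0, tot, 1), np.nan)
    paired = pd.DataFrame(
        {
            "chrom": both["chrom"],
            "pos": both["pos_p"].astype(np.int64),
            "strand": ".",
            "meth": meth,
            "cov": tot.astype(np.int64),
        }
    )

    lone_plus = merged[merged["_merge"] == "left_only"]
    lone_plus = pd.DataFrame(
        {
            "chrom": lone_plus["chrom"],
            "pos": lone_plus["pos_p"],
            "strand": "+",
            "meth": lone_plus["meth_p"],
            "cov": lone_plus["cov_p"],
        }
    ).dropna(subset=["pos"])
    lone_minus = merged[merged["_merge"] == "right_only"]
    lone_minus = pd.DataFrame(
        {
            "chrom": lone_minus["chrom"],
            "pos": lone_minus["pos_m"],
            "strand": "-",
            "meth": lone_minus["meth_m"],
            "cov": lone_minus["cov_m"],
        }
    ).dropna(subset=["pos"])

    out = pd.concat([paired, lone_plus, lone_minus, other], ignore_index=True)
    return _finish_sites(out)


def merge_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool biological replicates by coverage-weighted averaging per site.

    Sites are matched on (chrom, pos, strand); a site present in only
    some replicates is included with the available data (union
    semantics).  Per site: cov = sum(cov_i), meth = sum(meth_i * cov_i)
    / sum(cov_i); NaN if the pooled coverage is 0.

    Raises
    ------
    ValueError
        If the replicate list is empty.
    """
    if not replicates:
        raise ValueError("merge_replicates requires at least one replicate")
    if len(replicates) == 1:
        return _finish_sites(replicates[0].copy())
    cat = pd.concat(replicates, ignore_index=True)
    cat["_wsum"] = cat["meth"].fillna(0.0) * cat["cov"]
    grouped = cat.groupby(["chrom", "pos", "strand"], as_index=False, sort=False).agg(
        cov=("cov", "sum"), _wsum=("_wsum", "sum")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["meth"] = np.where(
            grouped["cov"] > 0, grouped["_wsum"] / grouped["cov"].where(grouped["cov"] > 0, 1), np.nan
        )
    return _finish_sites(grouped.drop(columns="_wsum"))


def apply_chrom_filter(
    records: pd.DataFrame, chrom_filter: ChromFilter
) -> pd.DataFrame:
    """Drop sites or intervals on excluded chromosomes.

    Works on any DataFrame with a ``chrom`` column.  Logs a warning if
    everything was filtered out.
    """
    keep = ~records["chrom"].map(chrom_filter.is_excluded)
    out = records[keep].reset_index(drop=True)
    if len(records) and out.empty:
        logger.warning("chromosome filter removed all %d records", len(records))
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6, tolerating track/browser lines and # comments.

    Returns columns chrom, start, end and, when present, name, score,
    strand.  Coordinates stay 0-based half-open.
    """
    rows = []
    ncols = 3
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line.strip()
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED row with <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if not start < end:
                raise ValueError(f"{path}:{lineno}: empty/inverted interval {start}-{end}")
            rows.append(fields[:6])
            ncols = max(ncols, min(len(fields), 6))
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncols]
    df = pd.DataFrame((r[:ncols] + [None] * (ncols - len(r)) for r in rows), columns=names)
    if df.empty:
        df = pd.DataFrame(columns=names)
    df["start"] = df.get("start", pd.Series(dtype=np.int64)).astype(np.int64)
    df["end"] = df.get("end", pd.Series(dtype=np.int64)).astype(np.int64)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED (3-6 columns depending on what is present)."""
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column UCSC-style chrom.sizes file into {chrom: length}."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "length"], comment="#"
    )
    sizes = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    for chrom, length in sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
    return sizes
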