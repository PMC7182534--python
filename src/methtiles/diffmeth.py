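"""Threshold-based differential methylation calling between two conditions.

A region (1-kb tile or SNP-centred window) is a DMR when the absolute
difference between its mean methylation in the two conditions exceeds a
threshold (default 0.2, strict inequality).  The delta sign convention
is reference minus test: with activated B cells as reference and LCLs as
test, hypomethylation in LCLs appears as a positive delta
(direction "hypo_in_test").

Calls exist only for tiles with data — at least one covered CpG — in
BOTH conditions; that count is the denominator of every reported
percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .tiling import AnalysisConfig

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "tile_id", "chrom", "start", "end",
    "meth_ref", "meth_test", "delta", "is_dmr", "direction",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (table-style), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DMRSummary:
    """Bookkeeping for one locus list: loci in, tiles with data, DMRs out.

    ``pct_dmr`` is 100 * n_dmr / n_with_data rounded half-up to two
    decimals, or None when no tile has data.
    """

    n_loci: int
    n_with_data: int
    n_dmr: int
    n_hypo: int
    n_hyper: int

    def __post_init__(self) -> None:
        if not (self.n_dmr <= self.n_with_data <= self.n_loci):
            raise ValueError("require n_dmr <= n_with_data <= n_loci")
        if self.n_hypo + self.n_hyper != self.n_dmr:
            raise ValueError("directional counts must sum to n_dmr")

    @property
    def pct_dmr(self) -> float | None:
        if self.n_with_data == 0:
            return None
        return round_half_up(100.0 * self.n_dmr / self.n_with_data)

    @classmethod
    def from_counts(
        cls, n_loci: int, n_with_data: int, n_dmr: int,
        n_hypo: int | None = None, n_hyper: int | None = None,
    ) -> "DMRSummary":
        """Build a summary from printed count pairs (directional split
        defaults to all-hypomethylated when unspecified)."""
        if n_hypo is None:
            n_hypo = n_dmr if n_hyper is None else n_dmr - n_hyper
        if n_hyper is None:
            n_hyper = n_dmr - n_hypo
        return cls(n_loci, n_with_data, n_dmr, n_hypo, n_hyper)


def call_dmrs(
    meth_ref: pd.DataFrame,
    meth_test: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Call DMRs from per-tile methylation of two conditions.

    Tiles are matched by tile_id; a tile present in only one collection
    is excluded with a logged count (not an error).  One call row is
    produced per tile with non-missing methylation in both conditions.
    is_dmr uses strict inequality |delta| > threshold.
    """
    config = config or AnalysisConfig()
    thr = config.dmr_threshold
    ref = meth_ref[["tile_id", "chrom", "start", "end", "mean_meth"]].rename(
        columns={"mean_meth": "meth_ref"}
    )
    test = meth_test[["tile_id", "mean_meth"]].rename(columns={"mean_meth": "meth_test"})
    joined = ref.merge(test, on="tile_id", how="inner")
    n_matched = len(joined)
    n_unmatched = len(meth_ref) + len(meth_test) - 2 * n_matched
    if n_unmatched:
        logger.info("call_dmrs: %d tiles present in only one condition", n_unmatched)
    joined = joined.dropna(subset=["meth_ref", "meth_test"]).reset_index(drop=True)
    n_no_data = n_matched - len(joined)
    if n_no_data > 0:
        logger.info("call_dmrs: %d matched tiles lacked data in one or both conditions", n_no_data)
    delta = joined["meth_ref"] - joined["meth_test"]
    joined["delta"] = delta
    # strict inequality at the threshold, with a small guard so binary
    # representation noise (0.9 - 0.7 > 0.2 in float64) cannot flip a call
    eps = 1e-9
    joined["is_dmr"] = delta.abs() > thr + eps
    joined["direction"] = np.select(
        [delta > thr + eps, delta < -(thr + eps)],
        ["hypo_in_test", "hyper_in_test"], default="none",
    )
    return joined[CALL_COLUMNS]


def summarize_dmrs(calls: pd.DataFrame, n_loci: int) -> DMRSummary:
    """Table-style summary of a call set against its input locus count."""
    n_with_data = len(calls)
    if n_loci < n_with_data:
        raise ValueError("n_loci must be >= number of calls")
    n_dmr = int(calls["is_dmr"].sum())
    n_hypo = int((calls["direction"] == "hypo_in_test").sum())
    n_hyper = int((calls["direction"] == "hyper_in_test").sum())
    return DMRSummary(n_loci, n_with_data, n_dmr, n_hypo, n_hyper)


def genome_methylation_distribution(
    meth: pd.DataFrame, bins: int | np.ndarray = 20
) -> dict:
    """Histogram + quartile summary of per-tile methylation.

    Returns {"counts", "bin_edges", "n", "median", "q1", "q3", "iqr",
    "min", "max"}; the summary fields are None for empty input.  Bin
    counts sum to the number of tiles with data.
    """
    vals = meth["mean_meth"].dropna().to_numpy(dtype=np.float64)
    if vals.size == 0:
        edges = np.histogram_bin_edges([], bins=bins, range=(0.0, 1.0))
        return {
            "counts": np.zeros(len(edges) - 1, dtype=np.int64),
            "bin_edges": edges, "n": 0,
            "median": None, "q1": None, "q3": None, "iqr": None,
            "min": None, "max": None,
        }
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "counts": counts, "bin_edges": edges, "n": int(vals.size),
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "iqr": float(q3 - q1), "min": float(vals.min()), "max": float(vals.max()),
    }


def dmr_overlap(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> tuple[float | None, float | None]:
    """Reciprocal DMR overlap between two call sets on the same tile grid.

    Returns (pct of A's DMR tiles also DMRs in B, pct of B's DMR tiles
    also DMRs in A), each 100-scaled and half-up rounded to 2 decimals;
    None where a set has zero DMRs.
    """
    a_dmr = set(calls_a.loc[calls_a["is_dmr"], "tile_id"])
    b_dmr = set(calls_b.loc[calls_b["is_dmr"], "tile_id"])
    pct_a = round_half_up(100.0 * len(a_dmr & b_dmr) / len(a_dmr)) if a_dmr else None
    pct_b = round_half_up(100.0 * len(a_dmr & b_dmr) / len(b_dmr)) if b_dmr else None
    return pct_a, pct_b


def summary_table(summaries: dict[str, DMRSummary]) -> pd.DataFrame:
    """Stack named summaries into the canonical report layout."""
    return pd.DataFrame(
        {
            "list": list(summaries),
            "n_loci": [s.n_loci for s in summaries.values()],
            "tiles_with_data": [s.n_with_data for s in summaries.values()],
            "dmrs": [s.n_dmr for s in summaries.values()],
            "pct_dmr": [s.pct_dmr for s in summaries.values()],
            "n_hypo": [s.n_hypo for s in summaries.values()],
            "n_hyper": [s.n_hyper for s in summaries.values()],
        }
    )
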