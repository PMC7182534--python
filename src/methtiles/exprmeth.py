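"""Integration of expression log fold-changes with differential methylation.

Genes are split into high / low differential-expression classes by
|log2 FC| > 1 (the "single log-fold" rule, strict).  Per-annotation
methylation differences (exon, intron, promoter intervals) are then
related to the proximal gene's logFC in two ways: Pearson correlation
of (delta methylation, logFC) within each annotation class, and a
2 x 2 DMR-rate-by-DE-class contingency test per class.

Sign conventions: logFC positive means higher expression in the test
condition (LCL); delta methylation is reference minus test, so EBV
hypomethylation appears as positive delta.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import ContingencyResult, annotation_distribution_test, closest_genes
from .diffmeth import call_dmrs, round_half_up
from .tiling import AnalysisConfig, region_methylation

logger = logging.getLogger(__name__)

EXPR_CLASSES = ("exon", "intron", "promoter")


def classify_expression(
    records: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Add a de_class column: "high" iff |logfc| > threshold, else "low".

    ``records`` needs columns gene and logfc.  Records with missing
    logfc are excluded with a logged count.
    """
    config = config or AnalysisConfig()
    n_in = len(records)
    out = records.dropna(subset=["logfc"]).reset_index(drop=True)
    if len(out) < n_in:
        logger.info("classify_expression: excluded %d records with missing logfc", n_in - len(out))
    out = out.copy()
    out["de_class"] = np.where(
        out["logfc"].abs() > config.logfc_threshold, "high", "low"
    )
    return out


def expression_class_summary(classified: pd.DataFrame) -> dict:
    """Counts per DE class, the up/down split among high-DE genes, and
    the high-class percentage (half-up, 2 dp)."""
    n = len(classified)
    n_high = int((classified["de_class"] == "high").sum())
    high = classified[classified["de_class"] == "high"]
    return {
        "n": n,
        "n_high": n_high,
        "n_low": n - n_high,
        "n_up": int((high["logfc"] > 0).sum()),
        "n_down": int((high["logfc"] < 0).sum()),
        "pct_high": round_half_up(100.0 * n_high / n) if n else None,
    }


def annotation_meth_expr(
    annotations: pd.DataFrame,
    sites_ref: pd.DataFrame,
    sites_test: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Build the per-annotation integration table.

    ``annotations`` has columns chrom, start, end, klass (exon | intron
    | promoter).  Each interval gets its methylation difference
    (reference minus test, from the two site tables), its DMR status at
    the configured threshold, its proximal gene (closest interval;
    exact ties broken by the seeded RNG), and that gene's logfc and DE
    class.  Intervals whose gene has no expression record are dropped.
    """
    config = config or AnalysisConfig()
    ann = annotations.reset_index(drop=True).copy()
    ann["tile_id"] = [
        f"{k}:{c}:{s}-{e}"
        for k, c, s, e in zip(ann["klass"], ann["chrom"], ann["start"], ann["end"])
    ]
    regions = ann[["chrom", "start", "end", "tile_id"]]
    meth_ref = region_methylation(regions, sites_ref)
    meth_test = region_methylation(regions, sites_test)
    calls = call_dmrs(meth_ref, meth_test, config)
    rows = ann.merge(
        calls[["tile_id", "meth_ref", "meth_test", "delta", "is_dmr"]], on="tile_id"
    )
    rows["gene"] = closest_genes(rows, genes, seed=config.rng_seed)
    expr = classify_expression(expression, config)
    rows = rows.merge(
        expr[["gene", "logfc", "de_class"]], on="gene", how="inner"
    )
    return rows.rename(columns={"delta": "delta_meth"})


def correlate_meth_expression(
    rows: pd.DataFrame, klass: str, method: str = "pearson"
) -> tuple[float | None, int]:
    """Correlation of (delta methylation, logFC) within one annotation class.

    Returns (r, n); r is None when n < 3 or either variable has zero
    variance.  ``method`` is "pearson" (default) or "spearman".
    """
    sub = rows[rows["klass"] == klass].dropna(subset=["delta_meth", "logfc"])
    x = sub["delta_meth"].to_numpy(dtype=np.float64)
    y = sub["logfc"].to_numpy(dtype=np.float64)
    n = len(sub)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, n
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, n


def dmr_rate_by_de_class(
    rows: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict[str, dict]:
    """Per annotation class: DMR rates split by DE class, with chi-square.

    For each class present in ``rows`` builds the 2 x 2 table
    (DE class x DMR status), reports the DMR percentage within each DE
    class (half-up, 2 dp), and the Pearson chi-square test of
    independence.  Classes with no rows, or with an empty DE class, are
    skipped with a warning.
    """
    out: dict[str, dict] = {}
    for klass in EXPR_CLASSES:
        sub = rows[rows["klass"] == klass]
        if sub.empty:
            logger.warning("dmr_rate_by_de_class: no rows for class %s", klass)
            continue
        low = sub[sub["de_class"] == "low"]
        high = sub[sub["de_class"] == "high"]
        if low.empty or high.empty:
            logger.warning("dmr_rate_by_de_class: empty DE class for %s", klass)
            continue
        table = np.array(
            [
                [int(low["is_dmr"].sum()), int((~low["is_dmr"]).sum())],
                [int(high["is_dmr"].sum()), int((~high["is_dmr"]).sum())],
            ]
        )
        try:
            test: ContingencyResult | None = annotation_distribution_test(
                table[0], table[1], method="chi_square"
            )
        except ValueError:  # zero marginal (e.g. no DMR anywhere)
            test = None
        out[klass] = {
            "n_low": len(low),
            "n_high": len(high),
            "pct_dmr_low": round_half_up(100.0 * len(low[low["is_dmr"]]) / len(low)),
            "pct_dmr_high": round_half_up(100.0 * len(high[high["is_dmr"]]) / len(high)),
            "table": table,
            "chi_square": test,
        }
    return out
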