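"""Resampling-based depletion test for DMRs in a locus set.

The question: does a named locus set (e.g. disease-risk SNP windows)
contain fewer DMRs than expected given an unbiased background catalogue
of SNP windows?  The null is built by repeatedly drawing pseudo locus
sets of the same size from the background call set and counting DMRs in
each draw.  Significance is the add-one empirical lower-tail
probability

    p = (1 + #{draws <= observed}) / (1 + n_draws)

which is never exactly 0 with finitely many draws.  Each draw samples
tiles without replacement — a draw is itself a pseudo locus set.

A binomial lower-tail calculator is included for threshold-adjustment
arguments ("even if x% of these were DMRs, observing k or fewer would
have probability ...").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tiling import AnalysisConfig

# above this many sampled cells, fall back to a per-draw loop to bound memory
_VECTORIZED_CELL_LIMIT = 50_000_000


@dataclass(frozen=True)
class DepletionResult:
    """Observed DMR count against its resampled background distribution."""

    observed_dmr: int
    n_query: int
    draws: np.ndarray = field(repr=False)
    seed: int = 0
    tail: str = "lower"

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def min_draw(self) -> int:
        return int(self.draws.min())

    @property
    def max_draw(self) -> int:
        return int(self.draws.max())

    @property
    def empirical_p(self) -> float:
        if self.tail == "lower":
            k = int(np.sum(self.draws <= self.observed_dmr))
        else:
            k = int(np.sum(self.draws >= self.observed_dmr))
        return (1 + k) / (1 + self.n_draws)

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": self.observed_dmr,
                "n_query": self.n_query,
                "n_draws": self.n_draws,
                "seed": self.seed,
                "tail": self.tail,
                "min": self.min_draw,
                "max": self.max_draw,
                "empirical_p": self.empirical_p,
                "draws": self.draws.tolist(),
            }
        )


def _sample_dmr_counts(
    is_dmr: np.ndarray, n_query: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """DMR count in each of n_draws without-replacement samples of size
    n_query from the background 0/1 vector."""
    n_bg = len(is_dmr)
    if n_draws * n_bg <= _VECTORIZED_CELL_LIMIT:
        # rank the first n_query positions of a random permutation per draw
        keys = rng.random((n_draws, n_bg))
        idx = np.argpartition(keys, n_query - 1, axis=1)[:, :n_query]
        return is_dmr[idx].sum(axis=1).astype(np.int64)
    counts = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        counts[i] = is_dmr[rng.choice(n_bg, size=n_query, replace=False)].sum()
    return counts


def resample_depletion(
    observed_dmr: int,
    n_query: int,
    background_calls: pd.DataFrame,
    config: AnalysisConfig | None = None,
    *,
    tail: str = "lower",
) -> DepletionResult:
    """Empirical depletion test of a locus set against a background.

    Parameters
    ----------
    observed_dmr, n_query
        DMR count and tiles-with-data count of the query locus set
        (take them from a :class:`~methtiles.diffmeth.DMRSummary`).
    background_calls
        DMR call table for the background catalogue; each draw samples
        ``n_query`` of its rows without replacement.
    tail
        "lower" (depletion, the headline test) or "upper" (enrichment).

    Deterministic for a fixed ``config.rng_seed``.
    """
    config = config or AnalysisConfig()
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    is_dmr = background_calls["is_dmr"].to_numpy(dtype=bool).astype(np.int64)
    if len(is_dmr) < n_query:
        raise ValueError(
            f"background has {len(is_dmr)} tiles with data, fewer than n_query={n_query}"
        )
    rng = np.random.default_rng(config.rng_seed)
    draws = _sample_dmr_counts(is_dmr, n_query, config.n_resample_draws, rng)
    return DepletionResult(
        observed_dmr=int(observed_dmr),
        n_query=int(n_query),
        draws=draws,
        seed=config.rng_seed,
        tail=tail,
    )


def depletion_from_summary(
    query_summary, background_calls: pd.DataFrame, config: AnalysisConfig | None = None, **kw
) -> DepletionResult:
    """Convenience wrapper taking a DMRSummary for the query set."""
    return resample_depletion(
        query_summary.n_dmr, query_summary.n_with_data, background_calls, config, **kw
    )


def binomial_lower_tail(n: int, k: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), computed stably.

    Evaluated through the regularised incomplete beta function rather
    than naive term products, so it stays accurate for large n and
    extreme p.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("require 0 <= p <= 1")
    return float(stats.binom.cdf(k, n, p))
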