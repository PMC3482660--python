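"""Sliding-window functional enrichment along an abundance-ranked gene list.

Genes are ranked by absolute expression; a window of fixed size slides along
the ranking and, for each position, the overlap between the window and a
functional category is tested with a Fisher exact test (one-sided
over-representation by default, which for a 2x2 table equals the
hypergeometric upper tail).  P-values are corrected per category across all
windows with the Benjamini-Hochberg step-up.  A separate exact binomial test
serves paired gene-property associations (e.g. repression of sense genes
whose antisense partner is expressed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["sliding_window_test", "adjust_fdr", "binomial_association"]


def sliding_window_test(
    ranked: list[str] | pd.Index,
    category: set[str],
    window: int = 200,
    step: int = 1,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher exact test of category overlap in each window of a ranked list.

    Parameters
    ----------
    ranked : ordered gene ids (a permutation of the universe, no duplicates)
    category : gene ids forming the functional category (subset of universe)
    window, step : window size and slide increment, in genes
    alternative : 'greater' (over-representation, default) or 'two-sided'

    Returns a frame with one row per window: start rank (1-based), window
    size, overlap count ``k``, Fisher ``p`` and BH-adjusted ``q``.
    """
    ranked = list(ranked)
    n_universe = len(ranked)
    if len(set(ranked)) != n_universe:
        raise ValueError("ranked list contains duplicates")
    if not category:
        raise ValueError("empty category")
    if not set(category) <= set(ranked):
        raise ValueError("category is not a subset of the ranked universe")
    if not 1 <= window <= n_universe:
        raise ValueError("window must be between 1 and the universe size")
    in_cat = np.fromiter((g in category for g in ranked), dtype=bool, count=n_universe)
    k_total = int(in_cat.sum())
    cumulative = np.concatenate([[0], np.cumsum(in_cat)])
    starts = np.arange(0, n_universe - window + 1, step)
    k = cumulative[starts + window] - cumulative[starts]
    if alternative == "greater":
        # one-sided Fisher == hypergeometric upper tail P(X >= k)
        p = stats.hypergeom.sf(k - 1, n_universe, k_total, window)
    elif alternative == "two-sided":
        p = np.array(
            [
                stats.fisher_exact(
                    [[ki, window - ki], [k_total - ki, n_universe - window - k_total + ki]],
                    alternative="two-sided",
                )[1]
                for ki in k
            ]
        )
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = np.clip(p, 0.0, 1.0)
    q = adjust_fdr(p)
    return pd.DataFrame(
        {"start_rank": starts + 1, "window": window, "overlap": k, "p": p, "q": q}
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment ('FDR' correction)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_association(k_successes: int, n_trials: int, p0: float) -> float:
    """One-sided exact binomial tail ``P(X >= k | n, p0)``.

    ``p0`` is the background success fraction (e.g. the zone-1 fraction
    among all sense genes when testing whether antisense-associated genes
    are preferentially repressed).
    """
    if not 0 <= k_successes <= n_trials:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k_successes - 1, n_trials, p0))
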