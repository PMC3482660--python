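"""Expression-zone classification and abundance-distribution summaries.

mRNA abundance is stratified relative to the one-copy-per-cell mark into
three zones: zone 1 (< 0.5 copies/cell, tightly repressed), zone 2
(0.5-2 copies/cell, around a single copy), and zone 3 (> 2 copies/cell,
robust expression).  Features quantified at exactly 0.5 or 2.0 copies fall
in zone 2, keeping it a closed interval.  Features with no detectable
signal are a separate bucket, never zone 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable

__all__ = ["ZONE_LOW", "ZONE_HIGH", "zone_of", "zone_summary", "ZoneSummary", "cumulative_share", "powerlaw_rank_fit", "RankFit"]

ZONE_LOW = 0.5
ZONE_HIGH = 2.0


def zone_of(copies, t_low: float = ZONE_LOW, t_high: float = ZONE_HIGH):
    """Zone (1, 2 or 3) for a copies/cell value or array of values."""
    c = np.asarray(copies, dtype=float)
    if np.any(c < 0):
        raise ValueError("copies/cell must be non-negative")
    z = np.where(c < t_low, 1, np.where(c <= t_high, 2, 3))
    return int(z) if z.ndim == 0 else z


@dataclass
class ZoneSummary:
    """Per-zone bookkeeping over a declared feature universe.

    ``table`` is indexed by zone (1, 2, 3) plus a ``no_signal`` row, with
    columns: count, fraction_percent (one decimal, of the universe),
    protein_detected_percent and median_copies.  ``frac_below_10`` is the
    fraction of zone-2/3 features at < 10 copies/cell.
    """

    table: pd.DataFrame
    universe_size: int
    frac_below_10: float
    assignments: pd.Series


def zone_summary(
    expression: ExpressionTable,
    detected_proteins: set[str] | None = None,
    universe: set[str] | None = None,
    t_low: float = ZONE_LOW,
    t_high: float = ZONE_HIGH,
) -> ZoneSummary:
    """Classify every quantified feature and tally per-zone statistics.

    Universe members missing from the expression table, or present but
    undetected, are counted in the ``no_signal`` bucket.
    """
    if universe is None:
        universe_idx = expression.data.index
    else:
        universe_idx = pd.Index(sorted(universe))
    if len(universe_idx) == 0:
        raise ValueError("empty universe")
    copies = expression.copies.reindex(universe_idx)
    quantified = copies.notna() & (copies > 0)
    zones = pd.Series("no_signal", index=universe_idx, dtype=object)
    zones[quantified] = zone_of(copies[quantified].to_numpy(), t_low, t_high)

    prot = set() if detected_proteins is None else set(detected_proteins)
    rows = []
    for z in [1, 2, 3, "no_signal"]:
        members = universe_idx[zones == z]
        n = len(members)
        with_prot = sum(1 for m in members if m in prot)
        rows.append(
            {
                "zone": z,
                "count": n,
                "fraction_percent": round(100.0 * n / len(universe_idx), 1),
                "protein_detected_percent": round(100.0 * with_prot / n, 1) if n else np.nan,
                "median_copies": float(copies[members].median()) if n and z != "no_signal" else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("zone")
    in23 = copies[(zones == 2) | (zones == 3)]
    frac_below_10 = float((in23 < 10).mean()) if len(in23) else np.nan
    return ZoneSummary(
        table=table,
        universe_size=len(universe_idx),
        frac_below_10=frac_below_10,
        assignments=zones,
    )


def cumulative_share(copies: pd.Series, top_fraction: float) -> float:
    """Share of total molecules carried by the top expressed features.

    Features are sorted by descending abundance; the top
    ``ceil(top_fraction * n)`` features' summed copies are divided by the
    grand total.
    """
    vals = copies.dropna().to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("empty expression table")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    vals = np.sort(vals)[::-1]
    k = int(np.ceil(top_fraction * len(vals)))
    return float(vals[:k].sum() / vals.sum())


@dataclass(frozen=True)
class RankFit:
    """Power-law fit of abundance against expression rank, in log-log space."""

    exponent: float
    intercept: float
    rank_range: tuple[int, int]


def powerlaw_rank_fit(copies: pd.Series, rank_range: tuple[int, int]) -> RankFit:
    """Least-squares slope of log(abundance) on log(rank) over a rank window.

    Ranks are 1-based over features sorted by descending abundance;
    ``rank_range`` is inclusive.  Zero abundances inside the window are
    excluded with a warning.
    """
    import warnings

    lo, hi = rank_range
    vals = np.sort(copies.dropna().to_numpy(dtype=float))[::-1]
    if not (1 <= lo < hi <= len(vals)):
        raise ValueError(f"rank range {rank_range} outside data of size {len(vals)}")
    window = vals[lo - 1 : hi]
    ranks = np.arange(lo, hi + 1, dtype=float)
    pos = window > 0
    if not pos.all():
        warnings.warn(f"excluding {int((~pos).sum())} zero abundance(s) in rank range", stacklevel=2)
    if pos.sum() < 2:
        raise ValueError("fewer than 2 positive abundances in rank range")
    res = stats.linregress(np.log(ranks[pos]), np.log(window[pos]))
    return RankFit(exponent=float(res.slope), intercept=float(res.intercept), rank_range=(lo, hi))
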