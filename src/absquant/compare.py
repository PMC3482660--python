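"""Proliferation-versus-quiescence comparison.

Covers cell-volume geometry (rod with hemispherical caps), per-cell versus
per-volume retention of molecule classes between two conditions,
fold-change bookkeeping, correction of relative time courses for the global
decline in total RNA per cell, and protein/mRNA ratio analysis.

Retention on a per-cell basis is the ratio of total molecules per cell in
condition B over condition A (x100).  Because quiescent cells are smaller,
concentration changes are judged per volume: per-volume retention is the
per-cell retention divided by the volume ratio B/A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable

__all__ = [
    "CellGeometry",
    "cell_volume",
    "median_volume",
    "ConditionComparison",
    "retention_stats",
    "retention_from_totals",
    "fold_change_census",
    "TimeCourseTable",
    "correct_timecourse",
    "protein_mrna_ratios",
]


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped cell: length L, diameter D (um) and derived volume (um^3)."""

    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        if not self.length_um >= self.diameter_um > 0:
            raise ValueError("need L >= D > 0 (capped-rod geometry)")

    @property
    def volume_um3(self) -> float:
        return cell_volume(self.length_um, self.diameter_um)


def cell_volume(length_um: float, diameter_um: float) -> float:
    """Volume of a cylindrical cell with hemispherical caps.

    ``V = pi * D^2 * (L - D/3) / 4``; at L = D this reduces to the sphere
    volume ``pi * D^3 / 6``.
    """
    L = np.asarray(length_um, dtype=float)
    D = np.asarray(diameter_um, dtype=float)
    if np.any(~(L >= D)) or np.any(~(D > 0)):
        raise ValueError("need L >= D > 0 (capped-rod geometry)")
    V = np.pi * D**2 * (L - D / 3.0) / 4.0
    return float(V) if V.ndim == 0 else V


def median_volume(cells: pd.DataFrame) -> float:
    """Median volume of a cell-measurement table (length_um, width_um)."""
    return float(np.median(cell_volume(cells["length_um"].to_numpy(), cells["width_um"].to_numpy())))


@dataclass
class ConditionComparison:
    """Aggregate retention of one molecule class between two conditions."""

    total_a: float
    total_b: float
    volume_a: float
    volume_b: float
    per_cell_retention_percent: float
    per_volume_retention_percent: float

    @property
    def volume_ratio(self) -> float:
        return self.volume_b / self.volume_a


def retention_from_totals(
    total_a: float, total_b: float, volume_a: float = 1.0, volume_b: float = 1.0
) -> ConditionComparison:
    """Retention percentages from per-cell totals and (median) cell volumes."""
    if total_a <= 0 or total_b < 0:
        raise ValueError("totals must be positive (A) and non-negative (B)")
    if volume_a <= 0 or volume_b <= 0:
        raise ValueError("volumes must be positive")
    per_cell = 100.0 * total_b / total_a
    per_volume = per_cell / (volume_b / volume_a)
    return ConditionComparison(
        total_a=total_a,
        total_b=total_b,
        volume_a=volume_a,
        volume_b=volume_b,
        per_cell_retention_percent=per_cell,
        per_volume_retention_percent=per_volume,
    )


def retention_stats(
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    volume_a: float,
    volume_b: float,
) -> ConditionComparison:
    """Per-cell and per-volume retention of total molecules between states."""
    return retention_from_totals(expr_a.total(), expr_b.total(), volume_a, volume_b)


def fold_change_census(
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    threshold: float = 2.0,
) -> pd.Series:
    """Count features above/below a fold-change threshold between conditions.

    Ratios B/A strictly above ``threshold`` count as up, strictly below
    ``1/threshold`` as down, everything else (including ratios exactly at
    the boundary) as within.  Features detected in only one condition are
    tallied separately (``only_a``, ``only_b``), and undetected-in-both as
    ``neither``; the five buckets partition the shared universe.
    """
    universe = expr_a.data.index.union(expr_b.data.index)
    a = expr_a.copies.reindex(universe)
    b = expr_b.copies.reindex(universe)
    in_a = a.notna() & (a > 0)
    in_b = b.notna() & (b > 0)
    both = in_a & in_b
    ratio = b[both] / a[both]
    up = int((ratio > threshold).sum())
    down = int((ratio < 1.0 / threshold).sum())
    within = int(both.sum()) - up - down
    return pd.Series(
        {
            "up": up,
            "down": down,
            "within": within,
            "only_a": int((in_a & ~in_b).sum()),
            "only_b": int((in_b & ~in_a).sum()),
            "neither": int((~in_a & ~in_b).sum()),
            "universe": len(universe),
        }
    )


@dataclass
class TimeCourseTable:
    """Relative expression time course with total-RNA content fractions.

    ``ratios``: genes x time points, each gene normalized to its t0 value
    (so the t0 column is 1); ``content_fraction``: total RNA per cell at
    each time point relative to t0 (1 at t0).  Because the relative ratios
    are blind to the global decline of RNA per cell, multiplying each
    column by its content fraction recovers ratios on an absolute scale.
    """

    ratios: pd.DataFrame
    content_fraction: pd.Series

    def __post_init__(self) -> None:
        t0 = self.ratios.columns[0]
        if not np.allclose(self.ratios[t0].dropna(), 1.0):
            raise ValueError("gene ratios must equal 1 at the first time point")
        if not np.isclose(self.content_fraction.iloc[0], 1.0):
            raise ValueError("content fraction must equal 1 at the first time point")


def correct_timecourse(tc: TimeCourseTable) -> pd.DataFrame:
    """Multiply each time point's ratios by its total-RNA content fraction.

    Time points without a content fraction are dropped with a warning.
    """
    frac = tc.content_fraction.reindex(tc.ratios.columns)
    missing = frac.index[frac.isna()]
    if len(missing):
        warnings.warn(f"dropping {len(missing)} time point(s) without content fraction", stacklevel=2)
    keep = frac.index[frac.notna()]
    return tc.ratios[keep].mul(frac[keep], axis=1)


@dataclass
class ProteinMrnaRatios:
    """Per-gene protein/mRNA ratios with a sliding median and group test."""

    ratios: pd.Series
    sliding_median: pd.Series
    n_excluded: int
    mean_ratio: float
    median_ratio: float
    ratio_of_medians: float
    group_test_p: float | None = None


def protein_mrna_ratios(
    rna: ExpressionTable,
    protein: ExpressionTable,
    highlight: set[str] | None = None,
    window: int = 200,
) -> ProteinMrnaRatios:
    """Protein amplification per mRNA, across the abundance spectrum.

    For genes detected in both tables the per-gene ratio protein/mRNA is
    computed; a sliding median of the ratio is taken over genes ranked by
    protein abundance.  If ``highlight`` is given, its members' ratios are
    compared to abundance-matched background genes (nearest protein-
    abundance ranks) with a one-sided Wilcoxon rank-sum test for lower
    ratios in the highlighted group.

    Three amplification summaries are reported: mean and median of per-gene
    ratios, and the ratio of the two medians (median protein / median mRNA).
    """
    r = rna.copies
    p = protein.copies
    common = r.dropna().index.intersection(p.dropna().index)
    r = r[common]
    p = p[common]
    usable = (r > 0) & (p > 0)
    n_excluded = int((~usable).sum())
    r, p = r[usable], p[usable]
    if len(r) == 0:
        raise ValueError("no gene detected in both tables")
    ratios = (p / r).rename("protein_per_mrna")
    order = p.sort_values().index
    win = min(window, len(order))
    sliding = ratios[order].rolling(win, center=True, min_periods=max(1, win // 2)).median()

    group_p = None
    if highlight:
        members = [g for g in order if g in highlight]
        if len(members) >= 3:
            prank = pd.Series(np.arange(len(order)), index=order)
            bg_pool = [g for g in order if g not in highlight]
            bg_rank = prank[bg_pool]
            matched = []
            used = set()
            for g in members:
                # nearest unused background gene by protein-abundance rank
                dist = (bg_rank - prank[g]).abs().sort_values()
                for cand in dist.index:
                    if cand not in used:
                        used.add(cand)
                        matched.append(cand)
                        break
            group_p = float(
                stats.mannwhitneyu(ratios[members], ratios[matched], alternative="less").pvalue
            )
    return ProteinMrnaRatios(
        ratios=ratios,
        sliding_median=sliding,
        n_excluded=n_excluded,
        mean_ratio=float(ratios.mean()),
        median_ratio=float(ratios.median()),
        ratio_of_medians=float(p.median() / r.median()),
        group_test_p=group_p,
    )
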