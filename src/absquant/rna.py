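"""RNA quantification: RPK scores, mappability correction, sequencibility,
spike-in calibration and anchor-based conversion to copies/cell.

The chain is: reads per feature -> RPK (reads per kilobase of feature) ->
division by simulated-read correction factors (uneven mappability) ->
log-log regression against a calibration set of anchor mRNAs whose absolute
abundance was measured on a molecule-counting platform with external spikes
of known concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CalibrationModel,
    ErrorEstimate,
    ExpressionTable,
    bootstrap_fold_error,
    fit_loglog,
    predict_copies,
)

__all__ = [
    "ReadCountTable",
    "CorrectionFactors",
    "NCounterRun",
    "compute_rpk",
    "mappability_factors",
    "apply_correction",
    "sequencibility",
    "calibrate_spikes",
    "fit_anchor_model",
    "predict_copies",
    "bootstrap_fold_error",
]


@dataclass
class ReadCountTable:
    """Reads and feature lengths for one sequencing sample.

    ``data`` is indexed by feature id with integer column ``reads`` (>= 0)
    and column ``length_nt`` (>= 1).
    """

    sample_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = {"reads", "length_nt"} - set(self.data.columns)
        if missing:
            raise ValueError(f"read count table missing columns: {sorted(missing)}")
        if (self.data["reads"] < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.data["length_nt"] < 1).any():
            raise ValueError("feature lengths must be >= 1 nt")

    def rpk(self) -> pd.Series:
        return compute_rpk(self.data["reads"], self.data["length_nt"])


@dataclass
class CorrectionFactors:
    """Median-centered per-feature correction factors from simulated reads.

    ``factors`` holds positive factors for quantifiable features; features
    with zero simulated coverage are listed in ``unquantifiable`` and carry
    no factor.  By construction the median of defined factors is 1.
    """

    factors: pd.Series
    unquantifiable: pd.Index
    provenance: str = "simulated reads"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("correction factors must be positive")


@dataclass
class NCounterRun:
    """Molecule-counting measurements: anchor probes plus spiked controls.

    ``counts``: probe x replicate count matrix; ``spike_copies``: known
    copies/cell for the spike probes; ``anchor_ids``: probes to calibrate;
    ``run_of_replicate`` maps replicate column -> instrument run label, used
    for the within-run-then-between-run averaging.
    """

    counts: pd.DataFrame
    spike_copies: pd.Series
    anchor_ids: list[str]
    run_of_replicate: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts < 0).to_numpy().any():
            raise ValueError("counts must be non-negative")
        if self.spike_copies.nunique() < 3:
            raise ValueError("need >= 3 spikes with distinct known copies")


def compute_rpk(reads, length_nt):
    """Reads per kilobase of feature: ``reads / (length_nt / 1000)``."""
    index = getattr(reads, "index", None)
    r = np.asarray(reads, dtype=float)
    length = np.asarray(length_nt, dtype=float)
    if np.any(length < 1):
        raise ValueError("feature length must be >= 1 nt")
    out = r / (length / 1000.0)
    if out.ndim == 0:
        return float(out)
    return pd.Series(out, index=index) if index is not None else out


def mappability_factors(simulated: ReadCountTable) -> CorrectionFactors:
    """Median-centered simulated-read RPK scores used as correction factors.

    A feature's factor is its simulated RPK divided by the median simulated
    RPK over all features; zero simulated coverage makes a feature
    unquantifiable.
    """
    if len(simulated.data) == 0:
        raise ValueError("empty simulated read table")
    rpk = simulated.rpk()
    zero = rpk == 0
    defined = rpk[~zero]
    if defined.empty:
        raise ValueError("no feature with nonzero simulated coverage")
    factors = defined / defined.median()
    return CorrectionFactors(factors=factors, unquantifiable=rpk.index[zero])


def apply_correction(rpk: pd.Series, factors: CorrectionFactors) -> pd.Series:
    """Divide raw RPK scores by the per-feature correction factor.

    Features without a defined factor are dropped with a warning.
    """
    have = rpk.index.intersection(factors.factors.index)
    dropped = rpk.index.difference(have)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} feature(s) without a correction factor",
            stacklevel=2,
        )
    return rpk.loc[have] / factors.factors.loc[have]


def sequencibility(
    dna: ReadCountTable,
    simulated: ReadCountTable,
    low: float = 0.5,
    high: float = 2.0,
) -> pd.DataFrame:
    """'DNA over simulated' ratio of median-centered RPK scores.

    Ratios well below 1 mark regions hard to sequence; well above 1 mark
    copy-number excess (duplicated or multi-copy features).  Features with
    zero simulated RPK get an undefined ratio and are flagged.
    """
    common = dna.data.index.intersection(simulated.data.index)
    if common.empty:
        raise ValueError("no shared features between DNA and simulated tables")
    d = dna.rpk().loc[common]
    s = simulated.rpk().loc[common]
    d_centered = d / d[d > 0].median()
    s_centered = s / s[s > 0].median()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d_centered / s_centered
    ratio[s_centered == 0] = np.nan
    out = pd.DataFrame({"ratio": ratio})
    out["flag"] = "ok"
    out.loc[ratio < low, "flag"] = "low"
    out.loc[ratio > high, "flag"] = "high"
    out.loc[ratio.isna(), "flag"] = "undefined"
    return out


def calibrate_spikes(run: NCounterRun, log_base: float = np.e) -> tuple[pd.Series, pd.DataFrame]:
    """Convert anchor counts to copies/cell using the spiked controls.

    Per replicate, a log-log least-squares line of known spike copies on
    spike counts is fitted and inverted onto the anchor counts.  Anchor
    estimates are then averaged in linear copies space, first within and
    then between instrument runs.  Returns ``(averaged, per_replicate)``.
    """
    per_rep = {}
    for rep in run.counts.columns:
        counts = run.counts[rep]
        spikes = counts.reindex(run.spike_copies.index)
        usable = spikes > 0
        if (~usable).any():
            warnings.warn(
                f"replicate {rep}: excluding {int((~usable).sum())} spike(s) with zero counts",
                stacklevel=2,
            )
        if usable.sum() < 3:
            raise ValueError(f"replicate {rep}: fewer than 3 usable spikes")
        model = fit_loglog(spikes[usable], run.spike_copies[usable], log_base=log_base)
        anchor_counts = counts.reindex(run.anchor_ids)
        per_rep[rep] = pd.Series(model.predict(anchor_counts), index=anchor_counts.index)
    per_replicate = pd.DataFrame(per_rep)
    runs = pd.Series(run.run_of_replicate)
    within = per_replicate.T.groupby(runs).mean().T  # anchors x runs
    averaged = within.mean(axis=1)
    averaged.name = "copies"
    return averaged, per_replicate


def fit_anchor_model(
    corrected_scores: pd.Series,
    anchor_copies: pd.Series,
    log_base: float = np.e,
) -> CalibrationModel:
    """Log-log regression of anchor copies/cell on corrected RPK scores."""
    return fit_loglog(corrected_scores, anchor_copies, log_base=log_base)
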