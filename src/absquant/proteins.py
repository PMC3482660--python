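"""Protein quantification: tryptic digestion, intensity normalization,
anchor calibration, replicate variability and complex stoichiometry.

Summed per-protein MS precursor intensities scale with both protein copy
number and the number of peptides the protein can contribute to the
measurement.  Dividing the summed intensity by the count of "MS-suitable"
fully tryptic peptides (monoisotopic precursor mass within the instrument
window, 700-6000 Da by default) yields a score proportional to copies/cell,
which is then calibrated against a set of anchor proteins of independently
known abundance (heavy-peptide standards) via the shared log-log model.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .core import CalibrationModel, ErrorEstimate, bootstrap_fold_error, fit_loglog

__all__ = [
    "DigestResult",
    "digest",
    "count_ms_suitable",
    "normalized_intensity",
    "fit_protein_model",
    "replicate_cv",
    "complex_stoichiometry",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
MASS_WINDOW_DA = (700.0, 6000.0)

# cleave C-terminal of K/R unless the next residue is proline
_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


@dataclass
class DigestResult:
    """Fully tryptic peptides of one protein with monoisotopic masses.

    ``peptides`` tile the input sequence without overlap; ``n_ms_suitable``
    counts those whose mass falls in the accepted precursor window.  Peptides
    containing nonstandard residues carry mass NaN and are never counted as
    MS-suitable; ``has_nonstandard`` flags the protein.
    """

    protein_id: str
    peptides: list[tuple[str, float]]
    n_ms_suitable: int
    has_nonstandard: bool = False

    @property
    def sequence(self) -> str:
        return "".join(p for p, _ in self.peptides)


def peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass (residue masses + one water), in daltons."""
    if not set(sequence) <= STANDARD_AA:
        return float("nan")
    return float(_pmass.fast_mass(sequence, ion_type="M", charge=0))


def digest(
    sequence: str,
    protein_id: str = "",
    mass_window: tuple[float, float] = MASS_WINDOW_DA,
) -> DigestResult:
    """In-silico tryptic digest with full specificity and 0 missed cleavages.

    Cleaves after lysine or arginine unless the following residue is proline.
    ``n_ms_suitable`` is the count of peptides whose monoisotopic mass lies
    within ``mass_window`` (inclusive).
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    sequence = sequence.upper()
    nonstandard = not (set(sequence) <= STANDARD_AA)
    peptides = [(p, peptide_mass(p)) for p in _TRYPSIN.split(sequence) if p]
    lo, hi = mass_window
    n_ok = sum(1 for _, m in peptides if np.isfinite(m) and lo <= m <= hi)
    return DigestResult(
        protein_id=protein_id,
        peptides=peptides,
        n_ms_suitable=n_ok,
        has_nonstandard=nonstandard,
    )


def count_ms_suitable(sequence: str, mass_window: tuple[float, float] = MASS_WINDOW_DA) -> int:
    return digest(sequence, mass_window=mass_window).n_ms_suitable


def normalized_intensity(summed_intensity: float, n_ms_suitable: int) -> float:
    """Summed precursor intensity divided by the expected-peptide count.

    Proteins with no MS-suitable peptide are unquantifiable by this scheme;
    callers should exclude them (``n_ms_suitable = 0`` raises).
    """
    if n_ms_suitable < 1:
        raise ValueError("protein with no MS-suitable peptide is unquantifiable")
    if summed_intensity < 0:
        raise ValueError("intensity must be non-negative")
    return summed_intensity / n_ms_suitable


def normalize_table(intensities: pd.Series, n_peptides: pd.Series) -> pd.Series:
    """Vectorized peptide-count normalization; proteins with zero expected
    peptides are dropped with a warning."""
    common = intensities.index.intersection(n_peptides.index)
    n = n_peptides.loc[common]
    bad = n < 1
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} protein(s) with no MS-suitable peptides",
            stacklevel=2,
        )
    keep = common[~bad]
    return intensities.loc[keep] / n_peptides.loc[keep]


def fit_protein_model(
    normalized_scores: pd.Series,
    anchor_copies: pd.Series,
    log_base: float = np.e,
) -> CalibrationModel:
    """Anchor regression for one condition (models are fitted per sample)."""
    return fit_loglog(normalized_scores, anchor_copies, log_base=log_base)


def protein_bootstrap_error(
    normalized_scores: pd.Series,
    anchor_copies: pd.Series,
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> ErrorEstimate:
    return bootstrap_fold_error(normalized_scores, anchor_copies, n_resamples, rng)


def replicate_cv(
    intensities: pd.DataFrame,
    n_peptides: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent coefficient of variation across replicate columns.

    Returns ``(per_protein, summary)``: per-protein %CV (sample standard
    deviation over mean, x100), and a summary stratified by the number of
    quantified peptides (classes 1, 2, 3+) when ``n_peptides`` is given.
    All-zero proteins are skipped (CV undefined at mean 0).
    """
    if intensities.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    mean = intensities.mean(axis=1)
    keep = mean > 0
    sd = intensities.loc[keep].std(axis=1, ddof=1)
    cv = pd.DataFrame({"cv_percent": 100.0 * sd / mean[keep]})
    if n_peptides is None:
        summary = pd.DataFrame(
            {"n_proteins": [len(cv)], "median_cv": [cv["cv_percent"].median()], "mean_cv": [cv["cv_percent"].mean()]},
            index=pd.Index(["all"], name="peptide_class"),
        )
        return cv, summary
    classes = n_peptides.reindex(cv.index).clip(upper=3)
    labels = classes.map({1: "1", 2: "2", 3: "3+"})
    grouped = cv.groupby(labels)["cv_percent"]
    summary = pd.DataFrame(
        {"n_proteins": grouped.size(), "median_cv": grouped.median(), "mean_cv": grouped.mean()}
    )
    summary.index.name = "peptide_class"
    return cv, summary


@dataclass
class ComplexStoichiometry:
    """Member/median abundance ratios for one protein complex."""

    member_ratios: pd.Series
    cv_percent: float
    flagged: list[str]
    n_detected: int


def complex_stoichiometry(
    copies: pd.Series,
    members: list[str],
    fold_threshold: float = 2.0,
) -> ComplexStoichiometry:
    """Check a 1:1-stoichiometry complex for outlier members.

    Ratios are member abundance over the median member abundance; members
    deviating more than ``fold_threshold``-fold in either direction are
    flagged.  Fewer than 2 detected members -> undefined (raises).
    """
    present = copies.reindex(members).dropna()
    present = present[present > 0]
    if len(present) < 2:
        raise ValueError(f"complex has {len(present)} detected member(s); stoichiometry undefined")
    med = present.median()
    ratios = present / med
    flagged = list(ratios.index[(ratios > fold_threshold) | (ratios < 1 / fold_threshold)])
    cv = float(100.0 * present.std(ddof=1) / present.mean())
    return ComplexStoichiometry(member_ratios=ratios, cv_percent=cv, flagged=flagged, n_detected=len(present))
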