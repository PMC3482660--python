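"""Shared calibration machinery.

Both the RNA and the protein stage map a relative score (corrected RPK, or
peptide-normalized MS intensity) to absolute copies/cell through the same
log-log linear model fitted on a small set of anchors with independently
measured copy numbers.  The model, the prediction step and the bootstrap
error estimate live here; :mod:`absquant.rna` and :mod:`absquant.proteins`
wrap them with stage-specific preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "ExpressionTable",
    "ErrorEstimate",
    "fit_loglog",
    "predict_copies",
    "bootstrap_fold_error",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Log-space linear model ``log(copies) = intercept + slope * log(score)``.

    Parameters are stored in the log base used for fitting (``log_base``);
    predicted copy numbers are invariant to that base because the fit is an
    affine reparameterization.
    """

    slope: float
    intercept: float
    residual_sd: float
    n_anchors: int
    log_base: float = np.e

    def __post_init__(self) -> None:
        if self.n_anchors < 3:
            raise ValueError(f"need at least 3 anchors, got {self.n_anchors}")
        if self.residual_sd < 0:
            raise ValueError("residual spread must be non-negative")

    def predict(self, scores: pd.Series | np.ndarray) -> np.ndarray:
        """Predicted copies/cell for positive scores (NaN where score is 0)."""
        s = np.asarray(scores, dtype=float)
        if np.any(s < 0):
            raise ValueError("scores must be non-negative")
        with np.errstate(divide="ignore"):
            logs = np.log(s) / np.log(self.log_base)
        out = np.power(self.log_base, self.intercept + self.slope * logs)
        return np.where(s > 0, out, np.nan)


@dataclass
class ExpressionTable:
    """Per-feature estimated copies/cell for one condition.

    ``data`` is indexed by feature id with columns ``copies`` (float, NaN for
    undetected features) and ``detected`` (bool).  A feature is undetected
    exactly when its corrected score was zero.
    """

    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = {"copies", "detected"} - set(self.data.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        copies = self.data["copies"]
        if (copies.dropna() < 0).any():
            raise ValueError("copies/cell must be non-negative")

    @property
    def copies(self) -> pd.Series:
        return self.data["copies"]

    @property
    def detected(self) -> pd.Series:
        return self.data["detected"]

    def detected_ids(self) -> pd.Index:
        return self.data.index[self.data["detected"]]

    def total(self) -> float:
        """Total molecules/cell summed over detected features."""
        return float(self.data.loc[self.data["detected"], "copies"].sum())

    @classmethod
    def from_copies(cls, condition: str, copies: pd.Series) -> "ExpressionTable":
        detected = copies.notna() & (copies > 0)
        return cls(condition, pd.DataFrame({"copies": copies.where(detected), "detected": detected}))


@dataclass
class ErrorEstimate:
    """Bootstrap fold-error summary: per-anchor mean fold errors (each >= 1)."""

    fold_errors: pd.Series
    mean_fold_error: float
    n_resamples: int

    def __post_init__(self) -> None:
        if self.mean_fold_error < 1 - 1e-12:
            raise ValueError("mean fold error cannot be below 1")


def _validated_log(scores: pd.Series, copies: pd.Series, context: str) -> tuple[pd.Series, pd.Series]:
    common = scores.index.intersection(copies.index)
    s = scores.loc[common].astype(float)
    c = copies.loc[common].astype(float)
    bad = (s <= 0) | (c <= 0) | s.isna() | c.isna()
    if bad.any():
        warnings.warn(
            f"{context}: excluding {int(bad.sum())} anchor(s) with non-positive "
            f"score or copies: {list(common[bad][:5])}...",
            stacklevel=3,
        )
    return s[~bad], c[~bad]


def fit_loglog(
    scores: pd.Series,
    anchor_copies: pd.Series,
    log_base: float = np.e,
) -> CalibrationModel:
    """Least-squares fit of log(copies) on log(score) over the anchor set.

    ``scores`` are relative measurements, ``anchor_copies`` the independently
    known copies/cell; copies is the response so the fitted line predicts
    absolute abundance directly.  Anchors with zero score or copies are
    excluded with a warning; fewer than 3 usable anchors is an error.
    """
    s, c = _validated_log(scores, anchor_copies, "fit_loglog")
    if len(s) < 3:
        raise ValueError(f"need at least 3 usable anchors, got {len(s)}")
    x = np.log(s.to_numpy()) / np.log(log_base)
    y = np.log(c.to_numpy()) / np.log(log_base)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ddof = 2 if len(s) > 2 else 0
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(len(s) - ddof, 1)))
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        n_anchors=len(s),
        log_base=log_base,
    )


def predict_copies(model: CalibrationModel, scores: pd.Series, condition: str = "") -> ExpressionTable:
    """Apply a fitted model to corrected scores.

    Zero scores yield ``detected=False`` with no copies value; negative
    scores are rejected.
    """
    copies = pd.Series(model.predict(scores), index=scores.index, name="copies")
    detected = scores > 0
    return ExpressionTable(condition, pd.DataFrame({"copies": copies.where(detected), "detected": detected}))


def bootstrap_fold_error(
    scores: pd.Series,
    anchor_copies: pd.Series,
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
    log_base: float = np.e,
) -> ErrorEstimate:
    """Bootstrap the anchor regression and summarize prediction fold errors.

    Anchors are resampled with replacement, the model refitted, and every
    anchor's copies re-predicted; the per-anchor fold error is
    ``exp(|log(predicted) - log(true)|)`` averaged over resamples.  Degenerate
    resamples (a single distinct anchor) are skipped.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    rng = np.random.default_rng() if rng is None else rng
    s, c = _validated_log(scores, anchor_copies, "bootstrap_fold_error")
    if len(s) < 3:
        raise ValueError(f"need at least 3 usable anchors, got {len(s)}")
    logs = np.log(s.to_numpy())
    logc = np.log(c.to_numpy())
    n = len(s)
    acc = np.zeros(n)
    used = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        x, y = logs[idx], logc[idx]
        if np.ptp(x) == 0:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        pred = intercept + slope * logs
        acc += np.exp(np.abs(pred - logc))
        used += 1
    if used == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    fold = pd.Series(acc / used, index=s.index, name="fold_error")
    return ErrorEstimate(fold_errors=fold, mean_fold_error=float(fold.mean()), n_resamples=used)
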