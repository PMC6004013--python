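"""Multiplicative scatter correction and Pareto scaling.

MSC regresses each sample spectrum on a reference profile (ordinary
least squares, x = a + b*ref) and removes the fitted offset and gain:
corrected = (x - a) / b.  The reference is the per-feature median over
the pooled-QC samples, which carry no class information.  Pareto scaling
then mean-centers each feature and divides by the square root of its
standard deviation; both statistics are estimated on the training
samples only and frozen before being applied to validation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import FeatureTable, ROLE_QC

logger = logging.getLogger("uromet")

_B_TOL = 1e-12


def median_qc_reference(table: FeatureTable) -> np.ndarray:
    """Per-feature median over QC samples: the MSC reference profile."""
    qc = table.intensities.loc[table.role_mask(ROLE_QC)]
    if qc.empty:
        raise ValueError("no QC samples to build the MSC reference from")
    return np.nanmedian(qc.to_numpy(float), axis=0)


def msc_fit_apply(sample_profile, reference) -> np.ndarray:
    """Correct one sample against the reference profile.

    OLS of the sample on the reference over the features where both are
    finite; corrected = (x - a) / b.  A near-zero slope (|b| < 1e-12)
    leaves the sample uncorrected with a warning.
    """
    x = np.asarray(sample_profile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ok = np.isfinite(x) & np.isfinite(ref)
    if ok.sum() < 2:
        raise ValueError("need at least 2 common finite features for MSC")
    b, a = np.polyfit(ref[ok], x[ok], 1)
    if abs(b) < _B_TOL:
        logger.warning("MSC slope ~ 0; sample returned uncorrected")
        return x.copy()
    out = np.full_like(x, np.nan)
    out[np.isfinite(x)] = (x[np.isfinite(x)] - a) / b
    return out


def msc_apply_matrix(X, reference) -> np.ndarray:
    """Row-wise MSC of a (samples x features) matrix."""
    X = np.asarray(X, dtype=float)
    return np.vstack([msc_fit_apply(row, reference) for row in X])


@dataclass
class ScalingParams:
    """Frozen Pareto statistics (train-only)."""

    mean: np.ndarray   # per-feature mean
    sd: np.ndarray     # per-feature sample standard deviation

    @property
    def scale(self) -> np.ndarray:
        return np.sqrt(self.sd)


def pareto_fit(train_matrix) -> ScalingParams:
    """Per-feature mean and sample sd (ddof=1) from training rows only."""
    X = np.asarray(train_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples for Pareto scaling")
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    if np.any(sd == 0):
        logger.warning("%d constant feature(s); Pareto maps them to 0", int((sd == 0).sum()))
    return ScalingParams(mean=mean, sd=sd)


def pareto_apply(matrix, params: ScalingParams) -> np.ndarray:
    """z = (x - mean) / sqrt(sd); zero-variance features map to 0."""
    X = np.asarray(matrix, dtype=float)
    scale = params.scale
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (X - params.mean) / scale
    z[:, params.sd == 0] = 0.0
    return z


@dataclass
class Preprocessor:
    """MSC-then-Pareto pipeline with train-frozen statistics.

    MSC is always fitted over the full feature profile — never over a
    reduced panel, where the per-sample gain regression would absorb the
    class effect itself.  When the downstream model uses only a feature
    subset (e.g. after VIP screening), ``columns`` selects those columns
    *after* the full-profile MSC; ``transform`` then expects full-width
    input and returns the subset.
    """

    reference: np.ndarray
    scaling: ScalingParams | None = None
    columns: np.ndarray | None = None  # int indices into the full profile

    @classmethod
    def fit(cls, X_train, reference, columns=None) -> "Preprocessor":
        ref = np.asarray(reference, dtype=float)
        cols = None if columns is None else np.asarray(columns, dtype=int)
        corrected = msc_apply_matrix(X_train, ref)
        if cols is not None:
            corrected = corrected[:, cols]
        return cls(reference=ref, scaling=pareto_fit(corrected), columns=cols)

    def transform(self, X) -> np.ndarray:
        if self.scaling is None:
            raise ValueError("Preprocessor not fitted")
        corrected = msc_apply_matrix(X, self.reference)
        if self.columns is not None:
            corrected = corrected[:, self.columns]
        return pareto_apply(corrected, self.scaling)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.tolist(),
            "mean": self.scaling.mean.tolist(),
            "sd": self.scaling.sd.tolist(),
            "columns": None if self.columns is None else self.columns.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        cols = d.get("columns")
        return cls(
            reference=np.asarray(d["reference"], float),
            scaling=ScalingParams(np.asarray(d["mean"], float), np.asarray(d["sd"], float)),
            columns=None if cols is None else np.asarray(cols, int),
        )
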