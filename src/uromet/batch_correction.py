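"""QC-anchored batch-effect correction for LC-MS peak tables.

Within each analytical batch, instrument response drifts smoothly with
injection order.  The periodic injections of a pooled quality-control
(QC) sample trace that drift per feature, and a support-vector regression
with a radial-basis kernel (QC-SVRC) fitted on (injection order, QC
intensity) provides a nonparametric drift curve.  Every sample intensity
is then normalized to the curve:

    x'(s, f) = x(s, f) * qc_reference(f, batch) / drift(f, batch)(order(s))

SVR hyperparameters follow fixed rules: the epsilon-insensitive tube is
+-2.5% of the per-feature QC median (the expected instrumental
precision), the cost C is the QC median itself, and the kernel width
gamma is picked from the grid [2^-3, 2^-2, ..., 2^9] by 10-fold
root-mean-squared cross-validation error (RMSECV), smallest gamma
winning ties.

Between batches, per-feature QC medians are equalized by scaling each
batch by pooled-QC-median / batch-QC-median.  Background features are
removed by comparing blank to QC medians, and features whose
post-correction QC RSD exceeds 15% are dropped as unreliable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .core_io import (
    FeatureTable,
    ROLE_BLANK,
    ROLE_QC,
    exclude_conditioning,
)

logger = logging.getLogger("uromet")

#: gamma candidates 2^-3 .. 2^9
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-3, 10))

DEFAULT_RSD_THRESHOLD = 15.0
DEFAULT_BLANK_RATIO = 1.0 / 3.0
#: drift predictions are clipped at this fraction of the QC reference
POSITIVE_FLOOR_FRACTION = 1e-6


class CorrectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# RSD
# ---------------------------------------------------------------------------

def compute_rsd(values) -> float:
    """Relative standard deviation in percent: sd / mean * 100.

    Sample (ddof=1) standard deviation over the finite entries.  Returns
    NaN when fewer than two finite values remain or the mean is not
    positive — callers treat NaN as "unreliable".
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m * 100.0)


def qc_rsd_per_feature(table: FeatureTable) -> pd.Series:
    """Pooled-across-batch QC RSD (%) for every feature."""
    qc = table.intensities.loc[table.role_mask(ROLE_QC)]
    return pd.Series(
        {fid: compute_rsd(qc[fid].to_numpy()) for fid in table.feature_ids},
        name="rsd_qc",
    )


# ---------------------------------------------------------------------------
# SVR hyperparameters and drift fitting
# ---------------------------------------------------------------------------

@dataclass
class SvrcHyperparams:
    epsilon: float
    cost: float
    gamma: float
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 10


@dataclass
class DriftModel:
    """Fitted drift curve for one (feature, batch)."""

    feature_id: str
    batch: int
    hyperparams: SvrcHyperparams
    qc_reference: float  # median QC intensity in this batch
    rmsecv_by_gamma: dict[float, float] = field(default_factory=dict)
    _svr: SVR | None = None
    constant: bool = False  # fallback: f == qc_reference

    def predict(self, orders) -> np.ndarray:
        orders = np.atleast_1d(np.asarray(orders, dtype=float))
        if self.constant or self._svr is None:
            out = np.full(orders.shape, self.qc_reference)
        else:
            out = self._svr.predict(orders.reshape(-1, 1))
        floor = POSITIVE_FLOOR_FRACTION * max(self.qc_reference, 1e-300)
        return np.maximum(out, floor)

    # spec alias: the model "is" the function f
    __call__ = predict


def _cv_blocks(n: int, folds: int) -> list[np.ndarray]:
    """Contiguous blocks over injection order (temporal structure kept)."""
    folds = min(folds, n)
    return [b for b in np.array_split(np.arange(n), folds) if b.size]


def select_hyperparams(
    qc_orders,
    qc_values,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 10,
) -> SvrcHyperparams:
    """Per-feature SVR hyperparameters from QC responses.

    epsilon = 2.5% of the QC median, cost = QC median, gamma = the grid
    member minimizing the k-fold RMSECV (leave-one-out when there are
    fewer QCs than folds; ties resolve to the smallest gamma).
    """
    orders = np.asarray(qc_orders, dtype=float)
    values = np.asarray(qc_values, dtype=float)
    ok = np.isfinite(values)
    orders, values = orders[ok], values[ok]
    if values.size < 3:
        raise CorrectionError("need at least 3 QC points to select hyperparameters")

    med = float(np.median(values))
    epsilon = 0.025 * med
    cost = med
    if cost <= 0:
        raise CorrectionError("QC median must be positive")

    idx = np.argsort(orders)
    orders, values = orders[idx], values[idx]
    blocks = _cv_blocks(values.size, cv_folds)

    rmsecv: dict[float, float] = {}
    X = orders.reshape(-1, 1)
    for gamma in gamma_grid:
        sq = []
        for held in blocks:
            mask = np.ones(values.size, bool)
            mask[held] = False
            if mask.sum() < 2:
                continue
            svr = SVR(kernel="rbf", C=cost, epsilon=epsilon, gamma=gamma)
            svr.fit(X[mask], values[mask])
            err = svr.predict(X[held]) - values[held]
            sq.extend((err**2).tolist())
        rmsecv[gamma] = float(np.sqrt(np.mean(sq))) if sq else float("inf")

    best = min(gamma_grid, key=lambda g: (rmsecv[g], g))
    hp = SvrcHyperparams(epsilon=epsilon, cost=cost, gamma=best,
                         gamma_grid=tuple(gamma_grid), cv_folds=cv_folds)
    hp.rmsecv = rmsecv  # kept for reporting
    return hp


def fit_drift(qc_orders, qc_values, hyperparams: SvrcHyperparams,
              feature_id: str = "", batch: int = 0) -> DriftModel:
    """Fit the radial-basis SVR drift curve on QC points."""
    orders = np.asarray(qc_orders, dtype=float)
    values = np.asarray(qc_values, dtype=float)
    ok = np.isfinite(values)
    orders, values = orders[ok], values[ok]
    qc_reference = float(np.median(values))

    svr = SVR(kernel="rbf", C=hyperparams.cost, epsilon=hyperparams.epsilon,
              gamma=hyperparams.gamma)
    svr.fit(orders.reshape(-1, 1), values)
    model = DriftModel(
        feature_id=feature_id,
        batch=batch,
        hyperparams=hyperparams,
        qc_reference=qc_reference,
        rmsecv_by_gamma=getattr(hyperparams, "rmsecv", {}),
        _svr=svr,
    )
    if np.all(svr.predict(orders.reshape(-1, 1)) <= 0):
        logger.warning(
            "degenerate SVR fit for feature %s batch %s; using constant reference",
            feature_id, batch,
        )
        model.constant = True
        model._svr = None
    return model


def fit_drift_models(
    table: FeatureTable,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 10,
) -> dict[tuple[str, int], DriftModel]:
    """Select hyperparameters and fit one drift model per (feature, batch).

    Features whose QCs cannot support an SVR fit (fewer than 3 finite QC
    points or non-positive median) fall back to a constant-median model so
    feature sets stay aligned across batches.
    """
    models: dict[tuple[str, int], DriftModel] = {}
    qc_mask = table.role_mask(ROLE_QC)
    for batch, grp in table.samples[qc_mask].groupby("batch"):
        orders = grp["injection_order"].to_numpy(float)
        block = table.intensities.loc[grp.index]
        for fid in table.feature_ids:
            values = block[fid].to_numpy(float)
            try:
                hp = select_hyperparams(orders, values, gamma_grid, cv_folds)
                models[(fid, batch)] = fit_drift(orders, values, hp, fid, batch)
            except CorrectionError:
                finite = values[np.isfinite(values)]
                ref = float(np.median(finite)) if finite.size else 1.0
                models[(fid, batch)] = DriftModel(
                    feature_id=fid, batch=batch,
                    hyperparams=SvrcHyperparams(0.0, max(ref, 1e-12), gamma_grid[0],
                                                tuple(gamma_grid), cv_folds),
                    qc_reference=max(ref, 1e-12), constant=True,
                )
    return models


def apply_within_batch(
    table: FeatureTable, drift_models: dict[tuple[str, int], DriftModel]
) -> FeatureTable:
    """Normalize every sample to its batch drift curve.

    x' = x * qc_reference / f(order); applied to every role; missing
    intensities stay missing.
    """
    out = table.copy()
    X = out.intensities.to_numpy(float)
    orders = out.samples["injection_order"].to_numpy(float)
    batches = out.samples["batch"].to_numpy()
    for b in np.unique(batches):
        rows = np.where(batches == b)[0]
        for j, fid in enumerate(out.feature_ids):
            model = drift_models.get((fid, int(b)))
            if model is None:
                raise CorrectionError(f"no drift model for feature {fid!r} batch {b}")
            f = model.predict(orders[rows])
            X[rows, j] = X[rows, j] * model.qc_reference / f
    out.intensities = pd.DataFrame(X, index=out.sample_ids, columns=out.feature_ids)
    return out


def apply_between_batch(table: FeatureTable) -> FeatureTable:
    """Equalize per-feature QC medians across batches.

    Each intensity in batch k is multiplied by
    median(QC, all batches) / median(QC, batch k), so every batch's QC
    median lands on the pooled value.
    """
    qc_mask = table.role_mask(ROLE_QC)
    if not qc_mask.any():
        raise CorrectionError("no QC samples: cannot scale between batches")
    out = table.copy()
    X = out.intensities.to_numpy(float)
    batches = out.samples["batch"].to_numpy()
    qc_rows = np.where(qc_mask)[0]

    batch_meds = {}
    for b in np.unique(batches):
        qc_b = np.intersect1d(qc_rows, np.where(batches == b)[0])
        if qc_b.size == 0:
            raise CorrectionError(f"batch {b} has no QC samples")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            batch_meds[b] = np.nanmedian(X[qc_b], axis=0)
    # cross-batch level: median over the per-batch QC medians
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled = np.nanmedian(np.vstack(list(batch_meds.values())), axis=0)
    for b, med_b in batch_meds.items():
        rows_b = np.where(batches == b)[0]
        factor = np.where(
            np.isfinite(med_b) & (med_b > 0) & np.isfinite(pooled), pooled / med_b, 1.0
        )
        X[rows_b] = X[rows_b] * factor
    out.intensities = pd.DataFrame(X, index=out.sample_ids, columns=out.feature_ids)
    return out


# ---------------------------------------------------------------------------
# feature filters and report
# ---------------------------------------------------------------------------

@dataclass
class CorrectionReport:
    """Per-feature record of the correction and filtering stages."""

    per_feature: pd.DataFrame  # rsd_before, rsd_after, retained, removal_reason
    n_samples_per_batch: dict[int, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.per_feature["retained"].sum())

    def summary(self) -> dict:
        pf = self.per_feature
        return {
            "n_features": int(len(pf)),
            "n_retained": self.n_retained,
            "n_removed_rsd": int((pf["removal_reason"] == "rsd").sum()),
            "n_removed_blank": int((pf["removal_reason"] == "blank").sum()),
            "median_rsd_before": float(np.nanmedian(pf["rsd_before"])),
            "median_rsd_after": float(np.nanmedian(pf["rsd_after"])),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "summary": self.summary(),
            "n_samples_per_batch": {str(k): v for k, v in self.n_samples_per_batch.items()},
            "per_feature": json.loads(
                self.per_feature.replace({np.nan: None}).to_json(orient="index")
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def filter_blank_features(
    table: FeatureTable, blank_ratio_threshold: float = DEFAULT_BLANK_RATIO
) -> tuple[FeatureTable, pd.Series]:
    """Drop background features: median blank >= threshold * median QC.

    Returns the filtered table and the boolean Series of removed features.
    With no blanks the stage is skipped with a warning.
    """
    blank_mask = table.role_mask(ROLE_BLANK)
    removed = pd.Series(False, index=table.feature_ids)
    if not blank_mask.any():
        logger.warning("no blank samples: background-feature removal skipped")
        return table.copy(), removed
    qc_mask = table.role_mask(ROLE_QC)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        blank_med = np.nanmedian(table.intensities.to_numpy(float)[blank_mask], axis=0)
        qc_med = np.nanmedian(table.intensities.to_numpy(float)[qc_mask], axis=0)
    ok = np.isfinite(qc_med) & (qc_med > 0) & np.isfinite(blank_med)
    removed[:] = ok & (blank_med >= blank_ratio_threshold * qc_med)
    kept = table.feature_ids[~removed.to_numpy()]
    return table.subset_features(kept), removed


def filter_rsd(
    table: FeatureTable, threshold_percent: float = DEFAULT_RSD_THRESHOLD
) -> tuple[FeatureTable, pd.Series]:
    """Drop features whose QC RSD exceeds the threshold (strict >).

    A feature sitting exactly at the threshold is retained.  Features with
    undefined RSD (too few QCs, non-positive mean) are removed as
    unreliable.  Returns (filtered table, per-feature RSD Series).
    """
    rsd = qc_rsd_per_feature(table)
    bad = rsd.isna() | (rsd > threshold_percent)
    kept = table.feature_ids[~bad.to_numpy()]
    return table.subset_features(kept), rsd


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class QcDiagnostics:
    scores: pd.DataFrame          # batch, injection_order, PC1..PCk
    explained_variance_ratio: np.ndarray
    rsd_values: np.ndarray        # sorted finite per-feature QC RSDs (%)
    median_rsd: float

    def rsd_cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, F(x)) empirical CDF of per-feature QC RSD."""
        x = self.rsd_values
        return x, np.arange(1, x.size + 1) / x.size


def qc_trend_diagnostics(table: FeatureTable, n_components: int = 3) -> QcDiagnostics:
    """PCA of QC replicates vs injection order plus the QC-RSD distribution.

    Scores come from the singular value decomposition of the mean-centered
    QC intensity matrix (missing entries set to the feature mean, i.e.
    zero after centering).
    """
    qc_mask = table.role_mask(ROLE_QC)
    if qc_mask.sum() < 3:
        raise CorrectionError("need at least 3 QC samples for trend diagnostics")
    qc = table.intensities.loc[qc_mask].to_numpy(float)
    centered = qc - np.nanmean(qc, axis=0)
    centered = np.where(np.isfinite(centered), centered, 0.0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    total = float((s**2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)

    meta = table.samples[qc_mask]
    frame = pd.DataFrame(
        {"batch": meta["batch"].to_numpy(), "injection_order": meta["injection_order"].to_numpy()},
        index=meta.index,
    )
    for i in range(k):
        frame[f"PC{i + 1}"] = scores[:, i]

    rsd = qc_rsd_per_feature(table).to_numpy(float)
    rsd = np.sort(rsd[np.isfinite(rsd)])
    median = float(np.median(rsd)) if rsd.size else float("nan")
    return QcDiagnostics(frame, evr, rsd, median)


# ---------------------------------------------------------------------------
# full stack
# ---------------------------------------------------------------------------

def correct_table(
    table: FeatureTable,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 10,
    rsd_threshold: float = DEFAULT_RSD_THRESHOLD,
    blank_ratio: float = DEFAULT_BLANK_RATIO,
) -> tuple[FeatureTable, CorrectionReport]:
    """Run the whole correction stack.

    Order: drop conditioning QCs -> per-feature per-batch QC-SVRC within-
    batch normalization -> between-batch QC-median equalization -> blank-
    based background removal -> QC-RSD reliability filter.  The report
    carries pre- and post-correction QC RSDs and the removal reason per
    feature.
    """
    work = exclude_conditioning(table)
    rsd_before = qc_rsd_per_feature(work)

    models = fit_drift_models(work, gamma_grid, cv_folds)
    work = apply_within_batch(work, models)
    if work.samples["batch"].nunique() > 1:
        work = apply_between_batch(work)

    rsd_after_all = qc_rsd_per_feature(work)
    work, blank_removed = filter_blank_features(work, blank_ratio)
    work, _ = filter_rsd(work, rsd_threshold)

    reason = pd.Series("none", index=rsd_before.index)
    reason[blank_removed.reindex(reason.index, fill_value=False)] = "blank"
    still = reason == "none"
    rsd_bad = rsd_after_all.isna() | (rsd_after_all > rsd_threshold)
    reason[still & rsd_bad] = "rsd"
    retained = reason == "none"

    per_feature = pd.DataFrame(
        {
            "rsd_before": rsd_before,
            "rsd_after": rsd_after_all,
            "retained": retained,
            "removal_reason": reason,
        }
    )
    counts = work.samples.groupby("batch").size().to_dict()
    report = CorrectionReport(per_feature, {int(k): int(v) for k, v in counts.items()})
    return work, report
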