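"""PLS-DA: NIPALS partial least squares on a coded binary class.

The classifier regresses a 0/1 class coding (CTRL -> 0, BC -> 1 by
default) on the preprocessed feature matrix with univariate-response
NIPALS:

    per component a:  w_a = X'y / ||X'y||,  t_a = X w_a,
                      p_a = X't_a / t_a't_a,  q_a = y't_a / t_a't_a,
                      X <- X - t_a p_a',  y <- y - q_a t_a

The regression vector is recovered as b = W (P'W)^-1 q and predictions
are y_hat = (x - x_mean) b + y_mean, thresholded at the midpoint of the
coding (0.5).  The number of latent variables is chosen by the root mean
square error of leave-one-patient-out cross-validation (RMSECV), with
all samples of the held-out patient excluded from fitting and the
Pareto statistics re-estimated inside every fold.  Feature importance is
the Variable Importance in Projection (VIP):

    VIP_j = sqrt( p * sum_a q_a^2 t_a't_a (w_ja/||w_a||)^2
                  / sum_a q_a^2 t_a't_a )

whose squares average to 1 over features; screening keeps VIP > 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import msc_apply_matrix, pareto_apply, pareto_fit

DEFAULT_CODING = ("CTRL", "BC")  # negative, positive -> 0, 1
DEFAULT_VIP_THRESHOLD = 3.0


class PlsdaError(ValueError):
    pass


def encode_labels(labels, coding=DEFAULT_CODING) -> np.ndarray:
    neg, pos = coding
    y = np.empty(len(labels), float)
    for i, lab in enumerate(labels):
        if lab == neg:
            y[i] = 0.0
        elif lab == pos:
            y[i] = 1.0
        else:
            raise PlsdaError(f"label {lab!r} not in coding {coding}")
    return y


@dataclass
class PlsdaModel:
    """Fitted NIPALS PLS-DA model."""

    weights: np.ndarray      # W, (p, A)
    x_loadings: np.ndarray   # P, (p, A)
    y_loadings: np.ndarray   # q, (A,)
    scores: np.ndarray       # T, (n, A) train scores
    x_mean: np.ndarray
    y_mean: float
    n_lv: int
    coding: tuple[str, str] = DEFAULT_CODING
    theta: float = 0.5
    feature_ids: list[str] = field(default_factory=list)

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b = W (P'W)^-1 q."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int):
    Xa = X.copy()
    ya = y.copy()
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise PlsdaError(
                f"component {a + 1} exceeds the rank of the training matrix"
            )
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise PlsdaError(
                f"component {a + 1} exceeds the rank of the training matrix"
            )
        pvec = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa -= np.outer(t, pvec)
        ya = ya - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
    return W, P, q, T


def fit(X, y, n_lv: int, coding=DEFAULT_CODING, theta: float = 0.5,
        feature_ids=None) -> PlsdaModel:
    """Fit a PLS-DA model on a preprocessed matrix and coded y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if n_lv < 1:
        raise PlsdaError("n_lv must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, n_lv)
    return PlsdaModel(
        weights=W, x_loadings=P, y_loadings=q, scores=T,
        x_mean=x_mean, y_mean=y_mean, n_lv=n_lv, coding=tuple(coding),
        theta=theta, feature_ids=list(feature_ids) if feature_ids is not None else [],
    )


def predict(model: PlsdaModel, X_new) -> np.ndarray:
    """Continuous predicted y per sample (deterministic)."""
    X = np.asarray(X_new, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.weights.shape[0]:
        raise PlsdaError(
            f"feature mismatch: model has {model.weights.shape[0]}, input {X.shape[1]}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


def classify(y_hat, theta: float = 0.5, coding=DEFAULT_CODING) -> list[str]:
    """Threshold predicted y: >= theta -> positive class."""
    neg, pos = coding
    return [pos if v >= theta else neg for v in np.atleast_1d(np.asarray(y_hat, float))]


@dataclass
class CvCurve:
    rmsecv: np.ndarray           # index a-1 -> RMSECV with a components
    a_max: int
    n_folds: int


def cross_validate(X, y, patient_ids, a_max: int,
                   msc_reference=None) -> CvCurve:
    """Leave-one-patient-out RMSECV for 1..a_max components.

    Folds are the distinct patients; every sample of the held-out patient
    is excluded from fitting.  When ``msc_reference`` is given, rows are
    MSC-corrected against it (the reference is QC-derived, hence fold-
    invariant) and Pareto statistics are re-estimated from each fold's
    training rows, so no held-out information enters the scaling.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    patients = np.asarray(patient_ids)
    unique = np.unique(patients)
    if unique.size < 2:
        raise PlsdaError("leave-one-patient-out needs at least 2 patients")
    if msc_reference is not None:
        X = msc_apply_matrix(X, msc_reference)

    sq: list[list[float]] = [[] for _ in range(a_max)]
    for pat in unique:
        held = patients == pat
        Xtr, ytr = X[~held], y[~held]
        Xte = X[held]
        if msc_reference is not None:
            params = pareto_fit(Xtr)
            Xtr = pareto_apply(Xtr, params)
            Xte = pareto_apply(Xte, params)
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        a_fit = min(a_max, min(Xtr.shape) - 1) or 1
        W, P, q, T = _nipals(Xtr - x_mean, ytr - y_mean, a_fit)
        for a in range(1, a_max + 1):
            aa = min(a, a_fit)
            b = W[:, :aa] @ np.linalg.solve(P[:, :aa].T @ W[:, :aa], q[:aa])
            pred = (Xte - x_mean) @ b + y_mean
            sq[a - 1].extend(((pred - y[held]) ** 2).tolist())
    rmsecv = np.array([np.sqrt(np.mean(s)) for s in sq])
    return CvCurve(rmsecv=rmsecv, a_max=a_max, n_folds=unique.size)


def select_n_lv(curve: CvCurve, override: int | None = None) -> int:
    """Global RMSECV minimum (ties -> fewer components); override wins."""
    if override is not None:
        return int(override)
    return int(np.argmin(curve.rmsecv)) + 1


@dataclass
class VipResult:
    vip: np.ndarray
    threshold: float
    selected: list[int]          # feature indices, VIP > threshold
    feature_ids: list[str] = field(default_factory=list)

    @property
    def selected_ids(self) -> list[str]:
        if self.feature_ids:
            return [self.feature_ids[j] for j in self.selected]
        return [str(j) for j in self.selected]


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable Importance in Projection; sum of squares equals p."""
    W, q, T = model.weights, model.y_loadings, model.scores
    p = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)  # q_a^2 * t_a't_a
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    denom = ssy.sum()
    if denom <= 0:
        return np.zeros(p)
    return np.sqrt(p * (wn**2 @ ssy) / denom)


def screen_features(model: PlsdaModel, threshold: float = DEFAULT_VIP_THRESHOLD) -> VipResult:
    """Keep features with VIP strictly above the threshold."""
    vip = vip_scores(model)
    selected = np.where(vip > threshold)[0].tolist()
    if not selected:
        raise PlsdaError(
            f"no feature has VIP > {threshold}; lower the threshold"
        )
    return VipResult(vip=vip, threshold=threshold, selected=selected,
                     feature_ids=model.feature_ids)
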