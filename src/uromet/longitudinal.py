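"""Per-patient surveillance trajectories of the discriminant score.

After resection, a monitored patient's urine profile should sit at the
CTRL level; a drift of the PLS-DA predicted y back toward the BC side
ahead of a positive cystoscopy is the signal of interest.  A trajectory
is the patient's predicted-y series ordered by visit, and a simple
trend flag summarizes it: Spearman rank correlation with visit index
plus whether/when the series crosses the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import FeatureTable, ROLE_STUDY
from .plsda import PlsdaModel, predict
from .preprocessing import Preprocessor

FLAG_RISING = "rising_toward_BC"
FLAG_STABLE = "stable"
FLAG_INCONSISTENT = "inconsistent"
FLAG_WITHHELD = "withheld"


@dataclass
class TrajectorySeries:
    patient_id: str
    visit_index: list[int]
    sample_ids: list[str]
    y_hat: list[float]
    class_labels: list[str]
    theta: float

    def __len__(self) -> int:
        return len(self.y_hat)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "theta": self.theta,
            "points": [
                {"visit_index": v, "sample_id": s, "y_hat": y, "class_label": c}
                for v, s, y, c in zip(
                    self.visit_index, self.sample_ids, self.y_hat, self.class_labels
                )
            ],
        }


@dataclass
class TrendFlag:
    patient_id: str
    flag: str
    statistic: float          # Spearman rho of y_hat vs visit index
    crossing: int | None      # first visit with y_hat >= theta


def patient_trajectory(model: PlsdaModel, preprocessor: Preprocessor,
                       table: FeatureTable, patient_id: str) -> TrajectorySeries:
    """Predicted-y series for one patient, ordered by visit index.

    Samples are preprocessed with the model's frozen train statistics;
    the result is invariant to the input row order.
    """
    meta = table.samples
    mask = (meta["role"] == ROLE_STUDY) & (meta["patient_id"] == patient_id)
    if not mask.any():
        raise KeyError(f"no STUDY samples for patient {patient_id!r}")
    sub = meta[mask].sort_values("visit_index")
    X = table.intensities.loc[sub.index].to_numpy(float)
    y_hat = predict(model, preprocessor.transform(X))
    return TrajectorySeries(
        patient_id=patient_id,
        visit_index=[int(v) for v in sub["visit_index"]],
        sample_ids=list(sub.index),
        y_hat=[float(v) for v in y_hat],
        class_labels=[str(c) for c in sub["class_label"]],
        theta=model.theta,
    )


def trend_flag(series: TrajectorySeries, min_visits: int = 3,
               rho_cut: float = 0.6, margin: float = 0.1) -> TrendFlag:
    """Classify a trajectory as rising toward BC, stable, or inconsistent.

    rising_toward_BC: rank correlation >= rho_cut and the last score ends
    at or near the threshold (y_hat >= theta - margin).  stable: weak
    correlation (|rho| < rho_cut) and no threshold crossing.  Anything
    else — crossings without a monotone trend, strong downward drifts —
    is inconsistent.  Fewer than ``min_visits`` points withholds the flag.

    Surveillance starts after resection: pre-TURBT samples (class BC)
    are excluded from the trend, which asks whether the post-resection
    profile drifts back toward the BC side.
    """
    keep = [i for i, c in enumerate(series.class_labels) if c != "BC"]
    y = np.asarray(series.y_hat, float)[keep]
    v = np.asarray(series.visit_index, float)[keep]
    crossing_idx = np.where(y >= series.theta)[0]
    crossing = int(v[crossing_idx[0]]) if crossing_idx.size else None

    if len(y) < min_visits:
        return TrendFlag(series.patient_id, FLAG_WITHHELD, float("nan"), crossing)

    if np.allclose(y, y[0]):
        rho = 0.0
    else:
        rho = float(stats.spearmanr(v, y).statistic)

    if rho >= rho_cut and y[-1] >= series.theta - margin:
        flag = FLAG_RISING
    elif abs(rho) < rho_cut and crossing is None:
        flag = FLAG_STABLE
    else:
        flag = FLAG_INCONSISTENT
    return TrendFlag(series.patient_id, flag, rho, crossing)


def surveillance_accuracy(model: PlsdaModel, preprocessor: Preprocessor,
                          table: FeatureTable, patient_ids=None) -> float:
    """Fraction of correctly classified BC/CTRL samples among monitored patients.

    ``patient_ids`` defaults to every patient that has at least one
    MONITOR sample.
    """
    meta = table.samples
    study = meta[meta["role"] == ROLE_STUDY]
    if patient_ids is None:
        patient_ids = sorted(
            set(study.loc[study["class_label"] == "MONITOR", "patient_id"])
        )
    mask = (
        study["patient_id"].isin(list(patient_ids))
        & study["class_label"].isin(["BC", "CTRL"])
    )
    labeled = study[mask]
    if labeled.empty:
        raise ValueError("no labeled BC/CTRL samples among the given patients")
    X = table.intensities.loc[labeled.index].to_numpy(float)
    y_hat = predict(model, preprocessor.transform(X))
    neg, pos = model.coding
    predicted = np.where(y_hat >= model.theta, pos, neg)
    return float(np.mean(predicted == labeled["class_label"].to_numpy()))
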