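"""End-to-end discriminant workflow on a corrected peak table.

Glue over the stage modules: patient-wise split, MSC + Pareto
preprocessing with train-frozen statistics, latent-variable selection by
leave-one-patient-out RMSECV (or an explicit override), VIP screening
with refit of the reduced model, and validation-set figures of merit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import diagnostics, plsda
from .core_io import FeatureTable, SplitPlan, split_by_patient
from .plsda import CvCurve, PlsdaModel, VipResult
from .preprocessing import Preprocessor, median_qc_reference


@dataclass
class DiscriminantResult:
    split: SplitPlan
    preprocessor: Preprocessor
    cv_curve: CvCurve | None
    n_lv: int
    model: PlsdaModel                       # full-feature train model
    vip: VipResult
    refit_preprocessor: Preprocessor        # on the VIP-selected features
    refit_model: PlsdaModel
    metrics: diagnostics.DiscriminantMetrics
    refit_metrics: diagnostics.DiscriminantMetrics
    selected_feature_ids: list[str] = field(default_factory=list)


def _study_xy(table: FeatureTable, sample_ids, coding):
    meta = table.samples.loc[sample_ids]
    keep = meta["class_label"].isin(list(coding))
    ids = meta.index[keep]
    X = table.intensities.loc[ids].to_numpy(float)
    y = plsda.encode_labels(meta.loc[ids, "class_label"], coding)
    patients = meta.loc[ids, "patient_id"].to_numpy()
    labels = meta.loc[ids, "class_label"].to_numpy()
    return X, y, patients, labels


def run_discriminant_analysis(
    table: FeatureTable,
    assignment: Mapping[str, str],
    coding: tuple[str, str] = ("CTRL", "BC"),
    n_lv_override: int | None = 3,
    a_max: int = 10,
    vip_threshold: float = 3.0,
    prevalences=(),
    theta: float = 0.5,
) -> DiscriminantResult:
    """Train on the assigned train patients, evaluate on validation.

    ``n_lv_override`` defaults to 3 latent variables (the usual choice
    for these cohorts); pass None to take the RMSECV minimum instead.
    Only samples whose class label is in ``coding`` enter the model;
    MONITOR and unlabeled samples ride along for trajectory scoring only.
    """
    split = split_by_patient(table, assignment)
    reference = median_qc_reference(table)

    X_tr, y_tr, pat_tr, _ = _study_xy(table, split.train_sample_ids, coding)
    X_va, _, _, labels_va = _study_xy(table, split.validation_sample_ids, coding)

    if X_tr.shape[0] < 4:
        raise ValueError("too few train samples for model development")

    curve = None
    if n_lv_override is None:
        a_cap = min(a_max, min(X_tr.shape) - 1)
        curve = plsda.cross_validate(X_tr, y_tr, pat_tr, a_cap, msc_reference=reference)
        n_lv = plsda.select_n_lv(curve)
    else:
        n_lv = int(n_lv_override)

    prep = Preprocessor.fit(X_tr, reference)
    model = plsda.fit(prep.transform(X_tr), y_tr, n_lv, coding=coding, theta=theta,
                      feature_ids=list(table.feature_ids))
    neg, pos = coding
    y_hat_va = plsda.predict(model, prep.transform(X_va))
    metrics = diagnostics.evaluate(y_hat_va, labels_va, pos, neg, theta=theta,
                                   prevalences=prevalences)

    # VIP screen on the full-feature train model, then refit on the subset.
    # MSC stays fitted on the full profile (a reduced panel of class-
    # affected features would let the gain regression absorb the signal);
    # the column subset is taken after scatter correction.
    vip = plsda.screen_features(model, vip_threshold)
    sel_ids = vip.selected_ids
    cols = [list(table.feature_ids).index(f) for f in sel_ids]
    prep2 = Preprocessor.fit(X_tr, reference, columns=cols)
    n_lv2 = min(n_lv, len(cols), X_tr.shape[0] - 1)
    model2 = plsda.fit(prep2.transform(X_tr), y_tr, n_lv2, coding=coding,
                       theta=theta, feature_ids=sel_ids)
    y_hat2 = plsda.predict(model2, prep2.transform(X_va))
    metrics2 = diagnostics.evaluate(y_hat2, labels_va, pos, neg, theta=theta,
                                    prevalences=prevalences)

    return DiscriminantResult(
        split=split, preprocessor=prep, cv_curve=curve, n_lv=n_lv, model=model,
        vip=vip, refit_preprocessor=prep2, refit_model=model2,
        metrics=metrics, refit_metrics=metrics2, selected_feature_ids=sel_ids,
    )
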