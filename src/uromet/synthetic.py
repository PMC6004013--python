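"""Synthetic urinary LC-MS cohorts with known ground truth.

The generator emulates the statistical structure an untargeted urine
metabolomics surveillance study presents to the analysis pipeline:

* two analytical batches with a pooled-QC injection every ``qc_interval``
  injections and a block of conditioning QCs at the start of each batch;
* smooth within-batch intensity drift (random cubic in injection order)
  and a per-feature multiplicative between-batch offset;
* heteroscedastic technical noise: multiplicative, log-normal, constant
  coefficient of variation, so the QC relative standard deviation (RSD)
  is the natural quality metric;
* a subset of discriminant features shifted on the log2 scale between
  pre-resection (BC) and post-resection (CTRL) urine profiles;
* designated background (contaminant) features that dominate blanks;
* per-patient MONITOR trajectories in which relapsing patients drift
  linearly from the CTRL profile back to the BC profile, reaching it at
  the recurrence visit.

Everything the generator injects is returned as :class:`GroundTruth` so
downstream stages (drift correction, VIP screening, trajectory flags)
can be scored against what was actually put in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import json
import numpy as np
import pandas as pd

from .core_io import (
    CLASS_BC,
    CLASS_CTRL,
    CLASS_MONITOR,
    FeatureTable,
    ROLE_BLANK,
    ROLE_CONDITIONING_QC,
    ROLE_QC,
    ROLE_STUDY,
)


@dataclass
class SyntheticConfig:
    """Knobs of the cohort generator.

    Defaults emulate the structure of a two-batch urine surveillance
    study: QC every 5 injections, 8 conditioning QCs per batch, ~10%
    technical CV with 30% within-batch drift amplitude so that raw QC
    RSDs land near 20% (median) and the correction stage has realistic
    work to do.

    ``baseline_log_sigma`` controls the between-feature spread of mean
    intensities.  It is deliberately narrow (0.35 on the natural-log
    scale, roughly a four-fold 95% range): under Pareto scaling a
    feature's leverage in the discriminant model grows with the square
    root of its intensity, so injected class effects stay recoverable by
    VIP screening only when markers do not sit orders of magnitude below
    the bulk.  Real untargeted peak tables span a far wider dynamic
    range; see the package methods note for what that implies.
    """

    n_features: int = 300
    n_discriminant: int = 30
    n_background: int = 15
    n_patients_bc: int = 30
    n_patients_monitor: int = 6
    n_batches: int = 2
    qc_interval: int = 5
    n_conditioning_qc: int = 8
    n_blanks: int = 4
    drift_amplitude: float = 0.3
    between_batch_log2_range: float = 0.5
    noise_rsd: float = 0.10
    effect_log2fc: float = 1.0
    n_monitor_visits: int = 6
    recurrence_fraction: float = 0.5
    baseline_log_mean: float = 9.0
    baseline_log_sigma: float = 0.35
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_discriminant + self.n_background > self.n_features:
            raise ValueError("n_discriminant + n_background exceeds n_features")
        if self.qc_interval < 2:
            raise ValueError("qc_interval must be >= 2")
        for name in ("drift_amplitude", "noise_rsd", "recurrence_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        return self


@dataclass
class GroundTruth:
    """What the generator injected, for scoring recovery downstream."""

    drift_functions: dict[tuple[str, int], Callable[[np.ndarray], np.ndarray]]
    batch_factors: dict[tuple[str, int], float]
    discriminant_feature_ids: list[str]
    background_feature_ids: list[str]
    true_effects: dict[str, float]  # log2 fold change BC vs CTRL
    recurrence_visit: dict[str, int | None]  # per monitored patient

    def to_json(self, path: str | Path) -> None:
        payload = {
            "discriminant_feature_ids": self.discriminant_feature_ids,
            "background_feature_ids": self.background_feature_ids,
            "true_effects": self.true_effects,
            "recurrence_visit": self.recurrence_visit,
            "batch_factors": {f"{k[0]}|{k[1]}": v for k, v in self.batch_factors.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class _Injection:
    role: str
    batch: int
    order: int
    patient_id: str | None = None
    class_label: str | None = None
    visit_index: int | None = None


def _cubic_drift(rng: np.random.Generator, amplitude: float, n_orders: int):
    """Random smooth positive drift: 1 + amplitude * cubic scaled to max |.| = 1."""
    coef = rng.normal(size=3)

    def f(order: np.ndarray) -> np.ndarray:
        t = (np.asarray(order, dtype=float) - 1.0) / max(n_orders - 1, 1)
        poly = coef[0] * t + coef[1] * t**2 + coef[2] * t**3
        tt = np.linspace(0.0, 1.0, 101)
        ref = coef[0] * tt + coef[1] * tt**2 + coef[2] * tt**3
        peak = np.max(np.abs(ref))
        if peak < 1e-12 or amplitude == 0.0:
            return np.ones_like(t)
        return 1.0 + amplitude * poly / peak

    return f


def inject_layout(config: SyntheticConfig, rng: np.random.Generator | None = None) -> list[_Injection]:
    """Build the per-batch injection sequence.

    Each batch opens with ``n_conditioning_qc`` conditioning QCs, then the
    randomized study/blank stream with a pooled-QC injection occupying
    every ``qc_interval``-th post-conditioning slot.  All samples of one
    patient stay in one batch; patient-to-batch allocation is randomized
    under the seed.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    # per-patient sample lists (patient kept whole within a batch)
    patients: list[list[tuple[str, str, int]]] = []  # (patient, class, visit)
    for i in range(config.n_patients_bc):
        pid = f"P{i + 1:03d}"
        patients.append([(pid, CLASS_BC, 0), (pid, CLASS_CTRL, 1)])
    for i in range(config.n_patients_monitor):
        pid = f"M{i + 1:03d}"
        visits = [(pid, CLASS_BC, 0), (pid, CLASS_CTRL, 1)]
        visits += [(pid, CLASS_MONITOR, 2 + v) for v in range(config.n_monitor_visits)]
        patients.append(visits)

    batch_of_patient = rng.integers(1, config.n_batches + 1, size=len(patients))
    blanks_batch = rng.integers(1, config.n_batches + 1, size=config.n_blanks)

    injections: list[_Injection] = []
    for batch in range(1, config.n_batches + 1):
        stream: list[_Injection] = []
        for pat, b in zip(patients, batch_of_patient):
            if b != batch:
                continue
            for pid, cls, visit in pat:
                stream.append(
                    _Injection(ROLE_STUDY, batch, 0, pid, cls, visit)
                )
        for b in blanks_batch:
            if b == batch:
                stream.append(_Injection(ROLE_BLANK, batch, 0))
        rng.shuffle(stream)  # randomized acquisition order

        if 0 < len(stream) < config.qc_interval:
            # the first QC slot would never be reached: no QC in this batch
            raise ValueError(
                f"batch {batch}: qc_interval {config.qc_interval} exceeds the "
                f"{len(stream)} injections available"
            )

        order = 1
        for _ in range(config.n_conditioning_qc):
            injections.append(_Injection(ROLE_CONDITIONING_QC, batch, order))
            order += 1
        slot = 0  # post-conditioning injection counter
        queue = list(stream)
        while queue:
            slot += 1
            if slot % config.qc_interval == 0:
                injections.append(_Injection(ROLE_QC, batch, order))
            else:
                inj = queue.pop(0)
                inj.order = order
                injections.append(inj)
            order += 1
    return injections


def generate_cohort(config: SyntheticConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a cohort table plus ground truth; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    feature_ids = [f"F{j + 1:04d}" for j in range(config.n_features)]
    mz = np.round(rng.uniform(70, 1000, size=config.n_features), 4)
    rt = np.round(rng.uniform(0.3, 9.5, size=config.n_features), 3)
    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id"))

    baselines = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, config.n_features)

    special = rng.choice(config.n_features, config.n_discriminant + config.n_background, replace=False)
    disc_idx = special[: config.n_discriminant]
    bg_idx = special[config.n_discriminant:]
    disc_ids = [feature_ids[j] for j in disc_idx]
    bg_ids = [feature_ids[j] for j in bg_idx]

    # symmetric up/down class effects on the log2 scale
    signs = rng.choice([-1.0, 1.0], size=config.n_discriminant)
    log2fc = {fid: float(s * config.effect_log2fc) for fid, s in zip(disc_ids, signs)}

    layout = inject_layout(config, rng)
    batches = sorted({inj.batch for inj in layout})
    orders_per_batch = {b: max(i.order for i in layout if i.batch == b) for b in batches}

    drift_fns: dict[tuple[str, int], Callable] = {}
    batch_factors: dict[tuple[str, int], float] = {}
    for j, fid in enumerate(feature_ids):
        for b in batches:
            drift_fns[(fid, b)] = _cubic_drift(rng, config.drift_amplitude, orders_per_batch[b])
            u = rng.uniform(-config.between_batch_log2_range, config.between_batch_log2_range)
            batch_factors[(fid, b)] = float(2.0**u) if config.between_batch_log2_range > 0 else 1.0

    # relapse schedule: relapsing patients reach the BC profile at their last visit
    monitor_ids = [f"M{i + 1:03d}" for i in range(config.n_patients_monitor)]
    n_relapse = int(round(config.recurrence_fraction * len(monitor_ids)))
    relapsers = set(rng.choice(monitor_ids, n_relapse, replace=False)) if monitor_ids else set()
    last_visit = 1 + config.n_monitor_visits
    recurrence_visit = {
        pid: (last_visit if pid in relapsers else None) for pid in monitor_ids
    }

    sigma = np.sqrt(np.log1p(config.noise_rsd**2))

    def noise(n: int) -> np.ndarray:
        if config.noise_rsd == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, sigma, n) - sigma**2 / 2.0)  # mean-1 log-normal

    is_bg = np.zeros(config.n_features, bool)
    is_bg[bg_idx] = True

    disc_pos = {fid: j for j, fid in enumerate(feature_ids) if fid in log2fc}

    def class_effect(inj: _Injection) -> np.ndarray:
        """Per-feature multiplicative class effect for one study sample."""
        e = np.ones(config.n_features)
        if inj.class_label == CLASS_BC:
            frac = 1.0
        elif inj.class_label == CLASS_MONITOR:
            rv = recurrence_visit.get(inj.patient_id)
            if rv is None:
                return e
            # linear CTRL -> BC interpolation: 0 at the first post-TURBT
            # visit (index 1), 1 at the recurrence visit
            frac = min(max((inj.visit_index - 1) / (rv - 1), 0.0), 1.0)
        else:  # CTRL or unlabeled
            return e
        for fid, fc in log2fc.items():
            e[disc_pos[fid]] = 2.0 ** (fc * frac)
        return e

    rows = []
    meta_rows = []
    counter = 0
    for inj in layout:
        counter += 1
        sid = f"S{counter:04d}"
        d = np.array([drift_fns[(fid, inj.batch)](np.array([inj.order]))[0] for fid in feature_ids])
        g = np.array([batch_factors[(fid, inj.batch)] for fid in feature_ids])
        eta = noise(config.n_features)
        if inj.role == ROLE_BLANK:
            base = np.where(is_bg, baselines, 0.0)
            x = base * d * g * eta
        elif inj.role in (ROLE_QC, ROLE_CONDITIONING_QC):
            # pooled aliquot of every study sample: baseline level, no class effect
            x = baselines * d * g * eta
        else:
            x = baselines * class_effect(inj) * d * g * eta
        rows.append(x)
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": inj.patient_id,
                "batch": inj.batch,
                "injection_order": inj.order,
                "role": inj.role,
                "class_label": inj.class_label,
                "visit_index": inj.visit_index,
            }
        )

    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    samples["visit_index"] = samples["visit_index"].astype("Int64")
    intensities = pd.DataFrame(np.vstack(rows), index=samples.index, columns=features.index)

    table = FeatureTable(intensities, samples, features).validate()
    truth = GroundTruth(
        drift_functions=drift_fns,
        batch_factors=batch_factors,
        discriminant_feature_ids=disc_ids,
        background_feature_ids=bg_ids,
        true_effects=log2fc,
        recurrence_visit=recurrence_visit,
    )
    return table, truth


def default_assignment(table: FeatureTable, train_fraction: float = 0.4,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> dict[str, str]:
    """Random patient-level train/validation assignment.

    BC/CTRL-only patients are split at ``train_fraction``; monitored
    patients always go to validation (surveillance trajectories are never
    used to fit the discriminant model).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    study = table.samples[table.samples["role"] == ROLE_STUDY]
    monitored = set(
        study.loc[study["class_label"] == CLASS_MONITOR, "patient_id"]
    )
    plain = sorted(set(study["patient_id"]) - monitored)
    n_train = int(round(train_fraction * len(plain)))
    train = set(rng.choice(plain, n_train, replace=False)) if plain else set()
    assignment = {p: ("train" if p in train else "validation") for p in plain}
    assignment.update({p: "validation" for p in monitored})
    return assignment
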