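"""Peak-table data model, delimited-text I/O and patient-wise splitting.

The central container is :class:`FeatureTable`: an intensity matrix
(samples x features, arbitrary units, NaN = missing) together with
per-sample metadata (batch, injection order, role, class label, patient,
visit index) and per-feature metadata (m/z in Da, retention time in
minutes).  Every pipeline stage consumes and returns a ``FeatureTable``.

On disk a table is a single UTF-8 CSV/TSV with samples in rows: reserved
leading metadata columns followed by one column per feature.  Feature
column headers encode identity as ``feature_id|mz|rt`` so a table round-
trips without a sidecar file.  Missing intensities are empty cells and are
kept distinct from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLE_QC = "QC"
ROLE_CONDITIONING_QC = "CONDITIONING_QC"
ROLE_BLANK = "BLANK"
ROLE_STUDY = "STUDY"
VALID_ROLES = frozenset({ROLE_QC, ROLE_CONDITIONING_QC, ROLE_BLANK, ROLE_STUDY})

CLASS_BC = "BC"
CLASS_CTRL = "CTRL"
CLASS_MONITOR = "MONITOR"
CLASS_NA = "NA"
VALID_CLASSES = frozenset({CLASS_BC, CLASS_CTRL, CLASS_MONITOR, CLASS_NA})

#: reserved metadata columns, in on-disk order
METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "batch",
    "injection_order",
    "role",
    "class_label",
    "visit_index",
)


class ValidationError(ValueError):
    """Raised when a table or its metadata violates an invariant."""


@dataclass
class FeatureTable:
    """Intensity matrix plus sample and feature metadata.

    Attributes
    ----------
    intensities:
        ``(n_samples, n_features)`` float frame; index = sample_id,
        columns = feature_id.  NaN encodes a missing intensity.
    samples:
        Frame indexed by sample_id with columns ``patient_id`` (object,
        None for QC/blank), ``batch`` (int >= 1), ``injection_order``
        (int >= 1, unique within batch), ``role``, ``class_label``
        (None for non-study samples) and ``visit_index``.
    features:
        Frame indexed by feature_id with columns ``mz`` (Da, > 0) and
        ``rt`` (minutes, >= 0).
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    def role_mask(self, role: str) -> np.ndarray:
        return (self.samples["role"] == role).to_numpy()

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = pd.Index(sample_ids)
        return FeatureTable(
            intensities=self.intensities.loc[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            features=self.features.copy(),
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(
            intensities=self.intensities.loc[:, ids].copy(),
            samples=self.samples.copy(),
            features=self.features.loc[ids].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.samples.copy(), self.features.copy()
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> "FeatureTable":
        """Check structural invariants; return self for chaining."""
        if self.intensities.shape[0] != len(self.samples):
            raise ValidationError("intensity rows do not match sample metadata")
        if self.intensities.shape[1] != len(self.features):
            raise ValidationError("intensity columns do not match feature metadata")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValidationError(f"duplicate feature_id: {dup!r}")
        if not self.intensities.index.equals(self.samples.index):
            raise ValidationError("intensity index and sample metadata index differ")
        if not self.intensities.columns.equals(self.features.index):
            raise ValidationError("intensity columns and feature metadata index differ")

        bad_role = set(self.samples["role"]) - VALID_ROLES
        if bad_role:
            raise ValidationError(f"unknown role token: {sorted(bad_role)[0]!r}")
        labels = self.samples["class_label"].dropna()
        bad_cls = set(labels) - VALID_CLASSES
        if bad_cls:
            raise ValidationError(f"unknown class token: {sorted(bad_cls)[0]!r}")

        study = self.samples[self.samples["role"] == ROLE_STUDY]
        if study["patient_id"].isna().any():
            sid = study.index[study["patient_id"].isna()][0]
            raise ValidationError(f"STUDY sample {sid!r} has no patient_id")
        if study["class_label"].isna().any():
            sid = study.index[study["class_label"].isna()][0]
            raise ValidationError(f"STUDY sample {sid!r} has no class_label")

        pairs = self.samples[["batch", "injection_order"]]
        if pairs.duplicated().any():
            raise ValidationError("(batch, injection_order) pairs are not unique")

        if (self.features["mz"] <= 0).any():
            raise ValidationError("feature mz must be positive")
        if (self.features["rt"] < 0).any():
            raise ValidationError("feature rt must be non-negative")

        # conditioning QCs precede every other injection in their batch
        for batch, grp in self.samples.groupby("batch"):
            cond = grp.loc[grp["role"] == ROLE_CONDITIONING_QC, "injection_order"]
            rest = grp.loc[grp["role"] != ROLE_CONDITIONING_QC, "injection_order"]
            if len(cond) and len(rest) and cond.max() > rest.min():
                raise ValidationError(
                    f"batch {batch}: conditioning QCs do not precede other injections"
                )
        return self


@dataclass
class SplitPlan:
    """Patient-wise train/validation partition of STUDY samples."""

    train_sample_ids: list[str]
    validation_sample_ids: list[str]
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_sample_ids": list(self.train_sample_ids),
            "validation_sample_ids": list(self.validation_sample_ids),
            "class_counts": self.class_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_sample_ids=payload["train_sample_ids"],
            validation_sample_ids=payload["validation_sample_ids"],
            class_counts=payload.get("class_counts", {}),
        )


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _feature_header(feature_id: str, mz: float, rt: float) -> str:
    return f"{feature_id}|{mz:.6g}|{rt:.6g}"


def _parse_feature_header(header: str) -> tuple[str, float, float]:
    parts = header.split("|")
    if len(parts) != 3:
        raise ValidationError(
            f"feature column {header!r} is not of the form 'feature_id|mz|rt'"
        )
    return parts[0], float(parts[1]), float(parts[2])


def _detect_sep(path: Path) -> str:
    head = path.open("r", encoding="utf-8").readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    """Serialize a table to delimited text (empty cell = missing)."""
    path = Path(path)
    meta = table.samples.reset_index()
    meta.columns = list(METADATA_COLUMNS)
    wide = table.intensities.copy()
    wide.columns = [
        _feature_header(fid, row["mz"], row["rt"])
        for fid, row in table.features.iterrows()
    ]
    out = pd.concat([meta.set_index(table.sample_ids), wide], axis=1)
    out.to_csv(path, sep=sep, index=False)


def read_feature_table(path: str | Path, sep: str | None = None) -> FeatureTable:
    """Read a delimited-text peak table and validate it.

    The delimiter is auto-detected (comma vs tab) unless given.  Missing
    intensities (empty cells) are preserved as NaN, never coerced to zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "patient_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValidationError(f"missing metadata columns: {missing_cols}")

    feature_cols = [c for c in raw.columns if c not in METADATA_COLUMNS]
    parsed = [_parse_feature_header(c) for c in feature_cols]
    features = pd.DataFrame(
        {"mz": [p[1] for p in parsed], "rt": [p[2] for p in parsed]},
        index=pd.Index([p[0] for p in parsed], name="feature_id"),
    )

    samples = raw[list(METADATA_COLUMNS)].copy()
    samples = samples.set_index("sample_id")
    samples["batch"] = samples["batch"].astype(int)
    samples["injection_order"] = samples["injection_order"].astype(int)
    samples["visit_index"] = samples["visit_index"].astype("Int64")
    samples["patient_id"] = samples["patient_id"].where(samples["patient_id"].notna(), None)
    samples["class_label"] = samples["class_label"].where(samples["class_label"].notna(), None)

    intensities = raw[feature_cols].astype(float)
    intensities.index = samples.index
    intensities.columns = features.index

    return FeatureTable(intensities, samples, features).validate()


# ---------------------------------------------------------------------------
# splitting and conditioning exclusion
# ---------------------------------------------------------------------------

def split_by_patient(
    table: FeatureTable, assignment: Mapping[str, str]
) -> SplitPlan:
    """Partition STUDY samples into train/validation by patient.

    Every STUDY patient must appear in ``assignment`` with value
    ``"train"`` or ``"validation"``; all of a patient's samples land in
    the assigned subset, so no patient can straddle the split.
    """
    study = table.samples[table.samples["role"] == ROLE_STUDY]
    patients = set(study["patient_id"])
    unassigned = patients - set(assignment)
    if unassigned:
        raise ValidationError(f"unassigned patients: {sorted(unassigned)}")
    bad = {p: v for p, v in assignment.items() if v not in ("train", "validation")}
    if bad:
        raise ValidationError(f"invalid subset labels: {bad}")

    train_ids: list[str] = []
    val_ids: list[str] = []
    for sid, row in study.iterrows():
        (train_ids if assignment[row["patient_id"]] == "train" else val_ids).append(sid)

    counts: dict[str, dict[str, int]] = {}
    for name, ids in (("train", train_ids), ("validation", val_ids)):
        sub = study.loc[ids, "class_label"].value_counts().to_dict()
        counts[name] = {str(k): int(v) for k, v in sub.items()}
    return SplitPlan(train_ids, val_ids, counts)


def exclude_conditioning(table: FeatureTable) -> FeatureTable:
    """Drop column-conditioning QC injections; idempotent."""
    keep = table.samples.index[table.samples["role"] != ROLE_CONDITIONING_QC]
    if len(keep) == table.n_samples:
        return table.copy()
    return table.subset_samples(keep)
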