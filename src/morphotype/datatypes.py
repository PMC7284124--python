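"""Core in-memory containers shared across the pipeline.

A :class:`FeatureTable` is a subjects x ROIs matrix of one cortical
parameter (thickness in mm or surface area in mm^2) extracted under one
parcellation; a :class:`SubjectRecord` carries the group / diagnosis /
covariate / phenotype fields of one subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "SubjectRecord", "records_to_frame", "frame_to_records"]


@dataclass
class FeatureTable:
    """Subjects x ROIs matrix of a single cortical parameter.

    Parameters
    ----------
    values
        Real matrix, one row per subject, one column per ROI. No missing
        values are allowed after ingestion.
    subject_ids, roi_ids
        Ordered, unique identifiers for rows and columns.
    parameter
        ``"CT"`` (cortical thickness) or ``"SA"`` (surface area).
    atlas_id
        Label of the parcellation the ROI means were extracted under.
    """

    values: np.ndarray
    subject_ids: list[str]
    roi_ids: list[str]
    parameter: str = "CT"
    atlas_id: str = "atlas"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.roi_ids = [str(r) for r in self.roi_ids]
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.subject_ids) or p != len(self.roi_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.roi_ids)} ROIs"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(set(self.roi_ids)) != p:
            raise ValueError("roi_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.roi_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, parameter: str = "CT",
                   atlas_id: str = "atlas") -> "FeatureTable":
        return cls(frame.to_numpy(dtype=float), list(frame.index.astype(str)),
                   list(frame.columns.astype(str)), parameter, atlas_id)

    def subset_subjects(self, subject_ids: Sequence[str]) -> "FeatureTable":
        """Row subset in the given order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[str(s)] for s in subject_ids]
        return replace(self, values=self.values[idx], subject_ids=[str(s) for s in subject_ids])

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SubjectRecord:
    """Metadata for one subject.

    ``group`` is ``"clinical"`` or ``"control"``; controls carry
    ``primary_diagnosis="none"`` and can never be flagged dual-diagnosis.
    Phenotype scores (IQ, AQ, CAARS) are optional and may be missing for a
    subset of subjects, as in real cohorts.
    """

    subject_id: str
    group: str
    primary_diagnosis: str = "none"
    dual_diagnosis: bool = False
    age: float = float("nan")
    handedness: float = float("nan")
    iq: Optional[float] = None
    aq_total: Optional[float] = None
    caars_total: Optional[float] = None
    medication: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.group not in ("clinical", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.primary_diagnosis not in ("ASD", "ADHD", "none"):
            raise ValueError(f"unknown diagnosis {self.primary_diagnosis!r}")
        if self.group == "control" and self.primary_diagnosis != "none":
            raise ValueError("control subjects cannot carry a clinical diagnosis")
        if self.dual_diagnosis and self.group != "clinical":
            raise ValueError("dual diagnosis implies group='clinical'")


_OPTIONAL_COLS = ("iq", "aq_total", "caars_total", "medication")


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records for TSV output (stable column order)."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "group": r.group,
            "primary_diagnosis": r.primary_diagnosis,
            "dual_diagnosis": int(r.dual_diagnosis),
            "age": r.age, "handedness": r.handedness,
            "iq": r.iq, "aq_total": r.aq_total,
            "caars_total": r.caars_total,
            "medication": None if r.medication is None else int(r.medication),
        })
    return pd.DataFrame(rows).set_index("subject_id")


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for sid, row in frame.iterrows():
        kwargs = {}
        for col in _OPTIONAL_COLS:
            if col in row and pd.notna(row[col]):
                v = row[col]
                kwargs[col] = bool(int(v)) if col == "medication" else float(v)
        records.append(SubjectRecord(
            subject_id=str(sid), group=str(row["group"]),
            primary_diagnosis=str(row["primary_diagnosis"]),
            dual_diagnosis=bool(int(row["dual_diagnosis"])),
            age=float(row["age"]), handedness=float(row["handedness"]),
            **kwargs))
    return records
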