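"""Refraction arithmetic, myopia classification and cohort-level summaries.

Refractive error is expressed as the spherical equivalent refraction
(SER = sphere + cylinder/2, in diopters). A subject's SER is the mean of
the two eyes, myopia is SER <= -0.50 D, and subjects with inter-eye SER
difference (anisometropia) of 1.00 D or more are excluded from analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MYOPIA_THRESHOLD_D = -0.50
ANISOMETROPIA_LIMIT_D = 1.00


class ValidationError(ValueError):
    """Raised when refraction input fails validation."""


@dataclass(frozen=True)
class RefractionExam:
    """One subject's cycloplegic autorefraction, both eyes.

    Cylinder powers follow the minus-cylinder convention (cylinder <= 0);
    a positive cylinder is rejected at construction.
    """

    subject_id: str
    sphere_right: float
    cylinder_right: float
    sphere_left: float
    cylinder_left: float
    age: float | None = None

    def __post_init__(self) -> None:
        for name in ("sphere_right", "cylinder_right", "sphere_left", "cylinder_left"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValidationError(f"{self.subject_id}: {name} must be finite, got {v!r}")
        for name in ("cylinder_right", "cylinder_left"):
            if getattr(self, name) > 0:
                raise ValidationError(
                    f"{self.subject_id}: {name} is positive; minus-cylinder convention required"
                )


@dataclass(frozen=True)
class SubjectRecord:
    """Derived per-subject refraction summary used throughout the pipeline."""

    subject_id: str
    ser: float
    myopic: bool
    anisometropia: float
    age: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ser):
            raise ValidationError(f"{self.subject_id}: SER must be finite")
        if self.anisometropia < 0:
            raise ValidationError(f"{self.subject_id}: anisometropia must be >= 0")
        if self.myopic != classify_myopia(self.ser):
            raise ValidationError(f"{self.subject_id}: myopic flag inconsistent with SER")


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """Spherical equivalent refraction: sphere + cylinder/2 (diopters)."""
    if not (math.isfinite(sphere) and math.isfinite(cylinder)):
        raise ValidationError("sphere and cylinder must be finite")
    return sphere + cylinder / 2.0


def binocular_ser(ser_right: float, ser_left: float) -> float:
    """Binocular SER: arithmetic mean of the two eyes."""
    if ser_right is None or ser_left is None:
        raise ValidationError("both eyes are required")
    if not (math.isfinite(ser_right) and math.isfinite(ser_left)):
        raise ValidationError("per-eye SER must be finite")
    return (ser_right + ser_left) / 2.0


def classify_myopia(ser: float) -> bool:
    """True iff SER <= -0.50 D (boundary inclusive)."""
    return ser <= MYOPIA_THRESHOLD_D


def subject_record(exam: RefractionExam) -> SubjectRecord:
    """Collapse a two-eye exam to the per-subject record."""
    ser_r = spherical_equivalent(exam.sphere_right, exam.cylinder_right)
    ser_l = spherical_equivalent(exam.sphere_left, exam.cylinder_left)
    ser = binocular_ser(ser_r, ser_l)
    return SubjectRecord(
        subject_id=exam.subject_id,
        ser=ser,
        myopic=classify_myopia(ser),
        anisometropia=abs(ser_r - ser_l),
        age=exam.age,
    )


def apply_inclusion_filters(
    exams: Iterable[RefractionExam], aniso_limit: float = ANISOMETROPIA_LIMIT_D
) -> list[SubjectRecord]:
    """Keep subjects with anisometropia strictly below ``aniso_limit``.

    Anisometropia is the absolute inter-eye SER difference. The limit is
    exclusive: a subject at exactly the limit is excluded.
    """
    exams = list(exams)
    if not exams:
        logger.warning("apply_inclusion_filters called with an empty exam list")
        return []
    records = [subject_record(e) for e in exams]
    kept = [r for r in records if r.anisometropia < aniso_limit]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("excluded %d/%d subjects with anisometropia >= %.2f D",
                    n_dropped, len(records), aniso_limit)
    return kept


def cohort_summary(records: Sequence[SubjectRecord]) -> dict:
    """Descriptive cohort statistics.

    Returns n, mean/SD of SER (sample SD, n-1 denominator; NaN and flagged
    when n == 1) and myopia prevalence as a percentage rounded to two
    decimals.
    """
    if not records:
        raise ValidationError("cohort_summary requires at least one record")
    sers = np.array([r.ser for r in records], dtype=float)
    n = len(records)
    n_myopic = int(sum(r.myopic for r in records))
    sd = float(np.std(sers, ddof=1)) if n > 1 else float("nan")
    return {
        "n": n,
        "n_myopic": n_myopic,
        "mean_ser": float(np.mean(sers)),
        "sd_ser": sd,
        "sd_defined": n > 1,
        "myopia_pct": round(100.0 * n_myopic / n, 2),
    }


def read_refraction_csv(path: str | Path) -> list[RefractionExam]:
    """Read exams from a CSV with header
    ``subject_id,sphere_r,cyl_r,sphere_l,cyl_l[,age]``."""
    df = pd.read_csv(path)
    required = ["subject_id", "sphere_r", "cyl_r", "sphere_l", "cyl_l"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    exams = []
    for row in df.itertuples(index=False):
        exams.append(
            RefractionExam(
                subject_id=str(row.subject_id),
                sphere_right=float(row.sphere_r),
                cylinder_right=float(row.cyl_r),
                sphere_left=float(row.sphere_l),
                cylinder_left=float(row.cyl_l),
                age=float(row.age) if "age" in df.columns and pd.notna(row.age) else None,
            )
        )
    return exams


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "ser": [r.ser for r in records],
            "myopic": [r.myopic for r in records],
            "anisometropia": [r.anisometropia for r in records],
            "age": [r.age for r in records],
        }
    )
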