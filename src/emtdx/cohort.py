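"""Subject-level cohort data model, CSV I/O, marker summarization and
stage-based imputation of the two established binary tests.

Conventions
-----------
All binary tests are coded ``1`` = positive (evidence supporting detachment)
and ``0`` = negative.  The continuous marker lives on a 0-3 intensity scale.
For an *epithelial* marker, expression **below** the cut point is test-positive
(score at or above the cut point is "high expression" and therefore negative);
for a *mesenchymal-or-inducer* marker the coding is reversed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortValidationError",
    "Stage",
    "NStage",
    "MarkerDirection",
    "SubjectRecord",
    "CohortTable",
    "PatternCounts",
    "PATTERNS",
    "summarize_cores",
    "dichotomize_marker",
    "impute_tests_from_stage",
    "pattern_counts",
    "read_cohort",
    "write_cohort",
]


class CohortValidationError(ValueError):
    """Raised when subject-level data violates the cohort schema."""


class Stage(enum.Enum):
    LOCAL = "local"
    REGIONAL = "regional"
    DISTANT = "distant"

    @classmethod
    def parse(cls, value) -> "Stage":
        if isinstance(value, Stage):
            return value
        text = str(value).strip().lower()
        mapping = {
            "local": cls.LOCAL,
            "i": cls.LOCAL,
            "ii": cls.LOCAL,
            "1": cls.LOCAL,
            "2": cls.LOCAL,
            "regional": cls.REGIONAL,
            "iii": cls.REGIONAL,
            "3": cls.REGIONAL,
            "distant": cls.DISTANT,
            "iv": cls.DISTANT,
            "4": cls.DISTANT,
        }
        if text not in mapping:
            raise CohortValidationError(f"unparseable stage code {value!r}")
        return mapping[text]


class NStage(enum.Enum):
    N0 = "N0"
    N1ORN2 = "N1orN2"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"

    @classmethod
    def parse(cls, value) -> "NStage":
        if isinstance(value, NStage):
            return value
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return cls.NOT_APPLICABLE
        text = str(value).strip().lower()
        mapping = {
            "n0": cls.N0,
            "n1": cls.N1ORN2,
            "n2": cls.N1ORN2,
            "n1orn2": cls.N1ORN2,
            "n1 or n2": cls.N1ORN2,
            "unknown": cls.UNKNOWN,
            "not_applicable": cls.NOT_APPLICABLE,
            "na": cls.NOT_APPLICABLE,
            "": cls.NOT_APPLICABLE,
        }
        if text not in mapping:
            raise CohortValidationError(f"unparseable n_stage code {value!r}")
        return mapping[text]


class MarkerDirection(enum.Enum):
    """Biological direction of the marker relative to detachment.

    ``EPITHELIAL`` markers fall during the transition (low score = positive);
    ``MESENCHYMAL_OR_INDUCER`` markers rise (high score = positive).
    """

    EPITHELIAL = "epithelial"
    MESENCHYMAL_OR_INDUCER = "mesenchymal_or_inducer"

    @classmethod
    def parse(cls, value) -> "MarkerDirection":
        if isinstance(value, MarkerDirection):
            return value
        text = str(value).strip().lower()
        for member in cls:
            if member.value == text:
                return member
        raise CohortValidationError(f"unknown marker direction {value!r}")


def summarize_cores(
    core_intensities: Sequence[float], core_areas: Sequence[float]
) -> float:
    """Area-weighted average of per-core intensity scores.

    Returns sum(intensity * area) / sum(area); invariant to rescaling all
    areas by a common positive constant.
    """
    intensities = np.asarray(core_intensities, dtype=float)
    areas = np.asarray(core_areas, dtype=float)
    if intensities.size == 0 or areas.size == 0:
        raise CohortValidationError("core lists must be nonempty")
    if intensities.shape != areas.shape:
        raise CohortValidationError(
            f"core list length mismatch: {intensities.size} intensities "
            f"vs {areas.size} areas"
        )
    if np.any(areas <= 0):
        raise CohortValidationError("core areas must be positive")
    if np.any((intensities < 0) | (intensities > 3)):
        raise CohortValidationError("core intensities must lie in [0, 3]")
    return float(np.average(intensities, weights=areas))


def dichotomize_marker(
    marker_score: float,
    cut_point: float,
    direction: MarkerDirection | str = MarkerDirection.EPITHELIAL,
) -> int:
    """Binary marker test from a continuous score.

    Epithelial: positive (1) iff score < cut_point; score at or above the
    cut point counts as high expression and is negative.  Mesenchymal or
    inducer: positive iff score >= cut_point.
    """
    direction = MarkerDirection.parse(direction)
    if not (0 < cut_point <= 3):
        raise CohortValidationError(f"cut_point {cut_point} outside (0, 3]")
    if direction is MarkerDirection.EPITHELIAL:
        return int(marker_score < cut_point)
    return int(marker_score >= cut_point)


def impute_tests_from_stage(
    stage: Stage | str, n_stage: NStage | str | None = None
) -> tuple[int, int]:
    """Impute (ln_test, ri_test) from TNM stage.

    Local -> both negative; regional -> node-positive, imaging-negative;
    distant -> imaging-positive with node status from N-stage (N0 negative,
    N1/N2 or unknown positive).  A distant subject whose n_stage field is
    absent entirely (as opposed to the value "unknown") is an error.
    """
    stage = Stage.parse(stage)
    if stage is Stage.LOCAL:
        return (0, 0)
    if stage is Stage.REGIONAL:
        return (1, 0)
    # distant disease
    if n_stage is None:
        raise CohortValidationError(
            "distant-stage subject requires an n_stage value "
            "(use 'unknown' if N-stage was not recorded)"
        )
    n_stage = NStage.parse(n_stage)
    if n_stage is NStage.NOT_APPLICABLE:
        raise CohortValidationError(
            "distant-stage subject requires an n_stage value "
            "(use 'unknown' if N-stage was not recorded)"
        )
    ln = 0 if n_stage is NStage.N0 else 1
    return (ln, 1)


@dataclass
class SubjectRecord:
    """One subject: stage, marker data, binary tests and censored follow-up."""

    subject_id: str
    stage: Stage
    followup_time: float
    death: int
    n_stage: NStage = NStage.NOT_APPLICABLE
    marker_score: float | None = None
    core_intensities: list[float] | None = None
    core_areas: list[float] | None = None
    ln_test: int | None = None
    ri_test: int | None = None

    def __post_init__(self):
        self.stage = Stage.parse(self.stage)
        self.n_stage = NStage.parse(self.n_stage)
        self.validate()

    def validate(self) -> None:
        sid = self.subject_id
        if self.followup_time < 0:
            raise CohortValidationError(
                f"subject {sid!r}: followup_time is negative "
                f"({self.followup_time})"
            )
        if self.death not in (0, 1):
            raise CohortValidationError(
                f"subject {sid!r}: death must be 0 or 1, got {self.death!r}"
            )
        has_cores = self.core_intensities is not None or self.core_areas is not None
        if has_cores:
            if self.core_intensities is None or self.core_areas is None:
                raise CohortValidationError(
                    f"subject {sid!r}: core_intensities and core_areas "
                    "must be provided together"
                )
            if len(self.core_intensities) != len(self.core_areas):
                raise CohortValidationError(
                    f"subject {sid!r}: core list length mismatch"
                )
        if self.marker_score is None:
            if has_cores:
                self.marker_score = summarize_cores(
                    self.core_intensities, self.core_areas
                )
            else:
                raise CohortValidationError(
                    f"subject {sid!r}: marker_score missing and no core "
                    "data to derive it from"
                )
        if not (0 <= self.marker_score <= 3):
            raise CohortValidationError(
                f"subject {sid!r}: marker_score {self.marker_score} "
                "outside [0, 3]"
            )
        for name in ("ln_test", "ri_test"):
            value = getattr(self, name)
            if value is not None and value not in (0, 1):
                raise CohortValidationError(
                    f"subject {sid!r}: {name} must be 0/1, got {value!r}"
                )

    def resolved_tests(self) -> tuple[int, int]:
        """Observed (ln, ri) if present, else imputed from stage."""
        if self.ln_test is not None and self.ri_test is not None:
            return (self.ln_test, self.ri_test)
        n_stage = None if self.n_stage is NStage.NOT_APPLICABLE else self.n_stage
        imputed_ln, imputed_ri = impute_tests_from_stage(self.stage, n_stage)
        ln = self.ln_test if self.ln_test is not None else imputed_ln
        ri = self.ri_test if self.ri_test is not None else imputed_ri
        return (ln, ri)


@dataclass
class CohortTable:
    """Ordered collection of subject records plus the marker's direction."""

    records: list[SubjectRecord]
    marker_direction: MarkerDirection = MarkerDirection.EPITHELIAL

    def __post_init__(self):
        self.marker_direction = MarkerDirection.parse(self.marker_direction)
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def marker_scores(self) -> np.ndarray:
        return np.array([r.marker_score for r in self.records], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([r.followup_time for r in self.records], dtype=float)

    def deaths(self) -> np.ndarray:
        return np.array([r.death for r in self.records], dtype=int)

    def resolved_tests(self) -> np.ndarray:
        """(n, 2) array of (ln, ri), imputing from stage where needed."""
        return np.array([r.resolved_tests() for r in self.records], dtype=int)

    def marker_tests(self, cut_point: float) -> np.ndarray:
        return np.array(
            [
                dichotomize_marker(r.marker_score, cut_point, self.marker_direction)
                for r in self.records
            ],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "stage": r.stage.value,
                    "n_stage": r.n_stage.value,
                    "marker_score": r.marker_score,
                    "followup_time_years": r.followup_time,
                    "death": r.death,
                    "ln_test": r.ln_test if r.ln_test is not None else "",
                    "ri_test": r.ri_test if r.ri_test is not None else "",
                }
            )
        return pd.DataFrame(rows)


# Fixed pattern order used everywhere a flat 8-vector appears.
PATTERNS: tuple[tuple[int, int, int], ...] = tuple(
    (emt, ln, ri) for emt in (0, 1) for ln in (0, 1) for ri in (0, 1)
)


@dataclass
class PatternCounts:
    """Counts of the 8 joint (emt, ln, ri) test-result patterns."""

    counts: dict[tuple[int, int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        full = {p: 0 for p in PATTERNS}
        for key, value in self.counts.items():
            key = tuple(int(k) for k in key)
            if key not in full:
                raise CohortValidationError(f"invalid pattern {key}")
            if value < 0:
                raise CohortValidationError(f"negative count for pattern {key}")
            full[key] = int(value)
        self.counts = full

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_array(self) -> np.ndarray:
        return np.array([self.counts[p] for p in PATTERNS], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"emt": p[0], "ln": p[1], "ri": p[2], "count": self.counts[p]}
                for p in PATTERNS
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PatternCounts":
        required = {"emt", "ln", "ri", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise CohortValidationError(
                f"pattern-counts table missing columns: {sorted(missing)}"
            )
        counts = {
            (int(row.emt), int(row.ln), int(row.ri)): int(row.count)
            for row in frame.itertuples()
        }
        return cls(counts)


def pattern_counts(
    cohort: CohortTable,
    cut_point: float,
    direction: MarkerDirection | str | None = None,
) -> PatternCounts:
    """Cross-classify the cohort into the 8 joint test patterns.

    The marker test comes from dichotomizing each subject's score at
    ``cut_point``; LN/RI come from the recorded tests or stage imputation.
    """
    direction = (
        cohort.marker_direction if direction is None else MarkerDirection.parse(direction)
    )
    counts: dict[tuple[int, int, int], int] = {p: 0 for p in PATTERNS}
    for record in cohort:
        emt = dichotomize_marker(record.marker_score, cut_point, direction)
        ln, ri = record.resolved_tests()
        counts[(emt, ln, ri)] += 1
    return PatternCounts(counts)


_REQUIRED_COLUMNS = ("subject_id", "stage", "followup_time_years", "death")


def read_cohort(
    path: str | Path,
    cores_path: str | Path | None = None,
    marker_direction: MarkerDirection | str = MarkerDirection.EPITHELIAL,
    schema: Mapping[str, str] | None = None,
) -> CohortTable:
    """Read a cohort CSV (one row per subject), optionally joining a
    long-format per-core CSV keyed by subject_id.

    ``schema`` maps standard column names to the file's column names when
    they differ.
    """
    path = Path(path)
    if not path.exists():
        raise CohortValidationError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, dtype={"subject_id": str})
    rename = {v: k for k, v in (schema or {}).items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(
            f"cohort file {path.name} missing required columns: {missing}"
        )

    cores: dict[str, tuple[list[float], list[float]]] = {}
    if cores_path is not None:
        cores_frame = pd.read_csv(cores_path, dtype={"subject_id": str})
        needed = {"subject_id", "core_intensity", "core_area"}
        if not needed <= set(cores_frame.columns):
            raise CohortValidationError(
                f"cores file missing columns: {sorted(needed - set(cores_frame.columns))}"
            )
        for sid, group in cores_frame.groupby("subject_id", sort=False):
            cores[str(sid)] = (
                group["core_intensity"].astype(float).tolist(),
                group["core_area"].astype(float).tolist(),
            )

    def _opt(row, name):
        if name not in row or pd.isna(row[name]) or row[name] == "":
            return None
        return row[name]

    records = []
    for idx, row in frame.iterrows():
        sid = str(row["subject_id"])
        marker = _opt(row, "marker_score")
        ln = _opt(row, "ln_test")
        ri = _opt(row, "ri_test")
        intensities, areas = cores.get(sid, (None, None))
        try:
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    stage=row["stage"],
                    n_stage=_opt(row, "n_stage"),
                    marker_score=float(marker) if marker is not None else None,
                    core_intensities=intensities,
                    core_areas=areas,
                    ln_test=int(ln) if ln is not None else None,
                    ri_test=int(ri) if ri is not None else None,
                    followup_time=float(row["followup_time_years"]),
                    death=int(row["death"]),
                )
            )
        except CohortValidationError as err:
            raise CohortValidationError(f"row {idx}: {err}") from err
    return CohortTable(records=records, marker_direction=marker_direction)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort to the CSV dialect consumed by :func:`read_cohort`."""
    cohort.to_frame().to_csv(path, index=False)
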