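"""Core domain types for the MLTC cluster-assignment pipeline.

The pipeline works on three tables: a many-to-one map of long-term
conditions (LTCs) to disease clusters, a patient table with demographics
and three binary 1-year outcomes, and a diagnosis-event table holding the
earliest recorded age at diagnosis for each (patient, disease) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three 1-year binary outcomes analysed throughout.
OUTCOMES = ("death", "ed_attendance", "emergency_admission")

#: The seven cluster-to-person assignment strategies.
STRATEGIES = ("ge1", "ge2", "ge3", "modal", "majority", "count", "proportion")

#: Strategies whose per-cluster values are binary 0/1.
BINARY_STRATEGIES = ("ge1", "ge2", "ge3", "modal", "majority")

CLUSTER_MAP_COLUMNS = ("disease_id", "disease_name", "cluster_id", "cluster_name")
PATIENT_COLUMNS = (
    "patient_id",
    "age_at_index",
    "gender",
    "ethnicity",
    "imd_decile",
    "deregistered",
    "death",
    "ed_attendance",
    "emergency_admission",
)
EVENT_COLUMNS = ("patient_id", "disease_id", "age_at_diagnosis")


class ValidationError(ValueError):
    """An input violates a pipeline invariant."""


class FormatError(ValidationError):
    """A file does not conform to the documented schema."""


class PartitionError(ValidationError):
    """The disease->cluster map is not a many-to-one partition."""


class ReferentialError(ValidationError):
    """A record references an entity that does not exist."""


@dataclass(frozen=True)
class ClusterMap:
    """A many-to-one partition of diseases into clusters.

    ``frame`` has one row per disease with columns
    (disease_id, disease_name, cluster_id, cluster_name).  Every disease
    belongs to exactly one cluster and every cluster has at least one
    disease; cluster order follows first appearance in the frame.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLUSTER_MAP_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"cluster map is missing columns: {missing}")
        if len(self.frame) == 0:
            raise FormatError("cluster map has no diseases")
        dup = self.frame["disease_id"][self.frame["disease_id"].duplicated()]
        if len(dup):
            raise PartitionError(
                "diseases mapped to more than one cluster (partition violation): "
                + ", ".join(sorted(set(dup)))
            )

    @property
    def n_diseases(self) -> int:
        return len(self.frame)

    @property
    def n_clusters(self) -> int:
        return self.frame["cluster_id"].nunique()

    @property
    def disease_ids(self) -> list[str]:
        return list(self.frame["disease_id"])

    @property
    def cluster_ids(self) -> list[str]:
        """Cluster identifiers in order of first appearance."""
        return list(self.frame["cluster_id"].drop_duplicates())

    @property
    def disease_to_cluster(self) -> pd.Series:
        """Series mapping disease_id -> cluster_id."""
        return self.frame.set_index("disease_id")["cluster_id"]

    def members(self, cluster_id: str) -> list[str]:
        """disease_ids belonging to ``cluster_id``."""
        sel = self.frame.loc[self.frame["cluster_id"] == cluster_id, "disease_id"]
        if len(sel) == 0:
            raise ReferentialError(f"unknown cluster_id: {cluster_id}")
        return list(sel)


@dataclass
class Cohort:
    """Patients with demographics, outcomes and diagnosis events.

    ``patients``: one row per patient with PATIENT_COLUMNS; boolean columns
    (deregistered and the three outcomes) are stored as 0/1 integers.
    ``events``: one row per (patient, disease) carrying the earliest age at
    diagnosis.  Every patient has at least two distinct diseases (the MLTC
    inclusion rule).
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    index_date_label: str = "index"

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self, cluster_map: ClusterMap | None = None) -> None:
        """Raise ValidationError on any invariant breach."""
        missing = [c for c in PATIENT_COLUMNS if c not in self.patients.columns]
        if missing:
            raise FormatError(f"patient table missing columns: {missing}")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        if self.patients["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id in patient table")
        if (self.patients["age_at_index"] < 18).any():
            raise ValidationError("patients younger than 18 at index")
        imd = self.patients["imd_decile"]
        if ((imd < 1) | (imd > 10)).any():
            raise ValidationError("imd_decile outside [1, 10]")
        if self.events.duplicated(["patient_id", "disease_id"]).any():
            raise ValidationError("multiple events for one (patient, disease) pair")
        known = set(self.patients["patient_id"])
        orphan = set(self.events["patient_id"]) - known
        if orphan:
            raise ReferentialError(
                f"events reference unknown patients: {sorted(orphan)[:5]}"
            )
        ages = self.events["patient_id"].map(
            self.patients.set_index("patient_id")["age_at_index"]
        )
        bad = self.events.loc[
            (self.events["age_at_diagnosis"] > ages + 1e-9)
            | (self.events["age_at_diagnosis"] <= 0)
        ]
        if len(bad):
            raise ValidationError(
                "diagnosis ages outside (0, age_at_index] for rows: "
                f"{bad.index.tolist()[:10]}"
            )
        per_patient = self.events.groupby("patient_id")["disease_id"].nunique()
        if not known.issubset(per_patient.index) or (per_patient < 2).any():
            raise ValidationError(
                "cohort contains patients with fewer than two distinct diseases"
            )
        if cluster_map is not None:
            unknown = set(self.events["disease_id"]) - set(cluster_map.disease_ids)
            if unknown:
                raise ReferentialError(
                    f"events reference diseases absent from the cluster map: "
                    f"{sorted(unknown)[:5]}"
                )


@dataclass
class AssignmentResult:
    """Per-patient per-cluster representation under one strategy.

    ``values`` is a patients x clusters DataFrame (index patient_id,
    columns cluster_id): 0/1 for the binary strategies, nonnegative
    integers for ``count`` and proportions summing to 1 for ``proportion``.
    ``modal_tie`` is defined only for the modal strategy.
    """

    strategy: str
    values: pd.DataFrame
    modal_tie: pd.Series | None = None


@dataclass
class AssignmentSummary:
    """Assignment-pattern summary for one strategy (Table-2-style metrics)."""

    strategy: str
    n_patients: int
    pct_none: float
    pct_one: float
    pct_multi: float
    pct_fully_represented: float
    median_unassigned_ltcs: float
    iqr_unassigned_ltcs: tuple[float, float]
    pct_modal_ties: float | None = None

    def to_dict(self) -> dict:
        d = {
            "strategy": self.strategy,
            "n_patients": self.n_patients,
            "pct_none": self.pct_none,
            "pct_one": self.pct_one,
            "pct_multi": self.pct_multi,
            "pct_fully_represented": self.pct_fully_represented,
            "median_unassigned_ltcs": self.median_unassigned_ltcs,
            "iqr_unassigned_low": self.iqr_unassigned_ltcs[0],
            "iqr_unassigned_high": self.iqr_unassigned_ltcs[1],
            "pct_modal_ties": self.pct_modal_ties,
        }
        return d


@dataclass
class DesignMatrix:
    """A regression design: intercept + exposure block + covariate block."""

    X: pd.DataFrame  # rows indexed by patient_id, float64
    exposure_columns: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelFit:
    """A fitted logistic regression with AIC bookkeeping.

    ``aic`` is always 2*k - 2*loglik with k the number of estimated
    coefficients (intercept included; dropped zero-variance columns are
    not estimated and do not count).
    """

    coefficients: pd.Series
    standard_errors: pd.Series
    loglik: float
    k: int
    aic: float
    converged: bool
    n_iterations: int
    n_obs: int
    separation_flags: pd.Series
    exposure_columns: list[str]
    dropped_columns: list[str]


@dataclass
class DispersionSummary:
    """Within- vs between-cluster spread of adjusted log-odds ratios."""

    outcome: str
    variant: str  # all_diseases | significant_only
    within_range: pd.Series  # per-cluster max-min of member-disease log-aORs
    between_range: float  # max-min over cluster-level log-aORs
    median_within_range: float
    within_exceeds_between: bool
    excluded_clusters: list[str] = field(default_factory=list)


def as_bool01(values) -> np.ndarray:
    """Coerce a boolean-ish column to 0/1 int8."""
    return np.asarray(values).astype(bool).astype(np.int8)
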