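"""Readers and writers for the three pipeline tables.

All files are comma-separated UTF-8 with a header row.  Booleans are
written as 0/1.  Ages are stored in (possibly fractional) years; the
pipeline never handles calendar dates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .types import (
    CLUSTER_MAP_COLUMNS,
    EVENT_COLUMNS,
    PATIENT_COLUMNS,
    ClusterMap,
    Cohort,
    FormatError,
    ReferentialError,
    ValidationError,
)

logger = logging.getLogger(__name__)


def read_cluster_map(path: str | Path) -> ClusterMap:
    """Read and validate a disease->cluster map from CSV.

    Raises FormatError on schema problems and PartitionError if any
    disease appears under more than one cluster.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty cluster map file: {path}") from exc
    missing = [c for c in CLUSTER_MAP_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return ClusterMap(frame[list(CLUSTER_MAP_COLUMNS)])


def write_cluster_map(cluster_map: ClusterMap, path: str | Path) -> None:
    cluster_map.frame.to_csv(path, index=False)


def read_patients(path: str | Path) -> pd.DataFrame:
    try:
        patients = pd.read_csv(
            path,
            dtype={"patient_id": str, "gender": str, "ethnicity": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty patient file: {path}") from exc
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("deregistered", "death", "ed_attendance", "emergency_admission"):
        patients[col] = patients[col].astype(int)
    return patients


def read_events(path: str | Path) -> pd.DataFrame:
    try:
        events = pd.read_csv(path, dtype={"patient_id": str, "disease_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty event file: {path}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return events


def load_cohort(
    patients_path: str | Path,
    events_path: str | Path,
    cluster_map: ClusterMap | None = None,
    index_date_label: str = "index",
) -> Cohort:
    """Load and validate a cohort from patient and event CSVs.

    Duplicate (patient, disease) rows are collapsed to the earliest age at
    diagnosis with a warning.  Patients with fewer than two distinct
    diseases are dropped (the MLTC inclusion rule) and the drop is logged.
    Events referencing diseases absent from ``cluster_map`` raise
    ReferentialError; diagnosis ages above the patient's index age raise
    ValidationError.
    """
    patients = read_patients(patients_path)
    events = read_events(events_path)

    n_dup = events.duplicated(["patient_id", "disease_id"]).sum()
    if n_dup:
        logger.warning(
            "collapsing %d duplicate diagnosis rows to the earliest age", n_dup
        )
        events = (
            events.groupby(["patient_id", "disease_id"], as_index=False, sort=False)
            ["age_at_diagnosis"]
            .min()
        )

    if cluster_map is not None:
        unknown = set(events["disease_id"]) - set(cluster_map.disease_ids)
        if unknown:
            raise ReferentialError(
                f"events reference diseases absent from the cluster map: "
                f"{sorted(unknown)[:5]}"
            )

    orphan = set(events["patient_id"]) - set(patients["patient_id"])
    if orphan:
        raise ReferentialError(
            f"events reference unknown patients: {sorted(orphan)[:5]}"
        )
    index_age = events["patient_id"].map(
        patients.set_index("patient_id")["age_at_index"]
    )
    bad = events.loc[events["age_at_diagnosis"] > index_age + 1e-9]
    if len(bad):
        raise ValidationError(
            "age_at_diagnosis exceeds age_at_index for rows: "
            f"{bad.index.tolist()[:10]}"
        )

    counts = events.groupby("patient_id")["disease_id"].nunique()
    mltc_ids = set(counts.index[counts >= 2])
    dropped = len(patients) - patients["patient_id"].isin(mltc_ids).sum()
    if dropped:
        logger.info(
            "dropped %d patients with fewer than two distinct diseases", dropped
        )
    patients = patients[patients["patient_id"].isin(mltc_ids)].reset_index(drop=True)
    events = events[events["patient_id"].isin(mltc_ids)].reset_index(drop=True)

    cohort = Cohort(patients, events, index_date_label)
    cohort.validate(cluster_map)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write patients.csv and events.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out_dir / "patients.csv",
        "events": out_dir / "events.csv",
    }
    cohort.patients[list(PATIENT_COLUMNS)].to_csv(paths["patients"], index=False)
    cohort.events[list(EVENT_COLUMNS)].to_csv(paths["events"], index=False)
    return paths
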