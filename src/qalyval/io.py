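"""Readers and writers for the package's plain-text interchange formats.

Patient-level data travel as two CSVs: ``patients.csv`` (one row per
patient: id, covariates, baseline history flags, death/censor times) and
``events.csv`` (long format: patient_id, event_type, occurrence_index,
year_index). Utility tables and risk-equation sets travel as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .microsim import RiskEquationSet
from .qaly import (
    EventOccurrence,
    EventType,
    InputError,
    PatientRecord,
    UtilityTable,
)

__all__ = [
    "records_to_frames",
    "records_from_frames",
    "read_patients",
    "write_patients",
    "read_utility_table",
    "write_utility_table",
    "read_equations",
    "write_equations",
]

_HIST_PREFIX = "hist_"


def records_to_frames(
    records: Sequence[PatientRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(patients, events) DataFrames for a set of patient records."""
    prows, erows = [], []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "female": int(rec.female),
            "diabetes_duration": rec.diabetes_duration,
            "death_time": rec.death_time,
            "censor_time": rec.censor_time,
            "administrative_end_time": rec.administrative_end_time,
        }
        for ev in EventType:
            row[_HIST_PREFIX + ev.value] = rec.prior_count(ev)
        prows.append(row)
        for occ in rec.events:
            erows.append(
                {
                    "patient_id": rec.patient_id,
                    "event_type": occ.event_type.value,
                    "occurrence_index": occ.occurrence_index,
                    "year_index": occ.year_index,
                }
            )
    patients = pd.DataFrame(prows)
    events = pd.DataFrame(
        erows, columns=["patient_id", "event_type", "occurrence_index", "year_index"]
    )
    return patients, events


def records_from_frames(
    patients: pd.DataFrame, events: pd.DataFrame
) -> list[PatientRecord]:
    """Rebuild :class:`PatientRecord` objects from the two CSV frames."""
    by_patient: dict[str, list[EventOccurrence]] = {}
    for row in events.itertuples(index=False):
        by_patient.setdefault(str(row.patient_id), []).append(
            EventOccurrence(
                EventType(row.event_type),
                int(row.occurrence_index),
                int(row.year_index),
            )
        )
    records = []
    for row in patients.itertuples(index=False):
        pid = str(row.patient_id)
        prior = {
            ev: int(getattr(row, _HIST_PREFIX + ev.value, 0)) for ev in EventType
        }
        death = getattr(row, "death_time", None)
        death = None if death is None or pd.isna(death) else float(death)
        records.append(
            PatientRecord(
                patient_id=pid,
                age=float(row.age),
                female=bool(row.female),
                diabetes_duration=float(row.diabetes_duration),
                prior_events={ev: c for ev, c in prior.items() if c},
                events=sorted(
                    by_patient.get(pid, []), key=lambda o: (o.year_index, o.event_type)
                ),
                death_time=death,
                censor_time=float(row.censor_time),
                administrative_end_time=float(row.administrative_end_time),
            )
        )
    return records


def write_patients(
    records: Sequence[PatientRecord], patients_path, events_path
) -> None:
    patients, events = records_to_frames(records)
    patients.to_csv(patients_path, index=False)
    events.to_csv(events_path, index=False)


def read_patients(patients_path, events_path) -> list[PatientRecord]:
    patients = pd.read_csv(patients_path)
    events = pd.read_csv(events_path)
    if patients.empty:
        raise InputError(f"no patients in {patients_path}")
    return records_from_frames(patients, events)


def write_utility_table(table: UtilityTable, path) -> None:
    Path(path).write_text(yaml.safe_dump(table.to_dict(), sort_keys=True))


def read_utility_table(path) -> UtilityTable:
    return UtilityTable.from_dict(yaml.safe_load(Path(path).read_text()))


def write_equations(eqs: RiskEquationSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(eqs.to_dict(), sort_keys=True))


def read_equations(path) -> RiskEquationSet:
    return RiskEquationSet.from_dict(yaml.safe_load(Path(path).read_text()))
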