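"""Person-level record containers and tabular round-tripping.

A :class:`PatientRecord` is one patient's coded longitudinal history anchored
at the index stroke (day 0): baseline covariates, prescription events with
days-supply, first-occurrence diagnosis events per outcome label, death and
transfer days, and the deterioration-state onset used as the time-varying
covariate.  A :class:`Cohort` is an ordered collection of records plus the
simulation config (when generated) and converts to/from three flat tables
(patients, prescriptions, events) in CSV or Parquet.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import SimulationConfig

#: baseline covariate columns stored per patient (raw scale)
BASE_RAW_COLUMNS = (
    "age", "female", "af", "chd", "diabetes", "heart_failure", "hypertension",
    "smoking", "bmi", "imd", "subtype", "consultations",
)


@dataclass
class PatientRecord:
    patient_id: int
    registration_start: int                      # days of history before index (positive)
    covariates: dict                             # raw baseline covariates (BASE_RAW_COLUMNS)
    prescriptions: list[tuple[int, int]] = field(default_factory=list)  # (day, days_supply)
    events: list[tuple[str, int]] = field(default_factory=list)         # (label, day), first per label
    death_day: Optional[int] = None
    transfer_day: Optional[int] = None
    linked: bool = True
    deterioration_day: Optional[int] = None      # onset of the time-varying state

    def __post_init__(self) -> None:
        self.prescriptions = sorted(self.prescriptions)
        seen: dict[str, int] = {}
        for label, day in sorted(self.events, key=lambda e: e[1]):
            if label not in seen:
                seen[label] = day
        self.events = sorted(seen.items(), key=lambda e: e[1])

    def first_event_day(self, label: str) -> Optional[int]:
        for lab, day in self.events:
            if lab == label:
                return day
        return None

    def rx_days(self) -> list[int]:
        return [d for d, _ in self.prescriptions]


class Cohort:
    """Ordered collection of patient records."""

    def __init__(self, records: Iterable[PatientRecord], config: Optional[SimulationConfig] = None):
        self.records = list(records)
        self.config = config
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep: Iterable[PatientRecord]) -> "Cohort":
        return Cohort(keep, config=self.config)

    # -- tabular views --------------------------------------------------
    def patients_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"patient_id": r.patient_id, "registration_start": r.registration_start}
            row.update({c: r.covariates.get(c) for c in BASE_RAW_COLUMNS})
            row["death_day"] = r.death_day
            row["transfer_day"] = r.transfer_day
            row["linked"] = r.linked
            row["deterioration_day"] = r.deterioration_day
            rows.append(row)
        return pd.DataFrame(rows)

    def prescriptions_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": r.patient_id, "day": d, "days_supply": s}
            for r in self.records
            for d, s in r.prescriptions
        ]
        return pd.DataFrame(rows, columns=["patient_id", "day", "days_supply"])

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": r.patient_id, "label": lab, "day": d}
            for r in self.records
            for lab, d in r.events
        ]
        return pd.DataFrame(rows, columns=["patient_id", "label", "day"])

    # -- file IO ---------------------------------------------------------
    def write_tables(self, outdir, fmt: str = "csv") -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("patients", self.patients_frame()),
            ("prescriptions", self.prescriptions_frame()),
            ("events", self.events_frame()),
        ):
            path = outdir / f"{name}.{ 'parquet' if fmt == 'parquet' else 'csv'}"
            if fmt == "parquet":
                df.to_parquet(path, index=False)
            else:
                df.to_csv(path, index=False)
            paths[name] = str(path)
        return paths

    @classmethod
    def read_tables(cls, indir, fmt: Optional[str] = None) -> "Cohort":
        indir = Path(indir)

        def _read(name):
            pq, csv = indir / f"{name}.parquet", indir / f"{name}.csv"
            if fmt == "parquet" or (fmt is None and pq.exists()):
                return pd.read_parquet(pq)
            if not csv.exists():
                from .errors import ArtefactError

                raise ArtefactError(f"missing cohort table: {csv}")
            return pd.read_csv(csv)

        return cls.from_frames(_read("patients"), _read("prescriptions"), _read("events"))

    @classmethod
    def from_frames(cls, patients: pd.DataFrame, prescriptions: pd.DataFrame,
                    events: pd.DataFrame) -> "Cohort":
        rx_by = {k: list(zip(g["day"], g["days_supply"])) for k, g in prescriptions.groupby("patient_id")}
        ev_by = {k: list(zip(g["label"], g["day"])) for k, g in events.groupby("patient_id")}
        records = []
        for row in patients.itertuples(index=False):
            d = row._asdict()
            pid = int(d["patient_id"])
            cov = {}
            for c in BASE_RAW_COLUMNS:
                v = d.get(c)
                if isinstance(v, float) and math.isnan(v):
                    v = None  # missing smoking/BMI round-trip as NaN
                cov[c] = v
            def _day(v):
                return None if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)
            records.append(
                PatientRecord(
                    patient_id=pid,
                    registration_start=int(d["registration_start"]),
                    covariates=cov,
                    prescriptions=[(int(a), int(b)) for a, b in rx_by.get(pid, [])],
                    events=[(str(l), int(dd)) for l, dd in ev_by.get(pid, [])],
                    death_day=_day(d.get("death_day")),
                    transfer_day=_day(d.get("transfer_day")),
                    linked=bool(d.get("linked", True)),
                    deterioration_day=_day(d.get("deterioration_day")),
                )
            )
        return cls(records)
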