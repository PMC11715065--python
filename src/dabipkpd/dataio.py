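"""NONMEM-convention long-format dataset container and CSV round trip.

Columns (header required): ID, TIME, EVID, CMT, AMT, RATE, DV, DVID, MDV,
WT, plus the generator's TRUNC flag (optional on read, default 0).
Semantics: EVID 1 rows are dose events (CMT 1 = dabigatran into the central
compartment, CMT 4 = idarucizumab reversal input) with AMT in mg and RATE
in mg/min; EVID 0 rows are observations with DV on channel DVID (1 =
plasma concentration mg/L, 2 = R-time min) and MDV = 1 marking a missing
value that is retained but excluded from fitting.  Missing numeric cells
are written as ".".  Times are minutes, weights kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DatasetError
from .model import DABIGATRAN, IDARUCIZUMAB, Regimen

__all__ = ["COLUMNS", "StudyDataset", "SubjectRecords", "read_dataset",
           "write_dataset"]

COLUMNS = ("ID", "TIME", "EVID", "CMT", "AMT", "RATE", "DV", "DVID", "MDV",
           "WT", "TRUNC")
REQUIRED = ("ID", "TIME", "EVID", "AMT", "RATE", "DV", "DVID", "MDV", "WT")


@dataclass
class SubjectRecords:
    """One subject's data unpacked into fitting-ready arrays."""

    id: object
    weight: float
    events: np.ndarray        # (m, 4): start, amount, duration, drug flag
    times: np.ndarray         # observation times (fitting rows only)
    y: np.ndarray
    channel: np.ndarray       # int64, 1 = concentration, 2 = R-time


class StudyDataset:
    """Long-format study records with validation and per-subject views."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        if "CMT" not in df.columns:
            df["CMT"] = np.where(df["EVID"] == 1, 1, 0)
        if "TRUNC" not in df.columns:
            df["TRUNC"] = 0
        self.df = df[list(COLUMNS)].reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        for col in REQUIRED:
            if col not in df.columns:
                raise DatasetError(f"missing required column {col}")
        for idx, row in df.iterrows():
            where = f"row {idx} (ID={row['ID']}, TIME={row['TIME']})"
            if row["TIME"] < 0 or not np.isfinite(row["TIME"]):
                raise DatasetError(f"negative or non-finite time at {where}")
            if not (row["WT"] > 0):
                raise DatasetError(f"missing or non-positive weight at {where}")
            if row["EVID"] == 1:
                if np.isfinite(row["DV"]):
                    raise DatasetError(f"dose row with DV set at {where}")
                if row["AMT"] < 0:
                    raise DatasetError(f"negative dose amount at {where}")
                if int(row["CMT"]) not in (1, 4):
                    raise DatasetError(f"unknown dose compartment at {where}")
            elif row["EVID"] == 0:
                if int(row["DVID"]) not in (1, 2):
                    raise DatasetError(f"observation channel must be 1 or 2 at {where}")
                if row["MDV"] == 0 and not np.isfinite(row["DV"]):
                    raise DatasetError(f"non-missing observation without DV at {where}")
            else:
                raise DatasetError(f"unsupported EVID {row['EVID']} at {where}")
        wt_per_id = df.groupby("ID")["WT"].nunique()
        if (wt_per_id > 1).any():
            bad = wt_per_id[wt_per_id > 1].index.tolist()
            raise DatasetError(f"weight varies within subject(s) {bad}")

    # -- views -------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"].tolist()))

    def observations(self, channel: int | None = None,
                     include_missing: bool = False) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        if not include_missing:
            obs = obs[obs["MDV"] == 0]
        if channel is not None:
            obs = obs[obs["DVID"] == channel]
        return obs

    def regimen_for(self, subject_id) -> Regimen:
        rows = self.df[(self.df["ID"] == subject_id) & (self.df["EVID"] == 1)]
        reg = Regimen()
        for _, r in rows.iterrows():
            drug = DABIGATRAN if int(r["CMT"]) == 1 else IDARUCIZUMAB
            dur = r["AMT"] / r["RATE"] if r["RATE"] > 0 else 0.0
            reg.add(drug, float(r["TIME"]), float(r["AMT"]), float(dur))
        return reg

    def subject_records(self, channels=(1, 2)) -> list[SubjectRecords]:
        """Fitting-ready arrays per subject (MDV = 0 rows, chosen channels)."""
        out = []
        for sid in self.subject_ids():
            sub = self.df[self.df["ID"] == sid]
            obs = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)
                      & (sub["DVID"].isin(channels))]
            events = self.regimen_for(sid).to_array()
            out.append(SubjectRecords(
                id=sid,
                weight=float(sub["WT"].iloc[0]),
                events=events,
                times=obs["TIME"].to_numpy(dtype=float),
                y=obs["DV"].to_numpy(dtype=float),
                channel=obs["DVID"].to_numpy(dtype=np.int64),
            ))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        a, b = self.df, other.df
        if a.shape != b.shape:
            return False
        num = a.select_dtypes(include=[np.number]).columns
        return bool(np.allclose(a[num].to_numpy(dtype=float),
                                b[num].to_numpy(dtype=float),
                                rtol=0, atol=1e-9, equal_nan=True))


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write the dataset as CSV, '.' for missing values."""
    df = dataset.df.copy()
    df.to_csv(path, index=False, na_rep=".")


def read_dataset(path) -> StudyDataset:
    """Read and validate a NONMEM-convention CSV dataset."""
    try:
        df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise DatasetError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s) {missing} in {path}")
    for col in ("ID", "EVID", "DVID", "MDV"):
        df[col] = df[col].fillna(0).astype(int)
    for col in ("TIME", "AMT", "RATE", "DV", "WT"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["AMT"] = df["AMT"].fillna(0.0)
    df["RATE"] = df["RATE"].fillna(0.0)
    return StudyDataset(df)
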