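"""Event-record dataset I/O (NONMEM column conventions).

A dataset is a flat CSV with one row per dose or observation event:

    ID, TIME, AMT, RATE, DUR, DV, EVID, MDV, OCC, AGE, WT, SCR, PMA

``EVID=1`` marks a dose (AMT in mg; duration from DUR, or AMT/RATE when DUR
is absent), ``EVID=0`` an observation (DV in mg/L, MDV=0).  Unknown columns
survive a round trip as covariate extras.  Times are hours from each
subject's first event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .popmodel import InfusionEvent, Regimen, SubjectCovariates

__all__ = ["DatasetError", "Subject", "TdmDataset", "read_dataset", "write_dataset"]

MANDATORY_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "OCC",
                     "AGE", "WT", "SCR"]
OPTIONAL_COLUMNS = ["RATE", "DUR", "PMA"]


class DatasetError(ValueError):
    """Raised for malformed event tables; messages name offending rows."""


@dataclass(frozen=True)
class Subject:
    """One subject's covariates, dosing history and observations."""

    id: int
    covariates: SubjectCovariates
    regimen: Regimen
    obs_times: np.ndarray       # h
    dv: np.ndarray              # mg/L
    obs_occ: np.ndarray         # occasion index per observation

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)


@dataclass
class TdmDataset:
    """Many subjects' event records, with optional simulation truth.

    ``truth`` (present for synthetic data) is a per-subject table of the
    realized random effects and individual parameters used to generate the
    observations; it is never read from or written to the event CSV.
    """

    df: pd.DataFrame
    truth: pd.DataFrame | None = None
    n_dropped_lloq: int = 0

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[int]:
        return list(dict.fromkeys(self.df["ID"].astype(int)))

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_obs(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def subject(self, sid: int) -> Subject:
        rows = self.df[self.df["ID"] == sid]
        if rows.empty:
            raise KeyError(f"no subject with ID {sid}")
        first = rows.iloc[0]
        pma = float(first["PMA"]) if "PMA" in rows and np.isfinite(first.get("PMA", np.nan)) else None
        cov = SubjectCovariates(
            age=float(first["AGE"]), wt=float(first["WT"]),
            scr=float(first["SCR"]), pma=pma,
        )
        doses = rows[rows["EVID"] == 1]
        events = tuple(
            InfusionEvent(float(r.TIME), float(r.AMT), float(r.DUR), int(r.OCC))
            for r in doses.itertuples()
        )
        obs = rows[rows["EVID"] == 0]
        t_end = max(
            [e.start + e.duration for e in events] + list(obs["TIME"]) + [0.0]
        )
        # horizon covers the standard 0-48 h exposure windows even for
        # subjects whose records end earlier
        reg = Regimen(events, horizon=max(t_end + 1e-6, 48.0))
        return Subject(
            id=int(sid), covariates=cov, regimen=reg,
            obs_times=obs["TIME"].to_numpy(dtype=float),
            dv=obs["DV"].to_numpy(dtype=float),
            obs_occ=obs["OCC"].to_numpy(dtype=int),
        )

    def subjects(self) -> Iterator[Subject]:
        for sid in self.subject_ids:
            yield self.subject(sid)

    def is_regular(self) -> bool:
        """True when every subject shares one infusion schedule (times,
        durations, occasions); doses may differ.  Regular datasets take the
        batched estimation path."""
        sig = None
        for sid in self.subject_ids:
            rows = self.df[(self.df["ID"] == sid) & (self.df["EVID"] == 1)]
            this = (tuple(rows["TIME"]), tuple(rows["DUR"]), tuple(rows["OCC"]))
            if sig is None:
                sig = this
            elif this != sig:
                return False
        return True

    def content_hash(self) -> str:
        import hashlib
        payload = self.df.round(12).to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()


def _require_columns(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing mandatory columns: {missing}")


def read_dataset(path) -> TdmDataset:
    """Read and validate an event-record CSV."""
    df = pd.read_csv(path)
    _require_columns(df)
    if "DUR" not in df.columns:
        df["DUR"] = np.nan
    if "PMA" not in df.columns:
        df["PMA"] = np.nan

    doses = df["EVID"] == 1
    bad = df.index[doses & df["DV"].notna() & (df["MDV"] == 0)]
    if len(bad):
        raise DatasetError(f"dose records carrying an observation at rows {list(bad + 2)}")
    bad = df.index[df["TIME"] < 0]
    if len(bad):
        raise DatasetError(f"negative TIME at rows {list(bad + 2)}")
    bad = df.index[doses & ~(df["AMT"] > 0)]
    if len(bad):
        raise DatasetError(f"dose records without positive AMT at rows {list(bad + 2)}")

    # infusion duration: DUR preferred, else AMT/RATE
    need_dur = doses & df["DUR"].isna()
    if "RATE" in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            derived = df["AMT"] / df["RATE"]
        df.loc[need_dur, "DUR"] = derived[need_dur]
    bad = df.index[doses & ~(df["DUR"] > 0)]
    if len(bad):
        raise DatasetError(
            f"cannot determine a positive infusion duration at rows {list(bad + 2)}"
        )
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return TdmDataset(df)


def write_dataset(ds: TdmDataset, path) -> None:
    df = ds.df.copy()
    if "RATE" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df.insert(df.columns.get_loc("AMT") + 1, "RATE", df["AMT"] / df["DUR"])
    df.to_csv(path, index=False)
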