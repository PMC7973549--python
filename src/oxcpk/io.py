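"""NONMEM-style event-record dataset: container, validation, CSV round trip.

One row per dose or observation.  Core columns:

    ID    subject identifier (rows of one subject are contiguous)
    TIME  event time (h); for steady-state dose rows the time of the last dose
    AMT   dose amount (mg) on dose rows, empty on observations
    DV    observed concentration (mg/L) on observation rows
    EVID  1 = dose, 0 = observation
    MDV   1 = DV missing/ignored
    SS    1 = dose row describes a steady-state regimen
    II    interdose interval tau (h) for steady-state dose rows
    WT, AGE, SEX, GFR, EIASM, STUDY   covariates (SEX 1 = male,
          STUDY 1 = registry steady-state arm, 2 = rich single-dose arm)

Unknown extra columns (e.g. concomitant-ASM flags) are preserved and exposed
as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CORE_COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "SS", "II",
    "WT", "AGE", "SEX", "GFR", "EIASM", "STUDY",
]
_INT_COLUMNS = ["ID", "EVID", "MDV", "SS", "SEX", "EIASM", "STUDY"]
_FLOAT_COLUMNS = ["TIME", "AMT", "DV", "II", "WT", "AGE", "GFR"]


class DatasetError(ValueError):
    """Raised when an event-record table violates the dataset invariants."""


@dataclass
class PKDataset:
    """Validated event-record table; the unit every pipeline stage consumes."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _normalize(self.df)
        _validate(self.df)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    @property
    def extra_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    def subject(self, sid) -> pd.DataFrame:
        return self.df[self.df["ID"] == sid]

    def subjects_table(self) -> pd.DataFrame:
        """One row per subject with its covariates (taken from the first row)."""
        return self.df.groupby("ID", sort=False).first().reset_index()

    def subset(self, ids, renumber: bool = False) -> "PKDataset":
        """New dataset restricted to ``ids`` (with repetition, e.g. bootstrap).

        With ``renumber`` each occurrence in ``ids`` becomes a fresh subject,
        so a bootstrap resample with duplicated subjects stays valid.
        """
        pieces = []
        for new_id, sid in enumerate(ids, start=1):
            block = self.df[self.df["ID"] == sid].copy()
            if block.empty:
                raise DatasetError(f"unknown subject id {sid!r}")
            if renumber:
                block["ID"] = new_id
            pieces.append(block)
        return PKDataset(pd.concat(pieces, ignore_index=True))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        return self.df.equals(other.df)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"column {col!r} is not integer-valued: {exc}") from exc
    for col in _FLOAT_COLUMNS:
        try:
            df[col] = df[col].astype(float)
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"column {col!r} is not numeric: {exc}") from exc
    ordered = CORE_COLUMNS + [c for c in df.columns if c not in CORE_COLUMNS]
    return df[ordered]


def _validate(df: pd.DataFrame) -> None:
    rows = df.index.to_numpy()
    dose = df["EVID"] == 1
    obs = df["EVID"] == 0

    bad = rows[~(dose | obs)]
    if bad.size:
        raise DatasetError(f"EVID must be 0 or 1; offending rows: {bad.tolist()}")

    bad = rows[dose & ~(df["AMT"] > 0)]
    if bad.size:
        raise DatasetError(f"dose rows must have AMT > 0; offending rows: {bad.tolist()}")
    bad = rows[dose & df["DV"].notna()]
    if bad.size:
        raise DatasetError(f"dose rows must not carry DV; offending rows: {bad.tolist()}")

    kept = obs & (df["MDV"] == 0)
    bad = rows[kept & ~(df["DV"] >= 0)]
    if bad.size:
        raise DatasetError(
            f"observation rows must have DV >= 0; offending rows: {bad.tolist()}"
        )

    bad = rows[(df["SS"] == 1) & ~(df["II"] > 0)]
    if bad.size:
        raise DatasetError(f"SS=1 rows must have II > 0; offending rows: {bad.tolist()}")

    ids = df["ID"].to_numpy()
    first_seen: dict = {}
    prev = None
    for i, sid in enumerate(ids):
        if sid != prev and sid in first_seen:
            raise DatasetError(
                f"subject ids must form contiguous blocks; id {sid} reappears at row {rows[i]}"
            )
        first_seen.setdefault(sid, i)
        prev = sid

    for sid, block in df.groupby("ID", sort=False):
        b_dose = block[block["EVID"] == 1]
        b_obs = block[(block["EVID"] == 0) & (block["MDV"] == 0)]
        if len(b_obs) and not len(b_dose):
            raise DatasetError(f"subject {sid} has observations but no dose record")
        if len(b_obs):
            t0 = b_dose["TIME"].min()
            early = b_obs.index[b_obs["TIME"] < t0]
            if early.size:
                raise DatasetError(
                    f"subject {sid}: observations before the first dose at rows "
                    f"{early.tolist()}"
                )


def read_dataset(path) -> PKDataset:
    """Read and validate an event-record CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    return PKDataset(df)


def write_dataset(ds: PKDataset, path) -> None:
    """Write the event-record CSV; ``read_dataset`` round-trips it losslessly."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # repr gives the shortest exact decimal, so floats survive the round trip
    ds.df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


@dataclass
class CompiledDataset:
    """Flat arrays over observation rows, the estimation hot-path layout.

    ``tau`` is the dosing interval for steady-state observations and ``inf``
    for single-dose observations; ``t_after_dose`` is time since the most
    recent dose (steady-state clock times are reduced modulo tau on compile).
    """

    ids: np.ndarray            # per subject, in order of appearance
    subj_idx: np.ndarray       # per observation -> subject index
    y: np.ndarray              # observed DV
    dose: np.ndarray           # per-administration dose amount
    tau: np.ndarray            # dosing interval (inf = single dose)
    t_after_dose: np.ndarray
    wt: np.ndarray             # per observation (subject weight broadcast)
    subjects: pd.DataFrame     # one covariate row per subject (index-aligned)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def covariate(self, name: str) -> np.ndarray:
        """Per-observation values of a subject-level covariate column."""
        if name not in self.subjects.columns:
            raise DatasetError(f"covariate column {name!r} not present in dataset")
        return self.subjects[name].to_numpy(dtype=float)[self.subj_idx]

    def obs_per_subject(self) -> np.ndarray:
        return np.bincount(self.subj_idx, minlength=self.n_subjects)


def compile_dataset(ds: PKDataset) -> CompiledDataset:
    """Resolve each observation against its governing dose event."""
    df = ds.df
    ids = df["ID"].unique()
    id_to_idx = {sid: k for k, sid in enumerate(ids)}

    subj_idx, y, dose, tau, t_ad, wt = [], [], [], [], [], []
    for sid, block in df.groupby("ID", sort=False):
        doses = block[block["EVID"] == 1]
        obs_rows = block[(block["EVID"] == 0) & (block["MDV"] == 0)]
        d_times = doses["TIME"].to_numpy()
        for _, row in obs_rows.iterrows():
            elig = doses[doses["TIME"] <= row["TIME"]]
            if elig.empty:
                raise DatasetError(
                    f"subject {sid}: observation at t={row['TIME']} precedes all doses"
                )
            drow = elig.iloc[np.argmax(elig["TIME"].to_numpy())]
            dt = row["TIME"] - drow["TIME"]
            if drow["SS"] == 1:
                ii = drow["II"]
                dt = dt % ii if dt >= ii else dt
                tau.append(ii)
            else:
                tau.append(np.inf)
            subj_idx.append(id_to_idx[sid])
            y.append(row["DV"])
            dose.append(drow["AMT"])
            t_ad.append(dt)
            wt.append(row["WT"])

    subjects = df.groupby("ID", sort=False).first().reset_index()
    return CompiledDataset(
        ids=np.asarray(ids),
        subj_idx=np.asarray(subj_idx, dtype=np.intp),
        y=np.asarray(y, dtype=float),
        dose=np.asarray(dose, dtype=float),
        tau=np.asarray(tau, dtype=float),
        t_after_dose=np.asarray(t_ad, dtype=float),
        wt=np.asarray(wt, dtype=float),
        subjects=subjects,
    )


__all__ = [
    "CORE_COLUMNS",
    "DatasetError",
    "PKDataset",
    "CompiledDataset",
    "read_dataset",
    "write_dataset",
    "compile_dataset",
]
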