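"""Plain-text readers and writers for every object the pipeline exchanges.

All formats are TSV/CSV/JSON: per-subject time series (T rows x R labeled
columns), the subjects table, FC matrices, edge-vector feature matrices, and
result tables.  Writers and readers round-trip losslessly at double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .simulate import CLINICAL_VARIABLES, SubjectRecord

_FLOAT_FMT = "%.17g"  # lossless for float64

SUBJECT_COLUMNS = ("id", "group") + CLINICAL_VARIABLES


def write_timeseries(path: str | Path, ts: np.ndarray, labels: list[str]) -> None:
    df = pd.DataFrame(np.asarray(ts, dtype=float), columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path, labels: list[str] | None = None) -> np.ndarray:
    """Read a T x R time-series TSV, validating the header against atlas labels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if labels is not None:
        if list(df.columns) != list(labels):
            raise ValueError(
                f"{path}: expected {len(labels)} region columns matching the atlas, "
                f"got {df.shape[1]}"
            )
    try:
        return df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric cell in time series ({err})") from None


def write_subjects(path: str | Path, records: list[SubjectRecord]) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read the subjects CSV; validates columns, group values and id uniqueness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subjects file not found: {path}")
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing subject columns: {sorted(missing)}")
    bad = set(df["group"].unique()) - {"OSA", "HC"}
    if bad:
        raise ValueError(f"{path}: unknown group value(s) {sorted(bad)}; allowed: ['HC', 'OSA']")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate subject id(s): {dup}")
    return df


def write_cohort(
    out_dir: str | Path,
    series: list[np.ndarray],
    records: list[SubjectRecord],
    atlas: RegionAtlas,
) -> None:
    """Write a full cohort: one time-series TSV per subject plus subjects.csv."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts, rec in zip(series, records):
        write_timeseries(out / "timeseries" / f"{rec.id}.tsv", ts, atlas.labels)
    write_subjects(out / "subjects.csv", records)


def read_cohort(in_dir: str | Path, atlas: RegionAtlas) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort` (or real data in that layout)."""
    in_dir = Path(in_dir)
    subjects = read_subjects(in_dir / "subjects.csv")
    series = [
        read_timeseries(in_dir / "timeseries" / f"{sid}.tsv", atlas.labels)
        for sid in subjects["id"]
    ]
    return series, subjects


def write_fc_matrix(path: str | Path, fc: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(fc, index=labels, columns=labels).to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_fc_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_feature_matrix(
    path: str | Path, x: np.ndarray, subject_ids: list[str], edge_labels: list[str]
) -> None:
    """Subjects x edges Fisher-z feature matrix as TSV (rows keyed by id)."""
    df = pd.DataFrame(np.asarray(x, dtype=float), index=subject_ids, columns=edge_labels)
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def write_edge_vector(path: str | Path, z: np.ndarray, edge_labels: list[str]) -> None:
    """One subject's Fisher-z edge vector keyed by 'label_i—label_j'."""
    pd.DataFrame({"edge": edge_labels, "z": np.asarray(z, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
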