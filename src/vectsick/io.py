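"""File formats: traces, questionnaires and the cohort feature table.

All formats are plain delimited text.  A cohort directory looks like::

    cohort/
      config.json          # generator / run configuration snapshot
      participants.csv     # id, sick
      ssq.csv              # id + the 16 canonical SSQ item columns (0-3)
      mssq.csv             # id + child_<type>/adult_<type> columns (0-3 or NE)
      beliefs.csv          # id, chair_answer, chair_certainty, drum_answer, ...
      fms.csv              # long format: id, time_min, score
      traces/
        <id>_vection.csv   # time_s, rating
        <id>_eye.csv       # time_s, eye_h_deg
        <id>_head.csv      # time_s, wx, wy, wz

The one binary reader is for a deposited XLSX workbook, isolated behind
``read_s1_workbook`` with a declared column mapping.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import scales
from .beliefs import BeliefReport
from .oculomotor import EyeTrace, HeadTrace
from .vection import VectionTrace

__all__ = [
    "COHORT_COLUMNS",
    "write_vection_trace",
    "read_vection_trace",
    "write_eye_trace",
    "read_eye_trace",
    "write_head_trace",
    "read_head_trace",
    "write_cohort_dir",
    "read_cohort_dir",
    "write_feature_table",
    "read_feature_table",
    "read_s1_workbook",
]

#: Schema of the per-participant feature table (CohortTable).
COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "ssq_ts",
    "mssq",
    "conflict_pb",
    "rl_chair",
    "rl_drum",
    "certainty_chair",
    "certainty_drum",
    "full_vection_pct",
    "sd_dv",
    "spev",
    "n_hm",
    "sick",
)

_COLUMN_RANGES: dict[str, tuple[float, float]] = {
    "ssq_ts": (0.0, scales.SSQ_MAX_TOTAL),
    "mssq": (0.0, 54.0),
    "conflict_pb": (0.0, 1.0),
    "rl_chair": (0.0, 1.0),
    "rl_drum": (0.0, 1.0),
    "certainty_chair": (0.0, 1.0),
    "certainty_drum": (0.0, 1.0),
    "full_vection_pct": (0.0, 100.0),
}


# ---------------------------------------------------------------- traces

def write_vection_trace(trace: VectionTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "rating": trace.ratings}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_vection_trace(path) -> VectionTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "rating"), path)
    return VectionTrace(times=df["time_s"].to_numpy(),
                        ratings=df["rating"].to_numpy())


def write_eye_trace(trace: EyeTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "eye_h_deg": trace.horizontal_position}
    ).to_csv(path, index=False, float_format="%.5f")


def read_eye_trace(path, sample_rate: float | None = None) -> EyeTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "eye_h_deg"), path)
    t = df["time_s"].to_numpy()
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 220.0
    return EyeTrace(times=t, horizontal_position=df["eye_h_deg"].to_numpy(),
                    sample_rate=sample_rate)


def write_head_trace(trace: HeadTrace, path) -> None:
    w = trace.angular_velocity
    pd.DataFrame(
        {"time_s": trace.times, "wx": w[:, 0], "wy": w[:, 1], "wz": w[:, 2]}
    ).to_csv(path, index=False, float_format="%.5f")


def read_head_trace(path, sample_rate: float | None = None) -> HeadTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "wx", "wy", "wz"), path)
    t = df["time_s"].to_numpy()
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 220.0
    return HeadTrace(
        times=t,
        angular_velocity=df[["wx", "wy", "wz"]].to_numpy(),
        sample_rate=sample_rate,
    )


# ------------------------------------------------------- questionnaires

def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _read_ssq_csv(path) -> dict[str, scales.SsqResponse]:
    df = pd.read_csv(path)
    _require_columns(df, ("id",) + scales.SSQ_ITEMS, path)
    out = {}
    for _, row in df.iterrows():
        ratings = {}
        for item in scales.SSQ_ITEMS:
            v = row[item]
            if v not in (0, 1, 2, 3):
                raise ValueError(
                    f"{path}: participant {row['id']!r}, column {item!r}: "
                    f"rating {v!r} outside {{0,1,2,3}}"
                )
            ratings[item] = int(v)
        out[str(row["id"])] = scales.SsqResponse(ratings=ratings)
    return out


def _mssq_cell(row, col, path):
    v = row[col]
    if isinstance(v, str) and v.strip().upper() == "NE":
        return None
    try:
        iv = int(v)
    except (TypeError, ValueError):
        iv = -1
    if iv not in (0, 1, 2, 3):
        raise ValueError(
            f"{path}: participant {row['id']!r}, column {col!r}: value {v!r} "
            f"must be a rating in {{0,1,2,3}} or 'NE'"
        )
    return iv


def _read_mssq_csv(path) -> dict[str, scales.MssqResponse]:
    df = pd.read_csv(path)
    cols = ["id"] + [
        f"{sec}_{t}" for sec in ("child", "adult") for t in scales.MSSQ_MOTION_TYPES
    ]
    _require_columns(df, cols, path)
    out = {}
    for _, row in df.iterrows():
        sections = {}
        for sec in ("child", "adult"):
            ratings, flagged = {}, set()
            for t in scales.MSSQ_MOTION_TYPES:
                v = _mssq_cell(row, f"{sec}_{t}", path)
                if v is None:
                    flagged.add(t)
                    ratings[t] = 0
                else:
                    ratings[t] = v
            sections[sec] = scales.MssqSection(
                ratings=ratings, not_experienced=frozenset(flagged)
            )
        out[str(row["id"])] = scales.MssqResponse(
            child_section=sections["child"], adult_section=sections["adult"]
        )
    return out


def _read_beliefs_csv(path) -> dict[str, BeliefReport]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("id", "chair_answer", "chair_certainty", "drum_answer", "drum_certainty"),
        path,
    )
    out = {}
    for _, row in df.iterrows():
        def yn(col):
            v = str(row[col]).strip().upper()
            if v not in ("Y", "N"):
                raise ValueError(
                    f"{path}: participant {row['id']!r}, column {col!r}: "
                    f"answer {row[col]!r} must be Y or N"
                )
            return v == "Y"

        out[str(row["id"])] = BeliefReport(
            chair_answer=yn("chair_answer"),
            chair_certainty=float(row["chair_certainty"]),
            drum_answer=yn("drum_answer"),
            drum_certainty=float(row["drum_certainty"]),
        )
    return out


def _read_fms_csv(path) -> dict[str, scales.FmsSeries]:
    df = pd.read_csv(path)
    _require_columns(df, ("id", "time_min", "score"), path)
    out = {}
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("time_min")
        out[str(pid)] = scales.FmsSeries(
            times=tuple(float(t) for t in grp["time_min"]),
            scores=tuple(int(s) for s in grp["score"]),
        )
    return out


# ------------------------------------------------------ cohort directory

def write_cohort_dir(records, directory, config=None) -> Path:
    """Write a synthetic cohort's raw data as a cohort directory."""
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    if config is not None:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))

    pd.DataFrame(
        {"id": [r.pid for r in records], "sick": [r.sick for r in records]}
    ).to_csv(directory / "participants.csv", index=False)

    pd.DataFrame(
        [{"id": r.pid, **r.ssq_response.ratings} for r in records]
    ).to_csv(directory / "ssq.csv", index=False)

    rows = []
    for r in records:
        row: dict = {"id": r.pid}
        for sec_name, sec in (
            ("child", r.mssq_response.child_section),
            ("adult", r.mssq_response.adult_section),
        ):
            for t in scales.MSSQ_MOTION_TYPES:
                row[f"{sec_name}_{t}"] = (
                    "NE" if t in sec.not_experienced else sec.ratings[t]
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "mssq.csv", index=False)

    pd.DataFrame(
        [
            {
                "id": r.pid,
                "chair_answer": "Y" if r.belief_report.chair_answer else "N",
                "chair_certainty": r.belief_report.chair_certainty,
                "drum_answer": "Y" if r.belief_report.drum_answer else "N",
                "drum_certainty": r.belief_report.drum_certainty,
            }
            for r in records
        ]
    ).to_csv(directory / "beliefs.csv", index=False, float_format="%.6f")

    pd.DataFrame(
        [
            {"id": r.pid, "time_min": t, "score": s}
            for r in records
            for t, s in zip(r.fms_series.times, r.fms_series.scores)
        ]
    ).to_csv(directory / "fms.csv", index=False)

    for r in records:
        write_vection_trace(r.vection_trace, directory / "traces" / f"{r.pid}_vection.csv")
        write_eye_trace(r.eye_trace, directory / "traces" / f"{r.pid}_eye.csv")
        write_head_trace(r.head_trace, directory / "traces" / f"{r.pid}_head.csv")
    return directory


def read_cohort_dir(directory) -> dict:
    """Load a cohort directory into per-participant raw records.

    Returns a dict with keys ``ids``, ``ssq``, ``mssq``, ``beliefs``,
    ``fms``, ``sick`` and per-id trace loaders under ``traces``.
    """
    directory = Path(directory)
    participants = pd.read_csv(directory / "participants.csv")
    _require_columns(participants, ("id", "sick"), directory / "participants.csv")
    ids = [str(i) for i in participants["id"]]
    sick = dict(zip(ids, participants["sick"].astype(bool)))

    def trace_paths(pid: str) -> dict[str, Path]:
        base = directory / "traces"
        return {
            "vection": base / f"{pid}_vection.csv",
            "eye": base / f"{pid}_eye.csv",
            "head": base / f"{pid}_head.csv",
        }

    return {
        "ids": ids,
        "sick": sick,
        "ssq": _read_ssq_csv(directory / "ssq.csv"),
        "mssq": _read_mssq_csv(directory / "mssq.csv"),
        "beliefs": _read_beliefs_csv(directory / "beliefs.csv"),
        "fms": _read_fms_csv(directory / "fms.csv"),
        "traces": {pid: trace_paths(pid) for pid in ids},
    }


# ------------------------------------------------------- feature table

def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def validate_feature_table(df: pd.DataFrame, path="<table>") -> pd.DataFrame:
    _require_columns(df, COHORT_COLUMNS, path)
    for col, (lo, hi) in _COLUMN_RANGES.items():
        x = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            bad = df["id"][~np.isfinite(x)].iloc[0]
            raise ValueError(f"{path}: participant {bad!r}, column {col!r}: not finite")
        if np.any(x < lo) or np.any(x > hi):
            bad = df["id"][(x < lo) | (x > hi)].iloc[0]
            raise ValueError(
                f"{path}: participant {bad!r}, column {col!r}: value outside "
                f"[{lo}, {hi}]"
            )
    return df


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_feature_table(df, path)


def read_s1_workbook(path, column_mapping: Mapping[str, str],
                     sheet_name=0) -> pd.DataFrame:
    """Ingest a deposited XLSX workbook into the cohort feature schema.

    ``column_mapping`` maps workbook column names to the canonical
    ``COHORT_COLUMNS`` names; unmapped canonical columns must be derivable
    (``conflict_pb`` is recomputed from FullVection and RL_chair when
    absent).
    """
    raw = pd.read_excel(path, sheet_name=sheet_name)
    df = raw.rename(columns=dict(column_mapping))
    if "conflict_pb" not in df.columns and {
        "full_vection_pct",
        "rl_chair",
    } <= set(df.columns):
        df["conflict_pb"] = (
            df["full_vection_pct"] / 100.0 - df["rl_chair"]
        ).abs()
    if "id" not in df.columns:
        df.insert(0, "id", [f"s{i + 1:02d}" for i in range(len(df))])
    if "sick" not in df.columns:
        df["sick"] = False
    return validate_feature_table(df[list(COHORT_COLUMNS)], path)
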