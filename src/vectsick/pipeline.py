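"""End-to-end pipeline: raw cohort data -> feature table -> analysis report.

``compute_features`` turns each participant's raw records (knob trace, eye
trace, head trace, questionnaires, belief answers) into the one-row-per-
participant feature table the statistics stage consumes.  ``analyze_table``
runs the correlation screen and the logit-linear conflict regression and
packages both into a JSON-serializable report.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from . import scales, stats
from .beliefs import conflict_pb, likelihoods_from_report
from .oculomotor import count_head_movements, spev
from .vection import vection_features

__all__ = [
    "RunConfig",
    "features_from_records",
    "features_from_cohort_dir",
    "analyze_table",
    "report_text",
    "run_pipeline",
    "reproduce_from_workbook",
]

_MIN_N = 5  # fewest participants the regression stage can sensibly handle


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Pipeline parameter overrides; unknown keys are rejected at load."""

    seed: int = 0
    logit_scale_max: float = scales.SSQ_MAX_TOTAL
    iterate_exclusion: bool = False
    fast_phase_accel_threshold: float = 1200.0
    spev_median_window_s: float = 0.25
    gaussian_sd_s: float = 0.005
    head_lowpass_hz: float = 10.0
    head_threshold: float = 3.0
    nhm_count_samples: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


def _participant_row(
    pid: str,
    vection_trace,
    eye_trace,
    head_trace,
    ssq_response,
    mssq_response,
    belief_report,
    sick: bool,
    config: RunConfig,
) -> dict:
    vf = vection_features(vection_trace)
    rl = likelihoods_from_report(belief_report)
    nys = spev(
        eye_trace,
        gaussian_sd_s=config.gaussian_sd_s,
        accel_threshold=config.fast_phase_accel_threshold,
        median_window_s=config.spev_median_window_s,
    )
    nhm = count_head_movements(
        head_trace,
        cutoff_hz=config.head_lowpass_hz,
        threshold=config.head_threshold,
        count_samples=config.nhm_count_samples,
    )
    return {
        "id": pid,
        "ssq_ts": scales.score_ssq(ssq_response).total_score,
        "mssq": scales.score_mssq(mssq_response),
        "conflict_pb": conflict_pb(vf.full_vection_pct, rl.rl_chair),
        "rl_chair": rl.rl_chair,
        "rl_drum": rl.rl_drum,
        "certainty_chair": belief_report.chair_certainty,
        "certainty_drum": belief_report.drum_certainty,
        "full_vection_pct": vf.full_vection_pct,
        "sd_dv": vf.sd_dv,
        "spev": nys.median_spev,
        "n_hm": nhm,
        "sick": bool(sick),
    }


def features_from_records(records, config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Feature table from in-memory synthetic ParticipantRecords."""
    rows = []
    for r in records:
        try:
            rows.append(
                _participant_row(
                    r.pid,
                    r.vection_trace,
                    r.eye_trace,
                    r.head_trace,
                    r.ssq_response,
                    r.mssq_response,
                    r.belief_report,
                    r.sick,
                    config,
                )
            )
        except Exception as exc:  # add participant context
            raise RuntimeError(f"feature extraction failed for {r.pid}") from exc
    return vio.validate_feature_table(pd.DataFrame(rows))


def features_from_cohort_dir(directory, config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Feature table from an on-disk cohort directory."""
    cohort = vio.read_cohort_dir(directory)
    rows = []
    for pid in cohort["ids"]:
        paths = cohort["traces"][pid]
        try:
            rows.append(
                _participant_row(
                    pid,
                    vio.read_vection_trace(paths["vection"]),
                    vio.read_eye_trace(paths["eye"]),
                    vio.read_head_trace(paths["head"]),
                    cohort["ssq"][pid],
                    cohort["mssq"][pid],
                    cohort["beliefs"][pid],
                    cohort["sick"][pid],
                    config,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for {pid}") from exc
    return vio.validate_feature_table(pd.DataFrame(rows))


def analyze_table(table: pd.DataFrame, config: RunConfig = RunConfig()) -> dict:
    """Correlation screen + conflict regression on a feature table."""
    if len(table) < _MIN_N:
        raise ValueError(
            f"insufficient n: {len(table)} participants (need >= {_MIN_N})"
        )
    screen = stats.spearman_screen(table)
    fit = stats.fit_conflict_model(
        table,
        scale_max=config.logit_scale_max,
        iterate_exclusion=config.iterate_exclusion,
    )
    return {
        "n": int(len(table)),
        "screen": {
            "n": screen.n,
            "m_tests": screen.m_tests,
            "rows": screen.table.reset_index().to_dict(orient="records"),
        },
        "regression": {
            "coefficients": fit.coefficients.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "r_squared_retained": fit.r_squared_retained,
            "r_squared_retained_adj": fit.r_squared_retained_adj,
            "r_squared_mssq_only": fit.r_squared_mssq_only,
            "r_squared_overall": fit.r_squared_overall,
            "excluded_ids": list(fit.excluded_ids),
            "nested_f": fit.nested_f,
            "n_total": fit.n_total,
            "n_retained": fit.n_retained,
        },
        "config": dataclasses.asdict(config),
    }


def report_text(report: dict) -> str:
    """Human-readable rendering of an analysis report."""
    lines = ["Correlation screen (Spearman vs SSQ-TS, Bonferroni m="
             f"{report['screen']['m_tests']}, n={report['screen']['n']})"]
    for row in report["screen"]["rows"]:
        lines.append(
            f"  {row['predictor']:<18} rho={row['rho']:+.2f}  p={row['p']:.3f}"
            f"  p_adj={row['p_adjusted']:.3f}"
        )
    reg = report["regression"]
    lines.append(
        f"Regression: logit(SSQ-TS) ~ MSSQ + Conflict_PB "
        f"(n={reg['n_retained']}/{reg['n_total']} retained; excluded: "
        f"{', '.join(map(str, reg['excluded_ids'])) or 'none'})"
    )
    for row in reg["coefficients"]:
        std = "" if not np.isfinite(row["standardized"]) else f"  std={row['standardized']:+.2f}"
        lines.append(
            f"  {row['term']:<12} b={row['estimate']:+.3f}  SE={row['se']:.3f}"
            f"{std}  p={row['p']:.4f}"
        )
    nf = reg["nested_f"]
    lines.append(
        f"  MSSQ-only R2 = {reg['r_squared_mssq_only']:.0f}% ; full R2 = "
        f"{reg['r_squared_retained']:.0f}% (retained) ; overall R2 = "
        f"{reg['r_squared_overall']:.0f}%"
    )
    lines.append(
        f"  nested F({nf['df1']},{nf['df2']}) = {nf['F']:.2f}, p = {nf['p']:.4f}"
    )
    return "\n".join(lines)


def run_pipeline(cohort_dir, out_dir, config: RunConfig = RunConfig()) -> dict:
    """Cohort directory -> features CSV + correlation CSV + report JSON/text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = features_from_cohort_dir(cohort_dir, config)
    vio.write_feature_table(table, out_dir / "features.csv")
    report = analyze_table(table, config)
    pd.DataFrame(report["screen"]["rows"]).to_csv(
        out_dir / "correlations.csv", index=False
    )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out_dir / "report.txt").write_text(report_text(report) + "\n")
    (out_dir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2)
    )
    return report


def reproduce_from_workbook(
    workbook_path,
    column_mapping,
    out_dir=None,
    config: RunConfig = RunConfig(),
) -> dict:
    """Recompute the study tables from a deposited workbook.

    Reads the individual-data XLSX with a declared column mapping, then runs
    exactly the same screen and regression as ``analyze_table``.
    """
    table = vio.read_s1_workbook(workbook_path, column_mapping)
    report = analyze_table(table, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vio.write_feature_table(table, out_dir / "features.csv")
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=float)
        )
        (out_dir / "report.txt").write_text(report_text(report) + "\n")
    return report
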