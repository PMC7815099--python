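"""Correlation screen and the logit-linear motion-sickness model.

The analysis proceeds in two stages over the per-participant feature table:

1. an exploratory screen — two-tailed Spearman correlations between the
   SSQ Total Score and each of the ten candidate predictors, Bonferroni
   corrected over the ten tests;
2. a multiple regression of the logit-transformed SSQ-TS on MSSQ and
   Conflict_PB.  Influential cases (|externally studentized residual| >
   1.96 or |DFFITS| > 1, judged on the two-predictor fit) are excluded in
   a single identify-then-refit pass (an iterated variant is available for
   sensitivity analysis).  On the retained cases the
   susceptibility-only and susceptibility+conflict models are compared with
   a nested F-test, and the retained-case model is also scored on the full
   cohort (squared Pearson correlation of observed vs predicted logit
   outcome) to give the "overall" explained variance.

The logit transform uses the SSQ scale ceiling 235.62 by default so the
outcome is an interior fraction of its scale; this constant is configurable
because it is the main reproduction risk for the intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .scales import SSQ_MAX_TOTAL

__all__ = [
    "SCREEN_PREDICTORS",
    "CorrelationTable",
    "RegressionResult",
    "spearman_screen",
    "logit_outcome",
    "inverse_logit_outcome",
    "influence_diagnostics",
    "influence_exclusion",
    "standardize_coefficients",
    "fit_conflict_model",
]

#: The ten candidate predictors screened against SSQ-TS, in table order.
SCREEN_PREDICTORS: tuple[str, ...] = (
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
)

STUDENTIZED_CUTOFF = 1.96
DFFITS_CUTOFF = 1.0


@dataclass(frozen=True)
class CorrelationTable:
    table: pd.DataFrame  # index = predictor; columns rho, p, p_adjusted
    n: int
    m_tests: int


@dataclass(frozen=True)
class RegressionResult:
    coefficients: pd.DataFrame  # index term; estimate, se, standardized, p
    r_squared_retained: float  # %, MSSQ+Conflict model, retained cases
    r_squared_retained_adj: float  # %, adjusted
    r_squared_mssq_only: float  # %, MSSQ-only model, retained cases
    r_squared_overall: float  # %, retained-case model scored on all cases
    excluded_ids: tuple = ()
    nested_f: dict = field(default_factory=dict)
    n_total: int = 0
    n_retained: int = 0


def spearman_screen(
    table: pd.DataFrame,
    outcome: str = "ssq_ts",
    predictors: tuple[str, ...] = SCREEN_PREDICTORS,
) -> CorrelationTable:
    """Two-tailed Spearman correlation of each predictor with the outcome,
    Bonferroni-adjusted over the ``len(predictors)`` tests.

    A constant predictor has no defined rank correlation; its row carries
    NaN and is flagged in the ``degenerate`` column.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 participants for a correlation screen")
    y = table[outcome].to_numpy(dtype=float)
    m = len(predictors)
    rows = []
    for name in predictors:
        x = table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, np.nan, np.nan, True))
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append((name, float(rho), float(p), min(1.0, m * float(p)), False))
    df = pd.DataFrame(
        rows, columns=["predictor", "rho", "p", "p_adjusted", "degenerate"]
    ).set_index("predictor")
    return CorrelationTable(table=df, n=len(table), m_tests=m)


def logit_outcome(ssq_ts, scale_max: float = SSQ_MAX_TOTAL):
    """ln(p / (1-p)) with p = ssq_ts / scale_max; requires 0 < ssq_ts < scale_max."""
    x = np.asarray(ssq_ts, dtype=float)
    if np.any(x <= 0) or np.any(x >= scale_max):
        raise ValueError(
            f"ssq_ts must lie strictly inside (0, {scale_max}) for the logit transform"
        )
    p = x / scale_max
    out = np.log(p / (1.0 - p))
    return float(out) if np.isscalar(ssq_ts) else out


def inverse_logit_outcome(eta, scale_max: float = SSQ_MAX_TOTAL):
    """Back-transform a logit-scale outcome to SSQ-TS points."""
    eta = np.asarray(eta, dtype=float)
    out = scale_max / (1.0 + np.exp(-eta))
    return float(out) if out.ndim == 0 else out


def _influence_arrays(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form externally studentized residuals and DFFITS.

    With hat values h_i and residuals e_i of the OLS fit, the leave-one-out
    residual variance is s_(i)^2 = (RSS - e_i^2/(1-h_i)) / (n - p - 1), the
    externally studentized residual t_i = e_i / (s_(i) sqrt(1-h_i)) and
    DFFITS_i = t_i sqrt(h_i / (1-h_i)).
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    Q, _ = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", Q, Q)
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    if n <= p + 1:
        raise ValueError("influence diagnostics need n > p + 1")
    rss = float(e @ e)
    if rss <= 1e-12 * max(float(y @ y), 1.0):  # numerically exact fit
        z = np.zeros(n)
        return z, z.copy()
    s2_loo = np.maximum((rss - e**2 / (1.0 - h)) / (n - p - 1), 1e-300)
    t = e / np.sqrt(s2_loo * (1.0 - h))
    dffits = t * np.sqrt(h / (1.0 - h))
    return t, dffits


def influence_diagnostics(fit) -> pd.DataFrame:
    """Externally studentized residuals and DFFITS for a fitted OLS model."""
    t, dffits = _influence_arrays(
        np.asarray(fit.model.endog, dtype=float),
        np.asarray(fit.model.exog, dtype=float),
    )
    return pd.DataFrame({"studentized_external": t, "dffits": dffits})


def influence_exclusion(
    y: np.ndarray,
    X: np.ndarray,
    ids: np.ndarray,
    iterate: bool = False,
) -> tuple[np.ndarray, list]:
    """Drop influential cases from an OLS fit.

    Cases with |externally studentized residual| > 1.96 or |DFFITS| > 1 are
    removed and the model refit.  By default the diagnostics are applied in
    a single pass (identify once, exclude, refit), which is how a 1.96
    cutoff behaves at small n: under normal residuals the *iterated* rule
    keeps flagging ~5% of the remaining cases each round and can cascade
    until the model is unfittable.  ``iterate=True`` repeats identify/refit
    until no case is flagged, for sensitivity analysis.  Returns the
    retained-row boolean mask and the excluded ids in exclusion order.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ids = np.asarray(ids)
    p = X.shape[1]
    keep = np.ones(y.size, dtype=bool)
    excluded: list = []
    if keep.sum() < p + 2:
        raise ValueError("too few cases to fit the model")
    while True:
        t, dffits = _influence_arrays(y[keep], X[keep])
        flags = (np.abs(t) > STUDENTIZED_CUTOFF) | (np.abs(dffits) > DFFITS_CUTOFF)
        if not flags.any():
            break
        kept_ids = ids[keep]
        excluded.extend(kept_ids[flags].tolist())
        drop = set(kept_ids[flags].tolist())
        keep &= ~np.isin(ids, list(drop))
        if keep.sum() < p + 2:
            raise ValueError(
                "influence exclusion left too few cases to fit the model"
            )
        if not iterate:
            break
    return keep, excluded


def standardize_coefficients(fit, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized slopes: estimate x SD(predictor) / SD(outcome).

    ``X`` includes the intercept column, whose entry is returned as NaN.
    """
    sx = np.std(np.asarray(X, dtype=float), axis=0, ddof=1)
    sy = np.std(np.asarray(y, dtype=float), ddof=1)
    if np.any(sx[1:] == 0):
        raise ValueError("zero-variance predictor; standardized estimate undefined")
    out = fit.params * sx / sy
    out[0] = np.nan
    return out


def fit_conflict_model(
    table: pd.DataFrame,
    scale_max: float = SSQ_MAX_TOTAL,
    iterate_exclusion: bool = False,
) -> RegressionResult:
    """Fit logit(SSQ-TS) ~ MSSQ and ~ MSSQ + Conflict_PB with influence-based
    case exclusion, nested-model comparison, and overall-variance scoring.
    """
    ids = table["id"].to_numpy() if "id" in table.columns else table.index.to_numpy()
    y = logit_outcome(table["ssq_ts"].to_numpy(dtype=float), scale_max=scale_max)
    X_full = np.column_stack(
        [
            np.ones(len(table)),
            table["mssq"].to_numpy(dtype=float),
            table["conflict_pb"].to_numpy(dtype=float),
        ]
    )
    keep, excluded = influence_exclusion(y, X_full, ids, iterate=iterate_exclusion)

    yk = y[keep]
    Xk = X_full[keep]
    full = sm.OLS(yk, Xk).fit()
    reduced = sm.OLS(yk, Xk[:, :2]).fit()
    f_stat, f_p, df_diff = full.compare_f_test(reduced)

    std = standardize_coefficients(full, Xk, yk)
    coef = pd.DataFrame(
        {
            "estimate": full.params,
            "se": full.bse,
            "standardized": std,
            "p": full.pvalues,
        },
        index=["intercept", "mssq", "conflict_pb"],
    )

    # retained-case model applied to every participant
    pred_all = X_full @ full.params
    r_overall = float(np.corrcoef(y, pred_all)[0, 1] ** 2)

    return RegressionResult(
        coefficients=coef,
        r_squared_retained=100.0 * float(full.rsquared),
        r_squared_retained_adj=100.0 * float(full.rsquared_adj),
        r_squared_mssq_only=100.0 * float(reduced.rsquared),
        r_squared_overall=100.0 * r_overall,
        excluded_ids=tuple(excluded),
        nested_f={
            "F": float(f_stat),
            "df1": int(df_diff),
            "df2": int(full.df_resid),
            "p": float(f_p),
        },
        n_total=int(len(table)),
        n_retained=int(keep.sum()),
    )
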