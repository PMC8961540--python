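"""Diagnostic-marker evaluation: threshold rules, 2x2 metrics, and ROC/AUC.

The 2x2 metrics follow the standard definitions: sensitivity and specificity
on the percent scale, positive likelihood ratio LR+ = sens / (1 - spec), and
a 95% CI for LR+ by the log method with

    SE(ln LR+) = sqrt(1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN)).

AUC confidence intervals use DeLong's placement-value variance estimator.
Covariate "adjustment" of a ROC analysis is implemented as the ROC of fitted
probabilities from a logit model containing the predictor(s) and covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._logistic import fit_logistic

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054

#: marker positivity cut-offs (strict inequalities): upper reference limits
DEFAULT_THRESHOLDS = {
    "GGT_M": 73.0,  # IU/L
    "GGT_F": 38.0,  # IU/L
    "MCV": 100.0,   # fL
    "CDT": 1.6,     # %
}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 diagnostic table; tp = risk drinkers with a positive marker."""

    tp: int
    fn: int
    fp: int
    tn: int
    note: str | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_diseased + self.n_healthy

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float          # %
    specificity: float          # %
    lr_plus: float              # ratio; inf when fp == 0 and tp > 0
    lr_ci: tuple[float, float] | None  # 95% CI, None when undefined
    flag: str | None = None


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    adjusted_for: tuple[str, ...] = ()


def apply_marker_thresholds(
    sex: str,
    ggt: float | None = None,
    mcv: float | None = None,
    cdt: float | None = None,
    thresholds: dict | None = None,
) -> dict[str, bool | None]:
    """Positivity flags for GGT/MCV/CDT; None for a missing value.

    All cut-offs are strict: a value exactly at the reference limit is
    negative.
    """
    if sex not in ("M", "F"):
        raise ValueError(f"unknown sex code {sex!r} (expected 'M' or 'F')")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    def _flag(value, limit):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return bool(value > limit)

    return {
        "GGT": _flag(ggt, thr["GGT_M"] if sex == "M" else thr["GGT_F"]),
        "MCV": _flag(mcv, thr["MCV"]),
        "CDT": _flag(cdt, thr["CDT"]),
    }


def diagnostic_metrics(t: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity, specificity and LR+ (with log-method 95% CI) from counts."""
    if t.n_diseased == 0 or t.n_healthy == 0:
        raise ValueError("both diseased and healthy margins must be positive")
    sens = 100.0 * t.tp / t.n_diseased
    spec = 100.0 * t.tn / t.n_healthy
    if t.tp == 0:
        return DiagnosticMetrics(sens, spec, 0.0, None, flag="zero_tp")
    if t.fp == 0:
        return DiagnosticMetrics(sens, spec, math.inf, None, flag="zero_fp")
    lr = (t.tp / t.n_diseased) / (t.fp / t.n_healthy)
    se = math.sqrt(1 / t.tp - 1 / t.n_diseased + 1 / t.fp - 1 / t.n_healthy)
    ci = (lr * math.exp(-Z95 * se), lr * math.exp(Z95 * se))
    return DiagnosticMetrics(sens, spec, lr, ci)


def _binary_outcome(values) -> np.ndarray:
    """Map an outcome column to 0/1; accepts bools, 0/1 ints, or risk labels."""
    arr = np.asarray(values)
    if arr.dtype.kind in "bif":
        out = arr.astype(float)
        if not np.all(np.isin(out, (0.0, 1.0))):
            raise ValueError("numeric outcome must be 0/1")
        return out
    mapping = {"risk": 1.0, "non-risk": 0.0}
    try:
        return np.array([mapping[str(v)] for v in arr])
    except KeyError as exc:
        raise ValueError(f"unrecognised outcome label {exc.args[0]!r}") from exc


def empirical_auc(scores, outcome) -> float:
    """Empirical AUC via the rank statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_outcome(outcome)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(scores)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = sps.rankdata(allv)
    v10 = (r_all[:m] - sps.rankdata(pos)) / n      # placement values of positives
    v01 = 1.0 - (r_all[m:] - sps.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, outcome, adjusted_for: tuple[str, ...] = ()) -> RocResult:
    """Empirical AUC with a DeLong 95% CI (clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_outcome(outcome)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    auc = empirical_auc(scores, y)
    se = math.sqrt(_delong_variance(scores[y == 1], scores[y == 0]))
    lo = max(0.0, auc - Z95 * se)
    hi = min(1.0, auc + Z95 * se)
    return RocResult(auc=auc, ci95=(lo, hi), n_pos=n_pos, n_neg=n_neg,
                     adjusted_for=tuple(adjusted_for))


def adjusted_scores(
    df: pd.DataFrame,
    predictor_columns,
    covariates=(),
    outcome_col: str = "risk",
) -> np.ndarray:
    """Per-subject fitted probabilities from outcome ~ predictors + covariates.

    With no predictors and no covariates this is the intercept-only model and
    every score equals the outcome prevalence. Separation is logged, not
    raised; the saturated probabilities are still returned.
    """
    y = _binary_outcome(df[outcome_col])
    cols = list(predictor_columns) + list(covariates)
    X = df[cols].to_numpy(dtype=float) if cols else np.empty((len(df), 0))
    _, prob, separated = fit_logistic(X, y)
    if separated:
        logger.warning("adjusted_scores: (quasi-)separation detected for %s", cols)
    return prob


def compare_marker_vs_balance(
    df: pd.DataFrame,
    marker_col: str,
    balance_scores,
    covariates=("age", "smoker"),
    outcome_col: str = "risk",
) -> dict[str, RocResult]:
    """Adjusted ROC for the marker alone, the balance alone, and both combined."""
    work = df.copy()
    work["_balance"] = np.asarray(balance_scores, dtype=float)
    out = {}
    for key, preds in (
        ("marker", [marker_col]),
        ("balance", ["_balance"]),
        ("combined", [marker_col, "_balance"]),
    ):
        sc = adjusted_scores(work, preds, covariates, outcome_col)
        out[key] = roc_auc(sc, work[outcome_col], adjusted_for=tuple(covariates))
    return out


def metrics_report(tables: dict[str, ContingencyTable]) -> pd.DataFrame:
    """Tabulate diagnostic_metrics over a dict of labelled 2x2 tables."""
    rows = []
    for label, tab in tables.items():
        m = diagnostic_metrics(tab)
        rows.append({
            "marker": label,
            "tp": tab.tp, "fn": tab.fn, "fp": tab.fp, "tn": tab.tn,
            "sensitivity_pct": m.sensitivity,
            "specificity_pct": m.specificity,
            "lr_plus": m.lr_plus,
            "lr_ci_lo": m.lr_ci[0] if m.lr_ci else np.nan,
            "lr_ci_hi": m.lr_ci[1] if m.lr_ci else np.nan,
            "flag": m.flag or "",
        })
    return pd.DataFrame(rows)
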