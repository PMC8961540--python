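"""Config-driven orchestration of the full analysis.

simulate-or-ingest cohort -> sex-stratified univariate peak screen with Holm
adjustment -> derived-trait table -> balance selection -> diagnostic-marker
evaluation (2x2 metrics plus covariate-adjusted ROC for markers, the
selected balance, and marker+balance combinations).

Sex strata are never pooled. Every output file carries the config hash so
artifacts from different runs cannot be mixed silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import forward_select
from .diagnostics import (ContingencyTable, apply_marker_thresholds,
                          compare_marker_vs_balance, metrics_report, roc_auc,
                          adjusted_scores)
from .stats import univariate_screen
from .synthetic import (PEAK_LABELS, default_cohort_spec, generate_cohort,
                        to_frame)
from .traits import trait_table

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "sex", "risk", "age", "smoker",
                    "alcohol_gweek") + PEAK_LABELS + ("GGT", "MCV", "CDT")
CLOSURE_TOL = 0.5  # absolute tolerance on sum(GP) for ingested tables


@dataclass
class RunConfig:
    mode: str = "simulate"                 # "simulate" | "ingest"
    input_path: str | None = None          # cohort CSV in ingest mode
    output_dir: str = "runs/latest"
    sexes: tuple[str, ...] = ("M", "F")
    seed: int | None = None
    n_per_stratum: int = 500               # simulate mode
    correlation_model: str = "one-factor"
    loading: float = 0.3
    univariate_columns: tuple[str, ...] = PEAK_LABELS
    covariates: tuple[str, ...] = ("age", "smoker")
    balance_max_size: int = 8
    balance_cv_folds: int = 5
    balance_cv_repeats: int = 2
    thresholds: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("seed is mandatory in simulate mode")
        if self.mode == "ingest":
            if not self.input_path:
                raise ValueError("ingest mode requires input_path")
            if not Path(self.input_path).exists():
                raise FileNotFoundError(self.input_path)
        self.sexes = tuple(self.sexes)
        self.univariate_columns = tuple(self.univariate_columns)
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        # hash the analytic parameters only: where results are written (and
        # how chattily) must not change what they contain
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("output_dir", "log_level")}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_cohort_csv(path) -> tuple[pd.DataFrame, list[str]]:
    """Schema/range validation; returns (frame, list of all violations).

    GP rows whose sum is within CLOSURE_TOL of 100 are re-closed with a
    recorded warning; rows further away are a hard violation (and are also
    re-closed so downstream code can still run on the remainder).
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV: surface pandas' line info
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    violations: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        violations.append(f"missing columns: {missing}")
        return df, violations
    bad_sex = df.loc[~df["sex"].astype(str).isin(["M", "F"])]
    for i in bad_sex.index:
        violations.append(f"row {i}: unknown sex {df.at[i, 'sex']!r}")
    bad_risk = df.loc[~df["risk"].astype(str).isin(["risk", "non-risk"])]
    for i in bad_risk.index:
        violations.append(f"row {i}: unknown risk label {df.at[i, 'risk']!r}")
    gp = df[list(PEAK_LABELS)].to_numpy(dtype=float)
    if np.any(gp < 0):
        for i in np.flatnonzero((gp < 0).any(axis=1)):
            violations.append(f"row {i}: negative peak area")
    sums = gp.sum(axis=1)
    off = np.abs(sums - 100.0)
    for i in np.flatnonzero((off > 1e-9) & (off <= CLOSURE_TOL)):
        violations.append(f"row {i}: GP sum {sums[i]:.4f} re-closed to 100")
    for i in np.flatnonzero(off > CLOSURE_TOL):
        violations.append(f"row {i}: GP sum {sums[i]:.4f} violates closure "
                          f"beyond +/-{CLOSURE_TOL}")
    with np.errstate(invalid="ignore"):
        df[list(PEAK_LABELS)] = 100.0 * gp / sums[:, None]
    for col in ("GGT", "MCV", "CDT", "alcohol_gweek"):
        bad = df.index[df[col].astype(float) < 0]
        for i in bad:
            violations.append(f"row {i}: negative {col}")
    bad_age = df.index[(df["age"] < 18) | (df["age"] > 91)]
    for i in bad_age:
        violations.append(f"row {i}: age {df.at[i, 'age']} outside [18, 91]")
    return df, violations


def _marker_tables(df: pd.DataFrame, thresholds: dict) -> dict[str, ContingencyTable]:
    tables = {}
    for marker, col in (("GGT", "GGT"), ("MCV", "MCV"), ("CDT", "CDT")):
        tp = fn = fp = tn = 0
        for _, row in df.iterrows():
            flags = apply_marker_thresholds(row["sex"], ggt=row["GGT"],
                                            mcv=row["MCV"], cdt=row["CDT"],
                                            thresholds=thresholds or None)
            flag = flags[marker]
            if flag is None:
                continue
            if row["risk"] == "risk":
                tp, fn = (tp + 1, fn) if flag else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if flag else (fp, tn + 1)
        tables[marker] = ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)
    return tables


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    if config.mode == "simulate":
        frames = []
        for i, sex in enumerate(config.sexes):
            spec = default_cohort_spec(
                sex, n_per_stratum=config.n_per_stratum,
                seed=config.seed + i,
                correlation_model=config.correlation_model,
                loading=config.loading)
            frames.append(to_frame(generate_cohort(spec)))
        cohort = pd.concat(frames, ignore_index=True)
        _write_csv(cohort, out / "cohort.csv", cfg_hash)
        violations: list[str] = []
    else:
        cohort, violations = validate_cohort_csv(config.input_path)
        hard = [v for v in violations if "violates closure" in v
                or "missing columns" in v]
        if hard:
            raise ValueError("cohort validation failed: " + "; ".join(hard))
        for v in violations:
            logger.warning("cohort validation: %s", v)

    for sex in config.sexes:
        sub = cohort[cohort["sex"].astype(str) == sex].reset_index(drop=True)
        if sub.empty:
            logger.warning("no subjects for sex %s; skipping", sex)
            continue
        tag = sex.lower()

        uni = univariate_screen(sub, config.univariate_columns)
        _write_csv(uni, out / f"univariate_{tag}.csv", cfg_hash)

        traits = trait_table(sub)
        _write_csv(traits, out / f"traits_{tag}.csv", cfg_hash)

        sel = forward_select(sub, covariates=config.covariates,
                             max_size=config.balance_max_size,
                             cv_folds=config.balance_cv_folds,
                             cv_repeats=config.balance_cv_repeats,
                             seed=(config.seed or 0) + 1000)
        payload = json.loads(sel.to_json())
        payload["config_hash"] = cfg_hash
        (out / f"selection_{tag}.json").write_text(json.dumps(payload, indent=2))
        _write_csv(pd.DataFrame({"subject_id": sub["subject_id"],
                                 "balance_score": sel.scores}),
                   out / f"balance_scores_{tag}.csv", cfg_hash)

        tables = _marker_tables(sub, config.thresholds)
        diag = metrics_report(tables)
        aucs = []
        for marker in ("GGT", "MCV", "CDT"):
            comp = compare_marker_vs_balance(sub, marker, sel.scores,
                                             covariates=config.covariates)
            aucs.append({"predictor": marker, **_roc_row(comp["marker"])})
            aucs.append({"predictor": f"{marker}+balance",
                         **_roc_row(comp["combined"])})
        bal_scores = adjusted_scores(
            sub.assign(_balance=sel.scores), ["_balance"], config.covariates)
        aucs.append({"predictor": "balance",
                     **_roc_row(roc_auc(bal_scores, sub["risk"],
                                        adjusted_for=config.covariates))})
        _write_csv(diag.merge(pd.DataFrame(aucs), how="outer",
                              left_on="marker", right_on="predictor"),
                   out / f"diagnostics_{tag}.csv", cfg_hash)

    manifest = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "versions": {"glycorisk": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "validation_warnings": violations,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _roc_row(r) -> dict:
    return {"auc": r.auc, "auc_ci_lo": r.ci95[0], "auc_ci_hi": r.ci95[1]}
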