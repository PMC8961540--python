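"""Derived glycan traits from the 46-peak composition.

Each trait is a fixed linear combination of the 46 glycan peaks (GP1..GP46,
% of total area). Mixed peaks are split fractionally: GP6, GP12, GP21 and
GP44 contribute one half, GP41 and GP46 one third, to the traits that share
them. The coefficient table is data, not code, so an independent evaluator
can be written against the same published formula strings.

Three exact partition identities hold for every closed input:
  S0+S1+S2+S3+S4 = 100
  G0+G1+G2+G3+G4+OM = 100
  A1+A2+A3+A4+OM = 100
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import holm_adjust, rank_sum

N_PEAKS = 46
PEAK_LABELS = tuple(f"GP{i}" for i in range(1, N_PEAKS + 1))


def _ones(*idx: int) -> dict[int, float]:
    return {i: 1.0 for i in idx}


def _span(a: int, b: int) -> dict[int, float]:
    return {i: 1.0 for i in range(a, b + 1)}


#: trait -> {1-based peak index -> coefficient}
TRAIT_COEFFS: dict[str, dict[int, float]] = {
    # sialylation
    "S0": _span(1, 15),
    "S1": {**_span(16, 23), 30: 1.0},
    "S2": {**_span(24, 29), 31: 1.0},
    "S3": _span(32, 40),
    "S4": _span(41, 46),
    # galactosylation
    "G0": {1: 1.0, 2: 1.0, 4: 1.0, 5: 1.0, 6: 0.5, 12: 0.5},
    "G1": {3: 1.0, **_span(7, 10), 12: 0.5, **_span(16, 18), 21: 0.5},
    "G2": {**_span(13, 15), 19: 1.0, 20: 1.0, 21: 0.5, **_span(22, 28)},
    "G3": {29: 1.0, **_span(31, 37)},
    "G4": {30: 1.0, **_span(38, 46)},
    # branching (antennarity)
    "A1": {1: 1.0, 2: 1.0, 3: 1.0, 12: 0.5, 21: 0.5},
    "A2": {4: 1.0, 5: 1.0, 6: 0.5, **_span(7, 10), 12: 0.5, **_span(13, 20),
           21: 0.5, **_span(22, 28)},
    "A3": {29: 1.0, **_span(31, 37)},
    "A4": {30: 1.0, **_span(38, 46)},
    # oligomannose
    "OM": {6: 0.5, 11: 1.0},
    # fucosylation
    "CF": {2: 1.0, 5: 1.0, 6: 0.5, **_span(8, 10), 14: 1.0, 15: 1.0,
           17: 1.0, 18: 1.0, 22: 1.0, 23: 1.0, 27: 1.0, 28: 1.0,
           36: 1.0, 44: 0.5},
    "OF": {37: 1.0, 40: 1.0, 41: 1.0 / 3.0, 45: 1.0, 46: 1.0 / 3.0},
}

TRAIT_ORDER = ("G0", "G1", "G2", "G3", "G4",
               "S0", "S1", "S2", "S3", "S4",
               "A1", "A2", "A3", "A4", "OM", "CF", "OF")

# dense (n_traits, 46) coefficient matrix, rows in TRAIT_ORDER
_COEF_MATRIX = np.zeros((len(TRAIT_ORDER), N_PEAKS))
for _t, _trait in enumerate(TRAIT_ORDER):
    for _i, _c in TRAIT_COEFFS[_trait].items():
        _COEF_MATRIX[_t, _i - 1] = _c


@dataclass(frozen=True)
class TraitVector:
    G0: float; G1: float; G2: float; G3: float; G4: float
    S0: float; S1: float; S2: float; S3: float; S4: float
    A1: float; A2: float; A3: float; A4: float
    OM: float; CF: float; OF: float

    def as_dict(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in TRAIT_ORDER}


def derive_traits(gp, atol: float = 1e-6) -> TraitVector:
    """Trait abundances (%) from one closed 46-peak composition."""
    gp = np.asarray(gp, dtype=float)
    if gp.shape != (N_PEAKS,):
        raise ValueError(f"expected a 46-vector, got shape {gp.shape}")
    if np.any(gp < 0):
        raise ValueError("peak areas must be non-negative")
    if abs(gp.sum() - 100.0) > atol:
        raise ValueError(f"composition must sum to 100, got {gp.sum()!r}")
    vals = _COEF_MATRIX @ gp
    return TraitVector(**dict(zip(TRAIT_ORDER, vals.tolist())))


def traits_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append all trait columns to a cohort frame with GP1..GP46 columns."""
    gp = df[list(PEAK_LABELS)].to_numpy(dtype=float)
    sums = gp.sum(axis=1)
    if np.any(np.abs(sums - 100.0) > 1e-6):
        raise ValueError("every row must be closed to 100")
    vals = gp @ _COEF_MATRIX.T
    out = df.copy()
    for t, col in zip(TRAIT_ORDER, vals.T):
        out[t] = col
    return out


def trait_group_compare(
    df: pd.DataFrame,
    trait_name: str,
    group_col: str = "risk",
    sex_col: str = "sex",
    stratify_by_sex: bool = True,
) -> pd.DataFrame:
    """Per-sex two-group comparison of one trait: medians, IQRs, rank-sum p."""
    if trait_name not in TRAIT_ORDER:
        raise ValueError(f"unknown trait {trait_name!r}")
    work = df if trait_name in df.columns else traits_frame(df)
    strata = sorted(work[sex_col].astype(str).unique()) if stratify_by_sex else ["all"]
    rows = []
    for sex in strata:
        sub = work if sex == "all" else work[work[sex_col].astype(str) == sex]
        labels = sub[group_col].astype(str)
        y = sub.loc[labels == "risk", trait_name].to_numpy(dtype=float)
        x = sub.loc[labels == "non-risk", trait_name].to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"stratum {sex!r} has fewer than 2 subjects per group")
        res = rank_sum(x, y)
        rows.append({
            "sex": sex, "trait": trait_name,
            "median_nonrisk": float(np.median(x)),
            "q1_nonrisk": float(np.percentile(x, 25)),
            "q3_nonrisk": float(np.percentile(x, 75)),
            "median_risk": float(np.median(y)),
            "q1_risk": float(np.percentile(y, 25)),
            "q3_risk": float(np.percentile(y, 75)),
            "p_raw": res.p_raw,
        })
    return pd.DataFrame(rows)


def trait_table(df: pd.DataFrame, group_col: str = "risk") -> pd.DataFrame:
    """All-trait two-group summary (single sex stratum) with Holm column."""
    work = traits_frame(df)
    rows = []
    for t in TRAIT_ORDER:
        sub = trait_group_compare(work, t, group_col=group_col,
                                  stratify_by_sex=False)
        rows.append(sub.iloc[0].drop(labels=["sex"]))
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out
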