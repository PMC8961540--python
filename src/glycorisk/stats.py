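"""Univariate statistical toolkit: rank-sum, chi-squared, trend test, Holm.

Conventions:
- all p-values are two-sided;
- the Mann-Whitney test is exact (enumeration) when the combined sample size
  is at most 20 and there are no ties, otherwise a normal approximation with
  tie and continuity corrections is used;
- the Jonckheere-Terpstra test uses the no-tie normal approximation, falling
  back to a seeded Monte-Carlo permutation null when tied cross-pairs exceed
  10% of all cross-pairs;
- "sequential Bonferroni" is the Holm step-down adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    method: str
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError(f"p_raw out of [0, 1]: {self.p_raw}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("p_adjusted must be >= p_raw")


def rank_sum(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U for the first sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # degenerate tie-saturated case: U at its null mean, p = 1
        return TestResult(statistic=x.size * y.size / 2.0, p_raw=1.0,
                          method="mann-whitney (degenerate)",
                          n_per_group=(x.size, y.size))
    n_total = x.size + y.size
    has_ties = np.unique(combined).size < n_total
    method = "exact" if (n_total <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic),
                      p_raw=min(1.0, float(res.pvalue)),
                      method=f"mann-whitney ({method})",
                      n_per_group=(x.size, y.size))


def proportion_test(table, yates: bool = False) -> TestResult:
    """Pearson chi-squared test on a 2x2 table (no continuity correction
    by default; Yates available behind the flag)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-squared test undefined")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=yates)
    return TestResult(statistic=float(stat), p_raw=min(1.0, float(p)),
                      method="chi-squared" + (" (yates)" if yates else ""),
                      n_per_group=(int(arr[0].sum()), int(arr[1].sum())))


def _jt_statistic(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """J = sum over group pairs k<l of #(x_k < x_l) + 0.5 #(x_k = x_l).

    Returns (J, tied cross-pairs, total cross-pairs).
    """
    j = 0.0
    tied = 0
    total = 0
    for k in range(len(groups) - 1):
        xk = groups[k][:, None]
        for l in range(k + 1, len(groups)):
            xl = groups[l][None, :]
            j += np.sum(xk < xl) + 0.5 * np.sum(xk == xl)
            tied += int(np.sum(xk == xl))
            total += xk.size * xl.size
    return float(j), tied, total


def jonckheere_terpstra(
    groups,
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    force_permutation: bool = False,
    tie_threshold: float = 0.10,
) -> TestResult:
    """Two-sided Jonckheere-Terpstra trend test across ordered groups.

    The reported statistic is the standardized J:
    z = (J - E0[J]) / sqrt(Var0[J]) with E0[J] = (N^2 - sum n_k^2)/4 and the
    standard no-tie variance. When tied cross-pairs exceed ``tie_threshold``
    (or ``force_permutation``), the p-value comes from a seeded permutation
    null on |J - E0[J]| instead of the normal approximation.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("need at least 3 ordered groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    sizes = np.array([g.size for g in gs])
    n = int(sizes.sum())
    j, tied, total = _jt_statistic(gs)
    e0 = (n * n - np.sum(sizes**2)) / 4.0
    var0 = (n * n * (2 * n + 3) - np.sum(sizes**2 * (2 * sizes + 3))) / 72.0
    z = (j - e0) / np.sqrt(var0) if var0 > 0 else 0.0

    use_perm = force_permutation or (tied / total > tie_threshold)
    if use_perm:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(gs)
        cuts = np.cumsum(sizes)[:-1]
        obs = abs(j - e0)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            j_star, _, _ = _jt_statistic(np.split(perm, cuts))
            if abs(j_star - e0) >= obs - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        method = f"jonckheere-terpstra (permutation, B={n_perm})"
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "jonckheere-terpstra (normal)"
    return TestResult(statistic=float(z), p_raw=float(p), method=method,
                      n_per_group=tuple(int(s) for s in sizes))


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    return adjusted.tolist()


def univariate_screen(
    df: pd.DataFrame,
    columns,
    group_col: str = "risk",
    positive_label: str = "risk",
) -> pd.DataFrame:
    """Two-group rank-sum screen over columns with Holm adjustment.

    Output mirrors the published peak-table layout: per-group medians and
    quartiles plus raw and Holm-adjusted p-values, one row per column.
    """
    labels = df[group_col].astype(str)
    pos = df.loc[labels == positive_label]
    neg = df.loc[labels != positive_label]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for col in columns:
        x = neg[col].to_numpy(dtype=float)
        y = pos[col].to_numpy(dtype=float)
        res = rank_sum(x, y)
        rows.append({
            "variable": col,
            "n_nonrisk": x.size, "n_risk": y.size,
            "median_nonrisk": float(np.median(x)),
            "q1_nonrisk": float(np.percentile(x, 25)),
            "q3_nonrisk": float(np.percentile(x, 75)),
            "median_risk": float(np.median(y)),
            "q1_risk": float(np.percentile(y, 25)),
            "q3_risk": float(np.percentile(y, 75)),
            "p_raw": res.p_raw,
        })
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out
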