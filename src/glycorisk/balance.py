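"""Log-contrast balance selection for a binary outcome (selbal-style).

A balance between disjoint part sets N (size p) and D (size q) of a closed
composition x is

    B(x) = sqrt(pq / (p + q)) * (mean_{i in N} ln x_i - mean_{j in D} ln x_j),

which is invariant to the closure constant. The forward search starts from
the exhaustive best two-part balance, then greedily adds one unused part per
step to whichever side most improves the criterion -- the in-sample AUC of a
logit model outcome ~ balance + covariates. Model size is chosen by repeated
stratified k-fold cross-validation (highest mean test AUC, ties to the
smaller size; an optional one-standard-error rule is off by default).

All tie-breaks are lexicographic on peak labels and every random draw comes
from the caller's seed, so results are fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logistic import fit_logistic, predict_logistic
from .diagnostics import _binary_outcome, empirical_auc


@dataclass(frozen=True)
class Balance:
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValueError("numerator and denominator must be non-empty")
        if num & den:
            raise ValueError(f"overlapping parts: {sorted(num & den)}")

    @property
    def size(self) -> int:
        return len(self.numerator) + len(self.denominator)


@dataclass(frozen=True)
class SelectionResult:
    balance: Balance
    criterion_trace: tuple[float, ...]   # full-data criterion at sizes 2..max
    cv_table: tuple[dict, ...]           # per size: mean/sd test criterion
    chosen_size: int
    covariates_used: tuple[str, ...]
    seed: int
    scores: np.ndarray = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps({
            "numerator": list(self.balance.numerator),
            "denominator": list(self.balance.denominator),
            "chosen_size": self.chosen_size,
            "criterion_trace": list(self.criterion_trace),
            "cv_table": list(self.cv_table),
            "covariates": list(self.covariates_used),
            "seed": self.seed,
        }, indent=2)


def balance_score(gp, numerator, denominator, labels=None) -> np.ndarray | float:
    """Balance value(s) for one composition (1-D) or a matrix of rows (2-D).

    ``numerator``/``denominator`` are label collections when ``gp`` is a
    DataFrame or ``labels`` is given, otherwise 0-based column indices.
    """
    if isinstance(gp, pd.DataFrame):
        labels = list(gp.columns)
        gp = gp.to_numpy(dtype=float)
    arr = np.asarray(gp, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if labels is not None:
        index = {lab: i for i, lab in enumerate(labels)}
        num_idx = [index[l] for l in numerator]
        den_idx = [index[l] for l in denominator]
    else:
        num_idx, den_idx = list(numerator), list(denominator)
    if set(num_idx) & set(den_idx):
        raise ValueError("numerator and denominator must be disjoint")
    if not num_idx or not den_idx:
        raise ValueError("numerator and denominator must be non-empty")
    sub = arr[:, num_idx + den_idx]
    if np.any(sub <= 0):
        raise ValueError("all named parts must be strictly positive; "
                         "apply zero_replace first")
    p, q = len(num_idx), len(den_idx)
    coef = np.sqrt(p * q / (p + q))
    ln = np.log(arr, where=arr > 0, out=np.full_like(arr, -np.inf))
    out = coef * (ln[:, num_idx].mean(axis=1) - ln[:, den_idx].mean(axis=1))
    return float(out[0]) if single else out


def zero_replace(gp, method: str = "multiplicative") -> np.ndarray:
    """Make a closed composition strictly positive.

    ``pseudocount``: set zero cells to delta = half the smallest observed
    positive value, then re-close to 100. ``multiplicative``: zero cells get
    delta and positive cells are shrunk proportionally, preserving their
    ratios exactly. Inputs without zeros are returned unchanged.
    """
    arr = np.asarray(gp, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if np.any(arr < 0):
        raise ValueError("composition must be non-negative")
    out = arr.copy()
    for r in range(out.shape[0]):
        row = out[r]
        if row.sum() <= 0:
            raise ValueError(f"row {r} is all-zero")
        zeros = row == 0
        if not zeros.any():
            continue
        delta = row[row > 0].min() / 2.0
        if method == "pseudocount":
            row[zeros] = delta
            row *= 100.0 / row.sum()
        elif method == "multiplicative":
            n_zero = int(zeros.sum())
            row[~zeros] *= 1.0 - n_zero * delta / 100.0
            row[zeros] = delta
        else:
            raise ValueError(f"unknown zero-replacement method {method!r}")
    return out[0] if single else out


def evaluate_candidate(
    df: pd.DataFrame,
    balance: Balance,
    covariates=(),
    outcome_col: str = "risk",
) -> float:
    """In-sample AUC of outcome ~ balance_score + covariates (logit link)."""
    labels = list(balance.numerator) + list(balance.denominator)
    comp = df[labels].to_numpy(dtype=float)
    scores = balance_score(comp, list(range(len(balance.numerator))),
                           list(range(len(balance.numerator), len(labels))))
    y = _binary_outcome(df[outcome_col])
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    cov = df[list(covariates)].to_numpy(dtype=float) if covariates else None
    X = scores[:, None] if cov is None else np.column_stack([scores, cov])
    _, prob, _ = fit_logistic(X, y)
    return empirical_auc(prob, y)


# ---------------------------------------------------------------------------
# forward search internals (index-based for speed)

def _score_from_logs(L: np.ndarray, num: list[int], den: list[int]) -> np.ndarray:
    p, q = len(num), len(den)
    coef = np.sqrt(p * q / (p + q))
    return coef * (L[:, num].mean(axis=1) - L[:, den].mean(axis=1))


def _criterion(L, C, y, num, den, train, test=None) -> float:
    scores = _score_from_logs(L, num, den)
    X = scores[:, None] if C is None else np.column_stack([scores, C])
    beta, prob, _ = fit_logistic(X[train], y[train])
    if test is None:
        return empirical_auc(prob, y[train])
    return empirical_auc(predict_logistic(beta, X[test]), y[test])


def _forward_path(L, C, y, train, max_size: int) -> list[tuple[list[int], list[int], float]]:
    """Greedy path of balances for sizes 2..max_size on the training rows.

    Candidates are scanned in lexicographic label order (columns of L are
    pre-sorted), so equal criteria resolve to the smallest labels.
    """
    n_parts = L.shape[1]
    best_pair, best_crit = None, -np.inf
    for i in range(n_parts):
        for j in range(n_parts):
            if i == j:
                continue
            crit = _criterion(L, C, y, [i], [j], train)
            if crit > best_crit + 1e-12:
                best_crit, best_pair = crit, ([i], [j])
    num, den = best_pair
    path = [(list(num), list(den), best_crit)]
    used = set(num) | set(den)
    for _size in range(3, max_size + 1):
        best_cand, best_c = None, -np.inf
        for k in range(n_parts):
            if k in used:
                continue
            for cand in ((num + [k], den), (num, den + [k])):
                crit = _criterion(L, C, y, cand[0], cand[1], train)
                if crit > best_c + 1e-12:
                    best_c, best_cand = crit, (list(cand[0]), list(cand[1]))
        num, den = best_cand
        used = set(num) | set(den)
        path.append((list(num), list(den), best_c))
    return path


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Fold assignment (length-n int array values 0..k-1), stratified on y."""
    assign = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % k
    return assign


def forward_select(
    df: pd.DataFrame,
    covariates=(),
    *,
    peaks=None,
    outcome_col: str = "risk",
    max_size: int = 12,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int,
    one_se: bool = False,
    zero_method: str = "multiplicative",
) -> SelectionResult:
    """Forward log-contrast balance selection with CV model-size choice."""
    labels = sorted(peaks) if peaks is not None else sorted(
        c for c in df.columns if c.startswith("GP"))
    if len(labels) < 2:
        raise ValueError("need at least 2 peaks")
    if max_size > len(labels):
        raise ValueError(f"max_size={max_size} exceeds {len(labels)} peaks")
    if max_size < 2:
        raise ValueError("max_size must be at least 2")
    comp = zero_replace(df[labels].to_numpy(dtype=float), method=zero_method)
    L = np.log(comp)
    C = df[list(covariates)].to_numpy(dtype=float) if covariates else None
    y = _binary_outcome(df[outcome_col])
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")

    rng = np.random.default_rng(seed)
    sizes = list(range(2, max_size + 1))
    cv_scores = np.full((cv_repeats * cv_folds, len(sizes)), np.nan)
    row = 0
    for _rep in range(cv_repeats):
        assign = _stratified_folds(y, cv_folds, rng)
        for f in range(cv_folds):
            train = assign != f
            test = ~train
            if np.unique(y[test]).size < 2 or np.unique(y[train]).size < 2:
                continue  # stratification makes this possible only for tiny n
            path = _forward_path(L, C, y, train, max_size)
            for s_i, (num, den, _c) in enumerate(path):
                cv_scores[row, s_i] = _criterion(L, C, y, num, den, train, test)
            row += 1
    with np.errstate(invalid="ignore"):
        means = np.nanmean(cv_scores, axis=0)
        sds = np.nanstd(cv_scores, axis=0, ddof=1)
    best_i = int(np.nanargmax(np.round(means, 12)))  # ties -> smaller size
    for i in range(best_i):
        if means[i] >= means[best_i] - 1e-12:
            best_i = i
            break
    if one_se:
        thresh = means[best_i] - sds[best_i] / np.sqrt(np.sum(~np.isnan(cv_scores[:, best_i])))
        for i in range(best_i + 1):
            if means[i] >= thresh:
                best_i = i
                break
    chosen_size = sizes[best_i]

    full = np.ones(y.size, dtype=bool)
    path = _forward_path(L, C, y, full, chosen_size)
    trace = tuple(c for _n, _d, c in path)
    num_idx, den_idx, _ = path[-1]
    balance = Balance(numerator=tuple(labels[i] for i in num_idx),
                      denominator=tuple(labels[i] for i in den_idx))
    scores = _score_from_logs(L, num_idx, den_idx)
    cv_table = tuple(
        {"size": s, "mean": float(means[i]), "sd": float(sds[i])}
        for i, s in enumerate(sizes)
    )
    return SelectionResult(balance=balance, criterion_trace=trace,
                           cv_table=cv_table, chosen_size=chosen_size,
                           covariates_used=tuple(covariates), seed=seed,
                           scores=scores)
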