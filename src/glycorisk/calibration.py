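"""Chromatogram reduction: GU calibration, peak binning, closure.

A dextran ladder (retention time vs glucose units) is fitted with a
fifth-order least-squares polynomial; the fitted curve must be strictly
increasing over the ladder's retention-time range. Peaks are binned into 46
contiguous half-open GU windows [lo, hi) -- a peak sitting exactly on a
boundary belongs to the upper window -- and areas are closed to % of total.

The exact GU boundaries of the published 46-peak scheme are not printed in
the source material; the default window table (46 equal windows spanning
GU 4.4-12.0) is a configurable placeholder, not ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_PEAKS = 46


@dataclass(frozen=True)
class DextranLadder:
    """Calibration points (retention time in minutes, glucose units)."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 7:
            raise ValueError(f"need at least 7 ladder points, got {len(self.points)}")
        pts = sorted(self.points, key=lambda p: p[1])
        rts = np.array([p[0] for p in pts])
        gus = np.array([p[1] for p in pts])
        if np.any(np.diff(gus) <= 0):
            raise ValueError("GU values must be distinct")
        if np.any(np.diff(rts) <= 0):
            raise ValueError("retention times must increase strictly with GU")
        object.__setattr__(self, "points", tuple((float(r), float(g)) for r, g in pts))

    @property
    def rt(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def gu(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class GUCalibration:
    """Degree-5 polynomial mapping retention time (min) to GU."""

    coefficients: tuple[float, ...]  # ascending powers, length 6
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.coefficients) != 6:
            raise ValueError("expected 6 polynomial coefficients")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("valid_range must be an increasing interval")

    def gu_at(self, rt) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(rt, dtype=float),
                                                np.asarray(self.coefficients))


@dataclass(frozen=True)
class PeakList:
    """Integrated peaks: (retention time in minutes, area >= 0)."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        areas = np.array([p[1] for p in self.peaks], dtype=float)
        if np.any(areas < 0):
            raise ValueError("peak areas must be non-negative")
        if not np.any(areas > 0):
            raise ValueError("at least one peak must have positive area")


@dataclass(frozen=True)
class GUWindowTable:
    """46 contiguous half-open GU windows labelled GP1..GP46."""

    edges: tuple[float, ...]  # 47 strictly increasing boundaries

    def __post_init__(self) -> None:
        if len(self.edges) != N_PEAKS + 1:
            raise ValueError(f"expected {N_PEAKS + 1} edges, got {len(self.edges)}")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("window edges must be strictly increasing")

    @classmethod
    def default(cls) -> "GUWindowTable":
        # placeholder scheme: 46 equal windows on GU 4.4-12.0 (see module docs)
        return cls(edges=tuple(np.linspace(4.4, 12.0, N_PEAKS + 1).tolist()))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"GP{i}" for i in range(1, N_PEAKS + 1))

    def to_frame(self) -> pd.DataFrame:
        e = np.asarray(self.edges)
        return pd.DataFrame({"label": self.labels, "lo": e[:-1], "hi": e[1:]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GUWindowTable":
        lo = df["lo"].to_numpy(dtype=float)
        hi = df["hi"].to_numpy(dtype=float)
        if not np.allclose(lo[1:], hi[:-1]):
            raise ValueError("windows must be contiguous (hi_i == lo_{i+1})")
        return cls(edges=tuple(np.concatenate([lo, hi[-1:]]).tolist()))


def fit_gu_curve(ladder: DextranLadder) -> GUCalibration:
    """Least-squares degree-5 fit of GU on retention time.

    Raises if the fitted polynomial is not strictly increasing on the
    ladder's retention-time range (a non-invertible calibration is useless).
    """
    rt, gu = ladder.rt, ladder.gu
    poly = np.polynomial.Polynomial.fit(rt, gu, deg=5)
    coefs = poly.convert().coef
    coefs = np.pad(coefs, (0, 6 - len(coefs)))
    cal = GUCalibration(coefficients=tuple(coefs.tolist()),
                        valid_range=(float(rt.min()), float(rt.max())))
    grid = np.linspace(cal.valid_range[0], cal.valid_range[1], 2001)
    vals = cal.gu_at(grid)
    if np.any(np.diff(vals) <= 0):
        bad = grid[np.argmin(np.diff(vals))]
        raise ValueError(
            f"fitted degree-5 calibration is non-monotone near rt={bad:.3f} min; "
            "check ladder coverage/spacing")
    return cal


def assign_peaks(
    peaks: PeakList,
    cal: GUCalibration,
    windows: GUWindowTable | None = None,
) -> tuple[np.ndarray, float]:
    """Bin peak areas into the 46 GU windows.

    Returns (46-vector of areas, unassigned area). Peaks whose retention time
    falls outside the calibration range, or whose GU falls outside every
    window, are counted as unassigned (with a logged warning).
    """
    windows = windows or GUWindowTable.default()
    edges = np.asarray(windows.edges)
    areas = np.zeros(N_PEAKS)
    unassigned = 0.0
    lo, hi = cal.valid_range
    for rt, area in peaks.peaks:
        if rt < lo or rt > hi:
            logger.warning("peak at rt=%.4f min outside calibration range "
                           "[%.4f, %.4f]; counted as unassigned", rt, lo, hi)
            unassigned += area
            continue
        gu = float(cal.gu_at(rt))
        idx = int(np.searchsorted(edges, gu, side="right")) - 1
        if 0 <= idx < N_PEAKS:
            areas[idx] += area
        else:
            logger.warning("peak at rt=%.4f min (GU=%.4f) outside all windows; "
                           "counted as unassigned", rt, gu)
            unassigned += area
    return areas, unassigned


def close_to_percent(areas) -> np.ndarray:
    """Rescale a non-negative area vector to sum to 100."""
    arr = np.asarray(areas, dtype=float)
    if np.any(arr < 0):
        raise ValueError("areas must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot close an all-zero area vector")
    return 100.0 * arr / total


def integrate_trace(time, signal) -> PeakList:
    """Convenience valley-to-valley integrator for synthetic traces.

    Splits the trace at local minima and integrates each segment by the
    trapezoid rule; the peak retention time is the segment's maximum. Not a
    production peak picker -- fixtures only.
    """
    t = np.asarray(time, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.shape != s.shape or t.size < 3:
        raise ValueError("time and signal must be equal-length with >= 3 samples")
    interior = np.where((s[1:-1] <= s[:-2]) & (s[1:-1] <= s[2:]))[0] + 1
    bounds = np.concatenate([[0], interior, [t.size - 1]])
    peaks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1:
            continue
        seg_t, seg_s = t[a:b + 1], s[a:b + 1]
        area = float(np.trapezoid(seg_s, seg_t))
        if area > 0:
            peaks.append((float(seg_t[np.argmax(seg_s)]), area))
    return PeakList(peaks=tuple(peaks))


# ---------------------------------------------------------------------------
# CSV helpers

def read_peak_list(path) -> PeakList:
    df = pd.read_csv(path)
    return PeakList(peaks=tuple(zip(df["rt"].astype(float), df["area"].astype(float))))


def read_ladder(path) -> DextranLadder:
    df = pd.read_csv(path)
    return DextranLadder(points=tuple(zip(df["rt"].astype(float), df["gu"].astype(float))))


def read_windows(path) -> GUWindowTable:
    return GUWindowTable.from_frame(pd.read_csv(path))
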