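"""Trajectory statistics for oligotype time series.

Pairwise cross-correlation of abundance trajectories (Pearson, Spearman,
or Kendall) with two-sided significance from the Student-t transform

    t = r * sqrt((n - 2) / (1 - r^2)),  df = n - 2

and Bonferroni correction by a configurable test count (defaulting to the
square of the number of trajectories, the convention of correcting a full
correlation matrix).  Also: linear interpolation of unsampled days,
normalized autocorrelation over a +/-21-day window, Fourier periodograms,
and detection of dominance switches — days on which the most abundant
member of a group of close variants is replaced by another and the
newcomer holds its majority for a sustained run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

METHODS = ("pearson", "spearman", "kendall")


@dataclass
class CorrelationConfig:
    """Correlation method, Bonferroni multiplier, and the matrix basis.

    ``correction_n`` of None defaults to (number of trajectories)^2; the
    basis records whether counts or percent abundances were correlated
    (both are supported analyses).
    """

    method: str = "pearson"
    correction_n: int | None = None
    data_basis: str = "counts"  # "counts" | "percent"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.correction_n is not None and self.correction_n < 1:
            raise ValueError("correction_n must be >= 1")


def bonferroni_correct(p_raw: float | np.ndarray, correction_n: int) -> float | np.ndarray:
    """Multiply raw p by the test count, capping at 1."""
    if correction_n < 1:
        raise ValueError("correction_n must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p_raw must lie in [0, 1]")
    out = np.minimum(1.0, p * correction_n)
    return float(out) if np.isscalar(p_raw) else out


def _t_pvalue(r: float, n: int) -> float:
    if n <= 2:
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def cross_correlate(matrix: pd.DataFrame, config: CorrelationConfig) -> pd.DataFrame:
    """All unordered pairwise trajectory correlations with corrected p-values.

    ``matrix`` holds one trajectory per row (oligotypes × samples).  Rows
    with zero variance are flagged and excluded from testing.  Returns a
    table with columns id_a, id_b, method, n, r, p_raw, p_adj, flag.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 shared samples per pair")
    ids = list(matrix.index)
    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    constant = X.std(axis=1) == 0
    correction_n = config.correction_n or len(ids) ** 2

    with np.errstate(invalid="ignore", divide="ignore"):
        if config.method == "pearson":
            R = np.corrcoef(X)
        elif config.method == "spearman":
            ranks = np.apply_along_axis(stats.rankdata, 1, X)
            R = np.corrcoef(ranks)
        else:
            R = None  # kendall handled per pair

    rows = []
    for i, j in combinations(range(len(ids)), 2):
        if constant[i] or constant[j]:
            rows.append((ids[i], ids[j], config.method, n, np.nan, np.nan, np.nan, "constant"))
            continue
        if config.method == "kendall":
            r, p_raw = stats.kendalltau(X[i], X[j], variant="b", method="asymptotic")
            r, p_raw = float(r), float(p_raw)
        else:
            r = float(np.clip(R[i, j], -1.0, 1.0))
            p_raw = _t_pvalue(r, n)
        rows.append(
            (ids[i], ids[j], config.method, n, r, p_raw,
             bonferroni_correct(p_raw, correction_n), "ok")
        )
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "method", "n", "r", "p_raw", "p_adj", "flag"]
    )


def interpolate_missing_days(
    days: Sequence[int], values: Sequence[float], day_range: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fill unsampled days by linear interpolation between flanking observations.

    Returns (full daily grid, values); leading/trailing gaps hold the
    nearest observed value, observed days pass through unchanged.
    """
    days = np.asarray(days, dtype=int)
    values = np.asarray(values, dtype=float)
    if days.size != values.size:
        raise ValueError("days and values must align")
    if days.size < 2:
        raise ValueError("need at least 2 observed days to interpolate")
    order = np.argsort(days)
    days, values = days[order], values[order]
    if np.unique(days).size != days.size:
        raise ValueError("duplicate observation days")
    lo, hi = (int(days[0]), int(days[-1])) if day_range is None else day_range
    grid = np.arange(lo, hi + 1)
    return grid, np.interp(grid, days, values)


@dataclass
class AutocorrelationResult:
    lags: np.ndarray  # -W..W
    values: np.ndarray  # normalized, 1 at lag 0
    constant: bool = False


def autocorrelate(series: Sequence[float], window: int = 21) -> AutocorrelationResult:
    """Normalized autocorrelation of a daily series over lags -window..window.

    The series is mean-centered; the raw lagged sum is divided by the
    lag-0 value (biased estimator), so the result is 1 at lag 0 and
    symmetric in lag.  Constant series are flagged (values undefined).
    """
    x = np.asarray(series, dtype=float)
    if x.size <= window:
        raise ValueError("series must be longer than the window")
    lags = np.arange(-window, window + 1)
    if np.ptp(x) == 0.0:
        return AutocorrelationResult(lags, np.full(lags.shape, np.nan), constant=True)
    x = x - x.mean()
    c0 = float(np.dot(x, x))
    vals = np.empty(lags.shape)
    for idx, k in enumerate(lags):
        k = abs(int(k))
        vals[idx] = float(np.dot(x[: x.size - k], x[k:])) / c0
    return AutocorrelationResult(lags, vals)


@dataclass
class PeriodogramResult:
    frequencies: np.ndarray  # cycles/day, (0, 0.5]
    power: np.ndarray
    peak_frequency: float
    peak_power_fraction: float


def periodogram(series: Sequence[float]) -> PeriodogramResult:
    """Discrete-Fourier power spectrum of a daily series (mean removed).

    Reports frequencies in cycles/day up to the Nyquist limit 0.5 and the
    peak frequency with its fraction of total spectral power.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for a periodogram (need >= 8 points)")
    freqs, power = signal.periodogram(x, fs=1.0, detrend="constant")
    freqs, power = freqs[1:], power[1:]  # drop the zero-frequency bin
    total = power.sum()
    if total == 0.0:
        return PeriodogramResult(freqs, power, np.nan, 0.0)
    k = int(np.argmax(power))
    return PeriodogramResult(freqs, power, float(freqs[k]), float(power[k] / total))


@dataclass
class SwitchEvent:
    """A dominance replacement within a group of close variants."""

    group_id: str
    switch_day: int
    from_id: str
    to_id: str
    persistence: int


def detect_dominance_switch(
    shares: pd.DataFrame,
    group_id: str = "group",
    min_persistence: int = 14,
    dominance_threshold: float = 0.5,
) -> list[SwitchEvent]:
    """Detect replacements of the dominant oligotype within a variant group.

    ``shares`` holds daily (interpolated) abundances, one row per
    oligotype, columns ordered by day; they are renormalized to
    within-group shares.  An event fires when the most abundant oligotype
    changes and the newcomer's share stays above ``dominance_threshold``
    for at least ``min_persistence`` consecutive days; the switch day is
    the first day of that run.
    """
    if shares.shape[0] < 2:
        raise ValueError("need at least 2 oligotypes in the group")
    days = [int(c) for c in shares.columns]
    vals = shares.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, vals / totals, 0.0)

    # per-day dominant (None when nothing clears the threshold)
    dominant: list[str | None] = []
    ids = list(shares.index)
    for d in range(frac.shape[1]):
        top = int(np.argmax(frac[:, d]))
        dominant.append(ids[top] if frac[top, d] > dominance_threshold else None)

    # maximal runs of one dominant id
    runs: list[tuple[str, int, int]] = []  # (id, start index, length)
    for i, who in enumerate(dominant):
        if who is None:
            continue
        if runs and runs[-1][0] == who and runs[-1][1] + runs[-1][2] == i:
            runs[-1] = (who, runs[-1][1], runs[-1][2] + 1)
        else:
            runs.append((who, i, 1))

    events: list[SwitchEvent] = []
    established: str | None = None
    for who, start, length in runs:
        if length < min_persistence:
            continue
        if established is not None and who != established:
            events.append(
                SwitchEvent(group_id, days[start], established, who, length)
            )
        established = who
    return events
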