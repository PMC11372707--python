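"""The three trial-level outcomes: coefficient of variation, detrended
fluctuation analysis (DFA) scaling exponent, and sample entropy, plus the
robustness grid over neighboring entropy parameters.

Conventions
-----------
* CV uses the sample SD (n-1 denominator): ``100 * SD / mean``.
* DFA integrates the mean-centered series, splits the profile into
  non-overlapping forward windows of length m (remainder discarded), removes
  a per-window least-squares line, and takes F(m) as the *mean of the
  per-window RMS residuals*; the exponent is the OLS slope of
  log F(m) on log m. A pooled-RMS aggregation is available via
  ``aggregation="pooled"``.
* Sample entropy compares all ordered template pairs of length m and m+1
  drawn from the same N-m starting positions, self-matches excluded,
  with Euclidean distance by default (Chebyshev available) and radius r on
  the z-scaled series (so r is in units of the series SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    DegenerateFluctuationError,
    InvalidArgumentError,
    UndefinedCVError,
    UndefinedEntropyError,
)
from .preprocessing import AnalysisSeries, _as_series


@dataclass(frozen=True)
class DFAResult:
    window_sizes: Tuple[int, ...]
    fluctuation: Tuple[float, ...]
    alpha: float
    fit_r2: float
    n_windows_used: int

    def __post_init__(self):
        ws = np.asarray(self.window_sizes)
        if ws.size < 2 or np.any(np.diff(ws) <= 0) or np.any(ws < 4):
            raise InvalidArgumentError("window sizes must be strictly increasing, all >= 4")
        if np.any(np.asarray(self.fluctuation) < 0):
            raise InvalidArgumentError("fluctuations must be non-negative")
        if not np.isfinite(self.alpha):
            raise InvalidArgumentError("alpha must be finite")


@dataclass(frozen=True)
class SEnConfig:
    """Template length m, radius r (in SD units of the scaled series), norm."""

    m: int = 2
    r: float = 0.25
    norm: str = "euclidean"

    def __post_init__(self):
        if self.m < 1:
            raise InvalidArgumentError("m must be >= 1")
        if self.r <= 0:
            raise InvalidArgumentError("r must be positive")
        if self.norm not in ("euclidean", "chebyshev"):
            raise InvalidArgumentError(f"unknown norm {self.norm!r}")


@dataclass(frozen=True)
class ComplexityResult:
    """One analysis cell's (CV, DFA-alpha, SEn) with identifying keys.

    ``sen`` is None when entropy is undefined (no m+1 matches)."""

    cv: float
    dfa_alpha: float
    sen: Optional[float]
    participant_id: str = ""
    condition: str = ""
    hand: str = ""
    timepoint: int = 1
    group: Optional[str] = None
    sex: Optional[str] = None
    n_trials: int = 1
    dfa: Optional[DFAResult] = None
    match_count_m: Optional[int] = None
    match_count_m1: Optional[int] = None

    def __post_init__(self):
        if self.cv < 0:
            raise InvalidArgumentError("cv must be non-negative")
        if self.sen is not None and self.sen < 0:
            raise InvalidArgumentError("sen must be non-negative")
        cm, cm1 = self.match_count_m, self.match_count_m1
        if cm is not None and cm1 is not None and not (cm >= cm1 >= 0):
            raise InvalidArgumentError("match counts must satisfy Cm >= Cm+1 >= 0")

    def cell_key(self):
        return (self.participant_id, self.condition, self.hand, self.timepoint)


def coefficient_of_variation(series) -> float:
    """Percent coefficient of variation: 100 * sample SD / mean."""
    s = _as_series(series)
    mean = s.values.mean()
    if mean == 0:
        raise UndefinedCVError("series mean is zero; CV undefined")
    sd = s.values.std(ddof=1) if s.values.size > 1 else 0.0
    return float(100.0 * sd / mean)


def default_window_grid(min_m: int = 10, max_m: int = 200, count: int = 30) -> List[int]:
    """Exponentially spaced integer window sizes, duplicates removed."""
    if min_m < 4:
        raise InvalidArgumentError("min_m must be >= 4")
    if max_m <= min_m:
        raise InvalidArgumentError("max_m must exceed min_m")
    if count < 2:
        raise InvalidArgumentError("count must be >= 2")
    raw = np.exp(np.linspace(np.log(min_m), np.log(max_m), count))
    sizes = np.unique(np.round(raw).astype(int))
    return [int(v) for v in sizes]


def dfa_alpha(
    series,
    window_sizes: Optional[Sequence[int]] = None,
    aggregation: str = "mean_rms",
) -> DFAResult:
    """Detrended fluctuation analysis scaling exponent.

    Parameters
    ----------
    series : AnalysisSeries or array-like
    window_sizes : increasing ints, default :func:`default_window_grid`
    aggregation : "mean_rms" (mean of per-window RMS residuals) or
        "pooled" (RMS over all residuals pooled across windows).
    """
    if aggregation not in ("mean_rms", "pooled"):
        raise InvalidArgumentError(f"unknown aggregation {aggregation!r}")
    s = _as_series(series)
    x = s.values
    if window_sizes is None:
        window_sizes = default_window_grid()
    ws = np.asarray(list(window_sizes), dtype=int)
    if ws.size < 4:
        raise InvalidArgumentError("need at least 4 window sizes")
    if np.any(np.diff(ws) <= 0) or ws[0] < 4:
        raise InvalidArgumentError("window sizes must be strictly increasing, all >= 4")
    n = x.size
    if n < 2 * ws[-1]:
        raise InvalidArgumentError(
            f"series of length {n} too short for max window {ws[-1]} (need >= {2 * ws[-1]})"
        )

    profile = np.cumsum(x - x.mean())
    fluct = np.empty(ws.size)
    for i, m in enumerate(ws):
        k = n // m
        seg = profile[: k * m].reshape(k, m)
        t = np.arange(m, dtype=float)
        tc = t - t.mean()
        denom = tc @ tc
        slope = seg @ tc / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tc
        sq = (resid ** 2).mean(axis=1)
        if aggregation == "mean_rms":
            fluct[i] = np.sqrt(sq).mean()
        else:
            fluct[i] = np.sqrt(sq.mean())
    if np.any(fluct == 0):
        raise DegenerateFluctuationError("zero fluctuation at some window size")

    logm = np.log(ws)
    logf = np.log(fluct)
    slope, intercept = np.polyfit(logm, logf, 1)
    pred = slope * logm + intercept
    sst = ((logf - logf.mean()) ** 2).sum()
    r2 = 1.0 - ((logf - pred) ** 2).sum() / sst if sst > 0 else 1.0
    return DFAResult(
        window_sizes=tuple(int(v) for v in ws),
        fluctuation=tuple(float(v) for v in fluct),
        alpha=float(slope),
        fit_r2=float(r2),
        n_windows_used=int(ws.size),
    )


def _check_scaled(s: AnalysisSeries) -> np.ndarray:
    # plain arrays that are already numerically scaled are accepted too
    x = s.values
    if not s.scaled and (abs(x.mean()) > 1e-6 or abs(x.std(ddof=1) - 1.0) > 1e-6):
        raise InvalidArgumentError(
            "sample entropy requires a z-scaled series (mean 0, SD 1)"
        )
    return x


def sample_entropy(series, cfg: SEnConfig = SEnConfig()) -> Tuple[float, int, int]:
    """Sample entropy ``ln(Cm / Cm+1)`` with match counts.

    Both template lengths use the same N-m starting positions; self-matches
    are excluded; Cm and Cm+1 count *ordered* pairs.

    Returns ``(sen, Cm, Cm+1)``. Raises :class:`UndefinedEntropyError` when
    Cm+1 == 0 (entropy must be reported missing, never imputed as 0).
    """
    s = _as_series(series)
    x = _check_scaled(s)
    n = x.size
    if n <= cfg.m + 1:
        raise InvalidArgumentError(f"series of length {n} too short for m={cfg.m}")
    nt = n - cfg.m
    tm = np.lib.stride_tricks.sliding_window_view(x, cfg.m)[:nt]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, cfg.m + 1)[:nt]
    metric = "euclidean" if cfg.norm == "euclidean" else "chebyshev"
    cm = int((cdist(tm, tm, metric=metric) < cfg.r).sum()) - nt
    cm1 = int((cdist(tm1, tm1, metric=metric) < cfg.r).sum()) - nt
    if cm1 == 0:
        raise UndefinedEntropyError(
            f"no template matches at length m+1={cfg.m + 1}; entropy undefined"
        )
    return float(np.log(cm / cm1)), cm, cm1


ROBUSTNESS_M = (2, 3, 4)
ROBUSTNESS_R = (0.2, 0.25, 0.3)


def sen_robustness_grid(series, norm: str = "euclidean"):
    """Sample entropy over the m x r robustness grid.

    Returns a pandas DataFrame indexed by m with one column per r; cells
    where entropy is undefined hold NaN. Individual-cell failures never
    abort the rest of the grid.
    """
    import pandas as pd

    table = np.full((len(ROBUSTNESS_M), len(ROBUSTNESS_R)), np.nan)
    for i, m in enumerate(ROBUSTNESS_M):
        for j, r in enumerate(ROBUSTNESS_R):
            try:
                table[i, j] = sample_entropy(series, SEnConfig(m=m, r=r, norm=norm))[0]
            except UndefinedEntropyError:
                pass
    return pd.DataFrame(table, index=list(ROBUSTNESS_M), columns=list(ROBUSTNESS_R))
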