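"""Raw-trial preprocessing: ramp exclusion, MVC normalization, z-scaling,
and per-cell aggregation of computed measures.

All operations accept either a :class:`ForceTrial` or an
:class:`AnalysisSeries` where that makes sense, so they compose in any
order (ramp exclusion and unit normalization commute).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    EmptySeriesError,
    InvalidArgumentError,
    ZeroVarianceError,
)

HANDS = ("left", "right")
ROLES = ("stabilizing", "manipulating")
CONDITIONS = ("bimanual_constant", "role_differentiated")


@dataclass(frozen=True)
class ForceTrial:
    """One hand's sampled force for a single trial, in Newtons."""

    samples: np.ndarray
    rate_hz: float
    hand: str
    role: str
    condition: str
    participant_id: str
    timepoint: int
    mvc_n: float
    trial_index: int = 0
    group: Optional[str] = None
    sex: Optional[str] = None

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.rate_hz <= 0:
            raise InvalidArgumentError("rate_hz must be positive")
        if arr.size == 0:
            raise EmptySeriesError("trial has no samples")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("trial contains non-finite forces")
        if self.hand not in HANDS:
            raise InvalidArgumentError(f"unknown hand {self.hand!r}")
        if self.role not in ROLES:
            raise InvalidArgumentError(f"unknown role {self.role!r}")
        if self.condition not in CONDITIONS:
            raise InvalidArgumentError(f"unknown condition {self.condition!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass(frozen=True)
class AnalysisSeries:
    """A 1-D series ready for (or partway through) the measure pipeline.

    ``scaled`` is True only after :func:`zscale`; sample-entropy requires it.
    """

    values: np.ndarray
    rate_hz: float
    source: Optional[ForceTrial] = None
    scaled: bool = False
    units: str = "N"

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.size == 0:
            raise EmptySeriesError("empty analysis series")
        if self.scaled:
            if abs(arr.mean()) > 1e-9 or abs(arr.std(ddof=1) - 1.0) > 1e-9:
                raise InvalidArgumentError("scaled series must have mean 0 and SD 1")

    def __len__(self) -> int:
        return self.values.size


def _as_series(x) -> AnalysisSeries:
    if isinstance(x, AnalysisSeries):
        return x
    if isinstance(x, ForceTrial):
        return AnalysisSeries(values=x.samples, rate_hz=x.rate_hz, source=x)
    arr = np.asarray(x, dtype=float)
    return AnalysisSeries(values=arr, rate_hz=float("nan"))


def exclude_ramp(trial, ramp_s: float) -> AnalysisSeries:
    """Drop the initial ramp phase: samples before ``floor(ramp_s * rate_hz)``.

    The first retained sample is the one at t == ramp_s (half-open interval
    convention), so a 20 s trial at 120 Hz with a 6 s ramp keeps 1680 samples.
    """
    if ramp_s < 0:
        raise InvalidArgumentError("ramp_s must be non-negative")
    s = _as_series(trial)
    start = math.floor(ramp_s * s.rate_hz)
    if start >= s.values.size:
        raise EmptySeriesError(
            f"ramp exclusion of {ramp_s} s removes all {s.values.size} samples"
        )
    return replace(s, values=s.values[start:], scaled=False)


def normalize_to_mvc(trial, mvc_n: Optional[float] = None) -> AnalysisSeries:
    """Express forces as percent of maximum voluntary contraction."""
    s = _as_series(trial)
    if mvc_n is None:
        if s.source is None:
            raise InvalidArgumentError("mvc_n required when no source trial attached")
        mvc_n = s.source.mvc_n
    if mvc_n <= 0:
        raise InvalidArgumentError("mvc_n must be positive")
    return replace(s, values=100.0 * s.values / mvc_n, scaled=False, units="%MVC")


def zscale(series) -> AnalysisSeries:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    s = _as_series(series)
    sd = s.values.std(ddof=1) if s.values.size > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("cannot z-scale a constant series")
    vals = (s.values - s.values.mean()) / sd
    return replace(s, values=vals, scaled=True, units="sd")


def aggregate_cell(results: Sequence["ComplexityResult"]) -> "ComplexityResult":
    """Average trial-level measures into one value per analysis cell.

    All results must share (participant, condition, hand, timepoint); the
    aggregate is the unweighted arithmetic mean of each defined measure.
    Missing sample-entropy values are excluded from the entropy mean (the
    cell entropy stays missing only if every trial's entropy is missing).
    """
    from .measures import ComplexityResult  # local import: avoid cycle

    results = list(results)
    if not results:
        raise InvalidArgumentError("aggregate_cell requires a non-empty list")
    key = results[0].cell_key()
    for r in results[1:]:
        if r.cell_key() != key:
            raise InvalidArgumentError(
                f"mixed cell keys in aggregate_cell: {key} vs {r.cell_key()}"
            )
    if len(results) == 1:
        return results[0]
    cv = float(np.mean([r.cv for r in results]))
    alpha = float(np.mean([r.dfa_alpha for r in results]))
    sens = [r.sen for r in results if r.sen is not None]
    sen = float(np.mean(sens)) if sens else None
    first = results[0]
    return ComplexityResult(
        cv=cv,
        dfa_alpha=alpha,
        sen=sen,
        participant_id=first.participant_id,
        condition=first.condition,
        hand=first.hand,
        timepoint=first.timepoint,
        group=first.group,
        sex=first.sex,
        n_trials=sum(r.n_trials for r in results),
    )
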