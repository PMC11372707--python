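"""Synthetic benchmark noise, single bimanual trials, and full
cohort-sequential datasets.

Benchmark noise anchors the complexity measures (white noise has a DFA
exponent near 0.5, Brownian noise near 1.5); the power-law generator gives
analytic control over the target exponent via frequency-domain synthesis.
Cohorts mirror the study structure: two groups (CHI/MCI) classified by a
cognitive screening rule, up to 4 timepoints with monotone dropout, and
trial blocks per condition and stabilizing hand.

Cohort outcomes for parameter-recovery work are generated directly on the
measure scale (linear model with participant random intercepts); signal-level
trial synthesis is provided for end-to-end smoke tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import InvalidArgumentError
from .preprocessing import ForceTrial

GROUPS = ("CHI", "MCI")
SEXES = ("female", "male")

#: Participant counts per (group, timepoint) as configured by default.
DEFAULT_COHORT_COUNTS = {"CHI": (77, 52, 33, 11), "MCI": (55, 34, 15, 3)}

#: Default generative fixed effects on the CV (percent) scale. Treatment
#: coding: condition=1 for role_differentiated, group=1 for MCI, hand=1 for
#: right, sex=1 for female; timepoint enters as the numeric value 1-4.
DEFAULT_FIXED_EFFECTS = {
    "intercept": 4.33,
    "condition": 2.40,
    "group": 1.76,
    "hand": -0.36,
    "sex": 2.20,
    "timepoint": -0.10,
    "condition:group": -0.42,
    "condition:hand": 1.24,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of a single per-run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf8"))])
    )


@dataclass(frozen=True)
class NoiseSpec:
    kind: str
    n_samples: int
    seed: int
    target_alpha: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("white", "brownian", "power_law"):
            raise InvalidArgumentError(f"unknown noise kind {self.kind!r}")
        if self.n_samples < 16:
            raise InvalidArgumentError("n_samples must be >= 16")
        if self.kind == "power_law":
            if self.target_alpha is None:
                raise InvalidArgumentError("power_law noise requires target_alpha")
            if not (0.3 <= self.target_alpha <= 1.7):
                raise InvalidArgumentError("target_alpha must lie in [0.3, 1.7]")


def gen_noise(spec: NoiseSpec) -> np.ndarray:
    """Generate a benchmark noise series.

    white: i.i.d. standard Gaussian. brownian: cumulative sum of white.
    power_law: frequency-domain synthesis with amplitude ~ f^(-beta/2),
    beta = 2*target_alpha - 1, uniform random phases, unit-SD normalized;
    its DFA exponent approximates target_alpha.
    """
    # one stream for all kinds so brownian is exactly the cumsum of the
    # white draw with the same seed
    rng = substream(spec.seed, "noise")
    n = spec.n_samples
    if spec.kind == "white":
        return rng.standard_normal(n)
    if spec.kind == "brownian":
        return np.cumsum(rng.standard_normal(n))
    beta = 2.0 * spec.target_alpha - 1.0
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


@dataclass(frozen=True)
class TrialConfig:
    """Geometry and noise of one bimanual trial (targets in percent MVC)."""

    duration_s: float = 20.0
    ramp_s: float = 6.0
    rate_hz: float = 120.0
    mvc_n: float = 24.0
    constant_target_pct: float = 12.0
    sine_freq_hz: float = 0.2
    sine_lo_pct: float = 5.0
    sine_hi_pct: float = 12.0
    crosstalk_lambda: float = 0.0
    noise: Optional[NoiseSpec] = None
    noise_sd_pct: float = 0.5
    measurement_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= self.ramp_s:
            raise InvalidArgumentError("duration_s must exceed ramp_s")
        if self.rate_hz <= 2.0 * self.sine_freq_hz:
            raise InvalidArgumentError("rate_hz must exceed twice sine_freq_hz")
        if self.sine_lo_pct >= self.sine_hi_pct:
            raise InvalidArgumentError("sine_lo_pct must be below sine_hi_pct")
        if self.crosstalk_lambda < 0:
            raise InvalidArgumentError("crosstalk_lambda must be >= 0")
        if self.mvc_n <= 0:
            raise InvalidArgumentError("mvc_n must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


def gen_bimanual_trial(
    cfg: TrialConfig,
    stabilizing_hand: str = "left",
    participant_id: str = "sim",
    timepoint: int = 1,
    condition: str = "role_differentiated",
    trial_index: int = 0,
    group: Optional[str] = None,
    sex: Optional[str] = None,
) -> Tuple[ForceTrial, ForceTrial]:
    """Simulate one trial: (stabilizing-hand, manipulating-hand) force records.

    The stabilizing channel ramps linearly to the constant target over
    ``ramp_s`` then holds it, perturbed by scaled colored noise, additive
    crosstalk from the mean-centered manipulating oscillation, and white
    measurement noise. The manipulating channel ramps to the sine's start
    value then follows the sine between ``sine_lo_pct`` and ``sine_hi_pct``.
    Forces are stored in Newtons (percent of MVC times ``mvc_n``).
    """
    n = cfg.n_samples
    t = np.arange(n) / cfg.rate_hz
    post = t >= cfg.ramp_s

    mid = 0.5 * (cfg.sine_lo_pct + cfg.sine_hi_pct)
    amp = 0.5 * (cfg.sine_hi_pct - cfg.sine_lo_pct)
    sine = mid + amp * np.sin(2.0 * np.pi * cfg.sine_freq_hz * (t - cfg.ramp_s))
    manip = np.where(post, sine, mid * np.clip(t / cfg.ramp_s, 0.0, 1.0))

    stab = np.where(
        post,
        cfg.constant_target_pct,
        cfg.constant_target_pct * np.clip(t / cfg.ramp_s, 0.0, 1.0),
    )
    if cfg.noise_sd_pct > 0:
        spec = cfg.noise or NoiseSpec(kind="power_law", target_alpha=1.0,
                                      n_samples=n, seed=cfg.seed)
        if spec.n_samples != n:
            spec = replace(spec, n_samples=n)
        colored = gen_noise(spec)
        sd = colored.std(ddof=1)
        if sd > 0:
            colored = colored / sd
        stab = stab + cfg.noise_sd_pct * colored
    osc = np.where(post, sine - mid, 0.0)
    stab = stab + cfg.crosstalk_lambda * osc
    if cfg.measurement_noise_sd > 0:
        rng = substream(cfg.seed, "measurement")
        stab = stab + cfg.measurement_noise_sd * rng.standard_normal(n)

    manipulating_hand = "right" if stabilizing_hand == "left" else "left"
    common = dict(
        rate_hz=cfg.rate_hz,
        condition=condition,
        participant_id=participant_id,
        timepoint=timepoint,
        mvc_n=cfg.mvc_n,
        trial_index=trial_index,
        group=group,
        sex=sex,
    )
    stab_trial = ForceTrial(
        samples=stab * cfg.mvc_n / 100.0, hand=stabilizing_hand,
        role="stabilizing", **common)
    manip_trial = ForceTrial(
        samples=manip * cfg.mvc_n / 100.0, hand=manipulating_hand,
        role="manipulating", **common)
    return stab_trial, manip_trial


def classify_mci(moca: int, cerad_z: Sequence[float]) -> str:
    """Screening rule: MCI iff MoCA < 26 and at least one domain z < -1.5."""
    if not (0 <= moca <= 30):
        raise InvalidArgumentError("moca must lie in [0, 30]")
    cerad = np.asarray(list(cerad_z), dtype=float)
    if cerad.size != 9:
        raise InvalidArgumentError(f"expected 9 CERAD z-scores, got {cerad.size}")
    if moca < 26 and cerad.min() < -1.5:
        return "MCI"
    return "CHI"


@dataclass(frozen=True)
class SubjectProfile:
    id: str
    group: str
    sex: str
    age_y: float
    mvc_n: float
    moca: int
    cerad_z: Tuple[float, ...]
    random_intercept: float = 0.0

    def __post_init__(self):
        if self.mvc_n <= 0:
            raise InvalidArgumentError("mvc_n must be positive")
        if classify_mci(self.moca, self.cerad_z) != self.group:
            raise InvalidArgumentError(
                f"group {self.group} inconsistent with screening scores"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-sequential structure and the measure-scale generative model."""

    counts: Dict[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_COUNTS))
    timepoints: int = 4
    fixed_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    random_intercept_sd: float = 1.5
    residual_sd: float = 2.0
    trials_per_cell_constant: int = 2
    trials_per_cell_rd: int = 8
    trial: TrialConfig = field(default_factory=TrialConfig)
    seed: int = 0

    def __post_init__(self):
        for g, row in self.counts.items():
            if g not in GROUPS:
                raise InvalidArgumentError(f"unknown group {g!r}")
            if len(row) != self.timepoints:
                raise InvalidArgumentError(
                    f"counts for {g} must have {self.timepoints} entries")
            if any(c < 0 for c in row):
                raise InvalidArgumentError("counts must be non-negative")
        for term, beta in self.fixed_effects.items():
            if not np.isfinite(beta):
                raise InvalidArgumentError(f"beta for {term!r} is not finite")
        if min(self.random_intercept_sd, self.residual_sd) < 0:
            raise InvalidArgumentError("variance components must be >= 0")
        if min(self.trials_per_cell_constant, self.trials_per_cell_rd) < 0:
            raise InvalidArgumentError("trial counts must be >= 0")


def _draw_subject(rng: np.random.Generator, group: str, sid: str,
                  intercept_sd: float) -> SubjectProfile:
    """Rejection-sample screening scores consistent with the target group."""
    sex = "female" if rng.random() < (0.55 if group == "CHI" else 0.46) else "male"
    age = float(np.clip(rng.normal(82.4, 2.5), 80.0, 95.0))
    mvc = float(np.clip(rng.normal(23.9 if group == "CHI" else 22.1, 8.0), 5.0, 60.0))
    for _ in range(10_000):
        if group == "CHI":
            moca = int(np.clip(round(rng.normal(27.7, 1.2)), 0, 30))
            cerad = rng.normal(0.0, 1.0, 9)
        else:
            moca = int(np.clip(round(rng.normal(22.6, 1.8)), 0, 30))
            cerad = rng.normal(-0.5, 1.0, 9)
        if classify_mci(moca, cerad) == group:
            break
    else:  # pragma: no cover - acceptance probability is far from 0
        raise RuntimeError("rejection sampling failed to produce a valid subject")
    return SubjectProfile(
        id=sid, group=group, sex=sex, age_y=age, mvc_n=mvc, moca=moca,
        cerad_z=tuple(float(v) for v in cerad),
        random_intercept=float(rng.normal(0.0, intercept_sd)),
    )


def gen_subjects(cfg: CohortConfig) -> List[SubjectProfile]:
    """Draw the subject roster implied by the timepoint-1 counts."""
    rng = substream(cfg.seed, "cohort:subjects")
    subjects = []
    for group in GROUPS:
        if group not in cfg.counts:
            continue
        n1 = cfg.counts[group][0]
        for i in range(n1):
            subjects.append(_draw_subject(
                rng, group, f"{group}{i + 1:03d}", cfg.random_intercept_sd))
    return subjects


def subject_timepoints(cfg: CohortConfig, index_in_group: int, group: str) -> List[int]:
    """Timepoints attended: the first n_t subjects of a group attend t.

    This monotone-dropout rule reproduces the configured per-timepoint
    counts exactly (counts are non-increasing in the default pattern)."""
    return [
        t + 1
        for t in range(cfg.timepoints)
        if index_in_group < cfg.counts[group][t]
    ]


def _code_row(condition: str, group: str, hand: str, sex: str, timepoint: int
              ) -> Dict[str, float]:
    codes = {
        "condition": 1.0 if condition == "role_differentiated" else 0.0,
        "group": 1.0 if group == "MCI" else 0.0,
        "hand": 1.0 if hand == "right" else 0.0,
        "sex": 1.0 if sex == "female" else 0.0,
        "timepoint": float(timepoint),
    }
    return codes


def linear_predictor(fixed_effects: Dict[str, float], condition: str, group: str,
                     hand: str, sex: str, timepoint: int) -> float:
    """Evaluate the generative fixed-effect model for one design cell."""
    codes = _code_row(condition, group, hand, sex, timepoint)
    total = 0.0
    for term, beta in fixed_effects.items():
        if term == "intercept":
            total += beta
            continue
        prod = 1.0
        for part in term.split(":"):
            if part not in codes:
                raise InvalidArgumentError(f"unknown model term component {part!r}")
            prod *= codes[part]
        total += beta * prod
    return total


def gen_observation_table(cfg: CohortConfig, outcome: str = "cv"):
    """Measure-scale outcomes for every subject x timepoint x condition x hand.

    outcome = sum of fixed effects + subject random intercept + N(0, residual)
    noise; returns a long-format pandas DataFrame ready for model fitting.
    """
    import pandas as pd

    subjects = gen_subjects(cfg)
    rng = substream(cfg.seed, "cohort:residuals")
    counters: Dict[str, int] = {g: 0 for g in GROUPS}
    rows = []
    for subj in subjects:
        idx = counters[subj.group]
        counters[subj.group] += 1
        for t in subject_timepoints(cfg, idx, subj.group):
            for condition in ("bimanual_constant", "role_differentiated"):
                for hand in ("left", "right"):
                    mu = linear_predictor(cfg.fixed_effects, condition,
                                          subj.group, hand, subj.sex, t)
                    value = mu + subj.random_intercept + rng.normal(0.0, cfg.residual_sd)
                    rows.append(dict(
                        participant_id=subj.id, outcome=outcome, value=value,
                        condition=condition, group=subj.group, hand=hand,
                        sex=subj.sex, timepoint=t))
    return pd.DataFrame(rows)


def gen_cohort(cfg: CohortConfig) -> Tuple[List[SubjectProfile], List[ForceTrial]]:
    """Signal-level cohort: subjects plus every trial's force records.

    Per subject and attended timepoint: ``trials_per_cell_constant`` trials
    in the bimanual-constant condition (both hands stabilize, so each trial
    yields two stabilizing records) and ``trials_per_cell_rd`` trials per
    stabilizing-hand assignment in the role-differentiated condition. The
    colored-noise amplitude of the stabilizing channel is set from the CV
    linear predictor so measured CVs track the configured fixed effects.
    """
    subjects = gen_subjects(cfg)
    seed_rng = substream(cfg.seed, "cohort:trial-seeds")
    trials: List[ForceTrial] = []
    counters: Dict[str, int] = {g: 0 for g in GROUPS}
    for subj in subjects:
        idx = counters[subj.group]
        counters[subj.group] += 1
        for t in subject_timepoints(cfg, idx, subj.group):
            for condition, hands, n_trials in (
                ("bimanual_constant", ("left", "right"), cfg.trials_per_cell_constant),
                ("role_differentiated", ("left",), cfg.trials_per_cell_rd),
                ("role_differentiated", ("right",), cfg.trials_per_cell_rd),
            ):
                for k in range(n_trials):
                    tseed = int(seed_rng.integers(0, 2 ** 31 - 1))
                    for hand in hands:
                        mu = linear_predictor(cfg.fixed_effects, condition,
                                              subj.group, hand, subj.sex, t)
                        mu = max(mu + subj.random_intercept, 0.2)
                        tcfg = replace(
                            cfg.trial,
                            mvc_n=subj.mvc_n,
                            # CV ~ 100 * noise SD / target level
                            noise_sd_pct=mu * cfg.trial.constant_target_pct / 100.0,
                            # constant task: both hands stabilize, no oscillation
                            crosstalk_lambda=(cfg.trial.crosstalk_lambda
                                              if condition == "role_differentiated"
                                              else 0.0),
                            seed=tseed + (1 if hand == "right" else 0),
                        )
                        stab, manip = gen_bimanual_trial(
                            tcfg, stabilizing_hand=hand,
                            participant_id=subj.id, timepoint=t,
                            condition=condition, trial_index=k,
                            group=subj.group, sex=subj.sex)
                        trials.append(stab)
                        if condition == "role_differentiated":
                            trials.append(manip)
    return subjects, trials
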