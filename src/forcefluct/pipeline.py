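"""Pipeline orchestration: simulate -> measure -> infer, with a JSON run
manifest recording config, seed, per-stage row counts and warnings."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .exceptions import EmptySeriesError, ForceFluctError, InvalidArgumentError, UndefinedEntropyError
from .inference import OUTCOMES, stepwise_analysis, validate_observation_table
from .measures import (
    ComplexityResult,
    SEnConfig,
    coefficient_of_variation,
    default_window_grid,
    dfa_alpha,
    sample_entropy,
)
from .preprocessing import aggregate_cell, exclude_ramp, normalize_to_mvc, zscale
from .synthetic import CohortConfig, TrialConfig, gen_cohort

log = logging.getLogger("forcefluct")

STAGES = ("simulate", "measure", "infer")


@dataclass
class PipelineConfig:
    stages: tuple = STAGES
    out_dir: str = "forcefluct_out"
    trials_csv: Optional[str] = None    # input for measure when not simulating
    measures_csv: Optional[str] = None  # input for infer when not measuring
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sen: SEnConfig = field(default_factory=SEnConfig)
    ramp_s: float = 6.0
    dfa_min_m: int = 10
    dfa_max_m: int = 200
    dfa_count: int = 30
    aggregate_trials: bool = True  # mean per cell vs trial-level passthrough
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for st in self.stages:
            if st not in STAGES:
                raise InvalidArgumentError(f"unknown stage {st!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    config_sha: str
    stages_run: List[str] = field(default_factory=list)
    row_counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    failed_stage: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def measure_trials(df: pd.DataFrame, cfg: PipelineConfig,
                   warnings_out: Optional[List[str]] = None) -> pd.DataFrame:
    """Compute CV, DFA-alpha and SEn for every stabilizing-hand trial and
    aggregate per participant x condition x hand x timepoint cell.

    The ramp phase is excluded first and forces are normalized to percent
    MVC; entropy is computed on the z-scaled series. Cells whose entropy is
    undefined are reported with a missing ``sen`` and a warning.
    """
    if df.empty:
        raise InvalidArgumentError("no trial rows to measure")
    grid = default_window_grid(cfg.dfa_min_m, cfg.dfa_max_m, cfg.dfa_count)
    trials = io.frame_to_trials(df)
    cells: Dict[tuple, List[ComplexityResult]] = {}
    for tr in trials:
        if tr.role != "stabilizing":
            continue
        series = exclude_ramp(normalize_to_mvc(tr), cfg.ramp_s)
        cv = coefficient_of_variation(series)
        alpha = dfa_alpha(series, grid).alpha
        sen_val = cm = cm1 = None
        try:
            sen_val, cm, cm1 = sample_entropy(zscale(series), cfg.sen)
        except (UndefinedEntropyError, ForceFluctError) as exc:
            msg = (f"undefined SEn for {tr.participant_id} t{tr.timepoint} "
                   f"{tr.condition}/{tr.hand} trial {tr.trial_index}: {exc}")
            log.warning(msg)
            if warnings_out is not None:
                warnings_out.append(msg)
        res = ComplexityResult(
            cv=cv, dfa_alpha=alpha, sen=sen_val,
            participant_id=tr.participant_id, condition=tr.condition,
            hand=tr.hand, timepoint=tr.timepoint, group=tr.group, sex=tr.sex,
            match_count_m=cm, match_count_m1=cm1)
        cells.setdefault(res.cell_key(), []).append(res)

    rows = []
    for key in sorted(cells):
        group_results = cells[key]
        if cfg.aggregate_trials:
            group_results = [aggregate_cell(group_results)]
        for res in group_results:
            rows.append(dict(
                participant_id=res.participant_id, timepoint=res.timepoint,
                condition=res.condition, hand=res.hand, group=res.group,
                sex=res.sex, cv=res.cv, dfa_alpha=res.dfa_alpha,
                sen=np.nan if res.sen is None else res.sen,
                n_trials=res.n_trials,
                match_count_m=res.match_count_m, match_count_m1=res.match_count_m1))
    return pd.DataFrame(rows)


def measures_to_observations(measures: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Reshape the per-cell measure table into one observation table per
    outcome (cv, dfa_alpha, sen)."""
    if measures.empty:
        raise InvalidArgumentError("measure table is empty")
    out = {}
    for outcome in OUTCOMES:
        sub = measures[["participant_id", "timepoint", "condition", "hand",
                        "group", "sex", outcome]].copy()
        sub = sub.rename(columns={outcome: "value"})
        sub["outcome"] = outcome
        sub = sub.dropna(subset=["value"])
        if not sub.empty:
            out[outcome] = validate_observation_table(sub)
    return out


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the requested stages in order and write all artifacts.

    Outputs under ``cfg.out_dir``: trials.csv + subjects.csv (simulate),
    measures.csv (measure), contrasts_<outcome>.csv + model_trace.json
    (infer), and manifest.json always. Deterministic for a fixed seed."""
    logging.basicConfig(level=cfg.log_level)
    hashed = cfg.to_dict()
    for key in ("out_dir", "trials_csv", "measures_csv", "log_level"):
        hashed.pop(key, None)  # paths must not affect scientific identity
    cfg_hash = io.config_hash(hashed)
    manifest = RunManifest(config=cfg.to_dict(), version=__version__,
                           seed=cfg.seed, config_sha=cfg_hash)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        trials_df = None
        measures_df = None
        if "simulate" in cfg.stages:
            manifest.failed_stage = "simulate"
            cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
            subjects, trials = gen_cohort(cohort)
            trials_df = io.trials_to_frame(trials)
            io.write_csv(trials_df, out / "trials.csv", seed=cfg.seed,
                         cfg_hash=cfg_hash)
            io.write_csv(io.subjects_to_frame(subjects), out / "subjects.csv",
                         seed=cfg.seed, cfg_hash=cfg_hash)
            manifest.stages_run.append("simulate")
            manifest.row_counts["trials"] = len(trials_df)
            manifest.row_counts["subjects"] = len(subjects)
            log.info("simulate: %d subjects, %d trial rows",
                     len(subjects), len(trials_df))
        if "measure" in cfg.stages:
            manifest.failed_stage = "measure"
            if trials_df is None:
                if not cfg.trials_csv:
                    raise InvalidArgumentError(
                        "measure stage needs trials_csv when not simulating")
                trials_df = io.read_csv(cfg.trials_csv)
            measures_df = measure_trials(trials_df, cfg, manifest.warnings)
            io.write_csv(measures_df, out / "measures.csv", seed=cfg.seed,
                         cfg_hash=cfg_hash)
            manifest.stages_run.append("measure")
            manifest.row_counts["measures"] = len(measures_df)
            log.info("measure: %d cells", len(measures_df))
        if "infer" in cfg.stages:
            manifest.failed_stage = "infer"
            if measures_df is None:
                if not cfg.measures_csv:
                    raise InvalidArgumentError(
                        "infer stage needs measures_csv when not measuring")
                measures_df = io.read_csv(cfg.measures_csv)
            if measures_df.empty:
                raise InvalidArgumentError("infer received an empty measures table")
            obs = measures_to_observations(measures_df)
            trace_all = {}
            for outcome, table in obs.items():
                result = stepwise_analysis(table)
                io.write_csv(result["contrasts"],
                             out / f"contrasts_{outcome}.csv",
                             seed=cfg.seed, cfg_hash=cfg_hash)
                trace_all[outcome] = dict(trace=result["trace"],
                                          best_index=result["best_index"])
                manifest.row_counts[f"contrasts_{outcome}"] = len(result["contrasts"])
            io.write_json(trace_all, out / "model_trace.json")
            manifest.stages_run.append("infer")
            log.info("infer: outcomes %s", sorted(obs))
        manifest.failed_stage = None
    finally:
        io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def make_fixtures(out_dir) -> Dict[str, Path]:
    """Write small deterministic test inputs with precomputed oracle outputs.

    Contents: a 64-sample DFA fixture with its step-by-step fluctuation
    values, the alternating +1/-1 entropy fixture, and a 6-subject
    mini-cohort trial table. Repeated calls overwrite deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rng = np.random.default_rng(20240624)
    series = rng.standard_normal(64)
    windows = [4, 8, 16, 32]
    res = dfa_alpha(series, windows)
    fx = pd.DataFrame({"value": series})
    io.write_csv(fx, out / "dfa_fixture_series.csv", seed=20240624)
    io.write_json(dict(window_sizes=list(res.window_sizes),
                       fluctuation=list(res.fluctuation),
                       alpha=res.alpha), out / "dfa_fixture_oracle.json")
    paths["dfa_series"] = out / "dfa_fixture_series.csv"
    paths["dfa_oracle"] = out / "dfa_fixture_oracle.json"

    alt = np.tile([1.0, -1.0], 50)
    io.write_csv(pd.DataFrame({"value": alt}), out / "alternating_series.csv")
    zalt = zscale(alt)
    sen_val, cm, cm1 = sample_entropy(zalt, SEnConfig())
    io.write_json(dict(sen=sen_val, cm=cm, cm1=cm1),
                  out / "alternating_oracle.json")
    paths["alternating"] = out / "alternating_series.csv"

    mini = CohortConfig(
        counts={"CHI": (3, 2, 0, 0), "MCI": (3, 2, 0, 0)}, timepoints=4,
        trials_per_cell_constant=1, trials_per_cell_rd=1,
        trial=TrialConfig(duration_s=10.0, ramp_s=2.0, rate_hz=60.0),
        seed=7)
    _, trials = gen_cohort(mini)
    io.write_csv(io.trials_to_frame(trials), out / "mini_cohort_trials.csv",
                 seed=7)
    paths["mini_cohort"] = out / "mini_cohort_trials.csv"
    return paths
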