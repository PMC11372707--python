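"""Linear mixed-effects inference: participant random intercepts, stepwise
model sequence with AIC selection and likelihood-ratio tests, and contrast
tables with the sqrt(t^2/(t^2+df)) effect-size convention.

Contrast coding is treatment (dummy) coding with reference levels
bimanual_constant, CHI, left, male; timepoint enters as a numeric covariate
1-4. Denominator degrees of freedom follow a containment rule stratified by
whether a term varies within or only between participants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConvergenceError,
    InvalidArgumentError,
    NestingViolationError,
    RankDeficiencyError,
)

FACTORS = ("condition", "group", "hand", "sex", "timepoint")

#: treatment coding; the non-reference level of each factor
_CODES = {
    "condition": ("bimanual_constant", "role_differentiated"),
    "group": ("CHI", "MCI"),
    "hand": ("left", "right"),
    "sex": ("male", "female"),
}

_TERM_LABELS = {
    "condition": "Condition (RD-BC)",
    "group": "Group (MCI-CHI)",
    "hand": "Hand (right-left)",
    "sex": "Sex (female-male)",
    "timepoint": "Timepoint",
}

OUTCOMES = ("cv", "dfa_alpha", "sen")


def validate_observation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format observation table contract."""
    required = {"participant_id", "outcome", "value", "condition", "group",
                "hand", "sex", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"observation table missing columns {sorted(missing)}")
    if df.empty:
        raise InvalidArgumentError("observation table is empty")
    if df["value"].isna().all():
        raise InvalidArgumentError("observation table has no defined outcome values")
    bad_tp = set(df["timepoint"].unique()) - {1, 2, 3, 4}
    if bad_tp:
        raise InvalidArgumentError(f"timepoints outside 1-4: {sorted(bad_tp)}")
    for factor, (ref, alt) in _CODES.items():
        bad = set(df[factor].unique()) - {ref, alt}
        if bad:
            raise InvalidArgumentError(f"unknown levels for {factor}: {sorted(bad)}")
    return df


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of fixed-effect terms plus a participant intercept.

    Terms are main-effect names or colon-joined interactions
    (e.g. ``"condition:group"``). Hierarchy is enforced: an interaction may
    appear only when all its parents do.
    """

    fixed_terms: Tuple[str, ...] = ()
    reml: bool = False

    def __post_init__(self):
        seen = set()
        for term in self.fixed_terms:
            parts = term.split(":")
            for part in parts:
                if part not in FACTORS:
                    raise InvalidArgumentError(f"unknown factor {part!r} in {term!r}")
            if len(parts) > 1:
                for parent in parts:
                    if parent not in seen:
                        raise InvalidArgumentError(
                            f"interaction {term!r} lacks parent {parent!r}")
            if term in seen:
                raise InvalidArgumentError(f"duplicate term {term!r}")
            seen.add(term)

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.fixed_terms)  # + intercept

    def label(self) -> str:
        return "1" if not self.fixed_terms else "1 + " + " + ".join(self.fixed_terms)


def build_model_sequence(factors: Sequence[str] = FACTORS,
                         four_way: bool = False) -> List[ModelSpec]:
    """Stepwise model sequence: intercept-only, main effects added one at a
    time in fixed order, then all 2-way interactions, then the
    condition x group x timepoint interaction, then the 3-way interactions
    among condition, group, hand, sex (the full 4-way product only when
    ``four_way`` is set)."""
    factors = tuple(factors)
    for f in factors:
        if f not in FACTORS:
            raise InvalidArgumentError(f"unknown factor {f!r}")
    if tuple(sorted(factors)) != tuple(sorted(FACTORS)):
        raise InvalidArgumentError(f"expected factors {FACTORS}, got {factors}")

    specs = [ModelSpec(fixed_terms=())]
    terms: List[str] = []
    for f in FACTORS:
        terms = terms + [f]
        specs.append(ModelSpec(fixed_terms=tuple(terms)))
    two_way = [":".join(c) for c in itertools.combinations(FACTORS, 2)]
    terms = terms + two_way
    specs.append(ModelSpec(fixed_terms=tuple(terms)))
    terms = terms + ["condition:group:timepoint"]
    specs.append(ModelSpec(fixed_terms=tuple(terms)))
    quad = ("condition", "group", "hand", "sex")
    terms = terms + [":".join(c) for c in itertools.combinations(quad, 3)]
    specs.append(ModelSpec(fixed_terms=tuple(terms)))
    if four_way:
        terms = terms + [":".join(quad)]
        specs.append(ModelSpec(fixed_terms=tuple(terms)))
    return specs


def _coded_columns(df: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for factor, (ref, alt) in _CODES.items():
        cols[factor] = (df[factor] == alt).astype(float)
    cols["timepoint"] = df["timepoint"].astype(float)
    return pd.DataFrame(cols, index=df.index)


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Fixed-effects design matrix under treatment coding."""
    coded = _coded_columns(df)
    out = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for term in spec.fixed_terms:
        col = np.ones(len(df))
        for part in term.split(":"):
            col = col * coded[part].to_numpy()
        out[term] = col
    return out


@dataclass(frozen=True)
class ContrastRow:
    term: str
    beta: float
    se: float
    df: int
    t: float
    p: float
    r: float

    def __post_init__(self):
        expected = effect_size_r(self.t, self.df)
        if abs(self.r - expected) > 1e-9:
            raise InvalidArgumentError("r inconsistent with sqrt(t^2/(t^2+df))")


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    log_likelihood: float
    aic: float
    n_params: int
    coefficients: pd.DataFrame  # term, beta, se, df, t, p
    intercept_sd: float
    residual_sd: float
    n_obs: int
    n_participants: int
    converged: bool = True
    method: str = "ML"


def _containment_df(df: pd.DataFrame, X: pd.DataFrame) -> Dict[str, int]:
    """Denominator df per term: between-participant terms get
    n_participants - q_between; within-participant terms get
    n_obs - n_participants - q_within."""
    groups = df["participant_id"].to_numpy()
    n_obs = len(df)
    n_subj = len(np.unique(groups))
    between_terms, within_terms = [], []
    gdf = X.copy()
    gdf["_g"] = groups
    nunique = gdf.groupby("_g").nunique()
    for term in X.columns:
        if (nunique[term] <= 1).all():
            between_terms.append(term)
        else:
            within_terms.append(term)
    df_between = max(n_subj - len(between_terms), 1)
    df_within = max(n_obs - n_subj - len(within_terms), 1)
    return {t: (df_between if t in between_terms else df_within)
            for t in X.columns}


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the linear mixed model with a participant random intercept.

    ``spec.reml`` selects REML (coefficient tables) vs ML (model comparison).
    AIC is ``2k - 2 logLik`` with k = fixed effects + 2 variance components.
    """
    import statsmodels.api as sm

    df = validate_observation_table(data).dropna(subset=["value"]).copy()
    counts = df.groupby("participant_id").size()
    if (counts >= 2).sum() < 2:
        raise InvalidArgumentError(
            "need at least 2 participants with at least 2 observations")
    X = design_matrix(df, spec)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # greedy left-to-right scan: a column is aliased if it adds no rank
        aliased, r_prev = [], 0
        arr = X.to_numpy()
        for j in range(arr.shape[1]):
            r_now = np.linalg.matrix_rank(arr[:, : j + 1])
            if r_now == r_prev:
                aliased.append(X.columns[j])
            r_prev = r_now
        raise RankDeficiencyError(aliased)

    y = df["value"].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    n_subj = len(np.unique(groups))
    k = X.shape[1] + 2

    if np.var(y) < 1e-24:
        # degenerate constant response: closed form, avoids optimizer trouble
        beta = np.zeros(X.shape[1])
        beta[0] = y[0]
        coef = _coef_table(df, X, beta, np.full(X.shape[1], np.nan))
        return FitResult(spec=spec, log_likelihood=np.inf, aic=-np.inf,
                         n_params=k, coefficients=coef, intercept_sd=0.0,
                         residual_sd=0.0, n_obs=len(df), n_participants=n_subj,
                         method="REML" if spec.reml else "ML")

    model = sm.MixedLM(y, X, groups=groups)
    res = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "nm", "cg"):
            kwargs = {} if method is None else {"method": method}
            try:
                candidate = model.fit(reml=spec.reml, **kwargs)
            except Exception as exc:  # noqa: BLE001 - try the next optimizer
                last_exc = exc
                continue
            if candidate.converged:
                res = candidate
                break
    if res is None:
        raise ConvergenceError(f"mixed-model fit failed: {last_exc}")

    se = np.asarray(res.bse_fe)
    coef = _coef_table(df, X, np.asarray(res.fe_params), se)
    llf = float(res.llf)
    return FitResult(
        spec=spec,
        log_likelihood=llf,
        aic=2.0 * k - 2.0 * llf,
        n_params=k,
        coefficients=coef,
        intercept_sd=float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0))),
        residual_sd=float(np.sqrt(max(res.scale, 0.0))),
        n_obs=len(df),
        n_participants=n_subj,
        method="REML" if spec.reml else "ML",
    )


def _coef_table(df, X, beta, se) -> pd.DataFrame:
    ddf = _containment_df(df, X)
    rows = []
    for j, term in enumerate(X.columns):
        d = ddf[term]
        if np.isfinite(se[j]) and se[j] > 0:
            t = beta[j] / se[j]
            p = 2.0 * stats.t.sf(abs(t), d)
        else:
            t, p = np.nan, np.nan
        rows.append(dict(term=term, beta=float(beta[j]),
                         se=float(se[j]) if np.isfinite(se[j]) else np.nan,
                         df=int(d), t=float(t), p=float(p)))
    return pd.DataFrame(rows)


def select_best_model(fits: Sequence[FitResult]) -> int:
    """Index of the fit with the lowest AIC; ties go to the smaller model."""
    fits = list(fits)
    if not fits:
        raise InvalidArgumentError("select_best_model requires at least one fit")
    best = 0
    for i, fit in enumerate(fits[1:], start=1):
        if fit.aic < fits[best].aic - 1e-12:
            best = i
        elif abs(fit.aic - fits[best].aic) <= 1e-12:
            if fit.n_params < fits[best].n_params:
                best = i
    return best


def likelihood_ratio_test(reduced: FitResult, full: FitResult,
                          df_diff: int) -> Tuple[float, float]:
    """LR = 2 (logLik_full - logLik_reduced); p from chi-square(df_diff)."""
    if df_diff <= 0:
        raise InvalidArgumentError("df_diff must be a positive integer")
    lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if lr < -1e-6:
        raise NestingViolationError(
            f"full model log-likelihood below reduced ({full.log_likelihood} "
            f"< {reduced.log_likelihood}); models not nested or fit failed")
    lr = max(lr, 0.0)
    return lr, float(stats.chi2.sf(lr, df_diff))


def effect_size_r(t: float, df: float) -> float:
    """r = sqrt(t^2 / (t^2 + df)); sign of t is discarded."""
    if df <= 0:
        raise InvalidArgumentError("df must be positive")
    if not np.isfinite(t):
        raise InvalidArgumentError("t must be finite")
    return float(np.sqrt(t * t / (t * t + df)))


def summarize_contrasts(fit: FitResult) -> List[ContrastRow]:
    """One row per fixed-effect term with beta, SE, df, t, p, and r."""
    rows = []
    for _, rec in fit.coefficients.iterrows():
        t = rec["t"]
        r = effect_size_r(t, rec["df"]) if np.isfinite(t) else np.nan
        rows.append(ContrastRow(
            term=_label(rec["term"]), beta=rec["beta"], se=rec["se"],
            df=int(rec["df"]), t=float(t), p=float(rec["p"]),
            r=float(r)))
    return rows


def _label(term: str) -> str:
    if term == "Intercept":
        return "Intercept"
    return " x ".join(_TERM_LABELS.get(p, p) for p in term.split(":"))


def contrasts_frame(fit: FitResult) -> pd.DataFrame:
    rows = summarize_contrasts(fit)
    return pd.DataFrame(
        [dict(term=r.term, beta=r.beta, se=r.se, df=r.df, t=r.t, p=r.p, r=r.r)
         for r in rows])


def stepwise_analysis(data: pd.DataFrame, four_way: bool = False) -> dict:
    """Full inference pass for one outcome's observation table.

    Fits the stepwise sequence by ML, selects the lowest-AIC model, refits it
    by REML for the coefficient table, and records a per-step trace with
    log-likelihood, AIC and the LRT against the previous step.
    """
    specs = build_model_sequence(four_way=four_way)
    trace, fits, fitted_specs = [], [], []
    for i, spec in enumerate(specs):
        entry = dict(step=i, terms=list(spec.fixed_terms))
        try:
            fit = fit_mixed_model(data, spec)
        except (RankDeficiencyError, ConvergenceError) as exc:
            # small or unlucky cohorts can confound factors at later steps
            entry["skipped"] = str(exc)
            trace.append(entry)
            continue
        fits.append(fit)
        fitted_specs.append(spec)
        entry.update(log_likelihood=fit.log_likelihood, aic=fit.aic,
                     n_params=fit.n_params)
        if len(fits) > 1:
            df_diff = fit.n_params - fits[-2].n_params
            if df_diff > 0:
                lr, p = likelihood_ratio_test(fits[-2], fit, df_diff)
                entry["lr"] = lr
                entry["lr_p"] = p
        trace.append(entry)
    if not fits:
        raise InvalidArgumentError("no model in the sequence could be fit")
    best = select_best_model(fits)
    try:
        best_fit = fit_mixed_model(
            data, ModelSpec(fixed_terms=fitted_specs[best].fixed_terms, reml=True))
    except ConvergenceError:
        # REML can stall on tiny cohorts; the ML table is still valid
        best_fit = fits[best]
    return dict(trace=trace, best_index=best, best_fit=best_fit,
                contrasts=contrasts_frame(best_fit))
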