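"""Antibiotic-exposure summaries, AIC-based exposure screening, and the
stepwise multivariate pubertal-timing model.

Exposure candidates form a fixed grid: drug class x {cumulative DDD to ages
2, 5, 10; lifetime DDD; lifetime course count; time since last course}.
Never-exposed participants enter time-since-last candidates as a capped
value (their sampling age) plus a never-exposed indicator, so they are not
dropped. Post-selection p-values are optimistic and flagged as such in the
trace, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tables_io import AntibioticRecord, DRUG_CLASSES

DEFAULT_WINDOWS = (2.0, 5.0, 10.0)

SELECTION_CAVEAT = "p-values are post-selection and therefore optimistic"


@dataclass
class ExposureProfile:
    participant_id: str
    sampling_age: float
    ddd_by_window: dict[str, dict[float, float]]  # class -> window upper -> cumulative ddd
    lifetime_ddd: dict[str, float]
    lifetime_courses: dict[str, int]
    time_since_last: dict[str, float]  # +inf when never exposed
    warnings: list[str] = field(default_factory=list)


def build_exposures(
    records: Sequence[AntibioticRecord],
    participant_id: str,
    sampling_age: float,
    windows: Sequence[float] = DEFAULT_WINDOWS,
) -> ExposureProfile:
    """Summarize one participant's purchase history. Windows are [0, upper).
    Records after the sampling age are excluded with a warning."""
    profile = ExposureProfile(
        participant_id=participant_id,
        sampling_age=sampling_age,
        ddd_by_window={c: {w: 0.0 for w in windows} for c in DRUG_CLASSES},
        lifetime_ddd={c: 0.0 for c in DRUG_CLASSES},
        lifetime_courses={c: 0 for c in DRUG_CLASSES},
        time_since_last={c: math.inf for c in DRUG_CLASSES},
    )
    last_age = {c: -math.inf for c in DRUG_CLASSES}
    for rec in records:
        if rec.participant_id != participant_id:
            continue
        if rec.age_at_purchase > sampling_age:
            profile.warnings.append(
                f"record at age {rec.age_at_purchase:.2f} after sampling age "
                f"{sampling_age:.2f}: excluded"
            )
            continue
        cls = rec.drug_class
        profile.lifetime_ddd[cls] += rec.ddd
        profile.lifetime_courses[cls] += 1
        last_age[cls] = max(last_age[cls], rec.age_at_purchase)
        for w in windows:
            if rec.age_at_purchase < w:
                profile.ddd_by_window[cls][w] += rec.ddd
    for cls in DRUG_CLASSES:
        if profile.lifetime_courses[cls] > 0:
            profile.time_since_last[cls] = sampling_age - last_age[cls]
    return profile


def profiles_frame(profiles: Sequence[ExposureProfile]) -> pd.DataFrame:
    """One row per participant; +inf sentinels preserved for time since
    last course."""
    rows = {}
    for p in profiles:
        row: dict[str, float] = {"sampling_age": p.sampling_age}
        for cls in DRUG_CLASSES:
            for w, v in p.ddd_by_window[cls].items():
                row[f"{cls}_ddd_to_{w:g}"] = v
            row[f"{cls}_lifetime_ddd"] = p.lifetime_ddd[cls]
            row[f"{cls}_lifetime_courses"] = float(p.lifetime_courses[cls])
            row[f"{cls}_time_since_last"] = p.time_since_last[cls]
        rows[p.participant_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("participant_id")


def candidate_terms(
    exposures: pd.DataFrame, windows: Sequence[float] = DEFAULT_WINDOWS
) -> dict[str, pd.DataFrame]:
    """Candidate name -> design columns. Time-since-last candidates expand
    to (capped value, never-exposed indicator) column pairs."""
    candidates: dict[str, pd.DataFrame] = {}
    for cls in DRUG_CLASSES:
        for w in windows:
            name = f"{cls}_ddd_to_{w:g}"
            candidates[name] = exposures[[name]].astype(float)
        for name in (f"{cls}_lifetime_ddd", f"{cls}_lifetime_courses"):
            candidates[name] = exposures[[name]].astype(float)
        tsl = f"{cls}_time_since_last"
        never = ~np.isfinite(exposures[tsl].astype(float))
        capped = exposures[tsl].astype(float).where(~never, exposures["sampling_age"])
        candidates[tsl] = pd.DataFrame(
            {tsl: capped, f"{cls}_never_exposed": never.astype(float)},
            index=exposures.index,
        )
    return candidates


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    return 2.0 * n_params - 2.0 * loglik


@dataclass
class SelectionStep:
    action: str  # "candidate" | "add" | "drop" | "keep"
    term: str
    aic: float


@dataclass
class ModelSelectionTrace:
    response: str
    steps: list[SelectionStep] = field(default_factory=list)
    selected_terms: list[str] = field(default_factory=list)
    coefficients: Optional[pd.DataFrame] = None  # term, estimate, stderr, pvalue
    final_aic: float = math.nan
    caveat: str = SELECTION_CAVEAT
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"action": s.action, "term": s.term, "aic": s.aic} for s in self.steps]
        )


def _ols_fit(y: pd.Series, design: pd.DataFrame):
    X = sm.add_constant(design.astype(float)) if design.shape[1] else pd.DataFrame(
        {"const": np.ones(len(y))}, index=y.index
    )
    return sm.OLS(y.astype(float), X).fit()


def _fit_aic(y: pd.Series, design: pd.DataFrame) -> float:
    fit = _ols_fit(y, design)
    return aic(float(fit.llf), int(fit.df_model) + 2)  # + intercept + error variance


def screen_exposures(
    timing: pd.Series,
    exposures: pd.DataFrame,
    windows: Sequence[float] = DEFAULT_WINDOWS,
) -> tuple[str, pd.DataFrame, ModelSelectionTrace]:
    """Fit timing ~ candidate (OLS) for each exposure candidate; return the
    minimal-AIC candidate with its coefficient table and the full trace.
    Ties (< 1e-9) break by candidate declaration order; zero-variance
    candidates are skipped with a note."""
    shared = timing.index.intersection(exposures.index)
    y = timing.loc[shared].astype(float).dropna()
    trace = ModelSelectionTrace(response=timing.name or "time_from_peak")
    best_name, best_aic = None, math.inf
    candidates = candidate_terms(exposures.loc[y.index], windows)
    for name, cols in candidates.items():
        varying = cols.loc[y.index]
        if all(np.isclose(varying[c].std(ddof=0), 0.0) for c in varying.columns):
            trace.notes.append(f"candidate '{name}' constant: skipped")
            continue
        varying = varying.loc[:, varying.std(ddof=0) > 0]
        value = _fit_aic(y, varying)
        trace.steps.append(SelectionStep("candidate", name, value))
        if value < best_aic - 1e-9:
            best_name, best_aic = name, value
    if best_name is None:
        raise ValueError("no non-constant exposure candidates")
    cols = candidates[best_name].loc[y.index]
    cols = cols.loc[:, cols.std(ddof=0) > 0]
    fit = _ols_fit(y, cols)
    coef = pd.DataFrame(
        {
            "term": list(fit.params.index),
            "estimate": fit.params.to_numpy(),
            "stderr": fit.bse.to_numpy(),
            "pvalue": fit.pvalues.to_numpy(),
        }
    ).set_index("term")
    trace.selected_terms = [best_name]
    trace.coefficients = coef
    trace.final_aic = best_aic
    return best_name, coef, trace


def stepwise_aic(
    y: pd.Series,
    terms: dict[str, pd.DataFrame],
    max_steps: int = 200,
) -> ModelSelectionTrace:
    """Bidirectional stepwise selection by AIC from the intercept-only
    model. Each term is an all-or-nothing column block. Stops when no
    single add or drop improves AIC by more than 1e-9."""
    trace = ModelSelectionTrace(response=y.name or "response")
    y = y.astype(float).dropna()
    usable = {}
    for name, cols in terms.items():
        block = cols.loc[y.index].astype(float)
        if block.isna().any().any():
            trace.notes.append(f"term '{name}' has missing values: dropped")
            continue
        block = block.loc[:, block.std(ddof=0) > 0]
        if block.shape[1] == 0:
            trace.notes.append(f"term '{name}' constant: dropped")
            continue
        usable[name] = block

    if len(y) <= len(usable):
        keep = max(2, len(y) // 5)
        ranked = sorted(usable, key=lambda n: _fit_aic(y, usable[n]))
        dropped = ranked[keep:]
        usable = {n: usable[n] for n in ranked[:keep]}
        trace.notes.append(
            f"candidate pool pre-filtered by univariate AIC to {keep} terms "
            f"(n={len(y)}); dropped: {', '.join(dropped)}"
        )

    def design_for(selected: list[str]) -> pd.DataFrame:
        if not selected:
            return pd.DataFrame(index=y.index)
        return pd.concat([usable[n] for n in selected], axis=1)

    selected: list[str] = []
    current_aic = _fit_aic(y, design_for(selected))
    trace.steps.append(SelectionStep("keep", "<intercept>", current_aic))
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for name in usable:
            if name not in selected:
                moves.append((_fit_aic(y, design_for(selected + [name])), "add", name))
        for name in selected:
            remaining = [n for n in selected if n != name]
            moves.append((_fit_aic(y, design_for(remaining)), "drop", name))
        if not moves:
            break
        moves.sort(key=lambda m: m[0])
        best_aic, action, name = moves[0]
        if best_aic >= current_aic - 1e-9:
            break
        if action == "add":
            selected.append(name)
        else:
            selected.remove(name)
        current_aic = best_aic
        trace.steps.append(SelectionStep(action, name, current_aic))

    fit = _ols_fit(y, design_for(selected))
    trace.selected_terms = list(selected)
    trace.final_aic = current_aic
    trace.coefficients = pd.DataFrame(
        {
            "term": list(fit.params.index),
            "estimate": fit.params.to_numpy(),
            "stderr": fit.bse.to_numpy(),
            "pvalue": fit.pvalues.to_numpy(),
        }
    ).set_index("term")
    return trace


def multivariate_timing_model(
    timing: pd.Series,
    family_log_abundances: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    windows: Sequence[float] = DEFAULT_WINDOWS,
) -> ModelSelectionTrace:
    """Stepwise AIC model of pubertal timing on family-level log relative
    abundances, the exposure-candidate grid, and scalar covariates (BMI,
    probiotic arm, GI symptoms)."""
    shared = timing.dropna().index
    shared = shared.intersection(family_log_abundances.index).intersection(exposures.index)
    if covariates is not None:
        shared = shared.intersection(covariates.index)
    y = timing.loc[shared]
    terms: dict[str, pd.DataFrame] = {}
    for fam in family_log_abundances.columns:
        terms[f"family:{fam}"] = family_log_abundances.loc[shared, [fam]]
    terms.update(
        {k: v.loc[shared] for k, v in candidate_terms(exposures.loc[shared], windows).items()}
    )
    if covariates is not None:
        for col in covariates.columns:
            terms[col] = covariates.loc[shared, [col]]
    return stepwise_aic(y, terms)
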