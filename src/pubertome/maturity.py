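"""Adult-similarity microbiota maturity index and its association with
pubertal timing.

The index for an adolescent is the mean correlation (Pearson by default)
between that adolescent's log-transformed species-level relative-abundance
profile and the profile of every same-sex adult in a reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tables_io import CountTable

DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class MaturityScore:
    sample_id: str
    maturity: float  # mean pairwise correlation, in [-1, 1]
    n_adults_compared: int
    log_base: float
    pseudocount: float


@dataclass(frozen=True)
class AssociationResult:
    sex: str
    slope: float
    stderr: float
    pvalue: float
    n: int
    covariates: tuple[str, ...]


def log_profile(
    rel_row: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT, base: float = 10.0
) -> np.ndarray:
    """log_base(x + pseudocount), elementwise. Absent taxa (zeros) map to
    the finite floor log(pseudocount)."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    rel_row = np.asarray(rel_row, dtype=float)
    return np.log(rel_row + pseudocount) / np.log(base)


def pair_similarity(
    adolescent_profile: np.ndarray,
    adult_profile: np.ndarray,
    method: str = "pearson",
) -> float:
    """Correlation between two equal-length log-profiles over an identical
    taxon order. Zero variance in either vector -> NaN (missing pair)."""
    a = np.asarray(adolescent_profile, dtype=float)
    b = np.asarray(adult_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have identical length and taxon order")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method '{method}'")


def _aligned_log_profiles(
    adolescents: CountTable,
    adults: CountTable,
    pseudocount: float,
    base: float,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align both tables on the union taxon set (absent taxa = 0) and
    log-transform the relative abundances."""
    union = sorted(set(adolescents.taxon_ids) | set(adults.taxon_ids))
    ado = adolescents.relative_abundance().reindex(columns=union, fill_value=0.0)
    adu = adults.relative_abundance().reindex(columns=union, fill_value=0.0)
    return (
        log_profile(ado.to_numpy(), pseudocount, base),
        log_profile(adu.to_numpy(), pseudocount, base),
        union,
    )


def maturity_index(
    adolescents: CountTable,
    adults: CountTable,
    method: str = "pearson",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    base: float = 10.0,
) -> list[MaturityScore]:
    """Maturity score for every adolescent sample against the full adult
    panel (the panel must already be restricted to same-sex adults).
    Missing pairs (zero variance) are excluded from the mean."""
    if adults.n_samples == 0:
        raise ValueError("adult panel is empty")
    ado_logs, adu_logs, _ = _aligned_log_profiles(adolescents, adults, pseudocount, base)
    if method == "spearman":
        ado_r = np.apply_along_axis(stats.rankdata, 1, ado_logs)
        adu_r = np.apply_along_axis(stats.rankdata, 1, adu_logs)
    else:
        ado_r, adu_r = ado_logs, adu_logs

    # row-standardize, then all pairwise Pearson correlations in one matmul
    def _standardize(m: np.ndarray) -> np.ndarray:
        centered = m - m.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, centered / sd, np.nan)

    za, zu = _standardize(ado_r), _standardize(adu_r)
    n_taxa = za.shape[1]
    corr = za @ zu.T / n_taxa  # adolescents x adults; NaN rows propagate
    scores = []
    for i, sid in enumerate(adolescents.sample_ids):
        row = corr[i]
        valid = np.isfinite(row)
        scores.append(
            MaturityScore(
                sample_id=sid,
                maturity=float(np.mean(row[valid])) if valid.any() else float("nan"),
                n_adults_compared=int(valid.sum()),
                log_base=base,
                pseudocount=pseudocount,
            )
        )
    return scores


def scores_frame(scores: Sequence[MaturityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "maturity": [s.maturity for s in scores],
            "n_adults_compared": [s.n_adults_compared for s in scores],
        }
    ).set_index("sample_id")


def maturity_association(
    maturity: pd.Series,
    time_from_peak: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    sex: str = "",
) -> AssociationResult:
    """OLS of maturity on time_from_peak plus optional covariates, for one
    sex at a time. Returns the slope on time_from_peak with its two-sided
    p-value."""
    df = pd.DataFrame({"maturity": maturity, "time_from_peak": time_from_peak})
    cov_names: tuple[str, ...] = ()
    if covariates is not None and covariates.shape[1]:
        df = df.join(covariates, how="inner")
        cov_names = tuple(covariates.columns)
    df = df.dropna()
    n_params = 2 + len(cov_names)
    if len(df) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} complete observations, have {len(df)}"
        )
    X = sm.add_constant(df[["time_from_peak", *cov_names]])
    fit = sm.OLS(df["maturity"], X).fit()
    return AssociationResult(
        sex=sex,
        slope=float(fit.params["time_from_peak"]),
        stderr=float(fit.bse["time_from_peak"]),
        pvalue=float(fit.pvalues["time_from_peak"]),
        n=int(len(df)),
        covariates=cov_names,
    )
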