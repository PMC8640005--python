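"""Per-taxon association scan with a diagnostics-driven model cascade.

For each taxon the response is the raw read count and log(total reads) is
an offset, so count-model coefficients are depth-independent. Models are
attempted in a fixed order — negative binomial GLM, Poisson GLM, linear
model on (optionally log-transformed) relative abundances, then generalized
least squares with a power-of-the-mean variance structure — and the first
stage that converges and passes residual diagnostics (normality and absence
of a residual-vs-fitted trend) is accepted. If no stage passes, no p-value
is reported for that taxon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .maturity import DEFAULT_PSEUDOCOUNT
from .tables_io import CountTable

CASCADE_ORDER = ("negbin", "poisson", "lm", "gls")

#: alpha outside this range is treated as a dispersion-boundary failure
_NEGBIN_ALPHA_RANGE = (1e-6, 1e4)
_LOG_TRANSFORM_SKEWNESS = 1.0


@dataclass
class CascadeConfig:
    normality_alpha: float = 0.05
    trend_alpha: float = 0.05
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    log_skewness_threshold: float = _LOG_TRANSFORM_SKEWNESS


@dataclass
class StageDiagnostics:
    stage: str
    converged: bool
    normality_p: float
    trend_p: float
    accepted: bool
    note: str = ""


@dataclass
class CascadeFit:
    taxon_id: str
    model_used: str  # negbin | poisson | lm | gls | none
    estimate: Optional[float]  # coefficient on time_from_peak, link scale
    stderr: Optional[float]
    pvalue: Optional[float]
    log_transformed: bool = False
    diagnostics: list[StageDiagnostics] = field(default_factory=list)

    def __post_init__(self):
        if (self.model_used == "none") != (self.pvalue is None):
            raise ValueError("p-value must be absent exactly when no model is accepted")


def _residual_diagnostics(
    residuals: np.ndarray, fitted: np.ndarray, config: CascadeConfig
) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality p and Spearman residual-vs-fitted trend p;
    passes when both exceed their thresholds."""
    residuals = np.asarray(residuals, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if not np.all(np.isfinite(residuals)) or np.std(residuals) == 0:
        return 0.0, 0.0, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normality_p = float(stats.shapiro(residuals).pvalue)
        if np.std(fitted) == 0:
            trend_p = 1.0
        else:
            trend_p = float(stats.spearmanr(residuals, fitted).pvalue)
    passed = normality_p > config.normality_alpha and trend_p > config.trend_alpha
    return normality_p, trend_p, passed


def _negbin_deviance_residuals(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
        dev = 2.0 * (term1 - term2)
    dev = np.clip(dev, 0.0, None)
    return np.sign(y - mu) * np.sqrt(dev)


def _fit_negbin(y, X, offset):
    """Discrete NB-2 fit with estimated dispersion; newton first, bfgs as a
    fallback. Returns (params, bse, pvalues, mu, alpha, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, offset=offset)
        res = None
        for method in ("newton", "bfgs"):
            try:
                candidate = model.fit(method=method, maxiter=200, disp=0)
            except Exception:
                continue
            if candidate.mle_retvals.get("converged", False):
                res = candidate
                break
            res = res or candidate
        if res is None:
            return None
        converged = bool(res.mle_retvals.get("converged", False))
        alpha = float(res.params[-1])
        bse = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(bse)) or not np.all(np.isfinite(res.params)):
            converged = False
        if not (_NEGBIN_ALPHA_RANGE[0] < alpha < _NEGBIN_ALPHA_RANGE[1]):
            converged = False  # dispersion at its boundary
        mu = np.exp(np.asarray(X, dtype=float) @ res.params[:-1] + offset)
        return res, mu, alpha, converged


def fit_cascade(
    counts: np.ndarray,
    depth: np.ndarray,
    design: pd.DataFrame,
    taxon_id: str = "",
    config: CascadeConfig | None = None,
    term: str = "time_from_peak",
) -> CascadeFit:
    """Run the model cascade for one taxon.

    ``design`` holds the timing variable plus covariates (no constant; one
    is added). The reported coefficient is on ``term``.
    """
    config = config or CascadeConfig()
    y = np.asarray(counts, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if term not in design.columns:
        raise ValueError(f"design is missing the term of interest '{term}'")
    diags: list[StageDiagnostics] = []

    if np.all(y == 0) or np.std(y) == 0:
        diags.append(StageDiagnostics("negbin", False, 0.0, 0.0, False, "degenerate"))
        return CascadeFit(taxon_id, "none", None, None, None, diagnostics=diags)

    X = sm.add_constant(design.astype(float))
    offset = np.log(depth)
    term_pos = list(X.columns).index(term)

    # stage 1: negative binomial
    nb = _fit_negbin(y, X, offset)
    if nb is None:
        diags.append(StageDiagnostics("negbin", False, 0.0, 0.0, False, "fit error"))
    else:
        res, mu, alpha, converged = nb
        if converged:
            resid = _negbin_deviance_residuals(y, mu, alpha)
            norm_p, trend_p, passed = _residual_diagnostics(resid, mu, config)
            diags.append(StageDiagnostics("negbin", True, norm_p, trend_p, passed))
            if passed:
                params = np.asarray(res.params, dtype=float)
                bse = np.asarray(res.bse, dtype=float)
                pvalues = np.asarray(res.pvalues, dtype=float)
                return CascadeFit(
                    taxon_id, "negbin",
                    float(params[term_pos]), float(bse[term_pos]),
                    float(pvalues[term_pos]), diagnostics=diags,
                )
        else:
            diags.append(StageDiagnostics("negbin", False, 0.0, 0.0, False, "not converged"))

    # stage 2: Poisson
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        converged = bool(getattr(pois, "converged", True)) and np.all(np.isfinite(pois.bse))
    except Exception:
        pois, converged = None, False
    if pois is not None and converged:
        norm_p, trend_p, passed = _residual_diagnostics(
            pois.resid_deviance, pois.fittedvalues, config
        )
        diags.append(StageDiagnostics("poisson", True, norm_p, trend_p, passed))
        if passed:
            return CascadeFit(
                taxon_id, "poisson",
                float(pois.params.iloc[term_pos]), float(pois.bse.iloc[term_pos]),
                float(pois.pvalues.iloc[term_pos]), diagnostics=diags,
            )
    else:
        diags.append(StageDiagnostics("poisson", False, 0.0, 0.0, False, "not converged"))

    # stage 3: linear model on relative abundances (log if skewed)
    rel = y / depth
    log_transformed = bool(stats.skew(rel) > config.log_skewness_threshold)
    response = np.log10(rel + config.pseudocount) if log_transformed else rel
    try:
        ols = sm.OLS(response, X).fit()
        ols_ok = np.all(np.isfinite(ols.bse))
    except Exception:
        ols, ols_ok = None, False
    if ols is not None and ols_ok:
        norm_p, trend_p, passed = _residual_diagnostics(ols.resid, ols.fittedvalues, config)
        diags.append(StageDiagnostics("lm", True, norm_p, trend_p, passed))
        if passed:
            return CascadeFit(
                taxon_id, "lm",
                float(ols.params.iloc[term_pos]), float(ols.bse.iloc[term_pos]),
                float(ols.pvalues.iloc[term_pos]),
                log_transformed=log_transformed, diagnostics=diags,
            )
    else:
        diags.append(StageDiagnostics("lm", False, 0.0, 0.0, False, "not converged"))

    # stage 4: gls — weighted least squares with variance ∝ |fitted|^(2·delta)
    if ols is not None and ols_ok:
        fitted = np.abs(ols.fittedvalues.to_numpy() if hasattr(ols.fittedvalues, "to_numpy") else ols.fittedvalues)
        eps = max(1e-12, 1e-6 * float(np.mean(fitted)) if np.mean(fitted) > 0 else 1e-12)
        log_f = np.log(fitted + eps)
        log_r = np.log(np.abs(np.asarray(ols.resid)) + eps)
        if np.std(log_f) > 0:
            delta = float(np.polyfit(log_f, log_r, 1)[0])
        else:
            delta = 0.0
        weights = 1.0 / np.power(fitted + eps, 2.0 * delta)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gls = sm.WLS(response, X, weights=weights).fit()
            gls_ok = np.all(np.isfinite(gls.bse))
        except Exception:
            gls, gls_ok = None, False
        if gls is not None and gls_ok:
            std_resid = np.asarray(gls.resid) * np.sqrt(weights)
            norm_p, trend_p, passed = _residual_diagnostics(std_resid, gls.fittedvalues, config)
            diags.append(StageDiagnostics("gls", True, norm_p, trend_p, passed))
            if passed:
                return CascadeFit(
                    taxon_id, "gls",
                    float(gls.params.iloc[term_pos]), float(gls.bse.iloc[term_pos]),
                    float(gls.pvalues.iloc[term_pos]),
                    log_transformed=log_transformed, diagnostics=diags,
                )
        else:
            diags.append(StageDiagnostics("gls", False, 0.0, 0.0, False, "not converged"))
    else:
        diags.append(StageDiagnostics("gls", False, 0.0, 0.0, False, "no lm baseline"))

    return CascadeFit(taxon_id, "none", None, None, None, diagnostics=diags)


def scan_taxa(
    table: CountTable,
    timing: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    config: CascadeConfig | None = None,
    depth: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Cascade fit for every taxon in a (rank-aggregated) table.

    ``timing`` and ``covariates`` are indexed by sample id. ``depth``
    defaults to the table's row sums (total reads per sample); pass it
    explicitly when the table holds a subset of taxa. Reports raw p-values
    plus Benjamini-Hochberg adjusted values side by side; nothing is
    filtered on the adjusted values.
    """
    samples = [s for s in table.sample_ids if s in timing.index and np.isfinite(timing[s])]
    sub = table.subset_samples(samples)
    design = pd.DataFrame({"time_from_peak": timing.loc[samples]})
    if covariates is not None and covariates.shape[1]:
        design = design.join(covariates, how="left")
    design = design.astype(float)
    keep = design.dropna().index
    design = design.loc[keep]
    sub = sub.subset_samples(list(keep))
    if depth is None:
        depth = sub.depths.astype(float)
    else:
        depth = depth.loc[list(keep)].astype(float)
    depth = depth.to_numpy()

    rows = []
    for taxon in sub.taxon_ids:
        fit = fit_cascade(
            sub.data[taxon].to_numpy(), depth, design, taxon_id=taxon, config=config
        )
        accepted = next((d for d in fit.diagnostics if d.accepted), None)
        rows.append(
            {
                "taxon_id": taxon,
                "estimate": fit.estimate,
                "stderr": fit.stderr,
                "pvalue": fit.pvalue,
                "model_used": fit.model_used,
                "log_transformed": fit.log_transformed,
                "normality_p": accepted.normality_p if accepted else np.nan,
                "trend_p": accepted.trend_p if accepted else np.nan,
                "n_stages_tried": len(fit.diagnostics),
            }
        )
    out = pd.DataFrame(rows).set_index("taxon_id")
    out["p_adjusted"] = np.nan
    mask = out["pvalue"].notna()
    if mask.any():
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    return out
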