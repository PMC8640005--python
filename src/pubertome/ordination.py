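"""Bray-Curtis distances, classical PCoA, the summed first-two-axes score,
and stage-group contrasts on that score."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

EIGENVALUE_TOL = 1e-10


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes, eigenvalue order
    eigenvalues: np.ndarray  # positive eigenvalues, non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # summed |negative eigenvalues|, logged not corrected
    axis_flips: np.ndarray | None = None  # orientation record set by pc_sum_score


def bray_curtis(rel_abund: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity, d(a, b) = 1 - sum_i min(a_i, b_i)
    for rows that sum to 1."""
    X = np.asarray(rel_abund, dtype=float)
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must be relative abundances summing to 1")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(X[i], X[i + 1 :]).sum(axis=1)
        D[i, i + 1 :] = 1.0 - shared
    return D + D.T


def euclidean_log(rel_abund: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Alternative metric: Euclidean distance on log10-transformed relative
    abundances."""
    X = np.log10(np.asarray(rel_abund, dtype=float) + pseudocount)
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def pcoa(distance: np.ndarray, sample_ids: Sequence[str] | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Gower double-centering of -0.5 * D^2 followed by a symmetric
    eigendecomposition; axes with eigenvalue <= 1e-10 are dropped and the
    summed magnitude of negative eigenvalues is recorded (no Lingoes or
    Cailliez correction).
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > EIGENVALUE_TOL
    neg_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    total = lam.sum()
    return PCoAResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=lam / total if total > 0 else lam,
        negative_eigenvalue_mass=neg_mass,
    )


def pc_sum_score(result: PCoAResult, adult_ids: Sequence[str]) -> pd.Series:
    """Sum of the first two principal coordinates after orienting each so
    that the adult centroid is non-negative on it. Invariant to the
    eigensolver's arbitrary sign choices."""
    if result.coordinates.shape[1] < 2:
        raise ValueError("need at least 2 positive axes for the summed score")
    adult_ids = set(adult_ids)
    adult_idx = [i for i, s in enumerate(result.sample_ids) if s in adult_ids]
    if not adult_idx:
        raise ValueError("no adult samples present in the ordination")
    flips = np.ones(2)
    for axis in range(2):
        if result.coordinates[adult_idx, axis].mean() < 0:
            flips[axis] = -1.0
    result.axis_flips = flips
    oriented = result.coordinates[:, :2] * flips
    return pd.Series(oriented.sum(axis=1), index=result.sample_ids, name="pc_sum_score")


def stage_score_test(
    scores: pd.Series, stage_groups: pd.Series, reference_group: str
) -> pd.DataFrame:
    """Linear model of score on stage group (categorical); contrasts of each
    group against the reference with two-sided p-values. Degenerate
    (zero-variance) data yield zero contrasts with NaN p-values."""
    df = pd.DataFrame({"score": scores, "stage": stage_groups}).dropna()
    df = df[df["stage"] != ""]
    present = [g for g in df["stage"].unique()]
    if reference_group not in present:
        raise ValueError(f"reference group '{reference_group}' absent from data")
    others = [g for g in pd.unique(df["stage"]) if g != reference_group]
    counts = df["stage"].value_counts()
    small = counts[counts < 2]
    if len(df["stage"].unique()) < 2 or len(small) == len(counts):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    dummies = pd.get_dummies(df["stage"], dtype=float)[others]
    X = sm.add_constant(dummies)
    if np.allclose(df["score"].std(ddof=0), 0.0):
        return pd.DataFrame(
            {
                "group": others,
                "difference": 0.0,
                "stderr": np.nan,
                "pvalue": np.nan,
                "n": [int(counts[g]) for g in others],
            }
        ).set_index("group")
    fit = sm.OLS(df["score"], X).fit()
    return pd.DataFrame(
        {
            "group": others,
            "difference": [float(fit.params[g]) for g in others],
            "stderr": [float(fit.bse[g]) for g in others],
            "pvalue": [float(fit.pvalues[g]) for g in others],
            "n": [int(counts[g]) for g in others],
        }
    ).set_index("group")
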