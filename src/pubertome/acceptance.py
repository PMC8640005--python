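"""From-scratch recomputation of the package's simulation-based validation
metrics: APHV recovery, maturity-index power and null calibration, oracle
equivalence for the distance/ordination/similarity primitives, cascade
calibration, exposure-screen recovery, and qualitative direction checks.

Every function takes a seed and runs the full relevant chain (generate ->
estimate -> measure); nothing is looked up or hard-coded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import exposure_models, growth_timing, maturity, ordination, tables_io, taxon_models
from .synthetic_data import ScenarioConfig, TAXON_TREE, generate_cohort, taxon_ids


def estimate_timing(cohort) -> pd.DataFrame:
    sex = cohort.sex
    return growth_timing.timing_for_cohort(
        cohort.growth,
        {sex: cohort.reference},
        {p: sex for p in cohort.metadata.index},
        cohort.metadata["age_at_sampling"].astype(float).to_dict(),
    )


def _girls_config(**overrides) -> ScenarioConfig:
    defaults = dict(n_girls=80, n_adults_per_sex=100)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


# ---------------------------------------------------------------------------
# criterion 1: APHV recovery


def aphv_recovery(seed: int) -> dict:
    """Girls, n = 80, 6-monthly visits: median |APHV error| with 0.3 cm
    noise, and the worst error in the noiseless limit."""
    cohort = generate_cohort(_girls_config(), "female", seed=seed)
    timing = estimate_timing(cohort)
    ok = timing["aphv"].notna()
    err = (timing.loc[ok, "aphv"] - cohort.ground_truth.loc[ok[ok].index, "true_aphv"]).abs()

    noiseless = generate_cohort(
        _girls_config(height_noise_sd=0.0), "female", seed=seed + 1
    )
    timing0 = estimate_timing(noiseless)
    err0 = (timing0["aphv"] - noiseless.ground_truth["true_aphv"]).abs()
    return {
        "median_abs_error_y": float(err.median()),
        "n_detected": int(ok.sum()),
        "n": int(len(timing)),
        "noiseless_max_abs_error_y": float(err0.max()),
        "noiseless_n_missing": int(timing0["aphv"].isna().sum()),
    }


# ---------------------------------------------------------------------------
# criterion 2: maturity-index power and null calibration


def _maturity_pvalue(cohort, timing) -> tuple[float, float]:
    usable = [
        p for p in timing.index[timing["aphv"].notna()]
        if p in cohort.adolescent_counts.sample_ids
    ]
    species_ado, _ = tables_io.aggregate(cohort.adolescent_counts, cohort.taxonomy, "species")
    species_adu, _ = tables_io.aggregate(cohort.adult_counts, cohort.taxonomy, "species")
    scores = maturity.maturity_index(species_ado.subset_samples(usable), species_adu)
    frame = maturity.scores_frame(scores)
    assoc = maturity.maturity_association(
        frame["maturity"], timing.loc[usable, "time_from_peak"].astype(float)
    )
    return assoc.slope, assoc.pvalue


def maturity_power(seed: int, girls_reps: int = 50, boys_reps: int = 200) -> dict:
    """Power in the girls scenario (maturation slope 0.8) and type-I error
    in the boys scenario (slope 0)."""
    hits = 0
    for r in range(girls_reps):
        cohort = generate_cohort(_girls_config(), "female", seed=seed * 100_003 + r)
        slope, p = _maturity_pvalue(cohort, estimate_timing(cohort))
        hits += slope > 0 and p < 0.05
    rejections = 0
    for r in range(boys_reps):
        cohort = generate_cohort(
            ScenarioConfig(n_boys=80, n_adults_per_sex=100), "male",
            seed=seed * 200_003 + r,
        )
        _, p = _maturity_pvalue(cohort, estimate_timing(cohort))
        rejections += p < 0.05
    return {
        "girls_power_pct": 100.0 * hits / girls_reps,
        "girls_reps": girls_reps,
        "boys_rejection_rate_pct": 100.0 * rejections / boys_reps,
        "boys_reps": boys_reps,
    }


# ---------------------------------------------------------------------------
# criterion 3: oracle equivalence


def oracle_equivalence(seed: int) -> dict:
    """Maximum deviation between the package primitives and independent
    direct-formula / brute-force implementations."""
    rng = np.random.default_rng(seed)

    # pcoa vs brute-force double-centering + dense eigensolve
    pcoa_dev = 0.0
    for n in range(3, 11):
        pts = rng.normal(size=(n, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = ordination.pcoa(D)
        D2 = D**2
        row = D2.mean(axis=1)
        B = -0.5 * (D2 - row[:, None] - row[None, :] + D2.mean())
        vals, vecs = np.linalg.eig(B)
        vals, vecs = np.real(vals), np.real(vecs)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        pos = vals > 1e-10
        pcoa_dev = max(pcoa_dev, float(np.abs(res.eigenvalues - vals[pos]).max()))
        oracle = vecs[:, pos] * np.sqrt(vals[pos])
        for k in range(res.coordinates.shape[1]):
            a, b = res.coordinates[:, k], oracle[:, k]
            pcoa_dev = max(pcoa_dev, float(min(np.abs(a - b).max(), np.abs(a + b).max())))

    # bray_curtis vs direct formula, including the hand value
    bc_dev = 0.0
    for _ in range(50):
        counts = rng.integers(1, 300, size=(2, 3))
        X = counts / counts.sum(axis=1, keepdims=True)
        direct = 1.0 - np.minimum(X[0], X[1]).sum()
        bc_dev = max(bc_dev, abs(float(ordination.bray_curtis(X)[0, 1]) - direct))
    hand = float(ordination.bray_curtis(np.array([[0.6, 0.4], [0.2, 0.8]]))[0, 1])
    bc_dev = max(bc_dev, abs(hand - 0.4))

    # pair_similarity vs hand Pearson on 3-taxon toys
    ps_dev = 0.0
    for _ in range(50):
        a = maturity.log_profile(rng.dirichlet(np.ones(3)))
        b = maturity.log_profile(rng.dirichlet(np.ones(3)))
        ca, cb = a - a.mean(), b - b.mean()
        direct = float((ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum()))
        ps_dev = max(ps_dev, abs(maturity.pair_similarity(a, b) - direct))
    return {
        "pcoa_max_abs_dev": pcoa_dev,
        "bray_curtis_max_abs_dev": bc_dev,
        "bray_curtis_hand_value": hand,
        "pair_similarity_max_abs_dev": ps_dev,
    }


# ---------------------------------------------------------------------------
# criterion 4: cascade calibration


def cascade_calibration(
    seed: int, effect_reps: int = 200, null_reps: int = 200, n: int = 150, beta: float = 0.5
) -> dict:
    rng = np.random.default_rng(seed)
    k = 2.0  # NB size parameter (alpha = 0.5)
    covered = fitted = negbin_accepted = 0
    for _ in range(effect_reps):
        tfp = rng.normal(1.5, 1.0, n)
        depth = np.maximum(rng.lognormal(np.log(2e4), 0.3, n), 1000).astype(int)
        mu = depth * np.exp(-6.0 + beta * tfp)
        y = rng.negative_binomial(k, k / (k + mu))
        fit = taxon_models.fit_cascade(
            y, depth, pd.DataFrame({"time_from_peak": tfp})
        )
        if fit.model_used == "negbin":
            negbin_accepted += 1
        if fit.estimate is not None:
            fitted += 1
            covered += abs(fit.estimate - beta) < 1.96 * fit.stderr
    null_sig = null_fitted = 0
    for _ in range(null_reps):
        tfp = rng.normal(1.5, 1.0, n)
        depth = np.maximum(rng.lognormal(np.log(2e4), 0.3, n), 1000).astype(int)
        mu = depth * np.exp(-6.0)
        y = rng.negative_binomial(k, k / (k + mu))
        fit = taxon_models.fit_cascade(
            y, depth, pd.DataFrame({"time_from_peak": tfp})
        )
        if fit.pvalue is not None:
            null_fitted += 1
            null_sig += fit.pvalue < 0.05
    return {
        "negbin_acceptance_rate_pct": 100.0 * negbin_accepted / effect_reps,
        "ci95_coverage_pct": 100.0 * covered / max(fitted, 1),
        "n_fitted": fitted,
        "null_rejection_rate_pct": 100.0 * null_sig / max(null_fitted, 1),
        "null_fitted": null_fitted,
    }


# ---------------------------------------------------------------------------
# criterion 5: exposure-screen recovery


def _screen_once(seed: int, effect: float) -> str:
    cohort = generate_cohort(
        _girls_config(cephalosporin_effect=effect), "female", seed=seed
    )
    timing = estimate_timing(cohort)
    tfp = timing["time_from_peak"].astype(float).dropna()
    profiles = [
        exposure_models.build_exposures(
            cohort.antibiotic_records, pid, float(cohort.metadata.loc[pid, "age_at_sampling"])
        )
        for pid in cohort.metadata.index
    ]
    frame = exposure_models.profiles_frame(profiles)
    best, _, _ = exposure_models.screen_exposures(tfp, frame)
    return best


def exposure_screen_recovery(seed: int, reps: int = 100, null_reps: int = 100) -> dict:
    hits = sum(
        _screen_once(seed * 300_007 + r, effect=0.15) == "cephalosporin_1_2_ddd_to_10"
        for r in range(reps)
    )
    # with a zero plant the four drug classes are exchangeable: the winner's
    # class should be cephalosporin about a quarter of the time
    null_ceph = sum(
        _screen_once(seed * 400_009 + r, effect=0.0).startswith("cephalosporin")
        for r in range(null_reps)
    )
    return {
        "recovery_rate_pct": 100.0 * hits / reps,
        "reps": reps,
        "null_cephalosporin_class_rate_pct": 100.0 * null_ceph / null_reps,
        "null_reps": null_reps,
    }


# ---------------------------------------------------------------------------
# criterion 6: qualitative directions


STAGE_ORDER = {g: i for i, g in enumerate(growth_timing.STAGE_GROUPS)}


def direction_properties(seed: int, reps: int = 5) -> dict:
    """Girls scenario: Clostridia rise / Bacteroidia fall across stage
    groups, and the summed PC1+PC2 score is higher post-peak than in the
    earliest stage group present."""
    clos_ids = [t for t, tree in zip(taxon_ids(), TAXON_TREE) if tree[0] == "Clostridia"]
    bact_ids = [t for t, tree in zip(taxon_ids(), TAXON_TREE) if tree[0] == "Bacteroidia"]
    clos_corrs, bact_corrs, score_gaps = [], [], []
    for r in range(reps):
        cohort = generate_cohort(_girls_config(), "female", seed=seed * 500_009 + r)
        timing = estimate_timing(cohort)
        usable = list(timing.index[timing["aphv"].notna()])
        stages = timing.loc[usable, "stage_group"]
        rel = cohort.adolescent_counts.subset_samples(usable).relative_abundance()
        by_stage = sorted(set(stages), key=STAGE_ORDER.get)
        clos_means = [rel.loc[stages == g, clos_ids].sum(axis=1).mean() for g in by_stage]
        bact_means = [rel.loc[stages == g, bact_ids].sum(axis=1).mean() for g in by_stage]
        ranks = np.arange(len(by_stage))
        clos_corrs.append(stats.spearmanr(ranks, clos_means).statistic)
        bact_corrs.append(stats.spearmanr(ranks, bact_means).statistic)

        species_ado, _ = tables_io.aggregate(cohort.adolescent_counts, cohort.taxonomy, "species")
        species_adu, _ = tables_io.aggregate(cohort.adult_counts, cohort.taxonomy, "species")
        joint = tables_io.CountTable(
            pd.concat([species_ado.subset_samples(usable).data, species_adu.data])
        )
        res = ordination.pcoa(
            ordination.bray_curtis(joint.relative_abundance().to_numpy()),
            sample_ids=joint.sample_ids,
        )
        scores = ordination.pc_sum_score(res, species_adu.sample_ids)
        post = stages.isin(["post_peak_lt2y", "post_peak_gt2y"])
        earliest = by_stage[0]
        score_gaps.append(
            float(scores.loc[stages.index[post]].mean())
            - float(scores.loc[stages.index[stages == earliest]].mean())
        )
    return {
        "clostridia_stage_rank_corr": float(np.mean(clos_corrs)),
        "bacteroidia_stage_rank_corr": float(np.mean(bact_corrs)),
        "pc_score_post_minus_pre": float(np.mean(score_gaps)),
        "reps": reps,
    }
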