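"""Synthetic cohorts with known ground truth.

Growth curves use a Gaussian-bump velocity model
``v(t) = v0 * exp(-a*t) + A * exp(-(t - APHV)^2 / (2 sigma^2))`` integrated
to heights; the reference velocity curve is the (analytic) population mean
and SD of the prepubertal component. Microbiota follow a maturation
gradient: each participant's maturation m in [0, 1] interpolates, in log
space, between a child and an adult composition (Clostridia share rising,
Bacteroidia falling), and reads are Dirichlet-multinomial. Metadata,
antibiotic purchase histories and optional planted exposure -> timing
effects round out the cohort.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .tables_io import (
    AntibioticRecord,
    CountTable,
    DRUG_CLASSES,
    GrowthSeries,
    RANKS,
    Taxonomy,
    UNKNOWN,
)
from .growth_timing import APHV_MIN_AGE, ReferenceVelocityCurve

# (class, family, genus) per leaf; species is "<genus>_sp" or unclassified
TAXON_TREE: tuple[tuple[str, str, str], ...] = (
    ("Clostridia", "Ruminococcaceae", "Faecalibacterium"),
    ("Clostridia", "Ruminococcaceae", "Subdoligranulum"),
    ("Clostridia", "Ruminococcaceae", "Anaerofilum"),
    ("Clostridia", "Ruminococcaceae", "Anaerotruncus"),
    ("Clostridia", "Lachnospiraceae", "Dorea"),
    ("Clostridia", "Lachnospiraceae", "Syntrophococcus"),
    ("Bacteroidia", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidia", "Barnesiellaceae", "Barnesiella"),
    ("Bacteroidia", "Porphyromonadaceae", "Paludibacter"),
    ("Bacteroidia", "Porphyromonadaceae", "Macellibacteroides"),
    ("Bacilli", "Streptococcaceae", "Streptococcus"),
    ("Bacilli", "Lactobacillaceae", "Lactobacillus"),
    ("Coriobacteriia", "Coriobacteriaceae", ""),
    ("Gammaproteobacteria", "Enterobacteriaceae", "Escherichia"),
    ("Betaproteobacteria", "Neisseriaceae", ""),
    ("Gammaproteobacteria", "Pasteurellaceae", ""),
)

_CLASS_PHYLUM = {
    "Clostridia": "Firmicutes",
    "Bacilli": "Firmicutes",
    "Bacteroidia": "Bacteroidetes",
    "Coriobacteriia": "Actinobacteria",
    "Gammaproteobacteria": "Proteobacteria",
    "Betaproteobacteria": "Proteobacteria",
}
_CLASS_ORDER = {
    "Clostridia": "Clostridiales",
    "Bacilli": "Lactobacillales",
    "Bacteroidia": "Bacteroidales",
    "Coriobacteriia": "Coriobacteriales",
    "Gammaproteobacteria": "Enterobacteriales",
    "Betaproteobacteria": "Neisseriales",
}

CHILD_COMPOSITION = np.array(
    [0.12, 0.04, 0.02, 0.02, 0.06, 0.04,  # Clostridia (0.30)
     0.25, 0.06, 0.05, 0.04,              # Bacteroidia (0.40)
     0.08, 0.05, 0.05, 0.06, 0.03, 0.03]  # minor taxa (0.30)
)
ADULT_COMPOSITION = np.array(
    [0.20, 0.08, 0.05, 0.05, 0.10, 0.07,  # Clostridia (0.55)
     0.12, 0.025, 0.02, 0.015,            # Bacteroidia (0.18)
     0.05, 0.03, 0.04, 0.05, 0.05, 0.05]  # minor taxa (0.27)
)


def taxon_ids() -> list[str]:
    ids = []
    for cls, family, genus in TAXON_TREE:
        ids.append(f"{genus}_sp" if genus else f"{family}_unclassified")
    return ids


def build_taxonomy() -> Taxonomy:
    rows = {}
    for tid, (cls, family, genus) in zip(taxon_ids(), TAXON_TREE):
        rows[tid] = {
            "kingdom": "Bacteria",
            "phylum": _CLASS_PHYLUM[cls],
            "class": cls,
            "order": _CLASS_ORDER[cls],
            "family": family,
            "genus": genus if genus else UNKNOWN,
            "species": tid if genus else UNKNOWN,
        }
    return Taxonomy(pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)])


@dataclass
class ScenarioConfig:
    """All generator knobs plus the planted effects that recovery tests
    score against."""

    seed: int = 0
    n_girls: int = 80
    n_boys: int = 80
    n_adults_per_sex: int = 100
    sampling_age: float = 13.0

    # growth
    aphv_mean: dict = field(default_factory=lambda: {"female": 11.5, "male": 13.5})
    aphv_sd: float = 1.0
    aphv_truncation_sd: float = 1.7  # keep spurts inside the visit schedule
    spurt_amplitude: float = 5.0  # cm/y
    spurt_width: float = 0.7  # y
    baseline_v0_mean: float = 12.0  # cm/y at birth
    baseline_v0_sd: float = 1.0
    baseline_decay: float = 0.12  # 1/y
    birth_length: float = 50.0  # cm
    visit_start: float = 2.0
    visit_end: float = 13.5
    visit_spacing: float = 0.5
    height_noise_sd: float = 0.3  # cm

    # microbiota
    maturation_slope: dict = field(default_factory=lambda: {"female": 0.8, "male": 0.0})
    maturation_noise_sd: float = 0.4
    overdispersion_theta: float = 200.0  # Dirichlet concentration scale; inf => multinomial
    depth_log_mean: float = math.log(20000.0)
    depth_log_sd: float = 0.3

    # metadata and exposures
    bmi_mean: dict = field(default_factory=lambda: {"female": 19.5, "male": 19.0})
    bmi_sd: float = 2.5
    probiotic_prob: float = 0.5
    whole_grain_shape: float = 2.0
    whole_grain_scale: float = 1.0
    flatulence_prob: float = 0.3
    antibiotic_rate: dict = field(
        default_factory=lambda: {c: 0.25 for c in DRUG_CLASSES}
    )  # courses / year
    ddd_log_mean: float = math.log(7.0)
    ddd_log_sd: float = 0.3
    # planted effect: years of APHV shift per cephalosporin DDD before age 10
    # (positive = earlier puberty, i.e. larger time_from_peak at sampling)
    cephalosporin_effect: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for comp in (CHILD_COMPOSITION, ADULT_COMPOSITION):
            if not np.isclose(comp.sum(), 1.0):
                raise ValueError("composition vectors must sum to 1")
        if not (self.overdispersion_theta > 0):
            raise ValueError("overdispersion theta must be positive")
        if (self.visit_end - self.visit_start) / self.visit_spacing < 1:
            raise ValueError("visit schedule yields fewer than 2 visits")


# ---------------------------------------------------------------------------
# growth


def _velocity(t: np.ndarray, v0: float, decay: float, aphv: float, A: float, sigma: float) -> np.ndarray:
    return v0 * np.exp(-decay * t) + A * np.exp(-((t - aphv) ** 2) / (2.0 * sigma**2))


def reference_curve(config: ScenarioConfig, sex: str) -> ReferenceVelocityCurve:
    """Prepubertal reference: analytic mean and SD of the baseline velocity
    component across the generator population."""
    ages = np.arange(2.0, 18.01, 0.25)
    mean = config.baseline_v0_mean * np.exp(-config.baseline_decay * ages)
    sd = config.baseline_v0_sd * np.exp(-config.baseline_decay * ages)
    return ReferenceVelocityCurve(sex=sex, ages=ages, mean=mean, sd=sd)


def generate_growth(
    config: ScenarioConfig,
    sex: str,
    n: int,
    rng: np.random.Generator,
    aphv_true: Optional[np.ndarray] = None,
    participant_ids: Optional[Sequence[str]] = None,
) -> tuple[list[GrowthSeries], ReferenceVelocityCurve, pd.DataFrame]:
    """Simulate growth series on the visit schedule.

    Returns the series, the generator-consistent reference curve and a
    ground-truth frame with true APHV (numeric argmax of the velocity
    curve) and true take-off (first crossing of reference mean + 2 SD).
    """
    config.validate()
    visits = np.arange(config.visit_start, config.visit_end + 1e-9, config.visit_spacing)
    if len(visits) < 2:
        raise ValueError("visit schedule yields fewer than 2 visits")
    if aphv_true is None:
        lo = config.aphv_mean[sex] - config.aphv_truncation_sd * config.aphv_sd
        hi = config.aphv_mean[sex] + config.aphv_truncation_sd * config.aphv_sd
        aphv_true = np.clip(
            rng.normal(config.aphv_mean[sex], config.aphv_sd, size=n), lo, hi
        )
    else:
        aphv_true = np.asarray(aphv_true, dtype=float)
    if participant_ids is None:
        prefix = "G" if sex == "female" else "B"
        participant_ids = [f"{prefix}{i:03d}" for i in range(n)]

    ref = reference_curve(config, sex)
    fine = np.arange(0.0, 18.0 + 1e-9, 0.01)
    series: list[GrowthSeries] = []
    truth_rows = []
    for pid, aphv in zip(participant_ids, aphv_true):
        v0 = rng.normal(config.baseline_v0_mean, config.baseline_v0_sd)
        v_fine = _velocity(
            fine, v0, config.baseline_decay, aphv, config.spurt_amplitude, config.spurt_width
        )
        h_fine = config.birth_length + np.concatenate(
            ([0.0], np.cumsum((v_fine[1:] + v_fine[:-1]) / 2.0 * np.diff(fine)))
        )
        heights = np.interp(visits, fine, h_fine)
        if config.height_noise_sd > 0:
            heights = heights + rng.normal(0.0, config.height_noise_sd, size=len(visits))
        series.append(GrowthSeries(pid, visits.copy(), heights))

        min_age = APHV_MIN_AGE[sex]
        pubertal = fine > min_age
        peak_age = float(fine[pubertal][np.argmax(v_fine[pubertal])])
        envelope = ref.mean_at(fine) + 2.0 * ref.sd_at(fine)
        above = np.where((v_fine > envelope) & (fine >= 2.0) & (fine <= peak_age))[0]
        takeoff_age = float(fine[above[0]]) if len(above) else np.nan
        truth_rows.append(
            {
                "participant_id": pid,
                "sex": sex,
                "true_aphv": peak_age,
                "true_takeoff": takeoff_age,
                "aphv_param": float(aphv),
                "baseline_v0": float(v0),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("participant_id")
    return series, ref, truth


# ---------------------------------------------------------------------------
# microbiota


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def composition_for_maturation(m: np.ndarray) -> np.ndarray:
    """Log-space interpolation between child and adult compositions,
    renormalized (softmax over interpolated logits)."""
    m = np.atleast_1d(np.asarray(m, dtype=float))[:, None]
    logits = (1.0 - m) * np.log(CHILD_COMPOSITION) + m * np.log(ADULT_COMPOSITION)
    comp = np.exp(logits)
    return comp / comp.sum(axis=1, keepdims=True)


def _dirichlet_multinomial(
    rng: np.random.Generator, depth: int, composition: np.ndarray, theta: float
) -> np.ndarray:
    if np.isinf(theta):
        return rng.multinomial(depth, composition)
    p = rng.dirichlet(theta * composition)
    return rng.multinomial(depth, p)


def generate_microbiota(
    config: ScenarioConfig,
    time_from_peak: pd.Series,
    sex: str,
    rng: np.random.Generator,
) -> tuple[CountTable, CountTable, Taxonomy, pd.DataFrame]:
    """Adolescent counts along the maturation gradient plus an adult panel
    drawn at maturation m = 1.

    ``time_from_peak`` is indexed by adolescent sample id. Ground truth
    records each adolescent's maturation m.
    """
    config.validate()
    beta = config.maturation_slope[sex]
    tfp = time_from_peak.astype(float)
    eps = rng.normal(0.0, config.maturation_noise_sd, size=len(tfp))
    m = _logistic(beta * tfp.to_numpy() + eps)
    comps = composition_for_maturation(m)
    depths = np.maximum(
        rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=len(tfp)), 1000
    ).astype(int)
    counts = np.vstack(
        [
            _dirichlet_multinomial(rng, d, c, config.overdispersion_theta)
            for d, c in zip(depths, comps)
        ]
    )
    ados = CountTable(pd.DataFrame(counts, index=list(tfp.index), columns=taxon_ids()))

    adult_ids = [f"A{sex[0].upper()}{i:03d}" for i in range(config.n_adults_per_sex)]
    adult_comp = composition_for_maturation(np.array([1.0]))[0]
    adult_depths = np.maximum(
        rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=len(adult_ids)), 1000
    ).astype(int)
    adult_counts = np.vstack(
        [
            _dirichlet_multinomial(rng, d, adult_comp, config.overdispersion_theta)
            for d in adult_depths
        ]
    )
    adults = CountTable(pd.DataFrame(adult_counts, index=adult_ids, columns=taxon_ids()))
    truth = pd.DataFrame(
        {"maturation_m": m, "time_from_peak": tfp.to_numpy()}, index=tfp.index
    ).rename_axis("sample_id")
    return ados, adults, build_taxonomy(), truth


# ---------------------------------------------------------------------------
# metadata and exposures


def generate_metadata(
    config: ScenarioConfig,
    sex: str,
    n: int,
    rng: np.random.Generator,
    participant_ids: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, list[AntibioticRecord], pd.DataFrame]:
    """Covariates, antibiotic purchase histories and the planted
    exposure -> APHV shift (ground truth)."""
    if participant_ids is None:
        prefix = "G" if sex == "female" else "B"
        participant_ids = [f"{prefix}{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "participant_id": participant_ids,
            "sex": sex,
            "age_at_sampling": config.sampling_age,
            "bmi": rng.normal(config.bmi_mean[sex], config.bmi_sd, size=n),
            "probiotic_arm": np.where(
                rng.random(n) < config.probiotic_prob, "active", "placebo"
            ),
            "whole_grain_intake": rng.gamma(
                config.whole_grain_shape, config.whole_grain_scale, size=n
            ),
            "flatulence": rng.random(n) < config.flatulence_prob,
            "cohort": "adolescent",
        },
        index=pd.Index(participant_ids, name="sample_id"),
    )

    records: list[AntibioticRecord] = []
    ceph_ddd10 = np.zeros(n)
    for i, pid in enumerate(participant_ids):
        for cls in DRUG_CLASSES:
            rate = config.antibiotic_rate[cls]
            n_courses = rng.poisson(rate * config.sampling_age)
            ages = np.sort(rng.uniform(0.0, config.sampling_age, size=n_courses))
            for age in ages:
                ddd = float(rng.lognormal(config.ddd_log_mean, config.ddd_log_sd))
                records.append(AntibioticRecord(pid, float(age), cls, ddd))
                if cls == "cephalosporin_1_2" and age < 10.0:
                    ceph_ddd10[i] += ddd
    # centered on the expected exposure so the planted effect perturbs APHV
    # around its distributional mean instead of shifting the whole cohort
    expected_ceph10 = (
        config.antibiotic_rate["cephalosporin_1_2"]
        * min(10.0, config.sampling_age)
        * float(np.exp(config.ddd_log_mean + config.ddd_log_sd**2 / 2.0))
    )
    aphv_shift = -config.cephalosporin_effect * (ceph_ddd10 - expected_ceph10)
    truth = pd.DataFrame(
        {
            "ceph_ddd_to_10": ceph_ddd10,
            "aphv_shift": aphv_shift,
            "planted_cephalosporin_effect": config.cephalosporin_effect,
        },
        index=pd.Index(participant_ids, name="participant_id"),
    )
    return meta, records, truth


# ---------------------------------------------------------------------------
# full cohort


@dataclass
class Cohort:
    """Everything one scenario run produces, with ground truth attached."""

    config: ScenarioConfig
    sex: str
    metadata: pd.DataFrame
    antibiotic_records: list[AntibioticRecord]
    growth: list[GrowthSeries]
    reference: ReferenceVelocityCurve
    adolescent_counts: CountTable
    adult_counts: CountTable
    taxonomy: Taxonomy
    ground_truth: pd.DataFrame  # per participant

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from . import tables_io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = self.sex
        paths = {
            "metadata": out / f"metadata_{tag}.tsv",
            "antibiotics": out / f"antibiotics_{tag}.tsv",
            "growth": out / f"growth_{tag}.tsv",
            "reference": out / f"reference_curve_{tag}.tsv",
            "counts": out / f"counts_{tag}.tsv",
            "adults": out / f"adults_{tag}.tsv",
            "taxonomy": out / f"taxonomy_{tag}.tsv",
            "ground_truth": out / f"ground_truth_{tag}.tsv",
        }
        tables_io.write_metadata(self.metadata, paths["metadata"])
        tables_io.write_antibiotic_records(self.antibiotic_records, paths["antibiotics"])
        tables_io.write_growth_records(self.growth, paths["growth"])
        self.reference.to_tsv(paths["reference"])
        self.adolescent_counts.to_tsv(paths["counts"])
        self.adult_counts.to_tsv(paths["adults"])
        self.taxonomy.to_tsv(paths["taxonomy"])
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t")
        return paths


def generate_cohort(config: ScenarioConfig, sex: str, seed: int | None = None) -> Cohort:
    """End-to-end generation for one sex: metadata (with planted exposure
    effects shifting APHV), growth curves, and microbiota tied to the TRUE
    time from peak at sampling."""
    config.validate()
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence([seed, 0 if sex == "female" else 1])
    meta_rng, growth_rng, micro_rng = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    n = config.n_girls if sex == "female" else config.n_boys
    meta, records, exp_truth = generate_metadata(config, sex, n, meta_rng)

    lo = config.aphv_mean[sex] - config.aphv_truncation_sd * config.aphv_sd
    hi = config.aphv_mean[sex] + config.aphv_truncation_sd * config.aphv_sd
    aphv_base = np.clip(
        growth_rng.normal(config.aphv_mean[sex], config.aphv_sd, size=n), lo, hi
    )
    # keep the shifted spurt inside the visit schedule so it stays detectable
    aphv = np.clip(
        aphv_base + exp_truth["aphv_shift"].to_numpy(),
        APHV_MIN_AGE[sex] + 0.6,
        config.visit_end - 0.3,
    )
    growth, ref, growth_truth = generate_growth(
        config, sex, n, growth_rng, aphv_true=aphv, participant_ids=list(meta.index)
    )

    true_tfp = pd.Series(
        config.sampling_age - growth_truth["true_aphv"].to_numpy(),
        index=meta.index,
        name="true_time_from_peak",
    )
    ados, adults, taxonomy, micro_truth = generate_microbiota(
        config, true_tfp, sex, micro_rng
    )

    truth = growth_truth.join(exp_truth).join(
        micro_truth.rename_axis("participant_id"), how="left"
    )
    truth["true_time_from_peak"] = true_tfp
    truth["maturation_slope"] = config.maturation_slope[sex]
    return Cohort(
        config=config,
        sex=sex,
        metadata=meta,
        antibiotic_records=records,
        growth=growth,
        reference=ref,
        adolescent_counts=ados,
        adult_counts=adults,
        taxonomy=taxonomy,
        ground_truth=truth,
    )
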