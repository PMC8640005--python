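"""Pubertal timing from longitudinal growth data.

Velocities come from greedy chronological thinning of height measurements
(each interval >= 0.5 y). Take-off is the first velocity exceeding the
age- and sex-specific reference mean + 2 SD that is followed by sustained
acceleration; APHV is the maximal velocity after a sex-specific minimum
age (8 y girls, 9 y boys). Missing take-off is imputed as APHV - 0.5 y.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tables_io import GrowthSeries, TableValidationError

MIN_INTERVAL_YEARS = 0.5
APHV_MIN_AGE = {"female": 8.0, "male": 9.0}

STAGE_GROUPS = ("pre_takeoff", "pre_peak", "peak", "post_peak_lt2y", "post_peak_gt2y")


@dataclass(frozen=True)
class VelocityPoint:
    age: float  # interval midpoint, years
    velocity: float  # cm / year
    interval: tuple[float, float]

    def __post_init__(self):
        start, end = self.interval
        if end - start < MIN_INTERVAL_YEARS - 1e-12:
            raise ValueError(f"velocity interval shorter than {MIN_INTERVAL_YEARS} y")
        if not np.isfinite(self.velocity):
            raise ValueError("non-finite velocity")


@dataclass
class ReferenceVelocityCurve:
    """Age-gridded mean and SD of prepubertal growth velocity for one sex;
    evaluated by linear interpolation."""

    sex: str
    ages: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("reference age grid must be strictly increasing")
        if np.any(self.sd <= 0):
            raise ValueError("reference SD must be positive everywhere")
        if self.ages[0] > 2.0 or self.ages[-1] < 18.0:
            raise ValueError("reference age grid must cover [2, 18] years")

    def mean_at(self, age) -> np.ndarray:
        return np.interp(age, self.ages, self.mean)

    def sd_at(self, age) -> np.ndarray:
        return np.interp(age, self.ages, self.sd)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sex": self.sex, "age": self.ages, "mean_velocity": self.mean, "sd_velocity": self.sd}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sex: str) -> "ReferenceVelocityCurve":
        df = pd.read_csv(path, sep="\t")
        df = df[df["sex"] == sex].sort_values("age")
        if df.empty:
            raise ValueError(f"no reference rows for sex '{sex}' in {path}")
        return cls(sex, df["age"].to_numpy(), df["mean_velocity"].to_numpy(), df["sd_velocity"].to_numpy())


@dataclass
class PubertalTiming:
    participant_id: str
    takeoff_age: float
    aphv: float
    takeoff_imputed: bool
    sampling_age: float
    time_from_takeoff: float
    time_from_peak: float
    stage_group: str

    def __post_init__(self):
        if self.takeoff_imputed and abs(self.takeoff_age - (self.aphv - 0.5)) > 1e-12:
            raise ValueError("imputed take-off must equal APHV - 0.5 exactly")
        if self.takeoff_age > self.aphv + 1e-12:
            raise ValueError("take-off must not be later than APHV")


def compute_velocities(series: GrowthSeries) -> list[VelocityPoint]:
    """Greedy chronological thinning: from the first measurement, pair each
    anchor with the next measurement at least 0.5 y later. Returns [] when
    fewer than two retained measurements remain."""
    points: list[VelocityPoint] = []
    i = 0
    n = len(series)
    while i < n - 1:
        j = i + 1
        while j < n and series.ages[j] - series.ages[i] < MIN_INTERVAL_YEARS - 1e-12:
            j += 1
        if j >= n:
            break
        da = series.ages[j] - series.ages[i]
        dh = series.heights[j] - series.heights[i]
        points.append(
            VelocityPoint(
                age=(series.ages[i] + series.ages[j]) / 2.0,
                velocity=dh / da,
                interval=(series.ages[i], series.ages[j]),
            )
        )
        i = j
    return points


def detect_takeoff(
    velocities: Sequence[VelocityPoint],
    reference: ReferenceVelocityCurve,
) -> Optional[float]:
    """Earliest velocity above reference mean + 2 SD that is followed by
    sustained acceleration: the series maximum lies at or after the
    crossing, and every point between crossing and maximum stays above
    mean + 1 SD. Returns None when no crossing qualifies."""
    if not velocities:
        return None
    ages = np.array([p.age for p in velocities])
    vels = np.array([p.velocity for p in velocities])
    mean = reference.mean_at(ages)
    sd = reference.sd_at(ages)
    # the pubertal peak: maximal velocity after the sex-specific minimum age
    # (the prepubertal baseline is typically highest at the youngest ages)
    min_age = APHV_MIN_AGE.get(reference.sex)
    eligible = np.where(ages > min_age)[0] if min_age is not None else np.arange(len(ages))
    if len(eligible) == 0:
        eligible = np.arange(len(ages))
    peak_idx = int(eligible[np.argmax(vels[eligible])])  # earliest maximum on ties
    for i, point in enumerate(velocities):
        if vels[i] <= mean[i] + 2.0 * sd[i]:
            continue
        if peak_idx < i:
            continue
        # "followed by a period of accelerated growth": when later points
        # exist, the next velocity must itself sit above mean + 1 SD (an
        # isolated spike followed by a lull fails here)
        if i + 1 < len(velocities) and vels[i + 1] <= mean[i + 1] + sd[i + 1]:
            continue
        between = slice(i, peak_idx + 1)
        if np.all(vels[between] > mean[between] + sd[between]):
            return float(point.age)
    return None


def detect_aphv(velocities: Sequence[VelocityPoint], sex: str) -> Optional[float]:
    """Midpoint age of the maximal velocity among points after the
    sex-specific minimum age; ties break to the earliest age."""
    min_age = APHV_MIN_AGE[sex]
    eligible = [p for p in velocities if p.age > min_age]
    if not eligible:
        return None
    best = max(eligible, key=lambda p: (p.velocity, -p.age))
    return float(best.age)


def assign_stage(time_from_takeoff: float, time_from_peak: float) -> str:
    """Partition the time axis into the five pubertal stage groups.
    Boundaries: -0.25 inclusive toward peak, +0.5 inclusive to peak,
    +2.0 inclusive to the earlier group."""
    if time_from_takeoff < 0:
        return "pre_takeoff"
    if time_from_peak < -0.25:
        return "pre_peak"
    if time_from_peak <= 0.5:
        return "peak"
    if time_from_peak <= 2.0:
        return "post_peak_lt2y"
    return "post_peak_gt2y"


def finalize_timing(
    participant_id: str,
    takeoff: Optional[float],
    aphv: Optional[float],
    sampling_age: float,
) -> PubertalTiming:
    """Derive the timing variables; impute a missing take-off as
    APHV - 0.5 y. Participants without APHV are undeterminable."""
    if aphv is None:
        raise TableValidationError(f"{participant_id}: timing undeterminable (no APHV)")
    imputed = takeoff is None
    if imputed:
        takeoff = aphv - 0.5
    time_from_takeoff = sampling_age - takeoff
    time_from_peak = sampling_age - aphv
    return PubertalTiming(
        participant_id=participant_id,
        takeoff_age=float(takeoff),
        aphv=float(aphv),
        takeoff_imputed=imputed,
        sampling_age=float(sampling_age),
        time_from_takeoff=float(time_from_takeoff),
        time_from_peak=float(time_from_peak),
        stage_group=assign_stage(time_from_takeoff, time_from_peak),
    )


def timing_for_cohort(
    growth: Sequence[GrowthSeries],
    reference_by_sex: dict[str, ReferenceVelocityCurve],
    sex_by_participant: dict[str, str],
    sampling_age_by_participant: dict[str, float],
) -> pd.DataFrame:
    """Run the full timing chain per participant; participants without a
    detectable APHV are reported with NaNs and excluded from stage groups."""
    rows = []
    for series in growth:
        pid = series.participant_id
        sex = sex_by_participant[pid]
        sampling_age = sampling_age_by_participant[pid]
        vels = compute_velocities(series)
        aphv = detect_aphv(vels, sex)
        takeoff = detect_takeoff(vels, reference_by_sex[sex])
        if takeoff is not None and aphv is not None and takeoff > aphv:
            # spurious early crossing after the retained peak: treat as absent
            takeoff = None
        if aphv is None:
            rows.append(
                {
                    "participant_id": pid, "sex": sex, "takeoff_age": np.nan,
                    "aphv": np.nan, "takeoff_imputed": False,
                    "sampling_age": sampling_age, "time_from_takeoff": np.nan,
                    "time_from_peak": np.nan, "stage_group": "",
                    "aphv_below_envelope": False,
                }
            )
            continue
        timing = finalize_timing(pid, takeoff, aphv, sampling_age)
        ref = reference_by_sex[sex]
        peak_vel = max(
            (p.velocity for p in vels if p.age == timing.aphv), default=np.nan
        )
        below = bool(peak_vel <= ref.mean_at(timing.aphv) + ref.sd_at(timing.aphv))
        rows.append(
            {
                "participant_id": pid, "sex": sex,
                "takeoff_age": timing.takeoff_age, "aphv": timing.aphv,
                "takeoff_imputed": timing.takeoff_imputed,
                "sampling_age": sampling_age,
                "time_from_takeoff": timing.time_from_takeoff,
                "time_from_peak": timing.time_from_peak,
                "stage_group": timing.stage_group,
                "aphv_below_envelope": below,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def write_timing(timing: pd.DataFrame, path: str | Path) -> None:
    timing.to_csv(path, sep="\t", index_label="participant_id")


def read_timing(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="participant_id", dtype={"participant_id": str})
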