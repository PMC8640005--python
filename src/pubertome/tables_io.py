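"""Data model and TSV readers/writers for count tables, taxonomy, metadata,
growth records and antibiotic records.

All on-disk formats are tab-separated text with a header row. Count tables
default to samples-in-rows; the orientation is an explicit flag, never
guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: sentinel for a missing rank in a lineage
UNKNOWN = ""

_NA_STRINGS = {"", "na", "nan", "none", "unknown", "unclassified"}


class TableValidationError(ValueError):
    """Raised when a table violates a hard invariant."""


@dataclass
class ValidationReport:
    """Structured outcome of table validation: warnings are tolerated,
    errors are fatal."""

    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> None:
        self.warnings.extend(other.warnings)
        self.errors.extend(other.errors)


class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    Wraps a pandas DataFrame (rows = samples, columns = taxa). Duplicate
    sample or taxon identifiers and non-integral or negative entries are
    hard errors.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if validate:
            report = _validate_counts(data)
            if not report.ok:
                raise TableValidationError("; ".join(report.errors))
        self._data = data.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample (row sums)."""
        return self._data.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._data.shape[1]

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._data.equals(other._data)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self._data.loc[list(sample_ids)], validate=False)

    def validation_report(self) -> ValidationReport:
        report = _validate_counts(self._data)
        empty = [t for t in self.taxon_ids if self._data[t].sum() == 0]
        for t in empty:
            report.warnings.append(f"taxon '{t}' has zero total count (retained)")
        zero_depth = [s for s in self.sample_ids if self._data.loc[s].sum() == 0]
        for s in zero_depth:
            report.warnings.append(f"sample '{s}' has zero depth")
        return report

    # -- transforms --------------------------------------------------------
    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalize counts to proportions. Zero-depth samples are a
        hard error (named)."""
        depths = self.depths
        zero = depths[depths == 0]
        if len(zero):
            raise TableValidationError(
                "zero-depth sample(s): " + ", ".join(map(str, zero.index))
            )
        return self._data.div(depths, axis=0)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path, samples_in_rows: bool = True) -> None:
        df = self._data if samples_in_rows else self._data.T
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, samples_in_rows: bool = True) -> "CountTable":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if not samples_in_rows:
            raw = raw.T
        parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
        for col in raw.columns:
            for idx, value in raw[col].items():
                sample, taxon = (idx, col) if samples_in_rows else (idx, col)
                try:
                    as_float = float(value)
                except (TypeError, ValueError):
                    raise TableValidationError(
                        f"non-numeric count '{value}' at sample '{sample}', taxon '{taxon}'"
                    ) from None
                if not float(as_float).is_integer():
                    raise TableValidationError(
                        f"non-integer count '{value}' at sample '{sample}', taxon '{taxon}'"
                    )
                parsed.loc[idx, col] = int(as_float)
        return cls(parsed)


def _validate_counts(data: pd.DataFrame) -> ValidationReport:
    report = ValidationReport()
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique()
        report.errors.append("duplicated sample ids: " + ", ".join(map(str, dups)))
    if data.columns.has_duplicates:
        dups = data.columns[data.columns.duplicated()].unique()
        report.errors.append("duplicated taxon ids: " + ", ".join(map(str, dups)))
    values = data.to_numpy()
    if values.size:
        if not np.issubdtype(values.dtype, np.integer):
            frac = values.astype(float) - np.floor(values.astype(float))
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                report.errors.append(
                    f"non-integer count at sample '{data.index[i]}', taxon '{data.columns[j]}'"
                )
        if np.any(values.astype(float) < 0):
            i, j = np.argwhere(values.astype(float) < 0)[0]
            report.errors.append(
                f"negative count at sample '{data.index[i]}', taxon '{data.columns[j]}'"
            )
    return report


class Taxonomy:
    """taxon_id -> ranked lineage (kingdom..species); missing ranks are
    explicit empty strings."""

    def __init__(self, lineages: pd.DataFrame):
        missing = [r for r in RANKS if r not in lineages.columns]
        if missing:
            raise TableValidationError(f"taxonomy missing rank columns: {missing}")
        if lineages.index.has_duplicates:
            raise TableValidationError("duplicated taxon ids in taxonomy")
        df = lineages[list(RANKS)].copy()
        for rank in RANKS:
            df[rank] = df[rank].map(_normalize_rank_value)
        self._df = df

    @property
    def data(self) -> pd.DataFrame:
        return self._df

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.index)

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        return tuple(self._df.loc[taxon_id, list(RANKS)])

    def check_covers(self, table: CountTable) -> None:
        missing = [t for t in table.taxon_ids if t not in self._df.index]
        if missing:
            raise TableValidationError(
                "taxa without taxonomy entry: " + ", ".join(missing)
            )

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index_label="taxon_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        return cls(df)


def _normalize_rank_value(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return UNKNOWN
    text = str(value).strip()
    if text.lower() in _NA_STRINGS:
        return UNKNOWN
    return text


def read_count_table(
    path: str | Path, taxonomy_path: str | Path, samples_in_rows: bool = True
) -> tuple[CountTable, Taxonomy, ValidationReport]:
    """Read and cross-validate a count table and its taxonomy."""
    table = CountTable.from_tsv(path, samples_in_rows=samples_in_rows)
    taxonomy = Taxonomy.from_tsv(taxonomy_path)
    taxonomy.check_covers(table)
    return table, taxonomy, table.validation_report()


def aggregate(table: CountTable, taxonomy: Taxonomy, rank: str) -> tuple[CountTable, Taxonomy]:
    """Sum counts of taxa sharing the lineage prefix down to ``rank``.

    Taxa with an unknown value at ``rank`` collapse into one
    ``unclassified_<parent>`` bucket per parent lineage, so per-sample depth
    is conserved exactly. Returns the aggregated table plus a derived
    taxonomy truncated at ``rank``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank '{rank}'; expected one of {RANKS}")
    taxonomy.check_covers(table)
    rank_idx = RANKS.index(rank)

    groups: dict[tuple[str, ...], list[str]] = {}
    for taxon in table.taxon_ids:
        lineage = list(taxonomy.lineage(taxon)[: rank_idx + 1])
        if lineage[rank_idx] == UNKNOWN:
            parent = next(
                (v for v in reversed(lineage[:rank_idx]) if v != UNKNOWN), "root"
            )
            lineage[rank_idx] = f"unclassified_{parent}"
        groups.setdefault(tuple(lineage), []).append(taxon)

    labels = _disambiguate_labels(list(groups))
    agg = pd.DataFrame(
        {
            label: table.data[members].sum(axis=1)
            for label, members in zip(labels, groups.values())
        },
        index=table.data.index,
    )
    lineage_rows = {}
    for label, prefix in zip(labels, groups):
        row = dict.fromkeys(RANKS, UNKNOWN)
        for r, v in zip(RANKS[: rank_idx + 1], prefix):
            row[r] = v
        row[rank] = label  # label may carry a disambiguating suffix
        lineage_rows[label] = row
    derived = Taxonomy(pd.DataFrame.from_dict(lineage_rows, orient="index"))
    return CountTable(agg), derived


def _disambiguate_labels(prefixes: list[tuple[str, ...]]) -> list[str]:
    base = [p[-1] for p in prefixes]
    labels = []
    for i, name in enumerate(base):
        if base.count(name) > 1:
            parent = next((v for v in reversed(prefixes[i][:-1]) if v), "root")
            labels.append(f"{name}__{parent}")
        else:
            labels.append(name)
    return labels


def relative_abundance(table: CountTable) -> pd.DataFrame:
    return table.relative_abundance()


# ---------------------------------------------------------------------------
# sample metadata


REQUIRED_METADATA = ("participant_id", "sex", "age_at_sampling", "cohort")
SEXES = ("female", "male")
COHORTS = ("adolescent", "adult_reference")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample metadata frame (indexed by sample_id)."""
    for col in REQUIRED_METADATA:
        if col not in meta.columns:
            raise TableValidationError(f"metadata missing required column '{col}'")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise TableValidationError(f"invalid sex values: {sorted(bad_sex)}")
    bad_cohort = set(meta["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise TableValidationError(f"invalid cohort values: {sorted(bad_cohort)}")
    ages = pd.to_numeric(meta["age_at_sampling"])
    if (ages <= 0).any():
        bad = meta.index[ages <= 0].tolist()
        raise TableValidationError(f"non-positive age_at_sampling for samples {bad}")
    if meta.index.has_duplicates:
        raise TableValidationError("duplicated sample ids in metadata")
    out = meta.copy()
    out["age_at_sampling"] = ages
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# growth records


@dataclass
class GrowthSeries:
    """Longitudinal (age, height) measurements for one participant,
    sorted by age."""

    participant_id: str
    ages: np.ndarray  # years, strictly increasing
    heights: np.ndarray  # cm, > 0

    #: tolerance (cm) below which a height decrease is treated as noise
    SHRINK_TOLERANCE = 1.0

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.ages.shape != self.heights.shape:
            raise TableValidationError(
                f"{self.participant_id}: ages and heights differ in length"
            )
        if np.any(np.diff(self.ages) <= 0):
            raise TableValidationError(
                f"{self.participant_id}: ages not strictly increasing"
            )
        if np.any(self.heights <= 0):
            raise TableValidationError(f"{self.participant_id}: non-positive height")

    def __len__(self) -> int:
        return len(self.ages)

    def shrink_flags(self) -> list[str]:
        """Flag (not fail) height decreases beyond measurement noise."""
        drops = np.diff(self.heights)
        flags = []
        for i in np.where(drops < -self.SHRINK_TOLERANCE)[0]:
            flags.append(
                f"{self.participant_id}: height drops {-drops[i]:.1f} cm "
                f"between ages {self.ages[i]:.2f} and {self.ages[i + 1]:.2f}"
            )
        return flags


def read_growth_records(path: str | Path) -> list[GrowthSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    series = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("age")
        series.append(
            GrowthSeries(str(pid), grp["age"].to_numpy(), grp["height"].to_numpy())
        )
    return series


def write_growth_records(series: Iterable[GrowthSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for age, height in zip(s.ages, s.heights):
            rows.append({"participant_id": s.participant_id, "age": age, "height": height})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# antibiotic purchase records


DRUG_CLASSES = ("cephalosporin_1_2", "macrolide", "penicillin", "other")


@dataclass(frozen=True)
class AntibioticRecord:
    participant_id: str
    age_at_purchase: float  # years
    drug_class: str
    ddd: float  # defined daily doses

    def __post_init__(self):
        if self.ddd <= 0:
            raise TableValidationError(
                f"{self.participant_id}: ddd must be positive, got {self.ddd}"
            )
        if self.age_at_purchase < 0:
            raise TableValidationError(
                f"{self.participant_id}: negative age_at_purchase"
            )
        if self.drug_class not in DRUG_CLASSES:
            raise TableValidationError(
                f"{self.participant_id}: unknown drug class '{self.drug_class}'"
            )


def read_antibiotic_records(path: str | Path) -> list[AntibioticRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    return [
        AntibioticRecord(
            str(r.participant_id), float(r.age_at_purchase), str(r.drug_class), float(r.ddd)
        )
        for r in df.itertuples()
    ]


def write_antibiotic_records(records: Iterable[AntibioticRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "age_at_purchase": r.age_at_purchase,
                "drug_class": r.drug_class,
                "ddd": r.ddd,
            }
            for r in records
        ],
        columns=["participant_id", "age_at_purchase", "drug_class", "ddd"],
    ).to_csv(path, sep="\t", index=False)
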