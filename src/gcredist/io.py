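"""Death-certificate microdata schema, parsing, validation and reference tables.

The microdata model is one row per certified death: year, completed age,
sex, a free-form region stratifier, the ICD-10 underlying cause (UC), and
zero or more multiple-causes-of-death (MCOD) entries, each tagged with its
role on the certificate (immediate, intermediate or associated).  Records
arrive either as a single wide table (``mcod_1``/``mcod_role_1`` ... columns)
or as a deaths table plus a long companion table keyed by record id.

Reference inputs — a residual-life-expectancy life table, standard
populations on five-year age groups, and mid-year population counts — are
plain two/three-column CSV files.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
MCOD_ROLES = ("immediate", "intermediate", "associated")

#: codes identifying stillbirths, excluded from all analyses
DEFAULT_STILLBIRTH_CODES = frozenset({"P95"})

MAX_AGE = 122

_ICD_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]?$")


class ValidationError(ValueError):
    """Raised for malformed codes, tables or configuration."""


def normalize_icd(raw: str) -> str:
    """Normalize an ICD-10 code to its dotless, uppercase 3–4 character form.

    ``"I50.9" -> "I509"``, ``"r99" -> "R99"``.  Codes longer than four
    characters after dot removal are truncated to four.  Idempotent.

    Raises
    ------
    ValidationError
        If the input is empty or does not conform to the
        letter + two digits + optional alphanumeric pattern.
    """
    if raw is None:
        raise ValidationError("empty ICD-10 code")
    code = str(raw).strip().upper().replace(".", "")[:4]
    if not code:
        raise ValidationError("empty ICD-10 code")
    if not _ICD_PATTERN.match(code):
        raise ValidationError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclass
class DeathRecord:
    """One certified death.

    ``age`` and ``sex`` may be ``None`` on input; such records are removed by
    :func:`validate_records`.  Ages above 122 are clamped to 122 (the upper
    anchor of the reference life table) with a logged warning.
    """

    record_id: str
    year: int
    age: int | None
    sex: str | None
    region: str
    underlying_cause: str
    mcod: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(
                f"record {self.record_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.age is not None:
            self.age = int(self.age)
            if self.age < 0:
                raise ValidationError(f"record {self.record_id}: negative age")
            if self.age > MAX_AGE:
                logger.warning(
                    "record %s: age %d clamped to %d", self.record_id, self.age, MAX_AGE
                )
                self.age = MAX_AGE
        for _, role in self.mcod:
            if role not in MCOD_ROLES:
                raise ValidationError(
                    f"record {self.record_id}: unknown MCOD role {role!r}"
                )


@dataclass
class ReaderDialect:
    """Column roles and MCOD layout of a microdata file.

    ``mcod_layout`` is ``"wide"`` (``mcod_1``, ``mcod_role_1``, ... columns in
    the deaths file) or ``"long"`` (companion table with columns
    ``record_id``, ``code``, ``role``).
    """

    record_id: str = "record_id"
    year: str = "year"
    age: str = "age"
    sex: str = "sex"
    region: str = "region"
    underlying_cause: str = "underlying_cause"
    mcod_layout: str = "wide"
    mcod_code_prefix: str = "mcod_"
    mcod_role_prefix: str = "mcod_role_"
    mcod_record_id: str = "record_id"
    mcod_code: str = "code"
    mcod_role: str = "role"
    delimiter: str = ","
    sex_values: Mapping[str, str] = field(
        default_factory=lambda: {
            "male": "male", "female": "female", "m": "male", "f": "female",
            "1": "male", "2": "female",
        }
    )


def _parse_sex(value: str, dialect: ReaderDialect) -> str | None:
    v = value.strip().lower()
    if not v:
        return None
    if v not in dialect.sex_values:
        raise ValidationError(f"unknown sex value {value!r}")
    return dialect.sex_values[v]


def read_death_records(
    path: str | Path,
    dialect: ReaderDialect | None = None,
    mcod_path: str | Path | None = None,
) -> list[DeathRecord]:
    """Read a delimited microdata file into :class:`DeathRecord` objects.

    Row order is preserved and all ICD codes are normalized on read.  With a
    long MCOD layout, ``mcod_path`` names the companion table; entries keep
    the order in which they appear there.

    Raises
    ------
    ValidationError
        For unknown columns, or unparseable age/year values (the error
        message lists the offending row numbers).
    """
    dialect = dialect or ReaderDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    required = [dialect.record_id, dialect.year, dialect.age, dialect.sex,
                dialect.region, dialect.underlying_cause]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    mcod_by_id: dict[str, list[tuple[str, str]]] = {}
    wide_pairs: list[tuple[str, str]] = []
    if dialect.mcod_layout == "long" and mcod_path is not None:
        mdf = pd.read_csv(mcod_path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
        for col in (dialect.mcod_record_id, dialect.mcod_code, dialect.mcod_role):
            if col not in mdf.columns:
                raise ValidationError(f"{mcod_path}: missing column {col!r}")
        for rid, code, role in zip(
            mdf[dialect.mcod_record_id], mdf[dialect.mcod_code], mdf[dialect.mcod_role]
        ):
            mcod_by_id.setdefault(rid, []).append((normalize_icd(code), role))
    elif dialect.mcod_layout == "wide":
        k = 1
        while f"{dialect.mcod_code_prefix}{k}" in df.columns:
            wide_pairs.append(
                (f"{dialect.mcod_code_prefix}{k}", f"{dialect.mcod_role_prefix}{k}")
            )
            k += 1

    records: list[DeathRecord] = []
    bad_rows: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            year = int(row[dialect.year])
            age_raw = row[dialect.age].strip()
            age = int(age_raw) if age_raw else None
        except (ValueError, TypeError):
            bad_rows.append(i + 2)  # 1-based + header line
            continue
        rid = row[dialect.record_id]
        mcod: list[tuple[str, str]] = []
        for ccol, rcol in wide_pairs:
            code = row.get(ccol, "").strip()
            if not code:
                continue
            role = row.get(rcol, "").strip() or "associated"
            mcod.append((normalize_icd(code), role))
        if mcod_by_id:
            mcod.extend(mcod_by_id.get(rid, []))
        records.append(
            DeathRecord(
                record_id=rid,
                year=year,
                age=age,
                sex=_parse_sex(row[dialect.sex], dialect),
                region=row[dialect.region],
                underlying_cause=normalize_icd(row[dialect.underlying_cause]),
                mcod=mcod,
            )
        )
    if bad_rows:
        raise ValidationError(f"{path}: unparseable age/year in row(s) {bad_rows}")
    return records


def write_death_records(
    records: Sequence[DeathRecord],
    path: str | Path,
    dialect: ReaderDialect | None = None,
    mcod_path: str | Path | None = None,
) -> None:
    """Write records as delimited file(s); inverse of :func:`read_death_records`."""
    dialect = dialect or ReaderDialect()
    rows = []
    for r in records:
        rows.append({
            dialect.record_id: r.record_id,
            dialect.year: r.year,
            dialect.age: "" if r.age is None else r.age,
            dialect.sex: "" if r.sex is None else r.sex,
            dialect.region: r.region,
            dialect.underlying_cause: r.underlying_cause,
        })
    df = pd.DataFrame(rows, columns=[
        dialect.record_id, dialect.year, dialect.age, dialect.sex,
        dialect.region, dialect.underlying_cause,
    ])
    if dialect.mcod_layout == "wide":
        width = max((len(r.mcod) for r in records), default=0)
        for k in range(1, width + 1):
            df[f"{dialect.mcod_code_prefix}{k}"] = [
                r.mcod[k - 1][0] if len(r.mcod) >= k else "" for r in records
            ]
            df[f"{dialect.mcod_role_prefix}{k}"] = [
                r.mcod[k - 1][1] if len(r.mcod) >= k else "" for r in records
            ]
        df.to_csv(path, sep=dialect.delimiter, index=False)
    elif dialect.mcod_layout == "long":
        df.to_csv(path, sep=dialect.delimiter, index=False)
        mrows = [
            {dialect.mcod_record_id: r.record_id, dialect.mcod_code: c, dialect.mcod_role: role}
            for r in records for c, role in r.mcod
        ]
        if mcod_path is None:
            raise ValidationError("long MCOD layout requires mcod_path")
        pd.DataFrame(
            mrows, columns=[dialect.mcod_record_id, dialect.mcod_code, dialect.mcod_role]
        ).to_csv(mcod_path, sep=dialect.delimiter, index=False)
    else:
        raise ValidationError(f"unknown MCOD layout {dialect.mcod_layout!r}")


def validate_records(
    records: Sequence[DeathRecord],
    stillbirth_codes: frozenset[str] | set[str] = DEFAULT_STILLBIRTH_CODES,
) -> tuple[list[DeathRecord], dict[str, int]]:
    """Apply the standard exclusions and report them.

    Records with missing age or missing sex are excluded (each record is
    counted under a single reason, checked in that order), as are stillbirths
    (underlying cause in ``stillbirth_codes``, default ICD-10 P95).  Counts
    are conserved: ``len(kept) + sum(report.values()) == len(records)``.
    """
    kept: list[DeathRecord] = []
    report: dict[str, int] = {}

    def bump(reason: str) -> None:
        report[reason] = report.get(reason, 0) + 1

    sb = {normalize_icd(c) for c in stillbirth_codes}
    for r in records:
        if r.age is None:
            bump("missing_age")
        elif r.sex is None:
            bump("missing_sex")
        elif any(r.underlying_cause.startswith(c) for c in sb):
            bump("stillbirth")
        else:
            kept.append(r)
    return kept, report


def records_to_frames(records: Sequence[DeathRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten records into a deaths frame and a long MCOD frame (by position)."""
    deaths = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "year": [r.year for r in records],
        "age": [r.age for r in records],
        "sex": [r.sex for r in records],
        "region": [r.region for r in records],
        "underlying_cause": [r.underlying_cause for r in records],
    })
    mrows = [
        (i, c, role)
        for i, r in enumerate(records)
        for c, role in r.mcod
    ]
    mcod = pd.DataFrame(mrows, columns=["pos", "code", "role"])
    return deaths, mcod


# ---------------------------------------------------------------------------
# Reference tables


@dataclass(frozen=True)
class LifeTable:
    """Residual life expectancy by age; the SEYLL weight source.

    ``ages`` must be strictly increasing and expectancies non-negative.
    Monotone non-increase of the expectancies and the terminal (122, 0)
    anchor are enforced by :func:`gcredist.burden.complete_life_table`.
    """

    ages: np.ndarray
    residual_expectancy: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ex = np.asarray(self.residual_expectancy, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "residual_expectancy", ex)
        if ages.ndim != 1 or ages.shape != ex.shape or ages.size == 0:
            raise ValidationError("life table needs matching 1-d age/expectancy arrays")
        if not np.all(np.diff(ages) > 0):
            raise ValidationError("life-table ages must be strictly increasing")
        if np.any(ex < 0):
            raise ValidationError("residual life expectancy must be non-negative")
        if ages[-1] > MAX_AGE:
            raise ValidationError(f"life table extends beyond age {MAX_AGE}")

    @classmethod
    def from_csv(cls, path: str | Path, age_col: str = "age",
                 ex_col: str = "residual_expectancy") -> "LifeTable":
        df = pd.read_csv(path)
        if age_col not in df.columns or ex_col not in df.columns:
            raise ValidationError(f"{path}: expected columns {age_col!r}, {ex_col!r}")
        df = df.sort_values(age_col)
        return cls(df[age_col].to_numpy(float), df[ex_col].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "residual_expectancy": self.residual_expectancy}
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class StandardPopulation:
    """Standard population weights on five-year age groups.

    Groups are [lo, lo+5) with an open-ended terminal group; ``age_lo`` must
    start at 0 and advance in steps of five.
    """

    age_lo: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lo, dtype=int)
        w = np.asarray(self.weight, dtype=float)
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "weight", w)
        if lo.shape != w.shape or lo.size == 0:
            raise ValidationError("standard population needs matching age/weight arrays")
        if lo[0] != 0 or not np.all(np.diff(lo) == 5):
            raise ValidationError("standard population must use contiguous five-year groups from 0")
        if np.any(w <= 0):
            raise ValidationError("standard population weights must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, age_col: str = "age_lo",
                 weight_col: str = "weight") -> "StandardPopulation":
        df = pd.read_csv(path).sort_values(age_col)
        return cls(df[age_col].to_numpy(int), df[weight_col].to_numpy(float))

    def group_of(self, age: float) -> int:
        """Lower bound of the five-year group containing ``age``."""
        return int(min(5 * (int(age) // 5), self.age_lo[-1]))


@dataclass
class PopulationTable:
    """Mid-year population counts by (year, sex, region, five-year age group)."""

    counts: pd.DataFrame  # columns: year, sex, region, age_lo, population

    REQUIRED = ("year", "sex", "region", "age_lo", "population")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.counts.columns]
        if missing:
            raise ValidationError(f"population table missing column(s) {missing}")
        if (self.counts["population"] < 0).any():
            raise ValidationError("population counts must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        return cls(pd.read_csv(path))

    def total(self, year=None, sex=None, region=None) -> float:
        df = self.counts
        if year is not None:
            df = df[df["year"] == year]
        if sex is not None and sex != "all":
            df = df[df["sex"] == sex]
        if region is not None and region != "all":
            df = df[df["region"] == region]
        return float(df["population"].sum())

    def by_age(self, year=None, sex=None, region=None) -> dict[int, float]:
        df = self.counts
        if year is not None:
            df = df[df["year"] == year]
        if sex is not None and sex != "all":
            df = df[df["sex"] == sex]
        if region is not None and region != "all":
            df = df[df["region"] == region]
        g = df.groupby("age_lo")["population"].sum()
        return {int(k): float(v) for k, v in g.items()}


def write_estimates(tables: Mapping[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write result tables as CSV files ``<path>/<name>.csv``; returns the paths."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
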