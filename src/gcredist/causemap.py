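"""ICD-10 → GBD-style cause mapping and ill-defined-death classification.

The cause map assigns every underlying-cause code to a four-level cause
hierarchy (level 1 clusters: non-communicable diseases; communicable,
maternal, neonatal and nutritional diseases; injuries → level 2 groups →
level 3 causes → level 4 subcauses).  Codes that cannot be matched to a
specific level-4 cause are ill-defined deaths (IDDs, "garbage codes") and
carry one of three redistribution classes:

``icd_targeted``
    the code has a predefined list of ICD-10 target codes (e.g. C55,
    malignant neoplasm of uterus part unspecified, targets C53 and C54);
``packaged``
    the code belongs to a package of similar uninformative codes (e.g.
    "acute kidney failure" = {N19, N17.0, N17.9}) redistributed using
    multiple-causes-of-death mentions of the package codes;
``unassigned``
    no a-priori information (e.g. R99); resolved by internal or all-cause
    redistribution.

Combination rules override the underlying cause before classification; the
bundled demo map implements the EMCDDA drug-death definitions (X41/X44/X61/
X64/Y11 + T43.6 and X42/X62/Y12 + T40 → F19).

Map files live in a directory: ``entries.csv`` (required), ``packages.csv``,
``combination_rules.csv`` and ``sex_restrictions.csv`` (optional).  The demo
map under ``gcredist/data/demo_map`` is the canonical format example.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import DeathRecord, ValidationError, normalize_icd

IDD_CLASSES = ("specific", "icd_targeted", "packaged", "unassigned")
LEVEL1_CLUSTERS = ("ncd", "cmnn", "injuries")


@dataclass(frozen=True)
class CauseMapEntry:
    """One ICD-prefix row of the cause map."""

    icd_prefix: str
    idd_class: str
    gbd_l4: str | None = None
    gbd_l3: str | None = None
    gbd_l2: str | None = None
    gbd_l1: str | None = None
    target_codes: tuple[str, ...] = ()
    package_id: str | None = None

    def __post_init__(self) -> None:
        if self.idd_class not in IDD_CLASSES:
            raise ValidationError(f"{self.icd_prefix}: unknown idd_class {self.idd_class!r}")
        if (self.idd_class == "specific") != bool(self.gbd_l4):
            raise ValidationError(
                f"{self.icd_prefix}: gbd_l4 must be set exactly when idd_class is 'specific'"
            )
        if self.idd_class == "icd_targeted" and not self.target_codes:
            raise ValidationError(f"{self.icd_prefix}: icd_targeted entry with empty targets")
        if self.idd_class == "packaged" and not self.package_id:
            raise ValidationError(f"{self.icd_prefix}: packaged entry without package_id")


@dataclass(frozen=True)
class CombinationRule:
    """UC-set × MCOD-set → override UC code."""

    uc_codes: frozenset[str]
    mcod_codes: frozenset[str]
    override: str


@dataclass
class CauseMap:
    """Prefix-indexed cause map with hierarchy, packages and restrictions."""

    entries: dict[str, CauseMapEntry]
    packages: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    combination_rules: list[CombinationRule] = field(default_factory=list)
    sex_restrictions: dict[str, str] = field(default_factory=dict)  # cause_l4 -> allowed sex

    l4_to_l3: dict[str, str] = field(init=False, default_factory=dict)
    l3_to_l2: dict[str, str] = field(init=False, default_factory=dict)
    l2_to_l1: dict[str, str] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        for prefix, e in self.entries.items():
            if prefix != e.icd_prefix:
                raise ValidationError(f"entry key {prefix!r} != prefix {e.icd_prefix!r}")
            if e.idd_class != "specific":
                continue
            for child, parent, rel in (
                (e.gbd_l4, e.gbd_l3, self.l4_to_l3),
                (e.gbd_l3, e.gbd_l2, self.l3_to_l2),
                (e.gbd_l2, e.gbd_l1, self.l2_to_l1),
            ):
                if not child or not parent:
                    raise ValidationError(f"{prefix}: specific entry with incomplete hierarchy")
                if child in rel and rel[child] != parent:
                    raise ValidationError(
                        f"hierarchy is not a tree: {child!r} has parents "
                        f"{rel[child]!r} and {parent!r}"
                    )
                rel[child] = parent
            if e.gbd_l1 not in LEVEL1_CLUSTERS:
                raise ValidationError(f"{prefix}: unknown level-1 cluster {e.gbd_l1!r}")
        for prefix, e in self.entries.items():
            if e.idd_class == "packaged" and e.package_id not in self.packages:
                raise ValidationError(f"{prefix}: unknown package {e.package_id!r}")
            for t in e.target_codes:
                te = self.match(t)
                if te is None or te.idd_class != "specific":
                    raise ValidationError(
                        f"{prefix}: target code {t!r} does not resolve to a specific cause"
                    )
        for cause, sex in self.sex_restrictions.items():
            if sex not in ("male", "female"):
                raise ValidationError(f"sex restriction for {cause!r}: bad sex {sex!r}")

    # -- lookups ----------------------------------------------------------
    def match(self, code: str) -> CauseMapEntry | None:
        """Longest-prefix match: a 4-character entry shadows its 3-character parent."""
        code = normalize_icd(code)
        if len(code) == 4 and code in self.entries:
            return self.entries[code]
        return self.entries.get(code[:3])

    def specific_causes(self, level: int = 4) -> list[str]:
        if level == 4:
            return sorted(self.l4_to_l3)
        if level == 3:
            return sorted(self.l3_to_l2)
        if level == 2:
            return sorted(self.l2_to_l1)
        if level == 1:
            return sorted(set(self.l2_to_l1.values()))
        raise ValidationError(f"unknown hierarchy level {level}")

    def ancestor(self, cause_l4: str, level: int) -> str:
        """Hierarchy ancestor of a level-4 cause at the requested level."""
        if level == 4:
            return cause_l4
        l3 = self.l4_to_l3[cause_l4]
        if level == 3:
            return l3
        l2 = self.l3_to_l2[l3]
        if level == 2:
            return l2
        if level == 1:
            return self.l2_to_l1[l2]
        raise ValidationError(f"unknown hierarchy level {level}")

    def allowed_sexes(self, cause_l4: str) -> tuple[str, ...]:
        s = self.sex_restrictions.get(cause_l4)
        return (s,) if s else ("male", "female")

    def targets_as_causes(self, prefixes: Iterable[str]) -> set[str]:
        """Resolve ICD target prefixes to the level-4 causes they map to."""
        causes = set()
        for p in prefixes:
            e = self.match(p)
            if e is not None and e.idd_class == "specific":
                causes.add(e.gbd_l4)
        return causes


@dataclass(frozen=True)
class CauseAssignment:
    """Mapping outcome for one record; ``resolution_step`` is filled in later
    by redistribution (``mapped`` for originally specific causes)."""

    record_id: str
    cause_l4: str | None
    idd_class: str
    resolution_step: str | None = None


def load_cause_map(path: str | Path) -> CauseMap:
    """Load and validate a cause map from a directory of CSV files.

    ``entries.csv`` columns: icd_prefix, idd_class, gbd_l4, gbd_l3, gbd_l2,
    gbd_l1, target_codes (``;``-separated), package_id.
    ``packages.csv`` columns: package_id, name, icd_prefix (one member per row).
    ``combination_rules.csv`` columns: uc_codes, mcod_codes (``;``-separated),
    override.  ``sex_restrictions.csv`` columns: cause_l4, sex.
    """
    path = Path(path)
    entries_file = path / "entries.csv"
    if not entries_file.exists():
        raise ValidationError(f"cause map: {entries_file} not found")
    edf = pd.read_csv(entries_file, dtype=str, keep_default_na=False)

    entries: dict[str, CauseMapEntry] = {}
    for _, row in edf.iterrows():
        prefix = normalize_icd(row["icd_prefix"])
        if prefix in entries:
            raise ValidationError(f"cause map: duplicate prefix {prefix!r}")
        targets = tuple(
            normalize_icd(t) for t in row.get("target_codes", "").split(";") if t.strip()
        )
        entries[prefix] = CauseMapEntry(
            icd_prefix=prefix,
            idd_class=row["idd_class"].strip(),
            gbd_l4=row.get("gbd_l4", "").strip() or None,
            gbd_l3=row.get("gbd_l3", "").strip() or None,
            gbd_l2=row.get("gbd_l2", "").strip() or None,
            gbd_l1=row.get("gbd_l1", "").strip() or None,
            target_codes=targets,
            package_id=row.get("package_id", "").strip() or None,
        )

    packages: dict[str, tuple[str, tuple[str, ...]]] = {}
    pfile = path / "packages.csv"
    if pfile.exists():
        pdf = pd.read_csv(pfile, dtype=str, keep_default_na=False)
        for pid, grp in pdf.groupby("package_id", sort=True):
            name = grp["name"].iloc[0]
            members = tuple(normalize_icd(c) for c in grp["icd_prefix"])
            packages[pid] = (name, members)

    rules: list[CombinationRule] = []
    rfile = path / "combination_rules.csv"
    if rfile.exists():
        rdf = pd.read_csv(rfile, dtype=str, keep_default_na=False)
        for _, row in rdf.iterrows():
            rules.append(CombinationRule(
                uc_codes=frozenset(normalize_icd(c) for c in row["uc_codes"].split(";") if c.strip()),
                mcod_codes=frozenset(normalize_icd(c) for c in row["mcod_codes"].split(";") if c.strip()),
                override=normalize_icd(row["override"]),
            ))

    restrictions: dict[str, str] = {}
    sfile = path / "sex_restrictions.csv"
    if sfile.exists():
        sdf = pd.read_csv(sfile, dtype=str, keep_default_na=False)
        for _, row in sdf.iterrows():
            restrictions[row["cause_l4"].strip()] = row["sex"].strip()

    return CauseMap(entries=entries, packages=packages,
                    combination_rules=rules, sex_restrictions=restrictions)


def demo_map() -> CauseMap:
    """The bundled demonstration cause map (format example; not a full map)."""
    base = resources.files("gcredist") / "data" / "demo_map"
    with resources.as_file(base) as p:
        return load_cause_map(p)


def _prefix_match(code: str, prefixes: Iterable[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def apply_combination_rules(record: DeathRecord, cause_map: CauseMap) -> DeathRecord:
    """Override the UC when a combination rule's UC and MCOD sets both match.

    Rules are checked in file order; the first match wins.  The record is
    returned unchanged when no rule applies.
    """
    for rule in cause_map.combination_rules:
        if not _prefix_match(record.underlying_cause, rule.uc_codes):
            continue
        if any(_prefix_match(code, rule.mcod_codes) for code, _ in record.mcod):
            return dataclasses.replace(record, underlying_cause=rule.override)
    return record


def map_underlying_cause(record: DeathRecord, cause_map: CauseMap) -> CauseAssignment:
    """Classify a record's UC: specific level-4 cause or IDD routing class.

    Combination rules must already have been applied.  Codes absent from the
    map are routed to the ``unassigned`` class (step 3/4 material).
    """
    entry = cause_map.match(record.underlying_cause)
    if entry is None:
        return CauseAssignment(record.record_id, None, "unassigned")
    if entry.idd_class == "specific":
        return CauseAssignment(record.record_id, entry.gbd_l4, "specific", "mapped")
    return CauseAssignment(record.record_id, None, entry.idd_class)


def classify_records(
    records: Sequence[DeathRecord], cause_map: CauseMap
) -> list[CauseAssignment]:
    """Combination rules + mapping for a batch of records, in order."""
    return [
        map_underlying_cause(apply_combination_rules(r, cause_map), cause_map)
        for r in records
    ]
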