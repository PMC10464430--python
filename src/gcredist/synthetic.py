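"""Synthetic death-certificate microdata with known ground truth.

The generator emulates the schema and the ill-defined-death (IDD) regime of
a national multiple-causes-of-death database: an old-skewed age-at-death
distribution (mode near 80), a cause catalogue with age×sex-specific
prevalence, a configurable fraction of deaths whose underlying cause is
garbled into a garbage code, and MCOD chains that retain the true cause with
configurable probability.  Every record's true level-4 cause is returned in
a truth table, so redistribution accuracy can be measured exactly.

Default garble destinations are *cause-independent* in the sense that every
true cause sends the same total probability mass to proportionally
redistributed garbage (package codes, plus R99 when the MCOD chain does not
retain the truth), which makes package and all-cause redistribution unbiased
in expectation under the defaults.  Causes with a natural predefined-target
code (C55 for uterus-part-unspecified, I64 for unspecified stroke, J18.9 for
unspecified pneumonia) send part of their mass there instead; ICD-based
redistribution recovers those pro rata within the target set.  Per-cause
``garble_targets`` are fully configurable, so cause-dependent garbling (the
known failure mode of proportional redistribution) can be switched on to
study it.  Default MCOD noise codes are themselves garbage or unmappable
codes, so internal redistribution sees the retained true cause as its only
specific candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DeathRecord, PopulationTable
from .causemap import CauseMap

#: garble destinations for causes with a predefined-target garbage code;
#: ``natural`` is replaced per cause.  Mass to proportionally redistributed
#: garbage (packages + R99 without retained truth at p_mcod_truth = 0.8)
#: equals the non-targeted mix below (0.40 + 0.2·0.20 = 0.30 + 0.2·0.70).
_TARGETED_MIX = (("natural", 0.40), ("I509", 0.28), ("N19", 0.06),
                 ("I469", 0.04), ("J969", 0.02), ("R99", 0.20))
_GENERIC_MIX = (("I509", 0.21), ("N19", 0.045), ("I469", 0.03),
                ("J969", 0.015), ("R99", 0.70))

_NATURAL_TARGET = {
    "cervical_cancer": "C55",
    "uterine_cancer": "C55",
    "ischemic_stroke": "I64",
    "hemorrhagic_stroke": "I64",
    "lri": "J189",
    "lung_cancer": "C80",
    "breast_cancer": "C80",
    "prostate_cancer": "C80",
    "colorectal_cancer": "C80",
    "pancreatic_cancer": "C80",
}

#: default contributory-code pool: garbage or unmappable codes only
_NOISE_CODES = (("I500", 0.22), ("R54", 0.15), ("J969", 0.13), ("E869", 0.10),
                ("A419", 0.10), ("I469", 0.10), ("N19", 0.08), ("R092", 0.07),
                ("R53", 0.05))


@dataclass(frozen=True)
class CauseSpec:
    """One catalogue entry: prevalence, age/sex profile, UC codes, garbling."""

    cause_l4: str
    codes: tuple[str, ...]
    base_weight: float
    age_profile: tuple[float, ...]  # relative weight per redistribution age group
    sex_factor: tuple[float, float]  # (male, female); 0 disables a sex
    garble_targets: tuple[tuple[str, float], ...]


def _mix(cause: str) -> tuple[tuple[str, float], ...]:
    nat = _NATURAL_TARGET.get(cause)
    if nat is None:
        return _GENERIC_MIX
    return tuple((nat if c == "natural" else c, p) for c, p in _TARGETED_MIX)


def _spec(cause, codes, w, profile, sexf):
    return CauseSpec(cause, tuple(codes), w, tuple(profile), tuple(sexf), _mix(cause))


def default_catalogue() -> tuple[CauseSpec, ...]:
    """Cause catalogue matching the bundled demo map: prevalences and age/sex
    profiles chosen to mimic a high-income, ageing population (cardiovascular
    and cancer dominated, dementia concentrated at 85+, injuries young and
    male-skewed)."""
    return (
        _spec("ihd", ("I219", "I250", "I251"), .160, (0, 0, .2, 1, 3, 3), (1.3, .8)),
        _spec("ischemic_stroke", ("I630", "I639"), .070, (0, 0, .1, .6, 3, 4), (1, 1.1)),
        _spec("hemorrhagic_stroke", ("I610", "I619", "I609"), .030, (0, 0, .3, 1, 2, 2), (1, 1)),
        _spec("hypertensive_hd", ("I10", "I110", "I129"), .020, (0, 0, .1, .7, 2, 3), (.9, 1.1)),
        _spec("afib", ("I480", "I489"), .030, (0, 0, 0, .3, 2, 4), (.8, 1.2)),
        _spec("other_cvd", ("I709", "I710"), .030, (0, 0, .1, .7, 2, 3), (1, 1)),
        _spec("lung_cancer", ("C349", "C341", "C33"), .090, (0, 0, .1, 2, 3, .8), (1.5, .7)),
        _spec("breast_cancer", ("C509",), .040, (0, 0, .5, 2, 2, 1), (0, 1)),
        _spec("prostate_cancer", ("C61",), .035, (0, 0, 0, .8, 3, 3), (1, 0)),
        _spec("cervical_cancer", ("C539",), .013, (0, 0, 1, 2, 1.5, .8), (0, 1)),
        _spec("uterine_cancer", ("C541", "C549"), .013, (0, 0, .3, 2, 2, 1), (0, 1)),
        _spec("colorectal_cancer", ("C189", "C20"), .060, (0, 0, .2, 1.5, 3, 1.5), (1.1, .9)),
        _spec("pancreatic_cancer", ("C259",), .020, (0, 0, .1, 1.5, 3, 1), (1, 1)),
        _spec("dementia", ("G309", "F03", "F019"), .110, (0, 0, 0, .1, 2, 6), (.7, 1.3)),
        _spec("parkinson", ("G20",), .012, (0, 0, 0, .2, 2, 2.5), (1.1, .9)),
        _spec("copd", ("J440", "J449"), .065, (0, 0, 0, 1, 3, 2), (1.2, .8)),
        _spec("diabetes", ("E119", "E149", "E109"), .040, (0, 0, .2, 1, 2.5, 2), (1, 1)),
        _spec("ckd", ("N189",), .020, (0, 0, .1, .7, 2, 3), (1, 1)),
        _spec("cirrhosis", ("K709", "K746"), .020, (0, 0, .5, 3, 1.5, .3), (1.4, .6)),
        _spec("alcohol_use", ("F102",), .008, (0, 0, 1, 3, 1, .1), (1.6, .4)),
        _spec("drug_use", ("F191", "F110"), .004, (0, .1, 4, 2, .3, 0), (1.5, .5)),
        _spec("lri", ("J159", "J180", "J181", "J13"), .075, (.5, .2, .2, .8, 2.5, 4), (1, 1.05)),
        _spec("diarrheal", ("A090", "A047"), .005, (1, .3, .2, .5, 1.5, 3), (1, 1)),
        _spec("tb", ("A162",), .003, (.2, .2, 1, 1.5, 1.5, 1), (1.3, .7)),
        _spec("hiv", ("B20", "B24"), .003, (.1, .1, 3, 2, .5, 0), (1.4, .6)),
        _spec("maternal", ("O141", "O721", "O85"), .002, (0, 0, 1, 0, 0, 0), (0, 1)),
        _spec("neonatal_preterm", ("P070", "P220"), .004, (1, 0, 0, 0, 0, 0), (1, 1)),
        _spec("neonatal_other", ("P219", "P360"), .002, (1, 0, 0, 0, 0, 0), (1, 1)),
        _spec("road", ("V892", "V031", "V475"), .020, (.3, .8, 3, 1.5, .8, .3), (1.8, .5)),
        _spec("falls", ("W19", "W10", "W01"), .025, (.2, .2, .5, .8, 2, 4), (1.1, .9)),
        _spec("drowning", ("W74", "W67"), .003, (1, 1, 1, .8, .5, .2), (1.5, .5)),
        _spec("poisoning", ("X44", "X459"), .008, (.2, .1, 2.5, 2, .5, .1), (1.5, .6)),
        _spec("adverse_medical", ("Y831", "Y849", "Y620"), .006, (.3, .1, .3, .8, 2.5, 2.5), (1, 1)),
        _spec("self_harm", ("X70", "X740", "X80"), .025, (0, .2, 2.5, 2.5, 1, .5), (1.6, .5)),
        _spec("violence", ("X954", "X99", "Y009"), .005, (.3, .2, 3, 1.5, .5, .2), (1.5, .6)),
    )


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic microdata.

    Defaults follow the regime of a contemporary high-income vital
    registration system: roughly one third of deaths carry an ill-defined
    underlying cause (``idd_fraction = 0.34``), the true cause remains on
    the certificate's MCOD chain for 80% of garbled deaths
    (``p_mcod_truth = 0.8``), and age at death peaks near 80.
    """

    n_per_year: int = 5000
    years: tuple[int, int] = (2000, 2009)
    idd_fraction: float = 0.34
    p_mcod_truth: float = 0.8
    mcod_noise_mean: float = 1.2
    p_uc_in_chain: float = 0.6
    noise_codes: tuple[tuple[str, float], ...] = _NOISE_CODES
    regions: tuple[tuple[str, float], ...] = (("north", .57), ("south", .33), ("capital", .10))
    catalogue: tuple[CauseSpec, ...] = field(default_factory=default_catalogue)
    #: optional IDD-prevalence multipliers by age group / sex, e.g.
    #: (0.6, 0.6, 0.7, 0.8, 1.0, 1.3) to make IDDs more common at old age
    idd_age_multiplier: tuple[float, ...] | None = None
    idd_sex_multiplier: tuple[float, float] | None = None
    missing_age_rate: float = 0.0
    missing_sex_rate: float = 0.0
    stillbirth_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.idd_fraction < 1:
            raise ValueError("idd_fraction must be in [0, 1)")
        for name in ("p_mcod_truth", "p_uc_in_chain"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for spec in self.catalogue:
            if abs(sum(p for _, p in spec.garble_targets) - 1) > 1e-9:
                raise ValueError(f"{spec.cause_l4}: garble target probabilities must sum to 1")


def _draw_ages(n: int, rng: np.random.Generator) -> np.ndarray:
    """Old-skewed age-at-death mixture with mode near 80."""
    ages = np.clip(np.round(rng.normal(80, 11, n)), 0, 105).astype(int)
    u = rng.random(n)
    young = u < 0.015
    ages[young] = rng.integers(0, 15, young.sum())
    mid = (u >= 0.015) & (u < 0.085)
    ages[mid] = rng.integers(15, 65, mid.sum())
    return ages


def generate(config: GeneratorConfig | None = None) -> tuple[list[DeathRecord], pd.DataFrame]:
    """Generate microdata and its truth table.

    Returns the records (readable/writable through :mod:`gcredist.io`) and a
    truth table with one row per record: ``record_id``, ``year``,
    ``true_cause_l4`` and a ``garbled`` flag.  Reproducible under
    ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    cat = cfg.catalogue
    ncau = len(cat)
    base = np.array([s.base_weight for s in cat])
    profiles = np.array([s.age_profile for s in cat])  # (ncau, 6)
    sexf = np.array([s.sex_factor for s in cat])  # (ncau, 2)

    years = list(range(cfg.years[0], cfg.years[1] + 1))
    n = cfg.n_per_year * len(years)
    year = np.repeat(years, cfg.n_per_year)
    age = _draw_ages(n, rng)
    ag = np.searchsorted([0, 5, 15, 45, 65, 85], age, side="right") - 1
    sex = rng.integers(0, 2, n)
    region_names = [r for r, _ in cfg.regions]
    rw = np.array([w for _, w in cfg.regions], dtype=float)
    region = rng.choice(len(region_names), size=n, p=rw / rw.sum())

    cause = np.zeros(n, dtype=int)
    for a in range(6):
        for s in (0, 1):
            sel = np.nonzero((ag == a) & (sex == s))[0]
            if sel.size == 0:
                continue
            w = base * profiles[:, a] * sexf[:, s]
            if w.sum() == 0:
                w = base * sexf[:, s]
            cause[sel] = rng.choice(ncau, size=sel.size, p=w / w.sum())

    p_garble = np.full(n, cfg.idd_fraction)
    if cfg.idd_age_multiplier is not None:
        p_garble *= np.asarray(cfg.idd_age_multiplier)[ag]
    if cfg.idd_sex_multiplier is not None:
        p_garble *= np.asarray(cfg.idd_sex_multiplier)[sex]
    garbled = rng.random(n) < np.clip(p_garble, 0, 0.99)

    # underlying cause: a true-cause code, or a garbage code when garbled
    uc = np.empty(n, dtype=object)
    for k, spec in enumerate(cat):
        sel = np.nonzero(cause == k)[0]
        if sel.size == 0:
            continue
        uc[sel] = np.array(spec.codes, dtype=object)[rng.integers(len(spec.codes), size=sel.size)]
        gsel = sel[garbled[sel]]
        if gsel.size:
            codes = np.array([c for c, _ in spec.garble_targets], dtype=object)
            probs = np.array([p for _, p in spec.garble_targets])
            uc[gsel] = codes[rng.choice(len(codes), size=gsel.size, p=probs)]

    keep_truth = garbled & (rng.random(n) < cfg.p_mcod_truth)
    uc_in_chain = ~garbled & (rng.random(n) < cfg.p_uc_in_chain)
    n_noise = rng.poisson(cfg.mcod_noise_mean, n)
    noise_codes = np.array([c for c, _ in cfg.noise_codes], dtype=object)
    noise_p = np.array([p for _, p in cfg.noise_codes], dtype=float)
    noise_p /= noise_p.sum()

    missing_age = rng.random(n) < cfg.missing_age_rate
    missing_sex = rng.random(n) < cfg.missing_sex_rate
    stillbirth = rng.random(n) < cfg.stillbirth_rate

    sex_names = ("male", "female")
    roles = ("intermediate", "associated")
    records: list[DeathRecord] = []
    truth_rows = []
    for i in range(n):
        spec = cat[cause[i]]
        mcod: list[tuple[str, str]] = []
        if uc_in_chain[i]:
            mcod.append((str(uc[i]), "immediate"))
        if keep_truth[i]:
            code = spec.codes[rng.integers(len(spec.codes))]
            mcod.append((code, roles[rng.integers(2)]))
        for c in rng.choice(len(noise_codes), size=n_noise[i], p=noise_p):
            mcod.append((str(noise_codes[c]), "associated"))
        rid = f"D{year[i]}-{i:06d}"
        records.append(DeathRecord(
            record_id=rid,
            year=int(year[i]),
            age=None if missing_age[i] else int(age[i]),
            sex=None if missing_sex[i] else sex_names[sex[i]],
            region=region_names[region[i]],
            underlying_cause="P95" if stillbirth[i] else str(uc[i]),
            mcod=mcod,
        ))
        truth_rows.append((rid, int(year[i]), spec.cause_l4, bool(garbled[i])))
    truth = pd.DataFrame(truth_rows, columns=["record_id", "year", "true_cause_l4", "garbled"])
    return records, truth


#: plausible national age pyramid on five-year groups (shares, 0–95+)
_PYRAMID = np.array([
    .053, .055, .056, .057, .059, .061, .063, .063, .063, .065, .065, .063,
    .058, .050, .042, .035, .026, .016, .0075, .0025,
])


def population_table(config: GeneratorConfig | None = None,
                     persons_per_death: float = 100.0) -> PopulationTable:
    """Mid-year population counts consistent with the generator's regions and
    years; total population is ``n_per_year × persons_per_death`` (default
    gives a crude mortality rate near 1,000 per 100,000)."""
    cfg = config or GeneratorConfig()
    total = cfg.n_per_year * persons_per_death
    shares = _PYRAMID / _PYRAMID.sum()
    rw = np.array([w for _, w in cfg.regions], dtype=float)
    rw /= rw.sum()
    rows = []
    for yr in range(cfg.years[0], cfg.years[1] + 1):
        for (rname, _), rshare in zip(cfg.regions, rw):
            for si, (sname, sshare) in enumerate((("male", .49), ("female", .51))):
                for gi, share in enumerate(shares):
                    rows.append((yr, sname, rname, 5 * gi, total * rshare * sshare * share))
    return PopulationTable(pd.DataFrame(
        rows, columns=["year", "sex", "region", "age_lo", "population"]
    ))


def recovery_report(
    truth: pd.DataFrame,
    summary: pd.DataFrame,
    years: Sequence[int] | None = None,
    share_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-cause recovery of the redistribution against the ground truth.

    ``summary`` must be a level-4 summary over no stratifiers (one row per
    cause with mean/lower/upper), as produced by
    ``summarize_ensemble(ensemble, group_by=(), level=4)``; ``years``
    restricts the truth to the ensemble's report years.

    Returns one row per cause: true count, estimated mean and 95% UI,
    relative error ``(mean − true)/true``, UI coverage of the truth, and a
    ``major`` flag for causes holding at least ``share_threshold`` of deaths.
    """
    t = truth if years is None else truth[truth["year"].isin(list(years))]
    true_counts = t["true_cause_l4"].value_counts()
    est = summary.set_index("cause")
    missing = [c for c in true_counts.index if c not in est.index]
    if missing:
        raise KeyError(f"causes in truth but absent from summary: {missing}")
    out = []
    total = float(true_counts.sum())
    for cse in est.index:
        true_n = float(true_counts.get(cse, 0))
        mean, lo, hi = est.loc[cse, ["mean", "lower", "upper"]]
        out.append({
            "cause": cse,
            "true_count": true_n,
            "share": true_n / total if total else np.nan,
            "mean": float(mean), "lower": float(lo), "upper": float(hi),
            "rel_error": (mean - true_n) / true_n if true_n else np.nan,
            "covered": bool(lo <= true_n <= hi),
            "major": bool(total and true_n / total >= share_threshold),
        })
    return pd.DataFrame(out).sort_values("share", ascending=False).reset_index(drop=True)
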