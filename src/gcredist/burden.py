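"""Fatal burden of disease: SEYLL, crude and age-standardized rates.

Standard Expected Years of Life Lost (SEYLL) weights each death by the
residual life expectancy at the age of death taken from an aspirational
reference life table.  The table is completed with a zero anchor at age 122
(the highest observed human lifespan) and evaluated at arbitrary ages by
linear interpolation.  Deaths and SEYLL are reported as absolute numbers,
crude rates per 100,000 inhabitants, and age-standardized rates on five-year
age groups against a standard population (the bundled 2013 European Standard
Population, or any user-supplied standard), each with the mean and
2.5th/97.5th-percentile uncertainty interval across redistribution
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LifeTable, MAX_AGE, PopulationTable, StandardPopulation, ValidationError
from .redistribute import RedistributionEnsemble, _summary_frame

RATE_SCALE = 100_000.0


def _bundled(name: str):
    return resources.files("gcredist") / "data" / name


def demo_life_table() -> LifeTable:
    """Bundled synthetic reference life table (fabricated values on the
    published abridged-age structure; replace with a real reference table
    for substantive analyses)."""
    with resources.as_file(_bundled("synthetic_reference_life_table.csv")) as p:
        return LifeTable.from_csv(p)


def esp2013() -> StandardPopulation:
    """The 2013 European Standard Population on five-year age groups."""
    with resources.as_file(_bundled("esp2013.csv")) as p:
        return StandardPopulation.from_csv(p)


def complete_life_table(raw: LifeTable) -> LifeTable:
    """Append the (122, 0) anchor (idempotent) and validate monotonicity.

    Raises
    ------
    ValidationError
        If residual expectancy increases with age anywhere in the input, or
        a non-zero value is recorded at age 122.
    """
    if np.any(np.diff(raw.residual_expectancy) > 0):
        raise ValidationError("residual life expectancy must be non-increasing in age")
    if raw.ages[-1] == MAX_AGE:
        if raw.residual_expectancy[-1] != 0:
            raise ValidationError(f"residual expectancy at age {MAX_AGE} must be 0")
        return raw
    return LifeTable(
        np.append(raw.ages, MAX_AGE),
        np.append(raw.residual_expectancy, 0.0),
    )


@dataclass(frozen=True)
class SeyllWeightFunction:
    """Piecewise-linear SEYLL weight: age → expected years of life lost.

    Built on a completed life table; exact at the table knots, linearly
    interpolated between them, 0 at age 122, and non-increasing throughout.
    """

    life_table: LifeTable

    def __post_init__(self) -> None:
        object.__setattr__(self, "life_table", complete_life_table(self.life_table))

    def __call__(self, age) -> np.ndarray | float:
        a = np.asarray(age, dtype=float)
        if np.any(a < 0) or np.any(a > MAX_AGE):
            raise ValidationError(f"age outside [0, {MAX_AGE}]")
        out = np.interp(a, self.life_table.ages, self.life_table.residual_expectancy)
        return float(out) if np.isscalar(age) else out


def seyll_at_age(weights: SeyllWeightFunction, age: float) -> float:
    """SEYLL for a death at the given exact age (years)."""
    return float(weights(age))


def compute_seyll(
    ensemble: RedistributionEnsemble,
    weights: SeyllWeightFunction,
    group_by: Sequence[str] = ("year",),
    level: int = 3,
    age_offset: float = 0.0,
) -> pd.DataFrame:
    """Per-group, per-cause SEYLL: mean and 95% UI across iterations.

    SEYLL is additive over deaths: each death contributes the weight at its
    completed-years age (optionally shifted by ``age_offset``, e.g. 0.5 for a
    mid-interval correction).
    """
    w = weights(np.minimum(ensemble.age + age_offset, MAX_AGE))
    counts, groups, labels = ensemble.iteration_counts(
        by=group_by, level=level, record_weights=np.asarray(w, dtype=float)
    )
    return _summary_frame(counts, groups, labels)


def crude_rate(count: float, population: float) -> float:
    """Deaths (or SEYLL) per 100,000 inhabitants."""
    if population <= 0:
        raise ValidationError("population must be positive")
    return count / population * RATE_SCALE


def age_standardized_rate(
    counts_by_age: Mapping[int, float],
    population_by_age: Mapping[int, float],
    standard: StandardPopulation,
) -> float:
    """Directly age-standardized rate per 100,000 on five-year age groups.

    ``counts_by_age`` and ``population_by_age`` are keyed by the group lower
    bound (0, 5, ..., terminal open group of the standard).  A group with
    deaths but no population is an error; a group with neither contributes
    nothing.
    """
    num = 0.0
    for lo, w in zip(standard.age_lo, standard.weight):
        c = counts_by_age.get(int(lo), 0.0)
        pop = population_by_age.get(int(lo), 0.0)
        if pop <= 0:
            if c > 0:
                raise ValidationError(f"no population for age group {lo}+ with {c} deaths")
            continue
        num += w * (c / pop)
    return num / standard.weight.sum() * RATE_SCALE


def compute_burden(
    ensemble: RedistributionEnsemble,
    life_table: LifeTable,
    population: PopulationTable,
    standards: Mapping[str, StandardPopulation] | None = None,
    group_by: Sequence[str] = (),
    level: int = 3,
    age_offset: float = 0.0,
) -> pd.DataFrame:
    """Build the full burden table: deaths and SEYLL as counts, crude rates
    and age-standardized rates, with uncertainty intervals.

    ``group_by`` may contain ``"sex"`` and/or ``"region"``; results are
    always per year.  Each row carries (year, [sex, region], cause, level,
    measure ∈ {deaths, seyll}, statistic ∈ {count, crude_rate, asr},
    standard, mean, lower, upper); rates are per 100,000.
    """
    standards = standards if standards is not None else {"esp2013": esp2013()}
    for g in group_by:
        if g not in ("sex", "region"):
            raise ValidationError(f"group_by supports 'sex'/'region', got {g!r}")
    by = ["year", *group_by, "age5"]
    weights = SeyllWeightFunction(life_table)
    w = np.asarray(weights(np.minimum(ensemble.age + age_offset, MAX_AGE)), dtype=float)

    tensors = {
        "deaths": ensemble.iteration_counts(by=by, level=level),
        "seyll": ensemble.iteration_counts(by=by, level=level, record_weights=w),
    }
    _, groups, labels = tensors["deaths"]
    strat_cols = ["year", *group_by]
    strat_keys, strat_uniques = pd.factorize(
        pd.MultiIndex.from_frame(groups[strat_cols]), sort=True
    )
    strata = pd.DataFrame(list(strat_uniques), columns=strat_cols)
    S, G, L = len(strata), len(groups), len(labels)
    n_iter = ensemble.n_iterations

    # population per fine group (with age) and per stratum (marginal)
    pop_g = np.zeros(G)
    for i, row in groups.iterrows():
        sex = row["sex"] if "sex" in group_by else None
        region = row["region"] if "region" in group_by else None
        pop_g[i] = population.by_age(year=row["year"], sex=sex, region=region).get(
            int(row["age5"]), 0.0
        )
    pop_s = np.bincount(strat_keys, weights=pop_g, minlength=S)

    frames = []
    for measure, (counts, _, _) in tensors.items():
        # counts: (I, G, L) on (stratum × age) groups
        by_stratum = np.zeros((n_iter, S, L))
        for gi in range(G):
            by_stratum[:, strat_keys[gi], :] += counts[:, gi, :]
        f = _summary_frame(by_stratum, strata, labels)
        f["measure"], f["statistic"], f["standard"] = measure, "count", ""
        frames.append(f)

        bad = pop_s <= 0
        if bad.any():
            if by_stratum[:, bad, :].sum() > 0:
                missing = strata[bad].to_dict("records")
                raise ValidationError(f"no population for strata with deaths: {missing}")
        rates = np.divide(by_stratum, pop_s[None, :, None],
                          out=np.zeros_like(by_stratum), where=pop_s[None, :, None] > 0)
        f = _summary_frame(rates * RATE_SCALE, strata, labels)
        f["measure"], f["statistic"], f["standard"] = measure, "crude_rate", ""
        frames.append(f)

        for std_name, std in standards.items():
            age_rates = np.divide(counts, pop_g[None, :, None],
                                  out=np.zeros_like(counts), where=pop_g[None, :, None] > 0)
            if (counts[:, pop_g <= 0, :].sum()) > 0:
                missing = groups[pop_g <= 0].to_dict("records")
                raise ValidationError(f"no population for age groups with deaths: {missing}")
            wt = {int(lo): wgt for lo, wgt in zip(std.age_lo, std.weight)}
            gw = np.array([
                wt.get(int(min(a, std.age_lo[-1])), 0.0) for a in groups["age5"]
            ])
            asr = np.zeros((n_iter, S, L))
            for gi in range(G):
                asr[:, strat_keys[gi], :] += gw[gi] * age_rates[:, gi, :]
            asr *= RATE_SCALE / std.weight.sum()
            f = _summary_frame(asr, strata, labels)
            f["measure"], f["statistic"], f["standard"] = measure, "asr", std_name
            frames.append(f)

    out = pd.concat(frames, ignore_index=True)
    out["level"] = level
    for col in ("sex", "region"):
        if col not in out.columns:
            out[col] = "all"
    cols = ["year", "cause", "level", "sex", "region", "measure", "statistic",
            "standard", "mean", "lower", "upper"]
    return out[cols]


def leading_causes(
    table: pd.DataFrame,
    year: int,
    sex: str = "all",
    region: str = "all",
    level: int = 3,
    k: int = 10,
    measure: str = "deaths",
    statistic: str = "asr",
    baseline_year: int | None = None,
) -> pd.DataFrame:
    """Top-``k`` causes by mean value of the requested statistic, optionally
    with the percent change versus a baseline year ((new − old)/old × 100)."""
    def slice_(y):
        s = table[
            (table["year"] == y) & (table["sex"] == sex) & (table["region"] == region)
            & (table["level"] == level) & (table["measure"] == measure)
            & (table["statistic"] == statistic)
        ]
        if s.empty:
            raise ValidationError(f"no rows for year={y}, sex={sex}, region={region}")
        return s

    cur = slice_(year).sort_values("mean", ascending=False).head(k).reset_index(drop=True)
    cur.insert(0, "rank", np.arange(1, len(cur) + 1))
    if baseline_year is not None:
        base = slice_(baseline_year).set_index("cause")["mean"]
        cur["pct_change"] = [
            (m - base[c]) / base[c] * 100.0 if c in base.index and base[c] != 0 else np.nan
            for c, m in zip(cur["cause"], cur["mean"])
        ]
    return cur
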