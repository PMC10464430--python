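"""Four-step probabilistic redistribution of ill-defined deaths.

Every ill-defined death (IDD) in a report year is reassigned to a specific
level-4 cause by the first applicable of four steps:

1. **ICD-based redistribution** — codes with predefined ICD-10 target codes
   are redistributed pro rata to the occurrence of the target causes as
   underlying causes of death.
2. **Package redistribution** — intrinsically uninformative codes grouped
   into packages are redistributed pro rata to the underlying causes of
   deaths that mention a package code anywhere in their MCOD chain (as
   immediate, intermediate or associated cause) and that already carry a
   specific or redistributed underlying cause.
3. **Internal redistribution** — remaining uninformative codes are assigned
   uniformly at random to one of the specific causes mentioned on the same
   death certificate.
4. **All-cause redistribution** — anything left is redistributed pro rata
   over all specific causes.

Target distributions are built from the deaths of a rolling window (the
report year and the preceding ``window_years - 1`` years, five years by
default), stratified by age group (0–4, 5–14, 15–44, 45–64, 65–84, 85+) and
sex, with a sex-only fallback for sparse strata.  Level-3 causes with fewer
than ``rare_cause_min`` occurrences in the window and causes restricted to
the other sex are excluded as targets.  Within an iteration the target pool
is updated sequentially — earlier report years, earlier steps and earlier
groups within a step all feed the distributions used later — so redistributed
deaths accumulate as evidence.

The whole process is repeated for ``n_iterations`` independently seeded
iterations; summaries report the mean and the 2.5th/97.5th percentiles of
the per-iteration statistics.  ``mode="fractional"`` replaces sampling by
expected-value weight assignment, giving a single deterministic completed
dataset per iteration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .causemap import CauseAssignment, CauseMap, classify_records
from .io import DeathRecord, ValidationError

AGE_GROUP_LABELS = ("0-4", "5-14", "15-44", "45-64", "65-84", "85+")
_AGE_GROUP_LO = np.array([0, 5, 15, 45, 65, 85])

STEP_LABELS = ("mapped", "step1", "step2", "step3", "step4")

_SEXES = ("male", "female")


def age_group_index(age: int) -> int:
    """Index of the redistribution age group ([0,5), [5,15), [15,45), [45,65),
    [65,85), [85, ∞)) containing ``age``."""
    if age < 0:
        raise ValidationError(f"negative age {age}")
    return int(np.searchsorted(_AGE_GROUP_LO, age, side="right") - 1)


class InsufficientLeadInError(ValueError):
    """Raised when no year has a full lead-in window of data."""


class DegenerateInputError(RuntimeError):
    """Raised when step 4 cannot assign because no compatible specific cause
    exists anywhere in the pool."""


@dataclass(frozen=True)
class Stratum:
    """Target-distribution stratum: an age group and sex, sex only
    (``age_group=None``), or the whole pool (both ``None``)."""

    age_group: str | None
    sex: str | None

    def __post_init__(self) -> None:
        if self.age_group is not None and self.age_group not in AGE_GROUP_LABELS:
            raise ValidationError(f"unknown age group {self.age_group!r}")
        if self.sex is not None and self.sex not in _SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")


@dataclass
class RedistributionConfig:
    """Tunable parameters of the redistribution.

    ``window_years``: length of the rolling target window (5 = report year
    plus four preceding years).  ``rare_cause_min``: minimum level-3
    occurrence count in the window for a cause to be a valid target.
    ``sparse_stratum_min``: when the filtered support of an age×sex stratum
    falls below this count, the distribution is rebuilt on sex only.
    ``mode``: ``"sample"`` (one multinomial draw per death) or
    ``"fractional"`` (expected-value weights).  ``update``: whether the
    target pool absorbs new assignments after every group (``"per_group"``)
    or only after every step (``"per_step"``).  ``rare_filter``:
    ``"dynamic"`` re-evaluates the rare-cause filter whenever a distribution
    is built; ``"fixed"`` freezes it at the start of each report year.
    """

    window_years: int = 5
    n_iterations: int = 100
    rare_cause_min: int = 5
    sparse_stratum_min: int = 20
    master_seed: int = 0
    mode: str = "sample"
    update: str = "per_group"
    rare_filter: str = "dynamic"

    def __post_init__(self) -> None:
        if self.window_years < 1:
            raise ValidationError("window_years must be >= 1")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.mode not in ("sample", "fractional"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.update not in ("per_group", "per_step"):
            raise ValidationError(f"unknown update policy {self.update!r}")
        if self.rare_filter not in ("dynamic", "fixed"):
            raise ValidationError(f"unknown rare_filter policy {self.rare_filter!r}")


@dataclass
class TargetDistribution:
    """Stratum-specific probability mass over specific level-4 causes."""

    stratum: Stratum
    masses: dict[str, float]
    support_counts: dict[str, float]

    @property
    def empty(self) -> bool:
        return not self.masses

    def __post_init__(self) -> None:
        if self.masses:
            total = sum(self.masses.values())
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(f"target masses sum to {total}, not 1")


def build_target_distribution(
    pool: Iterable[tuple[DeathRecord, CauseAssignment]],
    year: int,
    stratum: Stratum,
    cause_map: CauseMap,
    restrict_to: Iterable[str] | None = None,
    config: RedistributionConfig | None = None,
) -> TargetDistribution:
    """Reference construction of a target distribution from an explicit pool.

    ``pool`` pairs each record with its current :class:`CauseAssignment`
    (original or already redistributed in the running iteration).  Only
    specific assignments within the rolling window count.  Causes whose
    level-3 parent occurs fewer than ``rare_cause_min`` times in the window
    (over the whole pool) are dropped, as are causes restricted to the other
    sex.  If the stratum's filtered support is below ``sparse_stratum_min``
    the distribution is rebuilt on sex only; an empty result is a valid
    return (the caller falls through to all-cause redistribution).

    This is the transparent counterpart of the vectorized engine inside
    :class:`Redistributor`; the two are kept in agreement by tests.
    """
    config = config or RedistributionConfig()
    lo = year - config.window_years + 1
    windowed = [
        (r, a) for r, a in pool
        if lo <= r.year <= year and a.cause_l4 is not None
    ]
    l3_counts: dict[str, int] = {}
    for _, a in windowed:
        l3 = cause_map.ancestor(a.cause_l4, 3)
        l3_counts[l3] = l3_counts.get(l3, 0) + 1

    allowed_causes = cause_map.targets_as_causes(restrict_to) if restrict_to is not None else None

    def ok(cause: str, sex: str | None) -> bool:
        if allowed_causes is not None and cause not in allowed_causes:
            return False
        if l3_counts.get(cause_map.ancestor(cause, 3), 0) < config.rare_cause_min:
            return False
        if sex is not None and sex not in cause_map.allowed_sexes(cause):
            return False
        return True

    def count(age_group: str | None, sex: str | None) -> dict[str, float]:
        support: dict[str, float] = {}
        for r, a in windowed:
            if sex is not None and r.sex != sex:
                continue
            if age_group is not None and AGE_GROUP_LABELS[age_group_index(r.age)] != age_group:
                continue
            if not ok(a.cause_l4, stratum.sex):
                continue
            support[a.cause_l4] = support.get(a.cause_l4, 0) + 1
        return support

    support = count(stratum.age_group, stratum.sex)
    used = stratum
    if stratum.age_group is not None and sum(support.values()) < config.sparse_stratum_min:
        support = count(None, stratum.sex)
        used = Stratum(None, stratum.sex)
    total = sum(support.values())
    if total == 0:
        return TargetDistribution(used, {}, {})
    masses = {c: n / total for c, n in sorted(support.items())}
    return TargetDistribution(used, masses, dict(sorted(support.items())))


def sample_from_distribution(
    dist: TargetDistribution, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` i.i.d. causes from a target distribution."""
    if dist.empty:
        raise ValidationError("cannot sample from an empty target distribution")
    causes = list(dist.masses)
    p = np.array([dist.masses[c] for c in causes])
    idx = rng.choice(len(causes), size=n, p=p)
    return [causes[i] for i in idx]


# ---------------------------------------------------------------------------
# Vectorized engine


@dataclass
class IterationState:
    """Mutable per-iteration assignment state.

    ``cur[i]`` is the current level-4 cause index of record ``i`` (−1 when
    unresolved); ``step[i]`` the step that resolved it (0 = mapped, 1–4).  In
    fractional mode resolved IDDs carry weight vectors in ``frac`` instead of
    a single ``cur`` entry.
    """

    cur: np.ndarray
    step: np.ndarray
    frac: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def resolved(self) -> np.ndarray:
        out = self.cur >= 0
        if self.frac:
            out = out.copy()
            out[list(self.frac)] = True
        return out


class Redistributor:
    """Prepares a dataset against a cause map and runs the four-step
    redistribution for every report year and iteration."""

    def __init__(
        self,
        records: Sequence[DeathRecord],
        cause_map: CauseMap,
        config: RedistributionConfig | None = None,
    ):
        self.cause_map = cause_map
        self.config = config or RedistributionConfig()
        self.records = list(records)
        self._prepare()

    # -- preparation ------------------------------------------------------
    def _prepare(self) -> None:
        cm, cfg = self.cause_map, self.config
        n = len(self.records)
        if n == 0:
            raise ValidationError("no records to redistribute")

        self.causes = cm.specific_causes(4)
        self.K = len(self.causes)
        cidx = {c: k for k, c in enumerate(self.causes)}
        l3s = cm.specific_causes(3)
        l3idx = {c: k for k, c in enumerate(l3s)}
        self.l3_names = l3s
        self.l3_of = np.array([l3idx[cm.ancestor(c, 3)] for c in self.causes])
        self.sex_ok = np.ones((2, self.K), bool)
        for k, c in enumerate(self.causes):
            allowed = cm.allowed_sexes(c)
            self.sex_ok[0, k] = "male" in allowed
            self.sex_ok[1, k] = "female" in allowed

        assignments = classify_records(self.records, cm)
        self.assignments = assignments

        self.rec_year = np.array([r.year for r in self.records])
        ages = np.array([r.age for r in self.records])
        if np.any(ages == None):  # noqa: E711 - object comparison on purpose
            raise ValidationError("records must be validated (no missing age/sex)")
        self.rec_age = ages.astype(int)
        self.rec_ag = np.searchsorted(_AGE_GROUP_LO, self.rec_age, side="right") - 1
        self.rec_sex = np.array([0 if r.sex == "male" else 1 for r in self.records])
        self.rec_region = np.array([r.region for r in self.records], dtype=object)
        self.rec_id = np.array([r.record_id for r in self.records], dtype=object)

        idd_codes = {"specific": 0, "icd_targeted": 1, "packaged": 2, "unassigned": 3}
        self.idd_class = np.array([idd_codes[a.idd_class] for a in assignments], dtype=np.int8)
        self.orig = np.array(
            [cidx[a.cause_l4] if a.cause_l4 is not None else -1 for a in assignments],
            dtype=np.int64,
        )

        # targeted groups, in deterministic lexicographic prefix order
        targeted_prefixes = sorted(
            p for p, e in cm.entries.items() if e.idd_class == "icd_targeted"
        )
        gid_of_prefix = {p: i for i, p in enumerate(targeted_prefixes)}
        self.group_prefixes = targeted_prefixes
        self.target_masks = []
        for p in targeted_prefixes:
            mask = np.zeros(self.K, bool)
            for c in cm.targets_as_causes(cm.entries[p].target_codes):
                mask[cidx[c]] = True
            self.target_masks.append(mask)

        self.pkg_ids = sorted(cm.packages)
        pid_of = {p: i for i, p in enumerate(self.pkg_ids)}

        self.gid = np.full(n, -1, dtype=np.int64)
        self.pid = np.full(n, -1, dtype=np.int64)
        # record-level MCOD-derived structures
        pkg_sets = []
        for p in self.pkg_ids:
            members = cm.packages[p][1]
            pkg_sets.append((
                {m for m in members if len(m) == 3},
                {m for m in members if len(m) == 4},
            ))
        pkg_records: list[list[int]] = [[] for _ in self.pkg_ids]
        self.mcod_cand: list[np.ndarray | None] = [None] * n

        for i, (rec, a) in enumerate(zip(self.records, assignments)):
            if a.idd_class == "icd_targeted":
                entry = cm.match(rec.underlying_cause)
                self.gid[i] = gid_of_prefix[entry.icd_prefix]
            elif a.idd_class == "packaged":
                entry = cm.match(rec.underlying_cause)
                self.pid[i] = pid_of[entry.package_id]
            for j, (s3, s4) in enumerate(pkg_sets):
                if any(code[:3] in s3 or code in s4 for code, _ in rec.mcod):
                    pkg_records[j].append(i)
            if a.idd_class != "specific" and rec.mcod:
                cands = set()
                for code, _ in rec.mcod:
                    e = cm.match(code)
                    if e is not None and e.idd_class == "specific":
                        cands.add(cidx[e.gbd_l4])
                if cands:
                    self.mcod_cand[i] = np.array(sorted(cands))
        self.pkg_records = [np.array(v, dtype=np.int64) for v in pkg_records]

        years = np.unique(self.rec_year)
        first = int(years.min()) + cfg.window_years - 1
        if first > years.max():
            raise InsufficientLeadInError(
                f"need {cfg.window_years} lead-in years; first reportable year "
                f"would be {first}, beyond the data ({years.max()})"
            )
        self.report_years = list(range(first, int(years.max()) + 1))
        self.report_pos = np.nonzero(self.rec_year >= first)[0]

    # -- distribution helpers --------------------------------------------
    def _rare_ok(self, C: np.ndarray) -> np.ndarray:
        l3c = np.bincount(self.l3_of, weights=C.sum(axis=(0, 1)), minlength=len(self.l3_names))
        return l3c[self.l3_of] >= self.config.rare_cause_min

    def _weights(
        self,
        T: np.ndarray,
        ag: int,
        sex: int,
        allowed: np.ndarray,
        final: bool,
        rare_ok: np.ndarray,
    ) -> np.ndarray | None:
        """Filtered support for one stratum with the sex-only (and, for
        step 4, pooled-total) fallbacks; ``None`` when empty."""
        w = T[ag, sex] * allowed
        if w.sum() < self.config.sparse_stratum_min:
            w = T[:, sex].sum(axis=0) * allowed
        if w.sum() > 0:
            return w
        if not final:
            return None
        w = T.sum(axis=(0, 1)) * allowed
        if w.sum() > 0:
            return w
        # last resort: relax the rare-cause filter, keep the sex restriction
        w = T.sum(axis=(0, 1)) * self.sex_ok[sex]
        if w.sum() > 0:
            return w
        return None

    def _assign_group(
        self,
        members: np.ndarray,
        T: np.ndarray,
        C: np.ndarray,
        state: IterationState,
        rng: np.random.Generator | None,
        step_no: int,
        mask: np.ndarray | None,
        final: bool,
        pending: list,
    ) -> None:
        """Assign all deaths of one group against the frozen tensor ``T``.

        Distributions are built per (age group, sex) stratum; assignments are
        queued in ``pending`` and only merged into the pool by the caller
        (per-group or per-step updating).
        """
        if members.size == 0:
            return
        rare_ok = self._rare_ok(C)
        strata = np.unique(self.rec_ag[members] * 2 + self.rec_sex[members])
        for code in strata:
            ag, sex = divmod(int(code), 2)
            sel = members[(self.rec_ag[members] == ag) & (self.rec_sex[members] == sex)]
            allowed = rare_ok & self.sex_ok[sex]
            if mask is not None:
                allowed = allowed & mask
            w = self._weights(T, ag, sex, allowed, final, rare_ok)
            if w is None:
                continue  # deferred to all-cause redistribution
            p = w / w.sum()
            if self.config.mode == "sample":
                draws = rng.choice(self.K, size=sel.size, p=p)
                state.cur[sel] = draws
                state.step[sel] = step_no
                pending.append((sel, draws, None))
            else:
                cs = np.nonzero(p)[0]
                ws = p[cs]
                for pos in sel:
                    state.frac[int(pos)] = (cs, ws)
                state.step[sel] = step_no
                pending.append((sel, cs, ws))

    def _apply_pending(self, C: np.ndarray, pending: list) -> None:
        for sel, a, b in pending:
            if b is None:
                np.add.at(C, (self.rec_ag[sel], self.rec_sex[sel], a), 1.0)
            else:
                for pos in sel:
                    C[self.rec_ag[pos], self.rec_sex[pos], a] += b
        pending.clear()

    def _pool_counts(self, inwin: np.ndarray, state: IterationState) -> np.ndarray:
        C = np.zeros((6, 2, self.K))
        m = inwin & (state.cur >= 0)
        np.add.at(C, (self.rec_ag[m], self.rec_sex[m], state.cur[m]), 1.0)
        for pos, (cs, ws) in state.frac.items():
            if inwin[pos]:
                C[self.rec_ag[pos], self.rec_sex[pos], cs] += ws
        return C

    # -- the four steps ---------------------------------------------------
    def new_state(self) -> IterationState:
        cur = self.orig.copy()
        step = np.full(len(self.records), -1, dtype=np.int8)
        step[cur >= 0] = 0
        return IterationState(cur=cur, step=step)

    def step1_icd_targets(self, state, year, rng, C=None, inwin=None) -> None:
        """ICD-based redistribution of this year's targeted IDDs."""
        C, inwin = self._year_context(state, year, C, inwin)
        thisyear = self.rec_year == year
        pend: list = []
        for g, mask in enumerate(self.target_masks):
            members = np.nonzero(thisyear & (state.cur < 0) & (self.gid == g))[0]
            members = members[[m not in state.frac for m in members]] if state.frac else members
            self._assign_group(members, C, C, state, rng, 1, mask, False, pend)
            if self.config.update == "per_group":
                self._apply_pending(C, pend)
        self._apply_pending(C, pend)

    def step2_packages(self, state, year, rng, C=None, inwin=None) -> None:
        """Package redistribution driven by MCOD mentions of package codes."""
        C, inwin = self._year_context(state, year, C, inwin)
        thisyear = self.rec_year == year
        pend: list = []
        for j in range(len(self.pkg_ids)):
            members = np.nonzero(thisyear & (state.cur < 0) & (self.pid == j))[0]
            if state.frac:
                members = members[[m not in state.frac for m in members]]
            if members.size == 0:
                continue
            cand = self.pkg_records[j]
            cand = cand[inwin[cand]]
            P = np.zeros_like(C)
            cm = cand[state.cur[cand] >= 0]
            np.add.at(P, (self.rec_ag[cm], self.rec_sex[cm], state.cur[cm]), 1.0)
            for pos in cand:
                fw = state.frac.get(int(pos))
                if fw is not None:
                    P[self.rec_ag[pos], self.rec_sex[pos], fw[0]] += fw[1]
            self._assign_group(members, P, C, state, rng, 2, None, False, pend)
            if self.config.update == "per_group":
                self._apply_pending(C, pend)
        self._apply_pending(C, pend)

    def step3_internal(self, state, year, rng, C=None, inwin=None) -> None:
        """Internal redistribution: uniform draw over the specific causes
        mentioned on the certificate (sex and rare-cause filters applied)."""
        C, inwin = self._year_context(state, year, C, inwin)
        thisyear = self.rec_year == year
        rare_ok = self._rare_ok(C)
        members = np.nonzero(thisyear & (state.cur < 0) & (self.idd_class == 3))[0]
        pend: list = []
        for pos in members:
            pos = int(pos)
            if pos in state.frac:
                continue
            cands = self.mcod_cand[pos]
            if cands is None:
                continue
            ok = cands[rare_ok[cands] & self.sex_ok[self.rec_sex[pos]][cands]]
            if ok.size == 0:
                continue
            if self.config.mode == "sample":
                c = int(ok[rng.integers(ok.size)])
                state.cur[pos] = c
                state.step[pos] = 3
                pend.append((np.array([pos]), np.array([c]), None))
            else:
                ws = np.full(ok.size, 1.0 / ok.size)
                state.frac[pos] = (ok, ws)
                state.step[pos] = 3
                pend.append((np.array([pos]), ok, ws))
        self._apply_pending(C, pend)

    def step4_all_cause(self, state, year, rng, C=None, inwin=None) -> None:
        """All-cause redistribution of every death still unresolved."""
        C, inwin = self._year_context(state, year, C, inwin)
        thisyear = self.rec_year == year
        members = np.nonzero(thisyear & (state.cur < 0))[0]
        if state.frac:
            members = members[[m not in state.frac for m in members]]
        pend: list = []
        self._assign_group(members, C, C, state, rng, 4, None, True, pend)
        self._apply_pending(C, pend)
        left = thisyear & (state.cur < 0)
        if state.frac:
            left[list(state.frac)] = False
        if left.any():
            raise DegenerateInputError(
                f"year {year}: no specific deaths available to redistribute "
                f"{int(left.sum())} remaining IDD(s)"
            )

    def _year_context(self, state, year, C, inwin):
        if inwin is None:
            inwin = (self.rec_year > year - self.config.window_years) & (self.rec_year <= year)
        if C is None:
            C = self._pool_counts(inwin, state)
        return C, inwin

    # -- orchestration ----------------------------------------------------
    def run_year(self, state: IterationState, year: int, rng: np.random.Generator) -> None:
        inwin = (self.rec_year > year - self.config.window_years) & (self.rec_year <= year)
        C = self._pool_counts(inwin, state)
        self.step1_icd_targets(state, year, rng, C, inwin)
        self.step2_packages(state, year, rng, C, inwin)
        self.step3_internal(state, year, rng, C, inwin)
        self.step4_all_cause(state, year, rng, C, inwin)

    def run_iteration(self, iteration: int) -> IterationState:
        """One complete four-step run over all report years, with a child RNG
        seeded as (master_seed, iteration)."""
        rng = np.random.default_rng((self.config.master_seed, iteration))
        state = self.new_state()
        for y in self.report_years:
            self.run_year(state, y, rng)
        return state

    def run(self) -> "RedistributionEnsemble":
        cfg = self.config
        m = self.report_pos
        assignments = np.zeros((cfg.n_iterations, m.size), dtype=np.int16)
        steps = np.zeros((cfg.n_iterations, m.size), dtype=np.int8)
        frac_rows: list[tuple[int, int, int, float]] = []
        for it in range(cfg.n_iterations):
            state = self.run_iteration(it)
            assignments[it] = state.cur[m]
            steps[it] = state.step[m]
            if cfg.mode == "fractional":
                pos_of = {int(p): j for j, p in enumerate(m)}
                for pos, (cs, ws) in sorted(state.frac.items()):
                    j = pos_of.get(pos)
                    if j is None:
                        continue
                    assignments[it, j] = -1
                    for c, w in zip(cs, ws):
                        frac_rows.append((it, j, int(c), float(w)))
        frac = None
        if cfg.mode == "fractional":
            frac = pd.DataFrame(frac_rows, columns=["iteration", "pos", "cause_idx", "weight"])
        levels = {
            lvl: np.array([self.cause_map.ancestor(c, lvl) for c in self.causes], dtype=object)
            for lvl in (1, 2, 3, 4)
        }
        return RedistributionEnsemble(
            record_ids=self.rec_id[m],
            year=self.rec_year[m],
            age=self.rec_age[m],
            age_group=np.array([AGE_GROUP_LABELS[a] for a in self.rec_ag[m]], dtype=object),
            sex=np.array([_SEXES[s] for s in self.rec_sex[m]], dtype=object),
            region=self.rec_region[m],
            orig_specific=self.orig[m] >= 0,
            causes=list(self.causes),
            cause_levels=levels,
            assignments=assignments,
            steps=steps,
            frac_weights=frac,
            config=dataclasses.replace(cfg),
        )


def run_redistribution(
    records: Sequence[DeathRecord],
    cause_map: CauseMap,
    config: RedistributionConfig | None = None,
) -> "RedistributionEnsemble":
    """Classify, then redistribute: the one-call entry point."""
    return Redistributor(records, cause_map, config).run()


# ---------------------------------------------------------------------------
# Ensemble container and summaries


@dataclass
class RedistributionEnsemble:
    """Per-iteration cause assignments for every report-year death.

    ``assignments[i, j]`` is the level-4 cause index of record ``j`` in
    iteration ``i`` (−1 marks a fractional assignment, spelled out in
    ``frac_weights``); ``steps[i, j]`` the resolving step (0 mapped, 1–4).
    """

    record_ids: np.ndarray
    year: np.ndarray
    age: np.ndarray
    age_group: np.ndarray
    sex: np.ndarray
    region: np.ndarray
    orig_specific: np.ndarray
    causes: list[str]
    cause_levels: dict[int, np.ndarray]
    assignments: np.ndarray
    steps: np.ndarray
    frac_weights: pd.DataFrame | None
    config: RedistributionConfig

    @property
    def n_iterations(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_records(self) -> int:
        return self.assignments.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (iteration, record_id, cause, step, weight)."""
        rows = []
        for it in range(self.n_iterations):
            sel = self.assignments[it] >= 0
            rows.append(pd.DataFrame({
                "iteration": it,
                "record_id": self.record_ids[sel],
                "cause_l4": np.array(self.causes, dtype=object)[self.assignments[it][sel]],
                "resolution_step": [STEP_LABELS[s] for s in self.steps[it][sel]],
                "weight": 1.0,
            }))
        if self.frac_weights is not None and len(self.frac_weights):
            fw = self.frac_weights
            rows.append(pd.DataFrame({
                "iteration": fw["iteration"].to_numpy(),
                "record_id": self.record_ids[fw["pos"].to_numpy()],
                "cause_l4": np.array(self.causes, dtype=object)[fw["cause_idx"].to_numpy()],
                "resolution_step": [
                    STEP_LABELS[s] for s in self.steps[fw["iteration"], fw["pos"]]
                ],
                "weight": fw["weight"].to_numpy(),
            }))
        return pd.concat(rows, ignore_index=True)

    # -- dense per-iteration counting ------------------------------------
    def _group_codes(self, by: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame]:
        cols = {}
        for name in by:
            if name == "year":
                cols[name] = self.year
            elif name == "sex":
                cols[name] = self.sex
            elif name == "region":
                cols[name] = self.region
            elif name == "age_group":
                cols[name] = self.age_group
            elif name == "age5":
                cols[name] = np.minimum(5 * (self.age // 5), 95)
            else:
                raise ValidationError(f"unknown stratifier {name!r}")
        if not cols:
            g = np.zeros(self.n_records, dtype=np.int64)
            return g, pd.DataFrame(index=[0])
        df = pd.DataFrame(cols)
        keys, uniques = pd.factorize(pd.MultiIndex.from_frame(df), sort=True)
        groups = pd.DataFrame(list(uniques), columns=list(by))
        return keys.astype(np.int64), groups

    def iteration_counts(
        self,
        by: Sequence[str] = ("year",),
        level: int = 3,
        record_weights: np.ndarray | None = None,
    ) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
        """Dense per-iteration (weighted) death counts.

        Returns ``(counts, groups, labels)`` with ``counts`` of shape
        (iterations, len(groups), len(labels)); zero cells are materialized so
        percentiles over iterations are correct.  ``record_weights`` turns
        death counts into weighted tallies (e.g. years of life lost).
        """
        g, groups = self._group_codes(by)
        lvl_names = sorted(set(self.cause_levels[level]))
        lvl_idx = {c: i for i, c in enumerate(lvl_names)}
        lvl_of = np.array([lvl_idx[c] for c in self.cause_levels[level]], dtype=np.int64)
        G, L = len(groups), len(lvl_names)
        counts = np.zeros((self.n_iterations, G, L))
        for it in range(self.n_iterations):
            a = self.assignments[it]
            sel = a >= 0
            flat = g[sel] * L + lvl_of[a[sel]]
            w = None if record_weights is None else record_weights[sel]
            counts[it] = np.bincount(flat, weights=w, minlength=G * L).reshape(G, L)
        if self.frac_weights is not None and len(self.frac_weights):
            fw = self.frac_weights
            pos = fw["pos"].to_numpy()
            w = fw["weight"].to_numpy().astype(float)
            if record_weights is not None:
                w = w * record_weights[pos]
            flat = g[pos] * L + lvl_of[fw["cause_idx"].to_numpy()]
            for it in np.unique(fw["iteration"]):
                sel = fw["iteration"].to_numpy() == it
                counts[it] += np.bincount(
                    flat[sel], weights=w[sel], minlength=G * L
                ).reshape(G, L)
        return counts, groups, lvl_names


def _summary_frame(
    counts: np.ndarray, groups: pd.DataFrame, labels: list[str], value: str = "mean"
) -> pd.DataFrame:
    mean = counts.mean(axis=0)
    lo, hi = np.percentile(counts, [2.5, 97.5], axis=0)
    G, L = mean.shape
    out = groups.loc[groups.index.repeat(L)].reset_index(drop=True)
    out["cause"] = labels * G
    out["mean"] = mean.ravel()
    out["lower"] = lo.ravel()
    out["upper"] = hi.ravel()
    return out


def summarize_ensemble(
    ensemble: RedistributionEnsemble,
    group_by: Sequence[str] = ("year",),
    level: int = 3,
) -> pd.DataFrame:
    """Mean and 95% uncertainty interval (2.5th/97.5th percentile across
    iterations) of per-cause death counts, by the requested stratifiers."""
    counts, groups, labels = ensemble.iteration_counts(by=group_by, level=level)
    return _summary_frame(counts, groups, labels)


def step_shares(
    ensemble: RedistributionEnsemble, by: Sequence[str] = ("year",)
) -> pd.DataFrame:
    """Mean share of deaths resolved at each stage (mapped, steps 1–4) per
    group; the shares partition each group's deaths and sum to 1."""
    g, groups = ensemble._group_codes(by)
    G, S = len(groups), len(STEP_LABELS)
    shares = np.zeros((ensemble.n_iterations, G, S))
    totals = np.bincount(g, minlength=G).astype(float)
    for it in range(ensemble.n_iterations):
        flat = g * S + ensemble.steps[it]
        shares[it] = np.bincount(flat, minlength=G * S).reshape(G, S) / totals[:, None]
    mean = shares.mean(axis=0)
    out = groups.loc[groups.index.repeat(S)].reset_index(drop=True)
    out["resolution_step"] = list(STEP_LABELS) * G
    out["share"] = mean.ravel()
    return out


def idd_share_by_cause(
    ensemble: RedistributionEnsemble, level: int = 3
) -> pd.DataFrame:
    """Mean proportion of each cause's final deaths that started as IDDs."""
    w_idd = (~ensemble.orig_specific).astype(float)
    redis, groups, labels = ensemble.iteration_counts(by=(), level=level, record_weights=w_idd)
    total, _, _ = ensemble.iteration_counts(by=(), level=level)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, redis / total, np.nan)
    mean_share = np.full(share.shape[1:], np.nan)
    seen = ~np.all(np.isnan(share), axis=0)
    mean_share[seen] = np.nanmean(share[:, seen], axis=0)
    return pd.DataFrame({
        "cause": labels,
        "mean_total": total.mean(axis=0).ravel(),
        "mean_redistributed": redis.mean(axis=0).ravel(),
        "idd_share": mean_share.ravel(),
    })


def check_conservation(ensemble: RedistributionEnsemble) -> dict[str, float]:
    """Verify that redistribution conserves deaths in every iteration and
    every (year, sex, age group, region) cell, and that no IDD remains.

    Returns a report with the largest absolute cell discrepancy and the
    number of unresolved records (both must be 0).
    """
    by = ("year", "sex", "age_group", "region")
    counts, groups, labels = ensemble.iteration_counts(by=by, level=1)
    g, _ = ensemble._group_codes(by)
    expected = np.bincount(g, minlength=len(groups)).astype(float)
    diff = np.abs(counts.sum(axis=2) - expected[None, :])
    unresolved = int((ensemble.steps < 0).sum())
    return {"max_abs_cell_diff": float(diff.max()), "n_unresolved": unresolved}
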