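# Methods

## Scope and data model

`gcredist` operates on cause-of-death microdata: one record per certified
death with calendar year, completed age at death (0–122), sex, a free-form
region stratifier, an ICD-10 underlying cause (UC), and zero or more
multiple-causes-of-death (MCOD) entries tagged immediate / intermediate /
associated. Records missing age or sex are excluded and counted, as are
stillbirths (UC in a configurable code set, default P95). Ages above 122
are clamped to 122, the upper anchor of the life table. ICD codes are
stored dotless at 3–4 characters; map lookup is by longest prefix, so a
4-character entry (J18.9) shadows its 3-character parent (J18) — this is
how codes that are ill-defined only at level 4 while specific at level 3
are represented: as targeted entries whose targets lie inside the same
level-3 cause, so "full redistribution to the level-3 parent" emerges from
the ordinary mechanism rather than a special case.

The cause map is an input, not a constant: a directory of CSVs defining
prefix→hierarchy entries (level 4 → 3 → 2 → 1), IDD classes, predefined
target lists, packages, sex restrictions and combination rules. The
bundled demo map (~420 prefixes, 35 level-4 / 33 level-3 causes across the
three level-1 clusters) is a *format example* scaled for tests and
demonstrations; substantive analyses should supply a complete national map.
Combination rules are applied before classification; the demo map encodes
the standard drug-death definitions (X41/X44/X61/X64/Y11 + T43.6, and
X42/X62/Y12 + T40, overriding the UC to F19).

## The four-step redistribution

For every report year `y` (the first year with a full lead-in window) the
ill-defined deaths of that year are resolved in order:

1. **ICD-based**: IDDs whose map entry carries predefined ICD targets,
   processed group by group (one group per garbage prefix, lexicographic
   order). The target distribution counts window deaths whose *current*
   cause is one of the target causes.
2. **Packages**: per package (lexicographic id order), candidates are
   window deaths with a package code anywhere in the MCOD chain *and* a
   specific-or-already-redistributed UC; the distribution is over the
   candidates' current causes. MCOD roles are deliberately ignored
   (immediate, intermediate and associated mentions count equally).
3. **Internal**: remaining IDDs of the *uninformative* class (R-chapter
   style codes with no targets or package) draw uniformly from the distinct
   specific level-4 causes mentioned on their own certificate, after sex
   and rare-cause filtering. Mentions are not weighted by multiplicity.
4. **All-cause**: every death still unresolved — including targeted or
   packaged deaths whose distribution came up empty, which skip step 3
   because their own certificate was already judged uninformative for
   targeting purposes — draws from the unrestricted distribution. No death
   may exit unassigned.

Target distributions are stratified by age group ([0,5), [5,15), [15,45),
[45,65), [65,85), [85,∞)) and sex. Filters and fallbacks, in order:

- **Rare-cause filter**: level-3 causes with fewer than `rare_cause_min`
  (default 5) occurrences in the window are excluded as targets. By
  default the filter is evaluated against the *current* pool each time a
  distribution is built (it can relax as redistributed deaths accumulate);
  `rare_filter="fixed"` freezes it at the start of each report year.
- **Sex restriction**: causes restricted to the other sex are excluded;
  restrictions are part of the map file (demo defaults: breast, cervical
  and uterine cancer and maternal disorders female-only, prostate cancer
  male-only).
- **Sparse-stratum fallback**: if the filtered support of the age×sex
  stratum sums to fewer than `sparse_stratum_min` deaths (default 20 — a
  conventional small-cell threshold; configurable), the distribution is
  rebuilt on sex only.
- **Empty distribution**: steps 1–2 defer the death to step 4. Step 4
  itself falls back from stratum to sex-only to the pooled total; if the
  rare-cause filter empties even the pooled total it is relaxed there (the
  sex restriction never is), because assignment at step 4 is mandatory. An
  error is raised only when no sex-compatible specific death exists
  anywhere in the pool.

**Sequential updating.** Within an iteration, evidence accumulates: report
years run in ascending order, steps in order, and after every *group*
within a step the newly assigned deaths join the pool (so the next group's
distribution sees them). `update="per_step"` defers pool updates to step
boundaries instead, for sensitivity analysis. Target counting includes both
originally specific deaths and deaths redistributed earlier in the
sequence, in all steps. Group processing order is deterministic
(lexicographic) since no natural order exists; this plus per-stratum
processing in fixed order makes runs exactly reproducible.

**Uncertainty.** The four-step process is repeated `n_iterations` times
(default 100; sampling noise in the mean is already small at 20). Iteration
`i` uses a child generator seeded from `(master_seed, i)`, so any iteration
can be reproduced independently. Summaries report the mean and the
2.5th/97.5th percentiles across iterations. `mode="fractional"` replaces
each multinomial draw by its expected value (per-death weight vectors),
yielding one deterministic completed dataset; sample-mode means converge to
fractional-mode counts up to Monte-Carlo error and a second-order
discrepancy from the sequential pool updates (the pool then carries
realized draws rather than expectations), which is well below one death per
cause at the fixture sizes used in the tests.

Conservation is exact in sample mode (every death gets exactly one cause)
and holds to float round-off (~1e-14 relative) in fractional mode; the CLI
verifies it on every run.

## Burden metrics

SEYLL weights come from a residual-life-expectancy table, completed with a
zero anchor at age 122 and interpolated linearly; the weight function is
exact at the knots, continuous and non-increasing. SEYLL is evaluated at
the integer completed-years age by default; a half-year offset
(`age_offset=0.5`) is available because mid-interval correction is a
defensible alternative and the choice measurably shifts totals at old ages.
The bundled life table is **synthetic** — fabricated values on the
published abridged-age structure (0, 1, 5, …, 95) — because redistributing
a real reference table is a licensing/content question left to the user;
tests only rely on its structural properties.

Crude rates are count/population × 100,000. Age-standardized rates use
direct standardization on five-year age groups: ASR = Σ w_g r_g / Σ w_g ×
100,000 with r_g the stratum rate and w_g the standard weights (bundled:
ESP 2013; the national standard is user-supplied). Deaths above the
standard's terminal group fold into it (95+). A group with deaths but no
population is an error; with neither, it contributes nothing. All
rate statistics are computed per iteration and then summarized, so their
uncertainty intervals propagate the redistribution uncertainty.

Percent changes in leading-cause tables compare the mean estimates of the
two years ((new − old)/old); iteration-paired differences were considered
and rejected as the default because the two years' iterations are not
coupled in any meaningful way.

## The synthetic generator

The generator emulates, with known ground truth: an old-skewed age-at-death
distribution (normal around 80, sd 11, plus small young/mid-age mixture
components; median ≈ 79); equal sexes; three regions; a 35-cause catalogue
with per-(age group, sex) prevalence profiles shaped like a high-income,
ageing population; an IDD fraction of 0.34 (the observed share in
contemporary high-quality European registers is about one third);
truth retained on the certificate for 80% of garbled deaths; and Poisson
contributory-code noise. Optional multipliers make IDD prevalence rise with
age and differ by sex, reproducing the qualitative pattern seen in real
registers; they are off by default so the realized IDD share is exactly
binomial around `idd_fraction`.

Two generator choices are deliberate and load-bearing:

- **Cause-independent garbling (default).** Every true cause routes the
  same total probability mass to *proportionally* redistributed garbage —
  package codes plus the share of R99 deaths whose chain does not retain
  the truth. Causes with a natural predefined-target code (C55, I64, J18.9,
  C80) send part of their mass there instead; within each target set the
  garble rate is uniform, so pro-rata step-1 recovery is unbiased, and the
  C76/C80 target set in the demo map contains exactly the cancers that feed
  it. Under these defaults steps 2 and 4 are unbiased in expectation, which
  is what makes the recovery tests sharp. Cause-*dependent* garbling — the
  documented failure mode of proportional redistribution — is one config
  change away (per-cause `garble_targets`).
- **Non-specific MCOD noise (default).** Contributory noise codes are
  themselves garbage or unmapped codes, so for an R99 death the retained
  true cause is the only specific candidate and internal redistribution
  reads the truth back exactly. Specific noise codes (hypertension,
  diabetes as contributory causes) would make step 3 a biased uniform draw;
  that regime can be produced by adding specific codes to `noise_codes`.

What the generator does **not** emulate: coding-practice drift over time,
correlation between MCOD chain length and cause, regional coding
differences, multi-morbidity structure in the chain, or any fitting to real
national marginals. Passing recovery tests therefore demonstrate that the
*mechanism* is implemented correctly and is unbiased under its stated
assumptions — not that real-world IDDs satisfy those assumptions.

The companion population table uses a fixed plausible age pyramid scaled to
100 persons per annual death (crude mortality ≈ 1,000 per 100,000),
constant across years.

## Numerical choices and degenerate inputs

- Probability normalization happens once per (group, stratum); masses sum
  to 1 within 1e-12.
- Percentiles use the default linear interpolation; with constant
  per-iteration counts the interval collapses to the mean exactly.
- Empty strata, empty MCOD chains, IDD-only MCOD chains, single-cause
  pools and pools with no valid target all take defined paths (fallback,
  deferral, or a named error), each covered by a test.
- Determinism contract: identical records, map, config and master seed give
  byte-identical ensembles and output files.

## Problem sizes

Default test and demonstration sizes are chosen so the full suite runs in a
few minutes on one CPU: unit fixtures of 10–10,000 records; conservation
checked on 20,000 deaths × 10 iterations; recovery on 50,000 deaths × 20
iterations, repeated over 20 generations for interval-calibration checks
(pooled coverage of the truth is ~85% — the intervals reflect reassignment
randomness only, not the garbling randomness of the data-generating
process, so modest under-coverage is expected and documented rather than
corrected). The acceptance script uses the same sizes. The engine
vectorizes over records (integer cause indices, per-stratum count tensors),
so a 50,000-death, 20-iteration run takes seconds; 100 iterations on a
decade of national-scale data (~100,000 deaths/year) extrapolates to
roughly an hour.

## Known limitations

- Step 3 treats every certificate mention equally (uniform over distinct
  causes); frequency- or role-weighted variants are not implemented.
- The demo cause map is illustrative, not a complete national map, and its
  sex-restriction list is a configurable default, not a standard.
- Fractional mode stores dense per-record weight vectors and is intended
  for small-to-medium datasets and validation, not production-scale runs.
- Rates assume the population table covers every stratum with deaths; there
  is no small-area smoothing.
- No regression-based or fixed-proportion redistribution is provided; the
  method is deliberately restricted to the four steps above.
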