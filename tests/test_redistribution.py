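"""The four-step redistribution: target distributions, steps, ensembles."""

import numpy as np
import pytest
from scipy import stats

import gcredist as g


def specific_pool(mk, counts, age=50, sex="female", years=(2000, 2004), mcod=()):
    """Specific deaths spread over the window years: ``counts`` maps UC code
    to the number of deaths carrying it."""
    recs = []
    i = 0
    yrs = list(range(years[0], years[1] + 1))
    for uc, n in counts.items():
        for k in range(n):
            recs.append(mk(f"p{i}", year=yrs[i % len(yrs)], age=age, sex=sex,
                           uc=uc, mcod=list(mcod)))
            i += 1
    return recs


def run_once(records, cmap, **overrides):
    cfg = g.RedistributionConfig(n_iterations=1, master_seed=17, **overrides)
    red = g.Redistributor(records, cmap, cfg)
    state = red.run_iteration(0)
    return red, state


def cause_of(red, state, rid):
    pos = int(np.nonzero(red.rec_id == rid)[0][0])
    if pos in state.frac:
        cs, ws = state.frac[pos]
        return {red.causes[c]: w for c, w in zip(cs, ws)}
    c = state.cur[pos]
    return red.causes[c] if c >= 0 else None


def step_of(red, state, rid):
    pos = int(np.nonzero(red.rec_id == rid)[0][0])
    return int(state.step[pos])


class TestBuildTargetDistribution:
    def paired(self, recs, cmap):
        return list(zip(recs, g.classify_records(recs, cmap)))

    def test_hand_counted_proportions(self, mk, cmap):
        pool = self.paired(specific_pool(mk, {"C539": 30, "C549": 70}), cmap)
        d = g.build_target_distribution(
            pool, 2004, g.Stratum("45-64", "female"), cmap, restrict_to=["C53", "C54"]
        )
        assert d.masses == {"cervical_cancer": pytest.approx(0.30),
                           "uterine_cancer": pytest.approx(0.70)}
        assert d.support_counts == {"cervical_cancer": 30, "uterine_cancer": 70}

    def test_sex_restriction_empties_male_stratum(self, mk, cmap):
        pool = self.paired(specific_pool(mk, {"C539": 30, "C549": 70}), cmap)
        d = g.build_target_distribution(
            pool, 2004, g.Stratum("45-64", "male"), cmap, restrict_to=["C53", "C54"]
        )
        assert d.empty

    def test_rare_cause_dropped_from_targets(self, mk, cmap):
        pool = self.paired(specific_pool(mk, {"C539": 4, "C549": 70}), cmap)
        d = g.build_target_distribution(
            pool, 2004, g.Stratum("45-64", "female"), cmap, restrict_to=["C53", "C54"]
        )
        assert d.masses == {"uterine_cancer": pytest.approx(1.0)}

    def test_window_excludes_older_years(self, mk, cmap):
        old = specific_pool(mk, {"C539": 50}, years=(1998, 1999))
        new = specific_pool(mk, {"C549": 70}, years=(2000, 2004))
        for i, r in enumerate(old):
            r.record_id = f"old{i}"
        pool = self.paired(old + new, cmap)
        d = g.build_target_distribution(
            pool, 2004, g.Stratum("45-64", "female"), cmap, restrict_to=["C53", "C54"]
        )
        assert set(d.masses) == {"uterine_cancer"}

    def test_sparse_stratum_falls_back_to_sex_only(self, mk, cmap):
        young = specific_pool(mk, {"C539": 10}, age=30)
        older = specific_pool(mk, {"C549": 30}, age=50)
        for i, r in enumerate(older):
            r.record_id = f"o{i}"
        pool = self.paired(young + older, cmap)
        d = g.build_target_distribution(
            pool, 2004, g.Stratum("15-44", "female"), cmap, restrict_to=["C53", "C54"]
        )
        # the 15-44 stratum alone holds 10 deaths (< 20): sex-only is used
        assert d.stratum == g.Stratum(None, "female")
        assert d.masses == {"cervical_cancer": pytest.approx(0.25),
                           "uterine_cancer": pytest.approx(0.75)}

    @pytest.mark.parametrize("case", range(6))
    def test_engine_agrees_with_reference(self, mk, cmap, case):
        """The vectorized all-cause step reproduces the reference
        target-distribution construction on randomized pools."""
        rng = np.random.default_rng(100 + case)
        codes = ["I219", "J449", "G309", "W10", "C349", "N189"]
        recs = []
        i = 0
        for code in codes:
            for _ in range(int(rng.integers(0, 25))):
                recs.append(mk(f"p{i}", year=int(rng.integers(2000, 2005)),
                               age=int(rng.choice([3, 30, 70, 90])),
                               sex=str(rng.choice(["male", "female"])), uc=code))
                i += 1
        age, sex = int(rng.choice([30, 70])), str(rng.choice(["male", "female"]))
        idd = mk("idd", year=2004, age=age, sex=sex, uc="R99")
        ref = g.build_target_distribution(
            list(zip(recs, g.classify_records(recs, cmap))), 2004,
            g.Stratum(g.AGE_GROUP_LABELS[g.age_group_index(age)], sex), cmap,
        )
        if ref.empty:
            pytest.skip("degenerate random pool")
        red, state = run_once(recs + [idd], cmap, mode="fractional")
        got = cause_of(red, state, "idd")
        assert set(got) == set(ref.masses)
        for c, w in ref.masses.items():
            assert got[c] == pytest.approx(w)


class TestStep1:
    def test_draws_match_binomial_oracle(self, mk, cmap):
        pool = specific_pool(mk, {"C539": 30, "C549": 70})
        idds = [mk(f"i{k}", year=2004, age=50, uc="C55") for k in range(10_000)]
        red, state = run_once(pool + idds, cmap)
        drawn = [cause_of(red, state, f"i{k}") for k in range(10_000)]
        frac_c53 = np.mean([c == "cervical_cancer" for c in drawn])
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(frac_c53 - 0.30) < 3 * se
        assert {step_of(red, state, f"i{k}") for k in range(100)} == {1}

    def test_no_observed_targets_defers_to_all_cause(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 40})
        idd = mk("idd", year=2004, age=50, uc="C55")
        red, state = run_once(pool + [idd], cmap)
        assert step_of(red, state, "idd") == 4
        assert cause_of(red, state, "idd") == "ihd"

    def test_fractional_even_split(self, mk, cmap):
        pool = specific_pool(mk, {"C539": 50, "C549": 50})
        idd = mk("idd", year=2004, age=50, uc="C55")
        red, state = run_once(pool + [idd], cmap, mode="fractional")
        assert cause_of(red, state, "idd") == {
            "cervical_cancer": pytest.approx(0.5), "uterine_cancer": pytest.approx(0.5)
        }


class TestStep2:
    def carriers(self, mk):
        recs = specific_pool(mk, {"E119": 6}, age=70,
                             mcod=[("N170", "associated")])
        extra = specific_pool(mk, {"I110": 2}, age=70,
                              mcod=[("N179", "intermediate")])
        floor = specific_pool(mk, {"I119": 3}, age=70)  # lifts hhd over the rare floor
        for i, r in enumerate(extra):
            r.record_id = f"x{i}"
        for i, r in enumerate(floor):
            r.record_id = f"f{i}"
        return recs + extra + floor

    def test_package_target_hand_count(self, mk, cmap):
        idd = mk("idd", year=2004, age=70, uc="N19")
        red, state = run_once(self.carriers(mk) + [idd], cmap,
                              mode="fractional", sparse_stratum_min=1)
        assert cause_of(red, state, "idd") == {
            "diabetes": pytest.approx(0.75), "hypertensive_hd": pytest.approx(0.25)
        }
        assert step_of(red, state, "idd") == 2

    def test_no_mcod_carriers_defers(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 40})
        idd = mk("idd", year=2004, age=50, uc="N19")
        red, state = run_once(pool + [idd], cmap)
        assert step_of(red, state, "idd") == 4

    def test_unresolved_carriers_do_not_count(self, mk, cmap):
        # the only deaths mentioning a package code are themselves IDDs that
        # are still unresolved when the package is processed
        pool = specific_pool(mk, {"I219": 40})
        bad = [mk(f"b{k}", year=2003, age=50, uc="R99",
                  mcod=[("N170", "associated")]) for k in range(5)]
        idd = mk("idd", year=2004, age=50, uc="N19")
        red, state = run_once(pool + bad + [idd], cmap)
        assert step_of(red, state, "idd") == 4


class TestStep3:
    def test_uniform_over_mentioned_causes(self, mk, cmap):
        pool = specific_pool(mk, {"C349": 6, "I10": 6})
        idds = [mk(f"i{k}", year=2004, age=50, uc="R99",
                   mcod=[("C349", "intermediate"), ("I10", "associated")])
                for k in range(10_000)]
        red, state = run_once(pool + idds, cmap)
        drawn = [cause_of(red, state, f"i{k}") for k in range(10_000)]
        assert set(drawn) == {"lung_cancer", "hypertensive_hd"}
        frac = np.mean([c == "lung_cancer" for c in drawn])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)
        assert step_of(red, state, "i0") == 3

    def test_empty_mcod_passes_to_step4(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 40})
        idd = mk("idd", year=2004, age=50, uc="R99")
        red, state = run_once(pool + [idd], cmap)
        assert step_of(red, state, "idd") == 4

    def test_idd_only_mcod_passes_to_step4(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 40})
        idd = mk("idd", year=2004, age=50, uc="R99", mcod=[("R54", "associated")])
        red, state = run_once(pool + [idd], cmap)
        assert step_of(red, state, "idd") == 4


class TestStep4:
    def test_draws_match_pool_proportions(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 90, "J449": 10})
        idds = [mk(f"i{k}", year=2004, age=50, uc="R99") for k in range(10_000)]
        red, state = run_once(pool + idds, cmap)
        drawn = [cause_of(red, state, f"i{k}") for k in range(10_000)]
        frac = np.mean([c == "ihd" for c in drawn])
        assert abs(frac - 0.9) < 3 * np.sqrt(0.09 / 10_000)

    def test_single_cause_pool_assigns_it(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 30})
        idd = mk("idd", year=2004, age=50, uc="R99")
        red, state = run_once(pool + [idd], cmap)
        assert cause_of(red, state, "idd") == "ihd"

    def test_empty_stratum_uses_sex_only_distribution(self, mk, cmap):
        pool = specific_pool(mk, {"I219": 50}, age=70)
        idd = mk("idd", year=2004, age=2, uc="R99")  # no specific deaths aged 0-4
        red, state = run_once(pool + [idd], cmap)
        assert cause_of(red, state, "idd") == "ihd"
        assert step_of(red, state, "idd") == 4

    def test_degenerate_pool_raises(self, mk, cmap):
        recs = [mk("only", year=2004, age=50, uc="R99")]
        with pytest.raises(g.DegenerateInputError):
            run_once(recs, cmap, window_years=1)


class TestSamplingHelpers:
    def test_two_target_frequencies(self):
        dist = g.TargetDistribution(g.Stratum(None, None),
                                    {"a": 0.30, "b": 0.70}, {"a": 30, "b": 70})
        rng = np.random.default_rng(4)
        draws = g.sample_from_distribution(dist, 10_000, rng)
        frac = np.mean([d == "a" for d in draws])
        assert abs(frac - 0.30) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_chi_square_goodness_of_fit(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        dist = g.TargetDistribution(
            g.Stratum(None, None),
            dict(zip("abcd", p)), dict(zip("abcd", 10 * p)),
        )
        rng = np.random.default_rng(12345)
        draws = g.sample_from_distribution(dist, 10_000, rng)
        observed = [draws.count(c) for c in "abcd"]
        gof = stats.chisquare(observed, f_exp=10_000 * p)
        assert gof.pvalue > 0.01


class TestOrchestration:
    def test_same_master_seed_identical_ensembles(self, cmap, small_synthetic):
        _, records, _, red, ensemble = small_synthetic
        again = g.Redistributor(records, cmap, red.config).run()
        assert np.array_equal(ensemble.assignments, again.assignments)
        assert np.array_equal(ensemble.steps, again.steps)

    def test_report_years_skip_lead_in(self, mk, cmap):
        recs = [mk(f"r{y}", year=y, age=70, uc="I219") for y in range(2000, 2020)]
        red = g.Redistributor(recs, cmap, g.RedistributionConfig(n_iterations=1))
        assert red.report_years == list(range(2004, 2020))

    def test_insufficient_lead_in_raises(self, mk, cmap):
        recs = [mk(f"r{y}", year=y, age=70, uc="I219") for y in range(2000, 2003)]
        with pytest.raises(g.InsufficientLeadInError, match="2004"):
            g.Redistributor(recs, cmap, g.RedistributionConfig(n_iterations=1))

    def test_single_fractional_iteration_is_deterministic(self, mk, cmap):
        recs = specific_pool(mk, {"C539": 30, "C549": 70}) + [
            mk("idd", year=2004, age=50, uc="C55")
        ]
        cfg = g.RedistributionConfig(n_iterations=1, mode="fractional")
        a = g.Redistributor(recs, cmap, cfg).run().to_frame()
        b = g.Redistributor(recs, cmap, cfg).run().to_frame()
        assert a.equals(b)

    def test_constant_counts_have_zero_width_interval(self, mk, cmap):
        recs = [mk(f"r{y}-{k}", year=y, age=70, uc="I219")
                for y in range(2000, 2006) for k in range(3)]
        ens = g.Redistributor(recs, cmap, g.RedistributionConfig(n_iterations=10)).run()
        s = g.summarize_ensemble(ens, group_by=("year",), level=3)
        assert (s["lower"] == s["mean"]).all() and (s["mean"] == s["upper"]).all()

    def test_step_shares_partition_deaths(self, small_synthetic):
        _, _, _, _, ensemble = small_synthetic
        shares = g.step_shares(ensemble, by=("year",))
        totals = shares.groupby("year")["share"].sum()
        assert np.allclose(totals, 1.0)

    def test_conservation_and_specificity(self, small_synthetic):
        _, _, _, _, ensemble = small_synthetic
        report = g.check_conservation(ensemble)
        assert report == {"max_abs_cell_diff": 0.0, "n_unresolved": 0}

    def test_idd_share_by_cause_bounded(self, small_synthetic):
        _, _, _, _, ensemble = small_synthetic
        share = g.idd_share_by_cause(ensemble)
        ok = share["idd_share"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()
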