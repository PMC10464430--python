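"""SEYLL weights, crude and age-standardized rates, leading causes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gcredist as g
from gcredist.io import ValidationError


class TestCompleteLifeTable:
    def test_appends_terminal_anchor(self):
        lt = g.complete_life_table(g.LifeTable([0, 50, 95], [85.0, 38.0, 6.0]))
        assert lt.ages[-1] == 122 and lt.residual_expectancy[-1] == 0.0
        assert lt.ages[-2] == 95 and lt.residual_expectancy[-2] == 6.0

    def test_idempotent_when_anchor_present(self):
        raw = g.LifeTable([0, 95, 122], [85.0, 6.0, 0.0])
        assert g.complete_life_table(raw) is raw

    def test_rejects_increasing_expectancy(self):
        with pytest.raises(ValidationError, match="non-increasing"):
            g.complete_life_table(g.LifeTable([0, 50, 95], [85.0, 40.0, 41.0]))

    def test_rejects_nonzero_terminal_value(self):
        with pytest.raises(ValidationError, match="122"):
            g.complete_life_table(g.LifeTable([0, 122], [85.0, 1.0]))


class TestSeyllAtAge:
    def test_zero_at_age_122(self):
        w = g.SeyllWeightFunction(g.demo_life_table())
        assert g.seyll_at_age(w, 122) == 0.0

    def test_exact_at_knots(self):
        lt = g.demo_life_table()
        w = g.SeyllWeightFunction(lt)
        for age, ex in zip(lt.ages, lt.residual_expectancy):
            assert g.seyll_at_age(w, age) == pytest.approx(ex)

    def test_linear_midpoint(self):
        w = g.SeyllWeightFunction(g.LifeTable([0, 95], [80.0, 10.0]))
        assert g.seyll_at_age(w, 108.5) == pytest.approx(5.0)

    def test_age_out_of_range(self):
        w = g.SeyllWeightFunction(g.demo_life_table())
        for bad in (-1, 123):
            with pytest.raises(ValidationError):
                g.seyll_at_age(w, bad)

    @given(st.floats(min_value=0, max_value=122, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_interpolation_bounded_by_bracketing_knots(self, age):
        lt = g.complete_life_table(g.demo_life_table())
        w = g.SeyllWeightFunction(lt)
        i = np.searchsorted(lt.ages, age, side="right")
        lo = max(i - 1, 0)
        hi = min(i, len(lt.ages) - 1)
        val = g.seyll_at_age(w, age)
        assert lt.residual_expectancy[hi] - 1e-9 <= val <= lt.residual_expectancy[lo] + 1e-9


class TestComputeSeyll:
    def ensemble(self, mk, cmap, records, iters=3):
        return g.Redistributor(
            records, cmap, g.RedistributionConfig(n_iterations=iters)
        ).run()

    def test_additivity_and_anchor(self, mk, cmap):
        lt = g.LifeTable([0, 95], [80.0, 10.0])
        w = g.SeyllWeightFunction(lt)
        recs = (
            [mk(f"a{y}", year=y, age=95, uc="I219") for y in range(2000, 2005)]
            + [mk("b1", year=2004, age=95, uc="I219"),
               mk("c1", year=2004, age=122, uc="J449")]
        )
        ens = self.ensemble(mk, cmap, recs)
        s = g.compute_seyll(ens, w, group_by=(), level=3)
        by_cause = s.set_index("cause")["mean"]
        assert by_cause["ischemic_heart_disease"] == pytest.approx(2 * 10.0)
        assert by_cause["copd"] == pytest.approx(0.0)  # death at the 122 anchor

    def test_constant_assignments_zero_width_interval(self, mk, cmap):
        recs = [mk(f"r{y}", year=y, age=70, uc="I219") for y in range(2000, 2006)]
        ens = self.ensemble(mk, cmap, recs, iters=8)
        s = g.compute_seyll(ens, g.SeyllWeightFunction(g.demo_life_table()))
        assert (s["lower"] == s["upper"]).all()


class TestRates:
    def test_crude_rate_definitional(self):
        assert g.crude_rate(972, 100_000) == pytest.approx(972.0)
        assert g.crude_rate(0, 100_000) == 0.0

    def test_crude_rate_arithmetic_oracle(self):
        assert g.crude_rate(101_250, 10_416_666) == pytest.approx(972.0, abs=0.05)

    def test_crude_rate_rejects_zero_population(self):
        with pytest.raises(ValidationError):
            g.crude_rate(10, 0)

    def test_asr_equals_crude_when_structures_match(self):
        std = g.esp2013()
        rng = np.random.default_rng(0)
        pop = {int(lo): float(w) * 50 for lo, w in zip(std.age_lo, std.weight)}
        counts = {a: p * rng.uniform(0.001, 0.05) for a, p in pop.items()}
        asr = g.age_standardized_rate(counts, pop, std)
        crude = g.crude_rate(sum(counts.values()), sum(pop.values()))
        assert asr == pytest.approx(crude, rel=1e-9)

    def test_asr_constant_rates(self):
        std = g.esp2013()
        pop = {int(lo): 10_000.0 for lo in std.age_lo}
        counts = {a: p * 0.012 for a, p in pop.items()}
        assert g.age_standardized_rate(counts, pop, std) == pytest.approx(1200.0)

    def test_two_group_hand_example(self):
        std = g.StandardPopulation([0, 5], [0.25, 0.75])
        counts = {0: 10.0, 5: 30.0}
        pop = {0: 100_000.0, 5: 100_000.0}
        # rates 10 and 30 per 100k, weights 0.25/0.75 -> 25 per 100k
        assert g.age_standardized_rate(counts, pop, std) == pytest.approx(25.0)

    def test_asr_missing_population_with_deaths_raises(self):
        std = g.StandardPopulation([0, 5], [1.0, 1.0])
        with pytest.raises(ValidationError):
            g.age_standardized_rate({0: 5.0, 5: 1.0}, {0: 1000.0}, std)

    @given(st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_asr_invariant_to_joint_scaling(self, factor):
        std = g.esp2013()
        pop = {int(lo): 5_000.0 + 37 * lo for lo in std.age_lo}
        counts = {a: p * (0.001 + a / 5_000) for a, p in pop.items()}
        base = g.age_standardized_rate(counts, pop, std)
        scaled = g.age_standardized_rate(
            {a: c * factor for a, c in counts.items()},
            {a: p * factor for a, p in pop.items()}, std)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestBurdenTable:
    def test_schema_and_interval_ordering(self, small_synthetic, cmap):
        cfg, _, _, _, ensemble = small_synthetic
        table = g.compute_burden(ensemble, g.demo_life_table(),
                                 g.population_table(cfg), group_by=("sex",))
        assert set(table["measure"]) == {"deaths", "seyll"}
        assert set(table["statistic"]) == {"count", "crude_rate", "asr"}
        assert (table["lower"] <= table["mean"] + 1e-9).all()
        assert (table["mean"] <= table["upper"] + 1e-9).all()

    def test_counts_match_summarize(self, small_synthetic, cmap):
        cfg, _, _, _, ensemble = small_synthetic
        table = g.compute_burden(ensemble, g.demo_life_table(), g.population_table(cfg))
        counts = table[(table["measure"] == "deaths") & (table["statistic"] == "count")]
        direct = g.summarize_ensemble(ensemble, group_by=("year",), level=3)
        merged = counts.merge(direct, on=["year", "cause"], suffixes=("", "_direct"))
        assert np.allclose(merged["mean"], merged["mean_direct"])


class TestLeadingCauses:
    def toy_table(self):
        rows = []
        for year, values in [(2004, [100, 80, 60, 40, 20]), (2019, [44, 90, 50, 45, 10])]:
            for cause, v in zip("abcde", values):
                rows.append({"year": year, "cause": cause, "level": 3, "sex": "all",
                             "region": "all", "measure": "deaths", "statistic": "asr",
                             "standard": "esp2013", "mean": float(v),
                             "lower": v * 0.9, "upper": v * 1.1})
        return pd.DataFrame(rows)

    def test_top_k_ordering(self):
        top = g.leading_causes(self.toy_table(), 2019, k=3)
        assert list(top["cause"]) == ["b", "c", "d"]
        assert list(top["rank"]) == [1, 2, 3]
        assert top["mean"].is_monotonic_decreasing

    def test_baseline_equal_year_zero_change(self):
        top = g.leading_causes(self.toy_table(), 2004, k=5, baseline_year=2004)
        assert np.allclose(top["pct_change"], 0.0)

    def test_percent_change_hand_example(self):
        top = g.leading_causes(self.toy_table(), 2019, k=5, baseline_year=2004)
        assert top.set_index("cause")["pct_change"]["a"] == pytest.approx(-56.0)

    def test_empty_slice_raises(self):
        with pytest.raises(ValidationError):
            g.leading_causes(self.toy_table(), 1999)
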