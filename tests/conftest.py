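import pytest

import gcredist as g


def make_record(rid, year=2004, age=70, sex="female", region="north",
                uc="C539", mcod=()):
    return g.DeathRecord(
        record_id=rid, year=year, age=age, sex=sex, region=region,
        underlying_cause=uc, mcod=list(mcod),
    )


@pytest.fixture(scope="session")
def mk():
    """Factory for terse death-record construction in fixtures."""
    return make_record


@pytest.fixture(scope="session")
def cmap():
    return g.demo_map()


@pytest.fixture(scope="session")
def small_synthetic(cmap):
    """A compact synthetic dataset with its redistribution ensemble,
    shared by tests that only read it."""
    cfg = g.GeneratorConfig(n_per_year=1200, years=(2000, 2006), seed=5)
    records, truth = g.generate(cfg)
    red = g.Redistributor(records, cmap,
                          g.RedistributionConfig(n_iterations=5, master_seed=3))
    ensemble = red.run()
    return cfg, records, truth, red, ensemble
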