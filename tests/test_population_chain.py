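"""Ageing-chain stocks, flows, budding and the high-risk predicate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dipsim.population_chain import (AgeingChain, PopulationTable,
                                     ValidationError, adips_high_risk,
                                     bud_agents, generate_population_table,
                                     init_stocks, step_chain)


def make_table(rows):
    return PopulationTable(pd.DataFrame(rows))


class TestInitStocks:
    def test_single_row_identity(self):
        tab = make_table([{"age_band": "15-19", "risk_group": "standard",
                           "count": 100}])
        chain = init_stocks(tab)
        assert chain.total == 100
        assert chain.stocks[3, 0] == 100
        assert (chain.stocks != 0).sum() == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            make_table([])

    def test_negative_count_names_row(self):
        with pytest.raises(ValidationError, match="row 1"):
            make_table([
                {"age_band": "15-19", "risk_group": "standard", "count": 5},
                {"age_band": "20-24", "risk_group": "standard", "count": -1},
            ])

    def test_fixture_generator_totals(self):
        tab = generate_population_table(10_000, 0.2, seed=1)
        assert tab.total == 10_000
        hr = tab.table.loc[tab.table.risk_group == "high_risk_ethnicity",
                           "count"].sum()
        # multinomial draw around the 20% target
        assert hr == pytest.approx(2000, abs=150)
        chain = init_stocks(tab)
        assert chain.total == 10_000

    def test_csv_round_trip(self, tmp_path, pop_table):
        p = tmp_path / "pop.csv"
        pop_table.to_csv(p)
        back = PopulationTable.from_csv(p)
        assert back.total == pop_table.total
        assert back.fraction_high_risk == pytest.approx(
            pop_table.fraction_high_risk)


class TestStepChain:
    def test_ageing_outflow(self):
        tab = make_table([{"age_band": "15-19", "risk_group": "standard",
                           "count": 50}])
        chain = init_stocks(tab, exit_rate=np.zeros(18))
        out = step_chain(chain, 1.0)
        assert out.stocks[3, 0] == pytest.approx(40.0)   # 50 - 50/5
        assert out.stocks[4, 0] == pytest.approx(10.0)

    def test_identity_with_infinite_residence(self):
        tab = make_table([{"age_band": "15-19", "risk_group": "standard",
                           "count": 50}])
        chain = init_stocks(tab, exit_rate=np.zeros(18),
                            aging_residence_time=np.inf)
        out = step_chain(chain, 1.0)
        assert np.array_equal(out.stocks, chain.stocks)

    def test_outflow_capped_at_stock(self):
        tab = make_table([{"age_band": "15-19", "risk_group": "standard",
                           "count": 1.0}])
        chain = init_stocks(tab, exit_rate=np.full(18, 5.0))
        out = step_chain(chain, 1.0)
        assert out.stocks.min() >= 0.0

    def test_rejects_nonpositive_dt(self, pop_table):
        with pytest.raises(ValueError):
            step_chain(init_stocks(pop_table), 0.0)

    def test_person_conservation_100_years(self, pop_table, rng):
        chain = init_stocks(pop_table)
        chain.entry_rate = np.array([120.0, 30.0])
        for _ in range(100 * 12):
            chain = step_chain(chain, 1 / 12)
        assert chain.conservation_error() < 1e-9

    def test_stationary_age_distribution(self):
        tab = generate_population_table(5000, 0.2, seed=3)
        chain = init_stocks(tab)  # default mortality schedule
        chain.entry_rate = np.array([100.0, 25.0])
        dist = None
        for step in range(210 * 4):
            chain = step_chain(chain, 0.25)
            if step == (200 * 4) - 1:
                dist = chain.stocks / chain.total
        dist10 = chain.stocks / chain.total
        assert np.abs(dist10 - dist).sum() < 0.01


class TestHighRiskPredicate:
    def test_ethnicity_alone_is_high_risk(self):
        assert adips_high_risk(True, 25, False, False, 22.0)

    def test_low_risk_profile(self):
        assert not adips_high_risk(False, 25, False, False, 22.0)

    def test_age_criterion(self):
        assert adips_high_risk(False, 41, False, False, 22.0)

    @given(eth=st.booleans(), age=st.floats(15, 60), gdm=st.booleans(),
           fh=st.booleans(), bmi=st.floats(16, 50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_every_risk_attribute(self, eth, age, gdm, fh, bmi):
        base = adips_high_risk(eth, age, gdm, fh, bmi)
        if base:
            assert adips_high_risk(True, age + 5, True, True, bmi + 5)


class TestBudding:
    def test_budding_conserves_persons(self, pop_table, rng):
        chain = init_stocks(pop_table)
        total0 = chain.total
        out, agents = bud_agents(chain, lambda i, g: 3 <= i <= 9, 10, rng)
        assert len(agents) == 10
        assert out.total == pytest.approx(total0 - 10)
        assert out.conservation_error() < 1e-9

    def test_bud_zero_is_identity(self, pop_table, rng):
        chain = init_stocks(pop_table)
        out, agents = bud_agents(chain, lambda i, g: True, 0, rng)
        assert agents == []
        assert np.array_equal(out.stocks, chain.stocks)

    def test_overdraw_raises(self, pop_table, rng):
        chain = init_stocks(pop_table)
        with pytest.raises(ValueError):
            bud_agents(chain, lambda i, g: i == 3, 10**9, rng)

    def test_seeded_budding_is_reproducible(self, pop_table):
        chain = init_stocks(pop_table)
        _, a1 = bud_agents(chain, lambda i, g: 3 <= i <= 9, 50,
                           np.random.default_rng(9))
        _, a2 = bud_agents(chain, lambda i, g: 3 <= i <= 9, 50,
                           np.random.default_rng(9))
        assert [x.bmi for x in a1] == [x.bmi for x in a2]
        assert [x.birth_time for x in a1] == [x.birth_time for x in a2]

    def test_agents_sampled_within_band_with_matching_ethnicity(self, pop_table):
        chain = init_stocks(pop_table)
        _, agents = bud_agents(chain, lambda i, g: i == 4 and g == 1, 20,
                               np.random.default_rng(4))
        for a in agents:
            assert 20 <= -a.birth_time < 25
            assert a.ethnicity_high_risk

    def test_rate_budding_preserves_expectation(self, pop_table):
        chain = init_stocks(pop_table)
        counts = []
        for s in range(30):
            _, agents = bud_agents(chain, lambda i, g: 3 <= i <= 9, 0.01,
                                   np.random.default_rng(s))
            counts.append(len(agents))
        eligible = chain.stocks[3:10].sum()
        assert np.mean(counts) == pytest.approx(0.01 * eligible, rel=0.25)
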