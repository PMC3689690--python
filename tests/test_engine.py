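import dataclasses

import numpy as np
import pytest

from drsim.cohort import CohortConfig, generate_cohort
from drsim.domain import (
    DRState,
    LogisticHazard,
    TransitionRates,
    ValidationError,
    make_agent,
)
from drsim.engine import (
    add_entrants,
    annual_event,
    run_simulation,
    summarize_groups,
)
from drsim.hazard import progression_probability
from drsim.lifetable import gompertz_table
from .conftest import constant_specs

CERTAIN_DEATH = gompertz_table(1e6, 0.0, max_age=300)


def make_test_agent(profile, state, record_history=True):
    return make_agent(profile, state, entry_year=0, record_history=record_history)


class TestAnnualEvent:
    def test_certain_onset(self, profile, zero_mortality_table, rng):
        agent = make_test_agent(profile, DRState.NO_DR)
        rates = TransitionRates(onset_annual=1.0)
        annual_event(agent, LogisticHazard({}, 0.0), rates, zero_mortality_table, rng, year=1)
        assert agent.state is DRState.NPDR

    def test_all_rates_zero_is_noop_on_state(self, profile, zero_mortality_table, rng):
        agent = make_test_agent(profile, DRState.PDR)
        age0, dur0 = agent.profile.age, agent.profile.dm_duration
        rates = TransitionRates(onset_annual=0.0, vl_annual=0.0, prp_annual=0.0)
        annual_event(agent, LogisticHazard({}, -50.0), rates, zero_mortality_table, rng, year=1)
        assert agent.state is DRState.PDR
        assert agent.profile.age == age0 + 1
        assert agent.profile.dm_duration == dur0 + 1

    def test_dead_agent_rejected(self, profile, zero_mortality_table, rng):
        agent = make_test_agent(profile, DRState.PDR)
        agent.state = DRState.DEATH
        with pytest.raises(ValidationError, match="dead"):
            annual_event(agent, LogisticHazard({}, 0.0), TransitionRates(),
                         zero_mortality_table, rng, year=1)

    def test_death_precedes_progression(self, profile, rng):
        # event order: increment, then mortality at the new age, then DR
        # transitions only if alive — certain death blocks certain onset
        agent = make_test_agent(profile, DRState.NO_DR)
        rates = TransitionRates(onset_annual=1.0)
        annual_event(agent, LogisticHazard({}, 0.0), rates, CERTAIN_DEATH, rng, year=1)
        assert agent.state is DRState.DEATH
        assert agent.profile.age == profile.age  # same object, incremented
        assert agent.history == [(0, DRState.NO_DR), (1, DRState.DEATH)]

    def test_increment_happens_before_mortality_lookup(self, profile, rng):
        # qx = 1 only at age 68: a 67-year-old must die this year
        qx = np.zeros(200)
        qx[68] = 1.0
        qx[-1] = 1.0
        from drsim.lifetable import LifeTable

        table = LifeTable(qx, qx)
        agent = make_test_agent(dataclasses.replace(profile, age=67.0), DRState.NPDR)
        annual_event(agent, LogisticHazard({}, -50.0), TransitionRates(), table, rng, year=1)
        assert agent.state is DRState.DEATH

    def test_at_most_one_forward_transition_per_year(self, profile, zero_mortality_table, rng):
        # even with certain onset AND certain progression probability, an
        # agent starting at NO_DR only reaches NPDR within one event
        agent = make_test_agent(profile, DRState.NO_DR)
        rates = TransitionRates(onset_annual=1.0, vl_annual=1.0)
        annual_event(agent, LogisticHazard({}, 50.0), rates, zero_mortality_table, rng, year=1)
        assert agent.state is DRState.NPDR

    def test_prp_reverts_pdr_to_npdr(self, profile, zero_mortality_table, rng):
        agent = make_test_agent(profile, DRState.PDR)
        rates = TransitionRates(vl_annual=0.0, prp_annual=1.0)
        annual_event(agent, LogisticHazard({}, 0.0), rates, zero_mortality_table, rng, year=1)
        assert agent.state is DRState.NPDR

    def test_vl_draw_precedes_prp(self, profile, zero_mortality_table, rng):
        agent = make_test_agent(profile, DRState.PDR)
        rates = TransitionRates(vl_annual=1.0, prp_annual=1.0)
        annual_event(agent, LogisticHazard({}, 0.0), rates, zero_mortality_table, rng, year=1)
        assert agent.state is DRState.VL

    def test_onset_frequency_within_monte_carlo_error(self, zero_mortality_table, profile):
        # 50k one-year draws against the 7.7% onset rate
        rng = np.random.default_rng(99)
        rates = TransitionRates()
        hz = LogisticHazard({}, 0.0)
        n = 50_000
        onsets = 0
        for _ in range(n):
            agent = make_test_agent(dataclasses.replace(profile), DRState.NO_DR,
                                    record_history=False)
            annual_event(agent, hz, rates, zero_mortality_table, rng)
            onsets += agent.state is DRState.NPDR
        se = np.sqrt(0.077 * (1 - 0.077) / n)
        assert abs(onsets / n - 0.077) < 3 * se

    def test_vision_loss_frequency_within_monte_carlo_error(self, zero_mortality_table, profile):
        rng = np.random.default_rng(98)
        rates = TransitionRates()
        hz = LogisticHazard({}, 0.0)
        n = 50_000
        losses = 0
        for _ in range(n):
            agent = make_test_agent(dataclasses.replace(profile), DRState.PDR,
                                    record_history=False)
            annual_event(agent, hz, rates, zero_mortality_table, rng)
            losses += agent.state is DRState.VL
        se = np.sqrt(0.007 * (1 - 0.007) / n)
        assert abs(losses / n - 0.007) < 3 * se

    def test_npdr_progression_uses_logistic_probability(self, zero_mortality_table, profile):
        # progression frequency matches the agent's own predicted p
        rng = np.random.default_rng(97)
        hz = LogisticHazard({"dm_duration": 0.05}, -2.0)
        n = 50_000
        moved = 0
        for _ in range(n):
            agent = make_test_agent(dataclasses.replace(profile), DRState.NPDR,
                                    record_history=False)
            annual_event(agent, hz, TransitionRates(), zero_mortality_table, rng)
            moved += agent.state is DRState.PDR
        # note: probability is evaluated after the duration increment
        expected = progression_probability(
            hz, dataclasses.replace(profile, age=profile.age + 1,
                                    dm_duration=profile.dm_duration + 1)
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(moved / n - expected) < 3 * se

    def test_hazard_scale_applied(self, zero_mortality_table, profile):
        rng = np.random.default_rng(96)
        hz = LogisticHazard({}, 0.0)  # p = 0.5
        n = 20_000
        moved = 0
        for _ in range(n):
            agent = make_test_agent(dataclasses.replace(profile), DRState.NPDR,
                                    record_history=False)
            annual_event(agent, hz, TransitionRates(), zero_mortality_table, rng,
                         hazard_scale=0.5)
            moved += agent.state is DRState.PDR
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(moved / n - 0.25) < 3 * se


class TestAddEntrants:
    def test_zero_entrants_is_noop(self, training_config, rng):
        cohort = []
        assert add_entrants(cohort, 0, training_config, 3, rng) == []

    def test_entrant_no_dr_fraction(self, training_config):
        rng = np.random.default_rng(5)
        cohort = []
        add_entrants(cohort, 50_000, training_config, 1, rng)
        frac = np.mean([a.state is DRState.NO_DR for a in cohort])
        se = np.sqrt(0.715 * (1 - 0.715) / 50_000)
        assert abs(frac - 0.715) < 3 * se

    def test_entry_year_and_ids(self, training_config, rng):
        cohort = generate_cohort(training_config)
        n0 = len(cohort)
        add_entrants(cohort, 10, training_config, 4, rng)
        entrants = cohort[n0:]
        assert all(a.entry_year == 4 for a in entrants)
        assert [a.id for a in entrants] == list(range(n0, n0 + 10))

    def test_negative_entrants_rejected(self, training_config, rng):
        with pytest.raises(ValidationError):
            add_entrants([], -1, training_config, 0, rng)


def markov_matrix(onset, p_npdr, vl, prp, q):
    """Analytic one-year transition matrix for identical agents with
    constant mortality q, in state order NO_DR, NPDR, PDR, VL, DEATH."""
    s = 1.0 - q
    return np.array([
        [s * (1 - onset), s * onset, 0.0, 0.0, q],
        [0.0, s * (1 - p_npdr), s * p_npdr, 0.0, q],
        [0.0, s * (1 - vl) * prp, s * (1 - vl) * (1 - prp), s * vl, q],
        [0.0, 0.0, 0.0, s, q],
        [0.0, 0.0, 0.0, 0.0, 1.0],
    ])


class TestRunSimulation:
    def test_zero_years_is_identity(self, training_config):
        result = run_simulation(training_config, 0)
        cohort = generate_cohort(training_config)
        assert result.final_cohort == cohort
        assert len(result.yearly_counts) == 1

    def test_no_transitions_no_deaths_only_ages(self, zero_mortality_table):
        config = CohortConfig(
            n=50,
            seed=3,
            specs=constant_specs(),
            rates=TransitionRates(onset_annual=0.0, vl_annual=0.0),
            hazard=LogisticHazard({}, -1e4),  # predicted p ~ 0
        )
        result = run_simulation(config, 10, life_table=zero_mortality_table)
        start = generate_cohort(config)
        for a0, a10 in zip(start, result.final_cohort):
            assert a10.state is a0.state
            assert a10.profile.age == a0.profile.age + 10
            assert a10.profile.dm_duration == a0.profile.dm_duration + 10

    def test_yearly_counts_conserve_total(self, training_config):
        result = run_simulation(training_config, 5, entrants_per_year=20)
        for k, counts in enumerate(result.yearly_counts):
            total = sum(v for key, v in counts.items() if key != "year")
            assert total == training_config.n + 20 * k

    def test_death_count_non_decreasing(self, training_config):
        result = run_simulation(training_config, 10)
        deaths = [c["DEATH"] for c in result.yearly_counts]
        assert all(a <= b for a, b in zip(deaths, deaths[1:]))

    def test_vl_ever_reached_non_decreasing(self):
        config = CohortConfig(
            n=200, seed=17, specs=constant_specs(),
            rates=TransitionRates(vl_annual=0.2),
            hazard=LogisticHazard({}, 0.0), record_history=True,
        )
        result = run_simulation(config, 10)
        ever_vl = [
            sum(
                1 for a in result.final_cohort
                if any(y <= year and s is DRState.VL for y, s in (a.history or []))
            )
            for year in range(11)
        ]
        assert all(a <= b for a, b in zip(ever_vl, ever_vl[1:]))

    def test_living_state_index_monotone_without_prp(self, training_config):
        config = dataclasses.replace(training_config, record_history=True, n=300)
        result = run_simulation(config, 10)
        for agent in result.final_cohort:
            living = [s.index for _, s in agent.history if s is not DRState.DEATH]
            assert living == sorted(living)

    def test_seed_determinism(self, training_config):
        r1 = run_simulation(training_config, 5)
        r2 = run_simulation(training_config, 5)
        assert r1.yearly_counts == r2.yearly_counts
        assert r1.final_cohort == r2.final_cohort

    def test_monte_carlo_matches_analytic_markov_chain(self, frozen_config, flat_life_table):
        # frozen predictors + constant mortality make every agent an iid
        # draw from one 5-state Markov chain; compare the 10-step state
        # distribution against the matrix power, within 3 SE per state
        n, years = 30_000, 10
        config = dataclasses.replace(frozen_config, n=n, include_no_dr=True, no_dr_prob=0.4)
        result = run_simulation(config, years, life_table=flat_life_table)

        p_npdr = 1.0 / (1.0 + np.exp(1.5))  # expit(-1.5), constant profile
        q = flat_life_table.qx(80, True)
        M = markov_matrix(0.077, p_npdr, 0.007, 0.0, q)
        start_pdr = 0.6 * p_npdr
        pi0 = np.array([0.4, 0.6 - start_pdr, start_pdr, 0.0, 0.0])
        pi10 = pi0 @ np.linalg.matrix_power(M, years)

        final = result.yearly_counts[-1]
        for i, state in enumerate(["NO_DR", "NPDR", "PDR", "VL", "DEATH"]):
            se = np.sqrt(max(pi10[i] * (1 - pi10[i]), 1e-12) / n)
            assert abs(final[state] / n - pi10[i]) < 3 * se + 1e-9, state

    def test_geometric_time_to_onset(self, zero_mortality_table, profile):
        # with qx = 0 and onset 0.077 the waiting time is geometric with
        # mean 1/0.077 ~ 12.99 years
        rng = np.random.default_rng(2)
        rates = TransitionRates()
        hz = LogisticHazard({}, 0.0)
        n = 20_000
        waits = np.empty(n)
        for i in range(n):
            agent = make_test_agent(
                dataclasses.replace(profile, age=30.0, dm_duration=0.0),
                DRState.NO_DR, record_history=False,
            )
            t = 0
            while agent.state is DRState.NO_DR and t < 400:
                annual_event(agent, hz, rates, zero_mortality_table, rng)
                t += 1
            waits[i] = t
        mean, sd = 1 / 0.077, np.sqrt(1 - 0.077) / 0.077
        assert abs(waits.mean() - mean) < 3 * sd / np.sqrt(n)


class TestSummaries:
    def test_all_survive_gives_empty_deceased_summary(self, training_config, zero_mortality_table):
        result = run_simulation(training_config, 3, life_table=zero_mortality_table)
        assert result.deceased_summary.n == 0
        assert result.deceased_summary.mean_age is None
        assert result.survivor_summary.n == training_config.n

    def test_two_agent_toy_groups(self, profile, rng):
        young = make_test_agent(dataclasses.replace(profile, age=50.0, dm_duration=10.0),
                                DRState.NPDR)
        old = make_test_agent(dataclasses.replace(profile, age=80.0, dm_duration=30.0),
                              DRState.PDR)
        annual_event(old, LogisticHazard({}, 0.0), TransitionRates(), CERTAIN_DEATH, rng, year=1)
        survivors, deceased = summarize_groups([young, old])
        assert survivors.n == 1 and deceased.n == 1
        assert survivors.mean_age == 50.0
        assert deceased.mean_age == 81.0  # age at death, after the increment
        assert deceased.state_counts["DEATH"] == 1

    def test_ten_year_run_survivors_younger_than_deceased(self, training_config):
        result = run_simulation(training_config, 10)
        assert result.survivor_summary.mean_age < result.deceased_summary.mean_age
        assert (result.deceased_summary.mean_dm_duration
                < result.survivor_summary.mean_dm_duration)

    def test_result_json_serializes(self, training_config):
        import json

        result = run_simulation(training_config, 2)
        payload = json.loads(result.to_json())
        assert len(payload["yearly_counts"]) == 3
        assert payload["config_echo"]["n"] == training_config.n
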