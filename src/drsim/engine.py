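"""Simulation driver: the annual per-agent event, entrants, multi-year runs.

Per agent and year the event applies, in this fixed order:

1. age and diabetes duration each increase by one;
2. a mortality draw against the life table at the *new* age;
3. if alive, one state-specific transition draw (uniform u on [0, 1],
   advance iff u < p): onset for NO_DR, the logistic predicted
   probability for NPDR -> PDR, the constant vision-loss rate for PDR;
4. if still in PDR, an optional photocoagulation draw back to NPDR.

The ordering is a modeling choice (mortality sees the updated age, at
most one forward stage change per year) and is pinned by unit tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    CohortConfig,
    assign_initial_stage,
    calibrated_hazard,
    generate_cohort,
    sample_profiles,
)
from .domain import (
    Agent,
    DRState,
    LogisticHazard,
    TransitionRates,
    ValidationError,
    apply_transition,
    make_agent,
)
from .hazard import progression_probability
from .lifetable import LifeTable, default_life_table, load_life_table

__all__ = [
    "SimulationResult",
    "GroupSummary",
    "annual_event",
    "add_entrants",
    "run_simulation",
    "summarize_groups",
]


def annual_event(
    agent: Agent,
    hazard: LogisticHazard,
    rates: TransitionRates,
    table: LifeTable,
    rng: np.random.Generator,
    year: Optional[int] = None,
    hazard_scale: float = 1.0,
) -> Agent:
    """Apply one simulated year to a living agent, in place.

    Draw order per agent: one mortality uniform, then (if the state has a
    forward edge) one transition uniform, then (only while still PDR with
    a positive PRP rate) one PRP uniform.  Raises for a dead agent.
    """
    if not agent.alive:
        raise ValidationError(f"agent {agent.id} is dead and cannot receive events")
    p = agent.profile
    p.age += 1.0
    p.dm_duration += 1.0

    if rng.random() < table.qx(p.age, p.male):
        apply_transition(agent, DRState.DEATH, year)
        return agent

    state = agent.state
    if state is DRState.NO_DR:
        if rng.random() < rates.onset_annual:
            apply_transition(agent, DRState.NPDR, year)
    elif state is DRState.NPDR:
        prob = min(progression_probability(hazard, p) * hazard_scale, 1.0)
        if rng.random() < prob:
            apply_transition(agent, DRState.PDR, year)
    elif state is DRState.PDR:
        if rng.random() < rates.vl_annual:
            apply_transition(agent, DRState.VL, year)
        elif rates.prp_annual > 0.0 and rng.random() < rates.prp_annual:
            apply_transition(agent, DRState.NPDR, year)
    # VL: no living-state exit
    return agent


def add_entrants(
    cohort: list[Agent],
    n_new: int,
    config: CohortConfig,
    year: int,
    rng: np.random.Generator,
    hazard: Optional[LogisticHazard] = None,
) -> list[Agent]:
    """Append ``n_new`` entrants to the cohort, in place.

    Each entrant starts without retinopathy with probability
    ``rates.entrant_no_dr``; otherwise its NPDR/PDR split follows its own
    predicted probability, like the initial cohort.
    """
    if n_new < 0:
        raise ValidationError(f"n_new must be >= 0: {n_new}")
    if n_new == 0:
        return cohort
    profiles = sample_profiles(config, n_new, rng)
    hz = hazard if hazard is not None else calibrated_hazard(config, profiles)
    next_id = max((a.id for a in cohort), default=-1) + 1
    for i, profile in enumerate(profiles):
        state = assign_initial_stage(
            profile, hz, True, config.rates.entrant_no_dr, rng
        )
        cohort.append(
            make_agent(
                profile,
                state,
                entry_year=year,
                agent_id=next_id + i,
                record_history=config.record_history,
            )
        )
    return cohort


@dataclass
class GroupSummary:
    """Means and state tallies for one survival group."""

    n: int
    mean_age: Optional[float]
    mean_dm_duration: Optional[float]
    state_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_age": self.mean_age,
            "mean_dm_duration": self.mean_dm_duration,
            "state_counts": self.state_counts,
        }


@dataclass
class SimulationResult:
    """Outputs of one multi-year run."""

    yearly_counts: list[dict[str, int]]
    final_cohort: list[Agent]
    survivor_summary: GroupSummary
    deceased_summary: GroupSummary
    seed: int
    years: int
    entrants_per_year: int
    config_echo: dict = field(default_factory=dict)
    hazard: Optional[LogisticHazard] = None

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "seed": self.seed,
            "years": self.years,
            "entrants_per_year": self.entrants_per_year,
            "yearly_counts": self.yearly_counts,
            "survivor_summary": self.survivor_summary.to_dict(),
            "deceased_summary": self.deceased_summary.to_dict(),
            "config_echo": self.config_echo,
        }
        if self.hazard is not None:
            payload["hazard"] = {
                "beta": self.hazard.beta,
                "intercept": self.hazard.intercept,
            }
        return json.dumps(payload, indent=indent, sort_keys=True)


def _count_states(cohort: Sequence[Agent]) -> dict[str, int]:
    counts = {s.name: 0 for s in DRState}
    for a in cohort:
        counts[a.state.name] += 1
    return counts


def summarize_groups(cohort: Sequence[Agent]) -> tuple[GroupSummary, GroupSummary]:
    """Summaries of survivors and deceased (means are None for an empty
    group).  Deceased ages are ages at death: a dead agent's fields stop
    evolving once it leaves the living cohort."""

    def summarize(agents: list[Agent]) -> GroupSummary:
        if not agents:
            return GroupSummary(0, None, None, {})
        return GroupSummary(
            n=len(agents),
            mean_age=float(np.mean([a.profile.age for a in agents])),
            mean_dm_duration=float(np.mean([a.profile.dm_duration for a in agents])),
            state_counts=_count_states(agents),
        )

    return summarize([a for a in cohort if a.alive]), summarize(
        [a for a in cohort if not a.alive]
    )


def run_simulation(
    config: CohortConfig,
    years: int,
    entrants_per_year: int = 0,
    life_table: Optional[LifeTable] = None,
) -> SimulationResult:
    """Generate a cohort and run it forward ``years`` annual cycles.

    Year 0 is the freshly generated cohort; each subsequent year applies
    the annual event to every living agent (in id order) and then adds
    entrants.  Fully reproducible from ``config.seed``.
    """
    if years < 0:
        raise ValidationError(f"years must be >= 0: {years}")
    if entrants_per_year < 0:
        raise ValidationError(f"entrants_per_year must be >= 0: {entrants_per_year}")
    if life_table is None:
        life_table = (
            load_life_table(config.life_table_path)
            if config.life_table_path
            else default_life_table()
        )
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config, rng)
    hz = calibrated_hazard(config, [a.profile for a in cohort])

    yearly_counts = [{"year": 0, **_count_states(cohort)}]
    for year in range(1, years + 1):
        for agent in cohort:
            if agent.alive:
                annual_event(
                    agent,
                    hz,
                    config.rates,
                    life_table,
                    rng,
                    year=year,
                    hazard_scale=config.annual_hazard_scale,
                )
        if entrants_per_year:
            add_entrants(cohort, entrants_per_year, config, year, rng, hazard=hz)
        yearly_counts.append({"year": year, **_count_states(cohort)})

    survivors, deceased = summarize_groups(cohort)
    return SimulationResult(
        yearly_counts=yearly_counts,
        final_cohort=cohort,
        survivor_summary=survivors,
        deceased_summary=deceased,
        seed=config.seed,
        years=years,
        entrants_per_year=entrants_per_year,
        config_echo=_config_echo(config),
        hazard=hz,
    )


def _config_echo(config: CohortConfig) -> dict:
    return {
        "n": config.n,
        "seed": config.seed,
        "specs": {
            k: {kk: vv for kk, vv in vars(v).items() if vv is not None}
            for k, v in config.specs.items()
        },
        "rates": vars(config.rates),
        "hazard_beta": dict(config.hazard.beta),
        "hazard_intercept": config.hazard.intercept,
        "target_pdr_prevalence": config.target_pdr_prevalence,
        "annual_hazard_scale": config.annual_hazard_scale,
        "include_no_dr": config.include_no_dr,
        "no_dr_prob": config.no_dr_prob,
        "record_history": config.record_history,
        "life_table_path": config.life_table_path,
    }
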