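"""Core data model: disease states, predictor profiles, agents, model parameters.

The disease statechart has five states.  Living agents may move forward
along NO_DR -> NPDR -> PDR -> VL; the single backward edge among living
states is PDR -> NPDR (pan-retinal photocoagulation).  DEATH is reachable
from every living state and is absorbing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "DRState",
    "PredictorProfile",
    "Agent",
    "LogisticHazard",
    "TransitionRates",
    "ALLOWED_TRANSITIONS",
    "TransitionError",
    "ValidationError",
    "make_agent",
    "apply_transition",
    "PREDICTOR_FIELDS",
    "CONTINUOUS_PREDICTORS",
    "BINARY_PREDICTORS",
]


class ValidationError(ValueError):
    """A profile, agent or parameter set violates a model invariant."""


class TransitionError(ValueError):
    """An attempted state change is not an edge of the statechart."""


class DRState(Enum):
    """The five statechart states, numbered 1-5."""

    NO_DR = 1
    NPDR = 2
    PDR = 3
    VL = 4
    DEATH = 5

    @property
    def index(self) -> int:
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "DRState":
        try:
            return cls[name]
        except KeyError:
            raise ValidationError(f"unknown DR state name: {name!r}") from None


#: Permitted directed edges of the statechart.  Any living state may die;
#: the only backward edge among living states is PDR -> NPDR (PRP).
ALLOWED_TRANSITIONS: frozenset[tuple[DRState, DRState]] = frozenset(
    {
        (DRState.NO_DR, DRState.NPDR),
        (DRState.NPDR, DRState.PDR),
        (DRState.PDR, DRState.VL),
        (DRState.PDR, DRState.NPDR),
        (DRState.NO_DR, DRState.DEATH),
        (DRState.NPDR, DRState.DEATH),
        (DRState.PDR, DRState.DEATH),
        (DRState.VL, DRState.DEATH),
    }
)

PREDICTOR_FIELDS = (
    "age",
    "male",
    "dm_duration",
    "bmi",
    "hba1c",
    "hypertension",
    "dyslipidemia",
    "nephropathy",
    "tobacco",
)
CONTINUOUS_PREDICTORS = ("age", "dm_duration", "bmi", "hba1c")
BINARY_PREDICTORS = ("male", "hypertension", "dyslipidemia", "nephropathy", "tobacco")

#: Diabetes onset is assumed no earlier than age 18, so duration of
#: diabetes can never exceed age - 18.
ADULT_ONSET_AGE = 18.0


@dataclass
class PredictorProfile:
    """Demography and health-status fields carried by one agent.

    ``age`` and ``dm_duration`` are in years; ``bmi`` in kg/m^2; ``hba1c``
    in percent.  The five remaining fields are dichotomous flags.
    """

    age: float
    male: bool
    dm_duration: float
    bmi: float
    hba1c: float
    hypertension: bool
    dyslipidemia: bool
    nephropathy: bool
    tobacco: bool

    def validate(self) -> None:
        if not math.isfinite(self.age) or self.age < ADULT_ONSET_AGE:
            raise ValidationError(f"age must be finite and >= {ADULT_ONSET_AGE}: {self.age}")
        if not math.isfinite(self.dm_duration) or self.dm_duration < 0:
            raise ValidationError(f"dm_duration must be finite and >= 0: {self.dm_duration}")
        if self.dm_duration > self.age - ADULT_ONSET_AGE:
            raise ValidationError(
                f"dm_duration ({self.dm_duration}) exceeds age - {ADULT_ONSET_AGE:.0f} "
                f"({self.age - ADULT_ONSET_AGE})"
            )
        if not math.isfinite(self.bmi) or self.bmi <= 0:
            raise ValidationError(f"bmi must be finite and > 0: {self.bmi}")
        if not math.isfinite(self.hba1c) or self.hba1c <= 0:
            raise ValidationError(f"hba1c must be finite and > 0: {self.hba1c}")

    def value(self, name: str) -> float:
        """Numeric value of a predictor field (booleans as 0/1)."""
        if name not in PREDICTOR_FIELDS:
            raise ValidationError(f"unknown predictor field: {name!r}")
        return float(getattr(self, name))

    def copy(self) -> "PredictorProfile":
        return replace(self)


@dataclass
class LogisticHazard:
    """Logistic model p = 1 / (1 + exp(-(beta . x + intercept))).

    ``beta`` maps predictor-field names to log-odds per unit; ``intercept``
    may be ``None`` to mark it as pending calibration.
    """

    beta: dict[str, float]
    intercept: Optional[float] = None

    def __post_init__(self) -> None:
        for name, b in self.beta.items():
            if name not in PREDICTOR_FIELDS:
                raise ValidationError(f"coefficient {name!r} is not a predictor field")
            if not math.isfinite(b):
                raise ValidationError(f"coefficient {name!r} is not finite: {b}")
        if self.intercept is not None and not math.isfinite(self.intercept):
            raise ValidationError(f"intercept is not finite: {self.intercept}")

    @property
    def calibrated(self) -> bool:
        return self.intercept is not None

    def linear_predictor(self, profile: PredictorProfile) -> float:
        if self.intercept is None:
            raise ValidationError("hazard intercept has not been calibrated")
        return self.intercept + sum(b * profile.value(k) for k, b in self.beta.items())

    @classmethod
    def from_odds_ratios(
        cls, odds_ratios: dict[str, float], intercept: Optional[float] = None
    ) -> "LogisticHazard":
        for name, orr in odds_ratios.items():
            if orr <= 0:
                raise ValidationError(f"odds ratio for {name!r} must be positive: {orr}")
        return cls({k: math.log(v) for k, v in odds_ratios.items()}, intercept)


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1]: {value}")


@dataclass
class TransitionRates:
    """Constant annual transition probabilities of the statechart.

    onset_annual   NO_DR -> NPDR incidence (default 7.7%/yr)
    vl_annual      PDR -> VL incidence (default 0.7%/yr)
    entrant_no_dr  probability a new entrant starts without retinopathy
    prp_annual     PDR -> NPDR regression via photocoagulation (default off)
    """

    onset_annual: float = 0.077
    vl_annual: float = 0.007
    entrant_no_dr: float = 0.715
    prp_annual: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_probability(f.name, getattr(self, f.name))


_agent_ids = itertools.count()


@dataclass
class Agent:
    """One simulated patient: profile, current state, entry bookkeeping."""

    id: int
    profile: PredictorProfile
    state: DRState
    entry_year: int = 0
    history: Optional[list[tuple[int, DRState]]] = None

    @property
    def alive(self) -> bool:
        return self.state is not DRState.DEATH

    def record(self, year: int, state: DRState) -> None:
        if self.history is not None:
            if self.history and year < self.history[-1][0]:
                raise ValidationError("history years must be non-decreasing")
            self.history.append((year, state))


def make_agent(
    profile: PredictorProfile,
    state: DRState,
    entry_year: int = 0,
    agent_id: Optional[int] = None,
    record_history: bool = False,
) -> Agent:
    """Construct a validated, living agent with a fresh unique id.

    Raises :class:`ValidationError` for a dead initial state or a profile
    violating its invariants.
    """
    if not isinstance(state, DRState):
        raise ValidationError(f"state must be a DRState, got {state!r}")
    if state is DRState.DEATH:
        raise ValidationError("cannot create an agent in the DEATH state")
    profile.validate()
    if agent_id is None:
        agent_id = next(_agent_ids)
    history = [(entry_year, state)] if record_history else None
    return Agent(id=agent_id, profile=profile, state=state, entry_year=entry_year, history=history)


def apply_transition(agent: Agent, new_state: DRState, year: Optional[int] = None) -> None:
    """Move an agent along one statechart edge, in place.

    Raises :class:`TransitionError` if ``(agent.state, new_state)`` is not a
    permitted edge (in particular, for any transition out of DEATH).
    """
    if (agent.state, new_state) not in ALLOWED_TRANSITIONS:
        raise TransitionError(
            f"no statechart edge {agent.state.name} -> {new_state.name}"
        )
    agent.state = new_state
    if year is not None and agent.history is not None:
        agent.record(year, new_state)


# -- cohort CSV serialization -------------------------------------------------

COHORT_CSV_COLUMNS = (
    "id",
    "age",
    "male",
    "dm_duration",
    "bmi",
    "hba1c",
    "hypertension",
    "dyslipidemia",
    "nephropathy",
    "tobacco",
    "state",
    "entry_year",
)


def agent_to_row(agent: Agent) -> dict[str, object]:
    p = agent.profile
    return {
        "id": agent.id,
        "age": p.age,
        "male": int(p.male),
        "dm_duration": p.dm_duration,
        "bmi": p.bmi,
        "hba1c": p.hba1c,
        "hypertension": int(p.hypertension),
        "dyslipidemia": int(p.dyslipidemia),
        "nephropathy": int(p.nephropathy),
        "tobacco": int(p.tobacco),
        "state": agent.state.name,
        "entry_year": agent.entry_year,
    }


def agent_from_row(row: dict[str, object]) -> Agent:
    profile = PredictorProfile(
        age=float(row["age"]),
        male=bool(int(row["male"])),
        dm_duration=float(row["dm_duration"]),
        bmi=float(row["bmi"]),
        hba1c=float(row["hba1c"]),
        hypertension=bool(int(row["hypertension"])),
        dyslipidemia=bool(int(row["dyslipidemia"])),
        nephropathy=bool(int(row["nephropathy"])),
        tobacco=bool(int(row["tobacco"])),
    )
    return Agent(
        id=int(row["id"]),
        profile=profile,
        state=DRState.from_name(str(row["state"])),
        entry_year=int(row["entry_year"]),
    )


def write_cohort_csv(agents: Iterable[Agent], path) -> None:
    """Write agents as CSV, one row per agent, floats in shortest repr."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=COHORT_CSV_COLUMNS)
        writer.writeheader()
        for agent in agents:
            writer.writerow(agent_to_row(agent))


def read_cohort_csv(path) -> list[Agent]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COHORT_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"cohort CSV missing columns: {sorted(missing)}")
        return [agent_from_row(row) for row in reader]
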