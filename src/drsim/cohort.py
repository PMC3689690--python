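"""Synthetic cohort generation.

Predictor profiles are sampled from per-field distribution families
(moment-parameterized, with rejection against truncation bounds), and the
initial retinopathy stage is assigned from the logistic model's predicted
probabilities — NPDR versus PDR for the validation-replica cohort, with
an optional no-retinopathy share for steady-state entrants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import (
    ADULT_ONSET_AGE,
    BINARY_PREDICTORS,
    CONTINUOUS_PREDICTORS,
    Agent,
    DRState,
    LogisticHazard,
    PredictorProfile,
    TransitionRates,
    ValidationError,
    make_agent,
)
from .hazard import (
    DEFAULT_ODDS_RATIOS,
    calibrate_intercept,
    progression_probability,
)

__all__ = [
    "DistributionSpec",
    "CohortConfig",
    "sample_profile",
    "sample_profiles",
    "assign_initial_stage",
    "generate_cohort",
    "generate_abstraction_fixture",
    "default_config",
    "ConfigurationError",
]

_MAX_REJECTIONS = 1000

FAMILIES = ("normal", "lognormal", "gamma", "bernoulli", "constant")


class ConfigurationError(ValueError):
    """Infeasible or inconsistent cohort configuration."""


@dataclass(frozen=True)
class DistributionSpec:
    """One predictor's sampling family, parameterized by its moments.

    ``mean``/``sd`` are the target distribution's own mean and standard
    deviation (the lognormal and gamma are re-parameterized to match
    them).  ``lower``/``upper`` truncate by rejection sampling.
    """

    family: str
    mean: float = 0.0
    sd: float = 0.0
    lower: Optional[float] = None
    upper: Optional[float] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; use one of {FAMILIES}")
        if self.family == "bernoulli":
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ConfigurationError(f"bernoulli requires p in [0, 1], got {self.p}")
        elif self.family != "constant":
            if self.sd < 0:
                raise ConfigurationError(f"sd must be >= 0, got {self.sd}")
            if self.family in ("lognormal", "gamma") and self.mean <= 0:
                raise ConfigurationError(f"{self.family} requires mean > 0, got {self.mean}")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ConfigurationError(
                f"truncation bounds require lower < upper, got [{self.lower}, {self.upper}]"
            )

    def _draw_raw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "constant":
            return np.full(size, self.mean)
        if self.family == "bernoulli":
            return (rng.random(size) < self.p).astype(float)
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size)
        if self.family == "lognormal":
            if self.sd == 0:
                return np.full(size, self.mean)
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size)
        if self.family == "gamma":
            if self.sd == 0:
                return np.full(size, self.mean)
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            return rng.gamma(shape, scale, size)
        raise AssertionError(self.family)

    def _within(self, x: np.ndarray) -> np.ndarray:
        ok = np.ones(x.shape, dtype=bool)
        if self.lower is not None:
            ok &= x >= self.lower
        if self.upper is not None:
            ok &= x <= self.upper
        return ok

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ``size`` values, rejecting draws outside the truncation
        bounds; raises after 1000 consecutive fully-rejected rounds."""
        out = self._draw_raw(rng, size)
        if self.family in ("constant", "bernoulli"):
            if not np.all(self._within(out)):
                raise ConfigurationError(
                    f"{self.family} value {out[~self._within(out)][0]} violates "
                    f"bounds [{self.lower}, {self.upper}]"
                )
            return out
        bad = ~self._within(out)
        rounds = 0
        while np.any(bad):
            rounds += 1
            if rounds > _MAX_REJECTIONS:
                raise ConfigurationError(
                    f"rejection sampling failed after {_MAX_REJECTIONS} rounds for "
                    f"family {self.family!r} with bounds [{self.lower}, {self.upper}]"
                )
            out[bad] = self._draw_raw(rng, int(bad.sum()))
            bad = ~self._within(out)
        return out


def _default_specs() -> dict[str, DistributionSpec]:
    # Training-cohort moments (n = 351) with documented truncation bounds.
    return {
        "age": DistributionSpec("normal", mean=67.5, sd=9.4, lower=21, upper=100),
        "male": DistributionSpec("bernoulli", p=345 / 351),
        "dm_duration": DistributionSpec("normal", mean=21.5, sd=9.0, lower=0, upper=80),
        "bmi": DistributionSpec("normal", mean=32.2, sd=6.3, lower=12, upper=70),
        "hba1c": DistributionSpec("normal", mean=8.2, sd=1.8, lower=4, upper=18),
        "hypertension": DistributionSpec("bernoulli", p=344 / 351),
        "dyslipidemia": DistributionSpec("bernoulli", p=297 / 351),
        "nephropathy": DistributionSpec("bernoulli", p=124 / 351),
        "tobacco": DistributionSpec("bernoulli", p=88 / 351),
    }


@dataclass
class CohortConfig:
    """Everything needed to generate and simulate one cohort."""

    n: int = 501
    seed: int = 0
    specs: dict[str, DistributionSpec] = field(default_factory=_default_specs)
    rates: TransitionRates = field(default_factory=TransitionRates)
    hazard: LogisticHazard = field(
        default_factory=lambda: LogisticHazard.from_odds_ratios(DEFAULT_ODDS_RATIOS)
    )
    target_pdr_prevalence: float = 93 / 351
    annual_hazard_scale: float = 1.0
    include_no_dr: bool = False
    no_dr_prob: float = 0.0
    record_history: bool = False
    life_table_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"cohort size must be >= 1, got {self.n}")
        missing = [k for k in CONTINUOUS_PREDICTORS + BINARY_PREDICTORS if k not in self.specs]
        if missing:
            raise ConfigurationError(f"missing distribution specs for: {missing}")
        if not (0.0 < self.target_pdr_prevalence < 1.0):
            raise ConfigurationError(
                f"target_pdr_prevalence must be in (0, 1): {self.target_pdr_prevalence}"
            )
        if self.annual_hazard_scale < 0:
            raise ConfigurationError("annual_hazard_scale must be >= 0")
        if not (0.0 <= self.no_dr_prob <= 1.0):
            raise ConfigurationError(f"no_dr_prob must be in [0, 1]: {self.no_dr_prob}")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def default_config(**overrides) -> CohortConfig:
    """The packaged configuration: training-cohort moments, published odds
    ratios, default transition rates, intercept pending calibration."""
    return CohortConfig(**overrides)


def sample_profiles(
    config: CohortConfig, size: int, rng: np.random.Generator
) -> list[PredictorProfile]:
    """Vectorized profile sampling honoring all profile invariants.

    Continuous fields are truncation-rejection sampled; the joint
    constraint dm_duration <= age - 18 is enforced by resampling the
    duration (the age draw is kept).
    """
    age = config.specs["age"].sample(rng, size)
    dur = config.specs["dm_duration"].sample(rng, size)
    cap = age - ADULT_ONSET_AGE
    bad = dur > cap
    rounds = 0
    while np.any(bad):
        rounds += 1
        if rounds > _MAX_REJECTIONS:
            raise ConfigurationError(
                "could not satisfy dm_duration <= age - 18 after "
                f"{_MAX_REJECTIONS} resampling rounds; bounds are infeasible"
            )
        dur[bad] = config.specs["dm_duration"].sample(rng, int(bad.sum()))
        bad = dur > cap
    bmi = config.specs["bmi"].sample(rng, size)
    hba1c = config.specs["hba1c"].sample(rng, size)
    flags = {
        name: config.specs[name].sample(rng, size).astype(bool)
        for name in BINARY_PREDICTORS
    }
    profiles = []
    for i in range(size):
        profile = PredictorProfile(
            age=float(age[i]),
            male=bool(flags["male"][i]),
            dm_duration=float(dur[i]),
            bmi=float(bmi[i]),
            hba1c=float(hba1c[i]),
            hypertension=bool(flags["hypertension"][i]),
            dyslipidemia=bool(flags["dyslipidemia"][i]),
            nephropathy=bool(flags["nephropathy"][i]),
            tobacco=bool(flags["tobacco"][i]),
        )
        profile.validate()
        profiles.append(profile)
    return profiles


def sample_profile(config: CohortConfig, rng: np.random.Generator) -> PredictorProfile:
    """Draw a single profile (see :func:`sample_profiles`)."""
    return sample_profiles(config, 1, rng)[0]


def assign_initial_stage(
    profile: PredictorProfile,
    hazard: LogisticHazard,
    include_no_dr: bool,
    no_dr_prob: float,
    rng: np.random.Generator,
) -> DRState:
    """Initial stage draw.

    With ``include_no_dr``, the agent starts without retinopathy with
    probability ``no_dr_prob``; otherwise (and with the remaining
    probability) it starts in PDR with its own predicted probability, else
    NPDR.
    """
    if not hazard.calibrated:
        raise ValidationError("hazard intercept must be calibrated before stage assignment")
    if include_no_dr and rng.random() < no_dr_prob:
        return DRState.NO_DR
    p = progression_probability(hazard, profile)
    return DRState.PDR if rng.random() < p else DRState.NPDR


def calibrated_hazard(
    config: CohortConfig, profiles: Sequence[PredictorProfile]
) -> LogisticHazard:
    """Config hazard with the intercept calibrated to the target PDR
    prevalence over ``profiles`` (no-op if already calibrated)."""
    if config.hazard.calibrated:
        return config.hazard
    m = calibrate_intercept(config.hazard.beta, profiles, config.target_pdr_prevalence)
    return LogisticHazard(dict(config.hazard.beta), m)


def generate_cohort(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> list[Agent]:
    """Generate ``config.n`` agents, reproducibly from ``config.seed``.

    The intercept, when marked for calibration, is calibrated against the
    cohort's own sampled profiles so that the expected PDR share equals
    the configured target prevalence.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profiles = sample_profiles(config, config.n, rng)
    hz = calibrated_hazard(config, profiles)
    agents = []
    for i, profile in enumerate(profiles):
        state = assign_initial_stage(
            profile, hz, config.include_no_dr, config.no_dr_prob, rng
        )
        agents.append(
            make_agent(
                profile,
                state,
                entry_year=0,
                agent_id=i,
                record_history=config.record_history,
            )
        )
    return agents


def generate_abstraction_fixture(
    n_total: int,
    n_missing_duration: int,
    rng: np.random.Generator,
    config: Optional[CohortConfig] = None,
    train_fraction: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emulate the chart-abstraction pipeline on synthetic records.

    Generates ``n_total`` records of which ``n_missing_duration`` have an
    undeterminable diabetes duration; those are excluded and the retained
    records are randomly split train/test at ``train_fraction`` (rounded,
    giving 351/150 for 535 records with 34 missing).

    Returns ``(records, train, test)`` data frames; ``records`` carries a
    ``duration_missing`` flag and includes the excluded rows.
    """
    if n_missing_duration >= n_total:
        raise ConfigurationError(
            f"n_missing_duration ({n_missing_duration}) must be < n_total ({n_total})"
        )
    if n_missing_duration < 0:
        raise ConfigurationError("n_missing_duration must be >= 0")
    if config is None:
        config = default_config(n=max(n_total, 1))
    profiles = sample_profiles(config, n_total, rng)
    hz = calibrated_hazard(config, profiles)
    rows = []
    for i, p in enumerate(profiles):
        stage = assign_initial_stage(p, hz, False, 0.0, rng)
        row = {"record_id": i, **{k: p.value(k) for k in CONTINUOUS_PREDICTORS}}
        row.update({k: int(p.value(k)) for k in BINARY_PREDICTORS})
        row["stage"] = stage.name
        rows.append(row)
    records = pd.DataFrame(rows)
    missing_idx = rng.choice(n_total, size=n_missing_duration, replace=False)
    records["duration_missing"] = False
    records.loc[missing_idx, "duration_missing"] = True
    records.loc[missing_idx, "dm_duration"] = np.nan

    retained = records.loc[~records["duration_missing"]].reset_index(drop=True)
    n_train = int(round(train_fraction * len(retained)))
    perm = rng.permutation(len(retained))
    train = retained.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = retained.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return records, train, test
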