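"""Cohort validation battery.

A simulated cohort is compared variable-by-variable against reference
summaries: Student's t-tests for the continuous predictors (age, diabetes
duration, BMI, HbA1c) and Pearson chi-square tests for the dichotomous
ones plus the NPDR/PDR stage split.  The criterion is *non*-significance:
a variable passes when p > 0.05.  No multiple-testing adjustment is
applied; each variable is tested at alpha = 0.05 individually.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .domain import Agent, DRState, ValidationError

__all__ = [
    "ReferenceSummary",
    "ValidationReport",
    "VariableResult",
    "t_test_from_summary",
    "chi_square_test",
    "validate_cohort",
    "default_reference",
    "CONTINUOUS_VARIABLES",
    "DICHOTOMOUS_VARIABLES",
]

ALPHA = 0.05

CONTINUOUS_VARIABLES = ("age", "dm_duration", "bmi", "hba1c")
DICHOTOMOUS_VARIABLES = ("male", "hypertension", "dyslipidemia", "nephropathy", "tobacco")
STAGE_VARIABLE = "dr_stage"


def t_test_from_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    pooled: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics.

    ``pooled=True`` gives the classical equal-variance Student test;
    ``pooled=False`` the Welch test.  Degenerate zero-variance inputs
    follow the limit convention: equal means -> (0, 1); unequal means ->
    (+/-inf, 0).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"both groups need n >= 2, got {n1} and {n2}")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            return 0.0, 1.0
        return math.copysign(math.inf, mean1 - mean2), 0.0
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled
    )
    return float(t), float(p)


def chi_square_test(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of homogeneity on a 2x2 count table.

    Continuity (Yates) correction is off by default.  A zero marginal has
    no valid chi-square approximation and raises.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValidationError("table entries must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError(
            "a marginal total is zero; the chi-square approximation is invalid "
            "(consider an exact test)"
        )
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


@dataclass
class ReferenceSummary:
    """Reference cohort summaries in published-table form.

    continuous:  name -> (n, mean, sd)
    dichotomous: name -> (n, count with trait)
    stages:      {"NPDR": count, "PDR": count}
    """

    continuous: dict[str, tuple[int, float, float]]
    dichotomous: dict[str, tuple[int, int]]
    stages: dict[str, int]

    def __post_init__(self) -> None:
        for name, (n, _, sd) in self.continuous.items():
            if sd < 0:
                raise ValidationError(f"{name}: sd must be >= 0")
            if n < 2:
                raise ValidationError(f"{name}: n must be >= 2")
        for name, (n, count) in self.dichotomous.items():
            if not 0 <= count <= n:
                raise ValidationError(f"{name}: count must be in [0, n]")
        for name, count in self.stages.items():
            if count < 0:
                raise ValidationError(f"{name}: stage count must be >= 0")

    @classmethod
    def from_json(cls, path) -> "ReferenceSummary":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            continuous={k: tuple(v) for k, v in raw["continuous"].items()},
            dichotomous={k: tuple(v) for k, v in raw["dichotomous"].items()},
            stages=dict(raw["stages"]),
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "continuous": {k: list(v) for k, v in self.continuous.items()},
                "dichotomous": {k: list(v) for k, v in self.dichotomous.items()},
                "stages": self.stages,
            },
            indent=indent,
            sort_keys=True,
        )


def default_reference() -> ReferenceSummary:
    """The held-out test cohort's published summaries (n = 150)."""
    return ReferenceSummary(
        continuous={
            "age": (150, 67.3, 8.9),
            "dm_duration": (150, 20.5, 8.6),
            "bmi": (150, 32.3, 6.8),
            "hba1c": (150, 8.0, 1.5),
        },
        dichotomous={
            "male": (150, 148),
            "hypertension": (150, 149),
            "dyslipidemia": (150, 137),
            "nephropathy": (150, 51),
            "tobacco": (150, 25),
        },
        stages={"NPDR": 121, "PDR": 29},
    )


@dataclass
class VariableResult:
    variable: str
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of range: {self.p_value}")

    @property
    def passed(self) -> bool:
        return self.p_value > ALPHA

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "pass": self.passed,
        }


@dataclass
class ValidationReport:
    results: list[VariableResult] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(r.passed for r in self.results)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "results": [r.to_dict() for r in self.results],
                "overall_pass": self.overall_pass,
            },
            indent=indent,
        )

    def to_text(self) -> str:
        lines = [
            f"{'Variable':<16}{'Test':<12}{'Statistic':>12}{'P value':>10}  Pass",
            "-" * 56,
        ]
        for r in self.results:
            lines.append(
                f"{r.variable:<16}{r.test:<12}{r.statistic:>12.4f}{r.p_value:>10.4f}"
                f"  {'yes' if r.passed else 'NO'}"
            )
        lines.append("-" * 56)
        lines.append(f"overall: {'PASS' if self.overall_pass else 'FAIL'} "
                     f"(criterion: every p > {ALPHA})")
        return "\n".join(lines)


def validate_cohort(
    simulated: Sequence[Agent],
    reference: Optional[ReferenceSummary] = None,
    pooled: bool = True,
    correction: bool = False,
) -> ValidationReport:
    """Run the ten-variable battery on a simulated cohort.

    Continuous variables use the t-test from summaries; dichotomous
    variables and the NPDR/PDR split use chi-square on the (simulated x
    reference) 2x2 count table.
    """
    if not simulated:
        raise ValidationError("simulated cohort is empty")
    if reference is None:
        reference = default_reference()
    n_sim = len(simulated)
    report = ValidationReport()

    for name in CONTINUOUS_VARIABLES:
        if name not in reference.continuous:
            raise ValidationError(f"reference missing continuous variable {name!r}")
        values = np.array([a.profile.value(name) for a in simulated])
        n_ref, mean_ref, sd_ref = reference.continuous[name]
        t, p = t_test_from_summary(
            n_ref, mean_ref, sd_ref,
            n_sim, float(values.mean()), float(values.std(ddof=1)),
            pooled=pooled,
        )
        report.results.append(VariableResult(name, "t test", t, p))

    for name in DICHOTOMOUS_VARIABLES:
        if name not in reference.dichotomous:
            raise ValidationError(f"reference missing dichotomous variable {name!r}")
        count_sim = int(sum(a.profile.value(name) for a in simulated))
        n_ref, count_ref = reference.dichotomous[name]
        table = [
            [count_sim, n_sim - count_sim],
            [count_ref, n_ref - count_ref],
        ]
        if any(col == 0 for col in np.asarray(table).sum(axis=0)):
            # trait constant and identical in both cohorts: trivial agreement
            report.results.append(VariableResult(name, "chi square (degenerate)", 0.0, 1.0))
            continue
        chi2, p = chi_square_test(table, correction=correction)
        report.results.append(VariableResult(name, "chi square", chi2, p))

    for key in ("NPDR", "PDR"):
        if key not in reference.stages:
            raise ValidationError(f"reference missing stage count {key!r}")
    npdr_sim = sum(1 for a in simulated if a.state is DRState.NPDR)
    pdr_sim = sum(1 for a in simulated if a.state is DRState.PDR)
    table = [
        [npdr_sim, pdr_sim],
        [reference.stages["NPDR"], reference.stages["PDR"]],
    ]
    chi2, p = chi_square_test(table, correction=correction)
    report.results.append(VariableResult(STAGE_VARIABLE, "chi square", chi2, p))
    return report
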