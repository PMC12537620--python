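"""Risk-factor exposure groups, relative risks, and counterfactual scenarios.

Two modifiable exposures are modelled: mid-life hypertension (exposure
defined at ages 40-59, acting from age 40 onward) and late-life smoking
(current smoking after 65, acting from age 65 onward).  Every individual
belongs from birth to one of four mutually exclusive groups -- ``none``,
``smoking``, ``hypertension`` or ``both`` -- and the group's relative risks
multiply the baseline dementia-onset and other-cause mortality hazards
whenever the corresponding exposure window is active.

Scenarios reduce the *prevalence* of exposure while leaving the relative
risks of the remaining exposed untouched: a reduction fraction ``r`` removes
each factor independently from a fraction ``r`` of its carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

GROUPS = ("none", "smoking", "hypertension", "both")
SEXES = ("female", "male")

#: group index -> (carries smoking, carries hypertension)
GROUP_EXPOSURES = {
    "none": (False, False),
    "smoking": (True, False),
    "hypertension": (False, True),
    "both": (True, True),
}


class ConsistencyError(ValueError):
    """Raised when risk-group prevalences are mutually inconsistent."""


def combine_rr(rr_a: float, rr_b: float) -> float:
    """Combine two relative risks on the additive excess-risk scale.

    ``RR_both = 1 + (RR_a - 1) + (RR_b - 1)``.  Commutative with identity 1.
    """
    if rr_a <= 0 or rr_b <= 0:
        raise ValueError(f"relative risks must be positive, got {rr_a}, {rr_b}")
    return 1.0 + (rr_a - 1.0) + (rr_b - 1.0)


@dataclass(frozen=True)
class RiskGroupConfig:
    """Sex-specific exposure prevalences (%), relative risks and age windows.

    ``prev_*`` are survivor-prevalence targets in percent: smoking among
    those alive at 65-100, hypertension among those alive at 40-59, and the
    joint exposure among those alive at 65-100.  ``ci_*`` carry the 95%
    confidence bounds used by the univariate sensitivity analysis.
    """

    sex: str
    prev_smoking: float
    prev_hypertension: float
    prev_both: float
    rr_dementia_smoking: float
    rr_dementia_hypertension: float
    rr_mortality_smoking: float
    rr_mortality_hypertension: float
    ci_prev_smoking: tuple[float, float] | None = None
    ci_prev_hypertension: tuple[float, float] | None = None
    ci_prev_both: tuple[float, float] | None = None
    ci_rr_dementia_smoking: tuple[float, float] | None = None
    ci_rr_dementia_hypertension: tuple[float, float] | None = None
    ci_rr_mortality_smoking: tuple[float, float] | None = None
    ci_rr_mortality_hypertension: tuple[float, float] | None = None
    prev_hypertension_medication: float | None = None
    cooccurrence: float | None = None  # share of smokers with mid-life HTN
    window_smoking_start: int = 65
    window_hypertension_start: int = 40
    smoking_target_window: tuple[int, int] = (65, 100)
    hypertension_target_window: tuple[int, int] = (40, 59)
    #: if True, hypertension mortality RR applies only within 40-59
    mortality_hypertension_midlife_only: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        for name in ("prev_smoking", "prev_hypertension", "prev_both"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.prev_both > min(self.prev_smoking, self.prev_hypertension) + 1e-12:
            raise ConsistencyError(
                "joint prevalence exceeds a marginal: "
                f"both={self.prev_both}, smoking={self.prev_smoking}, "
                f"hypertension={self.prev_hypertension}"
            )
        for name in (
            "rr_dementia_smoking",
            "rr_dementia_hypertension",
            "rr_mortality_smoking",
            "rr_mortality_hypertension",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_param(self, name: str, value: float) -> "RiskGroupConfig":
        """Return a copy with one parameter replaced (sensitivity sweeps)."""
        return replace(self, **{name: value})


@dataclass(frozen=True)
class GroupFractions:
    """Birth-assignment probabilities of the four risk groups (sum to 1)."""

    f_none: float
    f_smoking: float
    f_hypertension: float
    f_both: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ConsistencyError(f"fractions outside [0,1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ConsistencyError(f"fractions sum to {arr.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_none, self.f_smoking, self.f_hypertension, self.f_both]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "GroupFractions":
        return cls(*(float(x) for x in arr))


def allocate_groups(config: RiskGroupConfig) -> GroupFractions:
    """Naive (pre-calibration) birth allocation from prevalence targets.

    Treats the survivor-prevalence targets directly as birth fractions:
    ``f_both`` from the joint prevalence, marginals minus the overlap for the
    single-exposure groups, remainder unexposed.  Differential mortality is
    ignored here; :mod:`demsim.calibrate` corrects for it.
    """
    f_both = config.prev_both / 100.0
    f_smoke = config.prev_smoking / 100.0 - f_both
    f_htn = config.prev_hypertension / 100.0 - f_both
    if f_smoke < -1e-12 or f_htn < -1e-12:
        raise ConsistencyError("joint prevalence exceeds a marginal prevalence")
    f_none = 1.0 - f_both - f_smoke - f_htn
    if f_none < -1e-12:
        raise ConsistencyError("prevalences sum above 100%")
    return GroupFractions(max(f_none, 0.0), max(f_smoke, 0.0), max(f_htn, 0.0), f_both)


def rr_at_age(group: str, age: float, endpoint: str, config: RiskGroupConfig) -> float:
    """Relative risk multiplier for ``group`` at ``age`` for one endpoint.

    Active single-factor RRs are combined additively on the excess-risk
    scale; a factor outside its exposure window contributes 1.
    """
    if group not in GROUP_EXPOSURES:
        raise ValueError(f"unknown group {group!r}")
    if endpoint not in ("dementia", "mortality"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    smokes, htn = GROUP_EXPOSURES[group]
    active = []
    if smokes and age >= config.window_smoking_start:
        active.append(
            config.rr_dementia_smoking
            if endpoint == "dementia"
            else config.rr_mortality_smoking
        )
    if htn and age >= config.window_hypertension_start:
        if (
            endpoint == "mortality"
            and config.mortality_hypertension_midlife_only
            and age > config.hypertension_target_window[1]
        ):
            pass
        else:
            active.append(
                config.rr_dementia_hypertension
                if endpoint == "dementia"
                else config.rr_mortality_hypertension
            )
    rr = 1.0
    for r in active:
        rr = combine_rr(rr, r)
    return rr


def rr_matrix(config: RiskGroupConfig, endpoint: str, max_age: int) -> np.ndarray:
    """(max_age+1, 4) array of RR multipliers by age and group."""
    ages = np.arange(max_age + 1)
    out = np.empty((max_age + 1, len(GROUPS)))
    for j, g in enumerate(GROUPS):
        out[:, j] = [rr_at_age(g, a, endpoint, config) for a in ages]
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual prevalence-reduction scenario.

    ``reduce_smoking`` / ``reduce_hypertension`` are the fractions of
    carriers from whom the factor is removed (1.0 = complete elimination).
    """

    label: str
    reduce_smoking: float = 0.0
    reduce_hypertension: float = 0.0

    def __post_init__(self) -> None:
        for name in ("reduce_smoking", "reduce_hypertension"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def is_reference(self) -> bool:
        return self.reduce_smoking == 0.0 and self.reduce_hypertension == 0.0


REFERENCE_SCENARIO = ScenarioSpec("reference", 0.0, 0.0)


def apply_scenario(fractions: GroupFractions, spec: ScenarioSpec) -> GroupFractions:
    """Transform birth fractions under a prevalence-reduction scenario.

    Each factor is removed independently from a fraction ``r`` of its
    carriers, so from the ``both`` group a share ``r_s (1-r_h)`` moves to
    ``hypertension``, ``(1-r_s) r_h`` to ``smoking`` and ``r_s r_h`` to
    ``none``.  Sums to one exactly and is monotone in both fractions.
    """
    rs, rh = spec.reduce_smoking, spec.reduce_hypertension
    f_both = fractions.f_both * (1 - rs) * (1 - rh)
    f_smoke = fractions.f_smoking * (1 - rs) + fractions.f_both * (1 - rs) * rh
    f_htn = fractions.f_hypertension * (1 - rh) + fractions.f_both * rs * (1 - rh)
    f_none = 1.0 - f_both - f_smoke - f_htn
    return GroupFractions(f_none, f_smoke, f_htn, f_both)


def default_scenarios() -> list[ScenarioSpec]:
    """The reference plus the twelve reduction scenarios of the base case.

    Reductions of 10/25/50/100% applied to smoking only, hypertension only,
    and both factors jointly.
    """
    with resources.files("demsim.data").joinpath("scenarios.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return [ScenarioSpec(**d) for d in raw["scenarios"]]


def load_scenarios(path) -> list[ScenarioSpec]:
    """Read scenario definitions from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [ScenarioSpec(**d) for d in raw["scenarios"]]
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario labels")
    return specs
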