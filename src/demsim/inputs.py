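"""Demographic and epidemiologic inputs: life tables and incidence schedules.

The analysis needs three inputs per sex: an other-cause mortality life table
for the simulated birth cohort, an age schedule of population-average
dementia-onset hazards, and the risk-factor parameter set (prevalences,
co-occurrence, relative risks).  Real national life tables and cohort-study
incidence curves are not redistributable, so this module also generates
synthetic stand-ins: a Gompertz-Makeham life table with male excess
mortality and an exponentially age-increasing onset hazard with an optional
linear secular decline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .risk import RiskGroupConfig, SEXES

# Non-paper defaults for the synthetic stand-in inputs; all overridable.
DEFAULT_MAX_AGE = 100
DEFAULT_ONSET_FLOOR_AGE = 40
DEFAULT_RATE_AT_65 = 0.002  # 1/year
DEFAULT_DOUBLING_TIME = 5.5  # years
#: linear secular decline in dementia incidence, fraction per decade, the
#: meta-analytic estimate for North American/European cohorts
DEFAULT_TREND_DECLINE = 0.13
#: cohort life expectancy targets (years at birth) emulating projected
#: mortality of a 1980 European birth cohort
DEFAULT_LIFE_EXPECTANCY = {"female": 86.8, "male": 84.1}
#: Gompertz slope; projected cohort tables are rectangularized, hence
#: steeper than the classic period-table value of ~0.1
DEFAULT_GOMPERTZ_C = 0.14  # 1/year
DEFAULT_MAKEHAM_A = 5e-4  # 1/year

_FIXTURE_SHA256 = "18aea759ab1eef5da27d2563f5deadaeaac90195eff30ff69ed78043fe642c7c"


class IntegrityError(RuntimeError):
    """Packaged fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz-Makeham hazard ``h(age) = a + b * exp(c * age)``."""

    makeham_a: float
    gompertz_b: float
    gompertz_c: float

    def __post_init__(self) -> None:
        if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_c <= 0:
            # b = 0 is allowed only through hazard(); guard the common misuse
            if not (self.gompertz_b == 0 and self.makeham_a >= 0):
                raise ValueError(f"invalid Gompertz-Makeham parameters: {self}")

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        with np.errstate(over="ignore"):
            h = self.makeham_a + self.gompertz_b * np.exp(
                self.gompertz_c * np.asarray(age, dtype=float)
            )
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite hazard from Gompertz parameters")
        return h

    def cumulative_hazard(self, age: float) -> float:
        """Closed-form integral of the hazard from 0 to ``age``."""
        if self.gompertz_b == 0:
            return self.makeham_a * age
        return self.makeham_a * age + (self.gompertz_b / self.gompertz_c) * (
            np.exp(self.gompertz_c * age) - 1.0
        )


@dataclass
class LifeTable:
    """Annual probabilities of other-cause death by single year of age.

    ``qx[a]`` is the probability of dying from causes other than dementia
    between exact ages ``a`` and ``a+1``; the table is closed with
    ``qx[max_age] = 1``.
    """

    sex: str
    qx: np.ndarray
    max_age: int = DEFAULT_MAX_AGE

    def __post_init__(self) -> None:
        self.qx = np.asarray(self.qx, dtype=float)
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.qx.shape != (self.max_age + 1,):
            raise ValueError(
                f"qx length {self.qx.shape} does not match max_age {self.max_age}"
            )
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            raise ValueError("qx outside [0, 1]")
        if self.qx[-1] != 1.0:
            raise ValueError("life table must be closed: qx[max_age] = 1")

    def hazard(self) -> np.ndarray:
        """Implied annual hazards ``-ln(1 - qx)`` (inf at the closing age)."""
        with np.errstate(divide="ignore"):
            return -np.log1p(-self.qx)

    def survival(self) -> np.ndarray:
        """Survivorship l(a) for a = 0..max_age+1, starting at 1."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])

    def life_expectancy(self) -> float:
        """Expected years lived at birth (half-year correction within ages)."""
        lx = self.survival()
        return float(np.sum(0.5 * (lx[:-1] + lx[1:])))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# life table (other-cause qx), sex={self.sex}, synthetic stand-in\n")
            fh.write("age,qx\n")
            for a, q in enumerate(self.qx):
                fh.write(f"{a},{float(q)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path, sex: str | None = None) -> "LifeTable":
        rows, file_sex = _read_commented_csv(path)
        qx = np.array([float(v) for _, v in rows])
        return cls(sex=sex or file_sex or "female", qx=qx, max_age=len(qx) - 1)


@dataclass
class IncidenceSchedule:
    """Population-average annual dementia-onset hazard by age.

    ``h_pop[a]`` is the hazard (1/year) of the onset event at age ``a`` in
    the total non-demented population; zero below ``onset_floor_age``.  A
    linear secular decline of ``trend_decline_per_decade`` (a fraction per
    ten calendar years relative to ``reference_year``) is applied at
    simulation time as a multiplier clipped at zero.
    """

    sex: str
    h_pop: np.ndarray
    trend_decline_per_decade: float = 0.0
    reference_year: int = 2015
    birth_year: int = 1980
    onset_floor_age: int = DEFAULT_ONSET_FLOOR_AGE
    max_age: int = DEFAULT_MAX_AGE

    def __post_init__(self) -> None:
        self.h_pop = np.asarray(self.h_pop, dtype=float)
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.h_pop.shape != (self.max_age + 1,):
            raise ValueError("h_pop length does not match max_age")
        if np.any(self.h_pop < 0):
            raise ValueError("negative incidence hazard")
        if np.any(self.h_pop[: self.onset_floor_age] != 0):
            raise ValueError("incidence must be zero below the onset floor age")

    def trend_multiplier(self, age: float) -> float:
        year = self.birth_year + age
        m = 1.0 - self.trend_decline_per_decade * (year - self.reference_year) / 10.0
        return max(0.0, m)

    def hazard_at(self, age: int) -> float:
        """Onset hazard at ``age`` including the secular-trend multiplier."""
        return float(self.h_pop[age] * self.trend_multiplier(age))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# dementia onset hazard, sex={self.sex}, "
                f"trend_decline_per_decade={self.trend_decline_per_decade!r}, "
                f"reference_year={self.reference_year}, birth_year={self.birth_year}, "
                f"onset_floor_age={self.onset_floor_age}, synthetic stand-in\n"
            )
            fh.write("age,hazard\n")
            for a, h in enumerate(self.h_pop):
                fh.write(f"{a},{float(h)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path, sex: str | None = None) -> "IncidenceSchedule":
        rows, file_sex, meta = _read_commented_csv(path, return_meta=True)
        h = np.array([float(v) for _, v in rows])
        kwargs = {}
        for key, cast in (
            ("trend_decline_per_decade", float),
            ("reference_year", int),
            ("birth_year", int),
            ("onset_floor_age", int),
        ):
            if key in meta:
                kwargs[key] = cast(meta[key])
        return cls(sex=sex or file_sex or "female", h_pop=h, max_age=len(h) - 1, **kwargs)


def _read_commented_csv(path, return_meta: bool = False):
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split(","):
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k.strip()] = v.strip()
                continue
            if line.split(",")[0] == "age":
                continue
            a, v = line.split(",")
            rows.append((a, v))
    sex = meta.get("sex")
    if return_meta:
        return rows, sex, meta
    return rows, sex


def make_life_table(
    params: GompertzParams, sex: str, max_age: int = DEFAULT_MAX_AGE
) -> LifeTable:
    """Build an other-cause life table from a Gompertz-Makeham hazard.

    ``qx(a) = 1 - exp(-(a_m + b exp(c a)))`` for ages below ``max_age``; the
    table is closed with ``qx(max_age) = 1``.
    """
    ages = np.arange(max_age + 1, dtype=float)
    h = np.asarray(params.hazard(ages), dtype=float)
    qx = -np.expm1(-h)
    qx[-1] = 1.0
    return LifeTable(sex=sex, qx=qx, max_age=max_age)


def subtract_dementia_share(
    table: LifeTable, share: float | np.ndarray
) -> LifeTable:
    """Remove a dementia-attributable share from an all-cause life table.

    ``share`` is the fraction of deaths at each age attributable to
    dementia; the returned table carries the other-cause remainder on the
    hazard scale, so the simulator's stage-specific dementia mortality does
    not double-count those deaths.  The closing age stays closed.
    """
    share = np.broadcast_to(np.asarray(share, dtype=float), table.qx.shape).copy()
    if np.any(share < 0) or np.any(share >= 1):
        raise ValueError("dementia share must be in [0, 1)")
    h = table.hazard()
    qx = -np.expm1(-h[:-1] * (1.0 - share[:-1]))
    return LifeTable(sex=table.sex, qx=np.append(qx, 1.0), max_age=table.max_age)


def make_incidence_schedule(
    rate_at_65: float,
    doubling_time: float,
    trend_decline_per_decade: float = 0.0,
    sex: str = "female",
    max_age: int = DEFAULT_MAX_AGE,
    onset_floor_age: int = DEFAULT_ONSET_FLOOR_AGE,
    reference_year: int = 2015,
    birth_year: int = 1980,
) -> IncidenceSchedule:
    """Exponentially age-increasing onset hazard.

    ``h(a) = rate_at_65 * 2**((a - 65) / doubling_time)`` for ages at or
    above the onset floor, zero below.  ``doubling_time = inf`` gives a flat
    hazard equal to ``rate_at_65``.
    """
    if rate_at_65 < 0:
        raise ValueError("rate_at_65 must be non-negative")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    ages = np.arange(max_age + 1, dtype=float)
    with np.errstate(over="raise"):
        h = rate_at_65 * np.power(2.0, (ages - 65.0) / doubling_time)
    h[:onset_floor_age] = 0.0
    return IncidenceSchedule(
        sex=sex,
        h_pop=h,
        trend_decline_per_decade=trend_decline_per_decade,
        reference_year=reference_year,
        birth_year=birth_year,
        onset_floor_age=onset_floor_age,
        max_age=max_age,
    )


def fit_gompertz_to_life_expectancy(
    e0_target: float,
    sex: str,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    makeham_a: float = DEFAULT_MAKEHAM_A,
    max_age: int = DEFAULT_MAX_AGE,
) -> GompertzParams:
    """Solve the Gompertz level ``b`` so the table's e0 matches a target."""
    from scipy.optimize import brentq

    def f(log_b: float) -> float:
        p = GompertzParams(makeham_a, float(np.exp(log_b)), gompertz_c)
        return make_life_table(p, sex, max_age).life_expectancy() - e0_target

    log_b = brentq(f, np.log(1e-9), np.log(1e-2), xtol=1e-12)
    return GompertzParams(makeham_a, float(np.exp(log_b)), gompertz_c)


def default_synthetic_inputs(
    sex: str,
    max_age: int = DEFAULT_MAX_AGE,
    rate_at_65: float = DEFAULT_RATE_AT_65,
    doubling_time: float = DEFAULT_DOUBLING_TIME,
    trend_decline_per_decade: float = DEFAULT_TREND_DECLINE,
    life_expectancy: float | None = None,
) -> tuple[LifeTable, IncidenceSchedule]:
    """Default synthetic stand-in inputs for one sex (non-paper defaults).

    The Gompertz-Makeham slope is fitted so life expectancy at birth is
    about 83 years for women and 79 for men, giving the characteristic male
    excess mortality; incidence doubles every 5.5 years of age and declines
    13% per decade of calendar time, so for the simulated birth cohort the
    effective old-age hazard is flatter than the cross-sectional curve.
    """
    e0 = life_expectancy if life_expectancy is not None else DEFAULT_LIFE_EXPECTANCY[sex]
    params = fit_gompertz_to_life_expectancy(e0, sex, max_age=max_age)
    table = make_life_table(params, sex, max_age)
    inc = make_incidence_schedule(
        rate_at_65,
        doubling_time,
        trend_decline_per_decade,
        sex=sex,
        max_age=max_age,
    )
    return table, inc


@dataclass
class ReferenceBundle:
    """Packaged risk-factor parameters plus default synthetic inputs."""

    risk_config: RiskGroupConfig
    life_table: LifeTable
    incidence: IncidenceSchedule


def load_risk_config(sex: str) -> RiskGroupConfig:
    """Load the packaged risk-factor parameter fixture for one sex.

    Raises :class:`IntegrityError` if the packaged file's checksum does not
    match the value recorded at release.
    """
    res = resources.files("demsim.data").joinpath("risk_factors.yaml")
    raw_bytes = res.read_bytes()
    digest = hashlib.sha256(raw_bytes).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"risk_factors.yaml checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    raw = yaml.safe_load(raw_bytes)[sex]
    return RiskGroupConfig(
        sex=sex,
        prev_smoking=raw["prev_smoking"]["point"],
        prev_hypertension=raw["prev_hypertension"]["point"],
        prev_both=raw["prev_both"]["point"],
        rr_dementia_smoking=raw["rr_dementia_smoking"]["point"],
        rr_dementia_hypertension=raw["rr_dementia_hypertension"]["point"],
        rr_mortality_smoking=raw["rr_mortality_smoking"]["point"],
        rr_mortality_hypertension=raw["rr_mortality_hypertension"]["point"],
        ci_prev_smoking=tuple(raw["prev_smoking"]["ci"]),
        ci_prev_hypertension=tuple(raw["prev_hypertension"]["ci"]),
        ci_prev_both=tuple(raw["prev_both"]["ci"]),
        ci_rr_dementia_smoking=tuple(raw["rr_dementia_smoking"]["ci"]),
        ci_rr_dementia_hypertension=tuple(raw["rr_dementia_hypertension"]["ci"]),
        ci_rr_mortality_smoking=tuple(raw["rr_mortality_smoking"]["ci"]),
        ci_rr_mortality_hypertension=tuple(raw["rr_mortality_hypertension"]["ci"]),
        prev_hypertension_medication=raw["prev_hypertension_medication"],
        cooccurrence=raw["cooccurrence_smokers_with_hypertension"],
    )


def load_reference_inputs(sex: str, max_age: int = DEFAULT_MAX_AGE) -> ReferenceBundle:
    """Risk-factor fixture plus the default synthetic life table/incidence."""
    table, inc = default_synthetic_inputs(sex, max_age=max_age)
    return ReferenceBundle(load_risk_config(sex), table, inc)
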