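"""DALY engine: years of life lost and years lived with disability.

DALY = YLL + YLD.  YLL is deaths times the (optionally discounted)
remaining life expectancy at the age of death; YLD is cases times
disability weight times the (optionally discounted) disability duration.
Women whose bleeding is controlled by the balloon alone carry the mild
maternal-haemorrhage weight for the six-week postpartum period; any
surgical or ICU pathway carries the severe weight instead (applied once
per patient — weights describe a health state, not events); hysterectomy
additionally causes secondary infertility for the remaining reproductive
life-span.  No age weighting is applied.

The discounting convention for future life-years is configurable because
published cohort analyses vary: ``annual_annuity`` uses
``(1 - (1+r)^-L) / r``, ``continuous`` uses ``(1 - exp(-rL)) / r``, and
``none`` leaves durations undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import PathwayPolicies, death_masses
from .tree import TerminalDistribution, TerminalPayload

__all__ = [
    "DALYParams",
    "DALYResult",
    "discounted_duration",
    "compute_yll",
    "compute_yld",
    "assign_outcome_profile",
    "compute_dalys",
]

DISCOUNT_METHODS = ("none", "annual_annuity", "continuous")


@dataclass(frozen=True)
class DALYParams:
    """Disability weights, durations and discounting policy."""

    dw_mild: float = 0.114
    dw_severe: float = 0.324
    dw_infertility: float = 0.005
    duration_haemorrhage: float = 0.11  # years (six-week postpartum period)
    infertility_end_age: float = 46.0
    cohort_age: float = 21.0
    life_expectancy_remaining: float = 53.79
    discount_rate: float = 0.03
    discount_method: str = "annual_annuity"

    def __post_init__(self) -> None:
        for w in (self.dw_mild, self.dw_severe, self.dw_infertility):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"disability weight {w} outside [0, 1]")
        if self.duration_haemorrhage <= 0 or self.life_expectancy_remaining <= 0:
            raise ValueError("durations must be positive")
        if not (0.0 <= self.discount_rate <= 0.05):
            raise ValueError("discount_rate must lie in [0, 0.05]")
        if self.discount_method not in DISCOUNT_METHODS:
            raise ValueError(f"unknown discount_method {self.discount_method!r}")

    @property
    def duration_infertility(self) -> float:
        """Remaining reproductive life-span after the index birth."""
        return self.infertility_end_age - self.cohort_age

    @classmethod
    def from_parameter_set(cls, params, **overrides) -> "DALYParams":
        """Build from a parameter registry (reference fixture or a PSA draw)."""
        def get(name: str, default: float) -> float:
            try:
                if hasattr(params, "value"):
                    return float(params.value(name))
                return float(params[name])
            except KeyError:
                return default

        base = cls(
            dw_mild=get("dw_mild_haem", 0.114),
            dw_severe=get("dw_severe_haem", 0.324),
            dw_infertility=get("dw_infertility", 0.005),
            duration_haemorrhage=get("duration_haemorrhage", 0.11),
            infertility_end_age=get("infertility_end_age", 46.0),
            cohort_age=get("cohort_age", 21.0),
            life_expectancy_remaining=get("life_expectancy_remaining", 53.79),
            discount_rate=min(get("discount_rate", 0.03), 0.05),
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class DALYResult:
    yll: float
    yld: float
    per_patient_daly: float

    @property
    def daly(self) -> float:
        return self.yll + self.yld


def discounted_duration(L: float, r: float, method: str = "annual_annuity") -> float:
    """Present value of ``L`` years of future life at discount rate ``r``."""
    if L < 0:
        raise ValueError(f"duration must be non-negative, got {L}")
    if method not in DISCOUNT_METHODS:
        raise ValueError(f"unknown discount method {method!r}")
    if r == 0.0 or method == "none":
        return L
    if method == "annual_annuity":
        return (1.0 - (1.0 + r) ** (-L)) / r
    import math

    return (1.0 - math.exp(-r * L)) / r


def compute_yll(deaths: float, dp: DALYParams) -> float:
    """Years of life lost: deaths times discounted remaining life expectancy."""
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    return deaths * discounted_duration(
        dp.life_expectancy_remaining, dp.discount_rate, dp.discount_method
    )


def compute_yld(cases: float, weight: float, duration: float, dp: DALYParams) -> float:
    """Years lived with disability for ``cases`` in one health state."""
    if cases < 0:
        raise ValueError("cases must be non-negative")
    if not (0.0 <= weight <= 1.0):
        raise ValueError(f"disability weight {weight} outside [0, 1]")
    return cases * weight * discounted_duration(
        duration, dp.discount_rate, dp.discount_method
    )


def assign_outcome_profile(
    payload: TerminalPayload, dp: DALYParams | None = None
) -> list[tuple[float, float]]:
    """Disability (weight, duration) contributions for one terminal state.

    Control by the balloon alone takes the mild haemorrhage weight; any
    devascularization, hysterectomy or ICU admission takes the severe
    weight once; hysterectomy appends the infertility weight over the
    remaining reproductive life-span.  Terminals with no outcome flags
    contribute nothing.
    """
    dp = dp or DALYParams()
    flags = payload.event_flags
    out: list[tuple[float, float]] = []
    if flags & {"devascularization", "hysterectomy", "icu"}:
        out.append((dp.dw_severe, dp.duration_haemorrhage))
    elif "ubt_only_control" in flags:
        out.append((dp.dw_mild, dp.duration_haemorrhage))
    if "hysterectomy" in flags:
        out.append((dp.dw_infertility, dp.duration_infertility))
    return out


def compute_dalys(
    td: TerminalDistribution,
    dp: DALYParams | None = None,
    *,
    pol: PathwayPolicies | None = None,
    background_death_prob: float = 0.0,
) -> DALYResult:
    """Aggregate DALYs over a terminal distribution.

    Deaths (assigned per the pathway death policy) accrue YLL only; the
    surviving mass at each terminal accrues YLD per its outcome profile.
    """
    dp = dp or DALYParams()
    pol = pol or PathwayPolicies()
    deaths = death_masses(td, pol, background_death_prob)
    yll = compute_yll(sum(deaths.values()), dp)
    yld = 0.0
    for tid, _, count, payload in td.rows:
        survivors = max(count - deaths.get(tid, 0.0), 0.0)
        for weight, duration in assign_outcome_profile(payload, dp):
            yld += compute_yld(survivors, weight, duration, dp)
    cohort = td.cohort
    daly = yll + yld
    return DALYResult(yll=yll, yld=yld,
                      per_patient_daly=(daly / cohort if cohort > 0 else 0.0))
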