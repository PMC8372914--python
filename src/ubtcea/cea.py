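"""Cost-effectiveness arithmetic: ICER, net monetary benefit, dominance.

A strategy is summarized by its total and per-patient costs (societal
and health-system) and per-patient DALYs.  Pairwise comparisons against
the comparator report the incremental cost, DALYs averted, the ICER
(incremental cost per DALY averted), and the incremental net monetary
benefit NMB = DALYs averted x WTP - incremental cost.  Because a bare
negative ICER is ambiguous (cost-saving-and-better versus
costlier-and-worse), every ICER is accompanied by a dominance quadrant
label and the NMB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import model as _model
from . import outcomes as _outcomes
from .model import EventCounts, PathwayPolicies, resolve_strategy
from .outcomes import DALYParams
from .params import ParameterSet
from .tree import rollback_evaluate

__all__ = [
    "CEASettings",
    "StrategyResult",
    "CEAResult",
    "compute_icer",
    "compute_nmb",
    "classify_dominance",
    "summarize_strategy",
    "convert_currency",
    "run_strategy",
    "compare_strategies",
]

#: |DALYs averted| below this is treated as a zero effect (ICER undefined)
_EFFECT_EPS = 1e-12


@dataclass(frozen=True)
class CEASettings:
    """Threshold and currency settings (2017-18 Indian reference case)."""

    wtp: float = 24_211.0  # INR per DALY averted
    gdp_per_capita: float = 127_816.0  # INR
    usd_rate: float = 64.5  # INR per USD

    def __post_init__(self) -> None:
        if min(self.wtp, self.gdp_per_capita, self.usd_rate) <= 0:
            raise ValueError("CEASettings values must be positive")

    @classmethod
    def from_parameter_set(cls, params) -> "CEASettings":
        get = params.value if hasattr(params, "value") else params.__getitem__
        return cls(wtp=float(get("wtp_per_daly")),
                   gdp_per_capita=float(get("gdp_per_capita")),
                   usd_rate=float(get("usd_rate")))


@dataclass(frozen=True)
class StrategyResult:
    """Per-strategy totals and per-patient values over the cohort."""

    strategy: str
    cohort: float
    total_societal_cost: float
    total_health_system_cost: float
    per_patient_societal_cost: float
    per_patient_health_system_cost: float
    per_patient_daly: float
    events: EventCounts


@dataclass(frozen=True)
class CEAResult:
    """Pairwise incremental comparison of intervention versus comparator."""

    comparator: str
    intervention: str
    delta_cost_per_patient: float
    dalys_averted_per_patient: float
    icer: float | None  # None marks an undefined ratio (zero effect)
    nmb_per_patient: float
    dominance: str


def compute_icer(delta_cost: float, dalys_averted: float) -> float | None:
    """Incremental cost per DALY averted; None when the effect is zero."""
    if abs(dalys_averted) < _EFFECT_EPS:
        return None
    return delta_cost / dalys_averted


def compute_nmb(delta_cost: float, dalys_averted: float, wtp: float) -> float:
    """Incremental net monetary benefit at a willingness-to-pay threshold."""
    if wtp <= 0:
        raise ValueError("wtp must be positive")
    return dalys_averted * wtp - delta_cost


def classify_dominance(delta_cost: float, dalys_averted: float) -> str:
    """Quadrant of the cost-effectiveness plane for the intervention.

    ``dominant``: saves money without losing effect; ``dominated``:
    costs more without gaining effect; ``tradeoff_ne``: buys effect at a
    cost; ``tradeoff_sw``: saves money but loses effect.  The exact
    origin (no difference at all) is reported as ``tradeoff_ne`` with
    zero magnitudes.
    """
    if delta_cost == 0.0 and dalys_averted == 0.0:
        return "tradeoff_ne"
    if delta_cost <= 0.0 and dalys_averted >= 0.0:
        return "dominant"
    if delta_cost >= 0.0 and dalys_averted <= 0.0:
        return "dominated"
    if delta_cost > 0.0 and dalys_averted > 0.0:
        return "tradeoff_ne"
    return "tradeoff_sw"


def convert_currency(inr: float, settings: CEASettings | None = None) -> float:
    """Convert INR to USD at the fixed 2017-18 rate."""
    settings = settings or CEASettings()
    return inr / settings.usd_rate


def summarize_strategy(
    strategy: str,
    cohort: float,
    total_societal_cost: float,
    total_health_system_cost: float,
    total_daly: float,
    events: EventCounts,
) -> StrategyResult:
    """Assemble a StrategyResult; per-patient values are totals / cohort."""
    if not math.isfinite(cohort) or cohort < 0:
        raise ValueError(f"invalid cohort {cohort}")
    div = cohort if cohort > 0 else math.nan
    return StrategyResult(
        strategy=strategy,
        cohort=cohort,
        total_societal_cost=total_societal_cost,
        total_health_system_cost=total_health_system_cost,
        per_patient_societal_cost=total_societal_cost / div if cohort > 0 else math.nan,
        per_patient_health_system_cost=(
            total_health_system_cost / div if cohort > 0 else math.nan
        ),
        per_patient_daly=total_daly / div if cohort > 0 else math.nan,
        events=events,
    )


def run_strategy(
    params,
    strategy: str,
    *,
    pol: PathwayPolicies | None = None,
    dp: DALYParams | None = None,
    cohort: float | None = None,
) -> StrategyResult:
    """Full pipeline for one device: build tree, roll back, cost, DALY.

    ``params`` is the reference registry or a sampled draw mapping; the
    cohort defaults to the registry's eligible-cohort entry.
    """
    s = resolve_strategy(strategy)
    pol = pol or PathwayPolicies()
    dp = dp or DALYParams.from_parameter_set(params)
    if cohort is None:
        cohort = (
            params.value("cohort_ubt_eligible")
            if isinstance(params, ParameterSet)
            else float(params["cohort_ubt_eligible"])
        )
    tree = _model.build_ubt_tree(s, params, pol)
    td = rollback_evaluate(tree, params, cohort)
    p_death = (
        params.value("p_mort_all_cause")
        if isinstance(params, ParameterSet)
        else float(params["p_mort_all_cause"])
    )
    events = _model.compute_event_counts(td, pol, background_death_prob=p_death)
    soc_total, _ = _model.accumulate_costs(td, "societal")
    hs_total, _ = _model.accumulate_costs(td, "health_system")
    dalys = _outcomes.compute_dalys(td, dp, pol=pol, background_death_prob=p_death)
    return summarize_strategy(s.name, cohort, soc_total, hs_total, dalys.daly, events)


def compare_strategies(
    intervention: StrategyResult,
    comparator: StrategyResult,
    settings: CEASettings | None = None,
    perspective: str = "societal",
) -> CEAResult:
    """Pairwise incremental comparison on per-patient values."""
    settings = settings or CEASettings()
    if perspective == "societal":
        dc = (intervention.per_patient_societal_cost
              - comparator.per_patient_societal_cost)
    elif perspective == "health_system":
        dc = (intervention.per_patient_health_system_cost
              - comparator.per_patient_health_system_cost)
    else:
        raise ValueError(f"unknown perspective {perspective!r}")
    de = comparator.per_patient_daly - intervention.per_patient_daly  # averted
    return CEAResult(
        comparator=comparator.strategy,
        intervention=intervention.strategy,
        delta_cost_per_patient=dc,
        dalys_averted_per_patient=de,
        icer=compute_icer(dc, de),
        nmb_per_patient=compute_nmb(dc, de, settings.wtp),
        dominance=classify_dominance(dc, de),
    )
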