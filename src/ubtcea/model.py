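"""Atonic-PPH management model with uterine balloon tamponade (UBT).

Builds the device-strategy decision tree for an annual cohort of Indian
women whose atonic post-partum hemorrhage is refractory to uterotonics.
The cohort splits across primary/secondary/tertiary public facilities;
primary-level cases are stabilized, receive the balloon, and are referred
to secondary care where the clinical pathway continues.  Bleeding is
either controlled by the device alone or proceeds down a surgical
cascade: immediate obstetric hysterectomy, or uterus-preserving
devascularization possibly followed by hysterectomy.  ICU care exists at
tertiary level only, so a secondary-level case needing ICU incurs one
extra referral.  Each terminal accrues the insertion, inpatient, surgery,
ICU, referral and provider-training costs (health-system payer) plus the
household out-of-pocket expenditure.

The decision among devices is represented as three structurally
identical trees, one per strategy, evaluated on the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .params import ParameterSet
from .tree import (
    COMPLEMENT,
    CostItem,
    DecisionTree,
    TerminalDistribution,
    TerminalPayload,
)

__all__ = [
    "Strategy",
    "PathwayPolicies",
    "EventCounts",
    "STRATEGIES",
    "resolve_strategy",
    "eligible_cohort",
    "build_ubt_tree",
    "compute_event_counts",
    "death_masses",
    "accumulate_costs",
]

LEVELS = ("primary", "secondary", "tertiary")
PROCEDURES = ("devascularization", "hysterectomy")


@dataclass(frozen=True)
class Strategy:
    """A UBT device strategy and the parameter names it draws costs from."""

    name: str
    effectiveness_param: str
    insertion_cost_params: Mapping[str, str]  # level -> parameter name
    surgery_cost_params: Mapping[tuple[str, str], str]  # (level, procedure) -> name


def _make_strategy(name: str, tag: str) -> Strategy:
    return Strategy(
        name=name,
        effectiveness_param=f"p_eff_{tag}",
        insertion_cost_params={lvl: f"cost_insert_{tag}_{lvl}" for lvl in LEVELS},
        surgery_cost_params={
            (lvl, "devascularization"): f"cost_devasc_{tag}_{lvl}"
            for lvl in ("secondary", "tertiary")
        }
        | {
            (lvl, "hysterectomy"): f"cost_hyst_{tag}_{lvl}"
            for lvl in ("secondary", "tertiary")
        },
    )


STRATEGIES: dict[str, Strategy] = {
    "condom_ubt": _make_strategy("condom_ubt", "condom"),
    "esm_ubt": _make_strategy("esm_ubt", "esm"),
    "bakri_ubt": _make_strategy("bakri_ubt", "bakri"),
}

_ALIASES = {
    "condom": "condom_ubt",
    "esm": "esm_ubt",
    "bakri": "bakri_ubt",
}


def resolve_strategy(name: str | Strategy) -> Strategy:
    if isinstance(name, Strategy):
        return name
    key = _ALIASES.get(name, name)
    try:
        return STRATEGIES[key]
    except KeyError:
        raise KeyError(
            f"unknown strategy {name!r}; expected one of {sorted(STRATEGIES)}"
        ) from None


@dataclass(frozen=True)
class PathwayPolicies:
    """Structural policy switches for the clinical pathway.

    ``death_model`` controls how maternal deaths are assigned:
    ``background_only`` spreads the all-cause maternal mortality
    probability across the whole cohort; ``background_plus_excess``
    additionally applies ``excess_pph_death_prob`` to the mass left
    uncontrolled after the balloon.
    """

    death_model: str = "background_only"
    excess_pph_death_prob: float = 0.0
    hysterectomy_definitive: bool = True
    referral_primary_to_secondary: bool = True
    icu_at_tertiary_only: bool = True

    def __post_init__(self) -> None:
        if self.death_model not in ("background_only", "background_plus_excess"):
            raise ValueError(f"unknown death_model {self.death_model!r}")
        if not (0.0 <= self.excess_pph_death_prob <= 1.0):
            raise ValueError("excess_pph_death_prob must lie in [0, 1]")


@dataclass(frozen=True)
class EventCounts:
    """Expected clinical event counts over the cohort."""

    patients_operated: float
    procedures: float
    hysterectomies: float
    icu_admissions: float
    deaths: float
    referrals: float


def _pv(params, name: str) -> float:
    """Look up a parameter value from a ParameterSet or a plain mapping."""
    if isinstance(params, ParameterSet):
        return params.value(name)
    return float(params[name])


def eligible_cohort(params) -> int:
    """Annual UBT-eligible cohort: deliveries in public facilities times
    PPH incidence, times the atonic share, times the share refractory to
    uterotonics; rounded to a whole number of women."""
    n = (
        _pv(params, "deliveries_public")
        * _pv(params, "p_pph_incidence")
        * _pv(params, "p_atonic_share")
        * _pv(params, "p_uterotonic_failure")
    )
    return int(round(n))


def _pathway(
    t: DecisionTree,
    prefix: str,
    s: Strategy,
    params,
    *,
    insertion_level: str,
    care_level: str,
    referred_in: bool,
    pol: PathwayPolicies,
) -> str:
    """Build the post-insertion clinical pathway; returns its entry node.

    ``insertion_level`` prices the balloon insertion; ``care_level``
    (secondary or tertiary) prices inpatient stay and surgery.
    """
    insertion = _pv(params, s.insertion_cost_params[insertion_level])
    ipd = _pv(params, f"cost_ipd_{care_level}")
    icu_cost = _pv(params, "cost_icu_tertiary")
    referral = _pv(params, "cost_referral")
    training = _pv(params, "cost_training")
    oope = _pv(params, "cost_oope")
    devasc = _pv(params, s.surgery_cost_params[(care_level, "devascularization")])
    hyst = _pv(params, s.surgery_cost_params[(care_level, "hysterectomy")])

    base_items = [
        CostItem("ubt_insertion", insertion, "health_system"),
        CostItem("ipd_admission", ipd, "health_system"),
        CostItem("provider_training", training, "health_system"),
        CostItem("oope_childbirth", oope, "household"),
    ]
    base_flags: set[str] = set()
    if referred_in:
        base_items.append(CostItem("referral", referral, "health_system"))
        base_flags.add("referred")
    # ICU sits at tertiary only: a case managed at secondary needs one
    # more referral to reach it.
    icu_needs_referral = pol.icu_at_tertiary_only and care_level == "secondary"

    def terminal(
        tag: str,
        flags: set[str],
        extra: list[CostItem],
        icu: bool,
        label: str,
    ) -> str:
        items = list(base_items) + list(extra)
        f = set(base_flags) | flags
        if icu:
            f.add("icu")
            items.append(CostItem("icu_admission", icu_cost, "health_system"))
            if icu_needs_referral:
                items.append(CostItem("referral", referral, "health_system"))
                f.add("referred")
        nid = f"{prefix}_{tag}"
        return t.add_terminal(
            nid,
            TerminalPayload(tuple(items), frozenset(f), "controlled"),
            label,
        )

    def icu_split(parent: str, tag: str, prob_param: str, flags: set[str],
                  extra: list[CostItem], label: str) -> None:
        t.add_branch(parent, terminal(f"{tag}_icu", flags, extra, True, f"{label}, ICU"),
                     prob_param)
        t.add_branch(parent, terminal(f"{tag}_noicu", flags, extra, False, label),
                     COMPLEMENT)

    ctrl = t.add_chance(f"{prefix}_controlled_q", "bleeding controlled by UBT?")

    icu_c = t.add_chance(f"{prefix}_ctrl_icu_q", "ICU needed despite control?")
    t.add_branch(ctrl, icu_c, s.effectiveness_param)
    icu_split(icu_c, "ctrl", "p_icu_controlled", {"ubt_only_control"}, [],
              "controlled by UBT alone")

    surg = t.add_chance(f"{prefix}_surgery_q", "immediate hysterectomy?")
    t.add_branch(ctrl, surg, COMPLEMENT)

    hyst_item = CostItem("hysterectomy", hyst, "health_system")
    devasc_item = CostItem("devascularization", devasc, "health_system")

    icu_hi = t.add_chance(f"{prefix}_hystimm_icu_q", "ICU after immediate hysterectomy?")
    t.add_branch(surg, icu_hi, "p_hyst_immediate")
    icu_split(icu_hi, "hystimm", "p_icu_uncontrolled", {"hysterectomy"},
              [hyst_item], "immediate hysterectomy")

    cascade = t.add_chance(f"{prefix}_devasc_q", "hysterectomy after devascularization?")
    t.add_branch(surg, cascade, COMPLEMENT)

    icu_dh = t.add_chance(f"{prefix}_devhyst_icu_q", "ICU after devascularization + hysterectomy?")
    t.add_branch(cascade, icu_dh, "p_hyst_after_devasc")
    icu_split(icu_dh, "devhyst", "p_icu_uncontrolled",
              {"devascularization", "hysterectomy"}, [devasc_item, hyst_item],
              "hysterectomy after devascularization")

    icu_dc = t.add_chance(f"{prefix}_devctrl_icu_q", "ICU after devascularization control?")
    t.add_branch(cascade, icu_dc, COMPLEMENT)
    icu_split(icu_dc, "devctrl", "p_icu_uncontrolled", {"devascularization"},
              [devasc_item], "controlled by devascularization")
    return ctrl


def build_ubt_tree(
    strategy: str | Strategy, params, pol: PathwayPolicies | None = None
) -> DecisionTree:
    """Build the full three-facility-level tree for one device strategy.

    Branch probabilities remain parameter references resolved at
    evaluation time; cost amounts are priced from ``params`` at build
    time, so sensitivity analyses rebuild the (cheap) structure per
    scenario.
    """
    s = resolve_strategy(strategy)
    pol = pol or PathwayPolicies()
    t = DecisionTree(root="facility")
    t.add_chance("facility", "facility level accessed")

    # Primary-level cases pay the primary insertion price plus one
    # referral, then follow the secondary-level pathway (no re-insertion).
    pri = _pathway(
        t, "pri", s, params,
        insertion_level="primary",
        care_level="secondary",
        referred_in=pol.referral_primary_to_secondary,
        pol=pol,
    )
    sec = _pathway(t, "sec", s, params,
                   insertion_level="secondary", care_level="secondary",
                   referred_in=False, pol=pol)
    ter = _pathway(t, "ter", s, params,
                   insertion_level="tertiary", care_level="tertiary",
                   referred_in=False, pol=pol)

    t.add_branch("facility", pri, "p_primary")
    t.add_branch("facility", sec, "p_secondary")
    t.add_branch("facility", ter, COMPLEMENT)
    return t


def _uncontrolled_mass(td: TerminalDistribution) -> float:
    """Mass that entered the surgical cascade (uncontrolled after UBT)."""
    return sum(
        r[2]
        for r in td.rows
        if r[3].event_flags & {"devascularization", "hysterectomy"}
    )


def death_masses(
    td: TerminalDistribution, pol: PathwayPolicies, background_death_prob: float
) -> dict[str, float]:
    """Expected deaths per terminal under the death policy.

    Background all-cause maternal mortality applies uniformly to every
    terminal; the optional excess probability applies on top of it to the
    surgical-cascade terminals only.
    """
    out: dict[str, float] = {}
    for tid, _, count, payload in td.rows:
        p = background_death_prob
        if (
            pol.death_model == "background_plus_excess"
            and payload.event_flags & {"devascularization", "hysterectomy"}
        ):
            p = min(1.0, p + pol.excess_pph_death_prob)
        out[tid] = count * p
    return out


def compute_event_counts(
    td: TerminalDistribution,
    pol: PathwayPolicies | None = None,
    background_death_prob: float = 0.0,
) -> EventCounts:
    """Reduce a terminal distribution to expected clinical event counts.

    ``patients_operated`` is the expected mass on surgical-cascade
    terminals (at least one procedure); ``procedures`` counts
    devascularizations and hysterectomies separately; ``referrals``
    counts referral events (a primary-level case later needing ICU from
    secondary care is referred twice).
    """
    pol = pol or PathwayPolicies()
    deaths = sum(death_masses(td, pol, background_death_prob).values())
    devasc = td.mass_with_flag("devascularization")
    hyst = td.mass_with_flag("hysterectomy")
    referrals = sum(
        count * sum(1 for c in payload.cost_items if c.label == "referral")
        for _, _, count, payload in td.rows
    )
    return EventCounts(
        patients_operated=_uncontrolled_mass(td),
        procedures=devasc + hyst,
        hysterectomies=hyst,
        icu_admissions=td.mass_with_flag("icu"),
        deaths=deaths,
        referrals=referrals,
    )


def accumulate_costs(
    td: TerminalDistribution, perspective: str = "societal"
) -> tuple[float, float]:
    """Total and per-patient cost under a payer perspective.

    The societal perspective sums health-system and household items;
    the health-system perspective drops household out-of-pocket spending.
    Costs are undiscounted (one-time events at the time of delivery).
    """
    if perspective == "societal":
        payers = ("health_system", "household")
    elif perspective == "health_system":
        payers = ("health_system",)
    else:
        raise ValueError(f"unknown perspective {perspective!r}")
    total = sum(count * payload.cost(payers) for _, _, count, payload in td.rows)
    cohort = td.cohort
    return total, (total / cohort if cohort > 0 else 0.0)
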