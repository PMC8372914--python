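"""Synthetic fixtures: micro-models with closed-form answers and
randomized-but-valid parameter files.

The micro-model is a reduced single-facility-level tree (optional
surgical cascade, optional ICU) whose expected counts, costs and DALYs
are also computed here by independent closed-form hand formulas, so the
tree engine and the DALY/cost reducers can be checked against arithmetic
that never touches them.  The random parameter files keep the reference
registry's names and statistical shape (bounded proportions with
interval limits, positively skewed costs) while drawing fresh values, so
pipeline tests do not silently depend on the reference numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .outcomes import DALYParams
from .params import (
    BETA_GROUPS,
    Parameter,
    ParameterSet,
    dump_parameter_table,
    load_reference_table,
)
from .tree import COMPLEMENT, CostItem, DecisionTree, TerminalPayload

__all__ = ["ScenarioSpec", "make_micro_model", "make_random_parameter_file"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A hand-checkable reduced scenario."""

    seed: int = 0
    cohort: float = 1000.0
    effectiveness: float = 0.9
    insertion_cost: float = 300.0
    ipd_cost: float = 1500.0
    devasc_cost: float = 4000.0
    hyst_cost: float = 7000.0
    icu_cost: float = 5000.0
    training_cost: float = 375.0
    oope: float = 2755.0
    p_hyst_immediate: float = 0.15
    p_hyst_after_devasc: float = 0.22
    p_icu_controlled: float = 0.025
    p_icu_uncontrolled: float = 0.769
    include_cascade: bool = True
    include_icu: bool = True

    def __post_init__(self) -> None:
        probs = (
            self.effectiveness, self.p_hyst_immediate, self.p_hyst_after_devasc,
            self.p_icu_controlled, self.p_icu_uncontrolled,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.cohort < 0:
            raise ValueError("cohort must be non-negative")

    @classmethod
    def random(cls, seed: int) -> "ScenarioSpec":
        rng = np.random.default_rng(seed)
        return cls(
            seed=seed,
            cohort=float(rng.integers(100, 100_000)),
            effectiveness=float(rng.uniform(0.5, 0.99)),
            insertion_cost=float(rng.lognormal(5.5, 0.5)),
            ipd_cost=float(rng.lognormal(7.0, 0.4)),
            devasc_cost=float(rng.lognormal(8.0, 0.4)),
            hyst_cost=float(rng.lognormal(8.5, 0.4)),
            icu_cost=float(rng.lognormal(8.3, 0.4)),
            training_cost=float(rng.lognormal(5.5, 0.3)),
            oope=float(rng.lognormal(7.6, 0.3)),
            p_hyst_immediate=float(rng.uniform(0.05, 0.4)),
            p_hyst_after_devasc=float(rng.uniform(0.05, 0.4)),
            p_icu_controlled=float(rng.uniform(0.0, 0.1)),
            p_icu_uncontrolled=float(rng.uniform(0.3, 0.95)),
            include_cascade=bool(rng.integers(0, 2)),
            include_icu=bool(rng.integers(0, 2)),
        )


def _micro_tree(spec: ScenarioSpec) -> DecisionTree:
    base = (
        CostItem("ubt_insertion", spec.insertion_cost, "health_system"),
        CostItem("ipd_admission", spec.ipd_cost, "health_system"),
        CostItem("provider_training", spec.training_cost, "health_system"),
        CostItem("oope_childbirth", spec.oope, "household"),
    )
    icu_item = CostItem("icu_admission", spec.icu_cost, "health_system")
    devasc_item = CostItem("devascularization", spec.devasc_cost, "health_system")
    hyst_item = CostItem("hysterectomy", spec.hyst_cost, "health_system")

    t = DecisionTree(root="controlled_q")
    t.add_chance("controlled_q", "controlled by UBT?")

    def attach(parent: str, prob, tag: str, flags: frozenset[str],
               extra: tuple[CostItem, ...], p_icu: float) -> None:
        if spec.include_icu:
            q = t.add_chance(f"{tag}_icu_q")
            t.add_branch(parent, q, prob)
            t.add_terminal(f"{tag}_icu",
                           TerminalPayload(base + extra + (icu_item,),
                                           flags | {"icu"}, "controlled"))
            t.add_terminal(f"{tag}_noicu",
                           TerminalPayload(base + extra, flags, "controlled"))
            t.add_branch(q, f"{tag}_icu", p_icu)
            t.add_branch(q, f"{tag}_noicu", COMPLEMENT)
        else:
            t.add_terminal(tag, TerminalPayload(base + extra, flags, "controlled"))
            t.add_branch(parent, tag, prob)

    attach("controlled_q", spec.effectiveness, "ctrl",
           frozenset({"ubt_only_control"}), (), spec.p_icu_controlled)

    if spec.include_cascade:
        t.add_chance("surgery_q", "immediate hysterectomy?")
        t.add_branch("controlled_q", "surgery_q", COMPLEMENT)
        attach("surgery_q", spec.p_hyst_immediate, "hystimm",
               frozenset({"hysterectomy"}), (hyst_item,), spec.p_icu_uncontrolled)
        t.add_chance("cascade_q", "hysterectomy after devascularization?")
        t.add_branch("surgery_q", "cascade_q", COMPLEMENT)
        attach("cascade_q", spec.p_hyst_after_devasc, "devhyst",
               frozenset({"devascularization", "hysterectomy"}),
               (devasc_item, hyst_item), spec.p_icu_uncontrolled)
        attach("cascade_q", COMPLEMENT, "devctrl",
               frozenset({"devascularization"}), (devasc_item,),
               spec.p_icu_uncontrolled)
    else:
        # pooled single surgery terminal (priced as one devascularization)
        attach("controlled_q", COMPLEMENT, "surg",
               frozenset({"devascularization"}), (devasc_item,),
               spec.p_icu_uncontrolled)
    return t


def _closed_form(spec: ScenarioSpec, dp: DALYParams) -> dict[str, float]:
    """Hand formulas for the micro-model's expected results."""
    N = spec.cohort
    e = spec.effectiveness
    unc = 1.0 - e
    if spec.include_cascade:
        hyst_frac = spec.p_hyst_immediate + (1.0 - spec.p_hyst_immediate) * spec.p_hyst_after_devasc
        devasc_frac = 1.0 - spec.p_hyst_immediate
    else:
        hyst_frac = 0.0
        devasc_frac = 1.0
    hyst_mass = N * unc * hyst_frac
    devasc_mass = N * unc * devasc_frac
    icu_mass = (
        N * (e * spec.p_icu_controlled + unc * spec.p_icu_uncontrolled)
        if spec.include_icu
        else 0.0
    )
    total_cost = (
        N * (spec.insertion_cost + spec.ipd_cost + spec.training_cost + spec.oope)
        + devasc_mass * spec.devasc_cost
        + hyst_mass * spec.hyst_cost
        + icu_mass * spec.icu_cost
    )
    household = N * spec.oope
    # YLD (no deaths in the micro-model): mild for UBT-alone control
    # except the ICU subset, severe for everything else, infertility on
    # top for hysterectomy.
    mild_mass = N * e * ((1.0 - spec.p_icu_controlled) if spec.include_icu else 1.0)
    severe_mass = N - mild_mass
    from .outcomes import discounted_duration

    d_h = discounted_duration(dp.duration_haemorrhage, dp.discount_rate, dp.discount_method)
    d_i = discounted_duration(dp.duration_infertility, dp.discount_rate, dp.discount_method)
    yld = (
        mild_mass * dp.dw_mild * d_h
        + severe_mass * dp.dw_severe * d_h
        + hyst_mass * dp.dw_infertility * d_i
    )
    return {
        "surgery_patients": N * unc,
        "procedures": devasc_mass + hyst_mass,
        "hysterectomies": hyst_mass,
        "icu_admissions": icu_mass,
        "total_societal_cost": total_cost,
        "total_health_system_cost": total_cost - household,
        "total_daly": yld,
    }


def make_micro_model(
    spec: ScenarioSpec, dp: DALYParams | None = None
) -> tuple[DecisionTree, ScenarioSpec, dict[str, float]]:
    """Reduced tree plus closed-form expected results for oracle tests."""
    dp = dp or DALYParams(discount_rate=0.0, discount_method="none")
    return _micro_tree(spec), spec, _closed_form(spec, dp)


def make_random_parameter_file(seed: int) -> str:
    """A valid randomized parameter file in the reference registry's shape.

    Values are jittered (log-normally for costs, clipped for bounded
    groups) and limits regenerated (±40% for costs, ±20% for bounded
    groups), deterministically per seed.  The facility shares are drawn
    jointly so they sum below one, and the discount rate stays within the
    recommended 0–5% band.
    """
    rng = np.random.default_rng(seed)
    ref = load_reference_table()
    out = ParameterSet(provenance=f"synthetic(seed={seed})")

    shares = rng.dirichlet((4.0, 7.0, 10.0))
    share_names = {"p_primary": 0, "p_secondary": 1, "p_tertiary": 2}

    for p in ref:
        if p.name in share_names:
            v = float(shares[share_names[p.name]])
            lo, hi = max(0.0, 0.8 * v), min(1.0, 1.2 * v)
        elif p.name == "discount_rate":
            v = float(rng.uniform(0.0, 0.05))
            lo, hi = 0.0, 0.05
        elif p.group in BETA_GROUPS:
            v = float(np.clip(p.value * rng.lognormal(0.0, 0.1), 1e-4, 0.98))
            lo, hi = max(0.0, 0.8 * v), min(1.0, 1.2 * v)
        else:
            v = float(max(p.value * rng.lognormal(0.0, 0.2), 1e-6))
            lo, hi = 0.6 * v, 1.4 * v
        out.add(
            Parameter(p.name, p.group, v, lo, hi, p.family, p.units, p.description)
        )
    return dump_parameter_table(out)
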