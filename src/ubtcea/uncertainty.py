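"""Sensitivity and value-of-information analysis.

One-way sensitivity analysis (OWSA) sweeps each parameter to its lower
and upper limit with everything else at base, recording the incremental
net monetary benefit (the tornado outcome scale — finite everywhere,
unlike the ICER near a zero effect difference) together with the ICER.

Probabilistic sensitivity analysis (PSA) jointly re-samples every
non-fixed parameter from its method-of-moments Beta/Gamma distribution,
independently across parameters, and re-evaluates both strategies of a
comparison on each draw.  Within a draw the two arms share the common
parameters (facility shares, ICU probabilities, surgery proportions,
mortality, weights, household spending) and price their own
device-specific parameters, so the comparison uses common random
numbers.  The cohort size and delivery counts are held at base inside
the PSA: per-patient incremental results are cohort-invariant and
re-sampling them would only add spurious noise.

From the PSA draws follow the cost-effectiveness acceptability curve
(probability of positive incremental NMB as a function of the WTP
threshold), the quadrant shares of the cost-effectiveness plane, and the
expected value of perfect information, EVPI =
E[max(0, NMB)] - max(0, E[NMB]) per person, scaled by an undiscounted
one-time population cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cea import (
    CEASettings,
    classify_dominance,
    compute_icer,
    compute_nmb,
    run_strategy,
)
from .model import PathwayPolicies, resolve_strategy
from .params import ParameterSet, derive_sampling_distribution, sample_parameter_set

__all__ = [
    "OWSARow",
    "OWSAResult",
    "PSAResult",
    "run_owsa",
    "run_psa",
    "compute_ceac",
    "compute_evpi",
    "default_wtp_grid",
    "PSA_HELD_FIXED",
]

#: parameters held at base value inside the PSA (cohort-scale inputs;
#: per-patient incremental results do not depend on them)
PSA_HELD_FIXED = frozenset(
    {"cohort_ubt_eligible", "deliveries_public", "age_onset"}
)


@dataclass(frozen=True)
class OWSARow:
    parameter: str
    nmb_at_low: float
    nmb_at_high: float
    icer_at_low: float | None
    icer_at_high: float | None

    @property
    def swing(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


@dataclass
class OWSAResult:
    intervention: str
    comparator: str
    base_nmb: float
    rows: list[OWSARow] = field(default_factory=list)

    def ranked(self) -> list[OWSARow]:
        return sorted(self.rows, key=lambda r: r.swing, reverse=True)


@dataclass
class PSAResult:
    """Per-draw incremental results and derived decision-uncertainty summaries."""

    intervention: str
    comparator: str
    n: int
    seed: int
    wtp: float
    delta_cost: np.ndarray  # per patient, intervention - comparator
    dalys_averted: np.ndarray  # per patient, comparator - intervention
    cost_intervention: np.ndarray
    cost_comparator: np.ndarray
    daly_intervention: np.ndarray
    daly_comparator: np.ndarray

    @property
    def nmb(self) -> np.ndarray:
        return self.dalys_averted * self.wtp - self.delta_cost

    @property
    def p_ce_at_base_wtp(self) -> float:
        return float(np.mean(self.nmb > 0.0))

    @property
    def quadrant_shares(self) -> dict[str, float]:
        shares = dict.fromkeys(
            ("dominant", "dominated", "tradeoff_ne", "tradeoff_sw"), 0.0
        )
        for dc, de in zip(self.delta_cost, self.dalys_averted):
            shares[classify_dominance(float(dc), float(de))] += 1.0 / self.n
        return shares

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> dict[float, float]:
        return compute_ceac(self, wtp_grid)

    def evpi(self, population: float) -> tuple[float, float]:
        nmb = self.nmb
        per_person = float(np.mean(np.maximum(nmb, 0.0)) - max(0.0, float(np.mean(nmb))))
        return per_person, per_person * population


def _pair_nmb(
    params,
    intervention: str,
    comparator: str,
    settings: CEASettings,
    pol: PathwayPolicies,
    perspective: str,
) -> tuple[float, float, float]:
    """(delta_cost, dalys_averted, nmb) per patient for one parameter state."""
    ri = run_strategy(params, intervention, pol=pol)
    rc = run_strategy(params, comparator, pol=pol)
    if perspective == "societal":
        dc = ri.per_patient_societal_cost - rc.per_patient_societal_cost
    else:
        dc = ri.per_patient_health_system_cost - rc.per_patient_health_system_cost
    de = rc.per_patient_daly - ri.per_patient_daly
    return dc, de, compute_nmb(dc, de, settings.wtp)


def run_owsa(
    intervention: str,
    comparator: str,
    params: ParameterSet,
    settings: CEASettings | None = None,
    *,
    pol: PathwayPolicies | None = None,
    perspective: str = "societal",
    parameters: Iterable[str] | None = None,
) -> OWSAResult:
    """One-way sweep of each parameter to its limits, all others at base."""
    settings = settings or CEASettings.from_parameter_set(params)
    pol = pol or PathwayPolicies()
    intervention = resolve_strategy(intervention).name
    comparator = resolve_strategy(comparator).name
    names = list(parameters) if parameters is not None else [p.name for p in params]
    _, _, base_nmb = _pair_nmb(params, intervention, comparator, settings, pol,
                               perspective)
    rows: list[OWSARow] = []
    for name in names:
        p = params[name]
        if p.high == p.low:
            rows.append(OWSARow(name, base_nmb, base_nmb, None, None))
            continue
        out: dict[str, tuple[float, float | None]] = {}
        for side, bound in (("low", p.low), ("high", p.high)):
            varied = params.with_value(name, bound)
            dc, de, nmb = _pair_nmb(varied, intervention, comparator, settings,
                                    pol, perspective)
            out[side] = (nmb, compute_icer(dc, de))
        rows.append(
            OWSARow(name, out["low"][0], out["high"][0], out["low"][1], out["high"][1])
        )
    return OWSAResult(intervention, comparator, base_nmb, rows)


def run_psa(
    intervention: str,
    comparator: str,
    params: ParameterSet,
    settings: CEASettings | None = None,
    *,
    n: int = 10_000,
    seed: int = 0,
    pol: PathwayPolicies | None = None,
    perspective: str = "societal",
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis for one comparison."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    settings = settings or CEASettings.from_parameter_set(params)
    pol = pol or PathwayPolicies()
    intervention = resolve_strategy(intervention).name
    comparator = resolve_strategy(comparator).name
    rng = np.random.default_rng(seed)
    specs = {p.name: derive_sampling_distribution(p) for p in params}

    dc = np.empty(n)
    de = np.empty(n)
    ci = np.empty(n)
    cc = np.empty(n)
    di = np.empty(n)
    dcmp = np.empty(n)
    for k in range(n):
        draw = sample_parameter_set(params, rng, hold_fixed=PSA_HELD_FIXED,
                                    specs=specs)
        ri = run_strategy(draw, intervention, pol=pol)
        rc = run_strategy(draw, comparator, pol=pol)
        if perspective == "societal":
            ci[k] = ri.per_patient_societal_cost
            cc[k] = rc.per_patient_societal_cost
        else:
            ci[k] = ri.per_patient_health_system_cost
            cc[k] = rc.per_patient_health_system_cost
        di[k] = ri.per_patient_daly
        dcmp[k] = rc.per_patient_daly
        dc[k] = ci[k] - cc[k]
        de[k] = dcmp[k] - di[k]
    return PSAResult(
        intervention=intervention,
        comparator=comparator,
        n=n,
        seed=seed,
        wtp=settings.wtp,
        delta_cost=dc,
        dalys_averted=de,
        cost_intervention=ci,
        cost_comparator=cc,
        daly_intervention=di,
        daly_comparator=dcmp,
    )


def default_wtp_grid(settings: CEASettings | None = None) -> list[float]:
    """0 to 400,000 INR in 1,000-INR steps, plus the named thresholds."""
    settings = settings or CEASettings()
    grid = set(float(w) for w in range(0, 400_001, 1000))
    grid.update((settings.wtp, settings.gdp_per_capita, 3.0 * settings.gdp_per_capita))
    return sorted(grid)


def compute_ceac(
    psa: PSAResult, wtp_grid: Sequence[float] | None = None
) -> dict[float, float]:
    """Probability of a positive incremental NMB at each WTP value."""
    grid = list(wtp_grid) if wtp_grid is not None else default_wtp_grid()
    if not grid:
        raise ValueError("wtp grid must be non-empty")
    if min(grid) < 0:
        raise ValueError("wtp values must be non-negative")
    de = psa.dalys_averted
    dc = psa.delta_cost
    return {
        float(w): float(np.mean(de * w - dc > 0.0)) for w in grid
    }


def compute_evpi(
    psa: PSAResult, settings: CEASettings | None = None, population: float = 1.0
) -> tuple[float, float]:
    """Expected value of perfect information, per person and for a population.

    With two strategies the comparator's incremental NMB is identically
    zero, so the per-person EVPI reduces to
    ``E[max(0, NMB)] - max(0, E[NMB])``.  The population figure scales by
    an undiscounted one-time cohort.
    """
    del settings  # the threshold is already baked into psa.nmb
    return psa.evpi(population)
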