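"""Parameter registry for the UBT decision model.

Every model input (probabilities, proportions, unit costs, disability
weights, cohort counts, the discount rate) is carried as a
:class:`Parameter` with a point estimate and lower/upper limits.  The
limits drive both one-way sensitivity analysis (set the parameter to each
limit in turn) and probabilistic sensitivity analysis, where each
parameter receives a Beta (probabilities, proportions, disability
weights) or Gamma (costs, counts, rates, durations) distribution whose
hyperparameters are recovered by method of moments: the mean equals the
point estimate and the standard deviation is ``(high - low) / 3.92``,
i.e. the interval is treated as a symmetric 95% confidence interval.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Parameter",
    "ParameterSet",
    "DistributionSpec",
    "ParameterFormatError",
    "ParameterValidationError",
    "load_parameter_table",
    "dump_parameter_table",
    "derive_sampling_distribution",
    "generate_reference_fixture",
    "load_reference_table",
    "load_reference_constants",
    "perturb_parameters",
    "sample_parameter_set",
]

log = logging.getLogger(__name__)

GROUPS = frozenset(
    {"probability", "proportion", "cost", "count", "weight", "rate", "duration"}
)
#: groups whose values live on [0, 1] and sample from a Beta distribution
BETA_GROUPS = frozenset({"probability", "proportion", "weight"})
#: groups with non-negative values that sample from a Gamma distribution
GAMMA_GROUPS = frozenset({"cost", "count", "rate", "duration"})

FAMILIES = frozenset({"beta", "gamma", "fixed"})

#: device-effectiveness parameters whose draws are capped at the highest
#: effectiveness reported in the literature (98.3%); draws above the
#: ceiling are resampled rather than clamped so the mean is approximately
#: preserved.
EFFECTIVENESS_PARAMS = frozenset({"p_eff_condom", "p_eff_esm", "p_eff_bakri"})
EFFECTIVENESS_CEILING = 0.983

#: the 95% CI spans 3.92 standard deviations under normality
CI_WIDTH_SD = 3.92

FIELDNAMES = ("name", "group", "value", "low", "high", "family", "units", "description")


class ParameterFormatError(ValueError):
    """Raised when a parameter table is structurally malformed."""


class ParameterValidationError(ValueError):
    """Raised when a parameter violates its group invariants."""


@dataclass(frozen=True)
class Parameter:
    """A single named model input with interval limits."""

    name: str
    group: str
    value: float
    low: float
    high: float
    family: str
    units: str = ""
    description: str = ""

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ParameterValidationError(
                f"{self.name}: unknown group {self.group!r}"
            )
        if self.family not in FAMILIES:
            raise ParameterValidationError(
                f"{self.name}: unknown family {self.family!r}"
            )
        if not (self.low <= self.value <= self.high):
            raise ParameterValidationError(
                f"{self.name}: value {self.value} outside limits "
                f"[{self.low}, {self.high}]"
            )
        if self.group in BETA_GROUPS:
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ParameterValidationError(
                    f"{self.name}: group {self.group} requires limits within [0, 1], "
                    f"got [{self.low}, {self.high}]"
                )
            if self.family not in ("beta", "fixed"):
                raise ParameterValidationError(
                    f"{self.name}: group {self.group} requires family beta or fixed"
                )
        else:
            if self.low < 0.0:
                raise ParameterValidationError(
                    f"{self.name}: group {self.group} requires low >= 0"
                )
            if self.family not in ("gamma", "fixed"):
                raise ParameterValidationError(
                    f"{self.name}: group {self.group} requires family gamma or fixed"
                )


@dataclass
class ParameterSet:
    """An ordered registry of uniquely named parameters."""

    entries: dict[str, Parameter] = field(default_factory=dict)
    provenance: str = ""

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def value(self, name: str) -> float:
        return self[name].value

    def add(self, p: Parameter) -> None:
        p.validate()
        if p.name in self.entries:
            raise ParameterValidationError(f"duplicate parameter name {p.name!r}")
        self.entries[p.name] = p

    def with_value(self, name: str, value: float, *, widen: bool = True) -> "ParameterSet":
        """Return a copy with ``name`` set to ``value``.

        With ``widen`` (default) the limits are stretched to contain the
        new value, so one-way sweeps to a limit stay valid.
        """
        p = self[name]
        low, high = p.low, p.high
        if widen:
            low, high = min(low, value), max(high, value)
        new = replace(p, value=value, low=low, high=high)
        new.validate()
        entries = dict(self.entries)
        entries[name] = new
        return ParameterSet(entries, self.provenance)

    def merged(self, other: "ParameterSet", provenance: str = "") -> "ParameterSet":
        out = ParameterSet(provenance=provenance or self.provenance)
        for p in self:
            out.add(p)
        for p in other:
            out.add(p)
        return out


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution derived from a parameter's interval limits.

    ``hyper1``/``hyper2`` are (alpha, beta) for the Beta family,
    (shape, scale) for the Gamma family, and (value, unused) for fixed
    parameters.  ``truncation_high`` caps draws by resampling.
    """

    family: str
    hyper1: float
    hyper2: float = 0.0
    truncation_high: float | None = None

    @property
    def mean(self) -> float:
        """Analytic mean (before any truncation)."""
        if self.family == "beta":
            return self.hyper1 / (self.hyper1 + self.hyper2)
        if self.family == "gamma":
            return self.hyper1 * self.hyper2
        return self.hyper1

    @property
    def sd(self) -> float:
        """Analytic standard deviation (before any truncation)."""
        if self.family == "beta":
            a, b = self.hyper1, self.hyper2
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        if self.family == "gamma":
            return math.sqrt(self.hyper1) * self.hyper2
        return 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        """Draw from the distribution, resampling above any ceiling."""
        n = 1 if size is None else size
        if self.family == "fixed":
            out = np.full(n, self.hyper1)
        elif self.family == "beta":
            out = rng.beta(self.hyper1, self.hyper2, size=n)
        elif self.family == "gamma":
            out = rng.gamma(self.hyper1, self.hyper2, size=n)
        else:  # pragma: no cover - guarded by validation
            raise ValueError(f"unknown family {self.family!r}")
        if self.truncation_high is not None and self.family != "fixed":
            bad = out > self.truncation_high
            while bad.any():
                k = int(bad.sum())
                if self.family == "beta":
                    out[bad] = rng.beta(self.hyper1, self.hyper2, size=k)
                else:
                    out[bad] = rng.gamma(self.hyper1, self.hyper2, size=k)
                bad = out > self.truncation_high
        return float(out[0]) if size is None else out


def _parse_float(raw: str, *, row: str, column: str) -> float:
    raw = raw.strip()
    try:
        return float(raw)
    except ValueError:
        raise ParameterFormatError(
            f"row {row!r}: column {column!r} is not numeric: {raw!r}"
        ) from None


def load_parameter_table(source: str | io.TextIOBase, provenance: str = "") -> ParameterSet:
    """Load a parameter table from CSV text or a readable text stream.

    The dialect is plain comma-separated UTF-8 with a single header row
    carrying exactly the fields of :class:`Parameter`.  The whole file is
    rejected on the first invariant violation.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return ParameterSet(provenance=provenance)
    missing = [c for c in FIELDNAMES if c not in reader.fieldnames]
    if missing:
        raise ParameterFormatError(f"missing column(s): {', '.join(missing)}")
    ps = ParameterSet(provenance=provenance)
    for row in reader:
        name = (row["name"] or "").strip()
        if not name:
            raise ParameterFormatError("row with empty parameter name")
        p = Parameter(
            name=name,
            group=(row["group"] or "").strip(),
            value=_parse_float(row["value"], row=name, column="value"),
            low=_parse_float(row["low"], row=name, column="low"),
            high=_parse_float(row["high"], row=name, column="high"),
            family=(row["family"] or "").strip(),
            units=(row["units"] or "").strip(),
            description=(row["description"] or "").strip(),
        )
        ps.add(p)
    return ps


def dump_parameter_table(ps: ParameterSet) -> str:
    """Serialize to the CSV dialect; round-trips bit-exactly via ``repr``."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(FIELDNAMES)
    for p in ps:
        writer.writerow(
            [p.name, p.group, repr(p.value), repr(p.low), repr(p.high),
             p.family, p.units, p.description]
        )
    return buf.getvalue()


def truncated_beta_mean(a: float, b: float, c: float) -> float:
    """Mean of a Beta(a, b) conditioned on being at most ``c``."""
    from scipy.special import betainc

    denom = betainc(a, b, c)
    if denom <= 0.0:
        return c
    return a / (a + b) * betainc(a + 1.0, b, c) / denom


def _truncated_beta_hypers(m: float, nu: float, c: float) -> tuple[float, float]:
    """Beta hyperparameters whose ceiling-truncated mean equals ``m``.

    Starting from the method-of-moments precision ``nu = alpha + beta``,
    root-finds the mean parameter upward until the truncated mean
    recovers the target.  When the ceiling makes the target unreachable
    at that precision (or leaves almost no mass below the ceiling, which
    would stall rejection sampling), the precision is raised — i.e. the
    spread narrows to what a mean-preserving truncated Beta can support.
    """
    from scipy.optimize import brentq
    from scipy.special import betainc

    hi = 1.0 - 1e-9
    for _ in range(64):
        def gap(mu: float, nu: float = nu) -> float:
            return truncated_beta_mean(mu * nu, (1.0 - mu) * nu, c) - m

        if gap(m) >= 0.0:  # ceiling not binding at this precision
            return m * nu, (1.0 - m) * nu
        if gap(hi) > 0.0:
            mu = brentq(gap, m, hi, xtol=1e-12)
            a, b = mu * nu, (1.0 - mu) * nu
            if betainc(a, b, c) >= 0.05:  # keep rejection sampling cheap
                return a, b
        nu *= 1.5
    raise RuntimeError(
        f"no mean-preserving truncated Beta found for mean={m}, ceiling={c}"
    )


def derive_sampling_distribution(p: Parameter) -> DistributionSpec:
    """Method-of-moments Beta/Gamma spec from a parameter's limits.

    Mean is the point estimate; sd is ``(high - low) / 3.92``.  Degenerate
    intervals give a fixed spec.  A beta-group parameter whose implied
    variance is infeasible (``var >= mean * (1 - mean)``) falls back to
    fixed with a logged warning.  Device-effectiveness parameters carry
    the literature ceiling as a truncation bound, and their Beta is
    re-centred so the truncated distribution keeps the point estimate as
    its mean (sampled means then recover the base values, which is what
    keeps the probabilistic analysis centred on the base case).
    """
    p.validate()
    trunc = EFFECTIVENESS_CEILING if p.name in EFFECTIVENESS_PARAMS else None
    if p.family == "fixed" or p.high == p.low:
        return DistributionSpec("fixed", p.value)
    sd = (p.high - p.low) / CI_WIDTH_SD
    var = sd * sd
    if p.family == "beta":
        m = p.value
        if m <= 0.0 or m >= 1.0 or var >= m * (1.0 - m):
            log.warning(
                "parameter %s: implied variance %.3g infeasible for a Beta "
                "with mean %.3g; holding fixed", p.name, var, m,
            )
            return DistributionSpec("fixed", p.value)
        nu = m * (1.0 - m) / var - 1.0
        if trunc is not None:
            # Effectiveness ceiling: choose the Beta so that the
            # *truncated* distribution keeps the point estimate as its
            # mean (conditioning alone would drag it well below).
            a, b = _truncated_beta_hypers(m, nu, trunc)
            return DistributionSpec("beta", a, b, truncation_high=trunc)
        return DistributionSpec("beta", m * nu, (1.0 - m) * nu)
    # gamma: mean = k * theta, var = k * theta^2
    if p.value <= 0.0:
        log.warning("parameter %s: non-positive mean; holding fixed", p.name)
        return DistributionSpec("fixed", p.value)
    theta = var / p.value
    k = p.value / theta
    return DistributionSpec("gamma", k, theta, truncation_high=trunc)


def _read_packaged_csv(filename: str) -> str:
    return (resources.files("ubtcea.data") / filename).read_text(encoding="utf-8")


def load_reference_table() -> ParameterSet:
    """The packaged reference parameter table (model inputs with limits)."""
    return load_parameter_table(_read_packaged_csv("table1_reference.csv"),
                                provenance="table1_reference")


def load_reference_constants() -> ParameterSet:
    """The packaged named constants (WTP, GDP, currency, life tables)."""
    return load_parameter_table(_read_packaged_csv("constants.csv"),
                                provenance="constants")


def generate_reference_fixture() -> ParameterSet:
    """The full reference registry: model inputs merged with constants."""
    return load_reference_table().merged(load_reference_constants(),
                                         provenance="reference")


def sample_parameter_set(
    ps: ParameterSet,
    rng: np.random.Generator,
    *,
    hold_fixed: Iterable[str] = (),
    specs: Mapping[str, DistributionSpec] | None = None,
) -> dict[str, float]:
    """One joint independent draw of all parameters, as name -> value.

    Parameters named in ``hold_fixed`` keep their base value.  Pass
    ``specs`` to reuse pre-derived distribution specs across many draws.
    """
    held = set(hold_fixed)
    out: dict[str, float] = {}
    for p in ps:
        if p.name in held:
            out[p.name] = p.value
            continue
        spec = specs[p.name] if specs is not None else derive_sampling_distribution(p)
        out[p.name] = float(spec.sample(rng))
    return out


def perturb_parameters(ps: ParameterSet, scale: float, seed: int) -> ParameterSet:
    """Synthetic variant of a parameter set for testing.

    Each non-fixed value is replaced by a draw from its sampling
    distribution shrunk by ``scale`` toward the mean (``scale == 1`` is a
    full-variance draw; ``scale -> 0`` returns the base values).  Limits
    are shifted consistently so invariants keep holding.  Deterministic
    given ``seed``.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    rng = np.random.default_rng(seed)
    out = ParameterSet(provenance=f"{ps.provenance}+perturbed(scale={scale},seed={seed})")
    for p in ps:
        spec = derive_sampling_distribution(p)
        if spec.family == "fixed":
            out.add(p)
            continue
        draw = float(spec.sample(rng))
        value = p.value + scale * (draw - p.value)
        if p.group in BETA_GROUPS:
            value = min(max(value, 0.0), 1.0)
        else:
            value = max(value, 0.0)
        shift = value - p.value
        low, high = p.low + shift, p.high + shift
        if p.group in BETA_GROUPS:
            low, high = max(low, 0.0), min(high, 1.0)
        else:
            low = max(low, 0.0)
        out.add(replace(p, value=value, low=min(low, value), high=max(high, value)))
    return out
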