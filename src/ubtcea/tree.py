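"""Generic decision-tree engine.

A tree is a rooted graph of chance nodes and terminal nodes.  Branch
probabilities are either numeric literals, named references resolved
against a :class:`~ubtcea.params.ParameterSet` at evaluation time, or a
complement marker (one minus the sum of the sibling branches).  Rollback
evaluation pushes an expected cohort mass from the root down every path;
an exhaustive depth-first path enumeration serves as an independent
oracle for the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "COMPLEMENT",
    "Node",
    "Branch",
    "CostItem",
    "TerminalPayload",
    "DecisionTree",
    "TerminalDistribution",
    "TreeStructureError",
    "ParameterLookupError",
    "validate_tree",
    "rollback_evaluate",
    "enumerate_paths",
    "tree_to_dict",
    "tree_from_dict",
    "tree_to_yaml",
    "tree_from_yaml",
]

#: complement marker: branch takes probability 1 - sum(resolved siblings)
COMPLEMENT = "~"

PAYERS = frozenset({"health_system", "household"})
EVENT_FLAGS = frozenset(
    {"ubt_only_control", "devascularization", "hysterectomy", "icu", "referred"}
)

_PROB_TOL = 1e-9


class TreeStructureError(ValueError):
    """Raised when a tree is structurally unusable (e.g. contains a cycle)."""


class ParameterLookupError(KeyError):
    """Raised when a branch references a parameter missing from the set."""


@dataclass(frozen=True)
class Node:
    id: str
    kind: str  # "chance" | "terminal"
    label: str = ""


@dataclass(frozen=True)
class Branch:
    parent: str
    child: str
    #: float literal, parameter name, or COMPLEMENT
    probability: float | str


@dataclass(frozen=True)
class CostItem:
    label: str
    amount: float
    payer: str  # "health_system" | "household"


@dataclass(frozen=True)
class TerminalPayload:
    cost_items: tuple[CostItem, ...] = ()
    event_flags: frozenset[str] = frozenset()
    bleeding_status: str = "controlled"  # "controlled" | "uncontrolled"

    @property
    def total_cost(self) -> float:
        return sum(c.amount for c in self.cost_items)

    def cost(self, payers: Iterable[str]) -> float:
        wanted = set(payers)
        return sum(c.amount for c in self.cost_items if c.payer in wanted)


@dataclass
class DecisionTree:
    root: str
    nodes: dict[str, Node] = field(default_factory=dict)
    branches: list[Branch] = field(default_factory=list)
    payloads: dict[str, TerminalPayload] = field(default_factory=dict)

    def children(self, node_id: str) -> list[Branch]:
        return [b for b in self.branches if b.parent == node_id]

    def add_chance(self, node_id: str, label: str = "") -> str:
        self.nodes[node_id] = Node(node_id, "chance", label)
        return node_id

    def add_terminal(self, node_id: str, payload: TerminalPayload, label: str = "") -> str:
        self.nodes[node_id] = Node(node_id, "terminal", label)
        self.payloads[node_id] = payload
        return node_id

    def add_branch(self, parent: str, child: str, probability: float | str) -> None:
        self.branches.append(Branch(parent, child, probability))

    def terminals(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind == "terminal"]


def _resolve(prob: float | str, params: Mapping[str, float] | None) -> float | None:
    """Resolve a non-complement branch probability; None if unresolvable."""
    if isinstance(prob, str):
        if prob == COMPLEMENT:
            raise ValueError("complement branches are resolved per sibling group")
        if params is None:
            return None
        try:
            if hasattr(params, "value"):
                return float(params.value(prob))  # type: ignore[attr-defined]
            return float(params[prob])
        except KeyError:
            raise ParameterLookupError(prob) from None
    return float(prob)


def _sibling_probabilities(
    t: DecisionTree, node_id: str, params: Mapping[str, float] | None
) -> list[float] | None:
    """Resolved probabilities of the branches under ``node_id``.

    Returns None when a parameter reference cannot be resolved because no
    parameter set was supplied (structural validation mode).
    """
    kids = t.children(node_id)
    fixed: list[float | None] = []
    comp_at: int | None = None
    for i, b in enumerate(kids):
        if isinstance(b.probability, str) and b.probability == COMPLEMENT:
            comp_at = i
            fixed.append(None)
        else:
            fixed.append(_resolve(b.probability, params))
    if any(v is None for i, v in enumerate(fixed) if i != comp_at):
        return None
    total = sum(v for i, v in enumerate(fixed) if i != comp_at)  # type: ignore[misc]
    if comp_at is not None:
        fixed[comp_at] = 1.0 - total
    return [float(v) for v in fixed]  # type: ignore[arg-type]


def validate_tree(
    t: DecisionTree, params: Mapping[str, float] | None = None
) -> list[str]:
    """Return a list of invariant violations (empty iff the tree is valid).

    Violations are data, not exceptions; each one names the node or
    branch and the rule broken.  Numeric sum-to-one checks run only where
    the sibling probabilities are resolvable (always for literal-only
    nodes; for parameter references when ``params`` is given).
    """
    violations: list[str] = []
    if t.root not in t.nodes:
        return [f"root {t.root!r} is not a node"]

    for b in t.branches:
        for end, role in ((b.parent, "parent"), (b.child, "child")):
            if end not in t.nodes:
                violations.append(f"branch {b.parent}->{b.child}: unknown {role} {end!r}")
        if not isinstance(b.probability, str):
            if not (0.0 <= b.probability <= 1.0):
                violations.append(
                    f"branch {b.parent}->{b.child}: literal probability "
                    f"{b.probability} outside [0, 1]"
                )

    # reachability (and cycle tolerance: a revisit is reported, not looped)
    seen: set[str] = set()
    stack = [t.root]
    while stack:
        nid = stack.pop()
        if nid in seen:
            continue
        seen.add(nid)
        stack.extend(b.child for b in t.children(nid) if b.child in t.nodes)
    for nid in t.nodes:
        if nid not in seen:
            violations.append(f"node {nid}: unreachable from root")

    for node in t.nodes.values():
        kids = t.children(node.id)
        if node.kind == "chance":
            if len(kids) < 2:
                violations.append(f"node {node.id}: chance node with < 2 branches")
            n_comp = sum(
                1 for b in kids
                if isinstance(b.probability, str) and b.probability == COMPLEMENT
            )
            if n_comp > 1:
                violations.append(f"node {node.id}: {n_comp} complement branches (max 1)")
            elif kids:
                try:
                    probs = _sibling_probabilities(t, node.id, params)
                except ParameterLookupError as exc:
                    violations.append(f"node {node.id}: unresolved parameter {exc.args[0]!r}")
                    continue
                if probs is not None:
                    if abs(sum(probs) - 1.0) > _PROB_TOL:
                        violations.append(
                            f"node {node.id}: branch probabilities sum to "
                            f"{sum(probs):.12g}, not 1"
                        )
                    if any(p < -_PROB_TOL or p > 1.0 + _PROB_TOL for p in probs):
                        violations.append(
                            f"node {node.id}: resolved probability outside [0, 1]"
                        )
        elif node.kind == "terminal":
            if kids:
                violations.append(f"node {node.id}: terminal node has branches")
            if node.id not in t.payloads:
                violations.append(f"node {node.id}: terminal without payload")
            else:
                pl = t.payloads[node.id]
                for c in pl.cost_items:
                    if c.amount < 0:
                        violations.append(
                            f"node {node.id}: negative cost item {c.label!r}"
                        )
                    if c.payer not in PAYERS:
                        violations.append(
                            f"node {node.id}: unknown payer {c.payer!r}"
                        )
                unknown = pl.event_flags - EVENT_FLAGS
                if unknown:
                    violations.append(
                        f"node {node.id}: unknown event flags {sorted(unknown)}"
                    )
        else:
            violations.append(f"node {node.id}: unknown kind {node.kind!r}")
    return violations


@dataclass
class TerminalDistribution:
    """Expected cohort mass at each terminal of an evaluated tree."""

    rows: list[tuple[str, float, float, TerminalPayload]]  # id, path prob, count, payload

    @property
    def cohort(self) -> float:
        return sum(r[2] for r in self.rows)

    def mass_with_flag(self, flag: str) -> float:
        return sum(r[2] for r in self.rows if flag in r[3].event_flags)

    def counts(self) -> dict[str, float]:
        return {r[0]: r[2] for r in self.rows}


def rollback_evaluate(
    t: DecisionTree, params: Mapping[str, float] | None, cohort: float
) -> TerminalDistribution:
    """Push the cohort mass from the root to every terminal.

    Each terminal's expected count is the cohort times the product of the
    resolved branch probabilities along its unique root path.
    """
    kids_map: dict[str, list[Branch]] = {}
    for b in t.branches:
        kids_map.setdefault(b.parent, []).append(b)
    getter = params.value if hasattr(params, "value") else (
        params.__getitem__ if params is not None else None
    )

    rows: list[tuple[str, float, float, TerminalPayload]] = []
    stack: list[tuple[str, float]] = [(t.root, 1.0)]
    while stack:
        nid, prob = stack.pop()
        node = t.nodes[nid]
        if node.kind == "terminal":
            rows.append((nid, prob, prob * cohort, t.payloads[nid]))
            continue
        kids = kids_map.get(nid, [])
        total = 0.0
        comp_at = -1
        probs = [0.0] * len(kids)
        for i, b in enumerate(kids):
            bp = b.probability
            if isinstance(bp, str):
                if bp == COMPLEMENT:
                    comp_at = i
                    continue
                if getter is None:
                    raise ParameterLookupError(
                        f"node {nid}: parameter references need a parameter set"
                    )
                try:
                    probs[i] = float(getter(bp))
                except KeyError:
                    raise ParameterLookupError(bp) from None
            else:
                probs[i] = float(bp)
            total += probs[i]
        if comp_at >= 0:
            probs[comp_at] = 1.0 - total
        for b, p in zip(kids, probs):
            stack.append((b.child, prob * p))
    rows.sort(key=lambda r: r[0])
    return TerminalDistribution(rows)


def enumerate_paths(
    t: DecisionTree, params: Mapping[str, float] | None
) -> list[tuple[str, float]]:
    """Exhaustive depth-first path listing: (terminal id, joint probability).

    Independent oracle for :func:`rollback_evaluate`; raises
    :class:`TreeStructureError` on a cycle.
    """
    out: list[tuple[str, float]] = []

    def walk(nid: str, joint: float, path: tuple[str, ...]) -> None:
        if nid in path:
            raise TreeStructureError(f"cycle through node {nid}")
        node = t.nodes[nid]
        if node.kind == "terminal":
            out.append((nid, joint))
            return
        kids = t.children(nid)
        probs = _sibling_probabilities(t, nid, params)
        if probs is None:
            raise ParameterLookupError(
                f"node {nid}: parameter references need a parameter set"
            )
        for b, p in zip(kids, probs):
            walk(b.child, joint * p, path + (nid,))

    walk(t.root, 1.0, ())
    out.sort(key=lambda r: r[0])
    return out


# -- serialization ----------------------------------------------------------

def tree_to_dict(t: DecisionTree) -> dict:
    return {
        "root": t.root,
        "nodes": [
            {"id": n.id, "kind": n.kind, "label": n.label} for n in t.nodes.values()
        ],
        "branches": [
            {"parent": b.parent, "child": b.child, "probability": b.probability}
            for b in t.branches
        ],
        "payloads": {
            nid: {
                "bleeding_status": pl.bleeding_status,
                "event_flags": sorted(pl.event_flags),
                "cost_items": [
                    {"label": c.label, "amount": c.amount, "payer": c.payer}
                    for c in pl.cost_items
                ],
            }
            for nid, pl in t.payloads.items()
        },
    }


def tree_from_dict(d: dict) -> DecisionTree:
    t = DecisionTree(root=d["root"])
    for n in d["nodes"]:
        t.nodes[n["id"]] = Node(n["id"], n["kind"], n.get("label", ""))
    for b in d["branches"]:
        t.branches.append(Branch(b["parent"], b["child"], b["probability"]))
    for nid, pl in d.get("payloads", {}).items():
        t.payloads[nid] = TerminalPayload(
            cost_items=tuple(
                CostItem(c["label"], float(c["amount"]), c["payer"])
                for c in pl.get("cost_items", [])
            ),
            event_flags=frozenset(pl.get("event_flags", [])),
            bleeding_status=pl.get("bleeding_status", "controlled"),
        )
    return t


def tree_to_yaml(t: DecisionTree) -> str:
    return yaml.safe_dump(tree_to_dict(t), sort_keys=False)


def tree_from_yaml(text: str) -> DecisionTree:
    return tree_from_dict(yaml.safe_load(text))
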