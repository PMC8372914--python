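import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubtcea.model import build_ubt_tree
from ubtcea.tree import (
    COMPLEMENT,
    Branch,
    CostItem,
    DecisionTree,
    Node,
    ParameterLookupError,
    TerminalPayload,
    TreeStructureError,
    enumerate_paths,
    rollback_evaluate,
    tree_from_yaml,
    tree_to_yaml,
    validate_tree,
)


def two_branch_tree(p1, p2) -> DecisionTree:
    t = DecisionTree(root="r")
    t.add_chance("r")
    t.add_terminal("a", TerminalPayload())
    t.add_terminal("b", TerminalPayload())
    t.add_branch("r", "a", p1)
    t.add_branch("r", "b", p2)
    return t


class TestValidate:
    def test_complement_resolution_is_clean(self):
        assert validate_tree(two_branch_tree(0.3, COMPLEMENT)) == []

    def test_sum_violation_names_node(self):
        violations = validate_tree(two_branch_tree(0.6, 0.6))
        assert any("node r" in v and "sum" in v for v in violations)

    def test_orphan_terminal_reported(self):
        t = two_branch_tree(0.3, COMPLEMENT)
        t.add_terminal("lost", TerminalPayload())
        assert any("lost" in v and "unreachable" in v for v in violations_of(t))

    def test_single_branch_chance_node_reported(self):
        t = DecisionTree(root="r")
        t.add_chance("r")
        t.add_terminal("a", TerminalPayload())
        t.add_branch("r", "a", 1.0)
        assert any("< 2 branches" in v for v in validate_tree(t))

    def test_two_complements_reported(self):
        assert any("complement" in v for v in validate_tree(
            two_branch_tree(COMPLEMENT, COMPLEMENT)))

    def test_negative_cost_reported(self):
        t = two_branch_tree(0.3, COMPLEMENT)
        t.payloads["a"] = TerminalPayload(
            (CostItem("x", -1.0, "health_system"),)
        )
        assert any("negative cost" in v for v in validate_tree(t))

    def test_parameter_refs_checked_when_params_given(self):
        t = two_branch_tree("p_x", COMPLEMENT)
        assert validate_tree(t) == []  # structural only
        assert validate_tree(t, {"p_x": 0.4}) == []
        assert any("unresolved" in v for v in validate_tree(t, {}))

    def test_reference_ubt_trees_are_valid(self, ref):
        for s in ("condom_ubt", "esm_ubt", "bakri_ubt"):
            t = build_ubt_tree(s, ref)
            assert validate_tree(t, ref) == []


def violations_of(t):
    return validate_tree(t)


class TestRollback:
    def test_two_branch_split(self):
        td = rollback_evaluate(two_branch_tree(0.2, 0.8), None, 100)
        assert td.counts() == {"a": pytest.approx(20.0), "b": pytest.approx(80.0)}

    def test_counts_sum_to_cohort(self, ref):
        td = rollback_evaluate(build_ubt_tree("condom", ref), ref, 59_962)
        assert td.cohort == pytest.approx(59_962, rel=1e-12)

    def test_path_probabilities_sum_to_one(self, ref):
        td = rollback_evaluate(build_ubt_tree("esm", ref), ref, 1.0)
        assert sum(r[1] for r in td.rows) == pytest.approx(1.0, abs=1e-9)

    def test_uncontrolled_mass_matches_hand_product(self, ref):
        # 59,962 x (1 - 0.923) for the condom device
        td = rollback_evaluate(build_ubt_tree("condom", ref), ref, 59_962)
        unc = sum(
            r[2] for r in td.rows
            if r[3].event_flags & {"devascularization", "hysterectomy"}
        )
        assert unc == pytest.approx(59_962 * 0.077, rel=1e-9)

    def test_unresolved_parameter_raises(self):
        t = two_branch_tree("p_missing", COMPLEMENT)
        with pytest.raises(ParameterLookupError):
            rollback_evaluate(t, {}, 10)


class TestEnumerate:
    def test_chain_of_binary_nodes_has_eight_paths(self):
        t = DecisionTree(root="n0")
        probs = [0.3, 0.6, 0.2]
        frontier = ["n0"]
        t.add_chance("n0")
        for level, p in enumerate(probs):
            nxt = []
            for nid in frontier:
                for side, pr in (("l", p), ("r", COMPLEMENT)):
                    child = f"{nid}{side}"
                    if level == len(probs) - 1:
                        t.add_terminal(child, TerminalPayload())
                    else:
                        t.add_chance(child)
                    t.add_branch(nid, child, pr)
                    nxt.append(child)
            frontier = nxt
        paths = enumerate_paths(t, None)
        assert len(paths) == 8
        joint = dict(paths)
        assert joint["n0lll"] == pytest.approx(0.3 * 0.6 * 0.2)
        assert sum(joint.values()) == pytest.approx(1.0)

    def test_degenerate_probabilities_leave_single_path(self):
        paths = enumerate_paths(two_branch_tree(1.0, COMPLEMENT), None)
        assert dict(paths) == {"a": pytest.approx(1.0), "b": pytest.approx(0.0)}

    def test_cycle_detected(self):
        t = DecisionTree(root="r")
        t.add_chance("r")
        t.add_chance("x")
        t.add_branch("r", "x", 0.5)
        t.add_branch("r", "x", COMPLEMENT)
        t.add_branch("x", "r", 0.5)
        t.add_branch("x", "r", COMPLEMENT)
        with pytest.raises(TreeStructureError):
            enumerate_paths(t, None)

    def test_reference_tree_agrees_with_rollback(self, ref):
        for s in ("condom_ubt", "esm_ubt", "bakri_ubt"):
            t = build_ubt_tree(s, ref)
            td = rollback_evaluate(t, ref, 1.0)
            oracle = dict(enumerate_paths(t, ref))
            for tid, prob, _, _ in td.rows:
                assert abs(prob - oracle[tid]) < 1e-12


def random_tree(rng: np.random.Generator) -> DecisionTree:
    """Random chance/terminal tree, <= 6 levels, <= 4 branches per node."""
    t = DecisionTree(root="n")
    max_depth = int(rng.integers(1, 6))

    def grow(nid: str, depth: int) -> None:
        if depth >= max_depth or rng.random() < 0.25:
            t.add_terminal(nid, TerminalPayload())
            return
        t.add_chance(nid)
        k = int(rng.integers(2, 5))
        raw = rng.dirichlet(np.ones(k))
        use_complement = rng.random() < 0.5
        for i in range(k):
            child = f"{nid}{i}"
            prob = COMPLEMENT if (use_complement and i == k - 1) else float(raw[i])
            # without a complement, force exact literals that sum to 1
            t.add_branch(nid, child, prob)
            grow(child, depth + 1)

    grow("n", 0)
    if t.nodes["n"].kind == "terminal":  # ensure at least one chance split
        t.nodes.clear(); t.payloads.clear(); t.branches.clear()
        t.add_chance("n")
        t.add_terminal("n0", TerminalPayload())
        t.add_terminal("n1", TerminalPayload())
        t.add_branch("n", "n0", 0.4)
        t.add_branch("n", "n1", COMPLEMENT)
    return t


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_rollback_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng)
        td = rollback_evaluate(t, None, 1.0)
        oracle = dict(enumerate_paths(t, None))
        assert set(td.counts()) == set(oracle)
        for tid, prob, _, _ in td.rows:
            assert abs(prob - oracle[tid]) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_under_random_cohorts(self, seed):
        rng = np.random.default_rng(seed + 1000)
        t = random_tree(rng)
        cohort = float(rng.integers(1, 10**6))
        td = rollback_evaluate(t, None, cohort)
        assert td.cohort == pytest.approx(cohort, rel=1e-9)


class TestMonotonicity:
    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_raising_branch_probability_shifts_mass_toward_it(self, p, q):
        lo, hi = sorted({p, min(q + 0.01, 0.99)})
        t = two_branch_tree(lo, COMPLEMENT)
        base = rollback_evaluate(t, None, 100).counts()
        t2 = two_branch_tree(hi, COMPLEMENT)
        more = rollback_evaluate(t2, None, 100).counts()
        assert more["a"] >= base["a"]
        assert more["b"] <= base["b"]


class TestSerialization:
    def test_yaml_round_trip(self, ref):
        t = build_ubt_tree("bakri", ref)
        again = tree_from_yaml(tree_to_yaml(t))
        assert again.root == t.root
        assert again.nodes == t.nodes
        assert again.branches == t.branches
        assert again.payloads == t.payloads
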