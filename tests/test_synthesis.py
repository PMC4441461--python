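"""Synthesis: global propagation, ideal vs distributive scoring, ratios."""

import numpy as np
import pytest

from ahp.errors import AHPError
from ahp.hierarchy import DecisionHierarchy, ObjectiveNode
from ahp.priorities import PriorityVector
from ahp.synthesis import (
    DISTRIBUTIVE,
    IDEAL,
    global_objective_priorities,
    relative_differences,
    score_alternatives,
)


def pv(items, weights):
    w = np.asarray(weights, dtype=float)
    return PriorityVector(tuple(items), w / w.sum())


@pytest.fixture
def two_criteria():
    """Two equally weighted criteria over three alternatives — the worked
    example whose scores are checked by hand arithmetic below."""
    h = DecisionHierarchy(
        goal="g",
        objectives=(ObjectiveNode("c1"), ObjectiveNode("c2")),
        alternatives=("A", "B", "C"),
    )
    locals_map = {
        "g": pv(["c1", "c2"], [0.5, 0.5]),
        "c1": pv(["A", "B", "C"], [0.7, 0.2, 0.1]),
        "c2": pv(["A", "B", "C"], [0.4, 0.35, 0.25]),
    }
    return h, locals_map


class TestGlobalPriorities:
    def test_equal_split_two_levels(self):
        h = DecisionHierarchy(
            goal="g",
            objectives=(
                ObjectiveNode("t1", (ObjectiveNode("a1"), ObjectiveNode("a2"))),
                ObjectiveNode("t2", (ObjectiveNode("b1"), ObjectiveNode("b2"))),
            ),
            alternatives=("X", "Y"),
        )
        locals_map = {
            "g": pv(["t1", "t2"], [0.5, 0.5]),
            "t1": pv(["a1", "a2"], [0.5, 0.5]),
            "t2": pv(["b1", "b2"], [0.5, 0.5]),
        }
        g = global_objective_priorities(h, locals_map)
        assert g["t1"] == pytest.approx(50.0)
        assert [g[k] for k in ("a1", "a2", "b1", "b2")] == pytest.approx([25.0] * 4)

    def test_single_child_inherits_parent_weight(self):
        h = DecisionHierarchy(
            goal="g",
            objectives=(
                ObjectiveNode("benefits", (ObjectiveNode("hba1c"),)),
                ObjectiveNode("harms"),
            ),
            alternatives=("X", "Y"),
        )
        g = global_objective_priorities(
            h, {"g": pv(["benefits", "harms"], [0.5483, 0.4517])}
        )
        assert g["benefits"] == pytest.approx(54.83)
        assert g["hba1c"] == pytest.approx(54.83)

    def test_children_sum_to_parent_exactly(self, diabetes_hierarchy, diabetes_locals):
        g = global_objective_priorities(diabetes_hierarchy, diabetes_locals)
        for node in [diabetes_hierarchy.find_node("Minimizing harms")] + [
            n for n in diabetes_hierarchy.nodes() if len(n.children) >= 2
        ]:
            child_sum = sum(g[c.name] for c in node.children)
            assert child_sum == pytest.approx(g[node.name], abs=1e-9)
        assert sum(g[o.name] for o in diabetes_hierarchy.objectives) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_missing_group_raises(self, two_criteria):
        h, locals_map = two_criteria
        del locals_map["g"]
        with pytest.raises(AHPError, match="no local priority"):
            global_objective_priorities(h, locals_map)


class TestScoreAlternatives:
    def test_worked_example_distributive(self, two_criteria):
        h, locals_map = two_criteria
        res = score_alternatives(h, locals_map, mode=DISTRIBUTIVE)
        assert res.alternative_scores.weights == pytest.approx(
            [0.55, 0.275, 0.175], abs=1e-12
        )

    def test_worked_example_ideal(self, two_criteria):
        h, locals_map = two_criteria
        res = score_alternatives(h, locals_map, mode=IDEAL)
        # raw: A = 1, B = 0.5*(2/7 + 0.875), C = 0.5*(1/7 + 0.625)
        raw_b = 0.5 * (0.2 / 0.7 + 0.35 / 0.4)
        raw_c = 0.5 * (0.1 / 0.7 + 0.25 / 0.4)
        assert res.raw_scores == pytest.approx([1.0, raw_b, raw_c], abs=1e-12)
        assert res.raw_scores[1:] == pytest.approx([0.5804, 0.3839], abs=5e-5)
        expected = np.array([1.0, raw_b, raw_c])
        assert res.alternative_scores.weights == pytest.approx(
            expected / expected.sum(), abs=1e-12
        )
        assert res.alternative_scores.weights == pytest.approx(
            [0.509, 0.295, 0.195], abs=5e-4
        )

    def test_single_leaf_scores_equal_locals(self):
        h = DecisionHierarchy(
            goal="g", objectives=(ObjectiveNode("only"),), alternatives=("A", "B", "C")
        )
        locals_map = {"only": pv(["A", "B", "C"], [0.5, 0.3, 0.2])}
        for mode in (IDEAL, DISTRIBUTIVE):
            res = score_alternatives(h, locals_map, mode=mode)
            assert res.alternative_scores.weights == pytest.approx(
                [0.5, 0.3, 0.2], abs=1e-12
            )

    def test_dominant_alternative_ranks_first_in_both_modes(self, rng=None):
        rng = np.random.default_rng(17)
        h = DecisionHierarchy(
            goal="g",
            objectives=(ObjectiveNode("c1"), ObjectiveNode("c2"), ObjectiveNode("c3")),
            alternatives=("win", "x", "y"),
        )
        for _ in range(25):
            locals_map = {"g": pv(["c1", "c2", "c3"], rng.dirichlet(np.ones(3)))}
            for leaf in ("c1", "c2", "c3"):
                w = rng.dirichlet(np.ones(3))
                w[0] = w.max() * 1.5  # "win" weakly dominates every leaf
                locals_map[leaf] = pv(["win", "x", "y"], w)
            ranks = {}
            for mode in (IDEAL, DISTRIBUTIVE):
                res = score_alternatives(h, locals_map, mode=mode)
                ranks[mode] = res.rank_of()
                assert ranks[mode]["win"] == 1
            assert ranks[IDEAL] == ranks[DISTRIBUTIVE]

    def test_leaf_vector_must_cover_alternatives(self, two_criteria):
        h, locals_map = two_criteria
        locals_map["c1"] = pv(["A", "B"], [0.6, 0.4])
        with pytest.raises(AHPError, match="alternatives"):
            score_alternatives(h, locals_map)

    def test_conservation_in_synthesis_result(self, diabetes_hierarchy, diabetes_locals):
        rng = np.random.default_rng(42)
        full = dict(diabetes_locals)
        for leaf in diabetes_hierarchy.leaves():
            full[leaf.name] = pv(
                diabetes_hierarchy.alternatives,
                rng.dirichlet(np.ones(len(diabetes_hierarchy.alternatives))),
            )
        res = score_alternatives(diabetes_hierarchy, full, mode=IDEAL)
        g = res.objective_globals
        assert g["Minimizing non-serious harms"] + g["Minimizing serious harms"] == (
            pytest.approx(g["Minimizing harms"], abs=1e-9)
        )
        assert float(res.alternative_scores.weights.sum()) == pytest.approx(1.0, abs=1e-12)


def extend_with_alternative(locals_map, leaves, new_label, raw_by_leaf):
    """Re-normalize each leaf's alternative vector after appending a new
    alternative with the given raw (unnormalized) priority."""
    out = dict(locals_map)
    for leaf in leaves:
        old = locals_map[leaf]
        w = np.append(old.weights, raw_by_leaf[leaf])
        out[leaf] = pv(old.items + (new_label,), w)
    return out


class TestRankReversalBehaviour:
    def make_instance(self, rng, n_alt=3, n_crit=2):
        h = DecisionHierarchy(
            goal="g",
            objectives=tuple(ObjectiveNode(f"c{k}") for k in range(n_crit)),
            alternatives=tuple(f"a{k}" for k in range(n_alt)),
        )
        locals_map = {"g": pv([f"c{k}" for k in range(n_crit)], rng.dirichlet(np.ones(n_crit)))}
        for k in range(n_crit):
            locals_map[f"c{k}"] = pv(
                [f"a{j}" for j in range(n_alt)], rng.dirichlet(np.ones(n_alt))
            )
        return h, locals_map

    def test_ideal_mode_preserves_ranks_under_irrelevant_addition(self):
        """Adding an alternative that is nowhere the leaf maximum must not
        change any pairwise order among the original alternatives."""
        rng = np.random.default_rng(404)
        for _ in range(200):
            h, locals_map = self.make_instance(rng)
            leaves = [n.name for n in h.leaves()]
            before = score_alternatives(h, locals_map, mode=IDEAL)
            raw_new = {
                leaf: float(locals_map[leaf].weights.max() * rng.uniform(0.1, 0.95))
                for leaf in leaves
            }
            h2 = DecisionHierarchy(
                goal=h.goal, objectives=h.objectives,
                alternatives=h.alternatives + ("new",),
            )
            after = score_alternatives(
                h2, extend_with_alternative(locals_map, leaves, "new", raw_new),
                mode=IDEAL,
            )
            r_before = before.rank_of()
            r_after = after.rank_of()
            for a in h.alternatives:
                for b in h.alternatives:
                    assert (r_before[a] < r_before[b]) == (r_after[a] < r_after[b])

    def test_distributive_mode_can_reverse_ranks(self):
        """A constructed instance where adding an alternative flips the
        distributive leader while the ideal leader is unaffected; found by a
        small deterministic grid search."""
        rng = np.random.default_rng(808)
        found = None
        for _ in range(3000):
            h, locals_map = self.make_instance(rng)
            leaves = [n.name for n in h.leaves()]
            before = score_alternatives(h, locals_map, mode=DISTRIBUTIVE)
            raw_new = {
                leaf: float(locals_map[leaf].weights.max() * 0.9) for leaf in leaves
            }
            h2 = DecisionHierarchy(
                goal=h.goal, objectives=h.objectives,
                alternatives=h.alternatives + ("new",),
            )
            ext = extend_with_alternative(locals_map, leaves, "new", raw_new)
            after = score_alternatives(h2, ext, mode=DISTRIBUTIVE)
            rb, ra = before.rank_of(), after.rank_of()
            reversed_pair = any(
                (rb[a] < rb[b]) != (ra[a] < ra[b])
                for a in h.alternatives
                for b in h.alternatives
                if a < b
            )
            if reversed_pair:
                found = (h, h2, locals_map, ext)
                break
        assert found is not None, "no distributive rank reversal found"
        # the same addition under ideal mode leaves original ranks alone
        h, h2, locals_map, ext = found
        ri_before = score_alternatives(h, locals_map, mode=IDEAL).rank_of()
        ri_after = score_alternatives(h2, ext, mode=IDEAL).rank_of()
        for a in h.alternatives:
            for b in h.alternatives:
                assert (ri_before[a] < ri_before[b]) == (ri_after[a] < ri_after[b])


class TestRelativeDifferences:
    def test_published_hypoglycemia_fracture_ratio(self):
        table = relative_differences({"Severe hypoglycemia": 14.01, "Risk of fracture": 2.57})
        assert table.pair_ratio("Severe hypoglycemia", "Risk of fracture") == (
            pytest.approx(5.45, abs=5e-3)
        )
        assert table.is_significant("Severe hypoglycemia", "Risk of fracture")

    def test_benefit_vs_nonserious_ratio(self):
        table = relative_differences({"hba1c": 54.83, "non-serious": 14.79})
        assert table.pair_ratio("hba1c", "non-serious") == pytest.approx(3.71, abs=5e-3)

    def test_equal_scores_not_significant(self):
        table = relative_differences({"x": 10.0, "y": 10.0})
        assert table.pair_ratio("x", "y") == pytest.approx(1.0)
        assert not table.is_significant("x", "y")

    def test_zero_score_rejected(self):
        with pytest.raises(AHPError, match="positive"):
            relative_differences({"x": 1.0, "y": 0.0})

    def test_layout_places_ratio_in_larger_row(self):
        table = relative_differences({"small": 2.0, "big": 6.0})
        i_small, i_big = 0, 1
        assert np.isnan(table.ratios[i_small, i_big])
        assert table.ratios[i_big, i_small] == pytest.approx(3.0)
        assert table.ratios[i_small, i_small] == 1.0

    def test_stored_ratios_at_least_one(self):
        rng = np.random.default_rng(3)
        scores = {f"s{k}": float(v) for k, v in enumerate(rng.uniform(0.1, 5.0, 6))}
        table = relative_differences(scores)
        stored = table.ratios[~np.isnan(table.ratios)]
        assert np.all(stored >= 1.0)

    def test_normalization_invariance(self):
        """Ratios do not change when all scores are rescaled."""
        scores = {"a": 3.0, "b": 1.5, "c": 0.5}
        t1 = relative_differences(scores)
        t2 = relative_differences({k: 7.3 * v for k, v in scores.items()})
        assert np.allclose(t1.ratios, t2.ratios, equal_nan=True)
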