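"""Percent-of-parent to percent-of-root expansion.

The independent oracle here is a naive recursion: a population with an
undefined marker is the sum of its positive and negative refinements, and a
fully defined population is the product of percent-of-parent values down its
quadrant path.  This mirrors the definition directly and never touches the
leaf-table marginalization used by the implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from combogate.compute import (
    GatingTreeValues,
    combo_value,
    compute_all,
    leaf_fractions,
    node_paths,
    path_states,
)
from combogate.core_model import (
    MarkerCombo,
    MarkerState,
    PanelSpec,
    enumerate_combos,
)
from combogate.errors import RangeError, StructureError, ValidationError
from conftest import random_tree

ANY, POS, NEG = MarkerState.ANY, MarkerState.POS, MarkerState.NEG


def recursive_value(tree: GatingTreeValues, panel: PanelSpec,
                    combo: MarkerCombo) -> float:
    """Naive reference: recurse over undefined markers, then chain the
    percent-of-parent product along the fully defined path."""
    for i, s in enumerate(combo.states):
        if s is ANY:
            return recursive_value(tree, panel, combo.with_state(i, POS)) + \
                recursive_value(tree, panel, combo.with_state(i, NEG))
    # fully defined: walk the quadrant path
    value = 100.0
    path = ()
    for level_markers in panel.levels:
        child = 0
        for m in level_markers:
            child = (child << 1) | (1 if combo[m] is NEG else 0)
        path = path + (child,)
        value *= tree[path] / 100.0
    return value


def quadrant_tree(panel4) -> GatingTreeValues:
    """Four-marker tree with quadrant A = M1+M2- at 25% of root and, within
    every first-level quadrant, sub-quadrants at (10, 20, 30, 40)%."""
    tree = GatingTreeValues()
    top = [15.0, 25.0, 35.0, 25.0]  # children: M1+M2+, M1+M2-, M1-M2+, M1-M2-
    for c, v in enumerate(top):
        tree[(c,)] = v
        for c2, v2 in enumerate([10.0, 20.0, 30.0, 40.0]):
            tree[(c, c2)] = v2
    return tree


class TestLeafFractions:
    def test_percent_of_parent_chain(self):
        """A leaf at 10% of a gate that is 25% of root is 2.5% of root."""
        panel = PanelSpec(["M1", "M2"], levels=[[0], [1]])
        tree = GatingTreeValues()
        tree[(0,)] = 25.0
        tree[(1,)] = 75.0
        for c in (0, 1):
            tree[(c, 0)] = 10.0
            tree[(c, 1)] = 90.0
        leaves = leaf_fractions(tree, panel)
        assert leaves[MarkerCombo((POS, POS))] == pytest.approx(2.5)
        assert leaves[MarkerCombo((POS, NEG))] == pytest.approx(22.5)

    def test_single_marker_panel(self, panel1):
        tree = GatingTreeValues({(0,): 60.0, (1,): 40.0})
        leaves = leaf_fractions(tree, panel1)
        assert leaves[MarkerCombo((POS,))] == 60.0
        assert leaves[MarkerCombo((NEG,))] == 40.0

    def test_degenerate_single_quadrant(self, panel4):
        """All events down one path: that leaf is 100, all others 0."""
        tree = GatingTreeValues()
        for c in range(4):
            tree[(c,)] = 100.0 if c == 0 else 0.0
            for c2 in range(4):
                tree[(c, c2)] = 100.0 if c2 == 0 else 0.0
        leaves = leaf_fractions(tree, panel4)
        all_pos = MarkerCombo((POS, POS, POS, POS))
        assert leaves[all_pos] == 100.0
        assert sum(v for k, v in leaves.items() if k != all_pos) == 0.0

    def test_leaf_count_is_two_to_the_m(self, panel4):
        leaves = leaf_fractions(quadrant_tree(panel4), panel4)
        assert len(leaves) == 16
        assert sum(leaves.values()) == pytest.approx(100.0)

    def test_missing_node_names_path(self, panel2):
        tree = GatingTreeValues({(0,): 50.0, (1,): 20.0, (2,): 20.0})
        with pytest.raises(StructureError, match=r"\(3,\)"):
            leaf_fractions(tree, panel2)

    def test_value_out_of_range(self, panel1):
        tree = GatingTreeValues({(0,): 101.0, (1,): -1.0})
        with pytest.raises(RangeError):
            leaf_fractions(tree, panel1)

    def test_sibling_sum_failure_beyond_two_percent(self, panel1):
        tree = GatingTreeValues({(0,): 60.0, (1,): 36.0})
        with pytest.raises(StructureError, match="sum"):
            leaf_fractions(tree, panel1)

    def test_sibling_sum_warning_for_rounding_drift(self, panel1):
        tree = GatingTreeValues({(0,): 60.0, (1,): 39.0})
        with pytest.warns(UserWarning, match="sum"):
            leaves = leaf_fractions(tree, panel1)
        assert leaves[MarkerCombo((POS,))] == 60.0

    def test_missing_children_under_empty_gate_imputed(self):
        """Descendants of a 0% gate may be absent; they count as 0."""
        panel = PanelSpec(["M1", "M2"], levels=[[0], [1]])
        tree = GatingTreeValues(
            {(0,): 0.0, (1,): 100.0, (1, 0): 30.0, (1, 1): 70.0}
        )
        with pytest.warns(UserWarning, match="imputed"):
            leaves = leaf_fractions(tree, panel)
        assert leaves[MarkerCombo((POS, POS))] == 0.0
        assert leaves[MarkerCombo((NEG, POS))] == 30.0


class TestComboValue:
    def test_quadrant_sum_example(self, panel4):
        """M1+ M2- M4+ = (%(A2) + %(A4)) x %(A) / 100 with A = M1+M2-."""
        leaves = leaf_fractions(quadrant_tree(panel4), panel4)
        combo = MarkerCombo((POS, NEG, ANY, POS))
        # A = 25% of root; A2 (M3+M4+) = 10%, A4 (M3-M4+) = 30% of A
        assert combo_value(leaves, combo) == pytest.approx((10 + 30) * 25 / 100)

    def test_fully_defined_is_identity(self, panel4):
        leaves = leaf_fractions(quadrant_tree(panel4), panel4)
        for combo, value in leaves.items():
            assert combo_value(leaves, combo) == value

    def test_two_marker_marginal(self, panel2):
        tree = GatingTreeValues(
            {(0,): 10.0, (1,): 20.0, (2,): 30.0, (3,): 40.0}
        )
        leaves = leaf_fractions(tree, panel2)
        assert combo_value(leaves, MarkerCombo((POS, ANY))) == pytest.approx(30.0)
        assert combo_value(leaves, MarkerCombo((ANY, NEG))) == pytest.approx(60.0)

    def test_length_mismatch_rejected(self, panel4):
        leaves = leaf_fractions(quadrant_tree(panel4), panel4)
        with pytest.raises(ValidationError):
            combo_value(leaves, MarkerCombo((POS, NEG)))


class TestComputeAll:
    @pytest.mark.parametrize("m,expected", [(4, 80), (6, 728)])
    def test_vector_length(self, m, expected, panel4, panel6):
        panel = panel4 if m == 4 else panel6
        vec = compute_all(random_tree(panel, np.random.default_rng(0)), panel)
        assert len(vec) == expected

    def test_uniform_leaves_give_dyadic_values(self, panel4):
        """With all 16 leaves equal, a combo defining m markers covers
        2^(4-m) of 16 leaves, i.e. 100 / 2^m percent."""
        tree = GatingTreeValues()
        for c in range(4):
            tree[(c,)] = 25.0
            for c2 in range(4):
                tree[(c, c2)] = 25.0
        vec = compute_all(tree, panel4)
        for combo, value in vec.items():
            assert value == pytest.approx(100.0 / 2**combo.n_defined)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_matches_naive_recursive_oracle(self, m):
        panel = PanelSpec([f"M{i + 1}" for i in range(m)])
        rng = np.random.default_rng(42 + m)
        for _ in range(3):
            tree = random_tree(panel, rng)
            vec = compute_all(tree, panel)
            for combo in enumerate_combos(panel):
                assert vec[combo] == pytest.approx(
                    recursive_value(tree, panel, combo), abs=1e-9
                )

    def test_order_matches_canonical_enumeration(self, panel4):
        vec = compute_all(random_tree(panel4, np.random.default_rng(1)), panel4)
        assert list(vec) == enumerate_combos(panel4)


@given(seed=st.integers(0, 2**31 - 1), m=st.sampled_from([2, 3, 4, 5]))
def test_marginalization_and_conservation(seed, m):
    """For every combo, value = value(POS at i) + value(NEG at i) for each
    undefined marker i; fully defined values sum to 100; single-marker
    POS/NEG marginals sum to 100; defining more markers never increases a
    value."""
    panel = PanelSpec([f"M{i + 1}" for i in range(m)])
    tree = random_tree(panel, np.random.default_rng(seed))
    vec = compute_all(tree, panel)

    total = sum(v for c, v in vec.items() if c.is_fully_defined)
    assert total == pytest.approx(100.0, abs=1e-6)

    for combo, value in vec.items():
        for i, s in enumerate(combo.states):
            if s is ANY:
                pos = vec[combo.with_state(i, POS)]
                neg = vec[combo.with_state(i, NEG)]
                assert value == pytest.approx(pos + neg, abs=1e-9)
                # refinement is monotone
                assert pos <= value + 1e-12 and neg <= value + 1e-12

    for i in range(m):
        states = [ANY] * m
        states[i] = POS
        pos = vec[MarkerCombo(tuple(states))]
        states[i] = NEG
        neg = vec[MarkerCombo(tuple(states))]
        assert pos + neg == pytest.approx(100.0, abs=1e-6)


def test_path_states_quadrant_encoding(panel4):
    """Child index bits: first level marker in the high bit, 0=POS, 1=NEG."""
    states = path_states((1,), panel4)  # M1+, M2-
    assert states == {0: POS, 1: NEG}
    states = path_states((2, 3), panel4)  # M1-, M2+, M3-, M4-
    assert states == {0: NEG, 1: POS, 2: NEG, 3: NEG}


def test_node_paths_orders_higher_levels_first(panel4):
    paths = list(node_paths(panel4))
    assert paths[:4] == [(0,), (1,), (2,), (3,)]
    assert len(paths) == 4 + 16
    assert all(len(p) == 1 for p in paths[:4])
    assert all(len(p) == 2 for p in paths[4:])
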