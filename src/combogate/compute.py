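"""Expand percent-of-parent gating values to percent-of-root populations.

The gating software exports, for every node of the nested quadrant tree, the
frequency of that gate relative to its parent.  Chaining these down a path
gives the percent-of-root of each of the 2^M fully defined phenotypes (the
leaf table, the panel's resolution limit); every other population is a
marginal of the leaf table, obtained by summing the positive and negative
branch for each marker that is left undefined.  For example, with quadrant A
(= M1+M2-) at 25% of root and, within A, sub-quadrants A2 (M3+M4+) at 10%
and A4 (M3-M4+) at 30% of A, the population M1+ M2- M4+ equals
(10 + 30) x 25 / 100 = 10% of root.

Computing the leaf table once and marginalizing by summation is
algebraically identical to recursing over undefined-marker subtrees (the
percent chain distributes over sums) but touches the tree only once.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

from .core_model import MarkerCombo, MarkerState, PanelSpec, enumerate_combos
from .errors import RangeError, StructureError, ValidationError

__all__ = [
    "GatingTreeValues",
    "LeafTable",
    "PopulationVector",
    "leaf_fractions",
    "combo_value",
    "compute_all",
    "node_paths",
    "path_states",
]

#: Children of a gate should sum to 100% of their parent.  Export rounding
#: typically leaves drift below half a percent: warn there, fail beyond two.
SIBLING_SUM_WARN = 0.5
SIBLING_SUM_FAIL = 2.0

NodePath = Tuple[int, ...]

#: percent-of-root per fully defined combination; exactly 2^M entries.
LeafTable = Dict[MarkerCombo, float]

#: percent-of-root per combination, in canonical enumeration order.
PopulationVector = Dict[MarkerCombo, float]


@dataclass
class GatingTreeValues:
    """One sample's nested gating result.

    ``values`` maps a node path -- one child index per gating level, root
    excluded -- to the node's percent-of-parent.  At a two-marker level the
    child index encodes the quadrant as two bits (first marker's sign in the
    high bit, 0 = positive, 1 = negative); at a one-marker level it is a
    single bit.  The implicit root (the starting population) is 100%.
    """

    values: Dict[NodePath, float] = field(default_factory=dict)

    def __getitem__(self, path: NodePath) -> float:
        return self.values[path]

    def __setitem__(self, path: NodePath, value: float) -> None:
        self.values[tuple(path)] = float(value)

    def __contains__(self, path: NodePath) -> bool:
        return tuple(path) in self.values

    def __len__(self) -> int:
        return len(self.values)


def node_paths(panel: PanelSpec, depth: int | None = None) -> Iterator[NodePath]:
    """All node paths of the panel's tree, level by level, parents first.

    This is the "higher to lower gating level" order of the export tables:
    all level-0 gates, then every child of each level-0 gate, and so on.
    """
    n_levels = panel.n_levels if depth is None else depth
    for level in range(n_levels):
        ranges = [range(panel.n_children(l)) for l in range(level + 1)]
        yield from itertools.product(*ranges)


def path_states(path: NodePath, panel: PanelSpec) -> Dict[int, MarkerState]:
    """Marker states implied by a (possibly partial) node path."""
    states: Dict[int, MarkerState] = {}
    for level, child in enumerate(path):
        markers = panel.levels[level]
        for bit, marker in enumerate(markers):
            sign = (child >> (len(markers) - 1 - bit)) & 1
            states[marker] = MarkerState.NEG if sign else MarkerState.POS
    return states


def _leaf_combo(path: NodePath, panel: PanelSpec) -> MarkerCombo:
    states = path_states(path, panel)
    return MarkerCombo(tuple(states[i] for i in range(panel.n_markers)))


def leaf_fractions(tree: GatingTreeValues, panel: PanelSpec) -> LeafTable:
    """Percent-of-root for each of the 2^M fully defined phenotypes.

    Each leaf's value is ``100 * prod(percent_of_parent / 100)`` along its
    path.  Structural checks: every node must be present (descendants of a
    0% gate may be absent and are imputed as 0 with a warning, since empty
    gates export inconsistently), every value must lie in [0, 100], and
    each sibling group must sum to 100 within tolerance.  Inputs are never
    renormalized; drift surfaces in the conservation check downstream.
    """
    # percent-of-root at each node, computed level by level
    root_frac: Dict[NodePath, float] = {(): 100.0}
    for path in node_paths(panel):
        parent = path[:-1]
        parent_frac = root_frac[parent]
        if path not in tree:
            if parent_frac == 0.0:
                warnings.warn(
                    f"node {path} missing under an empty (0%) parent gate; "
                    "imputed as 0",
                    stacklevel=2,
                )
                value = 0.0
            else:
                raise StructureError(
                    f"gating tree is missing node {path} "
                    f"(level {len(path) - 1}, child {path[-1]})"
                )
        else:
            value = tree[path]
        if not math.isfinite(value) or not 0.0 <= value <= 100.0:
            raise RangeError(
                f"percent-of-parent at node {path} is {value!r}, "
                "outside [0, 100]"
            )
        root_frac[path] = parent_frac * value / 100.0

    _check_sibling_sums(tree, panel, root_frac)

    leaves: LeafTable = {}
    depth = panel.n_levels
    for path, frac in root_frac.items():
        if len(path) == depth:
            leaves[_leaf_combo(path, panel)] = frac
    return leaves


def _check_sibling_sums(
    tree: GatingTreeValues,
    panel: PanelSpec,
    root_frac: Mapping[NodePath, float],
) -> None:
    parents: Iterator[NodePath] = itertools.chain(
        [()], node_paths(panel, depth=panel.n_levels - 1)
    )
    for parent in parents:
        if root_frac[parent] == 0.0 and parent != ():
            continue  # children of an empty gate contribute nothing
        level = len(parent)
        total = sum(
            tree[parent + (c,)]
            for c in range(panel.n_children(level))
            if parent + (c,) in tree
        )
        drift = abs(total - 100.0)
        if drift > SIBLING_SUM_FAIL:
            raise StructureError(
                f"children of node {parent or 'root'} sum to {total:.4f}%, "
                f"more than {SIBLING_SUM_FAIL}% away from 100%"
            )
        if drift > SIBLING_SUM_WARN:
            warnings.warn(
                f"children of node {parent or 'root'} sum to {total:.4f}% "
                "(rounded export?)",
                stacklevel=3,
            )


def combo_value(leaves: LeafTable, combo: MarkerCombo) -> float:
    """Percent-of-root of one combination, by marginalizing the leaf table.

    Sums the leaf values of every fully defined phenotype that agrees with
    ``combo`` on each defined marker; undefined (ANY) markers range over
    both signs.
    """
    m = len(next(iter(leaves)))
    if len(combo) != m:
        raise ValidationError(
            f"combination has {len(combo)} states but leaves have {m} markers"
        )
    choices = [
        (s,) if s is not MarkerState.ANY else (MarkerState.POS, MarkerState.NEG)
        for s in combo.states
    ]
    return sum(
        leaves[MarkerCombo(states)] for states in itertools.product(*choices)
    )


def _leaf_array(leaves: LeafTable, m: int) -> np.ndarray:
    """Leaf table as an (2,)*M tensor, axis index 0=POS, 1=NEG."""
    arr = np.empty((2,) * m)
    for combo, value in leaves.items():
        idx = tuple(0 if s is MarkerState.POS else 1 for s in combo.states)
        arr[idx] = value
    return arr


def compute_all(tree: GatingTreeValues, panel: PanelSpec) -> PopulationVector:
    """Percent-of-root for every one of the 3^M - 1 populations.

    Builds the leaf tensor once, then expands each marker axis from
    (POS, NEG) to (ANY, POS, NEG) where the ANY slice is the sum of the
    other two.  Flattening the resulting (3,)*M tensor in C order yields
    exactly the canonical enumeration order.
    """
    m = panel.n_markers
    leaves = leaf_fractions(tree, panel)
    t = _leaf_array(leaves, m)
    for axis in range(m):
        pos = t.take(0, axis=axis)
        neg = t.take(1, axis=axis)
        t = np.stack([pos + neg, pos, neg], axis=axis)
    flat = t.reshape(-1)[1:]  # drop the all-ANY entry
    combos = enumerate_combos(panel)
    return {c: float(v) for c, v in zip(combos, flat)}
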