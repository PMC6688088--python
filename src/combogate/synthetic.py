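"""Synthetic cytometry events: simulation, gating, and the counting oracle.

Real inputs to the pipeline are percent-of-parent frequencies produced by
thresholded (FMO-guided) gating, so events here carry binary marker states
rather than fluorescence intensities -- one row per cell, one 0/1 column per
marker.  Events are drawn multinomially from a probability vector over the
2^M fully defined phenotypes; gating them through the panel's nested
quadrant tree reproduces exactly what analysis software would export.

:func:`direct_fraction` counts events for any marker combination straight
from the event matrix.  Comparing it against the percent-of-parent expansion
pipeline automates the verification of computed population values against
direct gating: the two routes must agree for every combination.

Cohorts for clustering tests are built by perturbing group centroid
probability vectors with a Dirichlet draw (alpha = concentration * centroid),
which keeps samples on the simplex with a single dispersion knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .compute import GatingTreeValues, compute_all, node_paths, path_states
from .core_model import (
    MarkerCombo,
    MarkerState,
    PanelSpec,
    combo_name,
    enumerate_combos,
)
from .errors import ValidationError
from .io_tables import ColumnSchema, Dialect, SampleRecord, write_input_table

__all__ = [
    "EventMatrix",
    "GroupSpec",
    "CohortSpec",
    "phenotype_index",
    "simulate_sample",
    "gate_events",
    "direct_fraction",
    "simulate_cohort",
    "two_group_cohort_spec",
    "verify_pipeline",
    "VerificationReport",
]

#: n_events x M matrix of binary marker states, 1 = positive.
EventMatrix = np.ndarray

#: Floor applied to centroid entries before the Dirichlet draw, so that
#: structurally absent phenotypes do not produce zero concentration.
CENTROID_FLOOR = 1e-9


def phenotype_index(events: EventMatrix) -> np.ndarray:
    """Leaf index of each event: marker 0 is the most significant bit,
    bit value 0 = positive, 1 = negative (phenotype 0 = all-positive)."""
    n, m = events.shape
    weights = 1 << np.arange(m - 1, -1, -1)
    return (1 - events.astype(np.int64)) @ weights


def simulate_sample(
    leaf_probs: Sequence[float], n_events: int, seed
) -> EventMatrix:
    """Draw ``n_events`` binary-state events from phenotype probabilities.

    ``leaf_probs`` has length 2^M, indexed as in :func:`phenotype_index`.
    ``seed`` is anything :func:`numpy.random.default_rng` accepts, including
    a ``Generator`` for use inside larger seeded pipelines.
    """
    probs = np.asarray(leaf_probs, dtype=float)
    if probs.ndim != 1 or len(probs) < 2 or len(probs) & (len(probs) - 1):
        raise ValidationError(
            f"leaf probabilities must have length 2^M >= 2, got {probs.shape}"
        )
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            "leaf probabilities must be non-negative and sum to 1 "
            f"(sum = {probs.sum()!r})"
        )
    if n_events < 1:
        raise ValidationError(f"n_events must be >= 1, got {n_events}")
    m = int(np.log2(len(probs)))
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, probs / probs.sum())
    idx = np.repeat(np.arange(len(probs)), counts)
    bits = (idx[:, None] >> np.arange(m - 1, -1, -1)) & 1
    return (1 - bits).astype(np.int8)


def _match_mask(
    events: EventMatrix, states: dict[int, MarkerState]
) -> np.ndarray:
    mask = np.ones(len(events), dtype=bool)
    for marker, state in states.items():
        want = 1 if state is MarkerState.POS else 0
        mask &= events[:, marker] == want
    return mask


def gate_events(events: EventMatrix, panel: PanelSpec) -> GatingTreeValues:
    """Nested-count the events into percent-of-parent tree values.

    Each node's value is 100 x (events matching its full gate path) /
    (events matching its parent's path); children of an empty (0-event)
    parent are reported as 0.
    """
    events = np.asarray(events)
    if events.ndim != 2 or events.shape[1] != panel.n_markers:
        raise ValidationError(
            f"event matrix shape {events.shape} does not match "
            f"{panel.n_markers}-marker panel"
        )
    if len(events) == 0:
        raise ValidationError("event matrix is empty")

    counts: dict[tuple, int] = {(): len(events)}
    tree = GatingTreeValues()
    for path in node_paths(panel):
        n = int(_match_mask(events, path_states(path, panel)).sum())
        counts[path] = n
        parent_n = counts[path[:-1]]
        tree[path] = 100.0 * n / parent_n if parent_n else 0.0
    return tree


def direct_fraction(events: EventMatrix, combo: MarkerCombo) -> float:
    """Percent of all events agreeing with ``combo`` on its defined markers.

    The programmatic analog of gating the population directly, used as the
    brute-force oracle for the percent-of-parent expansion.
    """
    events = np.asarray(events)
    if len(combo) != events.shape[1]:
        raise ValidationError(
            f"combination has {len(combo)} states for "
            f"{events.shape[1]}-marker events"
        )
    states = {
        i: s for i, s in enumerate(combo.states) if s is not MarkerState.ANY
    }
    return 100.0 * _match_mask(events, states).sum() / len(events)


@dataclass
class GroupSpec:
    """One cohort group: its centroid on the phenotype simplex, how tightly
    samples concentrate around it, and how many samples to draw."""

    label: str
    centroid: np.ndarray | None  # length 2^M; None -> random from the rng
    concentration: float
    n_samples: int

    def validate(self, n_leaves: int) -> None:
        if self.n_samples < 1:
            raise ValidationError(
                f"group {self.label!r}: n_samples must be >= 1"
            )
        if self.concentration <= 0:
            raise ValidationError(
                f"group {self.label!r}: concentration must be positive"
            )
        if self.centroid is not None:
            c = np.asarray(self.centroid, dtype=float)
            if c.shape != (n_leaves,):
                raise ValidationError(
                    f"group {self.label!r}: centroid length {c.shape} "
                    f"!= 2^M = {n_leaves}"
                )
            if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"group {self.label!r}: centroid must be a probability "
                    "vector"
                )


@dataclass
class CohortSpec:
    """A labeled multi-sample cohort: groups, events per sample, seed."""

    panel: PanelSpec
    groups: List[GroupSpec]
    n_events: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValidationError("cohort needs at least one group")
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate group labels: {labels}")
        n_leaves = 2**self.panel.n_markers
        for g in self.groups:
            g.validate(n_leaves)


def simulate_cohort(
    spec: CohortSpec, dialect: Dialect = Dialect.POINT,
    schema: ColumnSchema | None = None,
) -> Tuple[List[SampleRecord], str]:
    """Simulate, gate, and serialize a labeled cohort.

    Per sample, a leaf-probability vector is drawn from
    ``Dirichlet(concentration * centroid)`` around its group centroid,
    events are simulated and gated, and the gating trees are serialized to
    input-table CSV text.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_leaves = 2**spec.panel.n_markers

    records: List[SampleRecord] = []
    for group in spec.groups:
        if group.centroid is None:
            centroid = rng.dirichlet(np.ones(n_leaves))
        else:
            centroid = np.asarray(group.centroid, dtype=float)
        alpha = group.concentration * np.clip(centroid, CENTROID_FLOOR, None)
        for i in range(group.n_samples):
            probs = rng.dirichlet(alpha)
            events = simulate_sample(probs, spec.n_events, rng)
            tree = gate_events(events, spec.panel)
            records.append(
                SampleRecord(f"{group.label}_{i + 1}", tree, group.label)
            )
    csv_text = write_input_table(records, spec.panel, dialect, schema)
    return records, csv_text


def two_group_cohort_spec(
    panel: PanelSpec | None = None,
    seed: int = 0,
    n_samples: int = 10,
    concentration: float = 300.0,
    n_events: int = 20_000,
) -> CohortSpec:
    """A well-separated two-group cohort for clustering checks.

    The groups sit on opposing linear gradients over the phenotype simplex
    (group A's centroid weights phenotype i proportionally to i+1, group B
    the reverse), so every marker's marginal differs between groups while
    no single population separates them on its own.  The default panel is
    four markers gated as two quadrant levels.
    """
    if panel is None:
        panel = PanelSpec(["M1", "M2", "M3", "M4"])
    n_leaves = 2**panel.n_markers
    a = np.arange(1, n_leaves + 1, dtype=float)
    a /= a.sum()
    b = a[::-1].copy()
    return CohortSpec(
        panel=panel,
        groups=[
            GroupSpec("A", a, concentration, n_samples),
            GroupSpec("B", b, concentration, n_samples),
        ],
        n_events=n_events,
        seed=seed,
    )


@dataclass
class VerificationReport:
    """Outcome of the computed-vs-counted agreement check."""

    n_trials: int
    n_combos_checked: int
    max_relative_deviation: float
    worst_combo: str
    passed: bool


def verify_pipeline(
    marker_counts: Sequence[int] = (2, 3, 4, 6),
    trials_per_panel: int = 25,
    n_events: int = 10_000,
    seed: int = 0,
    rtol: float = 1e-9,
    inject_fault: bool = False,
) -> VerificationReport:
    """Check the expansion pipeline against direct event counting.

    For each trial: draw a random phenotype-probability vector, simulate
    events, gate them into percent-of-parent values, expand those through
    :func:`combogate.compute.compute_all`, and compare every one of the
    3^M - 1 population values with the fraction counted straight from the
    events.  The two routes must agree to ``rtol`` relative (absolute where
    the counted value is 0).

    ``inject_fault`` corrupts one gating value per trial so the check's
    sensitivity can itself be tested.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_combo = ""
    n_checked = 0
    n_trials = 0
    passed = True
    for m in marker_counts:
        panel = PanelSpec([f"M{i + 1}" for i in range(m)])
        combos = enumerate_combos(panel)
        for _ in range(trials_per_panel):
            n_trials += 1
            probs = rng.dirichlet(np.ones(2**m))
            events = simulate_sample(probs, n_events, rng)
            tree = gate_events(events, panel)
            if inject_fault:
                path = next(iter(tree.values))
                tree[path] = min(100.0, tree[path] * 1.01 + 0.1)
            computed = compute_all(tree, panel)
            for combo in combos:
                counted = direct_fraction(events, combo)
                dev = abs(computed[combo] - counted)
                rel = dev / counted if counted else dev
                n_checked += 1
                if rel > worst:
                    worst = rel
                    worst_combo = combo_name(combo, panel)
                if rel > rtol:
                    passed = False
    return VerificationReport(
        n_trials=n_trials,
        n_combos_checked=n_checked,
        max_relative_deviation=worst,
        worst_combo=worst_combo,
        passed=passed,
    )
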