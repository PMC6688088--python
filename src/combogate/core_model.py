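"""Panel model and enumeration of combinatorial marker phenotypes.

A panel of ``M`` binary markers defines ``3^M - 1`` informative cell
populations: each marker is taken as positive, negative, or left out of the
definition ("any"), and the assignment where every marker is left out is
excluded.  Equivalently, summing over the number ``m`` of defined markers,

    sum_{m=1..M} C(M, m) * 2^m  =  3^M - 1.

Markers are grouped into ordered *gating levels* of one or two markers each.
A two-marker level splits its parent population into four quadrants, a
one-marker level into two halves; the level order is the nesting order of
the gating tree.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import PanelError, ValidationError

__all__ = [
    "Marker",
    "MarkerState",
    "MarkerCombo",
    "PanelSpec",
    "count_populations",
    "enumerate_combos",
    "combo_name",
]

#: Above this many markers the full enumeration (3^M - 1 columns) becomes
#: unwieldy for downstream tables; we warn but do not refuse.
SOFT_MARKER_LIMIT = 12


class MarkerState(enum.IntEnum):
    """Per-marker state in a population definition.

    ``ANY`` means the marker is not taken into account.  The integer values
    (ANY=0, POS=1, NEG=2) define the canonical mixed-radix base-3
    enumeration order, with marker 0 as the most significant digit.
    """

    ANY = 0
    POS = 1
    NEG = 2


_SIGN = {MarkerState.POS: "+", MarkerState.NEG: "-"}


@dataclass(frozen=True)
class Marker:
    """A single panel marker with its 0-based panel position."""

    name: str
    index: int


@dataclass(frozen=True)
class MarkerCombo:
    """One population definition: a state per marker, at least one defined.

    The all-ANY assignment describes no population and is rejected; it is
    the "-1" in the 3^M - 1 count.
    """

    states: tuple[MarkerState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("a combination needs at least one marker")
        if all(s is MarkerState.ANY for s in self.states):
            raise ValidationError(
                "the all-ANY combination defines no population and is excluded"
            )
        object.__setattr__(
            self, "states", tuple(MarkerState(s) for s in self.states)
        )

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> MarkerState:
        return self.states[i]

    @property
    def n_defined(self) -> int:
        return sum(s is not MarkerState.ANY for s in self.states)

    @property
    def is_fully_defined(self) -> bool:
        return self.n_defined == len(self.states)

    def with_state(self, index: int, state: MarkerState) -> "MarkerCombo":
        states = list(self.states)
        states[index] = state
        return MarkerCombo(tuple(states))


class PanelSpec:
    """Ordered markers plus their grouping into gating levels.

    Parameters
    ----------
    markers:
        Marker names in panel order (must be unique).
    levels:
        Ordered gating levels; each level holds one or two marker indices
        (or names).  Every marker appears in exactly one level.  If omitted,
        markers are paired in panel order (with a trailing singleton when M
        is odd).
    """

    def __init__(
        self,
        markers: Sequence[str],
        levels: Sequence[Sequence[int | str]] | None = None,
    ) -> None:
        names = list(markers)
        if not names:
            raise PanelError("panel must contain at least one marker")
        if len(set(names)) != len(names):
            raise PanelError(f"marker names are not unique: {names}")
        self.markers: tuple[Marker, ...] = tuple(
            Marker(name, i) for i, name in enumerate(names)
        )
        by_name = {m.name: m.index for m in self.markers}

        if levels is None:
            idx = list(range(len(names)))
            levels = [tuple(idx[i : i + 2]) for i in range(0, len(idx), 2)]
        resolved: list[tuple[int, ...]] = []
        for lvl in levels:
            ids = tuple(
                by_name[x] if isinstance(x, str) else int(x) for x in lvl
            )
            if len(ids) not in (1, 2):
                raise PanelError(
                    f"gating level {lvl!r} must hold 1 or 2 markers"
                )
            for i in ids:
                if not 0 <= i < len(names):
                    raise PanelError(f"marker index {i} out of range")
            resolved.append(ids)
        flat = [i for lvl in resolved for i in lvl]
        if sorted(flat) != list(range(len(names))):
            raise PanelError(
                "every marker must appear in exactly one gating level; "
                f"got level assignment {resolved} for {len(names)} markers"
            )
        self.levels: tuple[tuple[int, ...], ...] = tuple(resolved)

        if self.n_markers > SOFT_MARKER_LIMIT:
            warnings.warn(
                f"panel has {self.n_markers} markers -> "
                f"{count_populations(self.n_markers)} populations; output "
                "tables will be very wide",
                stacklevel=2,
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def n_children(self, level: int) -> int:
        """Number of child gates a node at ``level`` splits into (2 or 4)."""
        return 2 ** len(self.levels[level])

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PanelSpec)
            and self.marker_names == other.marker_names
            and self.levels == other.levels
        )

    def __repr__(self) -> str:
        return (
            f"PanelSpec(markers={list(self.marker_names)!r}, "
            f"levels={[list(l) for l in self.levels]!r})"
        )

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelSpec":
        try:
            markers = d["markers"]
        except (KeyError, TypeError):
            raise PanelError("panel file must define a 'markers' list")
        return cls(markers, d.get("levels"))

    @classmethod
    def from_file(cls, path) -> "PanelSpec":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                data = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise PanelError(f"cannot parse panel file {path}: {exc}")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "markers": list(self.marker_names),
            "levels": [list(l) for l in self.levels],
        }


def count_populations(nm: int) -> int:
    """Number of informative populations definable by ``nm`` markers.

    Each marker contributes one of three states (positive, negative, not
    considered), and the assignment with no marker considered is excluded,
    giving ``3**nm - 1`` exactly (integer arithmetic).
    """
    if isinstance(nm, bool) or not isinstance(nm, (int,)):
        raise ValidationError(f"marker count must be an integer, got {nm!r}")
    if nm < 1:
        raise ValidationError(f"marker count must be >= 1, got {nm}")
    return 3**nm - 1


def enumerate_combos(panel: PanelSpec) -> list[MarkerCombo]:
    """All 3^M - 1 informative combinations, in canonical order.

    The order is mixed-radix base 3 over the state vector with ANY=0,
    POS=1, NEG=2 and marker 0 as the most significant digit; the leading
    all-ANY vector is skipped.  The order is deterministic, so output
    columns are byte-stable across runs.
    """
    m = panel.n_markers
    it = itertools.product(
        (MarkerState.ANY, MarkerState.POS, MarkerState.NEG), repeat=m
    )
    next(it)  # all-ANY
    return [MarkerCombo(states) for states in it]


def combo_name(combo: MarkerCombo, panel: PanelSpec) -> str:
    """Compact label: ``<marker><sign>`` for each defined marker, in panel
    order; ANY markers omitted.  ASCII ``+``/``-`` signs.  Injective over
    the combinations of one panel."""
    if len(combo) != panel.n_markers:
        raise ValidationError(
            f"combination has {len(combo)} states for a "
            f"{panel.n_markers}-marker panel"
        )
    return "".join(
        f"{marker.name}{_SIGN[s]}"
        for marker, s in zip(panel.markers, combo.states)
        if s is not MarkerState.ANY
    )
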