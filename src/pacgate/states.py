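"""State enumeration for the proton-activated chloride (PAC) channel.

The channel carries three ligand sites: site 0 binds protons, while sites 1
and 2 bind the small-molecule modulator (activation and open-channel-block
sites, respectively).  Together with the pore (closed/open) this yields
8 occupancy permutations x 2 pore states = 16 candidate states.  Four
experimentally derived gating constraints reduce these to 8 achievable
states, canonically labelled C0-C5 (closed) and O1, O2 (open).

States are ordered deterministically: by the binary occupancy code
(site0, site1, site2), closed before open, so serialized state spaces are
diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable

import networkx as nx

__all__ = [
    "Pore",
    "SiteId",
    "BindingSite",
    "OccupancyPattern",
    "ChannelState",
    "GatingConstraint",
    "StateSpace",
    "BINDING_SITES",
    "CANONICAL_CONSTRAINTS",
    "CANONICAL_LABELS",
    "enumerate_candidate_states",
    "apply_constraints",
    "build_transition_graph",
    "EDGE_CLASSES",
]


class Pore(str, Enum):
    CLOSED = "closed"
    OPEN = "open"


class SiteId(str, Enum):
    SITE0 = "site0"
    SITE1 = "site1"
    SITE2 = "site2"


@dataclass(frozen=True)
class BindingSite:
    """One ligand site: which ligand it carries and when it is accessible."""

    site_id: SiteId
    ligand: str  # "proton" or "modulator"
    access_rule: str  # "any_state" or "open_state_only"

    def __post_init__(self) -> None:
        if self.ligand not in ("proton", "modulator"):
            raise ValueError(f"unknown ligand {self.ligand!r}")
        if self.access_rule not in ("any_state", "open_state_only"):
            raise ValueError(f"unknown access rule {self.access_rule!r}")


#: Site 0 carries the proton; sites 1 and 2 carry the modulator; only the
#: inhibition site 2 is gated behind the open pore.
BINDING_SITES: tuple[BindingSite, ...] = (
    BindingSite(SiteId.SITE0, "proton", "any_state"),
    BindingSite(SiteId.SITE1, "modulator", "any_state"),
    BindingSite(SiteId.SITE2, "modulator", "open_state_only"),
)


@dataclass(frozen=True, order=True)
class OccupancyPattern:
    """Ordered occupancy triple (site0, site1, site2)."""

    site0: bool
    site1: bool
    site2: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.site0, self.site1, self.site2)

    @property
    def code(self) -> int:
        """Binary code with site0 as the most significant bit."""
        return (self.site0 << 2) | (self.site1 << 1) | int(self.site2)

    @staticmethod
    def all_patterns() -> list["OccupancyPattern"]:
        return [
            OccupancyPattern(bool(c & 4), bool(c & 2), bool(c & 1))
            for c in range(8)
        ]


@dataclass(frozen=True)
class ChannelState:
    occupancy: OccupancyPattern
    pore: Pore
    label: str | None = None

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.occupancy.code, 0 if self.pore is Pore.CLOSED else 1)

    def relabeled(self, label: str | None) -> "ChannelState":
        return ChannelState(self.occupancy, self.pore, label)

    def differs_by(self, other: "ChannelState") -> dict[str, bool]:
        """Which elementary coordinates differ between two states."""
        a, b = self.occupancy, other.occupancy
        return {
            "site0": a.site0 != b.site0,
            "site1": a.site1 != b.site1,
            "site2": a.site2 != b.site2,
            "pore": self.pore != other.pore,
        }


@dataclass(frozen=True)
class GatingConstraint:
    """A pure predicate on a single state; True means the state is forbidden."""

    constraint_id: str
    description: str
    forbids: Callable[[ChannelState], bool] = field(compare=False)

    def __call__(self, state: ChannelState) -> bool:
        return self.forbids(state)


#: The four gating constraints deduced from the block/activation experiments:
#: (i)   modulator on site 1 alone cannot drive opening;
#: (ii)  site 2 occupancy requires the open (hence proton-bound) channel,
#:       so site 2 occupied implies site 0 occupied;
#: (iii) a site-2-bound channel is trapped closed (open-channel block);
#: (iv)  the pore does not open without a proton on site 0.
CANONICAL_CONSTRAINTS: tuple[GatingConstraint, ...] = (
    GatingConstraint(
        "i",
        "site 1 occupied alone (sites 0 and 2 empty) cannot be open",
        lambda s: (
            s.pore is Pore.OPEN
            and s.occupancy.site1
            and not s.occupancy.site0
            and not s.occupancy.site2
        ),
    ),
    GatingConstraint(
        "ii",
        "site 2 occupied requires site 0 occupied",
        lambda s: s.occupancy.site2 and not s.occupancy.site0,
    ),
    GatingConstraint(
        "iii",
        "site 2 occupied traps the pore closed",
        lambda s: s.occupancy.site2 and s.pore is Pore.OPEN,
    ),
    GatingConstraint(
        "iv",
        "an open pore requires site 0 occupied",
        lambda s: s.pore is Pore.OPEN and not s.occupancy.site0,
    ),
)

#: Canonical label of each achievable (occupancy, pore) combination.
CANONICAL_LABELS: dict[tuple[tuple[bool, bool, bool], str], str] = {
    ((False, False, False), "closed"): "C0",
    ((True, False, False), "closed"): "C1",
    ((False, True, False), "closed"): "C2",
    ((True, True, False), "closed"): "C3",
    ((True, False, False), "open"): "O1",
    ((True, True, False), "open"): "O2",
    ((True, False, True), "closed"): "C4",
    ((True, True, True), "closed"): "C5",
}

#: Edge class of each allowed elementary transition, keyed by unordered
#: label pair.  "site2" events are pore-coupled (open-channel block): binding
#: closes the pore, unbinding re-opens it, as one elementary event.
EDGE_CLASSES: dict[frozenset[str], str] = {
    frozenset({"C0", "C1"}): "proton",
    frozenset({"C2", "C3"}): "proton",
    frozenset({"C0", "C2"}): "site1",
    frozenset({"C1", "C3"}): "site1",
    frozenset({"O1", "O2"}): "site1",
    frozenset({"C4", "C5"}): "site1",
    frozenset({"C1", "O1"}): "pore",
    frozenset({"C3", "O2"}): "pore",
    frozenset({"O1", "C4"}): "site2",
    frozenset({"O2", "C5"}): "site2",
}


@dataclass
class StateSpace:
    states: list[ChannelState]
    edges: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = sorted(self.states, key=lambda s: s.sort_key)

    def labels(self) -> list[str]:
        return [s.label for s in self.states if s.label is not None]

    def by_label(self, label: str) -> ChannelState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def occupancy_patterns(self) -> set[OccupancyPattern]:
        return {s.occupancy for s in self.states}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels())
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    # -- JSON round-trip -------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "states": [
                {
                    "occupancy": list(s.occupancy.as_tuple()),
                    "pore": s.pore.value,
                    "label": s.label,
                }
                for s in self.states
            ],
            "edges": sorted(sorted(e) for e in self.edges),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StateSpace":
        payload = json.loads(text)
        states = [
            ChannelState(
                OccupancyPattern(*map(bool, item["occupancy"])),
                Pore(item["pore"]),
                item.get("label"),
            )
            for item in payload["states"]
        ]
        edges = [frozenset(e) for e in payload.get("edges", [])]
        return cls(states, edges)


def enumerate_candidate_states() -> StateSpace:
    """All 16 candidate states: 8 occupancy permutations x 2 pore states."""
    states = [
        ChannelState(pattern, pore)
        for pattern in OccupancyPattern.all_patterns()
        for pore in (Pore.CLOSED, Pore.OPEN)
    ]
    return StateSpace(states)


def apply_constraints(
    space: StateSpace,
    constraints: Iterable[GatingConstraint] = CANONICAL_CONSTRAINTS,
) -> StateSpace:
    """Filter the candidate space and label the surviving states.

    With the four canonical constraints this yields exactly the 8 achievable
    states C0-C5, O1, O2.  An empty constraint list retains all 16 states
    (unlabelled states keep ``label=None``).
    """
    if len(space.states) != 16 or len(space.occupancy_patterns()) != 8:
        raise ValueError("input must be the full 16-state candidate space")
    constraints = list(constraints)
    for c in constraints:
        if not isinstance(c, GatingConstraint):
            raise TypeError(f"not a GatingConstraint: {c!r}")
    kept = [
        s for s in space.states if not any(c(s) for c in constraints)
    ]
    labelled = [
        s.relabeled(
            CANONICAL_LABELS.get((s.occupancy.as_tuple(), s.pore.value))
        )
        for s in kept
    ]
    return StateSpace(labelled)


def _is_single_event(a: ChannelState, b: ChannelState) -> bool:
    d = a.differs_by(b)
    n_sites = d["site0"] + d["site1"] + d["site2"]
    if d["site2"]:
        # open-channel block: site-2 toggle and pore toggle are one event
        return n_sites == 1 and d["pore"]
    return (n_sites + d["pore"]) == 1


def build_transition_graph(space: StateSpace) -> StateSpace:
    """Add all single-elementary-event edges between achievable states.

    Elementary events: one proton or site-1 binding/unbinding, one pore
    opening/closure, or one pore-coupled site-2 block/unblock event.  All
    edges are reversible; partial reversibility of inhibition is a rate
    property handled by the kinetics module, not a topology property.
    """
    labels = space.labels()
    if sorted(labels) != sorted(CANONICAL_LABELS.values()):
        raise ValueError("input must be the labelled 8-state achievable space")
    edges: list[frozenset[str]] = []
    for i, a in enumerate(space.states):
        for b in space.states[i + 1:]:
            if _is_single_event(a, b):
                edges.append(frozenset({a.label, b.label}))
    for e in edges:
        if e not in EDGE_CLASSES:
            raise AssertionError(f"unclassified edge {sorted(e)}")
    return StateSpace(list(space.states), edges)
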