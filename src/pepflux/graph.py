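"""The cleavage graph: peptides, proteolytic events, pruning, ordering.

The degradation network is a bipartite digraph.  *Peptide nodes* are
sequences (every subsequence reachable by cleavage, keyed by sequence —
identical fragments from different lineages share one node).  *Event
nodes* represent one proteolytic event each: a peptidase cutting a
specific substrate at a specific bond, consuming one substrate particle
and producing one prefix and one suffix particle.  Each event carries the
affinity coefficient rho of its site for its peptidase.

Because both products of an event are strictly shorter than the
substrate, the peptide-node projection is a DAG and sorting nodes by
descending length (lexicographic within a length) is a topological order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .profiles import FrequencyMatrix, detect_cleavages


@dataclass
class PeptideNode:
    sequence: str
    is_precursor: bool = False
    #: observed LC-MS amount; ``None`` means the node is empty.
    y: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide node needs a non-empty sequence")
        if self.y is not None and self.y < 0:
            raise ValueError("observed amount must be non-negative")

    @property
    def observed(self) -> bool:
        return self.y is not None and self.y > 0


@dataclass(frozen=True)
class EventNode:
    substrate: str
    prefix: str
    suffix: str
    peptidase_id: str
    rho: float

    def __post_init__(self) -> None:
        if not self.prefix or not self.suffix:
            raise ValueError("cleavage products must be non-empty")
        if self.prefix + self.suffix != self.substrate:
            raise ValueError("prefix+suffix must concatenate to the substrate")
        if self.rho < 0:
            raise ValueError("affinity coefficient must be non-negative")


def _node_sort_key(sequence: str) -> tuple[int, str]:
    # descending length then lexicographic: a valid topological key because
    # every event's products are strictly shorter than its substrate
    return (-len(sequence), sequence)


class CleavageGraph:
    """Bipartite digraph of peptide nodes and proteolytic events."""

    def __init__(self) -> None:
        self.nodes: dict[str, PeptideNode] = {}
        self.events: list[EventNode] = []

    # -- construction -------------------------------------------------

    def add_node(self, sequence: str, *, is_precursor: bool = False,
                 y: float | None = None) -> PeptideNode:
        node = self.nodes.get(sequence)
        if node is None:
            node = PeptideNode(sequence, is_precursor=is_precursor, y=y)
            self.nodes[sequence] = node
        else:
            node.is_precursor = node.is_precursor or is_precursor
            if y is not None:
                node.y = y
        return node

    def add_event(self, event: EventNode) -> None:
        for seq in (event.substrate, event.prefix, event.suffix):
            self.add_node(seq)
        self.events.append(event)

    # -- structure ----------------------------------------------------

    def out_events(self, sequence: str) -> list[EventNode]:
        return [e for e in self.events if e.substrate == sequence]

    def in_events(self, sequence: str) -> list[EventNode]:
        return [e for e in self.events if sequence in (e.prefix, e.suffix)]

    def sources(self) -> set[str]:
        """Peptide nodes that are never produced by an event."""
        produced = {s for e in self.events for s in (e.prefix, e.suffix)}
        return set(self.nodes) - produced

    def leaves(self) -> set[str]:
        """Peptide nodes that are never cleaved."""
        cleaved = {e.substrate for e in self.events}
        return set(self.nodes) - cleaved

    def peptidases(self) -> set[str]:
        return {e.peptidase_id for e in self.events}

    def observed(self) -> dict[str, float]:
        """The observed set O: nodes with a strictly positive amount."""
        return {s: n.y for s, n in self.nodes.items() if n.observed}

    def copy(self) -> "CleavageGraph":
        g = CleavageGraph()
        for n in self.nodes.values():
            g.add_node(n.sequence, is_precursor=n.is_precursor, y=n.y)
        g.events = list(self.events)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CleavageGraph):
            return NotImplemented
        mine = {(n.sequence, n.is_precursor, n.y) for n in self.nodes.values()}
        theirs = {(n.sequence, n.is_precursor, n.y) for n in other.nodes.values()}
        return mine == theirs and set(self.events) == set(other.events)

    # -- serialisation ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peptide_nodes": [
                {"sequence": n.sequence, "is_precursor": n.is_precursor, "y": n.y}
                for n in sorted(self.nodes.values(), key=lambda n: _node_sort_key(n.sequence))
            ],
            "event_nodes": [
                {"substrate": e.substrate, "prefix": e.prefix, "suffix": e.suffix,
                 "peptidase_id": e.peptidase_id, "rho": e.rho}
                for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CleavageGraph":
        payload = json.loads(Path(path).read_text())
        g = cls()
        for rec in payload["peptide_nodes"]:
            g.add_node(rec["sequence"], is_precursor=rec["is_precursor"], y=rec["y"])
        for rec in payload["event_nodes"]:
            g.add_event(EventNode(rec["substrate"], rec["prefix"], rec["suffix"],
                                  rec["peptidase_id"], rec["rho"]))
        return g

    def to_networkx(self):
        """Export as a networkx DiGraph (event nodes as ``('event', i)``)."""
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes.values():
            g.add_node(n.sequence, kind="peptide", is_precursor=n.is_precursor,
                       y=-1.0 if n.y is None else n.y)
        for i, e in enumerate(self.events):
            ev = f"event:{i}:{e.peptidase_id}"
            g.add_node(ev, kind="event", peptidase_id=e.peptidase_id, rho=e.rho)
            g.add_edge(e.substrate, ev)
            g.add_edge(ev, e.prefix)
            g.add_edge(ev, e.suffix)
        return g


def in_silico_digest(
    precursors: Sequence[str],
    matrices: Sequence[FrequencyMatrix],
    threshold: float,
    gamma: float = 1.0,
    max_depth: int | None = None,
) -> CleavageGraph:
    """Digest precursors recursively until closure.

    Every sequence generated (precursor or product) is scanned against
    every specificity profile; each detected site becomes an event node.
    Duplicate sequences are merged into a single peptide node.  The
    optional ``max_depth`` bounds the number of cleavage generations (a
    safety valve for pathological thresholds); by default the closure is
    complete.
    """
    if not precursors:
        raise ValueError("no precursor sequences")
    if not matrices:
        raise ValueError("no frequency matrices")
    graph = CleavageGraph()
    queue: list[tuple[str, int]] = []
    for seq in precursors:
        graph.add_node(seq, is_precursor=True)
        queue.append((seq, 0))
    digested: set[str] = set()
    while queue:
        seq, depth = queue.pop()
        if seq in digested:
            continue
        digested.add(seq)
        if max_depth is not None and depth >= max_depth:
            continue
        for fm in matrices:
            for cut in detect_cleavages(seq, fm, threshold, gamma):
                graph.add_event(EventNode(seq, cut.prefix, cut.suffix,
                                          fm.peptidase_id, cut.rho))
                for product in (cut.prefix, cut.suffix):
                    if product not in digested:
                        queue.append((product, depth + 1))
    return graph


def prune(graph: CleavageGraph) -> CleavageGraph:
    """Recursively drop empty sources and empty leaves (fixed point).

    A node is *empty* when it has no observed amount (``y`` absent or
    zero).  Events that lose their substrate or either product are removed
    with the nodes.  Interior empty nodes are retained.  Idempotent.
    """
    g = graph.copy()
    while True:
        removable = {s for s in (g.sources() | g.leaves()) if not g.nodes[s].observed}
        if not removable:
            return g
        g.events = [e for e in g.events
                    if not ({e.substrate, e.prefix, e.suffix} & removable)]
        for seq in removable:
            del g.nodes[seq]


def classify_nodes(graph: CleavageGraph) -> tuple[set[str], set[str], set[str]]:
    """Partition peptide nodes into (sources S, leaves L, interior).

    Before pruning an isolated node belongs to both S and L; the returned
    interior set is the complement of their union.
    """
    s, l = graph.sources(), graph.leaves()
    return s, l, set(graph.nodes) - s - l


def topological_order(graph: CleavageGraph) -> list[str]:
    """Peptide nodes ordered so every substrate precedes its products.

    Descending sequence length with lexicographic tie-break — valid
    because cleavage strictly shortens sequences.  A corrupted graph in
    which some event's product is not shorter than its substrate has lost
    that guarantee and is rejected.
    """
    for e in graph.events:
        if len(e.prefix) >= len(e.substrate) or len(e.suffix) >= len(e.substrate):
            raise ValueError("cleavage graph is not acyclic")
    return sorted(graph.nodes, key=_node_sort_key)
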