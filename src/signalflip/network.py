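"""Parsing, filtering and merging of signed prior-knowledge networks.

The on-disk dialect is a 4-column TSV: ``source<TAB>effect<TAB>mechanism<TAB>target``
with ``#`` comment lines. Effect labels map Activation -> +1, Inhibition -> -1,
Unspecified -> 0. Parallel edges between the same node pair that differ in sign
or mechanism are kept as distinct edges; exact duplicates are collapsed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from signalflip.errors import InputError, NetworkParseError

EFFECT_LABELS = {"Activation": 1, "Inhibition": -1, "Unspecified": 0}
SIGN_LABELS = {1: "Activation", -1: "Inhibition", 0: "Unspecified"}

#: default exclusions applied to the signalling prior
SIGNALLING_EXCLUDED_EFFECTS = frozenset({"Technical", "Unspecified"})
SIGNALLING_EXCLUDED_MECHANISMS = frozenset(
    {
        "Technical",
        "Transcriptional Regulation",
        "Influence on Expression",
        "Catalysis",
        "Transport",
    }
)

#: mechanisms admitted into the transcriptional-regulation prior
REGULATORY_MECHANISMS = frozenset(
    {"Transcriptional regulation", "Influence on Expression", "Regulation"}
)


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A directed interaction with a sign and a mechanism label."""

    source: str
    target: str
    sign: int
    mechanism: str

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise InputError("edge endpoints must be non-empty strings")
        if self.sign not in (-1, 0, 1):
            raise InputError(f"edge sign must be -1, 0 or +1, got {self.sign!r}")


@dataclass
class SignedNetwork:
    """A directed, signed molecular interaction network.

    ``kind`` distinguishes the signalling prior from the transcriptional
    regulatory prior; both share the same representation.
    """

    kind: str = "signalling"
    nodes: set[str] = field(default_factory=set)
    edges: list[SignedEdge] = field(default_factory=list)

    def add_edge(self, edge: SignedEdge) -> None:
        self.nodes.add(edge.source)
        self.nodes.add(edge.target)
        self.edges.append(edge)

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.nodes == other.nodes
            and sorted(self.edges) == sorted(other.edges)
        )

    def out_edges(self, node: str) -> Iterator[SignedEdge]:
        return (e for e in self.edges if e.source == node)

    def in_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.target == node)

    def to_multidigraph(self) -> nx.MultiDiGraph:
        """Lossless networkx view; edge keys carry sign and mechanism."""
        g = nx.MultiDiGraph(kind=self.kind)
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges):
            g.add_edge(e.source, e.target, sign=e.sign, mechanism=e.mechanism)
        return g


def _dedupe(edges: Iterable[SignedEdge]) -> list[SignedEdge]:
    seen: set[SignedEdge] = set()
    out: list[SignedEdge] = []
    for e in edges:
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


def parse_network(path: str | Path | io.TextIOBase, kind: str = "signalling") -> SignedNetwork:
    """Parse a 4-column network TSV into a :class:`SignedNetwork`.

    Parameters
    ----------
    path
        File path or open text handle. Rows are
        ``source<TAB>effect<TAB>mechanism<TAB>target``; ``#`` starts a comment.
    kind
        ``"signalling"`` or ``"regulatory"``.

    Raises
    ------
    NetworkParseError
        On malformed rows or unknown effect labels, with the line number.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path, "r", encoding="utf-8")
        close = True
    net = SignedNetwork(kind=kind)
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise NetworkParseError(
                    f"expected 4 tab-separated fields, got {len(parts)}", lineno
                )
            source, effect, mechanism, target = (p.strip() for p in parts)
            if effect not in EFFECT_LABELS:
                raise NetworkParseError(
                    f"unknown effect label {effect!r} "
                    f"(expected one of {sorted(EFFECT_LABELS)})",
                    lineno,
                )
            if not source or not target:
                raise NetworkParseError("empty source or target", lineno)
            net.add_edge(SignedEdge(source, target, EFFECT_LABELS[effect], mechanism))
    finally:
        if close:
            handle.close()
    net.edges = _dedupe(net.edges)
    return net


def write_network(net: SignedNetwork, path: str | Path) -> None:
    """Write the network in the same TSV dialect :func:`parse_network` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# source\teffect\tmechanism\ttarget\n")
        for e in sorted(net.edges):
            fh.write(f"{e.source}\t{SIGN_LABELS[e.sign]}\t{e.mechanism}\t{e.target}\n")


def filter_interactions(
    net: SignedNetwork,
    excluded_effects: Iterable[str] = (),
    excluded_mechanisms: Iterable[str] = (),
) -> SignedNetwork:
    """Drop edges by effect label or mechanism label; nodes are retained.

    Isolated nodes survive filtering because they may still act as pathway
    source nodes downstream.
    """
    mech = set(excluded_mechanisms)
    excluded_labels = set(excluded_effects)
    kept = [
        e
        for e in net.edges
        if SIGN_LABELS[e.sign] not in excluded_labels and e.mechanism not in mech
    ]
    return SignedNetwork(kind=net.kind, nodes=set(net.nodes), edges=kept)


def default_signalling_filter(net: SignedNetwork) -> SignedNetwork:
    """Apply the standard signalling-prior exclusions."""
    return filter_interactions(
        net, SIGNALLING_EXCLUDED_EFFECTS, SIGNALLING_EXCLUDED_MECHANISMS
    )


def regulatory_prior(net: SignedNetwork, tf_universe: set[str]) -> SignedNetwork:
    """Restrict a regulatory-kind network to TF-TF transcriptional edges.

    Keeps edges whose mechanism is transcriptional (Transcriptional
    regulation / Influence on Expression / Regulation), whose effect is
    Activation, Inhibition or Unspecified, and whose endpoints both lie in
    ``tf_universe``.
    """
    if not tf_universe:
        raise InputError("tf_universe must be non-empty")
    kept = [
        e
        for e in net.edges
        if e.mechanism in REGULATORY_MECHANISMS
        and e.source in tf_universe
        and e.target in tf_universe
    ]
    nodes = set(net.nodes) & tf_universe
    return SignedNetwork(kind="regulatory", nodes=nodes, edges=kept)


def source_nodes(net: SignedNetwork) -> set[str]:
    """All nodes with in-degree 0 (canonical pathway entry points)."""
    targets = {e.target for e in net.edges}
    return {n for n in net.nodes if n not in targets}


def parse_blacklist(path: str | Path) -> set[tuple[str, str, str]]:
    """Parse an edge blacklist TSV: ``source<TAB>target<TAB>mechanism``."""
    entries: set[tuple[str, str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 3:
                raise NetworkParseError(
                    f"expected 3 tab-separated fields, got {len(parts)}", lineno
                )
            entries.add((parts[0], parts[1], parts[2]))
    return entries


def apply_blacklist(
    net: SignedNetwork, blacklist: set[tuple[str, str, str]]
) -> SignedNetwork:
    """Remove blacklisted (source, target, mechanism) edges after parsing."""
    kept = [
        e for e in net.edges if (e.source, e.target, e.mechanism) not in blacklist
    ]
    return SignedNetwork(kind=net.kind, nodes=set(net.nodes), edges=kept)


def merge_networks(nets: Iterable[SignedNetwork], kind: str) -> SignedNetwork:
    """Union of several networks (e.g. individual pathways) into one."""
    merged = SignedNetwork(kind=kind)
    for net in nets:
        merged.nodes |= net.nodes
        merged.edges.extend(net.edges)
    merged.edges = _dedupe(merged.edges)
    return merged


def export_gml(net: SignedNetwork, path: str | Path) -> None:
    """Optional GML export for visualization tools."""
    nx.write_gml(net.to_multidigraph(), str(path))
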