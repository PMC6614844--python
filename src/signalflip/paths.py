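"""Most-probably-expressed paths (MPPs) and per-molecule distributions P.

The probability of a signalling path is the product of the expression
probabilities of its *intermediate* nodes (source and target contribute a
factor of 1). Two variants exist:

* correlation — edge contributions are boosted to ``max(p(v), |r(u,v)|)``
  when the expression correlation exceeds a threshold and its sign matches
  the interaction sign;
* length — the path product is additionally multiplied by ``exp(-n)`` for a
  path of n edges.

The max-product search runs as a shortest path under additive -log costs
(plus 1 per edge in the length variant), with deterministic tie-breaking:
smaller cost, then fewer edges, then lexicographically smallest node
sequence. Sign-0 edges are removed beforehand so every path sign is +/-1.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from signalflip.errors import InputError, ParameterError
from signalflip.network import SignedNetwork
from signalflip.perturb import TFStatePair

logger = logging.getLogger(__name__)

VARIANTS = ("correlation", "length")
CORRELATION_THRESHOLD = 0.7
DEFAULT_NODE_PROBABILITY = 0.5


@dataclass
class NodeProbabilities:
    """Expression probabilities with a default for unmeasured molecules."""

    values: dict[str, float]
    default: float = DEFAULT_NODE_PROBABILITY

    def __post_init__(self) -> None:
        for node, p in self.values.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability of {node} outside [0, 1]: {p}")
        if not 0.0 <= self.default <= 1.0:
            raise ParameterError(f"default probability outside [0, 1]: {self.default}")

    def __getitem__(self, node: str) -> float:
        return self.values.get(node, self.default)

    def is_measured(self, node: str) -> bool:
        return node in self.values


@dataclass(frozen=True)
class MPPResult:
    """A most-probably-expressed path with its probability and sign."""

    source: str
    target: str
    path: tuple[str, ...]
    probability: float
    sign: int
    variant: str
    sign_tie: bool = False


@dataclass
class MoleculeProfile:
    """Distribution P of a molecule's influence over interface-TF states."""

    molecule: str
    direction: str  # "activation" | "inhibition"
    variant: str
    p: dict[TFStatePair, float] = field(default_factory=dict)
    mpps: dict[str, MPPResult] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.p


@dataclass
class ScoredGraph:
    """Signalling graph annotated with per-edge costs and signs.

    ``adj[u]`` maps successors v to ``(cost, sign, sign_tie)`` where cost is
    the -log contribution of traversing to v as an intermediate (the length
    penalty is added during search).
    """

    adj: dict[str, dict[str, tuple[float, int, bool]]]
    probs: NodeProbabilities
    variant: str

    @property
    def nodes(self) -> set[str]:
        out = set(self.adj)
        for succ in self.adj.values():
            out |= set(succ)
        return out


def read_correlations(path) -> dict[tuple[str, str], float]:
    """Read ``gene_a<TAB>gene_b<TAB>pearson_r``; symmetric, deduplicated."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["a", "b", "r"],
        dtype={"a": str, "b": str},
    )
    try:
        df["r"] = df["r"].astype(float)
    except ValueError:  # header row present
        df = df.iloc[1:].copy()
        df["r"] = df["r"].astype(float)
    out: dict[tuple[str, str], float] = {}
    for a, b, r in df.itertuples(index=False):
        if not -1.0 <= r <= 1.0:
            raise ParameterError(f"correlation of ({a}, {b}) outside [-1, 1]: {r}")
        out[(a, b)] = r
        out[(b, a)] = r
    return out


def edge_weights(
    signalling: SignedNetwork,
    probs: NodeProbabilities,
    variant: str,
    correlations: dict[tuple[str, str], float] | None = None,
    corr_threshold: float = CORRELATION_THRESHOLD,
) -> ScoredGraph:
    """Build the weighted search graph for one variant.

    Sign-0 edges are dropped. Parallel edges between the same pair collapse
    to the best (highest-contribution) one; an exact contribution tie between
    opposite signs keeps the activating edge and flags the tie.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    correlations = correlations or {}
    adj: dict[str, dict[str, tuple[float, int, bool]]] = {}
    for e in signalling.edges:
        if e.sign == 0:
            continue
        if e.source == e.target:  # self-loops can never sit on a simple path
            continue
        contrib = probs[e.target]
        if variant == "correlation":
            r = correlations.get((e.source, e.target))
            if r is not None and abs(r) > corr_threshold and _sign(r) == e.sign:
                contrib = max(contrib, abs(r))
        succ = adj.setdefault(e.source, {})
        prev = succ.get(e.target)
        if prev is None:
            succ[e.target] = (contrib, e.sign, False)
        else:
            prev_contrib, prev_sign, _ = prev
            if contrib > prev_contrib:
                succ[e.target] = (contrib, e.sign, False)
            elif contrib == prev_contrib and e.sign != prev_sign:
                # opposite-sign tie: keep the activating edge, deterministic
                succ[e.target] = (prev_contrib, 1, True)
                logger.debug(
                    "opposite-sign contribution tie on edge %s->%s", e.source, e.target
                )
    # store -log contribution as the additive cost
    cost_adj: dict[str, dict[str, tuple[float, int, bool]]] = {}
    for u, succ in adj.items():
        cost_adj[u] = {}
        for v, (contrib, sign, tie) in succ.items():
            cost = math.inf if contrib <= 0.0 else -math.log(contrib)
            cost_adj[u][v] = (cost, sign, tie)
    return ScoredGraph(adj=cost_adj, probs=probs, variant=variant)


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def mpp(graph: ScoredGraph, source: str, target: str) -> MPPResult | None:
    """The simple path from ``source`` to ``target`` maximizing the product of
    intermediate-node contributions (times ``exp(-n)`` in the length variant).

    Deterministic Dijkstra over keys (cost, n_edges, node sequence); the edge
    into the target costs nothing because the target contributes a factor 1.
    Returns None when the target is unreachable through positive-probability
    intermediates.
    """
    if source == target:
        raise InputError("MPP source and target must differ")
    length_penalty = 1.0 if graph.variant == "length" else 0.0
    # heap entries: (cost, n_edges, path, sign, sign_tie)
    heap: list[tuple[float, int, tuple[str, ...], int, bool]] = [
        (0.0, 0, (source,), 1, False)
    ]
    settled: set[str] = set()
    while heap:
        cost, n_edges, path, sign, tie = heapq.heappop(heap)
        node = path[-1]
        if node == target:
            return MPPResult(
                source=source,
                target=target,
                path=path,
                probability=math.exp(-cost),
                sign=sign,
                variant=graph.variant,
                sign_tie=tie,
            )
        if node in settled:
            continue
        settled.add(node)
        for v, (edge_cost, edge_sign, edge_tie) in graph.adj.get(node, {}).items():
            if v in settled or v in path:
                continue
            if v == target:
                step = length_penalty  # target contributes probability 1
            else:
                if edge_cost == math.inf or graph.probs[v] == 0.0:
                    continue  # zero-probability intermediates are excluded
                step = edge_cost + length_penalty
            heapq.heappush(
                heap,
                (cost + step, n_edges + 1, path + (v,), sign * edge_sign, tie or edge_tie),
            )
    return None


def path_sign(path: tuple[str, ...], graph: ScoredGraph) -> int:
    """Product of edge signs along a path chosen by the search."""
    sign = 1
    for u, v in zip(path, path[1:]):
        entry = graph.adj.get(u, {}).get(v)
        if entry is None or entry[1] == 0:
            raise InputError(f"path step {u}->{v} has no signed edge in the graph")
        sign *= entry[1]
    return sign


def molecule_profiles(
    graph: ScoredGraph,
    molecule: str,
    interface_tfs: list[str],
) -> tuple[MoleculeProfile, MoleculeProfile]:
    """Distributions P for the activation and the inhibition of a molecule.

    M values over all reachable interface TFs are normalized to sum to 1;
    a positive path sign maps activation of the molecule to TF state 1
    (inhibition to 0) and vice versa for negative signs. Both directions
    share the probabilities and carry complementary TF states.
    """
    results: dict[str, MPPResult] = {}
    for tf in interface_tfs:
        if tf == molecule:
            continue
        res = mpp(graph, molecule, tf)
        if res is not None and res.probability > 0.0:
            results[tf] = res
    act = MoleculeProfile(molecule, "activation", graph.variant, mpps=results)
    inh = MoleculeProfile(molecule, "inhibition", graph.variant, mpps=results)
    if not results:
        logger.debug("molecule %s reaches no interface TF; unrankable", molecule)
        return act, inh
    total = sum(r.probability for r in results.values())
    for tf, res in sorted(results.items()):
        p = res.probability / total
        act_state = 1 if res.sign == 1 else 0
        act.p[TFStatePair(tf, act_state)] = p
        inh.p[TFStatePair(tf, 1 - act_state)] = p
    return act, inh
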