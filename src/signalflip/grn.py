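"""Transition-specific Boolean GRN: majority dynamics and attractor pruning.

The GRN spans transcription factors whose Boolean state differs between the
initial and final cell states. Dynamics are synchronous majority (threshold)
logic: a node turns on when its active activators outnumber its active
inhibitors, off in the opposite case, and keeps its state on a tie or with no
regulators. Edges of unspecified sign (0) carry no dynamical weight but count
as connectivity.

Pruning removes the fewest edges needed so that both Booleanized states are
point attractors. The fixed-point condition of a node depends only on its own
in-edges, so an exact per-node subset search yields a globally maximal
consistent sub-network.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from signalflip.errors import InputError
from signalflip.expression import BooleanTransition
from signalflip.network import SIGN_LABELS, SignedEdge, SignedNetwork

logger = logging.getLogger(__name__)

#: a Boolean network state: TF id -> 0/1
BooleanState = dict[str, int]

MIN_CONNECTED_TFS = 10

# exact subset search is 2^in-degree; beyond this fall back to a greedy repair
_EXACT_INDEGREE_LIMIT = 18


@dataclass
class TransitionGRN:
    """A pruned Boolean network whose two cell states are point attractors."""

    tfs: list[str]
    edges: list[SignedEdge]
    s_init: BooleanState
    s_final: BooleanState
    removed_edges: list[tuple[SignedEdge, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        tf_set = set(self.tfs)
        for e in self.edges:
            if e.source not in tf_set or e.target not in tf_set:
                raise InputError(f"edge {e} has an endpoint outside the GRN TFs")
        for name, state in (("s_init", self.s_init), ("s_final", self.s_final)):
            missing = tf_set - set(state)
            if missing:
                raise InputError(f"{name} missing TFs: {sorted(missing)[:5]}")

    @property
    def regulators(self) -> dict[str, list[SignedEdge]]:
        by_target: dict[str, list[SignedEdge]] = {t: [] for t in self.tfs}
        for e in self.edges:
            by_target[e.target].append(e)
        return by_target

    def connected_tfs(self) -> set[str]:
        touched: set[str] = set()
        for e in self.edges:
            touched.add(e.source)
            touched.add(e.target)
        return touched

    def to_files(self, edge_path: str | Path, sidecar_path: str | Path) -> None:
        """Export the edge list TSV plus a JSON sidecar with states and log."""
        with open(edge_path, "w", encoding="utf-8") as fh:
            fh.write("# source\teffect\tmechanism\ttarget\n")
            for e in sorted(self.edges):
                fh.write(f"{e.source}\t{SIGN_LABELS[e.sign]}\t{e.mechanism}\t{e.target}\n")
        sidecar = {
            "tfs": self.tfs,
            "s_init": self.s_init,
            "s_final": self.s_final,
            "removed_edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "sign": e.sign,
                    "mechanism": e.mechanism,
                    "reason": reason,
                }
                for e, reason in self.removed_edges
            ],
        }
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)


def differential_tfs(transition: BooleanTransition, tf_universe: set[str]) -> set[str]:
    """TFs in the universe whose Boolean state differs between the two states."""
    out = set()
    for i, gene in enumerate(transition.genes):
        if gene in tf_universe and transition.state_initial[i] != transition.state_final[i]:
            out.add(gene)
    return out


def majority_update(
    state: BooleanState,
    grn: TransitionGRN,
    clamped: dict[str, int] | None = None,
) -> BooleanState:
    """One synchronous majority-logic step.

    ``clamped`` maps TF ids to fixed values that override the update. Every
    GRN TF must be present in ``state``; extra entries (external inputs) are
    carried through unchanged.
    """
    clamped = clamped or {}
    missing = [t for t in grn.tfs if t not in state]
    if missing:
        raise InputError(f"state missing TFs: {missing[:5]}")
    regs = grn.regulators
    new_state = dict(state)
    for tf in grn.tfs:
        if tf in clamped:
            new_state[tf] = clamped[tf]
            continue
        a = i = 0
        for e in regs[tf]:
            if state.get(e.source, 0) != 1:
                continue
            if e.sign == 1:
                a += 1
            elif e.sign == -1:
                i += 1
        if a - i > 0:
            new_state[tf] = 1
        elif a - i < 0:
            new_state[tf] = 0
        # tie or no regulators: keep current state
    for tf, v in clamped.items():
        new_state[tf] = v
    return new_state


def is_point_attractor(state: BooleanState, grn: TransitionGRN) -> bool:
    """True iff one unclamped synchronous step maps the state to itself."""
    nxt = majority_update(state, grn)
    return all(nxt[t] == state[t] for t in grn.tfs)


def _node_fixed(s_target: int, in_edges: list[SignedEdge], state: BooleanState) -> bool:
    """Fixed-point condition for one node under one attractor state."""
    a = sum(1 for e in in_edges if e.sign == 1 and state.get(e.source, 0) == 1)
    i = sum(1 for e in in_edges if e.sign == -1 and state.get(e.source, 0) == 1)
    if a - i > 0:
        return s_target == 1
    if a - i < 0:
        return s_target == 0
    return True  # tie keeps the current (= target) state


def _subset_sort_key(subset: tuple[SignedEdge, ...]) -> tuple:
    # prefer larger subsets, then more activating edges, then lexicographic
    n_act = sum(1 for e in subset if e.sign == 1)
    lex = tuple(sorted((e.source, -e.sign, e.mechanism) for e in subset))
    return (-len(subset), -n_act, lex)


def _repair_node(
    tf: str,
    in_edges: list[SignedEdge],
    s_init: BooleanState,
    s_final: BooleanState,
) -> tuple[list[SignedEdge], list[SignedEdge]]:
    """Choose the maximal in-edge subset keeping ``tf`` fixed in both states.

    Returns (kept, removed). Sign-0 edges have no dynamical effect and are
    always kept.
    """
    signed = [e for e in in_edges if e.sign != 0]
    neutral = [e for e in in_edges if e.sign == 0]

    def feasible(subset) -> bool:
        return _node_fixed(s_init[tf], list(subset), s_init) and _node_fixed(
            s_final[tf], list(subset), s_final
        )

    if feasible(signed):
        return in_edges, []

    if len(signed) <= _EXACT_INDEGREE_LIMIT:
        best: tuple[SignedEdge, ...] | None = None
        best_key: tuple | None = None
        for size in range(len(signed) - 1, -1, -1):
            for subset in itertools.combinations(signed, size):
                if feasible(subset):
                    key = _subset_sort_key(subset)
                    if best_key is None or key < best_key:
                        best, best_key = subset, key
            if best is not None:
                break
        assert best is not None  # empty subset is always feasible
        kept_signed = set(best)
    else:  # greedy fallback for pathological in-degrees
        logger.warning(
            "TF %s has %d signed regulators; using greedy repair", tf, len(signed)
        )
        kept = sorted(signed, key=lambda e: (-e.sign, e.source, e.mechanism))
        while not feasible(kept):
            kept.pop()
        kept_signed = set(kept)

    kept_edges = [e for e in in_edges if e.sign == 0 or e in kept_signed]
    removed = [e for e in signed if e not in kept_signed]
    return kept_edges, removed


def prune_to_attractors(
    prior: SignedNetwork,
    s_init: BooleanState,
    s_final: BooleanState,
) -> TransitionGRN:
    """Remove the fewest edges so both states are point attractors.

    ``prior`` must connect differential TFs only; its node set defines the
    GRN TFs. Always succeeds: the empty edge set keeps any state fixed under
    the keep-on-tie rule.
    """
    tfs = sorted(prior.nodes)
    for name, state in (("s_init", s_init), ("s_final", s_final)):
        missing = [t for t in tfs if t not in state]
        if missing:
            raise InputError(f"{name} missing TFs: {missing[:5]}")
    by_target: dict[str, list[SignedEdge]] = {t: [] for t in tfs}
    for e in prior.edges:
        by_target[e.target].append(e)
    kept_all: list[SignedEdge] = []
    removed_all: list[tuple[SignedEdge, str]] = []
    for tf in tfs:
        kept, removed = _repair_node(tf, by_target[tf], s_init, s_final)
        kept_all.extend(kept)
        removed_all.extend(
            (e, f"attractor conflict at {tf}") for e in removed
        )
    grn = TransitionGRN(
        tfs=tfs,
        edges=sorted(kept_all),
        s_init={t: s_init[t] for t in tfs},
        s_final={t: s_final[t] for t in tfs},
        removed_edges=removed_all,
    )
    assert is_point_attractor(grn.s_init, grn)
    assert is_point_attractor(grn.s_final, grn)
    return grn


def grn_passes_filter(grn: TransitionGRN, min_tfs: int = MIN_CONNECTED_TFS) -> bool:
    """True iff at least ``min_tfs`` TFs keep an incident edge after pruning."""
    return len(grn.connected_tfs()) >= min_tfs
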