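"""In-silico perturbation of interface TFs and selection of BPCs.

Interface TFs connect the signalling layer to the GRN: they regulate GRN-TFs,
are expressed at the initial time point, and are reachable from a signalling
source node through a fully expressed path. Combinations of up to ``max_size``
interface-TF states are clamped, the GRN is iterated synchronously to a fixed
point, and combinations are scored by how many GRN-TFs flip. The top-3
distinct scores (with ties) define the best-performing combinations (BPCs);
non-synergistic combinations are removed, and the per-TF-state frequencies
across BPCs are normalized into the distribution Q.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

from signalflip.errors import InputError
from signalflip.expression import BooleanTransition
from signalflip.grn import BooleanState, TransitionGRN
from signalflip.network import SignedEdge, SignedNetwork, source_nodes

logger = logging.getLogger(__name__)

MAX_COMBINATION_SIZE = 4
BEST_SCORES = 3
MIN_FLIP_FRACTION = 0.4


class TFStatePair(NamedTuple):
    """An interface TF together with an imposed activity state (1/0)."""

    tf: str
    state: int


@dataclass(frozen=True)
class PerturbationResult:
    """Outcome of clamping one combination of interface-TF states."""

    combination: frozenset[TFStatePair]
    flipped: frozenset[str]
    flipping_score: int
    converged: bool

    def sort_key(self) -> tuple:
        return tuple(sorted(self.combination))


@dataclass
class BPCSet:
    """Best-performing combinations plus the derived distribution Q."""

    combinations: list[PerturbationResult]
    q: dict[TFStatePair, float]
    best_score: int
    flip_fraction_flag: bool = False

    @property
    def tf_state_pairs(self) -> set[TFStatePair]:
        return set(self.q)


def identify_interface_tfs(
    signalling: SignedNetwork,
    regulatory: SignedNetwork,
    grn: TransitionGRN,
    transition: BooleanTransition,
    unmeasured_expressed: bool = True,
) -> list[str]:
    """Interface TFs: regulate GRN-TFs, expressed initially, and reachable
    from a pathway source node along a fully expressed signalling path.

    Nodes absent from the transition are treated as expressed when
    ``unmeasured_expressed`` is set (complexes and unmapped molecules).
    """
    grn_tfs = set(grn.tfs)
    regulators_of_grn = {
        e.source for e in regulatory.edges if e.target in grn_tfs
    }

    def expressed(node: str) -> bool:
        if node in transition:
            return transition.initial_state_of(node) == 1
        return unmeasured_expressed

    sources = {s for s in source_nodes(signalling) if expressed(s)}
    # forward BFS through expressed nodes only
    succ: dict[str, set[str]] = {}
    for e in signalling.edges:
        succ.setdefault(e.source, set()).add(e.target)
    reachable: set[str] = set(sources)
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in succ.get(u, ()):  # v must itself be expressed to extend the path
            if v not in reachable and expressed(v):
                reachable.add(v)
                queue.append(v)

    out = [
        t
        for t in sorted(regulators_of_grn)
        if expressed(t) and t in reachable
    ]
    return out


def _augmented_regulators(
    grn: TransitionGRN, interface_edges: Sequence[SignedEdge]
) -> dict[str, list[SignedEdge]]:
    """GRN regulators plus regulatory edges from external interface TFs."""
    regs = grn.regulators
    grn_tfs = set(grn.tfs)
    for e in interface_edges:
        if e.target in grn_tfs and e.source not in grn_tfs:
            regs[e.target].append(e)
    return regs


def simulate_clamped(
    grn: TransitionGRN,
    s_init: BooleanState,
    combination: Iterable[TFStatePair],
    external_inputs: dict[str, int],
    interface_edges: Sequence[SignedEdge] = (),
    max_steps: int = 1000,
) -> PerturbationResult:
    """Clamp a combination of interface-TF states and iterate to a fixed point.

    Non-perturbed external inputs are held at their value in
    ``external_inputs`` throughout; ``interface_edges`` are regulatory edges
    from external interface TFs into GRN-TFs that extend the update rule.
    On cycle detection or step exhaustion the result is flagged not-converged
    with flipping_score -1.
    """
    combo = frozenset(combination)
    by_tf: dict[str, int] = {}
    for pair in combo:
        if pair.tf in by_tf and by_tf[pair.tf] != pair.state:
            raise InputError(f"combination clamps {pair.tf} to both states")
        by_tf[pair.tf] = pair.state

    clamped = dict(external_inputs)
    clamped.update(by_tf)

    regs = _augmented_regulators(grn, interface_edges)
    grn_tfs = list(grn.tfs)
    state: BooleanState = {t: s_init[t] for t in grn_tfs}
    state.update(clamped)

    seen: set[tuple[int, ...]] = set()
    order = grn_tfs + sorted(set(clamped) - set(grn_tfs))

    def key(st: BooleanState) -> tuple[int, ...]:
        return tuple(st[t] for t in order)

    for _ in range(max_steps):
        seen.add(key(state))
        new_state = dict(state)
        for tf in grn_tfs:
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
        for tf, v in clamped.items():
            new_state[tf] = v
        if key(new_state) == key(state):
            flipped = frozenset(t for t in grn_tfs if new_state[t] != s_init[t])
            return PerturbationResult(combo, flipped, len(flipped), True)
        if key(new_state) in seen:
            return PerturbationResult(combo, frozenset(), -1, False)
        state = new_state
    return PerturbationResult(combo, frozenset(), -1, False)


def allowed_tf_states(
    interface_tfs: Sequence[str],
    transition: BooleanTransition,
    differential_tf_states: str = "final_only",
) -> dict[str, tuple[int, ...]]:
    """States enumerated per interface TF.

    A TF whose Boolean expression differs between the two cell states has a
    known target activity: only its final state is enumerated (configurable
    via ``differential_tf_states = "both"``). All others get both states.
    """
    if differential_tf_states not in ("final_only", "both"):
        raise InputError(
            f"differential_tf_states must be 'final_only' or 'both', "
            f"got {differential_tf_states!r}"
        )
    allowed: dict[str, tuple[int, ...]] = {}
    for tf in interface_tfs:
        if (
            differential_tf_states == "final_only"
            and tf in transition
            and transition.initial_state_of(tf) != transition.final_state_of(tf)
        ):
            allowed[tf] = (transition.final_state_of(tf),)
        else:
            allowed[tf] = (0, 1)
    return allowed


def enumerate_combinations(
    interface_tfs: Sequence[str],
    allowed: dict[str, tuple[int, ...]],
    max_size: int = MAX_COMBINATION_SIZE,
) -> Iterator[frozenset[TFStatePair]]:
    """All TF-state combinations of size 1..max_size, lexicographic order."""
    if max_size < 1:
        raise InputError(f"max_size must be >= 1, got {max_size}")
    tfs = sorted(set(interface_tfs))
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(tfs, size):
            for states in itertools.product(*(allowed[t] for t in subset)):
                yield frozenset(
                    TFStatePair(t, s) for t, s in zip(subset, states)
                )


def synergy_filter(
    bpcs: list[PerturbationResult],
    singleton_results: dict[TFStatePair, frozenset[str]],
) -> list[PerturbationResult]:
    """Drop multi-TF combinations whose flips equal the union of their
    constituents' singleton flips (no synergy). Singletons always survive."""
    out: list[PerturbationResult] = []
    for res in bpcs:
        if len(res.combination) == 1:
            out.append(res)
            continue
        union: set[str] = set()
        for pair in res.combination:
            if pair not in singleton_results:
                raise InputError(f"missing singleton result for {pair}")
            union |= singleton_results[pair]
        if set(res.flipped) != union:
            out.append(res)
        else:
            logger.debug("synergy filter removed %s", sorted(res.combination))
    return out


def select_bpcs(
    results: list[PerturbationResult],
    n_grn_tfs: int,
    best: int = BEST_SCORES,
    min_flip_fraction: float = MIN_FLIP_FRACTION,
) -> BPCSet:
    """Top-``best`` distinct flipping scores (ties included), synergy-filtered.

    The ``flip_fraction_flag`` is raised when the best score covers less than
    ``min_flip_fraction`` of the GRN-TFs; the flag is advisory and the set is
    still returned.
    """
    converged = [r for r in results if r.converged]
    n_dropped = len(results) - len(converged)
    if n_dropped:
        logger.info("excluding %d non-converged combination(s)", n_dropped)
    if not converged:
        raise InputError("no converged perturbation results to select from")

    singletons = {
        next(iter(r.combination)): r.flipped
        for r in converged
        if len(r.combination) == 1
    }
    scores = sorted({r.flipping_score for r in converged}, reverse=True)
    top_scores = set(scores[:best])
    top = [r for r in converged if r.flipping_score in top_scores]
    top.sort(key=lambda r: (-r.flipping_score, len(r.combination), r.sort_key()))
    kept = synergy_filter(top, singletons)
    best_score = scores[0]
    flag = best_score < min_flip_fraction * n_grn_tfs
    if flag:
        logger.warning(
            "best flipping score %d below %.0f%% of %d GRN-TFs",
            best_score,
            100 * min_flip_fraction,
            n_grn_tfs,
        )
    q = compute_q(kept) if kept else {}
    return BPCSet(combinations=kept, q=q, best_score=best_score, flip_fraction_flag=flag)


def compute_q(bpcs: list[PerturbationResult]) -> dict[TFStatePair, float]:
    """Normalized per-TF-state frequencies across BPCs (distribution Q)."""
    if not bpcs:
        raise InputError("cannot compute Q from an empty BPC set")
    k = len(bpcs)
    counts: dict[TFStatePair, int] = {}
    for res in bpcs:
        for pair in res.combination:
            counts[pair] = counts.get(pair, 0) + 1
    freqs = {pair: c / k for pair, c in counts.items()}
    total = sum(freqs.values())
    return {pair: f / total for pair, f in sorted(freqs.items())}
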