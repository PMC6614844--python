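"""End-to-end orchestration: expression -> GRN -> perturbations -> ranking.

``run_data`` executes the method on in-memory objects; ``run`` wraps it with
file I/O, output writing and provenance. All stages are deterministic given
the inputs; the only randomness in the package lives in the evaluation
analyses and the fixtures generator, which take explicit seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from signalflip import __version__
from signalflip.errors import InputError
from signalflip.expression import (
    BarcodeParams,
    BooleanTransition,
    booleanize_barcode,
    booleanize_detection_call,
    build_transition,
    read_expression_tsv,
)
from signalflip.grn import (
    TransitionGRN,
    differential_tfs,
    grn_passes_filter,
    prune_to_attractors,
)
from signalflip.network import (
    SignedEdge,
    SignedNetwork,
    apply_blacklist,
    default_signalling_filter,
    parse_blacklist,
    parse_network,
    regulatory_prior,
)
from signalflip.paths import (
    NodeProbabilities,
    MoleculeProfile,
    ScoredGraph,
    edge_weights,
    molecule_profiles,
    read_correlations,
    VARIANTS,
)
from signalflip.perturb import (
    BPCSet,
    TFStatePair,
    allowed_tf_states,
    enumerate_combinations,
    identify_interface_tfs,
    select_bpcs,
    simulate_clamped,
)
from signalflip.ranking import (
    CandidateRanking,
    build_ranking,
    evaluate_success,
    random_success_probability,
)

logger = logging.getLogger(__name__)

MAX_SELECTIVE_TARGETS = 30


@dataclass
class RunConfig:
    """All tunables of a run, with the documented defaults."""

    signalling: str | None = None
    regulatory: str | None = None
    expr_initial: str | None = None
    expr_final: str | None = None
    barcode_params: str | None = None
    detection_initial: str | None = None
    detection_final: str | None = None
    correlations: str | None = None
    targets: str | None = None
    blacklist: str | None = None
    out_dir: str | None = None

    barcode_cutoff: float = 0.95
    detection_threshold: float = 0.94
    min_connected_tfs: int = 10
    max_combination_size: int = 4
    best: int = 3
    min_flip_fraction: float = 0.4
    correlation_threshold: float = 0.7
    cutoff_fraction: float = 0.06
    default_node_probability: float = 0.5
    differential_tf_states: str = "final_only"
    max_steps: int = 1000
    sign_aware_success: bool = False

    def validate(self) -> None:
        for name in (
            "barcode_cutoff",
            "detection_threshold",
            "min_flip_fraction",
            "cutoff_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.default_node_probability <= 1.0:
            raise InputError("default_node_probability must lie in [0, 1]")


@dataclass
class RunResult:
    transition: BooleanTransition
    grn: TransitionGRN
    interface_tfs: list[str]
    bpcs: BPCSet
    profiles: dict[str, list[MoleculeProfile]]
    graphs: dict[str, ScoredGraph]
    ranking: CandidateRanking
    flags: dict[str, bool] = field(default_factory=dict)
    success: bool | None = None
    random_success: float | None = None
    n_universe: int = 0

    @property
    def candidates(self):
        return self.ranking.candidates


def run_data(
    signalling: SignedNetwork,
    regulatory: SignedNetwork,
    transition: BooleanTransition,
    config: RunConfig | None = None,
    correlations: dict[tuple[str, str], float] | None = None,
    targets: list[tuple[str, str | None]] | None = None,
    tf_universe: set[str] | None = None,
) -> RunResult:
    """Run the full method on parsed inputs.

    ``tf_universe`` defaults to the node set of the regulatory network.
    """
    cfg = config or RunConfig()
    cfg.validate()
    flags: dict[str, bool] = {}

    if tf_universe is None:
        tf_universe = set(regulatory.nodes)
    reg = regulatory_prior(regulatory, tf_universe)

    # transition-specific GRN over differential TFs
    diff = differential_tfs(transition, tf_universe)
    grn_prior = SignedNetwork(kind="regulatory", nodes=set(diff))
    for e in reg.edges:
        if e.source in diff and e.target in diff:
            grn_prior.add_edge(e)
    s_init = {t: transition.initial_state_of(t) for t in diff}
    s_final = {t: transition.final_state_of(t) for t in diff}
    grn = prune_to_attractors(grn_prior, s_init, s_final)
    flags["grn_too_small"] = not grn_passes_filter(grn, cfg.min_connected_tfs)
    if flags["grn_too_small"]:
        logger.warning(
            "GRN keeps %d connected TFs (< %d)",
            len(grn.connected_tfs()),
            cfg.min_connected_tfs,
        )

    interface_tfs = identify_interface_tfs(signalling, reg, grn, transition)
    if not interface_tfs:
        raise InputError("no interface TFs found; cannot perturb the GRN")

    # exhaustive clamped simulations
    grn_tf_set = set(grn.tfs)
    interface_edges = [
        e for e in reg.edges if e.source in interface_tfs and e.target in grn_tf_set
    ]
    external_inputs = {
        t: transition.initial_state_of(t) if t in transition else 1
        for t in interface_tfs
        if t not in grn_tf_set
    }
    allowed = allowed_tf_states(interface_tfs, transition, cfg.differential_tf_states)
    results = [
        simulate_clamped(
            grn,
            grn.s_init,
            combo,
            external_inputs,
            interface_edges,
            cfg.max_steps,
        )
        for combo in enumerate_combinations(
            interface_tfs, allowed, cfg.max_combination_size
        )
    ]
    bpcs = select_bpcs(results, len(grn.tfs), cfg.best, cfg.min_flip_fraction)
    flags["flip_fraction_below_min"] = bpcs.flip_fraction_flag

    # per-molecule path scoring, both variants
    probs = NodeProbabilities(
        values={
            g: transition.initial_prob_of(g)
            for g in transition.genes
            if g in signalling.nodes
        },
        default=cfg.default_node_probability,
    )
    graphs = {
        variant: edge_weights(
            signalling,
            probs,
            variant,
            correlations=correlations if variant == "correlation" else None,
            corr_threshold=cfg.correlation_threshold,
        )
        for variant in VARIANTS
    }
    profiles: dict[str, list[MoleculeProfile]] = {v: [] for v in VARIANTS}
    molecules = sorted(signalling.nodes)
    for variant in VARIANTS:
        graph = graphs[variant]
        for mol in molecules:
            act, inh = molecule_profiles(graph, mol, interface_tfs)
            profiles[variant].extend([act, inh])

    ranking = build_ranking(profiles, bpcs.q, cfg.cutoff_fraction)

    # evaluation against known targets, when supplied
    success = None
    random_success = None
    n_universe = len({mol for mol, _ in ranking.r})
    if targets:
        present = [t for t in targets if t[0] in signalling.nodes]
        flags["targets_not_selective"] = len(present) > MAX_SELECTIVE_TARGETS
        if present:
            success = evaluate_success(
                ranking.candidates, present, sign_aware=cfg.sign_aware_success
            )
            n_candidate_molecules = len({m for m, _ in ranking.candidates})
            ranked_molecules = {m for m, _ in ranking.r}
            k_targets = len({t[0] for t in present} & ranked_molecules)
            if k_targets:
                random_success = random_success_probability(
                    n_universe, k_targets, n_candidate_molecules
                )
        else:
            logger.warning("no supplied target is present in the signalling network")

    return RunResult(
        transition=transition,
        grn=grn,
        interface_tfs=interface_tfs,
        bpcs=bpcs,
        profiles=profiles,
        graphs=graphs,
        ranking=ranking,
        flags=flags,
        success=success,
        random_success=random_success,
        n_universe=n_universe,
    )


def _load_transition(cfg: RunConfig) -> BooleanTransition:
    import pandas as pd

    if cfg.expr_initial and cfg.expr_final:
        if not cfg.barcode_params:
            raise InputError("barcode route requires --barcode-params")
        params = BarcodeParams.from_tsv(cfg.barcode_params)
        mi = read_expression_tsv(cfg.expr_initial)
        mf = read_expression_tsv(cfg.expr_final)
        si, pi = booleanize_barcode(mi, params, cfg.barcode_cutoff)
        sf, pf = booleanize_barcode(mf, params, cfg.barcode_cutoff)
        return build_transition((si, pi), (sf, pf), list(mi.index), list(mf.index))
    if cfg.detection_initial and cfg.detection_final:
        pi = pd.read_csv(cfg.detection_initial, sep="\t", comment="#", index_col=0).iloc[:, 0]
        pf = pd.read_csv(cfg.detection_final, sep="\t", comment="#", index_col=0).iloc[:, 0]
        si, qi = booleanize_detection_call(pi, cfg.detection_threshold)
        sf, qf = booleanize_detection_call(pf, cfg.detection_threshold)
        return build_transition((si, qi), (sf, qf), list(pi.index), list(pf.index))
    raise InputError(
        "choose one Booleanization route: expression matrices + barcode "
        "params, or detection-call p-values"
    )


def _read_targets(path: str) -> list[tuple[str, str | None]]:
    out: list[tuple[str, str | None]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            out.append((parts[0], parts[1] if len(parts) > 1 else None))
    return out


def run(config: RunConfig) -> RunResult:
    """File-level entry point: parse inputs, execute, write outputs."""
    config.validate()
    if not config.signalling or not config.regulatory:
        raise InputError("signalling and regulatory network paths are required")
    signalling = default_signalling_filter(
        parse_network(config.signalling, kind="signalling")
    )
    if config.blacklist:
        signalling = apply_blacklist(signalling, parse_blacklist(config.blacklist))
    regulatory = parse_network(config.regulatory, kind="regulatory")
    transition = _load_transition(config)
    correlations = (
        read_correlations(config.correlations) if config.correlations else None
    )
    targets = _read_targets(config.targets) if config.targets else None

    result = run_data(
        signalling,
        regulatory,
        transition,
        config=config,
        correlations=correlations,
        targets=targets,
    )

    if config.out_dir:
        write_outputs(result, config, Path(config.out_dir))
    return result


def write_outputs(result: RunResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.ranking.to_tsv(out_dir / "ranking.tsv")
    result.grn.to_files(out_dir / "grn.tsv", out_dir / "grn.json")
    bpc_payload = {
        "best_score": result.bpcs.best_score,
        "flip_fraction_flag": result.bpcs.flip_fraction_flag,
        "q": {f"{p.tf}:{p.state}": v for p, v in result.bpcs.q.items()},
        "combinations": [
            {
                "combination": sorted(f"{p.tf}:{p.state}" for p in r.combination),
                "flipped": sorted(r.flipped),
                "flipping_score": r.flipping_score,
            }
            for r in result.bpcs.combinations
        ],
    }
    with open(out_dir / "bpcs.json", "w", encoding="utf-8") as fh:
        json.dump(bpc_payload, fh, indent=2, sort_keys=True)
    cfg_dict = asdict(config)
    provenance = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "flags": result.flags,
        "interface_tfs": result.interface_tfs,
        "n_candidates": len(result.ranking.candidates),
        "success": result.success,
        "random_success": result.random_success,
    }
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)


def predict_treated_state(
    grn: TransitionGRN,
    bpcs: BPCSet,
    molecule: str,
    direction: str,
    profiles: list[MoleculeProfile],
) -> tuple[dict[str, int], frozenset[str], list]:
    """GRN state expected after perturbing one molecule.

    Interface-TF-state pairs reached with positive probability by
    (molecule, direction) are collected; BPCs composed only of such pairs are
    kept, and the union of their flipped GRN-TFs is applied to the initial
    state. Returns (predicted state, flipped set, kept BPCs).
    """
    reachable: set[TFStatePair] = set()
    for prof in profiles:
        if prof.molecule == molecule and prof.direction == direction:
            reachable |= {pair for pair, p in prof.p.items() if p > 0.0}
    kept = [r for r in bpcs.combinations if set(r.combination) <= reachable]
    if not kept:
        logger.warning(
            "no BPC is fully covered by %s (%s); empty flip set", molecule, direction
        )
    flipped: set[str] = set()
    for r in kept:
        flipped |= set(r.flipped)
    state = dict(grn.s_init)
    for tf in flipped:
        state[tf] = 1 - state[tf]
    return state, frozenset(flipped), kept
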