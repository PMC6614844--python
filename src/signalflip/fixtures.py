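"""Fully synthetic, ground-truthed test cases.

Each case plants one perturbation with a known answer and emits every input
the pipeline consumes. The construction:

* the GRN splits into blocks of TFs that must flip 0 -> 1; each block is
  driven by an activating and an inhibiting interface TF whose baseline
  influences cancel (so the initial state is stable), and is internally
  connected by an activating chain;
* clamping a block's inhibiting interface TF to 0 flips exactly that block,
  so the best-performing combinations are those singleton inhibitions and Q
  is uniform over them;
* the planted molecule reaches exactly those inhibiting interface TFs
  through expressed intermediates with a consistent path sign, so one of its
  two directions matches Q almost perfectly;
* decoy molecules reach other interface-TF subsets with varied intermediate
  probabilities, populating the rest of the ranking.

Noise flips the initial Boolean expression of a fraction of non-GRN genes,
breaking expressed paths and degrading recovery.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from signalflip.errors import InputError
from signalflip.expression import (
    BarcodeParams,
    booleanize_barcode,
    build_transition,
    BooleanTransition,
)
from signalflip.network import SignedEdge, SignedNetwork

REG_MECH = "Transcriptional regulation"
SIG_MECH = "Phosphorylation"


@dataclass
class GeneratorConfig:
    n_blocks: int = 3
    block_size: int = 4
    n_sources: int = 3
    n_decoys: int = 28
    noise: float = 0.0  # fraction of non-GRN genes whose initial state flips
    max_combo_size: int = 3
    mu_range: tuple[float, float] = (3.0, 6.0)
    sigma_range: tuple[float, float] = (0.5, 1.0)
    upper: float = 15.0
    expressed_prob_range: tuple[float, float] = (0.96, 0.995)

    def validate(self) -> None:
        if self.n_sources < 1:
            raise InputError("n_sources must be >= 1 (no interface TFs otherwise)")
        if self.n_blocks < 1 or self.block_size < 1:
            raise InputError("n_blocks and block_size must be >= 1")
        if not 0.0 <= self.noise <= 1.0:
            raise InputError(f"noise must lie in [0, 1], got {self.noise}")
        if self.max_combo_size < self.n_blocks:
            raise InputError(
                "max_combo_size below n_blocks: the full transition would be "
                "unreachable by any single combination"
            )


@dataclass
class SyntheticCase:
    signalling: SignedNetwork
    regulatory: SignedNetwork
    expr_initial: pd.DataFrame
    expr_final: pd.DataFrame
    barcode: BarcodeParams
    correlations: dict[tuple[str, str], float]
    planted: tuple[str, str]  # (molecule, direction)
    truth: dict
    seed: int
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def transition(self) -> BooleanTransition:
        si, pi = booleanize_barcode(self.expr_initial, self.barcode)
        sf, pf = booleanize_barcode(self.expr_final, self.barcode)
        return build_transition(
            (si, pi), (sf, pf), list(self.expr_initial.index), list(self.expr_final.index)
        )


def value_for_probability(
    p: float, mu: float, sigma: float, upper: float
) -> float:
    """Invert the barcode mixture: a log2 value whose expression probability
    is exactly ``p`` (p = 0 maps below the uniform support)."""
    if p == 0.0:
        return mu - 2.0 * sigma
    if not 0.0 < p <= 1.0:
        raise InputError(f"probability must lie in (0, 1], got {p}")
    f_e = 1.0 / (upper - mu)
    f_n = f_e * (1.0 - p) / p
    c = f_n * sigma * np.sqrt(2.0 * np.pi)
    if c >= 1.0:
        raise InputError(f"probability {p} unreachable for mu={mu}, sigma={sigma}")
    x = mu + sigma * np.sqrt(-2.0 * np.log(c))
    if x >= upper:
        raise InputError(f"inverted value {x} exceeds the uniform support")
    return float(x)


def _sample_prob(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def generate_case(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCase:
    """Build one synthetic case; identical seeds give identical cases."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    blocks = {
        j: [f"G{j}_{i}" for i in range(cfg.block_size)] for j in range(cfg.n_blocks)
    }
    grn_tfs = [g for j in sorted(blocks) for g in blocks[j]]
    act_ifs = [f"IA{j}" for j in range(cfg.n_blocks)]
    inh_ifs = [f"II{j}" for j in range(cfg.n_blocks)]
    interface_tfs = act_ifs + inh_ifs
    sources = [f"S{k}" for k in range(cfg.n_sources)]
    planted_mol = "X0"
    planted_sign = int(rng.choice([-1, 1]))
    # positive overall sign: inhibition of X imposes state 0 on the II TFs;
    # negative: activation does
    planted_direction = "inhibition" if planted_sign == 1 else "activation"

    regulatory = SignedNetwork(kind="regulatory")
    for j in sorted(blocks):
        for g in blocks[j]:
            regulatory.add_edge(SignedEdge(act_ifs[j], g, 1, REG_MECH))
            regulatory.add_edge(SignedEdge(inh_ifs[j], g, -1, REG_MECH))
        chain = blocks[j]
        for a, b in zip(chain, chain[1:]):
            regulatory.add_edge(SignedEdge(a, b, 1, REG_MECH))

    signalling = SignedNetwork(kind="signalling")
    prob_targets: dict[str, float] = {}
    lo, hi = cfg.expressed_prob_range

    def expressed(node: str) -> None:
        if node not in prob_targets:
            prob_targets[node] = _sample_prob(rng, lo, hi)

    for s in sources:
        expressed(s)
    expressed(planted_mol)
    signalling.add_edge(SignedEdge(sources[0], planted_mol, 1, SIG_MECH))

    # planted molecule -> every block's inhibiting interface TF, overall sign
    # planted_sign on each path
    for j in range(cfg.n_blocks):
        v = f"V{j}"
        expressed(v)
        s1 = int(rng.choice([-1, 1]))
        signalling.add_edge(SignedEdge(planted_mol, v, s1, SIG_MECH))
        signalling.add_edge(SignedEdge(v, inh_ifs[j], planted_sign * s1, SIG_MECH))
        expressed(inh_ifs[j])

    # activating interface TFs hang off a different source
    for j in range(cfg.n_blocks):
        w = f"W{j}"
        expressed(w)
        src = sources[1 % len(sources)]
        signalling.add_edge(SignedEdge(src, w, 1, SIG_MECH))
        signalling.add_edge(SignedEdge(w, act_ifs[j], 1, SIG_MECH))
        expressed(act_ifs[j])

    # decoys: source -> decoy [-> intermediate] -> interface TF subset
    forbidden = {(t, planted_sign) for t in inh_ifs}
    for k in range(cfg.n_decoys):
        d = f"D{k}"
        expressed(d)
        src = sources[int(rng.integers(1, len(sources)))] if len(sources) > 1 else sources[0]
        signalling.add_edge(SignedEdge(src, d, int(rng.choice([-1, 1])), SIG_MECH))
        n_targets = int(rng.integers(1, 4))
        targets = sorted(
            rng.choice(interface_tfs, size=n_targets, replace=False).tolist()
        )
        reached: set[tuple[str, int]] = set()
        edges_planned: list[tuple[str, str, int, str | None]] = []
        for t in targets:
            sign = int(rng.choice([-1, 1]))
            if rng.random() < 0.6:  # go through a probability-bearing hop
                m = f"D{k}m{t}"
                expressed(m)
                s1 = int(rng.choice([-1, 1]))
                edges_planned.append((d, m, s1, None))
                edges_planned.append((m, t, sign * s1, None))
            else:
                edges_planned.append((d, t, sign, None))
            reached.add((t, sign))
        if reached >= forbidden:
            # never let a decoy replicate the planted molecule's full footprint
            t, _ = sorted(reached & forbidden)[0]
            edges_planned = [e for e in edges_planned if e[1] != t and not e[0].endswith(t)]
        for u, v, sign, _ in edges_planned:
            signalling.add_edge(SignedEdge(u, v, sign, SIG_MECH))

    # a few strong, sign-matching correlations on decoy edges plus weak noise
    correlations: dict[tuple[str, str], float] = {}
    signed_edges = sorted(
        (e for e in signalling.edges if e.source.startswith("D")),
        key=lambda e: (e.source, e.target),
    )
    for e in signed_edges[:3]:
        correlations[(e.source, e.target)] = 0.9 * e.sign
    all_nodes = sorted(signalling.nodes)
    for _ in range(10):
        a, b = rng.choice(all_nodes, size=2, replace=False)
        correlations.setdefault((str(a), str(b)), round(float(rng.uniform(-0.5, 0.5)), 3))

    # intended Boolean states
    state_init: dict[str, int] = {}
    state_final: dict[str, int] = {}
    for g in grn_tfs:
        state_init[g] = 0
        state_final[g] = 1
    for node in sorted(prob_targets):
        state_init.setdefault(node, 1)
        state_final.setdefault(node, 1)

    # noise: flip initial expression of a fraction of non-GRN genes
    flipped_by_noise: list[str] = []
    if cfg.noise > 0:
        eligible = sorted(set(prob_targets) - set(sources) - {planted_mol})
        for node in eligible:
            if rng.random() < cfg.noise:
                state_init[node] = 1 - state_init[node]
                flipped_by_noise.append(node)

    genes = sorted(set(grn_tfs) | set(prob_targets))
    mu = pd.Series(
        rng.uniform(*cfg.mu_range, size=len(genes)), index=genes
    ).round(4)
    sigma = pd.Series(
        rng.uniform(*cfg.sigma_range, size=len(genes)), index=genes
    ).round(4)
    barcode = BarcodeParams(mu, sigma, upper=cfg.upper)

    def matrix(states: dict[str, int]) -> pd.DataFrame:
        cols = {}
        for rep in ("rep1", "rep2"):
            vals = []
            for g in genes:
                if states.get(g, 0) == 1:
                    p = prob_targets.get(g, _sample_prob(rng, lo, hi))
                    p = min(hi, max(lo, p + float(rng.uniform(-0.002, 0.002))))
                    vals.append(
                        value_for_probability(p, mu[g], sigma[g], cfg.upper)
                    )
                else:
                    vals.append(value_for_probability(0.0, mu[g], sigma[g], cfg.upper))
            cols[rep] = vals
        return pd.DataFrame(cols, index=genes).round(6)

    expr_initial = matrix(state_init)
    expr_final = matrix(state_final)

    truth = {
        "blocks": {str(j): blocks[j] for j in sorted(blocks)},
        "grn_tfs": grn_tfs,
        "interface_tfs": interface_tfs,
        "activating_interface_tfs": act_ifs,
        "inhibiting_interface_tfs": inh_ifs,
        "sources": sources,
        "planted_molecule": planted_mol,
        "planted_direction": planted_direction,
        "planted_sign": planted_sign,
        "expected_q_support": [[t, 0] for t in inh_ifs],
        "state_initial": state_init,
        "state_final": state_final,
        "noise_flipped": flipped_by_noise,
    }
    return SyntheticCase(
        signalling=signalling,
        regulatory=regulatory,
        expr_initial=expr_initial,
        expr_final=expr_final,
        barcode=barcode,
        correlations=correlations,
        planted=(planted_mol, planted_direction),
        truth=truth,
        seed=seed,
        config=cfg,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def case_to_files(case: SyntheticCase, directory: str | Path) -> dict[str, str]:
    """Write all pipeline inputs plus the ground truth; returns a manifest of
    file name -> sha256."""
    from signalflip.network import write_network

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_network(case.signalling, directory / "signalling.tsv")
    write_network(case.regulatory, directory / "regulatory.tsv")
    case.expr_initial.rename_axis("gene").to_csv(
        directory / "expr_initial.tsv", sep="\t"
    )
    case.expr_final.rename_axis("gene").to_csv(
        directory / "expr_final.tsv", sep="\t"
    )
    case.barcode.to_tsv(directory / "barcode.tsv")
    with open(directory / "correlations.tsv", "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\tpearson_r\n")
        for (a, b), r in sorted(case.correlations.items()):
            fh.write(f"{a}\t{b}\t{r}\n")
    with open(directory / "targets.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"{case.planted[0]}\t{case.planted[1]}\n")
    truth = dict(case.truth)
    truth["seed"] = case.seed
    truth["config"] = asdict(case.config)
    with open(directory / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    manifest = {
        p.name: _sha256(p)
        for p in sorted(directory.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
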