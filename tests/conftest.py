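import io

import numpy as np
import pytest

from signalflip.grn import TransitionGRN
from signalflip.network import SignedEdge, SignedNetwork, parse_network


@pytest.fixture
def chain_net() -> SignedNetwork:
    net = SignedNetwork(kind="signalling")
    net.add_edge(SignedEdge("A", "B", 1, "Phosphorylation"))
    net.add_edge(SignedEdge("B", "C", 1, "Phosphorylation"))
    return net


def make_network(rows: str, kind: str = "signalling") -> SignedNetwork:
    """Parse an inline TSV body (whitespace-friendly helper)."""
    lines = []
    for line in rows.strip().splitlines():
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0].startswith("#") or len(tokens) < 4:
            lines.append(" ".join(tokens))
        else:  # multi-word mechanisms collapse into the third field
            lines.append(
                "\t".join([tokens[0], tokens[1], " ".join(tokens[2:-1]), tokens[-1]])
            )
    return parse_network(io.StringIO("\n".join(lines) + "\n"), kind=kind)


def random_signed_network(
    rng: np.random.Generator,
    n_nodes: int,
    n_edges: int,
    kind: str = "signalling",
    mechanism: str = "Phosphorylation",
    allow_zero_sign: bool = False,
) -> SignedNetwork:
    nodes = [f"N{i}" for i in range(n_nodes)]
    net = SignedNetwork(kind=kind)
    for n in nodes:
        net.add_node(n)
    signs = (-1, 0, 1) if allow_zero_sign else (-1, 1)
    seen = set()
    for _ in range(n_edges):
        u, v = rng.choice(nodes, size=2, replace=False)
        sign = int(rng.choice(signs))
        key = (str(u), str(v), sign)
        if key in seen:
            continue
        seen.add(key)
        net.add_edge(SignedEdge(str(u), str(v), sign, mechanism))
    return net


def random_grn(
    rng: np.random.Generator, n_tfs: int, n_edges: int
) -> TransitionGRN:
    """A random GRN with arbitrary (not necessarily attractor) states."""
    tfs = [f"T{i}" for i in range(n_tfs)]
    edges = []
    seen = set()
    for _ in range(n_edges):
        u, v = rng.choice(tfs, size=2, replace=True)
        sign = int(rng.choice([-1, 1]))
        key = (str(u), str(v), sign)
        if key in seen:
            continue
        seen.add(key)
        edges.append(SignedEdge(str(u), str(v), sign, "Transcriptional regulation"))
    s_init = {t: int(rng.integers(2)) for t in tfs}
    s_final = {t: int(rng.integers(2)) for t in tfs}
    return TransitionGRN(tfs=tfs, edges=edges, s_init=s_init, s_final=s_final)
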