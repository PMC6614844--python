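"""Validation analyses: phospho-enrichment of MPPs and topological distances.

Both analyses are supporting evidence, not part of the ranking itself:

* phospho enrichment asks whether the MPP between a perturbation target and
  an interface TF carries more differentially phosphorylated (DP) proteins
  than random simple paths between the same endpoints;
* distance analysis asks whether candidate molecules sit topologically
  closer to the known perturbation targets than non-candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from signalflip.errors import InputError
from signalflip.network import SignedNetwork
from signalflip.paths import MPPResult, ScoredGraph


@dataclass
class PathEnrichmentResult:
    source: str
    target: str
    mpp_dp_fraction: float
    random_dp_fractions: list[float]
    p_value: float | None
    verdict: str  # enriched | not_significant | no_dp_on_any_path


def _dp_fraction(path: tuple[str, ...], dp_proteins: set[str]) -> float:
    return sum(1 for n in path if n in dp_proteins) / len(path)


def sample_simple_paths(
    adj: dict[str, set[str]],
    source: str,
    target: str,
    n_paths: int,
    max_len: int,
    rng: np.random.Generator,
    max_attempts_factor: int = 50,
) -> list[tuple[str, ...]]:
    """Up to ``n_paths`` distinct simple paths (<= max_len edges) by
    randomized DFS with dead-end restarts.

    The walk picks uniformly among unvisited successors; duplicates are
    rejected. The sampler is biased towards short paths (documented caveat)
    but never returns a non-simple or overlong path.
    """
    found: set[tuple[str, ...]] = set()
    attempts = 0
    max_attempts = max_attempts_factor * n_paths
    while len(found) < n_paths and attempts < max_attempts:
        attempts += 1
        path = [source]
        visited = {source}
        while len(path) - 1 < max_len:
            choices = sorted(adj.get(path[-1], set()) - visited)
            if not choices:
                break
            nxt = choices[int(rng.integers(len(choices)))]
            path.append(nxt)
            visited.add(nxt)
            if nxt == target:
                found.add(tuple(path))
                break
    return sorted(found)


def collapse_phosphosites(
    site_lfcs: dict[str, list[float]], cutoff: float
) -> set[str]:
    """DP proteins: any site's |log fold change| at or above the cutoff.

    Helper for site-level tables; the per-protein fold change is the highest
    absolute value over its sites.
    """
    return {
        prot for prot, lfcs in site_lfcs.items() if lfcs and max(abs(x) for x in lfcs) >= cutoff
    }


def phospho_enrichment(
    graph: ScoredGraph,
    mpp: MPPResult,
    dp_proteins: set[str],
    n_random: int = 100,
    max_len: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
    test: str = "one_sample",
) -> PathEnrichmentResult:
    """Test whether the MPP is enriched in DP proteins vs random simple paths.

    One-sided (MPP fraction greater). ``test`` chooses between a one-sample
    t-test of the random-path fractions against the MPP value (default) and a
    Welch two-sample test.
    """
    rng = np.random.default_rng(seed)
    adj = {u: set(succ) for u, succ in graph.adj.items()}
    random_paths = sample_simple_paths(
        adj, mpp.source, mpp.target, n_random, max_len, rng
    )
    random_paths = [p for p in random_paths if p != mpp.path]
    if not random_paths and mpp.path is None:
        raise InputError(f"no path between {mpp.source} and {mpp.target}")

    mpp_frac = _dp_fraction(mpp.path, dp_proteins)
    random_fracs = [_dp_fraction(p, dp_proteins) for p in random_paths]

    if mpp_frac == 0.0 and all(f == 0.0 for f in random_fracs):
        return PathEnrichmentResult(
            mpp.source, mpp.target, mpp_frac, random_fracs, None, "no_dp_on_any_path"
        )
    if not random_fracs:
        return PathEnrichmentResult(
            mpp.source, mpp.target, mpp_frac, random_fracs, None,
            "enriched" if mpp_frac > 0 else "not_significant",
        )
    if test == "one_sample":
        # random-path mean below the MPP fraction -> enrichment
        res = stats.ttest_1samp(random_fracs, popmean=mpp_frac, alternative="less")
        p_value = float(res.pvalue)
    elif test == "welch":
        res = stats.ttest_ind(
            [mpp_frac], random_fracs, equal_var=False, alternative="greater"
        )
        p_value = float(res.pvalue)
    else:
        raise InputError(f"unknown test {test!r}")
    if np.isnan(p_value):  # zero variance in the random sample
        p_value = 0.0 if mpp_frac > float(np.mean(random_fracs)) else 1.0
    verdict = "enriched" if p_value < alpha else "not_significant"
    return PathEnrichmentResult(
        mpp.source, mpp.target, mpp_frac, random_fracs, p_value, verdict
    )


@dataclass
class DistanceTestResult:
    statistic: float
    p_value: float
    mean_candidate: float
    mean_non_candidate: float
    n_candidate: int
    n_non_candidate: int

    @property
    def candidates_closer(self) -> bool:
        return self.mean_candidate < self.mean_non_candidate


def _directed_distances(net: SignedNetwork) -> dict[str, dict[str, int]]:
    """All-pairs BFS hop distances over the directed edge set."""
    succ: dict[str, set[str]] = {}
    for e in net.edges:
        succ.setdefault(e.source, set()).add(e.target)
    dists: dict[str, dict[str, int]] = {}
    for start in net.nodes:
        d = {start: 0}
        frontier = [start]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in succ.get(u, ()):
                    if v not in d:
                        d[v] = depth
                        nxt.append(v)
            frontier = nxt
        dists[start] = d
    return dists


def average_target_distance(
    net: SignedNetwork, molecules: set[str], targets: set[str]
) -> dict[str, float]:
    """Mean over reachable targets of the shorter of the two directed
    distances (molecule -> target vs target -> molecule)."""
    dists = _directed_distances(net)
    out: dict[str, float] = {}
    for mol in molecules:
        per_target = []
        for t in targets:
            if t == mol:
                continue
            fwd = dists.get(mol, {}).get(t)
            rev = dists.get(t, {}).get(mol)
            best = min(d for d in (fwd, rev) if d is not None) if (
                fwd is not None or rev is not None
            ) else None
            if best is not None:
                per_target.append(best)
        if per_target:
            out[mol] = float(np.mean(per_target))
    return out


def distance_analysis(
    signalling: SignedNetwork,
    candidates: set[str],
    non_candidates: set[str],
    targets: set[str],
    n_mc: int = 100_000,
    seed: int | None = None,
) -> DistanceTestResult:
    """Rank-sum comparison of candidate vs non-candidate target distances.

    The observed Mann-Whitney U of the candidate group is compared against a
    Monte-Carlo permutation null of ``n_mc`` label shuffles; the p-value is
    one-sided (candidates closer) with the +1 continuity correction.
    """
    if candidates & non_candidates:
        raise InputError("candidate and non-candidate sets must be disjoint")
    if not targets:
        raise InputError("targets must be non-empty")
    avg = average_target_distance(
        signalling, candidates | non_candidates, targets
    )
    x = np.array([avg[m] for m in sorted(candidates) if m in avg])
    y = np.array([avg[m] for m in sorted(non_candidates) if m in avg])
    if x.size == 0 or y.size == 0:
        raise InputError("no molecule in one of the groups reaches any target")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = float(ranks[: x.size].sum())  # small rank-sum = candidates closer
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled.size)
        if ranks[perm[: x.size]].sum() <= obs:
            count += 1
    p_value = (count + 1) / (n_mc + 1)
    return DistanceTestResult(
        statistic=obs,
        p_value=p_value,
        mean_candidate=float(x.mean()),
        mean_non_candidate=float(y.mean()),
        n_candidate=int(x.size),
        n_non_candidate=int(y.size),
    )
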