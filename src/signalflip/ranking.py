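"""Jensen-Shannon ranking of candidate signalling molecules.

Every molecule enters the ranking twice, once for its activation and once for
its inhibition; each entry's JSD against the BPC-derived distribution Q is
computed for both scoring variants, ranked ascending (competition ranking),
and aggregated by the minimum rank R. Candidates are entries with
R < cutoff_fraction * max(R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import rankdata

from signalflip.errors import InputError, ParameterError
from signalflip.paths import MoleculeProfile
from signalflip.perturb import TFStatePair

CUTOFF_FRACTION = 0.06

Entry = tuple[str, str]  # (molecule, direction)


@dataclass
class CandidateRanking:
    """Per-(molecule, direction) JSD scores, ranks, and the candidate set."""

    jsd: dict[str, dict[Entry, float]] = field(default_factory=dict)  # variant -> entry -> jsd
    ranks: dict[str, dict[Entry, int]] = field(default_factory=dict)
    r: dict[Entry, int] = field(default_factory=dict)
    candidates: list[Entry] = field(default_factory=list)
    cutoff_fraction: float = CUTOFF_FRACTION

    def to_tsv(self, path: str | Path) -> None:
        candidate_set = set(self.candidates)
        entries = sorted(self.r, key=lambda e: (self.r[e], e))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "molecule\tdirection\tjsd_corr\tjsd_len\trank_corr\trank_len\tR\tcandidate\n"
            )
            for entry in entries:
                mol, direction = entry
                jc = self.jsd.get("correlation", {}).get(entry)
                jl = self.jsd.get("length", {}).get(entry)
                rc = self.ranks.get("correlation", {}).get(entry)
                rl = self.ranks.get("length", {}).get(entry)
                fh.write(
                    f"{mol}\t{direction}\t"
                    f"{'' if jc is None else format(jc, '.12g')}\t"
                    f"{'' if jl is None else format(jl, '.12g')}\t"
                    f"{'' if rc is None else rc}\t"
                    f"{'' if rl is None else rl}\t"
                    f"{self.r[entry]}\t{int(entry in candidate_set)}\n"
                )


def jsd(p: Mapping, q: Mapping, atol: float = 1e-9) -> float:
    """Jensen-Shannon divergence in nats over the union support.

    JSD(p||q) = 0.5 D(p||m) + 0.5 D(q||m), m = (p+q)/2, with 0 log(0/x) = 0.
    Bounded by ln 2; zero iff the distributions coincide.
    """
    sp, sq = sum(p.values()), sum(q.values())
    if abs(sp - 1.0) > atol or abs(sq - 1.0) > atol:
        raise ParameterError(
            f"distributions must sum to 1 (got {sp!r} and {sq!r})"
        )
    support = set(p) | set(q)
    total = 0.0
    for key in support:
        pi = p.get(key, 0.0)
        qi = q.get(key, 0.0)
        mi = 0.5 * (pi + qi)
        if pi > 0.0:
            total += 0.5 * pi * math.log(pi / mi)
        if qi > 0.0:
            total += 0.5 * qi * math.log(qi / mi)
    return max(0.0, total)


def jsd_profiles(
    profiles: Iterable[MoleculeProfile], q: Mapping[TFStatePair, float]
) -> dict[Entry, float]:
    """JSD of every non-empty profile of one variant against Q."""
    out: dict[Entry, float] = {}
    for prof in profiles:
        if prof.empty:
            continue
        out[(prof.molecule, prof.direction)] = jsd(prof.p, q)
    return out


def rank_variant(jsds: Mapping[Entry, float]) -> dict[Entry, int]:
    """Competition ranking of JSDs ascending; ties share the minimum rank."""
    entries = sorted(jsds)
    values = [jsds[e] for e in entries]
    ranks = rankdata(values, method="min")
    return {e: int(r) for e, r in zip(entries, ranks)}


def aggregate_ranks(
    rank_correlation: Mapping[Entry, int], rank_length: Mapping[Entry, int]
) -> dict[Entry, int]:
    """R = minimum rank across the two variants; single-variant entries keep
    their only rank."""
    out: dict[Entry, int] = {}
    for entry in set(rank_correlation) | set(rank_length):
        rs = [
            m[entry] for m in (rank_correlation, rank_length) if entry in m
        ]
        out[entry] = min(rs)
    return out


def select_candidates(
    r: Mapping[Entry, int], cutoff_fraction: float = CUTOFF_FRACTION
) -> list[Entry]:
    """Entries whose R is strictly below cutoff_fraction * max(R)."""
    if not r:
        return []
    if not 0.0 < cutoff_fraction < 1.0:
        raise ParameterError(
            f"cutoff_fraction must lie in (0, 1), got {cutoff_fraction}"
        )
    threshold = cutoff_fraction * max(r.values())
    return sorted(e for e, rank in r.items() if rank < threshold)


def build_ranking(
    profiles_by_variant: Mapping[str, Iterable[MoleculeProfile]],
    q: Mapping[TFStatePair, float],
    cutoff_fraction: float = CUTOFF_FRACTION,
) -> CandidateRanking:
    """Full ranking: JSDs per variant, competition ranks, R, candidates."""
    ranking = CandidateRanking(cutoff_fraction=cutoff_fraction)
    for variant, profiles in profiles_by_variant.items():
        ranking.jsd[variant] = jsd_profiles(profiles, q)
        ranking.ranks[variant] = rank_variant(ranking.jsd[variant])
    ranking.r = aggregate_ranks(
        ranking.ranks.get("correlation", {}), ranking.ranks.get("length", {})
    )
    ranking.candidates = select_candidates(ranking.r, cutoff_fraction)
    return ranking


def evaluate_success(
    candidates: Iterable[Entry],
    targets: Iterable[tuple[str, str | None]] | Iterable[str],
    sign_aware: bool = False,
) -> bool:
    """True iff any known perturbation target appears among the candidates.

    ``targets`` holds molecule ids or (molecule, direction) pairs; direction
    is only enforced when ``sign_aware`` is set and the target carries one.
    """
    normalized: list[tuple[str, str | None]] = []
    for t in targets:
        if isinstance(t, str):
            normalized.append((t, None))
        else:
            mol, direction = t
            normalized.append((mol, direction))
    if not normalized:
        raise InputError("targets must be non-empty")
    cand = list(candidates)
    cand_molecules = {mol for mol, _ in cand}
    cand_set = set(cand)
    for mol, direction in normalized:
        if sign_aware and direction is not None:
            if (mol, direction) in cand_set:
                return True
        elif mol in cand_molecules:
            return True
    return False


def random_success_probability(
    n_universe: int, n_targets: int, n_selected: int
) -> float:
    """P(a uniform random size-n subset contains >= 1 of K targets).

    Exact hypergeometric tail: 1 - C(N-K, n) / C(N, n).
    """
    if not 0 < n_targets <= n_universe:
        raise ParameterError(
            f"need 0 < n_targets <= n_universe, got {n_targets}, {n_universe}"
        )
    if not 0 <= n_selected <= n_universe:
        raise ParameterError(
            f"need 0 <= n_selected <= n_universe, got {n_selected}"
        )
    if n_selected > n_universe - n_targets:
        return 1.0
    none = math.comb(n_universe - n_targets, n_selected) / math.comb(
        n_universe, n_selected
    )
    return 1.0 - none
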