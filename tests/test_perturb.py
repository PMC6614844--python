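import itertools

import numpy as np
import pytest

from signalflip.errors import InputError
from signalflip.expression import BooleanTransition
from signalflip.grn import TransitionGRN
from signalflip.network import SignedEdge, SignedNetwork
from signalflip.perturb import (
    PerturbationResult,
    TFStatePair,
    allowed_tf_states,
    compute_q,
    enumerate_combinations,
    identify_interface_tfs,
    select_bpcs,
    simulate_clamped,
    synergy_filter,
)

from conftest import random_grn

REG = "Transcriptional regulation"
SIG = "Phosphorylation"


def transition_of(states_init, states_final=None, probs=None):
    genes = sorted(states_init)
    states_final = states_final or states_init
    si = np.array([states_init[g] for g in genes])
    sf = np.array([states_final.get(g, states_init[g]) for g in genes])
    p = np.array([(probs or {}).get(g, 0.99 if states_init[g] else 0.01) for g in genes])
    pf = np.array([(probs or {}).get(g, 0.99 if sf[i] else 0.01) for i, g in enumerate(genes)])
    return BooleanTransition(genes, si, sf, p, pf)


def simple_grn():
    return TransitionGRN(
        tfs=["g1", "g2"],
        edges=[SignedEdge("g1", "g2", 1, REG)],
        s_init={"g1": 0, "g2": 0},
        s_final={"g1": 1, "g2": 1},
    )


class TestIdentifyInterfaceTFs:
    def _nets(self):
        sig = SignedNetwork(kind="signalling")
        sig.add_edge(SignedEdge("S", "m", 1, SIG))
        sig.add_edge(SignedEdge("m", "t", 1, SIG))
        reg = SignedNetwork(kind="regulatory")
        reg.add_edge(SignedEdge("t", "g1", 1, REG))
        return sig, reg

    def test_all_conditions_met(self):
        sig, reg = self._nets()
        tr = transition_of({"S": 1, "m": 1, "t": 1, "g1": 0}, {"g1": 1})
        assert identify_interface_tfs(sig, reg, simple_grn(), tr) == ["t"]

    def test_not_expressed_excluded(self):
        sig, reg = self._nets()
        tr = transition_of({"S": 1, "m": 1, "t": 0}, {"t": 1})
        assert identify_interface_tfs(sig, reg, simple_grn(), tr) == []

    def test_unexpressed_intermediate_blocks_path(self):
        sig, reg = self._nets()
        tr = transition_of({"S": 1, "m": 0, "t": 1}, {"m": 1})
        assert identify_interface_tfs(sig, reg, simple_grn(), tr) == []

    def test_unmeasured_nodes_treated_as_expressed(self):
        sig, reg = self._nets()
        tr = transition_of({"t": 1})  # S and m unmeasured
        assert identify_interface_tfs(sig, reg, simple_grn(), tr) == ["t"]

    def test_non_regulator_excluded(self):
        sig, reg = self._nets()
        sig.add_edge(SignedEdge("S", "other", 1, SIG))
        tr = transition_of({"S": 1, "m": 1, "t": 1, "other": 1})
        assert "other" not in identify_interface_tfs(sig, reg, simple_grn(), tr)


class TestSimulateClamped:
    def test_noop_clamp_in_edgeless_grn(self):
        grn = TransitionGRN(
            tfs=["g"], edges=[], s_init={"g": 0}, s_final={"g": 1}
        )
        res = simulate_clamped(grn, {"g": 0}, [TFStatePair("I", 1)], {"I": 1})
        assert res.converged and res.flipping_score == 0

    def test_interface_cascade(self):
        # spec example: I -> A -> B, clamping I=1 flips both
        grn = TransitionGRN(
            tfs=["A", "B"],
            edges=[SignedEdge("A", "B", 1, REG)],
            s_init={"A": 0, "B": 0},
            s_final={"A": 1, "B": 1},
        )
        iface = [SignedEdge("I", "A", 1, REG)]
        res = simulate_clamped(
            grn, {"A": 0, "B": 0}, [TFStatePair("I", 1)], {"I": 0}, iface
        )
        assert res.converged
        assert res.flipped == frozenset({"A", "B"}) and res.flipping_score == 2

    def test_oscillation_detected(self):
        # clamped activation vs doubled mutual inhibition: (0,0) <-> (1,1)
        grn = TransitionGRN(
            tfs=["A", "B"],
            edges=[
                SignedEdge("A", "B", -1, "m1"),
                SignedEdge("A", "B", -1, "m2"),
                SignedEdge("B", "A", -1, "m1"),
                SignedEdge("B", "A", -1, "m2"),
            ],
            s_init={"A": 0, "B": 0},
            s_final={"A": 1, "B": 1},
        )
        iface = [SignedEdge("I", "A", 1, "m1"), SignedEdge("I", "B", 1, "m1")]
        res = simulate_clamped(
            grn, {"A": 0, "B": 0}, [TFStatePair("I", 1)], {"I": 0}, iface
        )
        assert not res.converged and res.flipping_score == -1

    def test_conflicting_clamp_errors(self):
        grn = simple_grn()
        with pytest.raises(InputError):
            simulate_clamped(
                grn, grn.s_init, [TFStatePair("I", 0), TFStatePair("I", 1)], {}
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_state_space_enumeration(self, seed):
        """Oracle: full 2^n successor table, trajectory followed explicitly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        grn = random_grn(rng, n, int(rng.integers(1, 14)))
        clamp_tfs = rng.choice(grn.tfs, size=int(rng.integers(0, n)), replace=False)
        combo = [TFStatePair(str(t), int(rng.integers(2))) for t in clamp_tfs]
        clamped = {p.tf: p.state for p in combo}

        regs = grn.regulators

        def step(state):
            out = {}
            for t in grn.tfs:
                if t in clamped:
                    out[t] = clamped[t]
                    continue
                a = sum(1 for e in regs[t] if e.sign == 1 and state[e.source] == 1)
                i = sum(1 for e in regs[t] if e.sign == -1 and state[e.source] == 1)
                out[t] = 1 if a > i else (0 if a < i else state[t])
            return out

        # oracle: successor of every one of the 2^n states
        table = {}
        for bits in itertools.product((0, 1), repeat=n):
            st = dict(zip(grn.tfs, bits))
            st.update(clamped)
            table[tuple(st[t] for t in grn.tfs)] = step(st)
        start = dict(grn.s_init)
        start.update(clamped)
        seen, cur = [], start
        while tuple(cur[t] for t in grn.tfs) not in [
            tuple(s[t] for t in grn.tfs) for s in seen
        ]:
            seen.append(cur)
            cur = table[tuple(cur[t] for t in grn.tfs)]
        converged = cur == seen[-1]
        res = simulate_clamped(grn, grn.s_init, combo, {}, [], max_steps=1000)
        assert res.converged == converged
        if converged:
            expected = frozenset(t for t in grn.tfs if cur[t] != grn.s_init[t])
            assert res.flipped == expected


class TestEnumerate:
    def test_two_tfs_size_one(self):
        allowed = {"A": (0, 1), "B": (0, 1)}
        combos = list(enumerate_combinations(["A", "B"], allowed, max_size=1))
        assert len(combos) == 4

    def test_two_tfs_size_two(self):
        allowed = {"A": (0, 1), "B": (0, 1)}
        combos = list(enumerate_combinations(["A", "B"], allowed, max_size=2))
        assert len(combos) == 8  # 4 singletons + 4 pairs

    def test_differential_tf_single_state(self):
        tr = transition_of({"A": 0}, {"A": 1})
        allowed = allowed_tf_states(["A"], tr)
        combos = list(enumerate_combinations(["A"], allowed))
        assert combos == [frozenset({TFStatePair("A", 1)})]

    def test_differential_both_mode(self):
        tr = transition_of({"A": 0}, {"A": 1})
        allowed = allowed_tf_states(["A"], tr, differential_tf_states="both")
        assert allowed["A"] == (0, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        tfs = [f"T{i}" for i in range(n)]
        allowed = {
            t: ((0, 1) if rng.random() < 0.5 else (int(rng.integers(2)),))
            for t in tfs
        }
        max_size = int(rng.integers(1, 5))
        got = list(enumerate_combinations(tfs, allowed, max_size))
        expected = 0
        for k in range(1, max_size + 1):
            for subset in itertools.combinations(tfs, k):
                prod = 1
                for t in subset:
                    prod *= len(allowed[t])
                expected += prod
        assert len(got) == expected
        assert len(set(got)) == len(got)  # no duplicates


def result_of(pairs, flipped, score=None):
    combo = frozenset(TFStatePair(t, s) for t, s in pairs)
    fl = frozenset(flipped)
    return PerturbationResult(combo, fl, len(fl) if score is None else score, True)


class TestSelectBPCs:
    def test_top_three_distinct_scores(self):
        results = [
            result_of([(f"T{i}", 1)], [f"g{j}" for j in range(s)])
            for i, s in enumerate([5, 5, 4, 3, 2])
        ]
        bpcs = select_bpcs(results, n_grn_tfs=10)
        assert sorted(r.flipping_score for r in bpcs.combinations) == [3, 4, 5, 5]

    def test_all_equal_scores_all_kept(self):
        results = [result_of([(f"T{i}", 1)], ["g1", "g2"]) for i in range(4)]
        bpcs = select_bpcs(results, n_grn_tfs=4)
        assert len(bpcs.combinations) == 4

    def test_flip_fraction_flag(self):
        results = [result_of([("T0", 1)], [f"g{j}" for j in range(7)])]
        bpcs = select_bpcs(results, n_grn_tfs=20)
        assert bpcs.flip_fraction_flag  # 7 < 0.4 * 20

    def test_no_flag_at_boundary(self):
        results = [result_of([("T0", 1)], [f"g{j}" for j in range(8)])]
        bpcs = select_bpcs(results, n_grn_tfs=20)
        assert not bpcs.flip_fraction_flag  # 8 >= 0.4 * 20

    def test_empty_results_error(self):
        with pytest.raises(InputError):
            select_bpcs([], n_grn_tfs=5)

    def test_non_converged_excluded(self):
        bad = PerturbationResult(
            frozenset({TFStatePair("T0", 1)}), frozenset(), -1, False
        )
        good = result_of([("T1", 1)], ["g1"])
        bpcs = select_bpcs([bad, good], n_grn_tfs=2)
        assert bpcs.combinations == [good]


class TestSynergyFilter:
    def test_union_equality_removed(self):
        singles = {
            TFStatePair("A", 1): frozenset({"x"}),
            TFStatePair("B", 1): frozenset({"y"}),
        }
        combo = result_of([("A", 1), ("B", 1)], ["x", "y"])
        assert synergy_filter([combo], singles) == []

    def test_strict_superset_kept(self):
        singles = {
            TFStatePair("A", 1): frozenset({"x"}),
            TFStatePair("B", 1): frozenset({"y"}),
        }
        combo = result_of([("A", 1), ("B", 1)], ["x", "y", "z"])
        assert synergy_filter([combo], singles) == [combo]

    def test_singletons_unconditionally_kept(self):
        single = result_of([("A", 1)], ["x"])
        assert synergy_filter([single], {}) == [single]

    def test_missing_singleton_errors(self):
        combo = result_of([("A", 1), ("B", 1)], ["x"])
        with pytest.raises(InputError):
            synergy_filter([combo], {TFStatePair("A", 1): frozenset()})


class TestComputeQ:
    def test_two_bpcs_example(self):
        bpcs = [
            result_of([("A", 1)], ["x"]),
            result_of([("A", 1), ("B", 0)], ["x", "y", "z"]),
        ]
        q = compute_q(bpcs)
        assert q[TFStatePair("A", 1)] == pytest.approx(2 / 3)
        assert q[TFStatePair("B", 0)] == pytest.approx(1 / 3)

    def test_single_bpc(self):
        q = compute_q([result_of([("A", 1)], ["x"])])
        assert q == {TFStatePair("A", 1): 1.0}

    def test_absent_pairs_have_no_mass(self):
        q = compute_q([result_of([("A", 1)], ["x"])])
        assert TFStatePair("B", 0) not in q

    def test_empty_errors(self):
        with pytest.raises(InputError):
            compute_q([])

    @pytest.mark.parametrize("seed", range(10))
    def test_q_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        bpcs = []
        for _ in range(int(rng.integers(1, 10))):
            k = int(rng.integers(1, 5))
            tfs = rng.choice([f"T{i}" for i in range(6)], size=k, replace=False)
            bpcs.append(
                result_of([(str(t), int(rng.integers(2))) for t in tfs], ["g"])
            )
        assert sum(compute_q(bpcs).values()) == pytest.approx(1.0, abs=1e-12)
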