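"""Structure learning: scores, constrained search, SEM, bootstrap averaging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import bnrisk as b
from bnrisk.structure import average_arcs


def _table(columns: dict, specs=None) -> b.CohortTable:
    names = list(columns)
    if specs is None:
        specs = [b.VariableSpec(n, tuple(sorted(set(columns[n]))), tier=1)
                 for n in names]
    return b.CohortTable(pd.DataFrame(columns), specs)


def _binary_table(arrays: dict) -> b.CohortTable:
    cols = {n: np.where(np.asarray(v) > 0, "1", "0") for n, v in arrays.items()}
    specs = [b.VariableSpec(n, ("0", "1"), tier=1) for n in cols]
    return b.CohortTable(pd.DataFrame(cols), specs)


def _all_dags(nodes):
    """Every DAG over the given nodes (exhaustive oracle)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(2 ** len(pairs)):
        arcs = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        try:
            yield b.Dag(nodes, arcs)
        except ValueError:
            continue


class TestDag:
    def test_cycles_rejected(self):
        d = b.Dag("abc", [("a", "b"), ("b", "c")])
        with pytest.raises(ValueError, match="cycle"):
            d.add_arc("c", "a")

    def test_duplicate_and_self_loop_rejected(self):
        d = b.Dag("ab", [("a", "b")])
        with pytest.raises(ValueError, match="duplicate"):
            d.add_arc("a", "b")
        with pytest.raises(ValueError, match="cycle"):
            d.add_arc("a", "a")

    def test_topological_order_respects_arcs(self):
        d = b.Dag("abcd", [("a", "b"), ("b", "c"), ("a", "d")])
        order = d.topological_order()
        for u, v in d.arcs:
            assert order.index(u) < order.index(v)

    def test_reversal_creating_cycle_errors(self):
        # reversing a->b adds b->a, closing the cycle b->a->c->b
        d = b.Dag("abc", [("a", "b"), ("a", "c"), ("c", "b")])
        with pytest.raises(ValueError, match="cycle"):
            d.reverse_arc("a", "b")
        assert d.has_arc("a", "b")  # restored

    def test_edge_list_roundtrip(self, tmp_path):
        d = b.Dag("abc", [("a", "b"), ("b", "c")])
        d.to_edge_list(tmp_path / "d.txt")
        assert b.Dag.from_edge_list(tmp_path / "d.txt", "abc") == d


class TestTierBlacklist:
    def test_brute_force_enumeration(self, dictionary):
        """The blacklist equals rule-by-rule enumeration of all ordered pairs."""
        cons = b.tier_blacklist(dictionary)
        tiers = {v.name: v.tier for v in dictionary}
        background = {v.name for v in dictionary if v.role == "background"}
        expected = {(u, v) for u in tiers for v in tiers if u != v
                    and (v in background or tiers[u] > tiers[v])}
        assert cons.blacklist == expected
        assert ("diabetes", "ifg") in cons.blacklist
        assert ("ifg", "diabetes") not in cons.blacklist

    def test_same_tier_unconstrained(self):
        specs = [b.VariableSpec("a", ("0", "1"), tier=1),
                 b.VariableSpec("b", ("0", "1"), tier=1)]
        cons = b.tier_blacklist(specs)
        assert cons.blacklist == set()

    def test_whitelist_blacklist_disjoint_enforced(self):
        with pytest.raises(ValueError, match="required and forbidden"):
            b.ArcConstraintSet(blacklist={("a", "b")}, whitelist={("a", "b")})

    def test_cyclic_whitelist_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            b.ArcConstraintSet(whitelist={("a", "b"), ("b", "a")})


class TestScore:
    def test_uniform_independent_closed_form(self):
        """Empty DAG on p balanced binary columns: loglik = -n*p*log2 exactly
        (each column split 50/50), penalty = p * log(n)/2."""
        n = 400
        cols = {f"v{i}": ["0", "1"] * (n // 2) for i in range(3)}
        t = _table(cols)
        got = b.score(b.Dag(t.variable_names), t)
        expected = -n * 3 * math.log(2) - 3 * 0.5 * math.log(n)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dependence_beats_independence(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 100)
        t = _binary_table({"a": a, "b": a})  # b copies a
        s_arc = b.score(b.Dag(["a", "b"], [("a", "b")]), t)
        s_empty = b.score(b.Dag(["a", "b"]), t)
        assert s_arc > s_empty

    def test_decomposability(self, cohort_4k):
        """Whole-graph score equals the sum of per-family contributions."""
        dag = b.Dag(cohort_4k.variable_names,
                    [("hypertension", "diabetes"), ("ifg", "diabetes"),
                     ("wc", "ifg")])
        whole = b.score(dag, cohort_4k)
        from bnrisk.structure import _Scorer
        cols = list(dag.nodes)
        sc = _Scorer(cohort_4k.codes(cols), cohort_4k.cardinalities(cols))
        pos = {n: i for i, n in enumerate(cols)}
        parts = sum(sc.family(pos[v], tuple(pos[p] for p in dag.parents(v)))
                    for v in cols)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_zero_row_data_rejected(self):
        t = _table({"a": []}, [b.VariableSpec("a", ("0", "1"), tier=1)])
        with pytest.raises(ValueError, match="zero-row"):
            b.score(b.Dag(["a"]), t)


class TestHillClimb:
    def test_two_node_strong_dependence_matches_exhaustive_max(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 1000)
        flip = rng.random(1000) < 0.05
        t = _binary_table({"a": a, "b": np.where(flip, 1 - a, a)})
        learned = b.hill_climb(t)
        best = max(_all_dags(["a", "b"]), key=lambda d: b.score(d, t))
        assert len(learned.arcs) == 1
        assert b.score(learned, t) == pytest.approx(b.score(best, t))

    def test_whitelist_kept_on_independent_data(self):
        rng = np.random.default_rng(2)
        t = _binary_table({"a": rng.integers(0, 2, 500),
                           "b": rng.integers(0, 2, 500)})
        cons = b.ArcConstraintSet(whitelist={("a", "b")})
        assert b.hill_climb(t, cons).has_arc("a", "b")

    def test_blacklist_everything_gives_empty_graph(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 500)
        t = _binary_table({"a": a, "b": a})
        cons = b.ArcConstraintSet(blacklist={("a", "b"), ("b", "a")})
        assert b.hill_climb(t, cons).arcs == []

    def test_three_node_global_optimum_rate(self):
        """On complete 3-node data the greedy search should land on the
        exhaustive-maximum score in at least 95 of 100 seeded datasets."""
        hits = 0
        dags = list(_all_dags(["a", "b", "c"]))
        assert len(dags) == 25
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 400
            a = rng.integers(0, 2, n)
            pb = np.where(a == 1, 0.8, 0.3)
            bb = (rng.random(n) < pb).astype(int)
            pc = np.where(bb == 1, 0.7, 0.2)
            c = (rng.random(n) < pc).astype(int)
            t = _binary_table({"a": a, "b": bb, "c": c})
            best = max(b.score(d, t) for d in dags)
            if b.score(b.hill_climb(t), t) >= best - 1e-9:
                hits += 1
        assert hits >= 95

    def test_constraints_never_violated(self, cohort_4k):
        cons = b.gbcs_constraints(cohort_4k.variables)
        dag = b.hill_climb(cohort_4k, cons)
        assert not set(dag.arcs) & cons.blacklist
        assert cons.whitelist <= set(dag.arcs)
        dag.topological_order()  # acyclic

    def test_missing_data_rejected(self, fixture):
        t = b.sample_cohort(fixture, n=200, seed=0)
        with pytest.raises(ValueError, match="complete"):
            b.hill_climb(t)


class TestStructuralEM:
    def test_complete_data_equals_hill_climb(self, cohort_4k):
        cons = b.gbcs_constraints(cohort_4k.variables)
        sub = cohort_4k.iloc_rows(np.arange(1500))
        res = b.structural_em(sub, cons, seed=0)
        assert res.dag == b.hill_climb(sub, cons)
        assert res.converged

    def test_single_node_em_fixed_point(self):
        """One binary variable, 50% MCAR: completed frequency approaches the
        observed-data frequency (the EM fixed point), true P(yes)=0.7."""
        rng = np.random.default_rng(4)
        n = 2000
        vals = np.where(rng.random(n) < 0.7, "yes", "no").astype(object)
        vals[rng.random(n) < 0.5] = pd.NA
        t = b.CohortTable(pd.DataFrame({"a": vals}),
                          [b.VariableSpec("a", ("no", "yes"), tier=1)])
        res = b.structural_em(t, seed=1)
        freq = (res.completed.data["a"] == "yes").mean()
        assert abs(freq - 0.7) < 0.05

    def test_chain_skeleton_recovery_under_mcar(self):
        """3-node chain with 5% MCAR: generating skeleton recovered in >=90%
        of 50 seeded replicates."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n = 1200
            a = rng.integers(0, 2, n)
            bb = (rng.random(n) < np.where(a == 1, 0.85, 0.15)).astype(int)
            c = (rng.random(n) < np.where(bb == 1, 0.85, 0.15)).astype(int)
            df = pd.DataFrame({k: np.where(v == 1, "1", "0").astype(object)
                               for k, v in {"a": a, "b": bb, "c": c}.items()})
            for col in df:
                df.loc[rng.random(n) < 0.05, col] = pd.NA
            t = b.CohortTable(df, [b.VariableSpec(k, ("0", "1"), tier=1)
                                   for k in "abc"])
            res = b.structural_em(t, seed=seed)
            skel = {frozenset(arc) for arc in res.dag.arcs}
            if skel == {frozenset(("a", "b")), frozenset(("b", "c"))}:
                hits += 1
        assert hits >= 45


class TestBootstrapAverage:
    def test_single_resample_returns_single_dag(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, 800)
        t = _binary_table({"a": a, "b": a})
        dag, strengths = b.bootstrap_average(t, B=1, threshold=0.5, seed=0)
        assert strengths.B == 1
        assert len(dag.arcs) == 1
        assert strengths.table["strength"].iloc[0] == 1.0

    def test_threshold_is_strictly_greater(self):
        nodes = ["a", "b", "c"]
        dags = ([b.Dag(nodes, [("a", "b"), ("b", "c")])] * 11
                + [b.Dag(nodes, [("a", "b")])] * 9)
        avg, st = average_arcs(nodes, dags, threshold=0.6)
        assert st.strength("a", "b") == 1.0
        assert st.strength("b", "c") == pytest.approx(0.55)
        assert avg.arcs == [("a", "b")]  # 0.55 <= 0.6 dropped

    def test_hand_built_frequency(self):
        nodes = ["a", "b"]
        dags = [b.Dag(nodes, [("a", "b")]), b.Dag(nodes, [("a", "b")]),
                b.Dag(nodes), b.Dag(nodes)]
        avg, st = average_arcs(nodes, dags, threshold=0.6)
        assert st.strength("a", "b") == 0.5
        assert avg.arcs == []

    def test_direction_conflict_resolved_by_frequency(self):
        nodes = ["a", "b"]
        dags = ([b.Dag(nodes, [("a", "b")])] * 7 + [b.Dag(nodes, [("b", "a")])] * 3)
        avg, _ = average_arcs(nodes, dags, threshold=0.2)
        assert avg.arcs == [("a", "b")]

    def test_direction_tie_drops_edge(self):
        nodes = ["a", "b"]
        dags = [b.Dag(nodes, [("a", "b")]), b.Dag(nodes, [("b", "a")])]
        avg, _ = average_arcs(nodes, dags, threshold=0.3)
        assert avg.arcs == []


class TestCuratedEdits:
    def test_packaged_edit_list_removes_and_reverses(self):
        nodes = ["diabetes", "tg", "lipid_lowering_drugs", "age", "family_history"]
        dag = b.Dag(nodes, [("diabetes", "tg"), ("lipid_lowering_drugs", "tg"),
                            ("age", "family_history")])
        out = b.apply_curated_edits(dag, b.GBCS_EDITS)
        assert not out.has_arc("diabetes", "tg")
        assert not out.has_arc("age", "family_history")
        assert out.has_arc("tg", "lipid_lowering_drugs")

    def test_empty_edit_list_is_identity(self, cohort_4k):
        dag = b.Dag(cohort_4k.variable_names, [("hypertension", "diabetes")])
        assert b.apply_curated_edits(dag, b.CuratedEditList()) == dag

    def test_absent_removal_warns_and_skips(self, caplog):
        dag = b.Dag(["a", "diabetes", "tg"], [])
        with caplog.at_level("WARNING"):
            out = b.apply_curated_edits(
                dag, b.CuratedEditList(removals=[("diabetes", "tg")]))
        assert out == dag
        assert "not present" in caplog.text

    def test_reversal_creating_cycle_errors(self):
        dag = b.Dag("abc", [("a", "b"), ("a", "c"), ("c", "b")])
        with pytest.raises(ValueError, match="cycle"):
            b.apply_curated_edits(dag, b.CuratedEditList(reversals=[("a", "b")]))
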