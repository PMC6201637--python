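"""Hierarchy construction, TRE, the randomisation filter, gTRE and ranking."""

import numpy as np
import pandas as pd
import pytest

import regutarget as rt
from conftest import split_tr_edges
from oracles import naive_significance_q, path_enumeration_gtre


def edges(*triples):
    return [rt.RegulatoryInteraction(u, v, 1, nrs=w) for u, v, w in triples]


class TestBuildHierarchy:
    def test_isolated_tr_is_top_level(self):
        h = rt.build_hierarchy(edges(("t1", "g_x", 1.0)))  # no TR->TR edges
        # both endpoints become nodes; with no retained incoming edges
        assert h.level["t1"] == 1

    def test_chain_levels_by_longest_path(self):
        h = rt.build_hierarchy(edges(("t1", "t2", 1.0), ("t2", "t3", 1.0)))
        assert (h.level["t1"], h.level["t2"], h.level["t3"]) == (1, 2, 3)
        assert h.h == 3

    def test_diamond_uses_longest_not_shortest_path(self):
        h = rt.build_hierarchy(
            edges(("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0))
        )
        assert h.level["c"] == 3  # a->b->c is longer than a->c

    def test_two_cycle_edges_excluded_nodes_kept(self):
        h = rt.build_hierarchy(
            edges(("t1", "t2", 1.0), ("t2", "t1", 1.0), ("t1", "t3", 1.0))
        )
        assert {(u, v) for u, v, _ in h.excluded_edges if _ == "cycle"} == {
            ("t1", "t2"), ("t2", "t1"),
        }
        assert h.level == {"t1": 1, "t2": 1, "t3": 2}
        assert h.h == 2

    def test_retained_edges_point_strictly_downward(self, toy_scored_interactions):
        _, tr_edges = split_tr_edges(toy_scored_interactions)
        h = rt.build_hierarchy(tr_edges)
        for u, v, _ in h.retained_edges:
            assert h.level[v] >= h.level[u] + 1

    def test_empty_input_is_valid(self):
        h = rt.build_hierarchy([])
        assert h.h == 0 and h.level == {} and h.retained_edges == []

    def test_toy_levels_match_planted_hierarchy(self, toy, toy_scored_interactions):
        _, tr_edges = split_tr_edges(toy_scored_interactions)
        h = rt.build_hierarchy(tr_edges)
        assert h.level == toy.ground_truth["levels"]
        assert h.h == toy.ground_truth["h"]


class TestComputeTRE:
    def test_single_term_product(self):
        gap = rt.GAPTable(
            table=pd.DataFrame(
                {"gene": ["g"], "reaction_id": ["r"], "gprf": [2.0], "ngap": [0.5]}
            )
        )
        tre = rt.compute_tre(gap, edges(("T", "g", 2.0)))
        assert tre["T"] == pytest.approx(1.0)

    def test_tr_with_only_zero_scored_genes(self):
        gap = rt.GAPTable(
            table=pd.DataFrame(
                {"gene": ["g"], "reaction_id": ["r"], "gprf": [1.0], "ngap": [0.0]}
            )
        )
        tre = rt.compute_tre(gap, edges(("T", "g", 3.0)))
        assert tre["T"] == 0.0

    def test_tr_without_measured_targets_scores_zero(self, toy_gap):
        tre = rt.compute_tre(toy_gap, [], tr_ids=["lonely"])
        assert tre["lonely"] == 0.0

    def test_toy_tre_matches_hand_summed_values(self, toy_gap, toy_scored_interactions):
        gene_edges, _ = split_tr_edges(toy_scored_interactions)
        tre = rt.compute_tre(toy_gap, gene_edges)
        # hand sums over the planted regulons (slopes +-5, complex factor 2):
        # t_act: 2*5 + 1.5*5 + 1*(5/2); t_drain: 1.2*(-5) + 1*(-5)
        assert tre["t_act"] == pytest.approx(20.0)
        assert tre["t_drain"] == pytest.approx(-11.0)
        assert tre["t_rep"] == pytest.approx(-5.0)
        assert tre["t_c1"] == pytest.approx(2.0)


class TestSignificanceFilter:
    def run_filter(self, toy_gap, toy_rap, gene_edges, tre, **kw):
        kw.setdefault("n_draws", 1000)
        kw.setdefault("seed", 42)
        return rt.significance_filter(toy_gap, toy_rap, gene_edges, tre, **kw)

    def test_seeded_runs_are_bit_identical(
        self, toy_gap, toy_rap, toy_scored_interactions
    ):
        gene_edges, _ = split_tr_edges(toy_scored_interactions)
        tre = rt.compute_tre(toy_gap, gene_edges)
        a = self.run_filter(toy_gap, toy_rap, gene_edges, tre)
        b = self.run_filter(toy_gap, toy_rap, gene_edges, tre)
        assert (a["q"] == b["q"]).all()

    def test_q_matches_independent_sampler(
        self, toy_gap, toy_rap, toy_scored_interactions
    ):
        gene_edges, _ = split_tr_edges(toy_scored_interactions)
        tre = rt.compute_tre(toy_gap, gene_edges)
        got = self.run_filter(toy_gap, toy_rap, gene_edges, tre)
        observed = toy_rap.nrap()
        expected = naive_significance_q(
            gap_rows=list(
                toy_gap.table[["gene", "reaction_id", "gprf"]].itertuples(index=False)
            ),
            interactions=[
                (ia.regulator, ia.target, ia.nrs) for ia in gene_edges
            ],
            tre={t: float(v) for t, v in tre.items() if abs(v) >= 1e-9},
            reaction_ids=list(observed.index),
            lo=float(observed.min()),
            hi=float(observed.max()),
            n_draws=1000,
            window=0.10,
            seed=42,
        )
        for t, q in expected.items():
            assert got.at[t, "q"] == q

    def test_degenerate_zero_width_range_fails_everything(
        self, toy_gap, toy_scored_interactions
    ):
        gene_edges, _ = split_tr_edges(toy_scored_interactions)
        tre = rt.compute_tre(toy_gap, gene_edges)
        # all observed slopes identical -> every random TRE equals the actual
        flat = rt.RAPTable(
            table=pd.DataFrame(
                {
                    "reaction_id": ["r1", "r2"],
                    "v_min": [0, 0],
                    "v_max": [1, 1],
                    "nrap": [3.0, 3.0],
                    "provenance": ["primary", "primary"],
                    "flag": ["ok", "ok"],
                }
            )
        )
        flat_gap = rt.compute_ngap(flat, {"r1": {"gP1": 1.0}, "r2": {"gD": 1.0}})
        flat_tre = rt.compute_tre(flat_gap, gene_edges)
        out = rt.significance_filter(
            flat_gap, flat, gene_edges, flat_tre, n_draws=500, seed=1
        )
        nonzero = flat_tre[flat_tre.abs() >= 1e-9].index
        assert (out.loc[nonzero, "q"] == 1.0).all()
        assert not out["significant"].any()

    def test_zero_tre_never_significant(self, toy_gap, toy_rap):
        tre = pd.Series({"T": 0.0})
        out = rt.significance_filter(toy_gap, toy_rap, [], tre, n_draws=10, seed=0)
        assert out.at["T", "q"] == 1.0 and not out.at["T", "significant"]

    def test_q_stable_between_1000_and_10000_draws(
        self, toy_gap, toy_rap, toy_scored_interactions
    ):
        gene_edges, _ = split_tr_edges(toy_scored_interactions)
        tre = rt.compute_tre(toy_gap, gene_edges)
        q1 = self.run_filter(toy_gap, toy_rap, gene_edges, tre, n_draws=1000)["q"]
        q2 = self.run_filter(toy_gap, toy_rap, gene_edges, tre, n_draws=10000)["q"]
        for t in q1.index:
            p = q2[t]
            se = np.sqrt(max(p * (1 - p), 1e-6) / 1000)
            assert abs(q1[t] - p) <= 3 * se + 1e-12

    def test_zero_draws_rejected(self, toy_gap, toy_rap):
        with pytest.raises(rt.ConfigurationError):
            rt.significance_filter(
                toy_gap, toy_rap, [], pd.Series(dtype=float), n_draws=0
            )


class TestComputeGTRE:
    def test_leaf_tr_keeps_its_own_effect(self):
        h = rt.build_hierarchy(edges(("t1", "t2", 1.0)))
        gtre = rt.compute_gtre(h, pd.Series({"t1": 0.0, "t2": 5.0}))
        assert gtre["t2"] == 5.0
        assert gtre["t1"] == 5.0  # 0 + 1.0 * 5

    def test_three_level_hand_evaluated_recursion(self):
        h = rt.build_hierarchy(
            edges(("t1", "t2", 0.5), ("t1", "t3", -1.0), ("t2", "t4", 2.0))
        )
        tre = pd.Series({"t1": 1.0, "t2": 2.0, "t3": 3.0, "t4": 4.0})
        gtre = rt.compute_gtre(h, tre)
        assert gtre["t4"] == 4.0
        assert gtre["t2"] == 2 + 2 * 4
        assert gtre["t3"] == 3.0
        assert gtre["t1"] == pytest.approx(1 + 0.5 * 10 + (-1) * 3)

    def test_zero_strength_edges_propagate_nothing(self):
        rng = np.random.default_rng(3)
        es = edges(*[(f"t{i}", f"t{j}", 0.0) for i in range(4) for j in range(i + 1, 5)])
        h = rt.build_hierarchy(es)
        tre = pd.Series({f"t{i}": float(rng.normal()) for i in range(5)})
        gtre = rt.compute_gtre(h, tre)
        for t in tre.index:
            assert gtre[t] == tre[t]

    def test_non_significant_trs_are_conduits_by_default(self):
        h = rt.build_hierarchy(edges(("a", "b", 1.0), ("b", "c", 1.0)))
        tre = pd.Series({"a": 1.0, "b": 100.0, "c": 7.0})
        sig = {"a": True, "b": False, "c": True}
        gtre = rt.compute_gtre(h, tre, significant=sig)
        assert gtre["b"] == 7.0  # own effect zeroed, child's conducted
        assert gtre["a"] == 1.0 + 7.0

    def test_strict_mode_severs_paths_through_failures(self):
        h = rt.build_hierarchy(edges(("a", "b", 1.0), ("b", "c", 1.0)))
        tre = pd.Series({"a": 1.0, "b": 100.0, "c": 7.0})
        sig = {"a": True, "b": False, "c": True}
        gtre = rt.compute_gtre(h, tre, significant=sig, strict=True)
        assert "b" not in gtre.index
        assert gtre["a"] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_random_dag_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        names = [f"t{i}" for i in range(n)]
        es = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    es.append((names[i], names[j], float(rng.normal())))
        tre = {t: float(rng.normal()) for t in names}
        h = rt.build_hierarchy(edges(*es))
        got = rt.compute_gtre(h, pd.Series(tre))
        expected = path_enumeration_gtre(es, tre, names)
        for t in names:
            assert got[t] == pytest.approx(expected[t], rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_cyclic_graphs_always_yield_finite_scores(self, seed):
        rng = np.random.default_rng(100 + seed)
        names = [f"t{i}" for i in range(8)]
        es = []
        for _ in range(20):  # dense random digraph: cycles guaranteed likely
            u, v = rng.choice(8, size=2)
            es.append((names[u], names[v], float(rng.normal(0, 2))))
        es.append(("t0", "t1", 3.0))
        es.append(("t1", "t0", 3.0))  # planted positive 2-cycle
        h = rt.build_hierarchy(edges(*es))
        tre = pd.Series({t: float(rng.normal()) for t in names})
        gtre = rt.compute_gtre(h, tre)
        assert np.isfinite(gtre.to_numpy()).all()


class TestRankTargets:
    def test_sort_and_direction_contract(self):
        scores = pd.DataFrame(
            {"tre": [1.0, -1.0, 0.5], "gtre": [3.0, -2.0, 0.0]},
            index=["a", "b", "c"],
        )
        out = rt.rank_targets(scores)
        assert list(out.index) == ["a", "c", "b"]
        assert out.at["a", "direction"] == "upregulate"
        assert out.at["b", "direction"] == "downregulate"
        assert out.at["c", "direction"] == "neutral"
        assert list(out["rank"]) == [1, 2, 3]

    def test_ties_break_by_tre_magnitude_then_id(self):
        scores = pd.DataFrame(
            {"tre": [0.1, -2.0, 0.1], "gtre": [1.0, 1.0, 1.0]},
            index=["b", "z", "a"],
        )
        out = rt.rank_targets(scores)
        assert list(out.index) == ["z", "a", "b"]
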