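"""Spearman machinery, association screens, co-occurrence networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sufucore as sc
from sufucore.networks import Edge, Network, ScreeningCriteria
from sufucore.tables import ValidationError

from conftest import make_abundance


def oracle_spearman(x, y):
    """Independent rank-then-Pearson oracle."""
    return float(stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0])


class TestSpearmanRho:
    def test_monotone(self):
        assert sc.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed(self):
        assert sc.spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert sc.spearman_rho(x, y) == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = rng.integers(4, 15)
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert sc.spearman_rho(x, y) == pytest.approx(
                oracle_spearman(x, y), abs=1e-12
            )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            sc.spearman_rho([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = sc.spearman_rho(x, y)
        assert sc.spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert sc.spearman_rho(x, y**3) == pytest.approx(base, abs=1e-12)
        assert sc.spearman_rho(stats.rankdata(x), y) == pytest.approx(base, abs=1e-12)


class TestSpearmanP:
    def test_exact_perm_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        p = sc.spearman_p(1.0, 5, method="exact_perm", x=x, y=x)
        assert p == pytest.approx(2 / 120)

    def test_zero_rho_two_sided(self):
        assert sc.spearman_p(0.0, 9) == pytest.approx(1.0)

    def test_perfect_rho_t_convention(self):
        assert sc.spearman_p(1.0, 9) == 0.0
        assert sc.spearman_p(-1.0, 9) == 0.0

    def test_t_approx_close_to_exact_at_n7(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(60):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            r = sc.spearman_rho(x, y)
            pt = sc.spearman_p(r, 7)
            pe = sc.spearman_p(r, 7, method="exact_perm", x=x, y=y)
            worst = max(worst, abs(pt - pe))
        assert worst <= 0.03

    def test_exact_perm_needs_small_n(self):
        with pytest.raises(ValidationError):
            sc.spearman_p(0.5, 9, method="exact_perm", x=np.arange(9), y=np.arange(9))


class TestSpearmanMatrix:
    def test_matches_scalar_path(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(9, 4)), columns=list("abcd"))
        Y = pd.DataFrame(rng.normal(size=(9, 3)), columns=list("xyz"))
        rho, p = sc.spearman_matrix(X, Y)
        for a in X.columns:
            for b in Y.columns:
                assert rho.loc[a, b] == pytest.approx(
                    sc.spearman_rho(X[a], Y[b]), abs=1e-12
                )
                assert p.loc[a, b] == pytest.approx(
                    sc.spearman_p(sc.spearman_rho(X[a], Y[b]), 9), abs=1e-12
                )

    def test_constant_column_yields_nan(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]})
        rho, p = sc.spearman_matrix(X)
        assert np.isnan(rho.loc["a", "b"])
        assert p.loc["a", "b"] == 1.0


class TestGenusFlavorScreen:
    def screen(self, abund, flav, stage="early", **kw):
        crit = ScreeningCriteria(**kw)
        return sc.genus_flavor_screen(abund, flav, crit, stage)

    def test_uncorrelated_genus_fails_with_zero_count(self):
        rng = np.random.default_rng(0)
        n = 9
        abund = pd.DataFrame({"g": np.arange(n, dtype=float)},
                             index=[f"s{i}" for i in range(n)])
        flav = pd.DataFrame(
            np.tile([1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 1.5, -1.5, 0.0], (5, 1)),
            index=[f"c{j}" for j in range(5)],
            columns=abund.index,
        )
        res = self.screen(abund, flav)
        assert res.qualifying_counts["g"] == 0
        assert res.passing == []

    def test_count_rule_boundary(self):
        # genus correlated perfectly with exactly 12 compounds
        n = 9
        sig = np.arange(n, dtype=float)
        abund = pd.DataFrame({"g": sig}, index=[f"s{i}" for i in range(n)])
        rng = np.random.default_rng(5)
        rows = [sig * (j + 1) for j in range(12)]
        rows += [rng.normal(size=n) * 0.0 + np.tile([1.0, 2.0, 0.0], 3) for _ in range(3)]
        flav = pd.DataFrame(
            rows, index=[f"c{j}" for j in range(15)], columns=abund.index
        )
        strict = self.screen(abund, flav, count_rule="strict_greater")
        atleast = self.screen(abund, flav, count_rule="at_least")
        assert strict.qualifying_counts["g"] == 12
        assert strict.passing == []  # "more than 12" read literally
        assert atleast.passing == ["g"]

    def test_planted_cores_pass_decoys_fail(self, synth_default, recovery_criteria):
        at, ft, ph, truth = synth_default
        rel = sc.assign_stages(at)
        stage_at = rel.restrict("early")
        dom = sc.dominant_genera(rel, "early")
        flav = ft.values[stage_at.sample_ids]
        res = sc.genus_flavor_screen(
            stage_at.values[dom], flav, recovery_criteria, "early"
        )
        assert set(truth.core_early) <= set(res.passing)
        decoys = set(dom) - set(truth.core_early) - set(truth.antagonists_early)
        assert not decoys & set(res.passing)
        # antagonists correlate negatively, so the promoter-only rule drops them
        assert not set(truth.antagonists_early) & set(res.passing)

    def test_screened_set_subset_of_dominant(self, synth_default, recovery_criteria):
        at, ft, ph, truth = synth_default
        rel = sc.assign_stages(at)
        for stage in ("early", "late"):
            stage_at = rel.restrict(stage)
            dom = sc.dominant_genera(rel, stage)
            res = sc.genus_flavor_screen(
                stage_at.values[dom], ft.values[stage_at.sample_ids],
                recovery_criteria, stage,
            )
            assert set(res.passing) <= set(dom)

    def test_misaligned_samples_rejected(self):
        abund = pd.DataFrame({"g": [1.0, 2, 3]}, index=["a", "b", "c"])
        flav = pd.DataFrame([[1.0, 2, 3]], index=["c0"], columns=["a", "b", "x"])
        with pytest.raises(ValidationError):
            sc.genus_flavor_screen(abund, flav, ScreeningCriteria(), "early")


class TestCooccurrenceNetwork:
    def test_planted_triangle(self):
        n = 9
        base = np.arange(n, dtype=float)
        rng = np.random.default_rng(2)
        vals = np.column_stack(
            [base + 1 + 0.01 * rng.random(n),
             base + 1 + 0.01 * rng.random(n),
             (n - base) + 0.01 * rng.random(n)]
        )
        at = make_abundance(vals, days=[10] * 3 + [20] * 3 + [30] * 3,
                            replicates=[1, 2, 3] * 3, genera=list("XYZ"))
        net = sc.cooccurrence_network(at, ["X", "Y", "Z"])
        assert len(net.edges) == 3
        assert all(net.degrees[v] == 2 for v in "XYZ")
        signs = {frozenset((e.source, e.target)): e.sign for e in net.edges}
        assert signs[frozenset("XY")] == "positive"
        assert signs[frozenset("XZ")] == "negative"

    def test_identical_profiles_single_positive_edge(self):
        v = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        at = make_abundance(np.column_stack([v, v]),
                            days=[10, 10, 20, 20, 30],
                            replicates=[1, 2, 1, 2, 1], genera=["p", "q"])
        net = sc.cooccurrence_network(at, ["p", "q"])
        assert len(net.edges) == 1
        assert net.edges[0].sign == "positive"
        assert net.degrees == {"p": 1, "q": 1}

    def test_independent_genera_rarely_connected(self):
        # planted rho = 0: per pair, P(edge) <= P(p < 0.05) ~ 0.05, so by
        # the union bound over the 3 pairs the network is empty in >= 85%
        # of draws (measured ~89%: the |rho| > 0.7 cut binds slightly
        # harder than p < 0.05 at n = 9)
        rng = np.random.default_rng(42)
        empty = 0
        reps = 500
        for _ in range(reps):
            vals = rng.random(size=(9, 3))
            at = make_abundance(vals, days=[10, 10, 10, 20, 20, 20, 30, 30, 30],
                                replicates=[1, 2, 3] * 3, genera=list("abc"))
            net = sc.cooccurrence_network(at, ["a", "b", "c"])
            empty += not net.edges
        assert empty / reps >= 0.85

    def test_too_few_samples_rejected(self):
        at = make_abundance([[1.0, 2], [2, 1]], days=[10, 20])
        with pytest.raises(ValidationError):
            sc.cooccurrence_network(at, ["g0", "g1"])


class TestDegreeAndInvariants:
    def test_star(self):
        edges = [Edge("hub", f"leaf{i}", 0.9, 0.01) for i in range(4)]
        net = Network.from_edges(["hub"] + [f"leaf{i}" for i in range(4)], edges)
        assert sc.degree(net, "hub") == 4
        assert all(sc.degree(net, f"leaf{i}") == 1 for i in range(4))

    def test_isolated_node(self):
        net = Network.from_edges(["a", "b"], [])
        assert sc.degree(net, "a") == 0

    def test_unknown_node_rejected(self):
        net = Network.from_edges(["a"], [])
        with pytest.raises(ValidationError):
            sc.degree(net, "zzz")

    def test_degree_matches_adjacency_oracle_and_sum_rule(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(8)]
        edges = []
        adj = np.zeros((8, 8), dtype=int)
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.3:
                    r = rng.uniform(-1, 1)
                    edges.append(Edge(nodes[i], nodes[j], r, 0.01))
                    adj[i, j] = adj[j, i] = 1
        net = Network.from_edges(nodes, edges)
        for i, v in enumerate(nodes):
            assert net.degrees[v] == adj[i].sum()
        assert sum(net.degrees.values()) == 2 * len(net.edges)

    def test_degree_sum_on_constructed_networks(self, synth_default):
        at, ft, ph, truth = synth_default
        rel = sc.assign_stages(at)
        for stage in ("early", "late"):
            dom = sc.dominant_genera(rel, stage)
            net = sc.cooccurrence_network(rel.restrict(stage), dom)
            assert sum(net.degrees.values()) == 2 * len(net.edges)

    def test_edge_retention_monotone_in_thresholds(self, synth_default):
        at, ft, ph, truth = synth_default
        rel = sc.assign_stages(at)
        dom = sc.dominant_genera(rel, "late")
        sub = rel.restrict("late")

        def edge_set(crit):
            net = sc.cooccurrence_network(sub, dom, crit)
            return {frozenset((e.source, e.target)) for e in net.edges}

        base = edge_set(ScreeningCriteria())
        assert edge_set(ScreeningCriteria(rho_min=0.85)) <= base
        assert edge_set(ScreeningCriteria(p_max=0.005)) <= base

    def test_sign_consistency_enforced(self):
        with pytest.raises(ValidationError):
            Edge("a", "b", -0.8, 0.01, sign="positive")

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError):
            Edge("a", "a", 0.8, 0.01)
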