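import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from keystonet.io import OtuTable
from keystonet.topology import (
    UNASSIGNED,
    ModulePartition,
    classify_roles,
    mcode_modules,
    module_eigengene,
    natural_connectivity,
    participation_coefficient,
    robustness_curve,
    within_module_degree_z,
)


def _graph(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestMcode:
    def test_two_disjoint_triangles(self):
        g = _graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = mcode_modules(g)
        assert sorted(map(sorted, part.modules)) == [[0, 1, 2], [3, 4, 5]]

    def test_k4_with_pendant_haircut(self):
        g = nx.complete_graph(4)
        g.add_edge(3, 9)
        part = mcode_modules(g, haircut=True)
        assert len(part.modules) == 1
        assert set(part.modules[0]) == {0, 1, 2, 3}
        assert part.assignments[9] == UNASSIGNED

    def test_edgeless_graph_all_unassigned(self):
        g = _graph([], nodes=range(5))
        part = mcode_modules(g)
        assert part.n_modules == 0
        assert all(v == UNASSIGNED for v in part.assignments.values())

    def test_relabeling_invariance(self, rng):
        g = nx.gnp_random_graph(18, 0.25, seed=3)
        mapping = dict(zip(g.nodes, rng.permutation([f"n{i}" for i in range(18)])))
        h = nx.relabel_nodes(g, mapping)
        part_g = mcode_modules(g)
        part_h = mcode_modules(h)
        relabeled = sorted(
            sorted(mapping[v] for v in mod) for mod in part_g.modules
        )
        assert relabeled == sorted(sorted(mod) for mod in part_h.modules)

    def test_absorption_requires_two_links(self):
        # pendant keeps out even with absorption; a 2-link satellite joins
        g = nx.complete_graph(4)
        g.add_edge(3, 9)            # pendant
        g.add_edges_from([(8, 0), (8, 1)])  # doubly-linked satellite
        part = mcode_modules(g, absorb_unassigned=True)
        assert part.assignments[9] == UNASSIGNED
        assert part.assignments[8] == part.assignments[0]


class TestZiPi:
    def test_z_hand_computed_example(self):
        # module {a,b,c} with within-degrees {2,1,1}
        g = _graph([("a", "b"), ("a", "c")])
        part = ModulePartition.from_modules([{"a", "b", "c"}], g.nodes)
        z = within_module_degree_z(g, part)
        assert z["a"] == pytest.approx((2 - 4 / 3) / np.sqrt(2 / 9), abs=1e-6)
        assert z["a"] == pytest.approx(1.4142, abs=1e-3)

    def test_equal_degrees_give_zero(self):
        g = nx.cycle_graph(6)
        part = ModulePartition.from_modules([set(range(6))], g.nodes)
        z = within_module_degree_z(g, part)
        assert np.allclose(z, 0.0)

    def test_z_is_local_to_the_module(self):
        g = _graph([("a", "b"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
        part = ModulePartition.from_modules(
            [{"a", "b", "c"}, {"x", "y", "z"}], g.nodes
        )
        before = within_module_degree_z(g, part)
        g.add_edge("x", "b")  # edge touching the other module only
        after = within_module_degree_z(g, part)
        assert after["a"] == before["a"]

    @pytest.mark.parametrize(
        "split, expected",
        [({0: 4}, 0.0), ({0: 2, 1: 2}, 0.5), ({0: 1, 1: 1, 2: 1}, 2 / 3)],
    )
    def test_participation_examples(self, split, expected):
        g = nx.Graph()
        modules = [{"hub", "m0a", "m0b", "m0c"}, {"m1a", "m1b", "m1c"},
                   {"m2a", "m2b", "m2c"}]
        for mod in modules:
            for a, b in itertools.combinations(sorted(mod - {"hub"}), 2):
                g.add_edge(a, b)
        i = 0
        for mod_idx, k in split.items():
            targets = sorted(modules[mod_idx] - {"hub"})
            for t in targets[:k]:
                g.add_edge("hub", t)
                i += 1
        part = ModulePartition.from_modules(modules, g.nodes)
        p = participation_coefficient(g, part)
        assert p["hub"] == pytest.approx(expected)

    def test_mean_z_zero_and_p_bounds(self, rng):
        g = nx.gnp_random_graph(25, 0.2, seed=11)
        part = mcode_modules(g, absorb_unassigned=True)
        if part.n_modules == 0:
            pytest.skip("random graph produced no module")
        z = within_module_degree_z(g, part)
        for mod in part.modules:
            assert np.mean([z[v] for v in mod]) == pytest.approx(0.0, abs=1e-9)
        p = participation_coefficient(g, part)
        assert ((p >= 0) & (p <= 1)).all()


class TestRoles:
    @pytest.mark.parametrize(
        "z, p, role",
        [
            (3.03, 0.21, "module hub"),
            (2.5, 0.1, "peripheral"),     # strict inequality at the cut
            (1.0, 0.8, "connector"),
            (3.0, 0.62, "network hub"),
            (2.51, 0.619, "module hub"),
        ],
    )
    def test_classification(self, z, p, role):
        assert classify_roles(z, p) == role

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_roles(np.nan, 0.2)


class TestEigengene:
    def _table_from_matrix(self, X):
        n, m = X.shape
        otus = [f"O{j}" for j in range(m)]
        counts = pd.DataFrame(
            np.rint(X).astype(int), index=[f"s{i}" for i in range(n)], columns=otus
        )
        taxonomy = pd.DataFrame(
            {"guild": ["AOA"] * m, "cluster": ["c"] * m, "genus": ["g"] * m},
            index=pd.Index(otus, name="otu_id"),
        )
        return OtuTable(counts, taxonomy)

    def test_identical_profiles_explain_everything(self, rng):
        profile = rng.integers(50, 500, size=10)
        # members proportional to one another share a single standardized
        # relative-abundance profile
        X = np.outer(profile, [1, 2, 3, 5])
        table = self._table_from_matrix(X)
        part = ModulePartition.from_modules([{"O0", "O1", "O2", "O3"}],
                                            table.otu_ids)
        eig = module_eigengene(table, part)
        assert eig.variance_explained["I"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_svd_oracle(self, rng):
        X = rng.integers(10, 2000, size=(12, 5))
        table = self._table_from_matrix(X)
        part = ModulePartition.from_modules([set(table.otu_ids)], table.otu_ids)
        eig = module_eigengene(table, part)
        rel = table.relative_abundance().to_numpy()
        Z = (rel - rel.mean(0)) / rel.std(0)
        u = np.linalg.svd(Z)[0][:, 0]
        corr = abs(np.corrcoef(eig.values["I"], u)[0, 1])
        assert corr > 1 - 1e-10

    def test_orientation_follows_mean_profile(self, rng):
        X = rng.integers(10, 2000, size=(12, 5))
        table = self._table_from_matrix(X)
        part = ModulePartition.from_modules([set(table.otu_ids)], table.otu_ids)
        eig = module_eigengene(table, part)
        rel = table.relative_abundance().to_numpy()
        Z = (rel - rel.mean(0)) / rel.std(0)
        assert float(eig.values["I"] @ Z.mean(axis=1)) >= 0

    def test_module_with_constant_shares_rejected(self, rng):
        # all members proportional -> constant relative abundances -> no
        # usable standardized profiles
        col = rng.integers(10, 99, size=(8, 1))
        X = np.hstack([2 * col, 3 * col, 5 * col])
        table = self._table_from_matrix(X)
        part = ModulePartition.from_modules([set(table.otu_ids)], table.otu_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigengene(table, part)


class TestNaturalConnectivity:
    def test_edgeless_is_zero(self):
        assert natural_connectivity(_graph([], nodes=range(7))) == pytest.approx(0.0)

    def test_complete_graph_closed_form(self):
        # K_n spectrum: (n-1) once, -1 with multiplicity n-1
        for n in (2, 4, 10):
            expected = np.logaddexp(n - 1.0, np.log(n - 1.0) - 1.0) - np.log(n)
            assert natural_connectivity(nx.complete_graph(n)) == pytest.approx(
                expected, abs=1e-10
            )
        # ln((e^3 + 3 e^-1)/4) = 1.66723...
        assert natural_connectivity(nx.complete_graph(4)) == pytest.approx(
            1.6672, abs=1e-4
        )

    def test_star_closed_form(self):
        s3 = np.sqrt(3.0)
        expected = np.log((np.exp(s3) + np.exp(-s3) + 2) / 4)
        assert natural_connectivity(nx.star_graph(3)) == pytest.approx(
            expected, abs=1e-10
        )
        assert natural_connectivity(nx.star_graph(3)) == pytest.approx(0.6716, abs=1e-4)

    def test_monotone_in_clique_size(self):
        vals = [natural_connectivity(nx.complete_graph(n)) for n in range(2, 12)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            natural_connectivity(nx.Graph())


class TestRobustness:
    def test_fraction_zero_is_intact_value(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        curve = robustness_curve(g, "random", fractions=[0.0, 0.2], n_reps=5, seed=0)
        assert curve.mean[0] == pytest.approx(natural_connectivity(g))
        assert curve.sd[0] == pytest.approx(0.0)

    def test_targeted_removal_on_k6_matches_closed_form(self):
        g = nx.complete_graph(6)
        fractions = [1 / 6, 2 / 6, 3 / 6, 4 / 6]
        curve = robustness_curve(g, "degree-targeted", fractions=fractions)
        for frac, got in zip(curve.fractions, curve.mean):
            m = 6 - round(frac * 6)
            expected = np.logaddexp(m - 1.0, np.log(m - 1.0) - 1.0) - np.log(m)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_random_curves_deterministic_given_seed(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        a = robustness_curve(g, "random", fractions=[0.1, 0.3], n_reps=8, seed=42)
        b = robustness_curve(g, "random", fractions=[0.1, 0.3], n_reps=8, seed=42)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_rejects_total_removal(self):
        with pytest.raises(ValueError):
            robustness_curve(nx.complete_graph(3), "random", fractions=[0.99])
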