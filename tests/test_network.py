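import itertools

import numpy as np
import pandas as pd
import pytest

from keystonet.io import OtuTable
from keystonet.network import (
    bh_adjust,
    build_network,
    edge_composition,
    exact_spearman_pvalue,
    pairwise_correlations,
    prevalence_filter,
    spearman_rp,
)


def _table(counts: np.ndarray, prefix_guilds=None) -> OtuTable:
    n_samples, n_otus = counts.shape
    otus = [f"O{j}" for j in range(n_otus)]
    guilds = prefix_guilds or ["AOA" if j % 2 == 0 else "AOB" for j in range(n_otus)]
    taxonomy = pd.DataFrame(
        {"guild": guilds, "cluster": ["c"] * n_otus, "genus": ["g"] * n_otus},
        index=pd.Index(otus, name="otu_id"),
    )
    frame = pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)], columns=otus
    )
    return OtuTable(frame, taxonomy)


class TestPrevalenceFilter:
    def test_strictly_more_than_threshold(self, rng):
        counts = rng.integers(1, 10, size=(12, 3))
        counts[:2, 0] = 0   # present 10/12 > 0.75 -> kept
        counts[:3, 1] = 0   # present 9/12 = 0.75 -> removed (strict)
        table = prevalence_filter(_table(counts))
        assert table.otu_ids == ["O0", "O2"]

    def test_all_present_unchanged(self, rng):
        counts = rng.integers(1, 10, size=(8, 4))
        assert prevalence_filter(_table(counts)).otu_ids == [f"O{j}" for j in range(4)]

    def test_empty_result_warns_not_raises(self, rng):
        counts = np.zeros((8, 2), dtype=int)
        counts[:2] = 1
        assert prevalence_filter(_table(counts)).n_otus == 0


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        r, p = spearman_rp(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r, p = spearman_rp(x, -(x**3))
        assert r == pytest.approx(-1.0)

    def test_exact_null_matches_simulated_frequency(self, rng):
        """|r| > 0.7 for independent pairs at n=6 occurs at the exact
        enumeration frequency."""
        n, reps = 6, 2000
        expected = exact_spearman_pvalue(0.7 + 1e-9, n)  # P(|rho| > 0.7)
        hits = 0
        for _ in range(reps):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, _ = spearman_rp(x, y)
            hits += abs(r) > 0.7
        freq = hits / reps
        sd = np.sqrt(expected * (1 - expected) / reps)
        assert abs(freq - expected) < 4 * sd

    def test_exact_p_agrees_with_scipy_for_small_n(self, rng):
        from scipy import stats

        x, y = rng.normal(size=8), rng.normal(size=8)
        r, p = spearman_rp(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        # scipy uses the t-approximation; exact p should be close but is
        # the enumeration value
        assert p == pytest.approx(exact_spearman_pvalue(r, 8))


class TestBH:
    def test_hand_run_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_equal_ps_and_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5)
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestPairwiseCorrelations:
    def test_matches_bruteforce_oracle(self, rng):
        counts = rng.integers(1, 500, size=(10, 8))
        table = _table(counts)
        corr = pairwise_correlations(table, method="spearman")
        rel = table.relative_abundance()
        for row in corr.itertuples(index=False):
            r, p = spearman_rp(rel[row.otu_i], rel[row.otu_j])
            assert row.r == pytest.approx(r, abs=1e-12)
            assert row.p == pytest.approx(p, abs=1e-12)
        assert len(corr) == 8 * 7 // 2

    def test_zero_variance_otu_excluded(self, rng):
        counts = rng.integers(1, 500, size=(6, 4)).astype(float)
        # O3 constant relative abundance: make it a fixed share of the total
        counts[:, 3] = counts[:, :3].sum(axis=1)
        corr = pairwise_correlations(_table(counts.astype(int)))
        assert not (corr["otu_i"] == "O3").any() and not (corr["otu_j"] == "O3").any()

    def test_needs_four_samples(self, rng):
        with pytest.raises(ValueError):
            pairwise_correlations(_table(rng.integers(1, 9, size=(3, 4))))

    def test_column_order_invariance(self, rng):
        counts = rng.integers(1, 500, size=(9, 6))
        t1 = _table(counts)
        perm = [3, 1, 5, 0, 2, 4]
        t2 = t1.subset_otus([f"O{j}" for j in perm])
        c1 = pairwise_correlations(t1).set_index(["otu_i", "otu_j"])["r"]
        c2 = pairwise_correlations(t2).set_index(["otu_i", "otu_j"])["r"]
        pd.testing.assert_series_equal(c1.sort_index(), c2.sort_index())


class TestBuildNetwork:
    def _corr(self, rows):
        df = pd.DataFrame(rows, columns=["otu_i", "otu_j", "r", "p", "q"])
        df["method"] = "spearman"
        return df

    def test_threshold_logic(self, rng):
        table = _table(rng.integers(1, 9, size=(6, 4)))
        corr = self._corr([
            ("O0", "O1", 0.8, 0.0005, 0.001),
            ("O0", "O2", 0.65, 0.0005, 0.001),
            ("O1", "O2", 0.9, 0.01, 0.02),
        ])
        net = build_network(corr, table)
        assert net.number_of_edges() == 1
        assert net.has_edge("O0", "O1")
        # isolated nodes dropped
        assert "O3" not in net

    def test_exact_boundary_excluded(self, rng):
        table = _table(rng.integers(1, 9, size=(6, 2)))
        corr = self._corr([("O0", "O1", 0.7, 0.001, 0.001)])
        assert build_network(corr, table).number_of_edges() == 0

    def test_negating_one_profile_flips_sign_not_magnitude(self, rng):
        """Negating one abundance profile flips its Spearman edge signs
        (hence edge membership is preserved under |r| thresholds)."""
        X = rng.normal(size=(12, 5))
        for a, b in itertools.combinations(range(5), 2):
            r, p = spearman_rp(X[:, a], X[:, b])
            r_neg, p_neg = spearman_rp(-X[:, a], X[:, b])
            assert r_neg == pytest.approx(-r, abs=1e-12)
            assert p_neg == pytest.approx(p, abs=1e-12)


def test_edge_composition_counts_and_pnc(rng):
    table = _table(rng.integers(1, 9, size=(6, 4)),
                   prefix_guilds=["AOA", "AOA", "AOB", "AOB"])
    corr = pd.DataFrame(
        [
            ("O0", "O2", -0.9, 0.001, 0.002),   # AOA-AOB negative
            ("O2", "O3", -0.8, 0.001, 0.002),   # AOB-AOB negative
            ("O0", "O1", 0.8, 0.001, 0.002),    # AOA-AOA positive
        ],
        columns=["otu_i", "otu_j", "r", "p", "q"],
    )
    corr["method"] = "spearman"
    comp = edge_composition(build_network(corr, table))
    assert comp.n_edges == 3
    assert comp.pnc == pytest.approx(200 / 3)
    assert sum(comp.counts.values()) == comp.n_edges
    assert comp.counts[("AOA", "AOB", "negative")] == 1
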