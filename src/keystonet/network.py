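"""Signed co-occurrence network inference from OTU tables.

The workflow is: prevalence filter (presence in strictly more than
three-fourths of samples), pairwise correlation on relative abundances
(Spearman by default, with an optional Spearman-and-Pearson ensemble),
Benjamini-Hochberg adjustment within the tested pair set, and strict
thresholding (|r| > 0.7, adjusted p < 0.01 by default).  With the very
small sample counts typical of field trials, Spearman p-values are exact
(full permutation null) for n <= 9 and t-approximated above.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "prevalence_filter",
    "pairwise_correlations",
    "bh_adjust",
    "build_network",
    "edge_composition",
    "EdgeComposition",
    "spearman_rp",
    "exact_spearman_pvalue",
]


def prevalence_filter(table: OtuTable, min_fraction: float = 0.75) -> OtuTable:
    """Keep OTUs present (count > 0) in strictly more than ``min_fraction``
    of samples; the sample set is unchanged."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    presence = (table.counts > 0).mean(axis=0)
    keep = presence.index[presence > min_fraction].tolist()
    if not keep:
        logger.warning("prevalence filter removed every OTU")
        empty = table.counts.iloc[:, :0]
        return OtuTable(empty, table.taxonomy.iloc[:0])
    return table.subset_otus(keep)


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman's rho over all n! rank orders."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    base = np.arange(n, dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    rho.sort()
    return rho


def exact_spearman_pvalue(r: float, n: int) -> float:
    """Two-sided exact p-value P(|rho_null| >= |r|) for tie-free data."""
    if n > 9:
        raise ValueError("exact null is enumerated only for n <= 9")
    null = _exact_spearman_null(n)
    return float(np.mean(np.abs(null) >= abs(r) - 1e-12))


def _t_approx_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def _spearman_pvalue(r: float, n: int, ties: bool) -> float:
    if n <= 9 and not ties:
        return exact_spearman_pvalue(r, n)
    return _t_approx_pvalue(r, n)


def spearman_rp(x, y) -> tuple[float, float]:
    """Spearman's rho and two-sided p (exact for n <= 9 without ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    return r, _spearman_pvalue(r, n, ties)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Correlation table and network
# ---------------------------------------------------------------------------

def pairwise_correlations(table: OtuTable, method: str = "spearman") -> pd.DataFrame:
    """All-pairs correlations on relative abundances.

    Returns a table with one row per unordered OTU pair (ids sorted within
    the pair) and columns ``otu_i, otu_j, r, p, q`` (+ ``r_pearson,
    p_pearson, q_pearson`` for the ensemble), where ``r`` is Spearman's rho
    (or Pearson's r when ``method="pearson"``) and ``q`` the BH-adjusted p
    over all tested pairs.  Zero-variance OTUs are excluded with a log
    entry, since their correlations are undefined.
    """
    if method not in ("spearman", "pearson", "ensemble"):
        raise ValueError(f"unknown correlation method {method!r}")
    n = table.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for correlation inference")
    rel = table.relative_abundance()
    variances = rel.var(axis=0, ddof=0)
    constant = variances.index[variances == 0].tolist()
    if constant:
        logger.info("excluding zero-variance OTUs: %s", constant)
        rel = rel.drop(columns=constant)
    otus = list(rel.columns)
    if len(otus) < 2:
        return _empty_corr_table(method)

    X = rel.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    has_ties = np.array([len(np.unique(X[:, j])) < n for j in range(X.shape[1])])
    r_spear = np.corrcoef(ranks, rowvar=False)
    r_pears = np.corrcoef(X, rowvar=False)

    rows = []
    for a, b in itertools.combinations(range(len(otus)), 2):
        oi, oj = sorted((otus[a], otus[b]))
        row = {"otu_i": oi, "otu_j": oj}
        rs = float(np.clip(r_spear[a, b], -1.0, 1.0))
        rp = float(np.clip(r_pears[a, b], -1.0, 1.0))
        ties = bool(has_ties[a] or has_ties[b])
        if method in ("spearman", "ensemble"):
            row["r"] = rs
            row["p"] = _spearman_pvalue(rs, n, ties)
        else:
            row["r"] = rp
            row["p"] = _t_approx_pvalue(rp, n)
        if method == "ensemble":
            row["r_pearson"] = rp
            row["p_pearson"] = _t_approx_pvalue(rp, n)
        rows.append(row)
    corr = pd.DataFrame(rows).sort_values(["otu_i", "otu_j"], ignore_index=True)
    corr["q"] = bh_adjust(corr["p"].to_numpy())
    if method == "ensemble":
        corr["q_pearson"] = bh_adjust(corr["p_pearson"].to_numpy())
    corr["method"] = method
    return corr


def _empty_corr_table(method: str) -> pd.DataFrame:
    cols = ["otu_i", "otu_j", "r", "p", "q"]
    if method == "ensemble":
        cols += ["r_pearson", "p_pearson", "q_pearson"]
    cols.append("method")
    return pd.DataFrame(columns=cols)


def build_network(
    corr: pd.DataFrame,
    table: OtuTable,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
    use_adjusted: bool = True,
) -> nx.Graph:
    """Threshold a correlation table into a signed co-occurrence network.

    An edge requires |r| strictly above ``r_threshold`` and (adjusted) p
    strictly below ``p_threshold``; for ensemble tables both measures must
    pass, and Spearman's rho is reported as the edge weight.  Isolated
    nodes are dropped.  Node attributes: guild and mean relative abundance
    over the table's samples.
    """
    rel = table.relative_abundance()
    mean_rel = rel.mean(axis=0)
    G = nx.Graph(
        r_threshold=float(r_threshold),
        p_threshold=float(p_threshold),
        use_adjusted=bool(use_adjusted),
        method=str(corr["method"].iloc[0]) if len(corr) else "spearman",
        n_samples=int(table.n_samples),
        sample_ids=",".join(map(str, table.sample_ids)),
    )
    pcol = "q" if use_adjusted else "p"
    ensemble = "r_pearson" in corr.columns
    for row in corr.itertuples(index=False):
        passes = abs(row.r) > r_threshold and getattr(row, pcol) < p_threshold
        if ensemble:
            p_pears = row.q_pearson if use_adjusted else row.p_pearson
            passes = passes and abs(row.r_pearson) > r_threshold and p_pears < p_threshold
        if not passes:
            continue
        for otu in (row.otu_i, row.otu_j):
            if otu not in G:
                G.add_node(
                    otu,
                    guild=table.guild_of(otu),
                    mean_relative_abundance=float(mean_rel[otu]),
                )
        G.add_edge(
            row.otu_i,
            row.otu_j,
            r=float(row.r),
            p=float(row.p),
            q=float(row.q),
            sign="positive" if row.r > 0 else "negative",
        )
    return G


@dataclasses.dataclass(frozen=True)
class EdgeComposition:
    """Edge counts split by guild pair and sign, plus the percentage of
    negative correlations (PNC)."""

    counts: dict
    n_edges: int
    pnc: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"guild_pair": f"{a}-{b}", "sign": s, "count": c}
            for (a, b, s), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["guild_pair", "sign", "count"])


def edge_composition(net: nx.Graph) -> EdgeComposition:
    """Tabulate edges into {AOA-AOA, AOA-AOB, AOB-AOB} x {positive, negative}."""
    counts: dict = {}
    n_neg = 0
    for u, v, data in net.edges(data=True):
        pair = tuple(sorted((net.nodes[u]["guild"], net.nodes[v]["guild"])))
        sign = data["sign"]
        counts[(pair[0], pair[1], sign)] = counts.get((pair[0], pair[1], sign), 0) + 1
        if sign == "negative":
            n_neg += 1
    n_edges = net.number_of_edges()
    pnc = 100.0 * n_neg / n_edges if n_edges else 0.0
    return EdgeComposition(counts=counts, n_edges=n_edges, pnc=pnc)
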