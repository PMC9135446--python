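"""Alpha diversity, Bray-Curtis ordination and composition summaries.

Shannon entropy uses the natural logarithm and Chao1 is the bias-corrected
estimator; both operate on raw counts (no rarefaction by default, with an
optional even-depth subsample for users who want it).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .io import OtuTable

__all__ = [
    "shannon",
    "chao1",
    "bray_curtis",
    "compositional_similarity",
    "bray_curtis_matrix",
    "nmds",
    "OrdinationResult",
    "cluster_relative_abundance",
    "alpha_diversity_table",
    "subsample_even_depth",
    "permutation_test_composition",
]


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over taxa with positive counts."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one positive count is required")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    if np.any(np.mod(c, 1) != 0):
        raise ValueError("Chao1 is defined for integer counts only")
    c = c.astype(np.int64)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("x and y cannot both be all-zero")
    return float(_scipy_braycurtis(x, y))


def compositional_similarity(x, y) -> float:
    """1 minus the Bray-Curtis dissimilarity."""
    return 1.0 - bray_curtis(x, y)


def bray_curtis_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Square Bray-Curtis distance matrix between the rows (samples)."""
    d = squareform(pdist(abundance.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


@dataclasses.dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray  # samples x k
    stress: float            # Kruskal stress-1
    converged: bool
    n_restarts_used: int


def nmds(
    dissimilarity,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
) -> OrdinationResult:
    """Non-metric multidimensional scaling (Kruskal stress-1), best of restarts."""
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("dissimilarities must be non-negative")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=1e-8,
        random_state=seed,
        metric="precomputed",
        normalized_stress=True,
    )
    coords = model.fit_transform(d)
    converged = bool(model.n_iter_ < max_iter)
    return OrdinationResult(
        coordinates=coords,
        stress=float(model.stress_),
        converged=converged,
        n_restarts_used=n_restarts,
    )


def cluster_relative_abundance(
    table: OtuTable,
    level: str = "cluster",
    within_guild: bool = True,
) -> pd.DataFrame:
    """Per-sample relative abundance aggregated at a taxonomy level.

    With ``within_guild=True`` fractions sum to 1 inside each guild per
    sample; otherwise over the whole sample.
    """
    if level not in ("guild", "genus", "cluster"):
        raise ValueError(f"unknown taxonomy level {level!r}")
    labels = table.taxonomy.loc[table.otu_ids, level]
    grouped = table.counts.T.groupby(labels).sum().T
    if within_guild and level != "guild":
        guild_of_group = (
            table.taxonomy.loc[table.otu_ids].groupby(level)["guild"].first()
        )
        out = grouped.astype(float)
        for guild in guild_of_group.unique():
            cols = guild_of_group.index[guild_of_group == guild]
            totals = grouped[cols].sum(axis=1)
            out.loc[:, cols] = grouped[cols].div(totals.replace(0, np.nan), axis=0)
        return out
    totals = grouped.sum(axis=1)
    return grouped.div(totals.replace(0, np.nan), axis=0)


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Shannon and Chao1 per sample and guild (AOA/AOB computed separately)."""
    rows = {}
    guilds = table.taxonomy.loc[table.otu_ids, "guild"]
    for guild in sorted(guilds.unique()):
        cols = guilds.index[guilds == guild]
        sub = table.counts[cols]
        rows[f"shannon_{guild.lower()}"] = sub.apply(shannon, axis=1)
        rows[f"chao1_{guild.lower()}"] = sub.apply(chao1, axis=1)
    return pd.DataFrame(rows)


def subsample_even_depth(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Optional even-depth subsampling (off by default everywhere else)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts.to_numpy())
    for i, (_, row) in enumerate(table.counts.iterrows()):
        total = int(row.sum())
        if total < depth:
            raise ValueError(f"sample {row.name!r} has fewer than {depth} reads")
        pool = np.repeat(np.arange(table.n_otus), row.to_numpy().astype(int))
        picked = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=table.n_otus)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(counts, table.taxonomy)


def permutation_test_composition(
    abundance: pd.DataFrame,
    grouping,
    permutations: int = 999,
    seed: int = 0,
):
    """PERMANOVA-style permutation test on Bray-Curtis distances.

    Tests whether composition differs between groups; returns the skbio
    result Series (test statistic pseudo-F and permutation p-value).
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova

    dm = DistanceMatrix(
        bray_curtis_matrix(abundance).to_numpy(), ids=list(abundance.index)
    )
    state = np.random.get_state()
    try:
        np.random.seed(seed)
        return permanova(dm, list(grouping), permutations=permutations)
    finally:
        np.random.set_state(state)
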