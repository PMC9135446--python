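"""Association tables between modules, taxa and sample metadata, and
Tukey-HSD compact letter displays for treatment comparisons.

Correlations are Spearman throughout (exact p-values for n <= 9 via the
permutation null); star labels use the raw p by default (``**`` p < 0.01,
``*`` p < 0.05) with an optional BH adjustment over the table.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .diversity import cluster_relative_abundance
from .io import OtuTable
from .network import bh_adjust, spearman_rp
from .topology import EigengeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "star_label",
    "eigengene_metadata_correlations",
    "taxon_metadata_correlations",
    "tukey_letters",
]


def star_label(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _correlation_table(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    targets,
    adjust: bool,
) -> pd.DataFrame:
    shared = [s for s in features.index if s in metadata.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    feats = features.loc[shared]
    meta = metadata.loc[shared]
    unknown = [t for t in targets if t not in meta.columns]
    if unknown:
        raise KeyError(f"metadata variables not found: {unknown}")
    rows = []
    for feat, target in itertools.product(feats.columns, targets):
        x = feats[feat].astype(float)
        y = pd.to_numeric(meta[target], errors="coerce")
        ok = x.notna() & y.notna()
        if ok.sum() < 4:
            logger.info("skipping %s ~ %s: fewer than 4 complete pairs", feat, target)
            continue
        xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            logger.info("skipping %s ~ %s: zero variance", feat, target)
            continue
        r, p = spearman_rp(xv, yv)
        rows.append({"feature_a": feat, "feature_b": target, "r": r, "p": p})
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        shown = out["q"] if adjust else out["p"]
        out["stars"] = [star_label(p) for p in shown]
    else:
        out["q"] = []
        out["stars"] = []
    return out


def eigengene_metadata_correlations(
    eigengenes: EigengeneMatrix,
    metadata: pd.DataFrame,
    targets,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman r/p between each module eigengene and each metadata variable.

    Samples are aligned by id, so any consistent reordering of both inputs
    leaves the table unchanged.
    """
    return _correlation_table(eigengenes.values, metadata, targets, adjust)


def taxon_metadata_correlations(
    table: OtuTable,
    metadata: pd.DataFrame,
    targets,
    level: str = "cluster",
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman r/p between taxonomy-level relative abundances and metadata.

    Constant (zero-variance) taxa are excluded with a log entry.
    """
    feats = cluster_relative_abundance(table, level=level)
    return _correlation_table(feats, metadata, targets, adjust)


def tukey_letters(values, groups, alpha: float = 0.05) -> dict:
    """Compact letter display from one-way ANOVA + Tukey HSD all-pairs tests.

    Groups sharing no letter differ significantly at ``alpha``.  Letters
    are assigned by the insert-and-absorb algorithm on the set of
    significant pairs, with groups ordered by descending mean.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    names, counts = np.unique(g, return_counts=True)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    singletons = names[counts < 2].tolist()
    if singletons:
        raise ValueError(f"groups with a single replicate: {singletons}")

    res = pairwise_tukeyhsd(v, g, alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    significant = {
        frozenset(pair)
        for pair, reject in zip(pairs, res.reject)
        if reject
    }

    order = sorted(names, key=lambda name: -v[g == name].mean())
    columns: list[set] = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop duplicates and strict subsets
        pruned = []
        for col in new_cols:
            if any(col < other or (col == other and col in pruned) for other in new_cols):
                continue
            if col not in pruned:
                pruned.append(col)
        columns = pruned
    columns.sort(key=lambda col: min(order.index(name) for name in col))
    letters = {name: "" for name in order}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for name in order:
            if name in col:
                letters[name] += letter
    return letters
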