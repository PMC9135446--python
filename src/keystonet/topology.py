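"""Network modules, node roles, module eigengenes, and spectral robustness.

Modules are detected with the MCODE procedure (vertex weighting by the
density of the highest k-core of each closed neighborhood, greedy seeded
expansion, haircut post-processing).  Node roles follow the classic
within-module degree z-score (Z) / participation coefficient (P) scheme:
module hubs — the network's candidate keystone taxa — have Z > 2.5 and
P < 0.62.  All role topology is computed on the unsigned skeleton; edge
signs are kept for reporting only.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io import OtuTable

logger = logging.getLogger(__name__)

UNASSIGNED = -1

__all__ = [
    "ModulePartition",
    "mcode_modules",
    "within_module_degree_z",
    "participation_coefficient",
    "classify_roles",
    "node_topology_table",
    "module_eigengene",
    "EigengeneMatrix",
    "natural_connectivity",
    "robustness_curve",
    "RobustnessCurve",
]


def _roman(n: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
                (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
                (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclasses.dataclass(frozen=True)
class ModulePartition:
    """Node -> module assignment; modules are disjoint node sets of size >= 3
    ordered by descending size and labeled I, II, ...  Nodes outside every
    module carry the sentinel ``UNASSIGNED`` (-1)."""

    assignments: dict
    modules: tuple

    def __post_init__(self) -> None:
        seen: set = set()
        for mod in self.modules:
            if len(mod) < 3:
                raise ValueError("every module must have at least 3 nodes")
            if seen & set(mod):
                raise ValueError("modules must be disjoint")
            seen |= set(mod)
        sizes = [len(m) for m in self.modules]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("modules must be ordered by descending size")

    @classmethod
    def from_modules(cls, modules, all_nodes) -> "ModulePartition":
        ordered = tuple(
            frozenset(m)
            for m in sorted(modules, key=lambda m: (-len(m), sorted(m)))
        )
        assignments = {node: UNASSIGNED for node in all_nodes}
        for idx, mod in enumerate(ordered):
            for node in mod:
                assignments[node] = idx
        return cls(assignments=assignments, modules=ordered)

    def label_of(self, node) -> str:
        idx = self.assignments.get(node, UNASSIGNED)
        return _roman(idx + 1) if idx != UNASSIGNED else "unassigned"

    @property
    def labels(self) -> list[str]:
        return [_roman(i + 1) for i in range(len(self.modules))]

    def members(self, label: str) -> frozenset:
        return self.modules[self.labels.index(label)]

    @property
    def n_modules(self) -> int:
        return len(self.modules)


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weight(G: nx.Graph, v) -> float:
    """Weight = k * density of the highest k-core of v's closed neighborhood."""
    nodes = set(G[v]) | {v}
    sub = G.subgraph(nodes)
    if sub.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(sub)
    k = max(core.values())
    kcore = sub.subgraph([n for n, c in core.items() if c >= k])
    return k * _density(kcore)


def mcode_modules(
    net: nx.Graph,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    absorb_unassigned: bool = False,
) -> ModulePartition:
    """MCODE complex detection on the unsigned network skeleton.

    Stages: (1) vertex weighting; (2) greedy expansion from the
    highest-weight unseen vertex, admitting neighbors whose weight is at
    least ``seed weight * (1 - node_score_cutoff)``; (3) post-processing —
    the haircut removes singly-connected vertices (iterated to a fixed
    point) and complexes whose densest core falls below ``k_core`` or that
    end up smaller than 3 nodes are discarded.  Complexes become modules
    ordered by size.

    With ``absorb_unassigned`` a greedy-modularity fallback assigns leftover
    nodes: each unassigned node joins the module that overlaps its
    greedy-modularity community most, provided it has at least two links
    into that module (so pendant noise nodes stay out).
    """
    if not 0 <= node_score_cutoff < 1:
        raise ValueError("node_score_cutoff must be in [0, 1)")
    weights = {v: _vertex_weight(net, v) for v in net.nodes}
    order = sorted(net.nodes, key=lambda v: (-weights[v], str(v)))
    seen: set = set()
    complexes: list[set] = []
    for seed in order:
        if seed in seen:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        seen.add(seed)
        while frontier:
            current = frontier.pop()
            for nbr in sorted(net[current], key=str):
                if nbr in seen:
                    continue
                if weights[nbr] >= threshold:
                    seen.add(nbr)
                    members.add(nbr)
                    frontier.append(nbr)
        sub = net.subgraph(members).copy()
        if haircut:
            while True:
                leaves = [v for v in sub.nodes if sub.degree(v) < 2]
                if not leaves:
                    break
                sub.remove_nodes_from(leaves)
        if sub.number_of_nodes() < 3:
            continue
        if max(nx.core_number(sub).values(), default=0) < k_core:
            continue
        complexes.append(set(sub.nodes))

    part = ModulePartition.from_modules(complexes, net.nodes)
    if absorb_unassigned and part.n_modules:
        part = _absorb_by_greedy_modularity(net, part)
    return part


def _absorb_by_greedy_modularity(net: nx.Graph, part: ModulePartition) -> ModulePartition:
    communities = list(nx.community.greedy_modularity_communities(net))
    comm_of = {}
    for comm in communities:
        for node in comm:
            comm_of[node] = comm
    modules = [set(m) for m in part.modules]
    for node, idx in sorted(part.assignments.items(), key=lambda kv: str(kv[0])):
        if idx != UNASSIGNED:
            continue
        comm = comm_of.get(node)
        if comm is None:
            continue
        best, best_overlap = None, 0
        for j, mod in enumerate(modules):
            overlap = len(mod & set(comm))
            if overlap > best_overlap:
                best, best_overlap = j, overlap
        if best is None:
            continue
        links = sum(1 for nbr in net[node] if nbr in modules[best])
        if links >= 2:
            modules[best].add(node)
    return ModulePartition.from_modules(modules, net.nodes)


# ---------------------------------------------------------------------------
# Zi-Pi roles
# ---------------------------------------------------------------------------

def within_module_degree_z(net: nx.Graph, part: ModulePartition) -> pd.Series:
    """Within-module degree z-score for every assigned node.

    Z_i = (kappa_i - mean kappa) / population SD of kappa over the node's
    module, with kappa the within-module degree.  A zero SD (including
    modules of size 1) yields Z = 0 by convention.
    """
    z = {}
    for mod in part.modules:
        kappa = {
            v: sum(1 for nbr in net[v] if nbr in mod) for v in sorted(mod, key=str)
        }
        vals = np.array(list(kappa.values()), dtype=float)
        mu = vals.mean()
        sd = vals.std(ddof=0)
        for v, k in kappa.items():
            z[v] = 0.0 if sd == 0 else (k - mu) / sd
    return pd.Series(z, dtype=float).sort_index()


def participation_coefficient(net: nx.Graph, part: ModulePartition) -> pd.Series:
    """P_i = 1 - sum_s (k_is / k_i)^2 over modules s, for assigned nodes.

    Edges to unassigned neighbors count toward a single pseudo-module, so
    the split always covers the full degree; k_i = 0 gives P = 0.
    """
    p = {}
    for node, idx in part.assignments.items():
        if idx == UNASSIGNED:
            continue
        k_i = net.degree(node)
        if k_i == 0:
            p[node] = 0.0
            continue
        split: dict = {}
        for nbr in net[node]:
            s = part.assignments.get(nbr, UNASSIGNED)
            split[s] = split.get(s, 0) + 1
        p[node] = 1.0 - sum((k / k_i) ** 2 for k in split.values())
    return pd.Series(p, dtype=float).sort_index()


def classify_roles(Z: float, P: float, z_cut: float = 2.5, p_cut: float = 0.62) -> str:
    """Topological role from (Z, P): module hubs (the candidate keystone
    taxa) have Z strictly above ``z_cut`` and P strictly below ``p_cut``."""
    if not (np.isfinite(Z) and np.isfinite(P)):
        raise ValueError("Z and P must be finite")
    if Z > z_cut:
        return "module hub" if P < p_cut else "network hub"
    return "connector" if P >= p_cut else "peripheral"


def node_topology_table(
    net: nx.Graph,
    part: ModulePartition,
    z_cut: float = 2.5,
    p_cut: float = 0.62,
) -> pd.DataFrame:
    """Per-node role table mirroring the usual keystone-taxon listing:
    OTU id, guild, module, degree, mean relative abundance (%), Z, P, role.
    Unassigned nodes are excluded (their Z is undefined)."""
    Z = within_module_degree_z(net, part)
    P = participation_coefficient(net, part)
    rows = []
    for node in Z.index:
        data = net.nodes[node]
        rows.append(
            {
                "otu_id": node,
                "guild": data.get("guild", ""),
                "module": part.label_of(node),
                "degree": net.degree(node),
                "abundance_pct": 100.0 * data.get("mean_relative_abundance", np.nan),
                "Z": Z[node],
                "P": P[node],
                "role": classify_roles(Z[node], P[node], z_cut=z_cut, p_cut=p_cut),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["otu_id", "guild", "module", "degree", "abundance_pct",
                 "Z", "P", "role"],
    )


# ---------------------------------------------------------------------------
# Module eigengenes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EigengeneMatrix:
    """Samples x modules eigengene scores (each column unit-norm), the
    variance explained by each first component, and the sign convention
    (oriented to correlate positively with the module's mean standardized
    profile)."""

    values: pd.DataFrame
    variance_explained: pd.Series
    orientation: str = "mean-profile-positive"


def module_eigengene(
    table: OtuTable,
    part: ModulePartition,
    samples=None,
) -> EigengeneMatrix:
    """First principal component of each module's standardized abundances.

    Member OTU profiles (relative abundance across the chosen samples) are
    z-scored, and the leading left singular vector of the samples x members
    matrix gives the eigengene (unit norm).  The sign is oriented so the
    eigengene correlates positively with the module's mean standardized
    profile.  Zero-variance members are dropped with a log entry; a module
    with fewer than 2 usable members is an error.
    """
    sub = table if samples is None else table.subset_samples(samples)
    rel = sub.relative_abundance()
    cols = {}
    varexp = {}
    for label in part.labels:
        members = sorted(part.members(label), key=str)
        missing = [m for m in members if m not in rel.columns]
        if missing:
            raise KeyError(f"module {label} members missing from table: {missing}")
        X = rel[members].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            dropped = [m for m, s in zip(members, sd) if s == 0]
            logger.info("module %s: dropping zero-variance members %s", label, dropped)
            keep = sd > 0
            X = X[:, keep]
        if X.shape[1] < 2:
            raise ValueError(f"module {label} has fewer than 2 usable members")
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        U, S, _ = np.linalg.svd(Xs, full_matrices=False)
        eig = U[:, 0]
        mean_profile = Xs.mean(axis=1)
        align = float(eig @ mean_profile)
        if align < 0 or (align == 0 and eig[np.argmax(np.abs(eig))] < 0):
            eig = -eig
        cols[label] = eig
        varexp[label] = float(S[0] ** 2 / (S**2).sum())
    values = pd.DataFrame(cols, index=rel.index)
    return EigengeneMatrix(values=values, variance_explained=pd.Series(varexp))


# ---------------------------------------------------------------------------
# Natural connectivity and robustness
# ---------------------------------------------------------------------------

def natural_connectivity(net: nx.Graph) -> float:
    """ln((1/n) sum_i exp(lambda_i)) over the eigenvalues of the unweighted
    adjacency matrix, computed with a max-shift for stability."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity is undefined for an empty node set")
    A = nx.to_numpy_array(net, weight=None)
    lam = np.linalg.eigvalsh(A)
    lmax = lam.max()
    return float(lmax + np.log(np.mean(np.exp(lam - lmax))))


@dataclasses.dataclass(frozen=True)
class RobustnessCurve:
    fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    replicates: np.ndarray  # n_reps x n_fractions (targeted: single row)
    strategy: str
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "mean": self.mean, "sd": self.sd}
        )


def robustness_curve(
    net: nx.Graph,
    strategy: str = "random",
    fractions=(0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
    n_reps: int = 20,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity under progressive node removal.

    ``random`` removes seeded uniform node subsets (``n_reps`` replicates,
    mean +/- SD reported); ``degree-targeted`` removes nodes in descending
    intact-network degree (deterministic, ties broken by node id).  The
    value at fraction 0 is exactly the intact network's natural
    connectivity.
    """
    if strategy not in ("random", "degree-targeted"):
        raise ValueError(f"unknown removal strategy {strategy!r}")
    fr = np.asarray(sorted(fractions), dtype=float)
    if np.any(fr < 0) or np.any(fr >= 1):
        raise ValueError("removal fractions must lie in [0, 1)")
    n = net.number_of_nodes()
    counts = np.rint(fr * n).astype(int)
    if np.any(counts >= n):
        raise ValueError("a removal fraction would delete every node")
    intact = natural_connectivity(net)
    nodes = sorted(net.nodes, key=str)

    def after_removal(removed) -> float:
        keep = [v for v in nodes if v not in removed]
        return natural_connectivity(net.subgraph(keep))

    if strategy == "degree-targeted":
        ranked = sorted(nodes, key=lambda v: (-net.degree(v), str(v)))
        vals = [intact if c == 0 else after_removal(set(ranked[:c])) for c in counts]
        reps = np.array([vals])
    else:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_reps, len(fr)))
        for i in range(n_reps):
            for j, c in enumerate(counts):
                if c == 0:
                    reps[i, j] = intact
                else:
                    removed = set(rng.choice(nodes, size=c, replace=False))
                    reps[i, j] = after_removal(removed)
    return RobustnessCurve(
        fractions=fr,
        mean=reps.mean(axis=0),
        sd=reps.std(axis=0, ddof=0),
        replicates=reps,
        strategy=strategy,
        seed=seed,
    )
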