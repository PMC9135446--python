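"""Readers, writers and the central in-memory containers.

On disk, OTU tables follow the common amplicon dialect (OTUs as rows,
samples as columns, first column the OTU id); in memory the orientation is
samples x OTUs.  All readers validate and reject malformed input rather
than coercing it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

GUILDS = ("AOA", "AOB")
DEFAULT_TREATMENTS = ("CK", "N", "NS", "NSM", "NB")

#: Metadata columns that must be non-negative where present.
_NONNEGATIVE_METADATA = (
    "SOC",
    "TN",
    "NO3_N",
    "NH4_N",
    "SWC",
    "grain_yield",
    "straw_biomass",
    "amoa_aoa_copies",
    "amoa_aob_copies",
)


@dataclasses.dataclass(frozen=True)
class OtuTable:
    """A samples x OTUs count matrix with per-OTU taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = sample ids, columns = OTU ids.
    taxonomy
        Indexed by OTU id with columns ``guild`` (``AOA``/``AOB``),
        ``cluster`` and ``genus``.  Every OTU in ``counts`` must appear.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        counts, taxonomy = self.counts, self.taxonomy
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dupes}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_offender(counts, lambda v: not _is_number(v))
            raise ValueError(f"non-numeric count at {bad}")
        if not np.isfinite(arr).all():
            bad = _first_offender(counts, lambda v: not np.isfinite(v))
            raise ValueError(f"non-finite count at {bad}")
        if (arr < 0).any():
            bad = _first_offender(counts, lambda v: v < 0)
            raise ValueError(f"negative count at {bad}")
        if np.any(np.mod(arr, 1) != 0):
            bad = _first_offender(counts, lambda v: v % 1 != 0)
            raise ValueError(f"non-integer count at {bad}")
        if taxonomy.index.duplicated().any():
            dupes = taxonomy.index[taxonomy.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids in taxonomy: {dupes}")
        missing = [o for o in counts.columns if o not in taxonomy.index]
        if missing:
            raise ValueError(f"OTUs lacking a taxonomy entry: {missing}")
        for col in ("guild", "cluster"):
            if col not in taxonomy.columns:
                raise ValueError(f"taxonomy is missing the '{col}' column")
        bad_guilds = sorted(set(taxonomy["guild"]) - set(GUILDS))
        if bad_guilds:
            raise ValueError(f"unknown guilds {bad_guilds}; expected {GUILDS}")

    # -- convenience views ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def guild_of(self, otu_id: str) -> str:
        return str(self.taxonomy.loc[otu_id, "guild"])

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by each sample's total over the combined table."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def subset_otus(self, otu_ids) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(
            self.counts.loc[:, list(otu_ids)],
            self.taxonomy.loc[list(otu_ids)],
        )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_offender(df: pd.DataFrame, pred) -> str:
    for col in df.columns:
        for row, v in df[col].items():
            try:
                offends = pred(v)
            except TypeError:
                offends = True
            if offends:
                return f"row '{row}', column '{col}' (value {v!r})"
    return "unknown position"


# ---------------------------------------------------------------------------
# OTU table / taxonomy / metadata TSV
# ---------------------------------------------------------------------------

def read_otu_table(
    table_path: str | Path,
    taxonomy_path: str | Path,
    orientation: str = "auto",
) -> OtuTable:
    """Read a tab-separated OTU table and its taxonomy map.

    ``orientation`` may be ``"otus_as_rows"`` (the on-disk default),
    ``"samples_as_rows"`` or ``"auto"``, which matches the row index against
    the taxonomy's OTU ids.
    """
    raw = pd.read_csv(table_path, sep="\t", index_col=0)
    taxonomy = read_taxonomy(taxonomy_path)
    if orientation == "auto":
        rows_are_otus = all(i in taxonomy.index for i in raw.index)
        cols_are_otus = all(c in taxonomy.index for c in raw.columns)
        if rows_are_otus and not cols_are_otus:
            orientation = "otus_as_rows"
        elif cols_are_otus and not rows_are_otus:
            orientation = "samples_as_rows"
        elif rows_are_otus and cols_are_otus:
            raise ValueError("ambiguous orientation; pass it explicitly")
        else:
            missing = [i for i in raw.index if i not in taxonomy.index]
            raise ValueError(f"OTUs lacking a taxonomy entry: {missing}")
    if orientation == "otus_as_rows":
        counts = raw.T
    elif orientation == "samples_as_rows":
        counts = raw
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    counts.index.name = "sample_id"
    counts.columns.name = "otu_id"
    return OtuTable(counts, taxonomy)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    tax.index.name = "otu_id"
    if "genus" not in tax.columns:
        tax["genus"] = ""
    return tax


def write_otu_table(table: OtuTable, table_path: str | Path,
                    taxonomy_path: str | Path | None = None) -> None:
    """Write counts (OTUs as rows) and, optionally, the taxonomy map."""
    out = table.counts.T
    out.index.name = "otu_id"
    out.to_csv(table_path, sep="\t")
    if taxonomy_path is not None:
        table.taxonomy.to_csv(taxonomy_path, sep="\t")


def read_metadata(path: str | Path, treatments=None) -> pd.DataFrame:
    """Read per-sample metadata; missing values stay missing (never zero)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index.name = "sample_id"
    return validate_metadata(meta, treatments=treatments)


def validate_metadata(meta: pd.DataFrame, treatments=None) -> pd.DataFrame:
    if meta.index.duplicated().any():
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    if "treatment" not in meta.columns:
        raise ValueError("metadata must have a 'treatment' column")
    declared = tuple(treatments) if treatments is not None else DEFAULT_TREATMENTS
    unknown = sorted(set(meta["treatment"].astype(str)) - set(declared))
    if unknown:
        raise ValueError(
            f"treatment labels {unknown} not in the declared set {declared}"
        )
    for col in _NONNEGATIVE_METADATA:
        if col in meta.columns:
            vals = pd.to_numeric(meta[col], errors="coerce")
            neg = meta.index[vals < 0].tolist()
            if neg:
                raise ValueError(f"negative values in '{col}' for samples {neg}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("guild", "mean_relative_abundance", "module", "Z", "P", "role")
_EDGE_ATTRS = ("r", "p", "q", "sign")


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-occurrence network for downstream tools (e.g., Gephi).

    ``graphml`` carries all node/edge annotations; ``edgelist_csv`` writes
    a CSV with columns source, target, r, p, q, sign.
    """
    if format == "graphml":
        clean = nx.Graph()
        clean.graph.update({k: v for k, v in net.graph.items()
                            if isinstance(v, (str, int, float, bool))})
        for node, data in net.nodes(data=True):
            attrs = {k: data[k] for k in _NODE_ATTRS if k in data and data[k] is not None}
            clean.add_node(node, **attrs)
        for u, v, data in net.edges(data=True):
            attrs = {k: data[k] for k in _EDGE_ATTRS if k in data and data[k] is not None}
            clean.add_edge(u, v, **attrs)
        nx.write_graphml(clean, path)
    elif format == "edgelist_csv":
        rows = [
            {"source": u, "target": v,
             "r": d.get("r"), "p": d.get("p"), "q": d.get("q"),
             "sign": d.get("sign")}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "p", "q", "sign"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
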