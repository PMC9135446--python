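"""Config-driven orchestration of the full analysis with a run manifest.

A run executes, per named sample group (e.g., the OM- and OM+ condition
subsets): prevalence filter -> correlations -> network -> MCODE modules ->
Zi-Pi roles -> module eigengenes -> robustness -> eigengene/metadata
associations, plus table-wide diversity and (optionally) PNA function
tables.  Every artifact lands in the run directory together with a
machine-readable manifest (versions, seeds, thresholds, input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc import eigengene_metadata_correlations
from .diversity import alpha_diversity_table
from .io import (
    OtuTable,
    read_metadata,
    read_otu_table,
    write_network,
)
from .network import (
    build_network,
    edge_composition,
    pairwise_correlations,
    prevalence_filter,
)
from .nfunction import partition_assays, read_pna_table
from .topology import (
    mcode_modules,
    module_eigengene,
    natural_connectivity,
    node_topology_table,
    robustness_curve,
)

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_GROUPS = {"OM-": ["CK", "N"], "OM+": ["NS", "NSM", "NB"]}
DEFAULT_ASSOC_TARGETS = [
    "pH", "SOC", "TN", "NO3_N", "NH4_N", "SWC",
    "grain_yield", "straw_biomass", "amoa_aoa_copies", "amoa_aob_copies",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    otu_path: str
    taxonomy_path: str
    metadata_path: str
    outdir: str
    pna_path: str | None = None
    sample_groups: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SAMPLE_GROUPS)
    )
    method: str = "spearman"
    prevalence: float = 0.75
    r_threshold: float = 0.7
    p_threshold: float = 0.01
    use_adjusted: bool = True
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    absorb_unassigned: bool = True
    z_cut: float = 2.5
    p_cut: float = 0.62
    assoc_targets: list = dataclasses.field(
        default_factory=lambda: list(DEFAULT_ASSOC_TARGETS)
    )
    robustness_fractions: list = dataclasses.field(
        default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    )
    robustness_reps: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate_groups(self, metadata: pd.DataFrame) -> None:
        present = set(metadata["treatment"].astype(str))
        for name, treatments in self.sample_groups.items():
            missing = sorted(set(treatments) - present)
            if missing:
                raise ValueError(
                    f"sample group {name!r} references treatments {missing} "
                    "absent from the metadata"
                )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure aborts with the stage name; partial outputs are
    retained next to a ``FAILED`` marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "keystonet",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "prevalence": config.prevalence,
            "r_threshold": config.r_threshold,
            "p_threshold": config.p_threshold,
            "use_adjusted": config.use_adjusted,
            "z_cut": config.z_cut,
            "p_cut": config.p_cut,
        },
        "inputs": {},
        "stages": {},
    }
    for key in ("otu_path", "taxonomy_path", "metadata_path", "pna_path"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        table = read_otu_table(config.otu_path, config.taxonomy_path)
        metadata = read_metadata(config.metadata_path)
        config.validate_groups(metadata)
        manifest["stages"][stage] = "completed"

        stage = "diversity"
        alpha_diversity_table(table).to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        manifest["stages"][stage] = "completed"

        for group, treatments in config.sample_groups.items():
            tag = group.replace("+", "plus").replace("-", "minus").replace(" ", "_")
            samples = metadata.index[
                metadata["treatment"].astype(str).isin(treatments)
            ].tolist()
            sub = table.subset_samples(samples)

            stage = f"network[{group}]"
            filtered = prevalence_filter(sub, config.prevalence)
            corr = pairwise_correlations(filtered, method=config.method)
            corr.to_csv(outdir / f"correlations_{tag}.tsv", sep="\t", index=False)
            net = build_network(
                corr, filtered,
                r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
                use_adjusted=config.use_adjusted,
            )
            manifest["stages"][stage] = "completed"

            stage = f"modules[{group}]"
            part = mcode_modules(
                net,
                node_score_cutoff=config.node_score_cutoff,
                k_core=config.k_core,
                haircut=config.haircut,
                absorb_unassigned=config.absorb_unassigned,
            )
            for node in net.nodes:
                net.nodes[node]["module"] = part.label_of(node)
            roles = node_topology_table(net, part, z_cut=config.z_cut,
                                        p_cut=config.p_cut)
            for row in roles.itertuples(index=False):
                net.nodes[row.otu_id]["Z"] = float(row.Z)
                net.nodes[row.otu_id]["P"] = float(row.P)
                net.nodes[row.otu_id]["role"] = row.role
            roles.to_csv(outdir / f"roles_{tag}.tsv", sep="\t", index=False)
            write_network(net, outdir / f"network_{tag}.graphml", "graphml")
            write_network(net, outdir / f"edges_{tag}.csv", "edgelist_csv")
            comp = edge_composition(net)
            (outdir / f"edge_composition_{tag}.json").write_text(
                json.dumps({"pnc": comp.pnc, "n_edges": comp.n_edges,
                            "counts": {f"{a}-{b}:{s}": c
                                       for (a, b, s), c in comp.counts.items()}},
                           indent=2)
            )
            manifest["stages"][stage] = "completed"

            stage = f"eigengenes[{group}]"
            if part.n_modules:
                eig = module_eigengene(sub, part)
                eig.values.to_csv(outdir / f"eigengenes_{tag}.tsv", sep="\t")
                assoc = eigengene_metadata_correlations(
                    eig, metadata,
                    [t for t in config.assoc_targets if t in metadata.columns],
                )
                assoc.to_csv(outdir / f"module_associations_{tag}.tsv",
                             sep="\t", index=False)
            manifest["stages"][stage] = "completed"

            stage = f"robustness[{group}]"
            if net.number_of_nodes():
                curve = robustness_curve(
                    net, strategy="random",
                    fractions=config.robustness_fractions,
                    n_reps=config.robustness_reps, seed=config.seed,
                )
                curve.as_frame().to_csv(outdir / f"robustness_{tag}.tsv",
                                        sep="\t", index=False)
                manifest.setdefault("natural_connectivity", {})[group] = (
                    natural_connectivity(net)
                )
            manifest["stages"][stage] = "completed"

        if config.pna_path:
            stage = "pna"
            assays = read_pna_table(config.pna_path)
            by_sample: dict = {}
            for assay in assays:
                by_sample.setdefault(assay.sample_id, {})[assay.octyne] = assay
            rows = []
            for sample, pair in sorted(by_sample.items()):
                if True in pair and False in pair:
                    res = partition_assays(pair[False], pair[True])
                    rows.append({"sample": sample, "pna_aoa": res.pna_aoa,
                                 "pna_aob": res.pna_aob,
                                 "pna_total": res.pna_total})
            pd.DataFrame(rows).to_csv(outdir / "pna_results.tsv", sep="\t",
                                      index=False)
            manifest["stages"][stage] = "completed"
    except Exception as exc:  # noqa: BLE001 - abort with stage provenance
        manifest["stages"][stage] = "failed"
        manifest["error"] = str(exc)
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
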