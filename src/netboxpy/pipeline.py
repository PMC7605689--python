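"""One-shot pipeline: load inputs, fit, assess, write a results bundle.

The bundle written by :func:`run_pipeline` contains::

    linker_table.tsv        all candidates with p-values and accepted flag
    module_table.tsv        gene, module_id, role for the extended network
    extended_network.sif    the extended network (SIF)
    extended_network.graphml  the same, for visualization tools
    dropped_altered.txt     mapped altered genes isolated in the extended set
    significance.tsv/.json  both significance tests
    manifest.json           config, seed, package version, input checksums

Runs are exactly reproducible from the manifest: same inputs + same config
+ same seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .model import NetBoxModel
from .network_io import load_edge_table, load_gene_list, load_sif, write_network
from .significance import DEFAULT_LCC_TRIALS, DEFAULT_MOD_TRIALS, DEFAULT_SWAP_FACTOR

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    network_path: str
    gene_list_path: str
    output_dir: str
    cutoff: float = 0.05
    linker_mode: str = "tail"
    community_method: str = "edge_betweenness"
    lcc_trials: int = DEFAULT_LCC_TRIALS
    mod_trials: int = DEFAULT_MOD_TRIALS
    swap_factor: float = DEFAULT_SWAP_FACTOR
    seed: int = 0
    network_format: str = "sif"  # or "edge-table"
    force: bool = False

    def validate(self) -> None:
        if not 0 < self.cutoff <= 1:
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.lcc_trials < 1 or self.mod_trials < 2:
            raise ValueError("lcc_trials must be >= 1 and mod_trials >= 2")
        if not Path(self.network_path).is_file():
            raise FileNotFoundError(f"network file not found: {self.network_path}")
        if not Path(self.gene_list_path).is_file():
            raise FileNotFoundError(f"gene list file not found: {self.gene_list_path}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("=== %s ===", name)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and write the results bundle.

    Returns the output directory. Raises with a stage-named message on any
    stage failure; refuses to write into a non-empty directory unless
    ``config.force`` is set.
    """
    config.validate()
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    _stage("load inputs")
    if config.network_format == "sif":
        network = load_sif(config.network_path)
    elif config.network_format == "edge-table":
        network = load_edge_table(config.network_path)
    else:
        raise ValueError(f"unknown network format {config.network_format!r}")
    altered = load_gene_list(config.gene_list_path, network)
    logger.info(
        "network: %d nodes / %d edges; altered: %d mapped, %d unmapped",
        network.number_of_nodes(), network.number_of_edges(),
        len(altered.mapped), len(altered.unmapped),
    )

    _stage("linker inference + community detection")
    model = NetBoxModel(network, altered)
    results = model.fit(
        cutoff=config.cutoff,
        linker_mode=config.linker_mode,
        community_method=config.community_method,
    )
    n_acc = sum(r.accepted for r in results.linker_results)
    logger.info(
        "candidates tested: %d; linkers accepted: %d; modules: %d (Q=%.4f)",
        len(results.linker_results), n_acc,
        results.partition.n_modules, results.partition.modularity,
    )

    _stage("significance tests")
    report = results.assess_significance(
        lcc_trials=config.lcc_trials,
        mod_trials=config.mod_trials,
        swap_factor=config.swap_factor,
        seed=config.seed,
    )
    logger.info("LCC p=%.4g; modularity z=%.2f p=%.4g", report.lcc_p, report.Q_z, report.Q_p)

    _stage("write bundle")
    results.linker_table.to_csv(out / "linker_table.tsv", sep="\t", index=False, lineterminator="\n")
    results.module_table.to_csv(out / "module_table.tsv", sep="\t", index=False, lineterminator="\n")
    write_network(results.extended.network, out / "extended_network.sif", format="sif")
    write_network(results.extended.network, out / "extended_network.graphml", format="graphml")
    (out / "dropped_altered.txt").write_text(
        "".join(f"{g}\n" for g in results.extended.dropped_altered), encoding="utf-8"
    )
    rep = report.to_dict()
    (out / "significance.json").write_text(json.dumps(rep, indent=2) + "\n", encoding="utf-8")
    scalar_keys = [k for k in rep if k != "lcc_null_sizes"]
    (out / "significance.tsv").write_text(
        "\t".join(scalar_keys) + "\n" + "\t".join(repr(rep[k]) for k in scalar_keys) + "\n",
        encoding="utf-8",
    )
    manifest = {
        "package": "netboxpy",
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items() if k != "force"},
        "inputs": {
            "network_sha256": _sha256(config.network_path),
            "gene_list_sha256": _sha256(config.gene_list_path),
        },
        "summary": {
            "nodes_mapped": len(altered.mapped),
            "candidates_tested": len(results.linker_results),
            "linkers_accepted": n_acc,
            "modules": results.partition.n_modules,
            "modularity": results.partition.modularity,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    (out / "summary.txt").write_text(results.summary(), encoding="utf-8")
    return out
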