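"""End-to-end pipeline: landscape -> tree -> clouds -> analyses -> CSVs.

``run_pipeline`` executes the full workflow with one reproducible
configuration: build and prune the wildcard lattice, encode and cluster
the leaves into activity clouds, fit the positional-influence model,
analyze the mutational graph, and write every export plus a manifest
(configuration, seed, library versions, final eps) into a single run
directory.  Identical configuration and seed yield byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import sklearn

from . import __version__
from .etr_data import (
    EtrMap,
    SyntheticLandscapeConfig,
    generate_synthetic_landscape,
)
from .lattice import PrunedLatticeTree
from .clouds import ActivityCloudPartitioner
from .influence import (
    PositionalInfluencePLS,
    high_etr_cloud_composition,
    level_composition,
)
from .mutgraph import (
    beneficial_fractions,
    build_hamming_graph,
    giant_fraction_histogram,
    intracloud_metrics,
    meta_matrices,
    transition_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run.  Defaults pin the published parameters:
    eps sweep 5.9 + 0.05 up to 400 labels with min_samples 1, spacers
    5-8 nt, 4 PLS components with an 80/20 split, read-count filter 500.
    """

    out_dir: str | Path = "run"
    etr_tsv: str | Path | None = None  # None -> synthetic landscape
    seed: int = 42
    # synthetic landscape (used when etr_tsv is None)
    baseline: float = 0.12
    noise_sd: float = 0.02
    # eps sweep
    eps_start: float = 5.9
    eps_step: float = 0.05
    label_cap: int = 400
    min_samples: int = 1
    # SD-core calling
    spacer_min: int = 5
    spacer_max: int = 8
    min_read_count: int = 500
    # positional influence
    pls_components: int = 4
    train_fraction: float = 0.8
    # graph exports
    high_etr_threshold: float = 0.75
    cloud_matrix_order: str = "mean_etr"  # or "label"
    max_path_nodes: int | None = 1500
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        if d["etr_tsv"] is not None:
            d["etr_tsv"] = str(d["etr_tsv"])
        return d


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _load_landscape(config: RunConfig) -> EtrMap:
    if config.etr_tsv is not None:
        return EtrMap.from_tsv(config.etr_tsv)
    return generate_synthetic_landscape(
        SyntheticLandscapeConfig(
            baseline=config.baseline,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write all exports; returns artifact paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def export(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = path
        return path

    def stage(name):
        logger.info("stage %s: start", name)

    try:
        stage("landscape")
        etr_map = _load_landscape(config)
        logger.info("stage landscape: %d cores", len(etr_map))
        export("etr_map.tsv", etr_map.to_tsv)

        stage("tree")
        tree = PrunedLatticeTree().fit(etr_map)
        logger.info("stage tree: %d paths", len(tree.leaf_paths_))
        export("paths.csv", tree.export_paths)

        stage("cluster")
        partitioner = ActivityCloudPartitioner(
            eps_start=config.eps_start,
            eps_step=config.eps_step,
            label_cap=config.label_cap,
            min_samples=config.min_samples,
        )
        cloud_table = partitioner.fit_tree(tree, etr_map)
        logger.info(
            "stage cluster: %d clouds at eps=%g",
            cloud_table.n_clouds,
            partitioner.eps_,
        )
        export("clusters_with_stats.csv", cloud_table.to_csv)

        stage("influence")
        infl = PositionalInfluencePLS(
            n_components=config.pls_components,
            train_fraction=config.train_fraction,
            random_state=config.seed,
        ).fit_landscape(etr_map)
        export(
            "influence_raw.csv", lambda p: infl.raw_.to_csv(p, index_label="symbol")
        )
        export(
            "influence_abs.csv",
            lambda p: infl.absolute_.to_csv(p, index_label="symbol"),
        )
        for level in (1, 2):
            comp = level_composition(tree, level)
            export(
                f"level{level}_composition.csv",
                lambda p, c=comp: c.to_csv(p, index_label="base"),
            )
        high = high_etr_cloud_composition(
            cloud_table, config.high_etr_threshold
        )
        export(
            "high_etr_composition.csv",
            lambda p: high.to_csv(p, index_label="base"),
        )

        stage("graph")
        G = build_hamming_graph(etr_map, cloud_table)
        logger.info(
            "stage graph: %d nodes, %d edges",
            G.number_of_nodes(),
            G.number_of_edges(),
        )
        metrics = intracloud_metrics(G, max_path_nodes=config.max_path_nodes)
        export("cloud_metrics.csv", lambda p: metrics.to_csv(p, index=False))
        counts, detr = meta_matrices(G, order=config.cloud_matrix_order)
        export(
            "bridge_counts.csv", lambda p: counts.to_csv(p, index_label="cloud")
        )
        export(
            "mean_abs_detr.csv", lambda p: detr.to_csv(p, index_label="cloud")
        )
        P = transition_matrix(G, order=config.cloud_matrix_order)
        export(
            "transition_matrix.csv", lambda p: P.to_csv(p, index_label="cloud")
        )
        B = beneficial_fractions(G, order=config.cloud_matrix_order)
        export(
            "beneficial_fractions.csv",
            lambda p: B.to_csv(p, index_label="cloud"),
        )
        hist = giant_fraction_histogram(metrics)
        export(
            "giant_fraction_hist.csv", lambda p: hist.to_csv(p, index=False)
        )
    except Exception as exc:  # annotate with the failing stage context
        raise PipelineError(f"pipeline failed: {exc}") from exc

    manifest = {
        "sdclouds_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "final_eps": partitioner.eps_,
        "n_clouds": cloud_table.n_clouds,
        "n_singleton_clouds": int((cloud_table.stats["n"] == 1).sum()),
        "n_paths": len(tree.leaf_paths_),
        "influence_r2": infl.r2_,
        "library_versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "networkx": networkx.__version__,
        },
        "artifact_sha256": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(artifacts.items())
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest.json"] = manifest_path
    return artifacts
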