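"""End-to-end orchestration: from tables (or the synthetic generator) to
networks, modules, core taxa, pathways, multivariate statistics and the
PLS path model, with every intermediate persisted and a manifest of
artifact paths, checksums and parameters.

A single root seed fans out to fixed per-stage offsets so individual
stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, cooccurrence, core_io, core_taxa, multivariate, pathway, plspm
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("rhizonet")

__all__ = ["PipelineConfig", "run_pipeline"]

STAGE_SEEDS = {"generator": 0, "permanova": 101, "mantel": 211,
               "core_taxa": 307, "plspm": 401}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full run.

    When ``feature_table`` is None the synthetic generator supplies the
    dataset (including nutrients and enzyme-gene abundances), and the
    planted ground truth is written alongside the outputs.
    """

    output_dir: str = "rhizonet_out"
    feature_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    nutrients: str | None = None
    gene_table: str | None = None
    gene_panels: str | None = None
    network_r_min: float = 0.70
    network_p_max: float = 0.01
    pathway_r_min: float = 0.60
    pathway_p_max: float = 0.05
    abundance_filter: float = 0.005
    min_module_size: int = 20
    n_perm: int = 999
    n_boot: int = 1000
    rf_trees: int = 100
    rf_perm: int = 30
    seed: int = 0
    generator: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        for name in ("network_r_min", "network_p_max", "pathway_r_min",
                     "pathway_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGE_SEEDS[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def save_df(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        artifacts[name] = str(path)
        return path

    stage = "load"
    try:
        truth = None
        if cfg.feature_table is None:
            stage = "simulate"
            gen = cfg.generator or GeneratorConfig(seed=cfg.stage_seed("generator"))
            table, meta, nutrients, genes, truth = generate_dataset(gen)
            core_io.write_feature_table(table, out / "feature_table.tsv")
            artifacts["feature_table.tsv"] = str(out / "feature_table.tsv")
            truth.to_json(out / "truth.json")
            artifacts["truth.json"] = str(out / "truth.json")
        else:
            table = core_io.read_feature_table(cfg.feature_table)
            table = core_io.to_relative_abundance(table)
            meta = core_io.read_metadata(cfg.metadata)
            nutrients = core_io.read_nutrients(cfg.nutrients) if cfg.nutrients else None
            genes = (core_io.read_feature_table(cfg.gene_table)
                     if cfg.gene_table else None)
            if cfg.taxonomy:
                tax = core_io.read_taxonomy(cfg.taxonomy)
                table = core_io.collapse_to_genus(table, tax)
        meta.check_covers(table)

        stage = "filter"
        filtered = core_io.filter_by_mean_relabund(table, cfg.abundance_filter)
        core_io.write_feature_table(filtered, out / "filtered_table.tsv")
        artifacts["filtered_table.tsv"] = str(out / "filtered_table.tsv")

        stage = "network"
        corr = cooccurrence.spearman_matrix(filtered)
        net = cooccurrence.build_network(corr, cfg.network_r_min, cfg.network_p_max)
        core_io.write_graph(net, out / "network.graphml", "graphml")
        core_io.write_graph(net, out / "network_edges.tsv", "edge_tsv")
        artifacts["network.graphml"] = str(out / "network.graphml")
        artifacts["network_edges.tsv"] = str(out / "network_edges.tsv")

        stage = "subnetworks"
        groups = sorted({meta.treatment(s) for s in meta.sample_ids})
        subs = {g: cooccurrence.treatment_subnetwork(net, filtered, meta, g)
                for g in groups}
        topo = cooccurrence.topology_table(subs)
        save_df(topo, "topology.tsv", index_label="subnetwork")
        try:
            comp = cooccurrence.complexity_scores(topo)
            save_df(comp, "complexity.tsv", index_label="subnetwork")
        except ValueError as exc:
            logger.warning("complexity scores skipped: %s", exc)

        stage = "modules"
        part = community.detect_modules(net)
        part = community.enforce_min_size(part, net, cfg.min_module_size)
        assign = pd.DataFrame(
            sorted(part.assignments.items()), columns=["taxon", "module"]
        ).set_index("taxon")
        save_df(assign, "modules.tsv")
        abund = community.module_abundance(part, filtered)
        save_df(abund, "module_abundance.tsv", index_label="sample_id")

        if nutrients is not None:
            stage = "module_nutrients"
            assoc = community.module_nutrient_table(abund, nutrients)
            save_df(assoc, "module_nutrient_regressions.tsv", index=False)

            stage = "core_taxa"
            cs = core_taxa.select_core_taxa(
                filtered, part, nutrients, alpha=0.05, n_perm=cfg.rf_perm,
                cfg=core_taxa.ForestConfig(n_trees=cfg.rf_trees,
                                           seed=cfg.stage_seed("core_taxa")))
            save_df(core_taxa.core_taxa_frame(cs), "core_taxa.tsv", index=False)

            if genes is not None:
                stage = "pathways"
                core_set = sorted(cs.all_taxa()) or filtered.taxon_ids
                mg = pathway.screen_bipartite_edges(
                    filtered.data[core_set], genes.data,
                    cfg.pathway_r_min, cfg.pathway_p_max, kind="microbe-gene")
                gn = pathway.screen_bipartite_edges(
                    genes.data, nutrients.data,
                    cfg.pathway_r_min, cfg.pathway_p_max, kind="gene-nutrient")
                paths = pathway.enumerate_complete_pathways(mg, gn)
                save_df(pathway.pathways_frame(paths), "pathways.tsv", index=False)
                panels = pathway.load_gene_panels(cfg.gene_panels)
                pathway.export_network(paths, str(out / "tripartite"),
                                       pathway.gene_cycle_map(panels))
                artifacts["tripartite.sif"] = str(out / "tripartite.sif")

        stage = "multivariate"
        alpha = multivariate.alpha_diversity(table)
        save_df(alpha, "alpha_diversity.tsv", index_label="sample_id")
        bc = multivariate.bray_curtis(table)
        save_df(bc, "bray_curtis.tsv", index_label="sample_id")
        coords, eig, prop = multivariate.pcoa(bc)
        save_df(coords, "pcoa.tsv", index_label="sample_id")
        perma = multivariate.permanova(bc, meta, n_perm=cfg.n_perm,
                                       seed=cfg.stage_seed("permanova"))
        save_df(perma.table, "permanova.tsv")
        perma_rev = multivariate.permanova(
            bc, meta, terms=("straw", "tillage", "tillage:straw"),
            n_perm=cfg.n_perm, seed=cfg.stage_seed("permanova"))
        save_df(perma_rev.table, "permanova_reversed.tsv")
        results_extra = {}
        if nutrients is not None:
            dn = pd.DataFrame(
                multivariate.squareform(multivariate.pdist(
                    (nutrients.data - nutrients.data.mean())
                    / nutrients.data.std(ddof=1))),
                index=bc.index, columns=bc.index)
            mt = multivariate.mantel(bc, dn, n_perm=cfg.n_perm,
                                     seed=cfg.stage_seed("mantel"))
            results_extra["mantel"] = mt
            design = plspm.encode_design(meta)
            vpa = multivariate.variation_partition(
                coords.iloc[:, :2],
                {"nutrients": nutrients.data, "design": design})
            results_extra["vpa"] = vpa.as_series().to_dict()

        stage = "plspm"
        if nutrients is not None:
            design = plspm.encode_design(meta)
            assembled = pd.concat(
                [design, alpha[["shannon"]], coords.iloc[:, :2], nutrients.data],
                axis=1).loc[design.index]
            nutr_block = list(nutrients.data.columns[:3])
            spec = plspm.PathModelSpec(
                blocks={"tillage": ["tillage"], "straw": ["straw"],
                        "community": ["shannon", "PCo1", "PCo2"],
                        "nutrients": nutr_block},
                paths={"community": ["tillage", "straw"],
                       "nutrients": ["tillage", "straw", "community"]},
                n_boot=cfg.n_boot, seed=cfg.stage_seed("plspm"))
            res = plspm.fit(spec, assembled)
            boot = plspm.bootstrap(spec, assembled, base=res)
            save_df(boot, "plspm_paths.tsv", index=False)
            results_extra["plspm_gof"] = res.gof
            results_extra["plspm_r2"] = res.r_squared

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "parameters": {k: v for k, v in asdict(cfg).items()
                           if not isinstance(v, (GeneratorConfig, dict))
                           and k != "generator"},
            "artifacts": {name: {"path": p, "sha256": _sha256(Path(p))}
                          for name, p in artifacts.items()},
            "extra": _jsonable(results_extra),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
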