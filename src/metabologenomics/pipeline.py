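"""One-command orchestration of the full metabologenomic workflow.

``run_all`` executes the metabolome stage (filter, scale, PCA, OPLS-DA,
differential testing, pathway enrichment), the microbiome stage
(rarefaction, diversity, UniFrac/PCoA/ANOSIM, LDA effect size, metagenome
prediction) and the integration stage (Procrustes, autocorrelation maps with
fixed-k clustering, cross-block correlation network), writing result tables,
a GraphML network and a JSON manifest with seeds, per-stage counts and file
checksums.  All stochastic steps (rarefaction, permutations, CV fold
shuffles) are driven by one master seed recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import integration as integ
from . import metabolome as mb
from . import microbiome as mc
from . import synthetic as sy
from . import tables_io as tio

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Inputs, thresholds and seed of one pipeline run.

    Either ``synthetic_seed`` is set (inputs are generated) or all of
    ``metabolome/counts/tree/meta/gene_content/pathway_library`` point to
    files written in the formats the I/O layer reads.
    """

    out_dir: str = "results"
    seed: int = 0
    synthetic_seed: int | None = None
    metabolome: str | None = None
    counts: str | None = None
    tree: str | None = None
    meta: str | None = None
    gene_content: str | None = None
    pathway_library: str | None = None
    min_detect: int = 4
    pc_loading_thresh: float = 0.11
    oplsda_cov_thresh_metabolome: float = 0.16
    oplsda_cov_thresh_genera: float = 0.11
    lda_thresh: float = 2.0
    fdr: float = 0.05
    rarefaction_depth: int = 16_014
    clusters_k: dict = field(default_factory=lambda: dict(integ.DEFAULT_CLUSTER_K))
    group_levels: tuple[str, str] = ("control", "AD")

    def __post_init__(self):
        for name in ("min_detect", "pc_loading_thresh", "lda_thresh", "fdr",
                     "rarefaction_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name!r} must be positive")
        if any(k < 1 for k in self.clusters_k.values()):
            raise ConfigError("cluster counts must be >= 1")
        if self.synthetic_seed is None:
            required = ("metabolome", "counts", "tree", "meta", "gene_content",
                        "pathway_library")
            for name in required:
                if getattr(self, name) is None:
                    raise ConfigError(f"config field {name!r} is required when "
                                      "no synthetic seed is given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "clusters_k" in raw:
            raw["clusters_k"] = {str(k): int(v)
                                 for k, v in raw["clusters_k"].items()}
        if "group_levels" in raw:
            raw["group_levels"] = tuple(raw["group_levels"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic_seed is not None:
        ds = sy.generate_dataset(cfg.synthetic_seed)
        return ds.meta, ds.metabolome, ds.counts, ds.tree, ds.gene_content, \
            ds.pathway_library
    meta = tio.read_metadata(cfg.meta)
    met = tio.read_feature_table(cfg.metabolome, block="metabolite",
                                 unit="concentration").align_to(meta)
    cts = tio.read_feature_table(cfg.counts, block="taxon").align_to(meta)
    tree = tio.read_newick(cfg.tree)
    ref = tio.read_gene_content(cfg.gene_content)
    lib = tio.read_pathway_library(cfg.pathway_library)
    return meta, met, cts, tree, ref, lib


def run_all(cfg: RunConfig) -> dict:
    """Run all three stages; return (and write) the output manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("metabologenomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(rng.integers(2 ** 31))
             for name in ("rarefy", "anosim_u", "anosim_w", "oplsda_met",
                          "oplsda_gen", "lefse")}
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stage_seeds": seeds, "stages": {}, "files": {},
                      "counts": {}}
    timings: dict[str, float] = {}
    files: dict[str, Path] = {}
    levels = cfg.group_levels
    current = {"stage": None}
    starts: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        current["stage"] = name
        starts[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - starts[name]
        log.info("stage %s done in %.2fs", name, timings[name])

    try:
        stage("load")
        meta, met_raw, cts_raw, tree, ref, lib = _load_inputs(cfg)
        done("load")

        # ----------------------------------------------------- metabolome
        stage("metabolome")
        met_f = mb.detection_filter(met_raw, meta, min_per_group=cfg.min_detect)
        met_i = mb.impute_half_minimum(met_f)
        met_s = mb.pareto_scale(met_i)
        pca_res = mb.pca(met_s)
        pca_hits = mb.loading_report(pca_res, "PC2", cfg.pc_loading_thresh)
        opls_met = mb.oplsda(met_s, meta.groups, seed=seeds["oplsda_met"])
        opls_met_hits = mb.covariance_report(
            opls_met, cfg.oplsda_cov_thresh_metabolome)
        met_diff = integ.select_differential(met_f, meta, cfg.fdr, levels)
        met_sel, met_report = met_diff
        query = set(met_sel.feature_ids)
        enrich = mb.msea_ora(query, lib) if query else pd.DataFrame()
        done("metabolome")

        # ----------------------------------------------------- microbiome
        stage("microbiome")
        rare = mc.rarefy(cts_raw, cfg.rarefaction_depth, seed=seeds["rarefy"])
        relab = mc.relative_abundance(rare)
        relab_pct = tio.FeatureTable(relab.data * 100.0, "taxon", "fraction")
        alpha = mc.alpha_diversity(rare)
        dm_u = mc.unifrac(rare, tree, weighted=False)
        dm_w = mc.unifrac(rare, tree, weighted=True)
        pcoa_w = mc.pcoa(dm_w)
        anosim_u = mc.anosim(dm_u, meta.groups, seed=seeds["anosim_u"])
        anosim_w = mc.anosim(dm_w, meta.groups, seed=seeds["anosim_w"])
        lda = mc.lda_effect_size(relab, meta.groups, threshold=cfg.lda_thresh,
                                 seed=seeds["lefse"])
        relab_s = mb.pareto_scale(relab_pct)
        opls_gen = mb.oplsda(relab_s, meta.groups, seed=seeds["oplsda_gen"])
        opls_gen_hits = mb.covariance_report(opls_gen,
                                             cfg.oplsda_cov_thresh_genera)
        predicted = mc.predict_metagenome(rare, ref)
        gen_sel, gen_report = integ.select_differential(relab_pct, meta,
                                                        cfg.fdr, levels)
        pwy_sel, pwy_report = integ.select_differential(
            predicted.pathway_table, meta, cfg.fdr, levels)
        done("microbiome")

        # ----------------------------------------------------- integration
        stage("integration")
        proc = integ.procrustes(pca_res.scores.iloc[:, :3],
                                pcoa_w.scores.iloc[:, :3])
        blocks_full = {"metabolite": met_i, "taxon": relab_pct,
                       "gene-set": predicted.pathway_table}
        clusters = {}
        for name, tbl in blocks_full.items():
            corr = integ.autocorrelation_map(tbl)
            clusters[name] = integ.hca_clusters(corr, cfg.clusters_k[name])
        directions = {}
        for report in (met_report, gen_report, pwy_report):
            up = report[f"mean_{levels[1]}"] > report[f"mean_{levels[0]}"]
            for feat, is_up in up.items():
                directions[feat] = (f"up-in-{levels[1]}" if is_up
                                    else f"up-in-{levels[0]}")
        met_sel_i = tio.FeatureTable(met_i.data[met_sel.feature_ids],
                                     "metabolite", met_i.unit)
        blocks_sel = {"metabolite": met_sel_i, "taxon": gen_sel,
                      "gene-set": pwy_sel}
        blocks_sel = {k: v for k, v in blocks_sel.items() if v.shape[1] > 0}
        net = integ.build_network(blocks_sel, q_thresh=cfg.fdr,
                                  clusters=clusters, directions=directions)
        done("integration")

        # ----------------------------------------------------- outputs
        stage("write")
        def save_df(df: pd.DataFrame, name: str, **kw):
            path = out / name
            df.to_csv(path, sep="\t", na_rep="", **kw)
            files[name] = path

        save_df(met_report.assign(
            fold_change_2dp=[integ_fmt(f) for f in met_report["fold_change"]]),
            "metabolome_differential.tsv")
        save_df(enrich, "metabolome_enrichment.tsv", index=False)
        save_df(pca_res.scores, "metabolome_pca_scores.tsv")
        save_df(pca_res.loadings, "metabolome_pca_loadings.tsv")
        save_df(opls_met.covariance.to_frame(), "metabolome_oplsda_covariance.tsv")
        save_df(alpha, "alpha_diversity.tsv")
        save_df(pd.DataFrame(dm_u.data, index=dm_u.ids, columns=dm_u.ids),
                "unifrac_unweighted.tsv")
        save_df(pd.DataFrame(dm_w.data, index=dm_w.ids, columns=dm_w.ids),
                "unifrac_weighted.tsv")
        save_df(pcoa_w.scores, "pcoa_weighted_scores.tsv")
        save_df(gen_report.assign(
            fold_change_2dp=[integ_fmt(f) for f in gen_report["fold_change"]]),
            "genera_differential.tsv")
        save_df(pwy_report, "genesets_differential.tsv")
        save_df(pd.DataFrame([(e.feature, e.lda_score, e.direction)
                              for e in lda],
                             columns=["feature", "lda_score", "direction"]),
                "lda_effect_size.tsv", index=False)
        save_df(pd.concat(clusters, names=["block", "feature"]).rename(
            "cluster").to_frame(), "clusters.tsv")
        proc_coords = pd.concat({"reference": proc.reference,
                                 "transformed": proc.transformed},
                                names=["configuration", "sample_id"])
        save_df(proc_coords, "procrustes_coordinates.tsv")
        gml, edges = tio.write_network(net, out / "network")
        files["network.graphml"] = gml
        files["network_edges.tsv"] = edges
        done("write")
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(
            f"pipeline failed in stage {current['stage']!r}: {exc}") from exc

    manifest["stages"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["counts"] = {
        "samples": len(meta.sample_ids),
        "metabolites_detected": met_f.shape[1],
        "metabolites_significant": met_sel.shape[1],
        "genera": cts_raw.shape[1],
        "genera_significant": gen_sel.shape[1],
        "genesets_significant": pwy_sel.shape[1],
        "pca_pc2_hits": int(len(pca_hits)),
        "oplsda_met_hits": int(len(opls_met_hits)),
        "oplsda_gen_hits": int(len(opls_gen_hits)),
        "lda_hits": len(lda),
        "network_nodes": net.graph.number_of_nodes(),
        "network_edges": net.n_edges,
    }
    manifest["statistics"] = {
        "anosim_unweighted_R": anosim_u.R, "anosim_unweighted_p": anosim_u.p,
        "anosim_weighted_R": anosim_w.R, "anosim_weighted_p": anosim_w.p,
        "oplsda_metabolome_Q2": opls_met.q2_cum,
        "oplsda_metabolome_R2X": opls_met.r2x_cum,
        "oplsda_genera_Q2": opls_gen.q2_cum,
        "procrustes_M2": proc.m2,
        "top_enriched_pathway": (str(enrich.iloc[0]["pathway"])
                                 if len(enrich) else None),
    }
    manifest["files"] = {name: {"path": str(p), "sha256": _sha256(p)}
                         for name, p in sorted(files.items())}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    root.removeHandler(handler)
    handler.close()
    return manifest


def integ_fmt(fc: float) -> str:
    from .stats import format_fold_change
    return format_fold_change(fc)
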