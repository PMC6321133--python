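"""Synthetic paired metabolome/microbiome datasets with known ground truth.

The generator emulates the design of a two-diet repeated-measures mouse
study: 6 control and 5 test-diet ("AD") animals sampled at weeks 8, 12, 24,
36 and 52 (55 samples), ~184 fecal metabolites and ~106 genera.  Metabolite
concentrations are log-normal with a per-(subject, feature) random intercept
for repeated measures and a planted diet effect on a subset of features;
genus counts are Dirichlet-multinomial with diet effects acting on the
Dirichlet weights; a random bifurcating phylogeny with exponential branch
lengths covers the genera.  A configurable set of (metabolite, genus) pairs
is coupled through a shared latent factor to a target Spearman correlation,
and the accompanying gene-content reference gives the coupled genera
elevated counts for the KOs of a designated "butyrate metabolism" pathway so
that the predicted pathway abundance co-varies with the coupled metabolite.
Ground truth (affected features, effect sizes, couplings, the enriched
metabolite pathway) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import (FeatureTable, GeneContentReference, PathwayLibrary,
                        PhyloTree, SampleMetadata, write_feature_table,
                        write_gene_content, write_metadata, write_newick,
                        write_pathway_library)

__all__ = [
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_design",
    "generate_metabolome",
    "generate_microbiome",
    "generate_couplings_and_reference",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_WEEKS = (8, 12, 24, 36, 52)


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic dataset.

    ``diet_affected_metabolites`` / ``diet_affected_genera`` map feature id
    to the signed planted log2 fold change (AD relative to control);
    ``couplings`` lists (metabolite, genus, target Spearman rho) triples;
    ``enriched_pathway`` is the metabolite pathway loaded with planted
    diet-affected metabolites; ``coupled_gene_pathway`` the KO pathway tied
    to the coupled genera.
    """

    diet_affected_metabolites: dict[str, float] = field(default_factory=dict)
    diet_affected_genera: dict[str, float] = field(default_factory=dict)
    couplings: list[tuple[str, str, float]] = field(default_factory=list)
    enriched_pathway: str | None = None
    coupled_gene_pathway: str | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SyntheticDataset:
    meta: SampleMetadata
    metabolome: FeatureTable
    counts: FeatureTable
    tree: PhyloTree
    gene_content: GeneContentReference
    pathway_library: PathwayLibrary
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# design


def generate_design(n_control: int = 6, n_ad: int = 5,
                    weeks=DEFAULT_WEEKS, seed: int | None = None
                    ) -> SampleMetadata:
    """Repeated-measures two-diet design: each animal sampled at every week."""
    if n_control < 1 or n_ad < 1:
        raise ValueError("group sizes must be positive")
    rows = []
    for group, n, prefix in (("control", n_control, "C"), ("AD", n_ad, "A")):
        for i in range(1, n + 1):
            subject = f"{prefix}{i}"
            for w in weeks:
                rows.append((f"{subject}_w{w:02d}", group, subject, int(w)))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "subject_id",
                                     "age_weeks"]).set_index("sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# metabolome


def generate_metabolome(meta: SampleMetadata, n_features: int = 184,
                        n_diet_affected: int = 40, effect_log2fc: float = 2.0,
                        noise_sd: float = 0.8, subject_sd: float = 0.4,
                        missing_rate: float = 0.05,
                        frac_decreased: float = 0.8,
                        seed: int | None = None
                        ) -> tuple[FeatureTable, SyntheticTruth]:
    """Log-normal fecal metabolite concentrations with planted diet effects.

    A fraction ``frac_decreased`` of the affected features decreases in the
    AD group (most changed fecal metabolites drop under the test diet in the
    emulated design).  About ``missing_rate`` of the values are masked as
    not-detected, preferentially at low concentrations.
    """
    if n_diet_affected > n_features:
        raise ValueError("n_diet_affected exceeds n_features")
    rng = np.random.default_rng(seed)
    feats = [f"met{j:03d}" for j in range(1, n_features + 1)]
    n = len(meta.sample_ids)
    is_ad = (meta.groups == "AD").to_numpy().astype(float)
    subjects = meta.df["subject_id"]

    base = rng.uniform(-2.0, 6.0, size=n_features)           # log2 nmol/g
    affected = list(rng.choice(feats, size=n_diet_affected, replace=False))
    sign = np.where(rng.random(n_diet_affected) < frac_decreased, -1.0, 1.0)
    beta = pd.Series(0.0, index=feats)
    beta.loc[affected] = sign * effect_log2fc

    # subject-level random intercepts (repeated measures)
    subj_levels = subjects.unique()
    subj_fx = pd.DataFrame(rng.normal(0.0, subject_sd, (len(subj_levels),
                                                        n_features)),
                           index=subj_levels, columns=feats)
    log2x = (base[None, :]
             + np.outer(is_ad, beta.to_numpy())
             + subj_fx.loc[subjects].to_numpy()
             + rng.normal(0.0, noise_sd, (n, n_features)))
    values = np.exp2(log2x)

    # mask ~missing_rate of values, preferentially at low concentrations
    if missing_rate > 0:
        order = values.argsort(axis=0).argsort(axis=0)  # within-feature ranks
        quantile = order / max(n - 1, 1)
        p_miss = np.clip(2.0 * missing_rate * (1.0 - quantile), 0.0, 1.0)
        values = np.where(rng.random(values.shape) < p_miss, np.nan, values)

    tbl = FeatureTable(pd.DataFrame(values, index=meta.sample_ids,
                                    columns=feats),
                       block="metabolite", unit="concentration")
    truth = SyntheticTruth(
        diet_affected_metabolites={f: float(b) for f, b in
                                   beta.loc[affected].items()},
        seed=seed)
    # stash the generative parameters needed by the coupling step
    truth_params = {"base": dict(zip(feats, base)), "noise_sd": noise_sd}
    tbl.data.attrs["generator"] = truth_params
    return tbl, truth


# ---------------------------------------------------------------------------
# microbiome


def _random_bifurcating_tree(names: list[str], rng: np.random.Generator,
                             branch_scale: float = 0.05) -> PhyloTree:
    """Random binary topology by repeated pairwise joining; Exp branch lengths."""
    nodes = [TreeNode(name=nm, length=float(rng.exponential(branch_scale)))
             for nm in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(length=float(rng.exponential(branch_scale)),
                          children=[a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def generate_microbiome(meta: SampleMetadata, n_genera: int = 106,
                        n_diet_affected: int = 15, effect_fold: float = 4.0,
                        depth_range: tuple[int, int] = (18_000, 26_000),
                        theta: float = 300.0, subject_sd: float = 0.3,
                        frac_decreased: float = 0.45,
                        seed: int | None = None
                        ) -> tuple[FeatureTable, PhyloTree, SyntheticTruth]:
    """Dirichlet-multinomial genus counts with planted diet effects.

    Per-sample composition p ~ Dirichlet(theta * w) where the weights w are
    log-normal across genera, multiplied by ``effect_fold`` (or its inverse)
    for planted genera in the AD group and by a per-(subject, genus)
    log-normal intercept; counts ~ Multinomial(depth, p) with depths drawn
    uniformly from ``depth_range`` (whose minimum must exceed the 16,014-read
    rarefaction depth so rarefaction is always exercised).
    """
    if depth_range[0] <= 16_014:
        raise ValueError("depth_range minimum must exceed the rarefaction depth")
    rng = np.random.default_rng(seed)
    genera = [f"genus{j:03d}" for j in range(1, n_genera + 1)]
    n = len(meta.sample_ids)
    is_ad = (meta.groups == "AD").to_numpy().astype(float)
    subjects = meta.df["subject_id"]
    subj_levels = subjects.unique()

    base_logw = rng.normal(0.0, 1.5, size=n_genera)
    # plant effects only on genera with a detectable baseline (>= 0.2% of the
    # community): a fold change on a taxon that never rises above the
    # sequencing floor is not an observable effect
    base_share = np.exp(base_logw) / np.exp(base_logw).sum()
    eligible = [g for g, s in zip(genera, base_share) if s >= 0.002]
    if len(eligible) < n_diet_affected:
        raise ValueError("too few sufficiently abundant genera to plant "
                         f"{n_diet_affected} effects")
    affected = list(rng.choice(eligible, size=n_diet_affected, replace=False))
    sign = np.where(rng.random(n_diet_affected) < frac_decreased, -1.0, 1.0)
    log2_effect = pd.Series(0.0, index=genera)
    log2_effect.loc[affected] = sign * np.log2(effect_fold)

    subj_fx = pd.DataFrame(rng.normal(0.0, subject_sd, (len(subj_levels),
                                                        n_genera)),
                           index=subj_levels, columns=genera)
    logw = (base_logw[None, :]  # natural-log base weights
            + np.outer(is_ad, log2_effect.to_numpy()) * np.log(2.0)
            + subj_fx.loc[subjects].to_numpy() * np.log(2.0))
    weights = np.exp(logw - logw.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)

    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n)
    counts = _draw_dm_counts(weights, depths, theta, rng)

    tbl = FeatureTable(pd.DataFrame(counts, index=meta.sample_ids,
                                    columns=genera),
                       block="taxon", unit="count")
    tree = _random_bifurcating_tree(genera, rng)
    truth = SyntheticTruth(
        diet_affected_genera={g: float(b) for g, b in
                              log2_effect.loc[affected].items()},
        seed=seed)
    tbl.data.attrs["generator"] = {"weights": weights, "depths": depths,
                                   "theta": theta}
    return tbl, tree, truth


def _draw_dm_counts(weights: np.ndarray, depths: np.ndarray, theta: float,
                    rng: np.random.Generator) -> np.ndarray:
    counts = np.empty(weights.shape, dtype=np.int64)
    for s in range(weights.shape[0]):
        p = rng.dirichlet(theta * weights[s])
        counts[s] = rng.multinomial(int(depths[s]), p)
    return counts


# ---------------------------------------------------------------------------
# couplings and references


def generate_couplings_and_reference(
        meta: SampleMetadata,
        metabolome: FeatureTable, metabolome_truth: SyntheticTruth,
        counts: FeatureTable, microbiome_truth: SyntheticTruth,
        n_couplings: int = 6, target_rho: float = 0.7,
        group_delta: float = 2.0, coupled_share: float = 0.03,
        coupled_log2_sd: float = 1.5,
        n_kos: int = 60, n_ko_pathways: int = 6,
        n_met_pathways: int = 8, enriched_pathway_size: int = 15,
        seed: int | None = None,
        ) -> tuple[FeatureTable, FeatureTable, GeneContentReference,
                   PathwayLibrary, SyntheticTruth]:
    """Couple metabolite-genus pairs through shared latent factors and build
    the gene-content reference and metabolite pathway library.

    For each coupling the metabolite column and the genus Dirichlet weight
    are regenerated as monotone functions of a bivariate-normal latent pair
    whose correlation is calibrated so that the *observed* Spearman rho
    (including the common diet effect of size ``group_delta`` latent SDs and
    the Dirichlet/multinomial counting noise of a genus holding roughly
    ``coupled_share`` of the community) lands near ``target_rho``; the
    realised value is checked empirically in the test suite (+-0.1,
    seed-averaged).  Coupled features are diet-affected by construction
    (elevated in AD, like the fermentation products the design emulates).

    The reference gives every genus a 16S copy number in 1..7 and a Poisson
    background over ``n_kos`` KO families; coupled genera carry an extra
    gene-dose for the KOs of the designated pathway so its predicted
    abundance tracks the coupled genera.  The metabolite library places
    planted diet-affected metabolites into one enriched pathway.
    """
    if not (-1.0 < target_rho < 1.0):
        raise ValueError("target rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    met = metabolome.copy()
    cts = counts.copy()
    genera = cts.feature_ids
    n = len(meta.sample_ids)
    is_ad = (meta.groups == "AD").to_numpy().astype(float)
    v = is_ad.var()

    gen = counts.data.attrs.get("generator")
    if gen is None:
        raise ValueError("counts table lacks generator metadata; use "
                         "generate_microbiome output")
    weights = gen["weights"].copy()
    depths = gen["depths"]
    theta = gen["theta"]

    met_aff = sorted(metabolome_truth.diet_affected_metabolites)
    gen_aff = sorted(microbiome_truth.diet_affected_genera)
    if n_couplings > min(len(met_aff), len(gen_aff)):
        raise ValueError("not enough planted features to couple")
    c_mets = list(rng.choice(met_aff, size=n_couplings, replace=False))
    c_gens = list(rng.choice(gen_aff, size=n_couplings, replace=False))

    # calibration: Spearman target -> Pearson on latents, de-attenuated for
    # Dirichlet-multinomial counting noise on the genus side
    rho_pearson = 2.0 * np.sin(np.pi * target_rho / 6.0)
    sd_lat_ln = coupled_log2_sd * np.log(2.0) * np.sqrt(group_delta ** 2 * v + 1.0)
    mean_depth = float(np.mean(depths))
    noise_var = 1.0 / (theta * coupled_share) + 1.0 / (mean_depth * coupled_share)
    lam = sd_lat_ln / np.sqrt(sd_lat_ln ** 2 + noise_var)
    rho_needed = min(rho_pearson / lam, 0.99)
    r_lat = rho_needed * (group_delta ** 2 * v + 1.0) - group_delta ** 2 * v
    r_lat = float(np.clip(r_lat, -0.99, 0.99))

    gstd = is_ad - is_ad.mean()
    met_gen = metabolome.data.attrs.get("generator", {})
    base_log2 = met_gen.get("base", {})
    couplings: list[tuple[str, str, float]] = []
    for m_id, g_id in zip(c_mets, c_gens):
        z = rng.normal(size=n)
        e1 = rng.normal(size=n)
        e2 = rng.normal(size=n)
        a = np.sqrt(r_lat) * z + np.sqrt(1.0 - r_lat) * e1
        b = np.sqrt(r_lat) * z + np.sqrt(1.0 - r_lat) * e2
        lat_a = group_delta * gstd + a
        lat_b = group_delta * gstd + b
        base = float(base_log2.get(m_id, 2.0))
        met.data[m_id] = np.exp2(base + lat_a)
        gi = genera.index(g_id)
        weights[:, gi] = coupled_share * np.exp2(coupled_log2_sd * lat_b)
        couplings.append((m_id, g_id, float(target_rho)))
        metabolome_truth.diet_affected_metabolites[m_id] = float(group_delta)
        microbiome_truth.diet_affected_genera[g_id] = float(
            coupled_log2_sd * group_delta)

    weights /= weights.sum(axis=1, keepdims=True)
    cts = FeatureTable(pd.DataFrame(
        _draw_dm_counts(weights, depths, theta, rng),
        index=cts.data.index, columns=genera), block="taxon", unit="count")
    cts.data.attrs["generator"] = {"weights": weights, "depths": depths,
                                   "theta": theta}

    # --- gene-content reference -------------------------------------------
    copy_number = pd.Series(rng.integers(1, 8, size=len(genera)), index=genera)
    ko_ids = [f"K{j:04d}" for j in range(1, n_kos + 1)]
    ko_content = pd.DataFrame(rng.poisson(1.5, (len(genera), n_kos)).astype(float),
                              index=genera, columns=ko_ids)
    ko_pw_names = ["ko_pwy_butyrate"] + [f"ko_pwy_{i}" for i in
                                         range(2, n_ko_pathways + 1)]
    assignment = np.arange(n_kos) % n_ko_pathways
    pathway_map: dict[str, set[str]] = {}
    for ko, pw_idx in zip(ko_ids, assignment):
        pathway_map[ko] = {ko_pw_names[pw_idx]}
        if rng.random() < 0.1:  # some KOs belong to two pathways
            pathway_map[ko].add(ko_pw_names[int(rng.integers(n_ko_pathways))])
    butyrate_kos = [ko for ko, pws in pathway_map.items()
                    if "ko_pwy_butyrate" in pws]
    for g_id in c_gens:
        ko_content.loc[g_id, butyrate_kos] += 25.0
    ref = GeneContentReference(copy_number, ko_content, pathway_map)

    # --- metabolite pathway library ---------------------------------------
    all_mets = met.feature_ids
    aff_pool = [m for m in metabolome_truth.diet_affected_metabolites
                if m in all_mets]
    n_from_aff = min(12, enriched_pathway_size - 3, len(aff_pool))
    members = set(rng.choice(aff_pool, size=n_from_aff, replace=False))
    others = [m for m in all_mets if m not in members]
    members |= set(rng.choice(others, size=enriched_pathway_size - len(members),
                              replace=False))
    pathways = {"pathway_enriched": members}
    for i in range(2, n_met_pathways + 1):
        size = int(rng.integers(12, 51))
        pathways[f"pathway_{i:02d}"] = set(rng.choice(all_mets, size=size,
                                                      replace=False))
    lib = PathwayLibrary(universe_size=len(all_mets), pathways=pathways,
                         universe=set(all_mets))

    truth = SyntheticTruth(
        diet_affected_metabolites=dict(metabolome_truth.diet_affected_metabolites),
        diet_affected_genera=dict(microbiome_truth.diet_affected_genera),
        couplings=couplings,
        enriched_pathway="pathway_enriched",
        coupled_gene_pathway="ko_pwy_butyrate",
        seed=seed)
    return met, cts, ref, lib, truth


# ---------------------------------------------------------------------------
# one-call bundle


def generate_dataset(seed: int = 0, **overrides) -> SyntheticDataset:
    """Generate a complete synthetic study (design, tables, tree, references,
    truth) from one master seed.

    Keyword overrides are forwarded to the individual generators by name
    prefix: ``met_*`` to the metabolome, ``mic_*`` to the microbiome and
    ``cpl_*`` to the coupling/reference step.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_met, s_mic, s_cpl = [int(s.generate_state(1)[0] % (2 ** 31))
                                     for s in ss.spawn(4)]
    split = {"met": {}, "mic": {}, "cpl": {}, "design": {}}
    for key, val in overrides.items():
        prefix, _, name = key.partition("_")
        if prefix not in split:
            raise TypeError(f"unknown override {key!r}")
        split[prefix][name] = val
    meta = generate_design(seed=s_design, **split["design"])
    met, met_truth = generate_metabolome(meta, seed=s_met, **split["met"])
    cts, tree, mic_truth = generate_microbiome(meta, seed=s_mic, **split["mic"])
    met, cts, ref, lib, truth = generate_couplings_and_reference(
        meta, met, met_truth, cts, mic_truth, seed=s_cpl, **split["cpl"])
    truth.seed = seed
    return SyntheticDataset(meta=meta, metabolome=met, counts=cts, tree=tree,
                            gene_content=ref, pathway_library=lib, truth=truth)


def write_dataset(ds: SyntheticDataset, directory) -> dict[str, str]:
    """Write every input file in the formats the I/O layer reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_metadata(ds.meta, d / "meta.tsv")
    write_feature_table(ds.metabolome, d / "metabolome.tsv")
    write_feature_table(ds.counts, d / "counts.tsv")
    write_newick(ds.tree, d / "tree.nwk")
    write_gene_content(ds.gene_content, d / "gene_content")
    write_pathway_library(ds.pathway_library, d / "pathway_library.tsv")
    ds.truth.to_json(d / "truth.json")
    return {
        "meta": str(d / "meta.tsv"),
        "metabolome": str(d / "metabolome.tsv"),
        "counts": str(d / "counts.tsv"),
        "tree": str(d / "tree.nwk"),
        "gene_content": str(d / "gene_content"),
        "pathway_library": str(d / "pathway_library.tsv"),
        "truth": str(d / "truth.json"),
    }
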