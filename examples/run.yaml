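# Example pipeline configuration.  Either point the input fields at files
# written by `metabologenomics synth`, or replace them all with a
# `synthetic_seed: <int>` line to generate inputs on the fly.
metabolome: data/metabolome.tsv
counts: data/counts.tsv
tree: data/tree.nwk
meta: data/meta.tsv
gene_content: data/gene_content
pathway_library: data/pathway_library.tsv
out_dir: results/run
seed: 7
min_detect: 4
pc_loading_thresh: 0.11
oplsda_cov_thresh_metabolome: 0.16
oplsda_cov_thresh_genera: 0.11
lda_thresh: 2.0
fdr: 0.05
rarefaction_depth: 16014
clusters_k:
  metabolite: 7
  taxon: 5
  gene-set: 3
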