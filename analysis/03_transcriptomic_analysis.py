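#!/usr/bin/env python
"""Transcriptomic workflow: CPM/HLA filtering, NB Wald differential
expression, sPLS-DA + RFE, the DEG intersection and the FI network.

Reads results/config.yaml and reports the DEG funnel, the network's
size, and its top hub genes."""

import argparse

from modnet.pipeline import RunConfig, run_transcriptomic

parser = argparse.ArgumentParser()
parser.add_argument("--config", default="results/config.yaml")
args = parser.parse_args()

cfg = RunConfig.from_yaml(args.config)
arts = run_transcriptomic(cfg)

n_sig = int((arts.de_table["padj"] < cfg.alpha).sum())
print(f"matrix after filtering: {len(arts.matrix.genes)} genes x "
      f"{len(arts.matrix.samples)} samples")
f1, f2 = arts.qc.pca_variance_fractions
print(f"PCA: PC1 {f1:.0%}, PC2 {f2:.0%} of variance")
print(f"univariate DEGs (padj<{cfg.alpha}): {n_sig}")
print(f"RFE retained: {len(arts.rfe.final_genes)} genes "
      f"({cfg.retain_fraction:.0%} target)")
print(f"intersection (final DEG list): {len(arts.degs)} genes")
n_link = sum(1 for _, d in arts.fi_network.nodes(data=True)
             if d['role'] == 'linker')
print(f"FI network: {arts.fi_network.number_of_nodes()} nodes "
      f"({n_link} linkers), {arts.fi_network.number_of_edges()} edges")
print("top hubs (edge count, in, out):")
print(arts.topology.head(7).to_string(index=False))
n_gsea = sum(1 for r in arts.gsea if r.fdr < cfg.alpha)
print(f"GSEA: {n_gsea} significantly enriched gene sets at FDR<{cfg.alpha}")
print(f"artifacts under {cfg.outdir}")
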