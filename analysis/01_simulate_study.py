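#!/usr/bin/env python
"""Generate the synthetic two-subject study used by the downstream
analysis scripts.

Writes a full input bundle (per-subject VCF + annotations, interactome,
FI database, counts, phenotype annotations, gene sets, planted truth)
under results/bundle/ plus a matching pipeline config."""

import argparse
from pathlib import Path

from modnet.pipeline import RunConfig
from modnet.synthio import simulate_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", default="results")
args = parser.parse_args()

out = Path(args.outdir)
bundle = simulate_study(seed=args.seed)
paths = bundle.write(out / "bundle")
cfg = RunConfig(
    outdir=str(out / "run"), seed=args.seed,
    vcf_subject1=paths["subject1_vcf"],
    annotations_subject1=paths["subject1_annotations"],
    vcf_subject2=paths["subject2_vcf"],
    annotations_subject2=paths["subject2_annotations"],
    interactome_mitab=paths["interactome"],
    fi_database=paths["fi_database"],
    counts=paths["counts"],
    hpo_annotations=paths["hpo_annotations"],
    gene_sets_gmt=paths["gene_sets"],
)
cfg.to_yaml(str(out / "config.yaml"))

print(f"bundle written under {out/'bundle'} (seed {args.seed})")
print(f"  genes: {len(bundle.genes)}, interactome edges: "
      f"{len(bundle.interactome)}, FI edges: {len(bundle.fi_db)}")
print(f"  planted modifier genes: {', '.join(bundle.truth.modifier_genes)}")
print(f"  planted DE genes: {len(bundle.truth.de_genes)}, "
      f"phenotype panel: {len(bundle.truth.panel_genes)} genes")
print(f"config written to {out/'config.yaml'}")
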