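# Methods

This note documents the models, the default parameters and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem setting

The pipeline targets a 1-vs-1 comparison: two subjects with the same
causal genotype for a rare Mendelian disease but discordant phenotypes.
Nothing here is an association test — with a single pair there is no
sampling distribution over subjects.  Instead, candidate genetic
modifiers are required to carry *convergent* evidence across independent
molecular layers: predicted-deleterious genotype differences,
transcriptional differences robust to two different selection
philosophies, and membership in the disease's phenotype neighbourhood of
the interactome.  The conjunction is the statistic.

## Variant filter cascade

Variants are one record per (variant, gene) annotation.  QC removes
records with missing chromosome or gene symbol, ALT alleles longer than
25 bp (kept at exactly 25: the exclusion rule is "longer than"), and
non-protein-coding biotypes.  The rare filter keeps AF strictly below
0.01 *or AF absent* — absence from the population database is evidence
of rarity, not missingness to impute.  The high-impact filter is
inclusive (CADD ≥ threshold): 30 for "highly deleterious" (top ~0.1% of
possible substitutions on the PHRED scale), 15 for "moderate impact"
(top ~3%).  pLI ≥ 0.9 is a *prioritization*, not a QC step: records
without a pLI annotation fail prioritization but pass everything else.
Rare and high-impact filters commute and are idempotent; every filter
emits per-reason removal counts so input = output + removed always
holds.

At the integration stage the AF filter is deliberately **not**
re-applied: common polymorphisms can act as modifiers of a monogenic
phenotype (e.g. a homozygous burden of common missense variants), so the
CADD ≥ 15 cut is applied to all overlaid variants regardless of
frequency.

## Networks

Subject PPI networks are the physical interactome induced on the
subject's (filtered) mutated genes.  This is implemented directly as the
induced subgraph, which is mathematically equivalent to the
build-then-prune description (add first-degree interactors, then remove
non-mutated interactors, self-loops and duplicate edges) and cheaper;
the equivalence is asserted against a brute-force pair loop in the
tests.  Component decompositions bin components into giant (largest,
ties broken by smallest member label), secondary clusters (≥ 4 nodes),
triads, pairs and singletons, and always run on the undirected skeleton
— weak connectivity is what the downstream summaries use even for the
directed FI network.

The FI network is directed.  Its nodes are the final DEGs present in
the FI database plus **linker genes** chosen by a documented heuristic:
a linker is a non-DEG gene adjacent (in either direction) to at least
two DEGs lying in different connected components of the DEG-induced
subgraph; candidates are added greedily by descending DEG-neighbour
count (ties lexicographic) until no further components can be merged.
The heuristic is a stand-in for whatever proprietary rule a given
network tool uses; linker-set sizes are therefore not comparable across
implementations and are never asserted as exact values.

Hub ranking uses edge count (= in + out degree) descending with
lexicographic tie-break for determinism.  Network intersection takes
the node intersection and the edges of a designated side (the FI side
in the integration workflow, so directed functional edges survive);
node attributes merge with the edge-source side winning collisions.

## Differential expression

The univariate test is a transparent negative-binomial Wald test:

* size factors by median-of-ratios; the reference geometric mean uses
  only genes with strictly positive counts in every sample;
* per-gene method-of-moments dispersion on normalized counts,
  `alpha = (pooled within-group variance − mu·mean(1/s_j)) / mu²`,
  clipped to [1e-8, 10];
* a mean-dispersion trend `alpha(mu) = a0 + a1/mu` fitted by least
  squares over well-estimated genes, with gene-wise estimates shrunk
  toward the trend on the log scale with weight 0.25 on the gene-wise
  value — with three replicates per group the gene-wise estimate is too
  noisy to dominate;
* the contrast is estimated as `log2(mean1 + 0.5) − log2(mean2 + 0.5)`
  (subject1 vs subject2 orientation); the 0.5 moderation only matters
  near zero and identical groups still give exactly 0;
* the Wald statistic uses the delta-method variance of the moderated
  log-means under NB sampling; p-values from the normal tail, BH
  adjustment, direction called at adjusted p < 0.05 with no additional
  fold-change cutoff.

This deliberately omits outlier replacement, independent filtering and
LFC shrinkage.  Correctness is established by calibration (raw p < 0.05
fraction within [0.03, 0.07] on null simulations of 5,000 genes) and by
sign-recovery of planted effects (≥ 95%), plus a cross-check against an
independent DESeq2-style implementation on a small matrix (matching
signs for planted genes, log2FC correlation > 0.9) — the reference
package is an oracle in one test, never the implementation.

## Sparse PLS-DA and RFE

Predictors are centered, unit-scaled log2(CPM+1) values (constant genes
dropped); the class indicator is centered.  Each component's loading
vector maximizes covariance with the response (`w ∝ X'y`),
soft-thresholded to its `keep` largest-magnitude entries and
renormalized; scores are `t = Xw`; X and y are deflated between
components.  With sparsity disabled the first loading equals the
closed-form dense PLS weight, which the tests verify.

RFE refits the model at every iteration (the "iteratively applied"
reading), ranks genes by absolute component-1 loading with lexicographic
tie-break, drops the bottom 20% per iteration (the endpoint, not the
schedule, is the published constraint) and truncates the final step to
exactly `floor(0.10 × initial gene count)` — 16,403 genes in, 1640 out,
which is the arithmetic contract `scripts/acceptance.py` recomputes.
No cross-validation is attempted for `keep` or the component count:
with three samples per class CV folds are degenerate, so the RFE
ranking runs dense (`keep = all`) with one component.

One caveat found during development: component-1 explained variance is
only *approximately* monotone as `keep` decreases — soft-thresholded
loading vectors are not nested across sparsity levels, and violations
of order 1e-4 occur.  The property test asserts monotonicity at 1e-3
tolerance.

## Enrichment

ORA uses the hypergeometric upper tail against a supplied protein-coding
universe (no genome is assumed); BH is applied per database collection.
Redundancy reduction is a greedy weighted set cover: each step picks the
term maximizing newly covered genes divided by its weight, with weight
`1/(−log10(fdr) + ε)` and `ε = 1e-300` guarding fdr = 1; ties break by
fdr then name.  Greedy cost stays within the harmonic bound of the
exhaustive optimum on small instances (verified in tests).

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum with
weight exponent p = 1 and a gene-label permutation null — sample
permutation is impossible at 3 + 3.  NES divides ES by the mean |null
ES| of matching sign; p-values are matching-sign exceedance rates with
an add-one correction; terms with fewer than 3 ranked genes are skipped.
With p = 0 the statistic reduces to the classical unweighted KS form,
checked against a direct implementation.

## The synthetic study generator

The generator's defaults *are* the study conditions the tests assume;
they were fixed once and are not tuned per test:

| parameter | default | rationale |
|---|---|---|
| gene universe | 1,500 genes (incl. 3 HLA-) | ~10× scale-down of an exome capture that keeps every stage non-trivial |
| variants | 2,500 shared + 400 private/subject | preserves the shared ≫ private structure of sibling exomes |
| AF model | Beta(0.2, 5), 10% missing | right-skewed population frequencies; the missing fraction exercises the unannotated branch of the rare filter |
| CADD | background U(0, 25), planted U(30, 50) | clean separation for recovery tests; boundary cases live in explicit fixtures |
| zygosity | Bernoulli(0.1) homozygous; planted forced hom | mirrors a homozygous-burden signature in the affected subject |
| counts | 3+3 NB, dispersion 0.05, lib sizes LogNormal(σ=0.2) | fibroblast-replicate-like; σ=0.2 makes median-of-ratios non-trivial |
| DE | 8% of genes at \|log2FC\| = 2; modifiers forced up in subject 1 | planted modifiers are expressed (baseline ≥ median) and DE, as real candidates were |
| interactome | Barabási–Albert m = 5 | scale-free, connected; degree scale ~10 matches dense curated interactomes after scale-down |
| FI database | BA m = 3, random orientations, + module edges p = 0.12 | DE genes are modelled as a perturbed functional module, so FI edges are enriched among DEGs + modifiers — the structure the linker/giant-component analysis presumes |
| phenotype panel | 12 terms × 20–60 genes, 50% of term mass on the disease module/modifier neighbourhood, modifiers always included | panels cover ~24% of the universe (the scale ratio of a real disease panel) and preferentially annotate disease-process genes |

What the generator does **not** emulate: linkage disequilibrium and
pedigree transmission, read-level noise, annotation errors, ontology
structure (terms are flat sets, no ancestor closure), batch effects, and
gene-length or GC biases in counts.  Passing recovery tests therefore
demonstrates that the pipeline's logic recovers a planted convergent
signature under its own model assumptions — not that it would rank true
modifiers first in any real exome, where annotation noise and module
mis-specification dominate.

Every generator is a pure function of its seed; study-level seeds
derive sub-seeds for each layer from one `numpy` Generator.

## Degenerate inputs and tie-breaks

Empty networks decompose to all-zero counts; an empty intersection or
giant component warns and yields empty outputs rather than failing;
all-zero count matrices and single-replicate groups are rejected
outright.  All rankings (hubs, RFE, shortlist, set cover) carry
deterministic tie-breaks (lexicographic gene/term names) so reruns are
byte-identical, which the manifest checksums assert.

## Problem sizes

The shipped configurations are chosen so the full test suite and the
analysis scripts run comfortably on a single CPU: the end-to-end
recovery experiment uses the 1,500-gene universe over 20 seeds; the RFE
arithmetic check runs at the full 16,403-gene scale (it is cheap — each
iteration is one rank-1 fit on a 6-sample matrix); calibration uses
5,000 null genes and 200 random gene sets at 1,000 permutations.

## Known limitations

* The linker heuristic and the set-cover weight are documented choices,
  not reimplementations of any specific tool; network-size figures are
  implementation-dependent.
* The NB test's normal-tail Wald p-values are approximate at n = 3+3;
  calibration holds under the generator's homogeneous dispersions but
  heavy-tailed real dispersions would need the omitted outlier
  handling.
* Evidence flags are binary and the shortlist ordering is lexicographic
  in (flag count, max CADD); no attempt is made to weight evidence
  layers against each other.
* HPO handling is flat term → gene lookup; no ontology traversal.
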