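# mgasnet

Multivariate gene-based genome-wide association coupled with
protein–protein-interaction (PPI) network module discovery, built as a
reusable, fully testable pipeline. It is aimed at imaging-genetics and
systems-biology analysts who want to go from a SNP × quantitative-trait
association matrix to gene-level p-values, to high-scoring network
modules, to consensus modules that replicate across randomized search
runs — all exercisable end to end on synthetic data with planted signal,
so every stage has a known ground truth.

## The statistics inside

**Gene-based combination (extended Simes).** For a gene with m = (#SNPs ×
#traits) association p-values, sorted p₍₁₎ ≤ … ≤ p₍ₘ₎,

    P_gene = min_j ( q_e · p₍ⱼ₎ / q_ej )

where q_e is the effective number of independent p-values in the gene and
q_ej the effective number among the top j. Effective numbers use the
eigenvalue rule q = m − Σ_{λᵢ>1}(λᵢ − 1) on the correlation matrix of the
p-values, which is obtained from the Kronecker product of the within-gene
LD matrix R_G and the trait correlation matrix R_T through an elementwise
polynomial transform of the statistic correlation. Under independence the
procedure reduces exactly to Simes; under dependence it stays close to
the nominal test level (verified by simulation at LD ρ ∈ {0, 0.5, 0.9}).

**Network module search.** Gene p-values map to node weights
z_g = Φ⁻¹(1 − p_g). A connected node set A scores
Z_A = Σ_{g∈A} z_g / √|A| (Stouffer), standardized against random
connected subnetworks of the same size ("adjusted network score").
Greedy expansion from high-z seed nodes, randomized per run, yields each
run's top five subnetworks with weight-permutation p-values.

**Consensus modules.** Each top subnetwork TN_ij of a reference run is
matched to its most similar subnetwork in every other run by the Dice
coefficient DC(x, y) = 2|x∩y| / (|x|+|y|); the consensus module is the
intersection of TN_ij with all of its matches. Genes that replicate
across runs survive; run-specific noise is stripped.

**Enrichment.** Consensus modules are tested for gene-set
over-representation with an upper-tail hypergeometric test and
Benjamini–Hochberg FDR against a GMT collection and an explicit universe.

## Worked example

The default synthetic study is 2,000 samples, 100 genes × 5 SNPs in LD,
eight correlated volumetric traits (bilateral pairs at r = 0.70–0.90),
five causal genes that double as a planted connected module in a 300-node
scale-free PPI graph:

```bash
mgasnet pipeline --seed 1 --runs 10 --out demo/
```

prints

```
top genes:
gene       p_mgas
G010 4.580657e-52
G040 4.666741e-47
G070 1.285569e-44
G025 1.932037e-41
G055 4.420253e-38
2 consensus module(s); artifacts in demo/
```

The five leading genes are exactly the five causal genes
(`truth.tsv` records them), and `demo/consensus.tsv` shows that the
top consensus module recovers the planted module perfectly with a
permutation p-value at the resolution floor of 1,000 permutations:

```
cm   size  nodes                     connected  adjusted  p
CM1  5     G010;G025;G040;G055;G070  True       13.31     9.99e-04
```

Each stage is also available separately (`mgasnet simulate`, `assoc`,
`mgas`, `modules`, `consensus`, `enrich`) reading and writing plain-text
formats: PLINK-style `.traw` genotypes, TSV phenotype/covariate tables,
BED gene annotation, two-column edge lists (SIF accepted), GMT gene sets.
The same functionality is importable from Python (`mgasnet.run_pipeline`,
`mgasnet.mgas_pvalue`, …).

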