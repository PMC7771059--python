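# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `mgasnet`.

## Gene-based multivariate association

Stage one regresses every quantitative trait on every SNP dosage
(additive coding 0/1/2) with an intercept and covariates, by ordinary
least squares. The implementation residualizes traits and dosages on the
covariate design once (Frisch–Waugh) and then solves each SNP–trait pair
as a simple regression; the dosage t-test is algebraically identical to
the full-model test and is checked against an independent normal-equations
oracle to 1e-10. Monomorphic SNPs are kept with β = 0, p = 1 so the
matrix shape is stable downstream; pairs with missing values fall back to
listwise deletion with the per-pair sample size recorded. Traits enter
only if they pass a one-way ANOVA screen across diagnostic groups
(default α = 0.05).

Stage two combines, per gene, the p-values of all its SNP × trait tests
with the extended Simes rule

    P_gene = min_j ( q_e · p₍ⱼ₎ / q_ej ),

with effective numbers of tests computed from eigenvalues of the p-value
correlation matrix, q = m − Σ_{λ>1}(λ − 1). Modeling choices:

- **Statistic correlation.** The correlation of the (SNP, trait) test
  statistics is modeled as separable, R_G ⊗ R_T, with R_G the within-gene
  dosage LD and R_T the Pearson trait correlation. This is exact for
  shared-sample OLS under the null up to covariate effects.
- **p-value correlation transform.** Two-sided p-values of correlated
  statistics are less correlated than the statistics. The default
  transform is the sixth-order polynomial
  0.2982|r|⁶ − 0.0127|r|⁵ + 0.0588|r|⁴ + 0.0099|r|³ + 0.6281|r|² − 0.0009|r|,
  an even-function approximation validated here by Monte Carlo: it tracks
  the empirical p-value correlation to < 0.01 over |r| ∈ [0.3, 0.99],
  whereas the simpler r² alternative (available as
  `transform="squared"`) overestimates it by ~0.11 at r = 0.9.
- **Prefix effective numbers.** q_ej is computed on the leading j × j
  submatrix of the p-sorted correlation matrix; ties in p use a stable
  sort. q_ej is forced nondecreasing in j (it is mathematically
  nondecreasing up to floating-point noise). A memoization hook caches
  effective numbers by prefix index set for repeated nulls on one matrix.
- **SNP→gene assignment** uses a BED annotation with a configurable
  flanking window (default 10 kb); a SNP inside two genes' windows
  contributes to both.
- **Calibration.** Simulated null genes (5 SNPs × 2 traits, exchangeable
  LD ρ ∈ {0, 0.5, 0.9}, trait correlation 0.6) give empirical test levels
  0.046–0.055 at α = 0.05 over 10,000 replicates — the combination is
  close to nominal and slightly conservative only in extreme LD.

Genome scans report Bonferroni (0.05/#genes) and Benjamini–Hochberg FDR.

## Network module search

Gene p-values become node weights z = Φ⁻¹(1 − p); network genes without a
result get z = 0 (p = 0.5) and are flagged. A node set A scores
Z_A = Σz/√|A|, standardized per size k against random connected
subnetworks: Z_adj = (Z_A − μ_k)/σ_k.

- **Null sampling.** Connected size-k sets are sampled by a random-growth
  walk (uniform random boundary absorption from a uniform random start,
  with restarts). The sampler is biased relative to the uniform
  distribution over connected subgraphs — exact uniform sampling is
  intractable — but is a fixed, documented null reference. All sizes up
  to `max_size` are calibrated from prefixes of the *same* 1,000 walks:
  a truncated walk has the law of a shorter one, so the per-size moments
  share randomness and adjusted scores compare smoothly across adjacent
  sizes (independent per-size sampling made the greedy stop rule noisy).
  A median/MAD option exists for extremely heavy-tailed weights; the
  default is mean/sd.
- **Greedy expansion.** Seeds are nodes with z above the `seed_quantile`
  (default top 5%). Each run visits a random `seed_fraction` (default
  0.8) subsample of seeds in an order randomized by the run's seed value
  and breaks exact score ties randomly — this is what makes runs differ,
  as required by the consensus stage; scores of any fixed node set are
  deterministic because the calibration is shared. Growth absorbs the
  boundary node maximizing the adjusted score and continues while the
  adjusted score gains more than `improvement` (default 0.05, on the
  standardized scale — an absolute bar, because a relative bar would make
  strong modules stop earlier than weak ones) **or** the raw Stouffer
  score still strictly increases (which requires the new node's z to
  exceed ≈ Z_A/(2√k), so it cannot chain weak nodes). When both fail, a
  two-step lookahead tries the best (bridge, follower) pair so that a
  single weak cut-vertex inside a module does not block recovery of what
  lies behind it. Bounds: `min_size` 2, `max_size` 20.
- **Module significance.** The permutation null permutes node weights
  over the whole network with topology fixed and re-scores the same node
  set (equivalently: draws |A| weights without replacement);
  p = (1 + #{Z_adj,perm ≥ Z_adj,obs}) / (1 + n_perm), floor 1/(1+n_perm),
  default n_perm = 1000. Re-running the whole search per permutation
  would be the only stricter null and is computationally disproportionate.
- **Reporting.** Identical node sets are deduplicated; overlapping but
  distinct sets are kept. The top 5 per run are reported by adjusted
  score. No external prior node weighting is applied.

## Consensus modules

For reference run j (default 1), each top subnetwork TN_ij is matched to
the argmax-Dice subnetwork among every other run's reported list; ties
break by better rank, then lexicographic node order, so results are
reproducible. CM_ij = TN_ij ∩ (∩ₙ SN_n(TN_ij)). Properties enforced and
tested: idempotence (identical runs return the subnetwork), monotone
shrinkage in the number of runs, at most `top_k` unique modules
(duplicates collapse, empty intersections are retained and flagged rather
than dropped). Consensus intersections need not be connected; they are
scored with the same Stouffer/adjusted/permutation machinery regardless,
with a connectivity flag in the output, since the consensus is a gene
set, not a subgraph.

## Enrichment

Upper-tail hypergeometric over-representation per gene set with BH-FDR
across sets. The universe is explicit configuration (default: union of
the collection's genes, or the PPI node set in the pipeline); enrichment
p-values are only comparable across analyses holding the universe fixed.
A display table keeps −log10(p) for sets significant at α in at least one
module, so every retained row carries at least one mark.

## Synthetic data generator

The generator emulates an imaging-genetics cohort at toy scale (defaults:
2,000 samples; 100 genes × 5 SNPs; 8 traits; 300-node PPI), chosen so the
full pipeline and its replicated simulations run in seconds on one core.

- **Genotypes.** Per gene, a latent Gaussian block with AR(1) (default
  ρ = 0.6) or exchangeable correlation is thresholded at the
  Hardy–Weinberg cut points of a MAF drawn from [0.1, 0.5], producing
  dosages in {0,1,2} with realistic LD. This is far simpler than
  coalescent simulation and sufficient for the LD structure the
  gene-based test consumes.
- **Phenotypes.** Eight traits named after bilateral subcortical volumes,
  with a paired correlation target (within-pair 0.70/0.83/0.55/0.90 over
  a 0.35 baseline — the strongest pairs match published bilateral
  hippocampus/putamen correlations) plus standardized additive effects of
  the causal SNPs (default one SNP per causal gene, 0.4 SD), covariate
  effects (age-like, binary sex-like, volume-like; 0.2 SD each) and
  ordered diagnostic-group mean shifts across five groups (so the ANOVA
  screen is exercised). With all effects at zero the realized trait
  correlation converges to the target.
- **PPI network.** Preferential-attachment background (m = 2) with
  shuffled node labels; the planted module is the causal genes (padded to
  `planted_module_size`), wired to be connected. When the network stage
  is exercised without the genetic stages, planted nodes receive
  p-values drawn log-uniformly from [1e-10, 1e-4] — the gene-level
  p-value range causal genes actually reach at the default effect size —
  and all other nodes are Uniform(0,1). Heavier-tailed signal
  distributions (e.g. Beta(0.1, 1)) are supported via explicit p-value
  injection but leave a substantial fraction of module members
  statistically indistinguishable from the background, which caps
  top-module recovery around Jaccard 0.75 for any search method.
- **Gene sets.** Thirty random sets plus one equal to the planted module.

What the generator does **not** emulate: population structure,
genotype missingness and QC artifacts, X-chromosome dosage, trait
non-Gaussianity, scale-free degree exponents of real PPI databases, or
literature bias in gene-set collections. Passing tests therefore certify
the statistical machinery under a clean, correctly specified null — not
robustness to the pathologies of real cohorts.

## Numerical choices and degenerate inputs

- p-values are clipped to [tiny, 1]; p = 0 inputs are clipped with a
  warning before Φ⁻¹.
- Correlation matrices are symmetrized and, if indefinite beyond −1e−8,
  projected to the nearest PSD matrix with re-normalized diagonal, with a
  warning.
- Constant traits, single-sample diagnostic groups, empty p-vectors,
  disconnected sets passed to the connected-score function, empty gene
  sets after universe restriction, and degenerate (zero-variance)
  calibration all raise informative errors rather than propagating NaN.
- All randomness flows through `numpy.random.Generator` seeds; every
  generator and search is reproducible bit-for-bit under a fixed seed.

## Limitations

- The adjusted score rewards selection: on exchangeable null weights the
  best size-k set's standardized score grows with k, so "best module" is
  meaningful relative to the greedy search procedure, not as a global
  optimum over all sizes.
- The walk-based null sampler over-weights high-degree neighborhoods;
  its moments are a stable reference, not the uniform-connected-subgraph
  ideal.
- The Kronecker statistic-correlation model ignores covariate-induced
  coupling and assumes shared samples across all tests.
- Consensus matching restricts candidates to each run's reported top
  list; modules outside it are invisible to the consensus stage.
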