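"""Simulation configuration for the synthetic imaging-genetics study.

The defaults describe the toy-scale study the package is exercised on:
2,000 samples, 100 genes with 5 SNPs each in within-gene LD, eight
correlated volumetric quantitative traits, a 300-node scale-free PPI
background graph, and a small set of causal genes that double as the
planted network module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Names used for the traits when exactly eight are simulated, mirroring
#: left/right subcortical volume pairs (amygdala, hippocampus, accumbens,
#: putamen).
SUBCORTICAL_TRAITS = (
    "LAmygVol", "RAmygVol",
    "LHippVol", "RHippVol",
    "LAccumVol", "RAccumVol",
    "LPutamVol", "RPutamVol",
)

#: Five diagnostic groups ordered by severity, with sampling probabilities
#: matching a typical aging-cohort composition.
DIAGNOSIS_LEVELS = ("CN", "SMC", "EMCI", "LMCI", "AD")
DIAGNOSIS_PROBS = (183 / 866, 95 / 866, 281 / 866, 177 / 866, 130 / 866)

#: Per-group trait mean shift multipliers (severity lowers volumes).
DIAGNOSIS_SHIFTS = (0.4, 0.3, 0.1, -0.2, -0.6)


def default_trait_corr(n_traits: int = 8) -> np.ndarray:
    """Default trait correlation matrix.

    For eight traits this is a paired left/right structure: within-pair
    correlations (0.70, 0.83, 0.55, 0.90) on a 0.35 between-region
    baseline, emulating the strong bilateral correlations of subcortical
    volumes (hippocampus ~0.83, putamen ~0.90). For other trait counts an
    exchangeable 0.35 correlation is returned.
    """
    R = np.full((n_traits, n_traits), 0.35)
    np.fill_diagonal(R, 1.0)
    if n_traits == 8:
        for k, rho in enumerate((0.70, 0.83, 0.55, 0.90)):
            i = 2 * k
            R[i, i + 1] = R[i + 1, i] = rho
    return R


def gene_id(i: int) -> str:
    return f"G{i + 1:03d}"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic data generator.

    Attributes
    ----------
    n_samples : number of individuals.
    n_genes : number of genes carrying SNPs.
    snps_per_gene : inclusive (low, high) range for SNPs per gene.
    maf_range : minor allele frequencies drawn uniformly from this range.
    ld_rho : within-gene latent correlation in [0, 1); ``ld_structure``
        chooses AR(1) ("ar1") or exchangeable ("ex") decay.
    n_traits : number of quantitative traits.
    trait_corr : target trait correlation matrix (symmetric PD, unit diag).
    causal_genes : gene ids whose first ``causal_snps_per_gene`` SNPs carry
        a standardized additive effect of ``effect_size`` on every trait.
    n_ppi_nodes : node count of the background interaction graph
        (>= n_genes; extra nodes model proteins without genotyped SNPs).
    ppi_model : "ba" (preferential attachment, default) or "er".
    planted_module_size : size of the connected module planted in the
        graph; padded with non-causal genes if there are fewer causal ones.
    planted_p_range : when the module search is exercised without a
        genetic stage, planted-node p-values are drawn log-uniformly from
        this range (emulating the gene-level p-values causal genes reach
        at the default effect size); all other nodes are Uniform(0, 1).
    covariate_effect : per-SD effect of each covariate on every trait.
    diagnosis_shift : scale of diagnostic-group trait mean shifts.
    """

    n_samples: int = 2000
    n_genes: int = 100
    snps_per_gene: tuple[int, int] = (5, 5)
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.6
    ld_structure: str = "ar1"
    n_traits: int = 8
    trait_corr: np.ndarray | None = None
    causal_genes: tuple[str, ...] = ("G010", "G025", "G040", "G055", "G070")
    causal_snps_per_gene: int = 1
    effect_size: float = 0.4
    covariate_effect: float = 0.2
    diagnosis_shift: float = 0.5
    n_ppi_nodes: int = 300
    ppi_model: str = "ba"
    ppi_attach: int = 2
    planted_module_size: int = 5
    planted_p_range: tuple[float, float] = (1e-10, 1e-4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_corr is None:
            self.trait_corr = default_trait_corr(self.n_traits)
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.snps_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("snps_per_gene must be an increasing range >= 1")
        a, b = self.maf_range
        if not (0.0 < a <= b <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(
                "ld_rho must be in [0, 1): the implied latent correlation "
                "matrix is otherwise not positive definite"
            )
        if self.ld_structure not in ("ar1", "ex"):
            raise ValueError("ld_structure must be 'ar1' or 'ex'")
        R = self.trait_corr
        if R.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_corr shape does not match n_traits")
        if not np.allclose(R, R.T):
            raise ValueError("trait_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("trait_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("trait_corr must be positive definite")
        genes = {gene_id(i) for i in range(self.n_genes)}
        unknown = set(self.causal_genes) - genes
        if unknown:
            raise ValueError(f"causal_genes not among simulated genes: {sorted(unknown)}")
        if self.n_ppi_nodes < self.n_genes:
            raise ValueError("n_ppi_nodes must be >= n_genes")
        if not (0 <= self.planted_module_size <= self.n_ppi_nodes):
            raise ValueError("planted_module_size must be <= n_ppi_nodes")
        if self.ppi_model not in ("ba", "er"):
            raise ValueError("ppi_model must be 'ba' or 'er'")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("snps_per_gene", "maf_range", "causal_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "trait_corr" in raw and raw["trait_corr"] is not None:
            raw["trait_corr"] = np.asarray(raw["trait_corr"], dtype=float)
        return cls(**raw)
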