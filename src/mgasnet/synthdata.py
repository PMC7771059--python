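"""Synthetic genotype / phenotype / PPI-network generator.

Everything downstream of this module (association scan, gene-based
combination, network module search, consensus, enrichment) is exercised
on data produced here, with a known truth record: which genes are causal
and which connected module is planted in the interaction graph.

Genotypes use a thresholded-Gaussian construction: per gene, a latent
multivariate normal block with AR(1) or exchangeable correlation is cut
at the two Hardy-Weinberg thresholds implied by the minor allele
frequency, giving additive dosages in {0, 1, 2} with realistic
within-gene LD. Phenotypes are correlated Gaussian traits plus planted
standardized SNP effects, covariate effects (age-like, sex-like,
volume-like) and diagnostic-group mean shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    DIAGNOSIS_LEVELS,
    DIAGNOSIS_PROBS,
    DIAGNOSIS_SHIFTS,
    SUBCORTICAL_TRAITS,
    SimulationConfig,
    gene_id,
)

__all__ = [
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_ppi",
    "simulate_gene_sets",
    "simulate_dataset",
]

_GENE_SPAN = 25_000
_GENE_STRIDE = 50_000


@dataclass
class SyntheticDataset:
    """A complete synthetic study with its ground truth."""

    genotypes: np.ndarray            # samples x SNPs, int8 dosages in {0,1,2}
    snps: pd.DataFrame               # snp, chrom, pos, gene, maf
    annotation: pd.DataFrame         # BED-like: chrom, start, end, gene
    phenotypes: pd.DataFrame         # samples x traits
    covariates: pd.DataFrame         # samples x (age, sex, vol)
    diagnosis: pd.Series             # categorical label per sample
    network: nx.Graph                # PPI graph, node attribute "p" when drawn
    gene_sets: dict[str, set[str]]   # GMT-style collection
    truth: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.phenotypes.index)


def _latent_correlation(k: int, rho: float, structure: str) -> np.ndarray:
    if structure == "ar1":
        idx = np.arange(k)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    C = np.full((k, k), rho)
    np.fill_diagonal(C, 1.0)
    return C


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Draw dosage matrix, SNP table and BED-like gene annotation.

    Returns ``(genotypes, snps, annotation)`` where genotypes is an
    ``n_samples x n_snps`` int8 matrix. Within each gene the latent
    Gaussians share correlation ``ld_rho`` (AR(1) or exchangeable) before
    thresholding at the Hardy-Weinberg genotype frequencies of the drawn
    MAF, so dosages inherit an LD-block structure.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.snps_per_gene
    blocks: list[np.ndarray] = []
    snp_rows: list[tuple] = []
    ann_rows: list[tuple] = []
    for g in range(config.n_genes):
        gene = gene_id(g)
        chrom = g % 22 + 1
        start = (g // 22) * _GENE_STRIDE + 10_000
        end = start + _GENE_SPAN
        k = int(rng.integers(lo, hi + 1))
        C = _latent_correlation(k, config.ld_rho, config.ld_structure)
        # Cholesky doubles as the positive-definiteness check.
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by config
            raise ValueError("implied latent correlation is not positive definite") from exc
        latent = rng.standard_normal((config.n_samples, k)) @ L.T
        maf = rng.uniform(*config.maf_range, size=k)
        # HWE cut points: P(0)=(1-q)^2, P(1)=2q(1-q), P(2)=q^2.
        t0 = norm.ppf((1.0 - maf) ** 2)
        t1 = norm.ppf(1.0 - maf**2)
        dose = (latent >= t0).astype(np.int8) + (latent >= t1).astype(np.int8)
        blocks.append(dose)
        positions = np.sort(rng.choice(np.arange(start, end), size=k, replace=False))
        for j in range(k):
            snp_rows.append((f"{gene}_S{j + 1:02d}", chrom, int(positions[j]), gene, maf[j]))
        ann_rows.append((chrom, start, end, gene))
    genotypes = np.concatenate(blocks, axis=1)
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "gene", "maf"])
    annotation = pd.DataFrame(ann_rows, columns=["chrom", "start", "end", "gene"])
    return genotypes, snps, annotation


def _trait_names(n_traits: int) -> list[str]:
    if n_traits == len(SUBCORTICAL_TRAITS):
        return list(SUBCORTICAL_TRAITS)
    return [f"T{i + 1}" for i in range(n_traits)]


def simulate_phenotypes(
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate correlated traits with planted genetic effects.

    traits = sum over causal SNPs of effect_size * standardized dosage
             + covariate effects + diagnostic-group shifts
             + Gaussian noise with correlation ``trait_corr``.

    With ``effect_size``, ``covariate_effect`` and ``diagnosis_shift`` all
    zero the realized trait correlation converges to ``trait_corr``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_samples
    if genotypes.shape[0] != n:
        raise ValueError("genotype matrix does not match configured sample count")
    known = set(snps["gene"])
    unknown = set(config.causal_genes) - known
    if unknown:
        raise ValueError(f"causal effect assigned to unknown gene(s): {sorted(unknown)}")

    names = _trait_names(config.n_traits)
    L = np.linalg.cholesky(config.trait_corr)
    Y = rng.standard_normal((n, config.n_traits)) @ L.T

    # Planted additive effects: first causal_snps_per_gene SNPs per causal gene.
    causal_snps: list[str] = []
    for gene in config.causal_genes:
        idx = np.flatnonzero(snps["gene"].to_numpy() == gene)[: config.causal_snps_per_gene]
        for j in idx:
            g = genotypes[:, j].astype(float)
            sd = g.std()
            if sd == 0:
                continue  # monomorphic draw carries no signal
            Y += config.effect_size * ((g - g.mean()) / sd)[:, None]
            causal_snps.append(snps["snp"].iloc[j])

    # Covariates: age-like, binary sex-like, continuous brain-volume-like.
    age = rng.normal(72.0, 7.0, size=n)
    sex = (rng.random(n) < 0.46).astype(float)
    vol = rng.normal(1500.0, 150.0, size=n)
    cov = pd.DataFrame({"age": age, "sex": sex, "vol": vol})
    if config.covariate_effect != 0.0:
        Z = (cov - cov.mean()) / cov.std(ddof=0)
        Y += config.covariate_effect * Z.to_numpy().sum(axis=1)[:, None]

    groups = rng.choice(len(DIAGNOSIS_LEVELS), size=n, p=DIAGNOSIS_PROBS)
    if config.diagnosis_shift != 0.0:
        shifts = config.diagnosis_shift * np.asarray(DIAGNOSIS_SHIFTS)
        Y += shifts[groups][:, None]

    samples = [f"S{i + 1:05d}" for i in range(n)]
    phenotypes = pd.DataFrame(Y, index=samples, columns=names)
    cov.index = phenotypes.index
    diagnosis = pd.Series(
        pd.Categorical.from_codes(groups, categories=list(DIAGNOSIS_LEVELS)),
        index=phenotypes.index,
        name="diagnosis",
    )
    phenotypes.attrs["causal_snps"] = causal_snps
    return phenotypes, cov, diagnosis


def _background_graph(config: SimulationConfig, rng: np.random.Generator) -> nx.Graph:
    seed = int(rng.integers(2**31 - 1))
    if config.ppi_model == "ba":
        return nx.barabasi_albert_graph(config.n_ppi_nodes, config.ppi_attach, seed=seed)
    # Erdos-Renyi with matched expected degree.
    p = 2 * config.ppi_attach / (config.n_ppi_nodes - 1)
    return nx.gnp_random_graph(config.n_ppi_nodes, p, seed=seed)


def simulate_ppi(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gene_pvalues: dict[str, float] | None = None,
) -> tuple[nx.Graph, frozenset[str]]:
    """Build a PPI graph with a connected planted module.

    Nodes are the ``n_genes`` gene ids plus anonymous protein nodes up to
    ``n_ppi_nodes``. The planted module consists of the causal genes,
    padded with further genes up to ``planted_module_size``, and is wired
    to be connected. Every node gets attribute ``p``: values from
    ``gene_pvalues`` when provided, otherwise log-uniform draws from
    ``planted_p_range`` inside the module and Uniform(0, 1) outside.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if gene_pvalues is None and config.planted_module_size < 2:
        raise ValueError("planted_module_size must be >= 2")
    G = _background_graph(config, rng)
    names = [gene_id(i) for i in range(config.n_genes)] + [
        f"N{i + 1:03d}" for i in range(config.n_genes, config.n_ppi_nodes)
    ]
    perm = rng.permutation(config.n_ppi_nodes)
    mapping = {i: names[perm[i]] for i in range(config.n_ppi_nodes)}
    G = nx.relabel_nodes(G, mapping)
    G.remove_edges_from(nx.selfloop_edges(G))

    planted = list(config.causal_genes)
    pool = [g for g in names[: config.n_genes] if g not in planted]
    extra = rng.permutation(pool)[: max(0, config.planted_module_size - len(planted))]
    planted = (planted + list(extra))[: config.planted_module_size]

    # Wire the module to be connected: join its components with random edges.
    if len(planted) >= 2:
        sub = G.subgraph(planted)
        # sort for hash-seed-independent reproducibility
        comps = sorted((sorted(c) for c in nx.connected_components(sub)),
                       key=lambda c: c[0])
        rng.shuffle(comps)
        acc = comps[0]
        for comp in comps[1:]:
            u = acc[int(rng.integers(len(acc)))]
            v = comp[int(rng.integers(len(comp)))]
            G.add_edge(u, v)
            acc.extend(comp)

    planted_set = frozenset(planted)
    for node in G.nodes:
        if gene_pvalues is not None and node in gene_pvalues:
            p = float(gene_pvalues[node])
        elif node in planted_set:
            lo, hi = np.log10(config.planted_p_range)
            p = float(10.0 ** rng.uniform(lo, hi))
        else:
            p = float(rng.random())
        G.nodes[node]["p"] = min(max(p, np.finfo(float).tiny), 1.0)
    return G, planted_set


def simulate_gene_sets(
    config: SimulationConfig,
    planted: frozenset[str],
    rng: np.random.Generator | None = None,
    n_sets: int = 30,
    set_size: tuple[int, int] = (5, 30),
) -> dict[str, set[str]]:
    """Random gene-set collection plus one set equal to the planted module."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    genes = np.array([gene_id(i) for i in range(config.n_genes)])
    sets: dict[str, set[str]] = {"PLANTED_MODULE": set(planted)}
    hi = min(set_size[1], config.n_genes)
    lo = min(set_size[0], hi)
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        sets[f"SET{i + 1:03d}"] = set(rng.choice(genes, size=k, replace=False))
    return sets


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generators under one seed and assemble the truth record."""
    rng = np.random.default_rng(config.seed)
    genotypes, snps, annotation = simulate_genotypes(config, rng)
    phenotypes, covariates, diagnosis = simulate_phenotypes(genotypes, snps, config, rng)
    network, planted = simulate_ppi(config, rng)
    gene_sets = simulate_gene_sets(config, planted, rng)
    truth = {
        "causal_genes": list(config.causal_genes),
        "causal_snps": phenotypes.attrs.get("causal_snps", []),
        "planted_module": sorted(planted),
    }
    return SyntheticDataset(
        genotypes=genotypes,
        snps=snps,
        annotation=annotation,
        phenotypes=phenotypes,
        covariates=covariates,
        diagnosis=diagnosis,
        network=network,
        gene_sets=gene_sets,
        truth=truth,
    )
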