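"""End-to-end orchestration: simulate -> associate -> combine -> search
-> consensus -> enrich, with optional TSV emission of every artifact."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .assoc import (
    PhenotypeScreenResult,
    PValueMatrix,
    TraitCorrelation,
    phenotype_screen,
    snp_qt_regression,
    trait_correlation,
)
from .config import SimulationConfig
from .consensus import (
    ConsensusModule,
    MatchTable,
    consensus_modules,
    consensus_score,
    match_across_runs,
)
from .enrich import GeneSetCollection, enrich_heatmap_table, hypergeom_enrich
from .mgas import genome_scan
from .netsearch import ScoreCalibration, SearchParams, Subnetwork, greedy_search, node_scores
from .synthdata import SyntheticDataset, simulate_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    screen: PhenotypeScreenResult
    pmatrix: PValueMatrix
    trait_corr: TraitCorrelation
    gene_table: pd.DataFrame
    runs: dict[int, list[Subnetwork]]
    match_table: MatchTable
    consensus: list[ConsensusModule]
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    heatmap: pd.DataFrame | None = None

    def consensus_table(self) -> pd.DataFrame:
        rows = []
        for cm in self.consensus:
            rows.append(
                (
                    f"CM{cm.index}",
                    cm.size,
                    ";".join(sorted(cm.nodes)),
                    cm.connected,
                    cm.raw_score,
                    cm.adjusted,
                    cm.p_value,
                    ";".join(f"{n}:{d:.3f}" for n, d in sorted(cm.dc.items())),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["cm", "size", "nodes", "connected", "raw", "adjusted", "p", "run_dc"],
        )

    def emit(self, outdir: str) -> None:
        io.ensure_dir(outdir)
        ds = self.dataset
        io.write_traw(f"{outdir}/genotypes.traw", ds.genotypes, ds.snps, ds.sample_ids)
        io.write_table(f"{outdir}/phenotypes.tsv", ds.phenotypes)
        io.write_table(f"{outdir}/covariates.tsv", ds.covariates)
        io.write_table(f"{outdir}/diagnosis.tsv", ds.diagnosis.to_frame())
        io.write_bed(f"{outdir}/annotation.bed", ds.annotation)
        io.write_edgelist(f"{outdir}/ppi_edges.tsv", ds.network)
        io.write_gmt(f"{outdir}/gene_sets.gmt", ds.gene_sets)
        io.write_table(
            f"{outdir}/truth.tsv",
            pd.DataFrame(
                [(k, ";".join(map(str, v))) for k, v in ds.truth.items()],
                columns=["key", "value"],
            ),
            index=False,
        )
        io.write_table(f"{outdir}/phenotype_screen.tsv", self.screen.table, index=False)
        io.write_table(f"{outdir}/pvalue_matrix.tsv", self.pmatrix.to_frame())
        io.write_table(f"{outdir}/beta_matrix.tsv", self.pmatrix.beta_frame())
        io.write_table(f"{outdir}/trait_correlation.tsv", self.trait_corr.to_frame())
        io.write_table(f"{outdir}/gene_results.tsv", self.gene_table, index=False)
        io.write_table(
            f"{outdir}/manhattan.tsv",
            self.gene_table[["gene", "chrom", "p_mgas", "neglog10_p"]],
            index=False,
        )
        io.write_modules(f"{outdir}/modules.tsv", self.runs)
        io.write_table(f"{outdir}/consensus.tsv", self.consensus_table(), index=False)
        ref = self.match_table.runs[0] if self.match_table.runs else 1
        dc = pd.DataFrame(
            self.match_table.dc_matrix(min(self.match_table.runs)),
            index=[f"TN{sn.rank}" for sn in self.match_table.subnetworks[min(self.match_table.runs)]],
            columns=[f"run{n}" for n in self.match_table.runs],
        )
        io.write_table(f"{outdir}/dc_matrix.tsv", dc)
        for name, df in self.enrichment.items():
            io.write_table(f"{outdir}/enrichment_{name}.tsv", df, index=False)
        if self.heatmap is not None:
            io.write_table(f"{outdir}/enrichment_heatmap.tsv", self.heatmap)


def run_pipeline(
    config: SimulationConfig,
    n_runs: int = 10,
    search_params: SearchParams | None = None,
    screen_alpha: float = 0.05,
    reference_run: int = 1,
    enrich_alpha: float = 0.05,
    calibration_samples: int = 1000,
    outdir: str | None = None,
) -> PipelineResult:
    """Run the full analysis on one synthetic study.

    The network-search stage runs ``n_runs`` times with seed values
    1..n_runs (one shared score calibration, since node weights are fixed)
    and consensus modules are reported relative to ``reference_run``.
    """
    ds = simulate_dataset(config)

    screen = phenotype_screen(ds.phenotypes, ds.diagnosis, alpha=screen_alpha)
    kept = screen.passed_traits
    if not kept:
        raise ValueError("no trait passes the diagnostic ANOVA screen")
    phenos = ds.phenotypes[kept]

    pmatrix = snp_qt_regression(
        ds.genotypes, phenos, ds.covariates, snp_ids=list(ds.snps["snp"])
    )
    r_t = trait_correlation(phenos)
    gene_table = genome_scan(
        pmatrix, ds.snps, ds.annotation, r_t, genotypes=ds.genotypes
    )

    gene_p = dict(zip(gene_table["gene"], gene_table["p_mgas"]))
    network, _ = node_scores(gene_p, ds.network)
    params = search_params or SearchParams()
    calibration = ScoreCalibration(
        network,
        seed=config.seed + 10_000,
        n_samples=calibration_samples,
        max_size=params.max_size,
    )
    runs = {
        seed_value: greedy_search(network, seed_value, calibration, params)
        for seed_value in range(1, n_runs + 1)
    }
    table = match_across_runs(runs)
    cms = consensus_modules(table, reference_run=reference_run)
    rng = np.random.default_rng(config.seed + 20_000)
    for cm in cms:
        consensus_score(cm, network, calibration, n_perm=params.n_perm, rng=rng)

    collection = GeneSetCollection(
        ds.gene_sets, universe=set(network.nodes) | set().union(*ds.gene_sets.values())
    )
    enrichment: dict[str, pd.DataFrame] = {}
    for cm in cms:
        if cm.empty:
            continue
        enrichment[f"CM{cm.index}"] = hypergeom_enrich(cm.nodes, collection)
    heatmap = None
    if enrichment:
        try:
            heatmap = enrich_heatmap_table(enrichment, alpha=enrich_alpha)
        except ValueError:
            heatmap = None

    result = PipelineResult(
        dataset=ds,
        screen=screen,
        pmatrix=pmatrix,
        trait_corr=r_t,
        gene_table=gene_table,
        runs=runs,
        match_table=table,
        consensus=cms,
        enrichment=enrichment,
        heatmap=heatmap,
    )
    if outdir is not None:
        result.emit(outdir)
    return result
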