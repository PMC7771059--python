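"""Generator contracts: determinism, LD structure, trait correlations,
planted-module connectivity, and truth-record consistency."""

import networkx as nx
import numpy as np
import pytest
from scipy.stats import norm

from mgasnet.config import SimulationConfig, default_trait_corr
from mgasnet.synthdata import (
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_ppi,
)


def _cfg(**kw) -> SimulationConfig:
    base = dict(
        n_samples=400, n_genes=10, snps_per_gene=(4, 4), n_traits=3,
        trait_corr=np.eye(3), causal_genes=(), n_ppi_nodes=40,
        planted_module_size=4, seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_deterministic_given_seed(self):
        g1, s1, a1 = simulate_genotypes(_cfg())
        g2, s2, a2 = simulate_genotypes(_cfg())
        np.testing.assert_array_equal(g1, g2)
        assert s1.equals(s2) and a1.equals(a2)

    def test_dosages_are_valid_and_fully_observed(self):
        g, snps, ann = simulate_genotypes(_cfg())
        assert set(np.unique(g)) <= {0, 1, 2}
        assert not np.isnan(g.astype(float)).any()

    def test_every_snp_maps_to_exactly_one_gene(self):
        _, snps, ann = simulate_genotypes(_cfg())
        assert snps["gene"].isin(ann["gene"]).all()
        # positions fall inside the annotated gene body
        merged = snps.merge(ann, on="gene")
        assert ((merged["pos"] >= merged["start"]) & (merged["pos"] < merged["end"])).all()

    def test_zero_ld_gives_near_independent_dosages(self):
        cfg = _cfg(ld_rho=0.0, n_samples=2000)
        g, snps, _ = simulate_genotypes(cfg)
        rs = []
        for gene, sub in snps.groupby("gene"):
            idx = sub.index.to_numpy()
            R = np.corrcoef(g[:, idx], rowvar=False)
            rs.extend(np.abs(R[np.triu_indices_from(R, 1)]))
        # most pairs below the 3/sqrt(n) Monte-Carlo band
        assert np.mean(np.array(rs) < 3 / np.sqrt(cfg.n_samples)) > 0.95

    def test_high_ld_gives_high_dosage_correlation(self):
        cfg = _cfg(ld_rho=0.99, maf_range=(0.5, 0.5), n_samples=2000)
        g, snps, _ = simulate_genotypes(cfg)
        rs = []
        for gene, sub in snps.groupby("gene"):
            idx = sub.index.to_numpy()
            R = np.corrcoef(g[:, idx], rowvar=False)
            rs.extend(R[np.triu_indices_from(R, 1)])
        assert np.median(rs) > 0.8

    def test_hardy_weinberg_frequencies(self):
        cfg = _cfg(maf_range=(0.3, 0.3), n_samples=5000, ld_rho=0.0)
        g, _, _ = simulate_genotypes(cfg)
        q = g.mean() / 2  # allele frequency estimate
        assert abs(q - 0.3) < 0.02
        hom = (g == 2).mean()
        assert abs(hom - 0.09) < 0.02

    @pytest.mark.parametrize(
        "bad",
        [
            dict(ld_rho=1.0),
            dict(maf_range=(0.0, 0.5)),
            dict(maf_range=(0.2, 0.6)),
            dict(snps_per_gene=(0, 3)),
            dict(causal_genes=("NOPE",)),
            dict(planted_module_size=99),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            _cfg(**bad)


class TestPhenotypes:
    def test_null_trait_correlation_matches_target(self):
        # bilateral-pair target: the strongest left/right correlations
        R = default_trait_corr(8)
        cfg = SimulationConfig(
            n_samples=5000, n_genes=5, n_traits=8, trait_corr=R,
            causal_genes=(), effect_size=0.0, covariate_effect=0.0,
            diagnosis_shift=0.0, n_ppi_nodes=10, planted_module_size=2, seed=3,
        )
        g, snps, _ = simulate_genotypes(cfg)
        phen, _, _ = simulate_phenotypes(g, snps, cfg)
        S = np.corrcoef(phen.to_numpy(), rowvar=False)
        assert abs(S[2, 3] - 0.83) < 0.03  # hippocampal pair
        assert abs(S[6, 7] - 0.90) < 0.03  # putamen pair

    def test_identity_target_gives_independent_traits(self):
        cfg = _cfg(effect_size=0.0, covariate_effect=0.0, diagnosis_shift=0.0,
                   n_samples=2000)
        g, snps, _ = simulate_genotypes(cfg)
        phen, _, _ = simulate_phenotypes(g, snps, cfg)
        S = np.corrcoef(phen.to_numpy(), rowvar=False)
        off = np.abs(S[np.triu_indices_from(S, 1)])
        assert off.mean() < 3 / np.sqrt(cfg.n_samples)

    def test_unknown_causal_gene_rejected(self):
        cfg = _cfg()
        g, snps, _ = simulate_genotypes(cfg)
        cfg.causal_genes = ("G999",)  # bypass config validation
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_phenotypes(g, snps, cfg)

    def test_planted_effect_recovered_by_least_squares(self):
        cfg = _cfg(causal_genes=("G003",), effect_size=0.5, n_samples=2000,
                   covariate_effect=0.0, diagnosis_shift=0.0)
        g, snps, _ = simulate_genotypes(cfg)
        phen, _, _ = simulate_phenotypes(g, snps, cfg)
        j = snps.index[snps["gene"] == "G003"][0]
        x = g[:, j].astype(float)
        xs = (x - x.mean()) / x.std()
        y = phen.iloc[:, 0].to_numpy()
        X = np.column_stack([np.ones_like(xs), xs])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = len(y) - 2
        sigma2 = res[0] / dof
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1] - 0.5) < 3 * se

    def test_deterministic(self):
        cfg = _cfg()
        g, snps, _ = simulate_genotypes(cfg)
        p1, c1, d1 = simulate_phenotypes(g, snps, cfg)
        p2, c2, d2 = simulate_phenotypes(g, snps, cfg)
        assert p1.equals(p2) and c1.equals(c2) and (d1 == d2).all()


class TestPPI:
    def test_planted_module_connected(self):
        for seed in range(5):
            cfg = _cfg(seed=seed, planted_module_size=8, n_ppi_nodes=50,
                       n_genes=20)
            net, planted = simulate_ppi(cfg)
            assert len(planted) == 8
            assert nx.is_connected(net.subgraph(planted))

    def test_simple_graph(self):
        net, _ = simulate_ppi(_cfg())
        assert nx.number_of_selfloops(net) == 0

    def test_deterministic_edges(self):
        e1 = sorted(map(tuple, map(sorted, simulate_ppi(_cfg())[0].edges)))
        e2 = sorted(map(tuple, map(sorted, simulate_ppi(_cfg())[0].edges)))
        assert e1 == e2

    def test_planted_zscores_exceed_background(self):
        # the classic heavy-low-tail Beta(0.1, 1) signal raises mean module z
        rng = np.random.default_rng(5)
        cfg = _cfg(planted_module_size=8, n_ppi_nodes=200, n_genes=100,
                   n_samples=100)
        net, planted = simulate_ppi(cfg, np.random.default_rng(5))
        beta_p = {v: float(rng.beta(0.1, 1.0)) for v in planted}
        net, planted = simulate_ppi(cfg, np.random.default_rng(5), gene_pvalues=beta_p)
        z = {v: norm.isf(np.clip(net.nodes[v]["p"], 1e-300, 1)) for v in net.nodes}
        z_in = np.mean([z[v] for v in planted])
        z_out = np.mean([z[v] for v in net.nodes if v not in planted])
        assert z_in > z_out

    def test_provided_pvalues_take_precedence(self):
        cfg = _cfg()
        net, _ = simulate_ppi(cfg, gene_pvalues={"G001": 0.123})
        assert net.nodes["G001"]["p"] == pytest.approx(0.123)


def test_dataset_truth_record_consistent():
    cfg = SimulationConfig(n_samples=300, n_genes=20, n_traits=4,
                           trait_corr=np.eye(4), causal_genes=("G002", "G007"),
                           n_ppi_nodes=50, planted_module_size=4, seed=2)
    ds = simulate_dataset(cfg)
    assert set(ds.truth["causal_genes"]) == {"G002", "G007"}
    assert set(ds.truth["causal_genes"]) <= set(ds.truth["planted_module"])
    assert len(ds.truth["planted_module"]) == 4
    assert nx.is_connected(ds.network.subgraph(ds.truth["planted_module"]))
    assert "PLANTED_MODULE" in ds.gene_sets
    assert ds.gene_sets["PLANTED_MODULE"] == set(ds.truth["planted_module"])
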