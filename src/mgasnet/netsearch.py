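"""Network module search on a p-value-weighted PPI graph.

Gene-level association p-values are mapped to node z-scores
z_g = Phi^{-1}(1 - p_g). A candidate node set A is scored by the
Stouffer aggregate Z_A = sum(z_g) / sqrt(|A|), standardized against
random connected subnetworks of the same size ("adjusted network
score"). Greedy expansion from high-z seed nodes, repeated across
randomized runs, yields the per-run top subnetworks that the consensus
stage later intersects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import norm

log = logging.getLogger(__name__)

__all__ = [
    "Subnetwork",
    "SearchParams",
    "ScoreCalibration",
    "node_scores",
    "subnetwork_score",
    "adjusted_score",
    "greedy_search",
    "module_pvalue",
    "enumerate_connected_sets",
]


def node_scores(
    gene_pvalues: dict[str, float], network: nx.Graph
) -> tuple[nx.Graph, list[str]]:
    """Attach z = Phi^{-1}(1 - p) node weights to the network.

    Genes absent from ``gene_pvalues`` get z = 0 (the p = 0.5 neutral
    value) and are returned as the flagged list; p-values of 0 are clipped
    to the smallest positive float with a warning. Genes with p-values but
    no network node are dropped with a logged count.
    """
    G = network.copy()
    missing: list[str] = []
    n_clipped = 0
    for node in G.nodes:
        p = gene_pvalues.get(node)
        if p is None:
            missing.append(node)
            z = 0.0
        else:
            if p <= 0:
                n_clipped += 1
                p = np.finfo(float).tiny
            z = float(norm.isf(min(p, 1.0)))
        G.nodes[node]["z"] = z
        G.nodes[node]["has_p"] = p is not None
    if n_clipped:
        log.warning("%d p-value(s) of 0 clipped to the smallest positive float", n_clipped)
    dropped = len(set(gene_pvalues) - set(G.nodes))
    if dropped:
        log.info("%d gene(s) with p-values absent from the network dropped", dropped)
    return G, missing


def _zvec(network: nx.Graph, nodes) -> np.ndarray:
    return np.array([network.nodes[v]["z"] for v in nodes], dtype=float)


def subnetwork_score(node_set, network: nx.Graph) -> float:
    """Stouffer-type raw score Z_A = sum(z) / sqrt(|A|) of a connected set."""
    nodes = list(node_set)
    if not nodes:
        raise ValueError("empty node set")
    if not nx.is_connected(network.subgraph(nodes)):
        raise ValueError("node set is not connected in the network")
    z = _zvec(network, nodes)
    return float(z.sum() / np.sqrt(len(nodes)))


class ScoreCalibration:
    """Null mean/sd of raw scores of random connected subnetworks per size.

    Sampling uses a random-growth walk with restart: start from a uniform
    random node and repeatedly absorb a uniform random boundary node until
    the target size is reached (restarting if the walk gets stuck). The
    sampler is not exactly uniform over connected subgraphs — a documented,
    stable bias — but provides a fixed null reference per (graph, weights).

    All sizes up to ``max_size`` are calibrated from the prefixes of the
    same ``n_samples`` growth walks (a truncated walk has the law of a
    shorter one), so the per-size (mu, sigma) estimates share randomness
    and adjusted scores compare smoothly across adjacent sizes.

    With ``robust=True`` location and scale are the median and the
    Gaussian-consistent MAD instead of mean and sd, an option for graphs
    whose weight distribution has extreme outliers.
    """

    def __init__(
        self,
        network: nx.Graph,
        seed: int = 0,
        n_samples: int = 1000,
        max_size: int = 20,
        max_restarts: int = 50,
        robust: bool = False,
    ):
        if n_samples < 1:
            raise ValueError("need at least one calibration sample per size")
        self.network = network
        self.n_samples = n_samples
        self.max_size = min(max_size, network.number_of_nodes())
        self.max_restarts = max_restarts
        self.robust = robust
        self._rng = np.random.default_rng(seed)
        self._adj = {v: list(network.adj[v]) for v in network.nodes}
        self._nodes = list(network.nodes)
        self._z = {v: network.nodes[v]["z"] for v in network.nodes}
        self._mu_sigma: dict[int, tuple[float, float]] | None = None

    def _walk(self, k: int, rng: np.random.Generator) -> list | None:
        """One growth walk, returning nodes in absorption order (or None)."""
        start = self._nodes[int(rng.integers(len(self._nodes)))]
        members = {start}
        order = [start]
        boundary = [v for v in self._adj[start] if v != start]
        while len(members) < k and boundary:
            v = boundary.pop(int(rng.integers(len(boundary))))
            if v in members:
                continue
            members.add(v)
            order.append(v)
            boundary.extend(u for u in self._adj[v] if u not in members)
        return order if len(order) == k else None

    def sample_connected(self, k: int, rng: np.random.Generator | None = None) -> list:
        rng = self._rng if rng is None else rng
        for _ in range(self.max_restarts):
            order = self._walk(k, rng)
            if order is not None:
                return order
        raise ValueError(f"could not sample a connected subnetwork of size {k}")

    def _calibrate(self) -> None:
        k_max = self.max_size
        scores = np.full((self.n_samples, k_max), np.nan)
        for i in range(self.n_samples):
            order = None
            for _ in range(self.max_restarts):
                order = self._walk(k_max, self._rng)
                if order is not None:
                    break
            if order is None:
                raise ValueError(
                    f"could not sample connected subnetworks of size {k_max}; "
                    "lower max_size"
                )
            z = np.array([self._z[v] for v in order])
            scores[i, :] = np.cumsum(z) / np.sqrt(np.arange(1, k_max + 1))
        self._mu_sigma = {}
        for k in range(1, self.max_size + 1):
            col = scores[:, k - 1]
            if self.robust:
                mu = float(np.median(col))
                sigma = 1.4826 * float(np.median(np.abs(col - mu)))
                if sigma == 0:  # constant bulk; fall back to moments
                    mu, sigma = float(col.mean()), float(col.std(ddof=1))
            else:
                mu, sigma = float(col.mean()), float(col.std(ddof=1))
            if sigma == 0:
                raise ValueError(
                    f"degenerate network: null score sd is 0 at size {k}"
                )
            self._mu_sigma[k] = (mu, sigma)

    def mu_sigma(self, k: int) -> tuple[float, float]:
        if k < 1:
            raise ValueError("size must be >= 1")
        if k > self.max_size:
            raise ValueError(
                f"size {k} exceeds calibrated max_size {self.max_size}"
            )
        if self._mu_sigma is None:
            self._calibrate()
        return self._mu_sigma[k]

    def adjust(self, raw: float, k: int) -> float:
        mu, sigma = self.mu_sigma(k)
        return (raw - mu) / sigma


def adjusted_score(raw: float, k: int, calibration: ScoreCalibration) -> float:
    """Standardize a raw score against same-size random connected subnetworks."""
    return calibration.adjust(raw, k)


@dataclass(order=True)
class Subnetwork:
    sort_key: float = field(repr=False, compare=True)
    run: int = field(compare=False, default=0)
    rank: int = field(compare=False, default=0)
    nodes: frozenset = field(compare=False, default_factory=frozenset)
    raw_score: float = field(compare=False, default=np.nan)
    adjusted: float = field(compare=False, default=np.nan)
    p_value: float = field(compare=False, default=np.nan)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class SearchParams:
    """Greedy-search knobs (all config-exposed; defaults are the study's).

    seed_quantile : nodes with z at or above this quantile seed the search.
    seed_fraction : fraction of eligible seeds visited per run (subsampled
        per run seed to create run-to-run variability).
    improvement : minimum gain in adjusted score (which is already on a
        standardized z scale) to keep growing once the module has reached
        ``min_size``.
    max_size / min_size : module size bounds.
    top_k : number of subnetworks reported per run.
    n_perm : weight permutations for module p-values.
    """

    seed_quantile: float = 0.95
    seed_fraction: float = 0.8
    improvement: float = 0.05
    max_size: int = 20
    min_size: int = 2
    top_k: int = 5
    n_perm: int = 1000


def _grow(
    network: nx.Graph,
    adj: dict,
    z: dict,
    start,
    calibration: ScoreCalibration,
    params: SearchParams,
    rng: np.random.Generator,
) -> frozenset | None:
    members = {start}
    zsum = z[start]
    boundary = set(adj[start])
    cur_adj = calibration.adjust(zsum, 1)
    cur_raw = zsum

    def _absorb(v: object) -> None:
        nonlocal zsum
        members.add(v)
        zsum += z[v]
        boundary.discard(v)
        boundary.update(u for u in adj[v] if u not in members)

    while len(members) < params.max_size and boundary:
        k_new = len(members) + 1
        best, best_score = [], -np.inf
        # sorted iteration keeps tie handling independent of hash seeds
        for v in sorted(boundary, key=str):
            s = calibration.adjust((zsum + z[v]) / np.sqrt(k_new), k_new)
            if s > best_score + 1e-12:
                best, best_score = [v], s
            elif abs(s - best_score) <= 1e-12:
                best.append(v)
        # Within a size the adjusted score is monotone in the raw score,
        # so the argmax candidate maximizes both. Growth continues while
        # either the adjusted score clears the improvement bar or the raw
        # Stouffer score still strictly increases (which requires the new
        # node's z to exceed roughly Z_A / (2 sqrt(k)): self-limiting).
        best_raw = (zsum + max(z[v] for v in best)) / np.sqrt(k_new)
        stalled = (
            best_score - cur_adj <= params.improvement
            and best_raw <= cur_raw + 1e-12
        )
        if len(members) >= params.min_size and stalled:
            # Two-step lookahead: a weak bridge node may hide a strong
            # neighbor; accept the best (bridge, follower) pair if the
            # pair clears either growth condition and the size budget.
            pair = None
            if len(members) + 2 <= params.max_size:
                pair_score, pair_raw = -np.inf, -np.inf
                for v in sorted(boundary, key=str):
                    for u in sorted(adj[v], key=str):
                        if u in members or u == v:
                            continue
                        r2 = (zsum + z[v] + z[u]) / np.sqrt(k_new + 1)
                        s2 = calibration.adjust(r2, k_new + 1)
                        if s2 > pair_score:
                            pair, pair_score, pair_raw = (v, u), s2, r2
                if pair is not None and (
                    pair_score - cur_adj > params.improvement
                    or pair_raw > cur_raw + 1e-12
                ):
                    _absorb(pair[0])
                    _absorb(pair[1])
                    cur_adj, cur_raw = pair_score, pair_raw
                    continue
            break
        v = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
        _absorb(v)
        cur_adj = calibration.adjust(zsum / np.sqrt(len(members)), len(members))
        cur_raw = zsum / np.sqrt(len(members))
    if len(members) < params.min_size:
        return None
    return frozenset(members)


def greedy_search(
    network: nx.Graph,
    seed_value: int,
    calibration: ScoreCalibration,
    params: SearchParams | None = None,
) -> list[Subnetwork]:
    """One randomized run of greedy module search.

    Seeds are the nodes with z above ``seed_quantile``; each run visits a
    ``seed_fraction`` subsample of them in an order randomized by
    ``seed_value``, grows each greedily by the neighbor that maximizes the
    adjusted score while the relative improvement exceeds the threshold,
    deduplicates identical node sets, and returns the ``top_k``
    subnetworks by adjusted score with permutation p-values.
    """
    params = params or SearchParams()
    rng = np.random.default_rng(seed_value)
    z = {v: network.nodes[v]["z"] for v in network.nodes}
    adj = {v: set(network.adj[v]) - {v} for v in network.nodes}
    zs = np.array(list(z.values()))
    threshold = np.quantile(zs, params.seed_quantile)
    seeds = [v for v in network.nodes if z[v] >= threshold]
    if not seeds:
        raise ValueError(
            "no node passes the seed quantile; lower params.seed_quantile"
        )
    seeds = list(np.array(seeds, dtype=object)[rng.permutation(len(seeds))])
    n_keep = max(1, int(round(params.seed_fraction * len(seeds))))
    seeds = seeds[:n_keep]

    found: dict[frozenset, float] = {}
    for s in seeds:
        module = _grow(network, adj, z, s, calibration, params, rng)
        if module is None:
            continue
        if module not in found:
            raw = sum(z[v] for v in module) / np.sqrt(len(module))
            found[module] = calibration.adjust(raw, len(module))

    ranked = sorted(
        found.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0], key=str)))
    )[: params.top_k]
    out = []
    for rank, (module, adjv) in enumerate(ranked, start=1):
        raw = sum(z[v] for v in module) / np.sqrt(len(module))
        pval = module_pvalue(module, network, calibration, params.n_perm, rng=rng)
        out.append(
            Subnetwork(
                sort_key=-adjv,
                run=seed_value,
                rank=rank,
                nodes=module,
                raw_score=raw,
                adjusted=adjv,
                p_value=pval,
            )
        )
    return out


def module_pvalue(
    node_set,
    network: nx.Graph,
    calibration: ScoreCalibration,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value of a module's adjusted score.

    Node weights are permuted over the whole network (topology preserved)
    and the same node set re-scored; with the add-one estimator
    p = (1 + #{permuted adjusted score >= observed}) / (1 + n_perm),
    bounded below by 1/(1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    nodes = list(node_set)
    k = len(nodes)
    if k == 0:
        raise ValueError("empty node set")
    rng = np.random.default_rng(0) if rng is None else rng
    z_all = np.array([network.nodes[v]["z"] for v in network.nodes])
    obs_raw = sum(network.nodes[v]["z"] for v in nodes) / np.sqrt(k)
    obs = calibration.adjust(obs_raw, k)
    # Permuting weights and summing over a fixed set == sampling k weights
    # without replacement; vectorized via argpartition of random keys.
    keys = rng.random((n_perm, z_all.size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    raw = z_all[idx].sum(axis=1) / np.sqrt(k)
    mu, sigma = calibration.mu_sigma(k)
    perm_adj = (raw - mu) / sigma
    return float((1 + np.sum(perm_adj >= obs)) / (1 + n_perm))


def enumerate_connected_sets(network: nx.Graph, min_size: int, max_size: int):
    """Yield every connected node set with min_size <= |A| <= max_size.

    Exhaustive; intended as a brute-force oracle on tiny graphs.
    """
    nodes = list(network.nodes)
    for k in range(min_size, max_size + 1):
        for combo in combinations(nodes, k):
            if nx.is_connected(network.subgraph(combo)):
                yield frozenset(combo)
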