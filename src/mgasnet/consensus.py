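"""Consensus modules across randomized network-search runs.

Each top subnetwork of a reference run is matched, via the Dice
coefficient, to its most similar subnetwork in every other run; the
consensus module is the intersection of the subnetwork with all of its
matches. Modules that replicate across runs survive intersection, while
run-specific noise genes are stripped away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netsearch import ScoreCalibration, Subnetwork, module_pvalue

log = logging.getLogger(__name__)

__all__ = [
    "MatchTable",
    "ConsensusModule",
    "dice",
    "match_across_runs",
    "consensus_modules",
    "consensus_score",
]


def dice(x, y) -> float:
    """Dice coefficient 2|x & y| / (|x| + |y|) of two node sets."""
    x, y = set(x), set(y)
    if not x or not y:
        raise ValueError("Dice coefficient is undefined for empty sets")
    return 2 * len(x & y) / (len(x) + len(y))


@dataclass
class MatchTable:
    """Best cross-run matches: (run j, rank i, other run n) -> match."""

    runs: list[int]
    subnetworks: dict[int, list[Subnetwork]]           # run -> ranked list
    matches: dict[tuple[int, int, int], tuple[Subnetwork, float]] = field(
        default_factory=dict
    )

    def match(self, run: int, rank: int, other: int) -> tuple[Subnetwork, float]:
        return self.matches[(run, rank, other)]

    def dc_matrix(self, reference_run: int) -> np.ndarray:
        """Rows = ranks of the reference run, columns = runs, entries = DC."""
        ranks = [sn.rank for sn in self.subnetworks[reference_run]]
        out = np.full((len(ranks), len(self.runs)), np.nan)
        for r_i, rank in enumerate(ranks):
            for c_j, n in enumerate(self.runs):
                out[r_i, c_j] = self.matches[(reference_run, rank, n)][1]
        return out


def match_across_runs(
    run_results: dict[int, list[Subnetwork]], pool: str = "top"
) -> MatchTable:
    """For each subnetwork, find the argmax-Dice subnetwork in every run.

    ``pool`` = "top" restricts candidates to each run's reported list
    (the default); "all" is accepted for API symmetry — the search stage
    only reports the top list, so both behave identically on its output.
    Ties are broken by better (lower) rank, then lexicographic node order.
    The self-match (n = j) is recorded with DC = 1.
    """
    if pool not in ("top", "all"):
        raise ValueError("pool must be 'top' or 'all'")
    runs = sorted(run_results)
    for j in runs:
        if not run_results[j]:
            raise ValueError(f"run {j} has no subnetworks")
    table = MatchTable(runs=runs, subnetworks=run_results)
    for j in runs:
        for sn in run_results[j]:
            for n in runs:
                if n == j:
                    table.matches[(j, sn.rank, n)] = (sn, 1.0)
                    continue
                best = min(
                    run_results[n],
                    key=lambda cand: (
                        -dice(sn.nodes, cand.nodes),
                        cand.rank,
                        tuple(sorted(cand.nodes)),
                    ),
                )
                table.matches[(j, sn.rank, n)] = (best, dice(sn.nodes, best.nodes))
    return table


@dataclass
class ConsensusModule:
    index: int
    nodes: frozenset
    reference: Subnetwork
    matched: dict[int, Subnetwork]      # other run -> matched subnetwork
    dc: dict[int, float]                # other run -> DC with the reference
    connected: bool | None = None
    raw_score: float = np.nan
    adjusted: float = np.nan
    p_value: float = np.nan

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def empty(self) -> bool:
        return self.size == 0


def consensus_modules(
    table: MatchTable, reference_run: int = 1, deduplicate: bool = True
) -> list[ConsensusModule]:
    """Intersect each reference-run subnetwork with all its matches.

    CM_i = TN_i  intersect  (intersection over other runs n of the
    argmax-Dice match of TN_i in run n). Duplicate consensus node sets are
    collapsed (keeping the best-ranked), and empty intersections are
    retained with size 0 rather than dropped.
    """
    if reference_run not in table.runs:
        raise ValueError(f"reference run {reference_run} not among runs {table.runs}")
    out: list[ConsensusModule] = []
    seen: set[frozenset] = set()
    for sn in table.subnetworks[reference_run]:
        nodes = set(sn.nodes)
        matched: dict[int, Subnetwork] = {}
        dc: dict[int, float] = {}
        for n in table.runs:
            if n == reference_run:
                continue
            m, d = table.matches[(reference_run, sn.rank, n)]
            matched[n] = m
            dc[n] = d
            nodes &= m.nodes
        cm_nodes = frozenset(nodes)
        if deduplicate and cm_nodes and cm_nodes in seen:
            continue
        seen.add(cm_nodes)
        if not cm_nodes:
            log.info("consensus module %d has an empty intersection", sn.rank)
        out.append(
            ConsensusModule(
                index=len(out) + 1,
                nodes=cm_nodes,
                reference=sn,
                matched=matched,
                dc=dc,
            )
        )
    return out


def consensus_score(
    cm: ConsensusModule,
    network: nx.Graph,
    calibration: ScoreCalibration,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> ConsensusModule:
    """Adjusted score and permutation p-value for a consensus module.

    Consensus intersections need not be connected in the PPI graph; the
    Stouffer aggregate and its size-matched calibration are applied to the
    node set regardless, and a connectivity flag is recorded. Empty
    modules get NaN scores.
    """
    if cm.empty:
        cm.connected = None
        cm.raw_score = cm.adjusted = cm.p_value = float("nan")
        return cm
    nodes = list(cm.nodes)
    cm.connected = nx.is_connected(network.subgraph(nodes))
    z = np.array([network.nodes[v]["z"] for v in nodes])
    cm.raw_score = float(z.sum() / np.sqrt(len(nodes)))
    cm.adjusted = calibration.adjust(cm.raw_score, len(nodes))
    cm.p_value = module_pvalue(cm.nodes, network, calibration, n_perm, rng=rng)
    return cm
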