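"""Plain-text readers and writers for every pipeline artifact.

Genotypes travel as PLINK-style .traw-compatible TSV, phenotypes and
covariates as sample-indexed TSV, SNP-to-gene annotation as BED-like TSV,
networks as two-column edge lists (SIF accepted on read), gene sets as
GMT, and module/consensus/enrichment tables as headered TSV.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .netsearch import Subnetwork

__all__ = [
    "write_traw", "read_traw",
    "write_bed", "read_bed",
    "write_table", "read_table",
    "write_edgelist", "read_network",
    "write_gmt", "read_gmt",
    "write_modules", "read_modules",
]


def write_traw(path: str, genotypes: np.ndarray, snps: pd.DataFrame, sample_ids) -> None:
    """PLINK .traw layout: CHR SNP (C)M POS COUNTED ALT + one column/sample."""
    df = pd.DataFrame(
        {
            "CHR": snps["chrom"].to_numpy(),
            "SNP": snps["snp"].to_numpy(),
            "(C)M": 0,
            "POS": snps["pos"].to_numpy(),
            "COUNTED": "A",
            "ALT": "G",
        }
    )
    dose = pd.DataFrame(
        np.asarray(genotypes).T, columns=list(sample_ids), index=df.index
    )
    pd.concat([df, dose], axis=1).to_csv(path, sep="\t", index=False)


def read_traw(path: str) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    samples = [c for c in df.columns if c not in meta_cols]
    snps = pd.DataFrame(
        {"snp": df["SNP"], "chrom": df["CHR"], "pos": df["POS"]}
    )
    genotypes = df[samples].to_numpy().T
    return genotypes, snps, samples


def write_bed(path: str, annotation: pd.DataFrame) -> None:
    annotation[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
    )


def write_table(path: str, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_edgelist(path: str, network: nx.Graph) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(map(sorted, network.edges())):
            fh.write(f"{u}\t{v}\n")


def read_network(path: str) -> nx.Graph:
    """Two-column TSV edge list, or three-column SIF (node relation node)."""
    G = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if len(parts) >= 3 and parts[1] and not parts[1][0].isdigit():
                u, v = parts[0], parts[2]  # SIF
            else:
                u, v = parts[0], parts[1]
            if u != v:
                G.add_edge(u, v)
    return G


def write_gmt(path: str, sets: dict[str, set[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gmt(path: str) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_modules(path: str, runs: dict[int, list[Subnetwork]]) -> None:
    rows = []
    for run in sorted(runs):
        for sn in runs[run]:
            rows.append(
                (run, sn.rank, len(sn.nodes), ";".join(sorted(sn.nodes)),
                 sn.raw_score, sn.adjusted, sn.p_value)
            )
    pd.DataFrame(
        rows, columns=["run", "rank", "size", "nodes", "raw", "adjusted", "p"]
    ).to_csv(path, sep="\t", index=False)


def read_modules(path: str) -> dict[int, list[Subnetwork]]:
    df = pd.read_csv(path, sep="\t")
    runs: dict[int, list[Subnetwork]] = {}
    for row in df.itertuples(index=False):
        sn = Subnetwork(
            sort_key=-row.adjusted,
            run=int(row.run),
            rank=int(row.rank),
            nodes=frozenset(str(row.nodes).split(";")),
            raw_score=float(row.raw),
            adjusted=float(row.adjusted),
            p_value=float(row.p),
        )
        runs.setdefault(int(row.run), []).append(sn)
    for run in runs:
        runs[run].sort(key=lambda s: s.rank)
    return runs


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
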