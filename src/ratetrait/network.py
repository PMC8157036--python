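"""Trait coevolution networks.

Pairwise Pearson correlations, partial correlations from the inverse
correlation matrix, and a sparse trait-dependence graph selected by BIC:
each candidate edge (i,j) of a Gaussian graphical model improves BIC by
-n*log(1 - r_ij^2) - log(n); the maximum-weight spanning forest over the
positive-gain edges (Kruskal) is the minimum-BIC forest.  Continuous traits
enter on the log scale, binary traits as 0/1 numeric, and rows may include
predicted ancestral branches alongside terminal ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import TraitTable

__all__ = [
    "CorrelationResult",
    "TraitGraph",
    "numeric_trait_frame",
    "pairwise_correlations",
    "partial_correlations",
    "min_bic_forest",
]


@dataclass
class CorrelationResult:
    traits: list[str]
    pairwise: pd.DataFrame  # symmetric, unit diagonal
    partial: pd.DataFrame | None  # rho_{ij.rest}, same shape
    n: int  # rows used (complete cases for the partial matrix)
    condition_number: float | None = None


@dataclass
class TraitGraph:
    """Undirected trait graph; edges carry partial correlation and BIC gain."""

    graph: nx.Graph
    forest: bool = True

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, d) for u, v, d in self.graph.edges(data=True)]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "trait_i": min(u, v),
                "trait_j": max(u, v),
                "partial_correlation": d.get("partial_correlation", np.nan),
                "bic_gain": d["bic_gain"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["trait_i", "trait_j", "partial_correlation", "bic_gain"]
        ).sort_values(["trait_i", "trait_j"]).reset_index(drop=True)

    def write_edge_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_dot(self, path) -> None:
        lines = ["graph traits {"]
        for node in sorted(self.graph.nodes):
            lines.append(f'  "{node}";')
        for u, v, d in sorted(self.graph.edges(data=True)):
            pc = d.get("partial_correlation", float("nan"))
            lines.append(f'  "{u}" -- "{v}" [label="{pc:.3f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def numeric_trait_frame(
    T: TraitTable,
    traits: list[str] | None = None,
    include_provenance: tuple[str, ...] = TraitTable.PROVENANCE_LEVELS,
) -> pd.DataFrame:
    """Numeric view of a trait table for correlation work.

    Continuous traits are natural-log transformed; binary traits pass as
    0/1.  Rows whose provenance is outside ``include_provenance`` for a
    given cell are masked to missing for that trait.
    """
    traits = list(traits) if traits is not None else list(T.values.columns)
    out = pd.DataFrame(index=T.values.index, columns=traits, dtype=float)
    for trait in traits:
        col = T.values[trait].astype(float)
        keep = T.provenance[trait].isin(include_provenance)
        col = col.where(keep)
        out[trait] = np.log(col) if T.schema[trait] == "continuous" else col
    return out


def _check_constant(df: pd.DataFrame) -> None:
    for c in df.columns:
        col = df[c].dropna()
        if col.nunique() <= 1:
            raise ValueError(f"trait {c!r} is constant; correlation undefined")


def pairwise_correlations(
    T: TraitTable, traits: list[str] | None = None, min_pairs: int = 3
) -> CorrelationResult:
    """Pearson correlations on complete rows within each trait pair."""
    df = numeric_trait_frame(T, traits)
    _check_constant(df)
    counts = df.notna().astype(int)
    pair_n = counts.T @ counts
    low = [
        (i, j)
        for i in df.columns
        for j in df.columns
        if i < j and pair_n.loc[i, j] < min_pairs
    ]
    if low:
        raise ValueError(f"trait pairs with < {min_pairs} complete rows: {low[:5]}")
    corr = df.corr(method="pearson")
    return CorrelationResult(
        traits=list(df.columns),
        pairwise=corr,
        partial=None,
        n=int(pair_n.to_numpy().min()),
    )


def partial_correlations(
    T: TraitTable, traits: list[str] | None = None
) -> CorrelationResult:
    """Partial correlation of each trait pair given all remaining traits.

    Complete-case rows across the selected traits; rho_{ij.rest} =
    -P_ij / sqrt(P_ii P_jj) with P the inverse of the correlation matrix.
    """
    df = numeric_trait_frame(T, traits).dropna()
    p = df.shape[1]
    if df.shape[0] < p + 3:
        raise ValueError(
            f"{df.shape[0]} complete rows for {p} traits; need >= {p + 3}"
        )
    _check_constant(df)
    corr = df.corr(method="pearson")
    cond = float(np.linalg.cond(corr.to_numpy()))
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"correlation matrix near-singular (condition {cond:.2e}); "
            "remove collinear traits"
        )
    P = np.linalg.inv(corr.to_numpy())
    d = np.sqrt(np.diag(P))
    partial = -P / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = pd.DataFrame(partial, index=corr.index, columns=corr.columns)
    return CorrelationResult(
        traits=list(df.columns),
        pairwise=corr,
        partial=partial,
        n=int(df.shape[0]),
        condition_number=cond,
    )


def bic_edge_gain(r: float, n: int) -> float:
    """BIC improvement from adding one edge with marginal correlation r."""
    return -n * np.log(1.0 - r * r) - np.log(n)


def min_bic_forest(
    T: TraitTable, traits: list[str] | None = None, min_rows: int = 20
) -> TraitGraph:
    """Maximum-weight spanning forest over edges with positive BIC gain.

    Kruskal's algorithm on edge weights w_ij = -n*log(1-r_ij^2) - log n;
    ties are broken by the lexicographic trait-name pair so the output does
    not depend on the input trait order.  Edges are annotated with the
    partial correlation computed on the same complete-case rows.
    """
    df = numeric_trait_frame(T, traits).dropna()
    n = df.shape[0]
    if n < min_rows:
        raise ValueError(f"{n} complete rows; need >= {min_rows}")
    res = partial_correlations(T, traits)
    corr = df.corr(method="pearson")
    names = sorted(df.columns)

    edges = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            i, j = names[a], names[b]
            w = bic_edge_gain(float(corr.loc[i, j]), n)
            if w > 0:
                edges.append((w, i, j))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    parent = {t: t for t in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    G = nx.Graph()
    G.add_nodes_from(names)
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            G.add_edge(
                i,
                j,
                bic_gain=float(w),
                partial_correlation=float(res.partial.loc[i, j]),
                correlation=float(corr.loc[i, j]),
            )
    return TraitGraph(graph=G, forest=True)
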