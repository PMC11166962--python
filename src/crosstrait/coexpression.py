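"""Guilt-by-association co-expression expansion of a seed gene set.

Each seed (eQTL) gene is correlated against every other gene in an
expression matrix; partners surviving a Bonferroni gate (family = all
(seed, partner) tests actually performed, adjusted p < 0.05 strict) join
the seed in a co-expression network, which is partitioned into modules.

Pearson correlation with the exact two-sided t-test p-value
(t = r * sqrt((n-2)/(1-r^2)) on n-2 df) is the default; Spearman is
offered as an option. Module detection defaults to connected components
of the retained-edge graph — the simplest deterministic rule — with
greedy modularity refinement available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import DomainError, FormatError

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate gene ids, e.g. {dups}")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need >= 3 samples, found {df.shape[1]}")
    return df.astype(float)


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform on n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlate_seeds(
    matrix: pd.DataFrame,
    seed_genes: Sequence[str],
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate every seed against every other gene in the matrix.

    Returns one row per tested (seed, partner) pair with columns
    ``seed, partner, r, p_raw``. Self-edges are excluded and seed-seed
    pairs appear once (lexicographic seed < partner). Seeds absent from
    the matrix and constant-expression genes are skipped with a warning.
    """
    n = matrix.shape[1]
    if n < 3:
        raise DomainError(f"need >= 3 samples for a correlation p-value, got {n}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    genes = matrix.index.to_list()
    present = [g for g in dict.fromkeys(seed_genes) if g in matrix.index]
    absent = [g for g in dict.fromkeys(seed_genes) if g not in matrix.index]
    if absent:
        log.warning("%d seed gene(s) absent from expression matrix (skipped)", len(absent))
    if not present:
        return pd.DataFrame(columns=["seed", "partner", "r", "p_raw"])

    X = matrix.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant-expression gene(s) skipped", int(constant.sum()))
    Xs = (X - X.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        Xs = Xs / (sd[:, None] * np.sqrt(n))

    gene_pos = {g: i for i, g in enumerate(genes)}
    seed_set = set(present)
    rows = []
    for s in present:
        i = gene_pos[s]
        if constant[i]:
            continue
        r_vec = Xs @ Xs[i]
        p_vec = correlation_pvalue(r_vec, n)
        for j, g in enumerate(genes):
            if g == s or constant[j]:
                continue
            if g in seed_set and not s < g:  # symmetric seed-seed pair: keep once
                continue
            rows.append((s, g, float(np.clip(r_vec[j], -1, 1)), float(p_vec[j])))
    return pd.DataFrame(rows, columns=["seed", "partner", "r", "p_raw"])


def bonferroni_gate(edges: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Retain edges with Bonferroni-adjusted p strictly below alpha.

    m = number of tests actually performed (rows of ``edges``);
    p_adj = min(1, m * p_raw).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = len(edges)
    if m == 0:
        out = edges.copy()
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out = edges.copy()
    out["p_adj"] = np.minimum(1.0, m * out["p_raw"])
    return out[m * out["p_raw"] < alpha].reset_index(drop=True)


def build_network(seed_genes: Sequence[str], retained_edges: pd.DataFrame) -> nx.Graph:
    """Graph over seeds ∪ significant partners; r stored as edge weight."""
    g = nx.Graph()
    g.add_nodes_from(dict.fromkeys(seed_genes))
    for row in retained_edges.itertuples(index=False):
        g.add_edge(row.seed, row.partner, weight=float(row.r), p_adj=float(row.p_adj))
    return g


def detect_modules(network: nx.Graph, method: str = "components") -> list[frozenset]:
    """Deterministic partition of the network's nodes into modules.

    ``components`` (default): connected components. ``greedy``: greedy
    modularity maximisation refining each component. Modules are ordered
    by size descending, ties broken by smallest node id, so identical
    inputs always give identical output order.
    """
    if network.number_of_nodes() == 0:
        raise DomainError("network is empty")
    if method == "components":
        groups = [frozenset(c) for c in nx.connected_components(network)]
    elif method == "greedy":
        groups = []
        for comp in nx.connected_components(network):
            sub = network.subgraph(comp)
            if sub.number_of_edges() == 0:
                groups.append(frozenset(comp))
            else:
                groups.extend(
                    frozenset(c)
                    for c in nx.community.greedy_modularity_communities(sub)
                )
    else:
        raise ValueError(f"unknown module method {method!r}")
    return sorted(groups, key=lambda m: (-len(m), min(m)))


class CoexpressionScreen:
    """Guilt-by-association screen of seed genes against an expression matrix.

    Parameters
    ----------
    matrix
        genes x samples expression DataFrame (assumed normalised).
    seed_genes
        The disorder's eQTL genes to expand.
    """

    def __init__(self, matrix: pd.DataFrame, seed_genes: Sequence[str], label: str = ""):
        if matrix.index.duplicated().any():
            raise FormatError("expression matrix has duplicate gene ids")
        if matrix.shape[1] < 3:
            raise DomainError("expression matrix needs >= 3 samples")
        self.matrix = matrix
        self.seed_genes = list(dict.fromkeys(seed_genes))
        self.label = label

    def fit(
        self,
        alpha: float = DEFAULT_ALPHA,
        method: str = "pearson",
        module_method: str = "components",
    ) -> "CoexpressionResults":
        edges = correlate_seeds(self.matrix, self.seed_genes, method=method)
        retained = bonferroni_gate(edges, alpha=alpha)
        seeds_present = [g for g in self.seed_genes if g in self.matrix.index]
        network = build_network(seeds_present, retained)
        modules = detect_modules(network, method=module_method) if network else []
        return CoexpressionResults(
            model=self,
            edges=edges,
            retained=retained,
            network=network,
            modules=modules,
            alpha=alpha,
            n_tests=len(edges),
        )


@dataclass
class CoexpressionResults:
    """Retained co-expression edges, the resulting network, and its modules."""

    model: CoexpressionScreen
    edges: pd.DataFrame
    retained: pd.DataFrame
    network: nx.Graph
    modules: list[frozenset]
    alpha: float
    n_tests: int
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = self.model.label

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.network.nodes)

    def module_frame(self) -> pd.DataFrame:
        rows = [
            {"module": i + 1, "gene": gene, "is_seed": gene in set(self.model.seed_genes)}
            for i, mod in enumerate(self.modules)
            for gene in sorted(mod)
        ]
        return pd.DataFrame(rows, columns=["module", "gene", "is_seed"])

    def summary(self) -> str:
        multi = [m for m in self.modules if len(m) > 1]
        lines = [
            f"Co-expression screen{' — ' + self.label if self.label else ''}",
            "=" * 42,
            f"Seeds: {len(self.model.seed_genes)} "
            f"({len([g for g in self.model.seed_genes if g in self.matrix_index])} in matrix)",
            f"Tests performed (Bonferroni family m): {self.n_tests}",
            f"Edges retained at adjusted p < {self.alpha}: {len(self.retained)}",
            f"Network nodes: {self.network.number_of_nodes()}",
            f"Modules: {len(self.modules)} ({len(multi)} with >1 gene)",
        ]
        return "\n".join(lines)

    @property
    def matrix_index(self):
        return self.model.matrix.index
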