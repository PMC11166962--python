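"""Hypergeometric gene-set enrichment with similarity-based term clustering.

Each query gene list is tested against every GMT term with the
hypergeometric upper tail P(X >= k) for k query genes inside a K-gene
term drawn n-from-N. A term is called significant under the express
convention: p < 0.01, overlap k >= 3, enrichment factor k/(n*K/N) >= 1.5
(all configurable); Benjamini-Hochberg q-values are emitted alongside for
transparency. Significant terms are linked whenever their Cohen's-kappa
membership similarity exceeds 0.3 and clusters are the single-linkage
transitive closure, each named after its most significant member term.
A cluster is "shared" when it holds at least one significant term for
each of the two query lists.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._util import DomainError, FormatError

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MIN_FACTOR = 1.5
DEFAULT_SIMILARITY_THRESHOLD = 0.3


@dataclass(frozen=True)
class GeneSetTerm:
    """One annotation term (pathway / GO category / gene set)."""

    term_id: str
    name: str
    source: str
    members: frozenset[str]


def _infer_source(term_id: str) -> str:
    tid = term_id.upper()
    if tid.startswith("GO:"):
        return "GO"
    if tid.startswith("R-HSA") or tid.startswith("R-"):
        return "Reactome"
    if tid.startswith(("KO:", "HSA", "KEGG")):
        return "KEGG"
    return "custom"


def read_gmt(path: str | Path) -> list[GeneSetTerm]:
    """Read a GMT file: per line ``term_id <tab> description <tab> gene...``."""
    terms: list[GeneSetTerm] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            term_id, desc = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {lineno}: term {term_id!r} has no genes")
            if term_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            terms.append(
                GeneSetTerm(
                    term_id=term_id,
                    name=desc or term_id,
                    source=_infer_source(term_id),
                    members=genes,
                )
            )
    return terms


def write_gmt(terms: Iterable[GeneSetTerm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 < K <= N):
        raise DomainError(f"inconsistent hypergeometric parameters k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment against one query list."""

    term: GeneSetTerm
    query_label: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float
    enrichment_factor: float
    significant: bool
    overlap_genes: frozenset[str] = frozenset()


def enrich(
    query_genes: Iterable[str],
    terms: Sequence[GeneSetTerm],
    background: Iterable[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_factor: float = DEFAULT_MIN_FACTOR,
    query_label: str = "",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a query list against a term collection.

    Query genes outside the background are logged and intersected away;
    term members are likewise restricted to the background before K is
    counted.
    """
    bg = set(background)
    query = set(query_genes)
    if not query or not bg:
        raise DomainError("query and background must be non-empty")
    outside = query - bg
    if outside:
        log.warning(
            "%d query gene(s) outside the background were dropped (%s...)",
            len(outside), sorted(outside)[:3],
        )
        query &= bg
        if not query:
            raise DomainError("no query genes remain inside the background")
    N, n = len(bg), len(query)
    results = []
    for t in terms:
        members = t.members & bg
        if not members:
            continue
        K = len(members)
        hits = members & query
        k = len(hits)
        p = hypergeometric_p(k, n, K, N)
        factor = k / (n * K / N)
        results.append(
            EnrichmentResult(
                term=t, query_label=query_label, k=k, n=n, K=K, N=N, p=p, q=1.0,
                enrichment_factor=factor,
                significant=(p < p_threshold and k >= min_overlap and factor >= min_factor),
                overlap_genes=frozenset(hits),
            )
        )
    if results:
        qvals = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                term=r.term, query_label=r.query_label, k=r.k, n=r.n, K=r.K, N=r.N,
                p=r.p, q=float(q), enrichment_factor=r.enrichment_factor,
                significant=r.significant, overlap_genes=r.overlap_genes,
            )
            for r, q in zip(results, qvals)
        ]
    return results


def term_similarity(
    term_a: GeneSetTerm | frozenset, term_b: GeneSetTerm | frozenset,
    reference_genes: Iterable[str],
) -> float:
    """Cohen's kappa between two terms' membership indicators over a reference.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the fraction of reference
    genes on which the two memberships agree and p_e the chance agreement
    from the marginal membership rates. Degenerate marginals (p_e = 1)
    give 1 for identical memberships, else 0.
    """
    ref = set(reference_genes)
    if not ref:
        raise DomainError("reference_genes must be non-empty")
    a = (term_a.members if isinstance(term_a, GeneSetTerm) else set(term_a)) & ref
    b = (term_b.members if isinstance(term_b, GeneSetTerm) else set(term_b)) & ref
    n = len(ref)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    p_o = (both + neither) / n
    pa, pb = len(a) / n, len(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return 1.0 if a == b else 0.0
    return (p_o - p_e) / (1 - p_e)


@dataclass
class TermCluster:
    """Similarity-linked group of enriched terms, named by its best member."""

    cluster_id: int
    members: tuple[GeneSetTerm, ...]
    representative: GeneSetTerm
    name: str
    best_p: float
    significant_for: frozenset[str] = frozenset()
    #: per query: count of that query's genes inside the cluster's terms
    gene_counts: dict[str, int] = field(default_factory=dict)
    #: count of genes inside the cluster's terms shared by both queries
    overlap_count: int = 0

    @property
    def shared(self) -> bool:
        return len(self.significant_for) >= 2

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(t.term_id for t in self.members)


def cluster_terms(
    significant_results: Sequence[EnrichmentResult],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    reference_genes: Iterable[str] | None = None,
) -> list[TermCluster]:
    """Single-linkage clusters of terms with pairwise similarity > threshold.

    Terms are linked when kappa > threshold; clusters are the connected
    components of that link graph (transitive closure). Each cluster takes
    the name of its member with the smallest enrichment p (across queries),
    ties broken by lexicographic term id. Reference genes default to the
    union of the significant terms' members.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    by_term: dict[str, GeneSetTerm] = {}
    best_p: dict[str, float] = {}
    for r in significant_results:
        by_term[r.term.term_id] = r.term
        best_p[r.term.term_id] = min(best_p.get(r.term.term_id, 1.0), r.p)
    if not by_term:
        return []
    if reference_genes is None:
        ref: set[str] = set()
        for t in by_term.values():
            ref |= t.members
    else:
        ref = set(reference_genes)

    ids = sorted(by_term)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if term_similarity(by_term[a], by_term[b], ref) > threshold:
                g.add_edge(a, b)

    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    clusters = []
    for comp in comps:
        rep_id = min(comp, key=lambda tid: (best_p[tid], tid))
        rep = by_term[rep_id]
        clusters.append(
            TermCluster(
                cluster_id=0,
                members=tuple(by_term[tid] for tid in comp),
                representative=rep,
                name=rep.name,
                best_p=best_p[rep_id],
            )
        )
    clusters.sort(key=lambda c: (c.best_p, c.representative.term_id))
    return [
        TermCluster(
            cluster_id=i + 1, members=c.members, representative=c.representative,
            name=c.name, best_p=c.best_p, significant_for=c.significant_for,
        )
        for i, c in enumerate(clusters)
    ]


def shared_clusters(
    clusters: Sequence[TermCluster],
    results_by_query: Mapping[str, Sequence[EnrichmentResult]],
) -> list[TermCluster]:
    """Flag clusters holding >= 1 significant term for each query."""
    if len(results_by_query) < 2:
        raise DomainError("shared_clusters needs results for two query labels")
    sig_terms: dict[str, set[str]] = {
        label: {r.term.term_id for r in results if r.significant}
        for label, results in results_by_query.items()
    }
    # per query and term: the query genes inside that term (k genes)
    hits: dict[str, dict[str, frozenset[str]]] = {
        label: {r.term.term_id: r.overlap_genes for r in results}
        for label, results in results_by_query.items()
    }
    out = []
    for c in clusters:
        member_ids = set(c.member_ids)
        flags = frozenset(
            label for label, terms in sig_terms.items() if member_ids & terms
        )
        genes_per_query: dict[str, set[str]] = {}
        for label, term_hits in hits.items():
            genes: set[str] = set()
            for tid in member_ids:
                genes |= term_hits.get(tid, frozenset())
            genes_per_query[label] = genes
        shared_genes: set[str] | None = None
        for genes in genes_per_query.values():
            shared_genes = genes if shared_genes is None else shared_genes & genes
        out.append(
            TermCluster(
                cluster_id=c.cluster_id, members=c.members,
                representative=c.representative, name=c.name, best_p=c.best_p,
                significant_for=flags,
                gene_counts={k: len(v) for k, v in sorted(genes_per_query.items())},
                overlap_count=len(shared_genes or set()),
            )
        )
    return out


class EnrichmentAnalysis:
    """Enrichment of one or more query gene lists with term clustering.

    Parameters
    ----------
    queries
        Mapping of query label -> gene set (e.g. per-disorder expanded lists).
    terms
        The annotation collection (from :func:`read_gmt`).
    background
        Background gene universe N; defaults to all genes appearing in the
        annotation collection. Supply e.g. all expressed genes to override.
    """

    def __init__(
        self,
        queries: Mapping[str, Iterable[str]],
        terms: Sequence[GeneSetTerm],
        background: Iterable[str] | None = None,
    ):
        self.queries = {label: set(genes) for label, genes in queries.items()}
        self.terms = list(terms)
        if background is None:
            bg: set[str] = set()
            for t in self.terms:
                bg |= t.members
            self.background = bg
        else:
            self.background = set(background)

    def fit(
        self,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
        min_factor: float = DEFAULT_MIN_FACTOR,
        similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    ) -> "EnrichmentResults":
        results_by_query = {
            label: enrich(
                genes, self.terms, self.background,
                p_threshold=p_threshold, min_overlap=min_overlap,
                min_factor=min_factor, query_label=label,
            )
            for label, genes in self.queries.items()
        }
        significant = [
            r for results in results_by_query.values() for r in results if r.significant
        ]
        clusters = cluster_terms(significant, threshold=similarity_threshold)
        if len(results_by_query) >= 2:
            clusters = shared_clusters(clusters, results_by_query)
        return EnrichmentResults(
            model=self,
            results_by_query=results_by_query,
            clusters=clusters,
            similarity_threshold=similarity_threshold,
        )


@dataclass
class EnrichmentResults:
    """Per-term enrichment results and the derived term clusters."""

    model: EnrichmentAnalysis
    results_by_query: dict[str, list[EnrichmentResult]]
    clusters: list[TermCluster]
    similarity_threshold: float = field(default=DEFAULT_SIMILARITY_THRESHOLD)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query": r.query_label,
                "term_id": r.term.term_id,
                "name": r.term.name,
                "source": r.term.source,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p": r.p, "q": r.q,
                "enrichment_factor": r.enrichment_factor,
                "significant": r.significant,
            }
            for label in sorted(self.results_by_query)
            for r in sorted(self.results_by_query[label], key=lambda x: (x.p, x.term.term_id))
        ]
        return pd.DataFrame(
            rows,
            columns=["query", "term_id", "name", "source", "k", "n", "K", "N",
                     "p", "q", "enrichment_factor", "significant"],
        )

    def cluster_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "name": c.name,
                "representative": c.representative.term_id,
                "best_p": c.best_p,
                "n_terms": len(c.members),
                "members": ",".join(c.member_ids),
                "significant_for": ",".join(sorted(c.significant_for)),
                "shared": c.shared,
                "gene_counts": ";".join(f"{k}={v}" for k, v in sorted(c.gene_counts.items())),
                "overlap_count": c.overlap_count,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster_id", "name", "representative", "best_p",
                     "n_terms", "members", "significant_for", "shared",
                     "gene_counts", "overlap_count"],
        )

    def term_network(self) -> nx.Graph:
        """Similarity graph of significant terms with per-query gene counts.

        Nodes carry per-query overlap counts (pie-chart semantics for
        Cytoscape import); edges link terms with similarity > threshold.
        """
        g = nx.Graph()
        by_term: dict[str, GeneSetTerm] = {}
        for label, results in self.results_by_query.items():
            for r in results:
                if r.significant:
                    by_term[r.term.term_id] = r.term
                    if not g.has_node(r.term.term_id):
                        g.add_node(r.term.term_id, name=r.term.name, source=r.term.source)
                    g.nodes[r.term.term_id][f"k_{label}"] = r.k
                    g.nodes[r.term.term_id][f"p_{label}"] = r.p
        ref: set[str] = set()
        for t in by_term.values():
            ref |= t.members
        ids = sorted(by_term)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                kappa = term_similarity(by_term[a], by_term[b], ref)
                if kappa > self.similarity_threshold:
                    g.add_edge(a, b, kappa=float(kappa))
        return g

    def summary(self) -> str:
        lines = ["Enrichment analysis", "=" * 42]
        for label in sorted(self.results_by_query):
            results = self.results_by_query[label]
            n_sig = sum(r.significant for r in results)
            lines.append(f"Query {label!r}: {len(results)} terms tested, {n_sig} significant")
        shared = [c for c in self.clusters if c.shared]
        lines.append(f"Clusters: {len(self.clusters)} ({len(shared)} shared)")
        for c in shared:
            lines.append(f"  shared cluster {c.cluster_id}: {c.name} (best p = {c.best_p:.3g})")
        return "\n".join(lines)
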