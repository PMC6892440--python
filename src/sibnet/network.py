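"""PPI connectivity, community structure, and gene-set enrichment of gene lists.

The reference interactome is a simple undirected :class:`networkx.Graph` of
gene symbols.  A candidate gene list is projected onto the graph; its
connectivity is scored by the induced edge count against a *within-degree*
permutation null (each listed gene is replaced by a random non-listed gene of
similar degree), communities are found by greedy modularity maximisation, and
each community is tested for overlap with curated gene sets by an exact
upper-tail hypergeometric test with Bonferroni correction over the sets
tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .burden import hypergeom_enrichment
from .genesets import GeneSetCollection

__all__ = [
    "induced_subgraph",
    "density",
    "detect_communities",
    "connectivity_permutation_p",
    "evaluate_communities",
    "community_enrichment",
    "jaccard",
    "curate_gene_sets",
    "CommunityResult",
    "PermutationResult",
]

logger = logging.getLogger(__name__)


def validate_ppi(graph: nx.Graph) -> nx.Graph:
    """Drop self-loops and assert the graph is simple and undirected."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("PPI network must be a simple undirected graph")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        logger.warning("removing %d self-loops from PPI network", len(loops))
        graph.remove_edges_from(loops)
    return graph


def induced_subgraph(network: nx.Graph, genes: Iterable[str]):
    """Subgraph induced by the listed genes present in the network.

    Returns ``(subgraph, unmatched)``; genes absent from the network are
    reported in ``unmatched`` rather than silently dropped.  An empty
    intersection yields an empty graph (with a logged warning).
    """
    genes = list(dict.fromkeys(genes))
    matched = [g for g in genes if g in network]
    unmatched = [g for g in genes if g not in network]
    if not matched:
        logger.warning("none of the %d listed genes are in the network", len(genes))
    return network.subgraph(matched).copy(), unmatched


def density(graph: nx.Graph) -> Optional[float]:
    """Edge count over possible edge count, n(n−1)/2; None for < 2 nodes."""
    n = graph.number_of_nodes()
    if n < 2:
        return None
    return graph.number_of_edges() / (n * (n - 1) / 2)


@dataclass
class CommunityResult:
    """Community assignments of a gene list on the PPI graph, with optional scores."""

    communities: Dict[int, Set[str]]
    densities: Dict[int, Optional[float]] = field(default_factory=dict)
    permutation_p: Dict[int, float] = field(default_factory=dict)
    overall_p: Optional[float] = None
    n_perm: int = 0
    seed: Optional[int] = None

    def membership(self) -> Dict[str, int]:
        return {g: cid for cid, members in self.communities.items() for g in members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "community": cid}
            for cid, members in self.communities.items()
            for g in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["gene", "community"])


def detect_communities(graph: nx.Graph, seed: int = 0) -> CommunityResult:
    """Partition a graph into communities by greedy modularity maximisation.

    Every node is assigned to exactly one community; isolated nodes become
    singletons.  Output ids are deterministic: communities are numbered by
    decreasing size, ties broken by smallest member symbol.  ``seed`` is
    accepted for interface uniformity; the greedy algorithm itself is
    deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities of an empty graph")
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    core = graph.subgraph([n for n in graph.nodes if graph.degree(n) > 0])
    if core.number_of_nodes() > 0:
        if core.number_of_edges() == core.number_of_nodes() * (core.number_of_nodes() - 1) / 2:
            parts = [set(core.nodes)]  # complete graph: one community
        else:
            parts = [set(c) for c in nx.community.greedy_modularity_communities(core)]
    else:
        parts = []
    parts.extend({n} for n in isolated)
    parts.sort(key=lambda s: (-len(s), min(s)))
    return CommunityResult(communities={i: members for i, members in enumerate(parts)}, seed=seed)


@dataclass
class PermutationResult:
    """Within-degree permutation test of gene-list connectivity."""

    p: float
    observed: float  # induced edge count of the listed genes
    null_mean: float
    n_perm: int
    seed: int


class _DegreeSampler:
    """Degree-binned replacement sampler over the nodes of a network.

    Bins are degree quantiles (default 10).  For a query gene list, each
    listed gene is replaced by a uniformly sampled *non-listed* node from the
    same bin, without replacement within a bin; bins with too few candidates
    are widened by merging neighbouring bins (logged).
    """

    def __init__(self, network: nx.Graph, degree_bins: int = 10, exact_degree: bool = False):
        self.nodes = np.array(list(network.nodes), dtype=object)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        deg = np.array([network.degree(n) for n in self.nodes])
        if exact_degree:
            _, self.bin_of = np.unique(deg, return_inverse=True)
        else:
            edges = np.unique(np.quantile(deg, np.linspace(0, 1, degree_bins + 1)))
            self.bin_of = np.clip(np.searchsorted(edges, deg, side="right") - 1, 0, len(edges) - 2)
        self.n_bins = int(self.bin_of.max()) + 1
        self.adj = nx.to_numpy_array(network, nodelist=list(self.nodes), dtype=bool)

    def edge_count(self, idx: np.ndarray) -> int:
        return int(self.adj[np.ix_(idx, idx)].sum()) // 2

    def plan(self, listed_idx: np.ndarray):
        """Precompute, per degree bin, the candidate pool and the number of draws."""
        listed_mask = np.zeros(len(self.nodes), dtype=bool)
        listed_mask[listed_idx] = True
        plan = []
        for b in range(self.n_bins):
            need = int(((self.bin_of == b) & listed_mask).sum())
            if need == 0:
                continue
            lo = hi = b
            cands = np.nonzero((self.bin_of == b) & ~listed_mask)[0]
            while len(cands) < need and (lo > 0 or hi < self.n_bins - 1):
                lo, hi = max(lo - 1, 0), min(hi + 1, self.n_bins - 1)
                cands = np.nonzero((self.bin_of >= lo) & (self.bin_of <= hi) & ~listed_mask)[0]
                logger.info("degree bin %d widened to [%d, %d] for %d replacements", b, lo, hi, need)
            plan.append((need, cands))
        return plan


def connectivity_permutation_p(
    network: nx.Graph,
    genes: Sequence[str],
    n_perm: int = 1000,
    degree_bins: int = 10,
    seed: int = 0,
    exact_degree: bool = False,
    sampler: Optional[_DegreeSampler] = None,
) -> PermutationResult:
    """Empirical connectivity significance of a gene list on the network.

    The observed statistic is the edge count of the induced subgraph.  Null
    replicates replace each listed gene with a random non-listed node drawn
    from the same degree bin; p = (1 + #{null ≥ observed}) / (1 + n_perm), so
    p is always positive and p = 1 whenever no replacement is possible (e.g.
    the list covers every node).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes_in = [g for g in dict.fromkeys(genes) if g in network]
    if not genes_in:
        raise ValueError("gene list does not intersect the network")
    s = sampler if sampler is not None else _DegreeSampler(network, degree_bins, exact_degree)
    listed_idx = np.array([s.index[g] for g in genes_in])
    observed = s.edge_count(listed_idx)
    plan = s.plan(listed_idx)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        parts = [
            cands[rng.choice(len(cands), size=need, replace=False)] if len(cands) >= need
            # degenerate bin with no candidates at all: keep the listed genes
            else np.concatenate([cands, listed_idx[: need - len(cands)]])
            for need, cands in plan
        ]
        idx = np.concatenate(parts) if parts else listed_idx
        null[i] = s.edge_count(idx)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        p=p, observed=float(observed), null_mean=float(null.mean()), n_perm=n_perm, seed=seed
    )


def evaluate_communities(
    network: nx.Graph,
    genes: Sequence[str],
    n_perm: int = 1000,
    degree_bins: int = 10,
    seed: int = 0,
) -> Tuple[CommunityResult, List[str]]:
    """Detect and score communities of a gene list against the reference network.

    Runs community detection on the induced subgraph, then computes each
    community's internal density and its within-degree permutation
    connectivity p, plus the whole-list connectivity p.  Returns the scored
    :class:`CommunityResult` and the list of genes absent from the network.
    """
    sub, unmatched = induced_subgraph(network, genes)
    if sub.number_of_nodes() == 0:
        return CommunityResult(communities={}, n_perm=n_perm, seed=seed), unmatched
    result = detect_communities(sub, seed=seed)
    sampler = _DegreeSampler(network, degree_bins)
    result.overall_p = connectivity_permutation_p(
        network, list(sub.nodes), n_perm=n_perm, seed=seed, sampler=sampler
    ).p
    for cid, members in result.communities.items():
        result.densities[cid] = density(sub.subgraph(members))
        result.permutation_p[cid] = connectivity_permutation_p(
            network, sorted(members), n_perm=n_perm, seed=seed + 1 + cid, sampler=sampler
        ).p
    result.n_perm = n_perm
    result.seed = seed
    return result, unmatched


def community_enrichment(
    communities: CommunityResult,
    sets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment of every community, Bonferroni-corrected.

    Each (community, set) pair gets an exact upper-tail hypergeometric p for
    the overlap within ``universe``; the Bonferroni factor is the number of
    gene sets tested.  Sets with members outside the universe are skipped with
    a log entry.  Rows are sorted by adjusted p.
    """
    universe = set(universe)
    usable = [(name, members) for name, members in sets if members <= universe]
    for name, members in sets:
        if not members <= universe:
            logger.warning(
                "gene set %s skipped: %d members outside the universe",
                name,
                len(members - universe),
            )
    m = len(usable)
    rows = []
    for cid, comm in communities.communities.items():
        comm_in = comm & universe
        if len(comm_in) < len(comm):
            raise ValueError(f"community {cid} has members outside the universe")
        for name, members in usable:
            res = hypergeom_enrichment(comm_in, members, universe)
            adj = min(1.0, res.p * m)
            rows.append(
                {
                    "community": cid,
                    "gene_set": name,
                    "overlap": res.k,
                    "community_size": res.n,
                    "set_size": res.K,
                    "p": res.p,
                    "p_bonferroni": adj,
                    "significant": adj < alpha,
                    "overlap_genes": ",".join(sorted(comm_in & members)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "community", "gene_set", "overlap", "community_size", "set_size",
            "p", "p_bonferroni", "significant", "overlap_genes",
        ],
    )
    return df.sort_values(["p_bonferroni", "p", "gene_set"], kind="mergesort").reset_index(drop=True)


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard similarity |A∩B| / |A∪B|; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(a | b)


def curate_gene_sets(sets: GeneSetCollection, max_jaccard: float = 0.5) -> GeneSetCollection:
    """Greedy redundancy filter over a gene-set collection.

    Sets are visited by decreasing size (name ascending on ties); a set is
    kept iff its Jaccard index with every already-kept set is ≤
    ``max_jaccard``.  Output order is deterministic.
    """
    order = sorted(sets.names(), key=lambda n: (-len(sets[n]), n))
    kept = GeneSetCollection()
    for name in order:
        members = sets[name]
        if all(jaccard(members, kept[k]) <= max_jaccard for k in kept.names()):
            kept.add(name, members, sets.descriptions.get(name, ""))
    return kept
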