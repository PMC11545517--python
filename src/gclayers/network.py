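"""Decomposable Gaussian graphical model over genes.

The network is learned in two steps: a maximum-likelihood spanning
forest (maximum-weight spanning tree on edge weights −(n/2)·log(1−r²),
with BIC-negative edges pruned), followed by a greedy forward search
that adds the chordality-preserving edge with the best BIC improvement
until no edge improves the score. The resulting graph is partitioned
into branches by edge-betweenness splitting; branches are annotated by
hypergeometric overrepresentation against user gene sets, and a
functional-node activity per sample is the mean expression of the
branch genes carrying the main annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "DecomposableGraph",
    "FunctionalNode",
    "is_decomposable",
    "gaussian_bic",
    "ml_spanning_tree",
    "forward_bic_search",
    "partition_branches",
    "enrich_branch",
    "node_activity",
    "build_functional_nodes",
]

log = logging.getLogger(__name__)


@dataclass
class DecomposableGraph:
    """Chordal graph over genes with per-edge BIC gains and total BIC."""

    graph: nx.Graph
    edge_gain: dict[tuple[str, str], float] = field(default_factory=dict)
    bic: float = float("nan")

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


@dataclass
class FunctionalNode:
    """A branch of the network labeled by its overrepresented function."""

    branch_id: int
    genes: list[str]
    main_function: str | None
    q_value: float | None
    activity: pd.Series  # per sample


# ---------------------------------------------------------------------------
# chordality


def is_decomposable(graph: nx.Graph) -> bool:
    """True iff the graph is chordal.

    Maximum cardinality search with the Tarjan–Yannakakis
    perfect-elimination-ordering check, applied per connected component.
    """
    for comp in nx.connected_components(graph):
        if not _mcs_component_chordal(graph, comp):
            return False
    return True


def _mcs_component_chordal(graph: nx.Graph, comp) -> bool:
    nodes = sorted(comp)
    if len(nodes) <= 2:
        return True
    weight = {v: 0 for v in nodes}
    numbered: dict[str, int] = {}
    order: list[str] = []
    unnumbered = set(nodes)
    for i in range(len(nodes)):
        # max weight, ties by lexicographic id for determinism
        v = min(unnumbered, key=lambda u: (-weight[u], u))
        numbered[v] = i
        order.append(v)
        unnumbered.discard(v)
        for u in graph[v]:
            if u in unnumbered:
                weight[u] += 1
    # PEO check on the reverse of the MCS order
    for v in order:
        prior = [u for u in graph[v] if u in numbered and numbered[u] < numbered[v]]
        if not prior:
            continue
        u = max(prior, key=lambda w: numbered[w])
        for w in prior:
            if w != u and not graph.has_edge(u, w):
                return False
    return True


# ---------------------------------------------------------------------------
# BIC machinery


def _cov(matrix) -> tuple[pd.DataFrame, int]:
    X = matrix.values.to_numpy()
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    S = (Xc @ Xc.T) / n  # ML covariance
    return pd.DataFrame(S, index=matrix.genes, columns=matrix.genes), n


def _logdet(S: pd.DataFrame, members) -> float:
    members = list(members)
    if not members:
        return 0.0
    sub = S.loc[members, members].to_numpy()
    sign, ld = np.linalg.slogdet(sub)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD clique covariance")
    return float(ld)


def _clique_separators(graph: nx.Graph):
    """Maximal cliques and separator multiset of a chordal graph, via a
    maximum-weight spanning tree of the clique-intersection graph."""
    cliques = [frozenset(c) for c in nx.chordal_graph_cliques(graph)]
    cg = nx.Graph()
    cg.add_nodes_from(range(len(cliques)))
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            w = len(cliques[i] & cliques[j])
            if w > 0:
                cg.add_edge(i, j, weight=w)
    jt = nx.maximum_spanning_tree(cg, weight="weight")
    separators = [cliques[i] & cliques[j] for i, j in jt.edges]
    return cliques, separators


def gaussian_bic(graph: nx.Graph, matrix) -> float:
    """From-scratch BIC of the decomposable Gaussian model on ``graph``.

    Maximized log-likelihood factorizes over cliques and separators of a
    junction tree; the parameter count is p means + p variances + one per
    edge.
    """
    if not is_decomposable(graph):
        raise ValueError("graph is not decomposable")
    S, n = _cov(matrix)
    p = len(graph.nodes)
    cliques, separators = _clique_separators(graph)
    ll = -(n / 2) * (p * math.log(2 * math.pi) + p)
    ll -= (n / 2) * (
        sum(_logdet(S, c) for c in cliques) - sum(_logdet(S, s) for s in separators)
    )
    k = 2 * p + graph.number_of_edges()
    return -2 * ll + k * math.log(n)


def _partial_corr(S: pd.DataFrame, u: str, v: str, sep) -> float:
    members = [u, v] + sorted(sep)
    sub = S.loc[members, members].to_numpy()
    omega = np.linalg.inv(sub)
    return float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))


# ---------------------------------------------------------------------------
# structure learning


def ml_spanning_tree(matrix) -> DecomposableGraph:
    """Maximum-likelihood spanning forest over genes.

    Edge weight between genes u, v is the likelihood gain
    −(n/2)·log(1−r²_uv); the maximum-weight spanning tree is computed and
    edges whose BIC change n·log(1−r²) + log n is non-negative are
    pruned, so weakly correlated parts of the tree fall apart into a
    forest.
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if matrix.n_missing:
        raise ValueError("ml_spanning_tree requires a complete matrix")
    X = matrix.values.to_numpy()
    n = X.shape[1]
    sds = X.std(axis=1)
    if (sds == 0).any():
        g = matrix.genes[int(np.argmax(sds == 0))]
        raise ValueError(f"gene {g!r} has zero variance")
    R = np.corrcoef(X)
    r2 = np.clip(R**2, 0.0, 1.0 - 1e-12)
    weight = -(n / 2) * np.log1p(-r2)
    np.fill_diagonal(weight, 0.0)
    # scipy MST minimizes; negate. Shift to keep zeros distinguishable.
    mst = minimum_spanning_tree(-(weight + 1.0)).tocoo()
    genes = matrix.genes
    g = nx.Graph()
    g.add_nodes_from(genes)
    gains: dict[tuple[str, str], float] = {}
    logn = math.log(n)
    for i, j in zip(mst.row, mst.col):
        dbic = n * math.log1p(-r2[i, j]) + logn
        if dbic < 0:
            e = tuple(sorted((genes[i], genes[j])))
            g.add_edge(*e)
            gains[e] = dbic
    dg = DecomposableGraph(graph=g, edge_gain=gains)
    dg.bic = gaussian_bic(g, matrix)
    return dg


def forward_bic_search(
    start: DecomposableGraph, matrix, max_added_edges: int | None = None
) -> DecomposableGraph:
    """Greedy forward edge search minimizing BIC among decomposable graphs.

    Candidate edges are the only ones that can keep a chordal graph
    chordal: non-adjacent pairs at distance 2 (a pair at distance ≥ 3
    would close a chordless cycle) and pairs in different components.
    Each candidate (u, v) is scored by ΔBIC = n·log(1−ρ²_{uv·S}) + log n,
    where S = N(u)∩N(v) (complete in a chordal graph, empty across
    components) and ρ is the partial correlation of u and v given S;
    candidates are tried best-first and accepted only if the graph stays
    chordal (full MCS re-check). The search stops when no edge improves
    the BIC or ``max_added_edges`` have been added.
    """
    if not is_decomposable(start.graph):
        raise ValueError("start graph is not decomposable")
    g = start.graph.copy()
    gains = dict(start.edge_gain)
    S, n = _cov(matrix)
    logn = math.log(n)
    added = 0
    bic = start.bic if not math.isnan(start.bic) else gaussian_bic(g, matrix)
    # pairs whose *marginal* correlation alone beats the BIC penalty;
    # only these can qualify as component-joining additions
    genes = list(S.index)
    sd = np.sqrt(np.diag(S.to_numpy()))
    R2 = np.clip((S.to_numpy() / np.outer(sd, sd)) ** 2, 0.0, 1.0 - 1e-12)
    dbic0 = n * np.log1p(-R2) + logn
    iu, ju = np.triu_indices(len(genes), k=1)
    strong = dbic0[iu, ju] < 0
    marginal_pairs = [
        (float(dbic0[i, j]), genes[i], genes[j])
        for i, j in zip(iu[strong], ju[strong])
    ]
    while max_added_edges is None or added < max_added_edges:
        candidates = []
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for v in comp:
                comp_of[v] = ci
        for u in g.nodes:
            nbrs_u = set(g[u])
            second = set()
            for w in nbrs_u:
                second |= set(g[w])
            for v in second - nbrs_u - {u}:
                if u < v:
                    sep = nbrs_u & set(g[v])
                    rho = _partial_corr(S, u, v, sep)
                    rho2 = min(rho**2, 1.0 - 1e-12)
                    dbic = n * math.log1p(-rho2) + logn
                    if dbic < 0:
                        candidates.append((dbic, u, v))
        # joining two components is always decomposability-preserving;
        # the separator is empty, so the marginal correlation applies
        candidates.extend(
            t for t in marginal_pairs if comp_of[t[1]] != comp_of[t[2]]
        )
        candidates.sort()
        accepted = False
        for dbic, u, v in candidates:
            g.add_edge(u, v)
            if is_decomposable(g):
                gains[(u, v)] = dbic
                bic += dbic
                added += 1
                accepted = True
                break
            g.remove_edge(u, v)
        if not accepted:
            break
    return DecomposableGraph(graph=g, edge_gain=gains, bic=bic)


# ---------------------------------------------------------------------------
# branches and functional nodes


def partition_branches(
    graph: nx.Graph,
    max_branch_size: int,
    min_branch_size: int = 1,
    n_branches: int | None = None,
) -> dict[str, int]:
    """Split the network into branches by removing high-betweenness edges.

    The highest-betweenness edge (ties by lexicographic edge id) is
    removed until every component has ≤ ``max_branch_size`` vertices —
    or, when ``n_branches`` is given, until at least that many components
    exist. Components smaller than ``min_branch_size`` are then merged
    into the neighbouring component (in the original graph) they share
    most edges with. Branch ids are 1..B ordered by smallest member id.
    """
    if min_branch_size > max_branch_size:
        raise ValueError("min_branch_size > max_branch_size")
    work = graph.copy()

    def done() -> bool:
        comps = list(nx.connected_components(work))
        if n_branches is not None:
            return len(comps) >= n_branches
        return all(len(c) <= max_branch_size for c in comps)

    while not done() and work.number_of_edges() > 0:
        btw = nx.edge_betweenness_centrality(work)
        # deterministic tie-break: among max betweenness, lexicographically
        # smallest sorted edge id
        top = max(btw.values())
        tied = sorted(tuple(sorted(e)) for e, b in btw.items() if b >= top - 1e-12)
        work.remove_edge(*tied[0])

    comps = [set(c) for c in nx.connected_components(work)]
    if n_branches is None and min_branch_size > 1:
        changed = True
        while changed and len(comps) > 1:
            changed = False
            comps.sort(key=lambda c: (len(c), min(c)))
            for c in comps:
                if len(c) >= min_branch_size:
                    continue
                # count original-graph edges to every other component
                counts = []
                for other in comps:
                    if other is c:
                        continue
                    k = sum(
                        1 for u in c for v in graph[u] if v in other
                    )
                    counts.append((k, -len(other), min(other), other))
                counts.sort(key=lambda t: (-t[0], t[2]))
                target = counts[0][3]
                target |= c
                comps.remove(c)
                changed = True
                break
    comps.sort(key=lambda c: min(c))
    assignment: dict[str, int] = {}
    for bid, c in enumerate(comps, start=1):
        for v in c:
            assignment[v] = bid
    return assignment


def enrich_branch(branch_genes, background, annotation: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric overrepresentation of annotation sets in a branch.

    p is the upper-tail hypergeometric probability of the observed
    overlap; q is the Benjamini–Hochberg adjustment across sets. Rows
    are ranked by (q, −overlap, name); the top row is the branch's main
    function.
    """
    if not annotation:
        raise ValueError("empty annotation")
    branch = set(branch_genes)
    bg = set(background)
    if not branch <= bg:
        raise ValueError("branch genes must be a subset of the background")
    M, N = len(bg), len(branch)
    rows = []
    for name in sorted(annotation):
        members = set(annotation[name]) & bg
        if not members:
            continue
        k = len(branch & members)
        n_set = len(members)
        p = float(hypergeom.sf(k - 1, M, n_set, N)) if k > 0 else 1.0
        fold = (k / N) / (n_set / M) if N and n_set else 0.0
        rows.append({"name": name, "overlap": k, "set_size": n_set, "fold": fold, "p": p})
    if not rows:
        raise ValueError("no annotation set intersects the background")
    df = pd.DataFrame(rows)
    df["q"] = false_discovery_control(df["p"].to_numpy(), method="bh")
    df = df.sort_values(["q", "overlap", "name"], ascending=[True, False, True])
    return df.reset_index(drop=True)


def node_activity(matrix, node_gene_sets: dict) -> pd.DataFrame:
    """Per-node, per-sample activity: unweighted mean expression of the
    node's member genes."""
    rows = {}
    for node, genes in node_gene_sets.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"node {node!r} has an empty gene set")
        rows[node] = matrix.subset_genes(genes).values.mean(axis=0)
    return pd.DataFrame(rows).T


def build_functional_nodes(
    matrix,
    branches: dict[str, int],
    annotation: dict[str, list[str]],
    q_threshold: float = 0.05,
    all_branch_genes: bool = False,
) -> list[FunctionalNode]:
    """Label every branch by its most overrepresented function and compute
    its activity.

    By default the activity averages only the branch genes annotated to
    the main function; ``all_branch_genes`` switches to the whole branch.
    Branches with no significant function keep a None label and use all
    branch genes.
    """
    background = sorted(branches)
    nodes = []
    for bid in sorted(set(branches.values())):
        genes = sorted(g for g, b in branches.items() if b == bid)
        table = enrich_branch(genes, background, annotation)
        top = table.iloc[0]
        main, q = (str(top["name"]), float(top["q"])) if top["q"] <= q_threshold else (None, None)
        if main is not None and not all_branch_genes:
            member = sorted(set(genes) & set(annotation[main]))
        else:
            member = genes
        act = node_activity(matrix, {bid: member}).loc[bid]
        nodes.append(
            FunctionalNode(
                branch_id=bid, genes=member, main_function=main, q_value=q, activity=act
            )
        )
    return nodes
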