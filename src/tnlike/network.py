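"""Gaussian graphical models over proteins and miRNAs.

Structure learning proceeds in two stages, both scored by the Bayesian
Information Criterion of the decomposable Gaussian model:

* **minimum-BIC forest** — a maximum-gain spanning forest (Kruskal),
  adding an edge only while it joins two components and its BIC gain
  ``n*ln(1 - r^2) + ln(n)`` is negative;
* **stepwise decomposable addition** — repeatedly add, among all absent
  edges that keep the graph chordal, the one with the most negative exact
  BIC change computed from the clique/separator determinant decomposition.

Connected components of the learned graph become *functional nodes*; a
node's activity in a sample is the mean z-scored expression of its member
proteins (miRNA members are excluded from the mean and instead correlated
against it).  Activity differences between sample classes are tested with
the Mann-Whitney U by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BicGraph",
    "FunctionalNode",
    "edge_bic_gain",
    "min_bic_forest",
    "stepw_add",
    "decomposable_bic",
    "split_functional_nodes",
    "node_activity",
    "compare_activity",
    "mirna_activity_correlation",
]


@dataclass
class BicGraph:
    """Undirected graph over features with per-edge BIC gains."""

    graph: nx.Graph
    n: int                       # sample size used for scoring

    @property
    def edges(self):
        return self.graph.edges

    @property
    def vertices(self):
        return self.graph.nodes

    def is_chordal(self) -> bool:
        return nx.is_chordal(self.graph)

    def total_gain(self) -> float:
        return sum(d["bic_gain"] for _, _, d in self.graph.edges(data=True))


@dataclass
class FunctionalNode:
    """A branch of the graphical model scored by mean protein expression."""

    node_id: str
    members: tuple
    label: str = "unannotated"
    activity: pd.Series | None = None


def edge_bic_gain(r: float, n: int) -> float:
    """BIC change from adding one edge with marginal correlation ``r`` to an
    empty pair: ``n*ln(1 - r^2) + ln(n)``.  Negative values improve BIC."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) >= 1:
        return -np.inf
    return n * math.log(1.0 - r * r) + math.log(n)


def _corr(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values: impute before network construction")
    return np.corrcoef(x)


def min_bic_forest(matrix: pd.DataFrame) -> BicGraph:
    """Maximum-gain spanning forest over the features of ``matrix``.

    Candidate edges are sorted by BIC gain ascending; Kruskal adds an edge
    iff it joins two components and its gain is negative.  The result
    minimises total BIC over all forests.
    """
    p, n = matrix.shape
    if p < 2:
        raise ValueError("need >= 2 features")
    corr = _corr(matrix)
    ids = list(matrix.index)

    cand = []
    for i in range(p):
        for j in range(i + 1, p):
            g = edge_bic_gain(corr[i, j], n)
            if g < 0:
                cand.append((g, i, j))
    cand.sort()

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    comp = list(range(p))  # union-find

    def find(a):
        while comp[a] != a:
            comp[a] = comp[comp[a]]
            a = comp[a]
        return a

    for g, i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            comp[ri] = rj
            graph.add_edge(ids[i], ids[j], bic_gain=g)
    return BicGraph(graph, n)


def _clique_separators(graph: nx.Graph):
    """Cliques and separators of a chordal graph via a max-weight clique tree."""
    cliques = [frozenset(c) for c in nx.chordal_graph_cliques(graph)]
    if len(cliques) <= 1:
        return cliques, []
    ct = nx.Graph()
    ct.add_nodes_from(range(len(cliques)))
    for a, b in itertools.combinations(range(len(cliques)), 2):
        w = len(cliques[a] & cliques[b])
        if w > 0:
            ct.add_edge(a, b, weight=w)
    tree = nx.maximum_spanning_tree(ct, weight="weight")
    seps = [cliques[a] & cliques[b] for a, b in tree.edges]
    return cliques, seps


def decomposable_bic(graph: nx.Graph, corr: pd.DataFrame, n: int) -> float:
    """Structure-dependent part of the BIC of a decomposable Gaussian model.

    ``n * (sum_cliques ln det R_C - sum_separators ln det R_S) + |E| ln n``
    where R is the sample correlation matrix.  Constant terms shared by all
    models on the same variables are dropped, so only differences matter.
    """
    if not nx.is_chordal(graph):
        raise ValueError("graph is not chordal")
    cliques, seps = _clique_separators(graph)

    def logdet(vs: frozenset) -> float:
        if len(vs) <= 1:
            return 0.0
        sub = corr.loc[list(vs), list(vs)].to_numpy()
        sign, ld = np.linalg.slogdet(sub)
        if sign <= 0:
            return -np.inf
        return ld

    ll = sum(logdet(c) for c in cliques) - sum(logdet(s) for s in seps)
    return n * ll + graph.number_of_edges() * math.log(n)


def stepw_add(bgraph: BicGraph, matrix: pd.DataFrame, max_edges: int | None = None) -> BicGraph:
    """Forward stepwise edge addition within the decomposable family.

    At each step the absent edge whose addition keeps the graph chordal and
    most decreases the exact decomposable-model BIC is added; stops when no
    addition decreases BIC or ``max_edges`` have been added.
    """
    graph = bgraph.graph.copy()
    if not nx.is_chordal(graph):
        raise ValueError("input graph must be chordal")
    n = bgraph.n
    corr = pd.DataFrame(_corr(matrix), index=matrix.index, columns=matrix.index)
    ids = list(matrix.index)
    added = 0
    current = decomposable_bic(graph, corr, n)
    while max_edges is None or added < max_edges:
        best = None
        for i, j in itertools.combinations(ids, 2):
            if graph.has_edge(i, j):
                continue
            graph.add_edge(i, j)
            if nx.is_chordal(graph):
                new = decomposable_bic(graph, corr, n)
                gain = new - current
                if gain < -1e-9 and (best is None or gain < best[0]):
                    best = (gain, i, j, new)
            graph.remove_edge(i, j)
        if best is None:
            break
        gain, i, j, current = best
        graph.add_edge(i, j, bic_gain=gain)
        added += 1
    return BicGraph(graph, n)


def split_functional_nodes(
    bgraph: BicGraph,
    max_size: int = 30,
    annotation: pd.Series | None = None,
) -> list[FunctionalNode]:
    """Partition the graph into functional nodes of at most ``max_size``.

    Components small enough are kept intact; larger ones are split by
    repeatedly removing the highest-betweenness edge (Girvan-Newman style)
    until every part fits.  A node's label is the majority annotation term
    among its members, or "unannotated".
    """
    graph = bgraph.graph.copy()
    parts = []
    stack = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    while stack:
        sub = stack.pop()
        if sub.number_of_nodes() <= max_size:
            parts.append(sorted(sub.nodes))
            continue
        while nx.is_connected(sub):
            bet = nx.edge_betweenness_centrality(sub)
            worst = max(bet, key=bet.get)
            sub.remove_edge(*worst)
        stack.extend(sub.subgraph(c).copy() for c in nx.connected_components(sub))
    parts.sort()

    nodes = []
    for k, members in enumerate(parts):
        label = "unannotated"
        if annotation is not None:
            terms = annotation.reindex(members).dropna()
            if len(terms):
                label = terms.mode().iloc[0]
        nodes.append(FunctionalNode(f"node{k:02d}", tuple(members), label))
    return nodes


def node_activity(
    node: FunctionalNode,
    matrix: pd.DataFrame,
    feature_kind: pd.Series | None = None,
) -> pd.Series:
    """Per-sample activity: mean expression of the node's protein members.

    miRNA members (per ``feature_kind``) are excluded; they are correlated
    against the activity instead of contributing to it.
    """
    members = [m for m in node.members if m in matrix.index]
    if feature_kind is not None:
        members = [m for m in members if feature_kind.get(m, "protein") == "protein"]
    if not members:
        raise ValueError(f"{node.node_id}: no protein members present in matrix")
    act = matrix.loc[members].mean(axis=0)
    act.name = node.node_id
    node.activity = act
    return act


def compare_activity(activity: pd.Series, labels, method: str = "mannwhitney"):
    """Two-class comparison of functional-node activity.

    Default Mann-Whitney U (two-sided); Welch t available via
    ``method="ttest"``.  Returns ``(statistic, p)``.
    """
    labels = pd.Series(np.asarray(labels), index=activity.index)
    levels = labels.unique()
    if len(levels) != 2:
        raise ValueError("exactly two labels required")
    a = activity[labels == levels[0]]
    b = activity[labels == levels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 samples")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def mirna_activity_correlation(mirna_row: pd.Series, activity: pd.Series):
    """Pearson correlation of a miRNA with a node activity, two-sided p."""
    common = mirna_row.index.intersection(activity.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    x, y = mirna_row[common], activity[common]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
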