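"""Comparison link-prediction scorers on the combined heterogeneous graph.

The combined graph is the union of the side-effect/drug bipartite graph
(weight 1 edges) and the drug-drug similarity graph (cosine weights), treated
as one undirected graph over the disjoint node sets. Neighborhoods N(x) are
binarized: y is a neighbor of x iff any positive-weight edge joins them.

Scorers: the four node-based proximity metrics (common neighbors, Jaccard,
Adamic/Adar, resource allocation), truncated Katz (walk counts attenuated by
beta^l), personalized PageRank (random walk with restart), and a seeded
random baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_io import BipartiteAdjacency, SimilarityGraph

logger = logging.getLogger(__name__)

NEIGHBORHOOD_METRICS = (
    "common_neighbors",
    "jaccard",
    "adamic_adar",
    "resource_allocation",
)


class CombinedGraph:
    """Union of the bipartite and similarity graphs, undirected.

    Node order is side effects first (biadjacency row order), then drugs
    (column order). ``adjacency(weighted=True)`` keeps cosine weights on
    drug-drug edges; the binarized form backs neighborhoods and the default
    Katz / PPR scorers.
    """

    def __init__(self, Y: BipartiteAdjacency, G: SimilarityGraph):
        if Y.col_labels != G.node_labels:
            raise ValueError("biadjacency columns and similarity nodes misaligned")
        overlap = set(Y.row_labels) & set(Y.col_labels)
        if overlap:
            raise ValueError(f"side-effect and drug label spaces overlap: {overlap}")
        self.side_effects = list(Y.row_labels)
        self.drugs = list(Y.col_labels)
        self.labels = self.side_effects + self.drugs
        self.index = {lab: k for k, lab in enumerate(self.labels)}
        m, n = Y.m, Y.n
        B = (Y.matrix > 0).astype(float)
        W = G.adjacency()
        self._adj_w = sp.bmat(
            [[sp.csr_matrix((m, m)), B], [B.T, W]], format="csr"
        )
        self._adj_b = (self._adj_w > 0).astype(float).tocsr()
        self._neighbors: list[set[int]] = [
            set(self._adj_b.indices[self._adj_b.indptr[k]:self._adj_b.indptr[k + 1]])
            for k in range(m + n)
        ]

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        return self._adj_w if weighted else self._adj_b

    def neighbors(self, label: str) -> set[str]:
        k = self._node(label)
        return {self.labels[j] for j in self._neighbors[k]}

    def degree(self, label: str) -> int:
        return len(self._neighbors[self._node(label)])

    def _node(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise KeyError(f"unknown node {label!r}") from None


@dataclass
class KatzParams:
    """Attenuation beta and truncation length for the Katz index.

    The geometric series over walk counts only converges when beta is below
    1 / (largest adjacency eigenvalue); beta * max_degree < 1 is a cheap
    sufficient proxy and we warn when it fails.
    """

    beta: float = 0.005
    l_max: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.beta < 1):
            raise ValueError("beta must be in (0, 1)")
        if self.l_max < 2:
            raise ValueError("l_max must be >= 2")


@dataclass
class PPRParams:
    restart: float = 0.15
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.restart < 1):
            raise ValueError("restart must be in (0, 1)")


def neighborhood_score(g: CombinedGraph, x: str, y: str, metric: str) -> float:
    """Node-based proximity between x and y from their shared neighbors.

    Adamic/Adar discounts each shared neighbor z by 1/ln|N(z)|; shared
    neighbors with |N(z)| <= 1 would divide by ln(1) = 0 and contribute 0
    (logged). Resource allocation uses 1/|N(z)|. All metrics are symmetric
    in x and y on this undirected graph.
    """
    if metric not in NEIGHBORHOOD_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    nx_, ny_ = g._neighbors[g._node(x)], g._neighbors[g._node(y)]
    common = nx_ & ny_
    if metric == "common_neighbors":
        return float(len(common))
    if metric == "jaccard":
        union = nx_ | ny_
        return len(common) / len(union) if union else 0.0
    total = 0.0
    for z in common:
        dz = len(g._neighbors[z])
        if metric == "adamic_adar":
            if dz <= 1:
                logger.warning("Adamic/Adar: shared neighbor %r has degree <= 1; "
                               "term skipped", g.labels[z])
                continue
            total += 1.0 / math.log(dz)
        else:  # resource_allocation
            total += 1.0 / dz
    return total


def katz_score(
    g: CombinedGraph,
    x: str,
    y: str,
    p: KatzParams = KatzParams(),
    weighted: bool = False,
) -> float:
    """Truncated Katz index: sum_{l=1}^{l_max} beta^l * (#walks x->y of length l).

    Walks (not simple paths) are counted, the standard Katz convention,
    via repeated sparse matrix-vector products from x's indicator vector.
    """
    A = g.adjacency(weighted=weighted)
    maxdeg = int((A > 0).sum(axis=1).max()) if g.n_nodes else 0
    if p.beta * maxdeg >= 1:
        logger.warning("katz: beta*max_degree = %.3f >= 1; series may diverge",
                       p.beta * maxdeg)
    ix, iy = g._node(x), g._node(y)
    v = np.zeros(g.n_nodes)
    v[ix] = 1.0
    score = 0.0
    for l in range(1, p.l_max + 1):
        v = A @ v
        score += p.beta ** l * v[iy]
    return float(score)


def ppr_scores(
    g: CombinedGraph,
    x: str,
    p: PPRParams = PPRParams(),
    weighted: bool = False,
) -> dict[str, float]:
    """Personalized PageRank from x: stationary distribution of a walk that
    restarts at x with probability ``restart`` and otherwise moves to a
    uniformly random neighbor.

    Solves pi = restart * e_x + (1 - restart) * P^T pi by power iteration to
    an infinity-norm change below ``tol``; dangling nodes send their mass
    back to x so that pi always sums to 1. Scores for all nodes are returned.
    """
    ix = g._node(x)
    A = g.adjacency(weighted=weighted)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if deg[ix] == 0:
        raise ValueError(f"node {x!r} is isolated; PPR undefined")
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    PT = (sp.diags(inv) @ A).T.tocsr()  # column-stochastic on non-dangling cols
    e_x = np.zeros(g.n_nodes)
    e_x[ix] = 1.0
    pi = e_x.copy()
    for _ in range(p.max_iter):
        dangling = pi[~nz].sum() if (~nz).any() else 0.0
        new = p.restart * e_x + (1 - p.restart) * (PT @ pi + dangling * e_x)
        delta = float(np.max(np.abs(new - pi)))
        pi = new
        if delta < p.tol:
            break
    else:
        raise RuntimeError(f"PPR did not converge in {p.max_iter} iterations "
                           f"(residual {delta:.2e})")
    return {lab: float(pi[k]) for k, lab in enumerate(g.labels)}


def random_score(
    pairs: list[tuple[str, str]],
    seed: int,
) -> dict[tuple[str, str], float]:
    """I.i.d. uniform(0, 1) scores per candidate pair, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return {pair: float(v) for pair, v in zip(pairs, rng.uniform(size=len(pairs)))}


# ---------------------------------------------------------------------------
# Vectorized full-matrix scorers (same definitions, computed for all
# (side effect, drug) pairs at once; cross-checked against the per-pair
# functions above in the test suite).
# ---------------------------------------------------------------------------

def neighborhood_score_matrix(g: CombinedGraph, metric: str) -> np.ndarray:
    """All-pairs (side effect, drug) scores for one neighborhood metric.

    For a side effect x, N(x) is a set of drugs; for a drug y, the drug part
    of N(y) comes from the similarity graph. Their intersection therefore
    lives among drugs, which reduces every metric to one sparse product.
    """
    if metric not in NEIGHBORHOOD_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    m = len(g.side_effects)
    n = len(g.drugs)
    A = g.adjacency()
    B = A[:m, m:]          # side effect x drug incidence
    Add = A[m:, m:]        # drug-drug binarized adjacency
    if metric == "common_neighbors":
        return np.asarray((B @ Add).todense())
    if metric == "jaccard":
        cn = np.asarray((B @ Add).todense())
        deg_x = np.asarray(A[:m].sum(axis=1)).ravel()
        deg_y = np.asarray(A[m:].sum(axis=1)).ravel()
        union = deg_x[:, None] + deg_y[None, :] - cn
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(union > 0, cn / np.maximum(union, 1e-300), 0.0)
        return out
    deg_drug = np.asarray(A[m:].sum(axis=1)).ravel()  # combined degree of drugs
    w = np.zeros(n)
    if metric == "adamic_adar":
        ok = deg_drug > 1
        w[ok] = 1.0 / np.log(deg_drug[ok])
    else:
        ok = deg_drug > 0
        w[ok] = 1.0 / deg_drug[ok]
    return np.asarray((B @ sp.diags(w) @ Add).todense())


def katz_score_matrix(
    g: CombinedGraph, p: KatzParams = KatzParams(), weighted: bool = False
) -> np.ndarray:
    """Truncated Katz scores for every (side effect, drug) pair."""
    m = len(g.side_effects)
    A = g.adjacency(weighted=weighted)
    block = A[:m].T  # n_nodes x m: walks ending at each side effect
    acc = np.zeros((g.n_nodes, m))
    V = np.asarray(block.todense())
    for l in range(1, p.l_max + 1):
        if l > 1:
            V = A @ V
        acc += p.beta ** l * V
    return acc[m:].T  # m x n


def ppr_score_matrix(
    g: CombinedGraph, p: PPRParams = PPRParams(), weighted: bool = False
) -> np.ndarray:
    """PPR scores for every (side effect, drug) pair: one personalized walk
    per side effect, restricted to the drug columns. Isolated side effects
    (no links in training) get all-zero rows."""
    m = len(g.side_effects)
    n = len(g.drugs)
    out = np.zeros((m, n))
    for i, se in enumerate(g.side_effects):
        if g.degree(se) == 0:
            continue
        pi = ppr_scores(g, se, p, weighted=weighted)
        out[i] = [pi[d] for d in g.drugs]
    return out
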