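"""Readers, writers and constructors for the two graphs and the score matrix.

The package works with two coupled graphs:

* a bipartite graph linking side effects (rows) to drugs (columns), stored as
  a sparse biadjacency matrix ``Y`` whose observed entries are 1.0;
* an undirected, weighted drug-drug similarity graph whose edge weights are
  cosine similarities between drug embeddings (or are read directly from an
  edge list).

Both are plain-text TSV formats; ``#`` lines are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


@dataclass
class BipartiteAdjacency:
    """Biadjacency matrix between side effects (rows) and drugs (columns).

    ``matrix`` holds 1.0 for every observed link before completion, and
    arbitrary nonnegative reals after NMF completion. Labels keep the
    first-appearance order of the source file.
    """

    row_labels: list[str]
    col_labels: list[str]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=float)
        m, n = self.matrix.shape
        if m != len(self.row_labels) or n != len(self.col_labels):
            raise ValueError("label counts do not match matrix shape")
        if len(set(self.row_labels)) != m or len(set(self.col_labels)) != n:
            raise ValueError("duplicate labels within a side")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("biadjacency entries must be nonnegative")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def nnz(self) -> int:
        return self.matrix.nnz

    def row_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.row_labels)}

    def col_index(self) -> dict[str, int]:
        return {lab: j for j, lab in enumerate(self.col_labels)}

    def observed_pairs(self) -> list[tuple[int, int]]:
        """Index pairs of nonzero cells, row-major order."""
        coo = self.matrix.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]],
        row_labels: list[str] | None = None,
        col_labels: list[str] | None = None,
    ) -> "BipartiteAdjacency":
        """Build a 0/1 biadjacency from (side effect, drug) label pairs.

        Duplicates collapse to a single entry. Label order is first-appearance
        order unless explicit label lists are given.
        """
        if row_labels is None:
            row_labels = list(dict.fromkeys(s for s, _ in pairs))
        if col_labels is None:
            col_labels = list(dict.fromkeys(d for _, d in pairs))
        ridx = {lab: i for i, lab in enumerate(row_labels)}
        cidx = {lab: j for j, lab in enumerate(col_labels)}
        rows = [ridx[s] for s, _ in pairs]
        cols = [cidx[d] for _, d in pairs]
        mat = sp.coo_matrix(
            (np.ones(len(pairs)), (rows, cols)),
            shape=(len(row_labels), len(col_labels)),
        ).tocsr()
        mat.data[:] = 1.0  # collapse duplicate pairs
        return cls(row_labels, col_labels, mat)


@dataclass
class SimilarityGraph:
    """Undirected weighted drug-drug graph.

    Edges are stored once per unordered pair with index keys ``(i, j), i < j``
    and strictly positive weights. ``tau`` flags nodes with at least one
    incident edge; isolated nodes are legal and stay index-aligned with the
    biadjacency columns.
    """

    node_labels: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("duplicate node labels")
        canon: dict[tuple[int, int], float] = {}
        for (i, j), w in self.edges.items():
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"edge ({i},{j}) has non-positive weight {w}")
            key = (min(i, j), max(i, j))
            if key in canon and canon[key] != w:
                raise ValueError(f"conflicting weights for edge {key}")
            canon[key] = float(w)
        self.edges = canon

    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        ii, jj, ww = [], [], []
        for (i, j), w in self.edges.items():
            ii += [i, j]
            jj += [j, i]
            ww += [w, w]
        return sp.coo_matrix((ww, (ii, jj)), shape=(self.n, self.n)).tocsr()

    def weighted_degree(self) -> np.ndarray:
        d = np.zeros(self.n)
        for (i, j), w in self.edges.items():
            d[i] += w
            d[j] += w
        return d

    def tau(self) -> np.ndarray:
        """1 for nodes with at least one incident edge, else 0."""
        return (self.weighted_degree() > 0).astype(float)

    def reindex(self, new_labels: list[str]) -> "SimilarityGraph":
        """Align the graph to a new node order (e.g. the biadjacency's drug
        order). Labels absent from the graph become isolated nodes; edges
        touching labels absent from ``new_labels`` are dropped."""
        pos = {lab: k for k, lab in enumerate(new_labels)}
        edges: dict[tuple[int, int], float] = {}
        for (i, j), w in self.edges.items():
            a = pos.get(self.node_labels[i])
            b = pos.get(self.node_labels[j])
            if a is None or b is None:
                continue
            edges[(min(a, b), max(a, b))] = w
        return SimilarityGraph(list(new_labels), edges)


@dataclass
class EmbeddingTable:
    """Token -> fixed-dimension real vector table (word2vec text format)."""

    vocab: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or len(self.vocab) != self.vectors.shape[0]:
            raise ValueError("vocab length does not match vector count")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("duplicate tokens in embedding vocabulary")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ScoreMatrix:
    """Predicted (side effect, drug) association scores with provenance."""

    row_labels: list[str]
    col_labels: list[str]
    scores: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("score shape inconsistent with labels")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def _iter_data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_bipartite_edges(path) -> BipartiteAdjacency:
    """Read a ``side_effect<TAB>drug`` edge list into a 0/1 biadjacency.

    Duplicate pairs collapse silently; label order is first-appearance order.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2 or not all(f.strip() for f in fields):
            raise ParseError(f"{path}:{lineno}: expected 2 non-empty fields, got {line!r}")
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValueError("empty bipartite graph")
    return BipartiteAdjacency.from_pairs(pairs)


def read_similarity_edges(path) -> SimilarityGraph:
    """Read a ``drug<TAB>drug<TAB>weight`` edge list into a SimilarityGraph.

    Both orientations of a pair may appear if their weights agree; self-loops
    and non-positive weights are dropped (counts logged). Every label seen on
    any line becomes a node, so drugs that lose all edges remain isolated.
    """
    labels: list[str] = []
    pos: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}
    n_dropped_nonpos = 0
    n_dropped_loops = 0
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3 or not all(f.strip() for f in fields[:2]):
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {line!r}")
        a, b = fields[0].strip(), fields[1].strip()
        try:
            w = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
        if not np.isfinite(w):
            raise ParseError(f"{path}:{lineno}: non-finite weight {w}")
        for lab in (a, b):
            if lab not in pos:
                pos[lab] = len(labels)
                labels.append(lab)
        if a == b:
            n_dropped_loops += 1
            continue
        if w <= 0:
            n_dropped_nonpos += 1
            continue
        i, j = pos[a], pos[b]
        key = (min(i, j), max(i, j))
        if key in edges and edges[key] != w:
            raise ValueError(
                f"{path}:{lineno}: conflicting weights for edge {a}-{b}: "
                f"{edges[key]} vs {w}"
            )
        edges[key] = w
    if n_dropped_nonpos:
        logger.info("dropped %d non-positive-weight edges", n_dropped_nonpos)
    if n_dropped_loops:
        logger.info("dropped %d self-loops", n_dropped_loops)
    return SimilarityGraph(labels, edges)


def read_word2vec_text(path) -> EmbeddingTable:
    """Parse word2vec *text* format: header ``count dim``, then one
    ``token v1 ... vdim`` line per token (space-separated)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}:1: expected header 'count dim'")
        count, dim = int(header[0]), int(header[1])
        vocab: list[str] = []
        vecs = np.empty((count, dim))
        for k in range(count):
            parts = fh.readline().split()
            if len(parts) != dim + 1:
                raise ParseError(f"{path}:{k + 2}: expected token + {dim} values")
            vocab.append(parts[0])
            vecs[k] = [float(v) for v in parts[1:]]
    return EmbeddingTable(vocab, vecs)


def build_similarity_from_embeddings(
    emb: EmbeddingTable,
    drugs: list[str],
    threshold: float = 0.0,
) -> SimilarityGraph:
    """Drug-drug similarity graph from embedding cosine similarities.

    An edge (i, j) exists iff cosine(v_i, v_j) > ``threshold``; the weight is
    the cosine itself. The default threshold 0 keeps every positive similarity
    while negative cosines never create an edge (the heat matrix requires
    nonnegative conductance). Drug labels are matched to tokens
    case-insensitively after trimming; unmatched drugs stay as isolated nodes
    so the graph remains index-aligned with the biadjacency columns.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    lookup = {tok.strip().lower(): k for k, tok in enumerate(emb.vocab)}
    idx_of: dict[int, int] = {}  # drug position -> embedding row
    missing = []
    for p, lab in enumerate(drugs):
        k = lookup.get(lab.strip().lower())
        if k is None:
            missing.append(lab)
        else:
            idx_of[p] = k
    if missing:
        logger.warning("%d drugs missing from embedding vocab: %s",
                       len(missing), missing[:10])
    if len(idx_of) < 2:
        raise ValueError("fewer than 2 drugs resolvable in the embedding")
    rows = np.array(sorted(idx_of))
    V = emb.vectors[[idx_of[p] for p in rows]]
    norms = np.linalg.norm(V, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"zero-norm vector for token {emb.vocab[idx_of[rows[zero[0]]]]!r}")
    U = V / norms[:, None]
    C = U @ U.T
    edges: dict[tuple[int, int], float] = {}
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            if C[a, b] > threshold:
                edges[(int(rows[a]), int(rows[b]))] = float(C[a, b])
    return SimilarityGraph(list(drugs), edges)


def write_predictions(scores: ScoreMatrix, k_top: int, path) -> None:
    """Write the top-``k_top`` drugs per side effect as a TSV.

    Columns: side_effect, drug, score, rank. Rows are sorted by descending
    score with ties broken by ascending drug label, so output is
    deterministic and round-trips exactly through :func:`read_predictions`.
    """
    if k_top < 1:
        raise ValueError("k_top must be >= 1")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# side_effect\tdrug\tscore\trank\n")
        for i, se in enumerate(scores.row_labels):
            order = sorted(
                range(len(scores.col_labels)),
                key=lambda j: (-scores.scores[i, j], scores.col_labels[j]),
            )
            for rank, j in enumerate(order[:k_top], start=1):
                fh.write(f"{se}\t{scores.col_labels[j]}\t"
                         f"{float(scores.scores[i, j])!r}\t{rank}\n")


def read_predictions(path) -> list[tuple[str, str, float, int]]:
    """Read a predictions TSV back as (side_effect, drug, score, rank) rows."""
    out = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields")
        out.append((fields[0], fields[1], float(fields[2]), int(fields[3])))
    return out
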