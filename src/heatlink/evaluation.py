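"""Evaluation machinery: stratified link folds, AUPR, method comparison with
paired t-tests, the degree-preserving permutation null, and the
training-fraction robustness sweep.

AUPR (area under the precision-recall curve) is the ranking metric
throughout: with ~1-2% of (side effect, drug) cells positive, precision at
high recall is the quantity of interest and ROC curves would saturate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .diffusion import DiffusionParams, build_heat_matrix
from .graph_io import BipartiteAdjacency, SimilarityGraph
from .nmf import NMFConfig, factorize


@dataclass
class FoldSplit:
    """Partition of the observed links into k folds, stratified per side
    effect: each row's links spread as evenly as possible over folds, so
    every training matrix keeps about (k-1)/k of every row's links."""

    k: int
    assignments: dict[tuple[int, int], int]
    seed: int

    def fold_links(self, f: int) -> list[tuple[int, int]]:
        return sorted(p for p, g in self.assignments.items() if g == f)


@dataclass
class PRcurve:
    """Precision-recall points (one per distinct score threshold) and the
    trapezoidal area under them."""

    recall: np.ndarray
    precision: np.ndarray
    aupr: float


@dataclass
class PermutationResult:
    pairs: list[tuple[str, str]]
    actual: np.ndarray
    omega: np.ndarray
    N: int

    @property
    def pvalues(self) -> np.ndarray:
        return self.omega / self.N


@dataclass
class ComparisonReport:
    """Per-fold AUPR per method, in method order; folds are comparable
    across methods because every method scores the same candidate pools."""

    method_names: list[str]
    per_fold: list[np.ndarray] = field(default_factory=list)

    def fold_aupr(self, name: str) -> np.ndarray:
        return self.per_fold[self.method_names.index(name)]

    def mean(self, name: str) -> float:
        return float(np.mean(self.fold_aupr(name)))

    def sd(self, name: str) -> float:
        return float(np.std(self.fold_aupr(name), ddof=1))

    def ttest(self, a: str, b: str) -> tuple[float, float]:
        return paired_ttest(self.fold_aupr(a), self.fold_aupr(b))


def split_folds(Y: BipartiteAdjacency, k: int, seed: int) -> FoldSplit:
    """Assign every observed link to one of k folds, stratified per row.

    Within each side effect's links the fold labels are dealt round-robin
    from a random offset after a random shuffle, so per-row fold sizes
    differ by at most one. Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    obs = Y.observed_pairs()
    if k > len(obs):
        raise ValueError(f"k={k} exceeds number of observed links {len(obs)}")
    rows: dict[int, list[tuple[int, int]]] = {}
    for i, j in obs:
        rows.setdefault(i, []).append((i, j))
    if len(rows) < Y.m:
        missing = sorted(set(range(Y.m)) - set(rows))
        raise ValueError(f"side effects without links: rows {missing[:5]}")
    rng = np.random.default_rng(seed)
    assignments: dict[tuple[int, int], int] = {}
    for i in sorted(rows):
        links = rows[i]
        rng.shuffle(links)
        offset = int(rng.integers(k))
        for t, pair in enumerate(links):
            assignments[pair] = (offset + t) % k
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def aupr(scores, labels) -> PRcurve:
    """Area under the precision-recall curve by the trapezoidal rule.

    Items are ranked by descending score; tied scores form a single
    threshold step (the whole tie group enters the ranking at once). One
    (recall, precision) point is emitted per distinct threshold; if the
    first point already has positive recall, the curve is anchored at
    (0, precision of that first point) before integrating over recall.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    P = int((y == 1).sum())
    Nn = int((y == 0).sum())
    if P == 0 or Nn == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = (y[order] == 1).astype(int)
    # last index of each tie group == threshold steps
    distinct = np.nonzero(np.diff(s_sorted))[0]
    steps = np.append(distinct, len(s_sorted) - 1)
    tp = np.cumsum(y_sorted)[steps]
    npred = steps + 1
    recall = tp / P
    precision = tp / npred
    if recall[0] > 0:
        recall = np.insert(recall, 0, 0.0)
        precision = np.insert(precision, 0, precision[0])
    area = float(np.trapezoid(precision, recall))
    return PRcurve(recall=recall, precision=precision, aupr=area)


def candidate_pools(
    Y: BipartiteAdjacency,
    train_links: set[tuple[int, int]],
    test_links: set[tuple[int, int]],
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Candidate (row, col) pairs and 0/1 labels for one evaluation round.

    Per side effect, every drug without a training link is a candidate;
    positives are the held-out test links, negatives the never-observed
    cells. Links held out but not under test (other folds) are excluded.
    """
    observed = set(Y.observed_pairs())
    cands: list[tuple[int, int]] = []
    labels: list[int] = []
    for i in range(Y.m):
        for j in range(Y.n):
            p = (i, j)
            if p in train_links:
                continue
            if p in test_links:
                cands.append(p)
                labels.append(1)
            elif p not in observed:
                cands.append(p)
                labels.append(0)
    return cands, np.asarray(labels)


def mask_links(Y: BipartiteAdjacency, remove: set[tuple[int, int]]) -> BipartiteAdjacency:
    """Copy of Y with the given links zeroed (the training matrix)."""
    Yd = Y.toarray()
    for i, j in remove:
        Yd[i, j] = 0.0
    return BipartiteAdjacency(Y.row_labels, Y.col_labels, Yd)


def cross_validate(
    Y: BipartiteAdjacency,
    G: SimilarityGraph,
    methods,
    split: FoldSplit,
) -> ComparisonReport:
    """k-fold link-level cross-validation of every scorer.

    Per fold: each method trains on Y minus the fold's links and scores the
    fold's candidate pool; the pooled AUPR over all side effects gives one
    number per (method, fold). Scorer seeds are derived from the split seed
    and the fold index only, so listing a method twice reproduces identical
    per-fold AUPR vectors.
    """
    observed = set(Y.observed_pairs())
    names = [m.name for m in methods]
    per_fold = [np.empty(split.k) for _ in methods]
    for f in range(split.k):
        test = set(split.fold_links(f))
        train = observed - test
        Ytr = mask_links(Y, test)
        if Ytr.nnz == 0:
            raise ValueError(f"fold {f} leaves an all-zero training matrix")
        cands, labels = candidate_pools(Y, train, test)
        fold_seed = (split.seed * 1009 + f) % (2**31)
        for t, method in enumerate(methods):
            sm = method(Ytr, G, fold_seed)
            scores = sm.scores[tuple(np.array(cands).T)]
            per_fold[t][f] = aupr(scores, labels).aupr
    return ComparisonReport(method_names=names, per_fold=per_fold)


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-fold AUPR vectors, df = k - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("degenerate t-test: all paired differences identical")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def degree_preserving_randomize(
    G: SimilarityGraph,
    seed: int,
    n_swaps: int | None = None,
) -> SimilarityGraph:
    """Rewire the similarity graph by double edge swaps.

    Each attempt picks two distinct edges (a-b, c-d) and proposes (a-d, c-b);
    the swap is applied unless it would create a self-loop or a multi-edge.
    Each weight travels with its rewired edge (first picked weight to the
    first new edge). The unweighted degree of every node is invariant.
    ``n_swaps`` attempts are made (default 10 |E|). A graph with fewer than
    2 edges has no legal swap and is returned unchanged.
    """
    edges = list(G.edges.items())
    if len(edges) < 2:
        return SimilarityGraph(list(G.node_labels), dict(G.edges))
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    pairs = [list(e) for e, _ in edges]
    weights = [w for _, w in edges]
    present = {tuple(sorted(p)) for p in pairs}
    for _ in range(n_swaps):
        e1, e2 = rng.choice(len(pairs), size=2, replace=False)
        a, b = pairs[e1]
        c, d = pairs[e2]
        if rng.integers(2):  # randomize orientation of the second edge
            c, d = d, c
        new1, new2 = (a, d), (c, b)
        if a == d or c == b:
            continue
        k1, k2 = tuple(sorted(new1)), tuple(sorted(new2))
        if k1 == k2 or k1 in present or k2 in present:
            continue
        present.discard(tuple(sorted(pairs[e1])))
        present.discard(tuple(sorted(pairs[e2])))
        pairs[e1] = list(new1)
        pairs[e2] = list(new2)
        present.add(k1)
        present.add(k2)
    out = {tuple(sorted(p)): w for p, w in zip(pairs, weights)}
    return SimilarityGraph(list(G.node_labels), out)


def permutation_pvalues(
    Y_train: BipartiteAdjacency,
    G: SimilarityGraph,
    test_pairs: list[tuple[str, str]],
    N: int,
    seed: int,
    nmf: NMFConfig | None = None,
    diffusion: DiffusionParams | None = None,
) -> PermutationResult:
    """Permutation significance of the diffusion scores of test pairs.

    The NMF seed matrix is fit once on the training data; the actual score
    of every test pair comes from diffusing those seeds over G. Then N
    times, G is degree-preservingly randomized and the *same* seeds are
    rediffused; Omega counts, per pair, how many randomized scores strictly
    exceed the actual one (ties do not count), giving p = Omega / N.
    Large p means the pair's score is matched by random wiring — a weak link.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    nmf = nmf or NMFConfig(rank=3)
    diffusion = diffusion or DiffusionParams()
    fp = factorize(Y_train, replace(nmf, seed=seed))
    seeds_matrix = fp.S @ fp.D.T  # m x n, rows = f(0) vectors

    ridx = Y_train.row_index()
    cidx = Y_train.col_index()
    rows = np.array([ridx[s] for s, _ in test_pairs])
    cols = np.array([cidx[d] for _, d in test_pairs])
    need_rows = np.unique(rows)

    def diffuse_rows(graph: SimilarityGraph) -> np.ndarray:
        Hm = build_heat_matrix(graph)
        T = seeds_matrix[need_rows].T.copy()
        step = diffusion.alpha / diffusion.M
        for _ in range(diffusion.M):
            T = T + step * (Hm.H @ T)
        return T.T  # len(need_rows) x n

    row_pos = {r: t for t, r in enumerate(need_rows)}
    F = diffuse_rows(G)
    actual = F[[row_pos[r] for r in rows], cols]

    omega = np.zeros(len(test_pairs), dtype=int)
    for b in range(N):
        Gr = degree_preserving_randomize(G, seed=(seed * 7919 + b) % (2**31))
        Fr = diffuse_rows(Gr)
        rand = Fr[[row_pos[r] for r in rows], cols]
        omega += (rand > actual).astype(int)
    return PermutationResult(pairs=list(test_pairs), actual=actual,
                             omega=omega, N=N)


def training_fraction_sweep(
    Y: BipartiteAdjacency,
    G: SimilarityGraph,
    fractions: list[float],
    repeats: int,
    seed: int,
    scorer=None,
) -> dict[float, float]:
    """Mean test AUPR as a function of the training fraction of links.

    For each fraction f, a random f of the observed links is kept for
    training and the rest is held out for testing; the mean over ``repeats``
    resamples is reported. Mirrors a robustness sweep from 10% to 90%
    training data.
    """
    from .pipeline import NMFDiffusionScorer

    scorer = scorer or NMFDiffusionScorer()
    observed = Y.observed_pairs()
    out: dict[float, float] = {}
    for fi, frac in enumerate(fractions):
        if not (0 < frac < 1):
            raise ValueError(f"fraction {frac} outside (0, 1)")
        n_train = int(round(frac * len(observed)))
        if n_train == 0:
            raise ValueError(f"fraction {frac} leaves zero training links")
        if n_train == len(observed):
            raise ValueError(f"fraction {frac} leaves zero test links")
        vals = []
        for rep in range(repeats):
            rng = np.random.default_rng((seed * 6007 + fi * 101 + rep) % (2**31))
            idx = rng.permutation(len(observed))
            train = {observed[i] for i in idx[:n_train]}
            test = {observed[i] for i in idx[n_train:]}
            Ytr = mask_links(Y, test)
            cands, labels = candidate_pools(Y, train, test)
            sm = scorer(Ytr, G, int(rng.integers(2**31)))
            scores = sm.scores[tuple(np.array(cands).T)]
            vals.append(aupr(scores, labels).aupr)
        out[frac] = float(np.mean(vals))
    return out
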