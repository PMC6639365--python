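"""Nonnegative matrix factorization completion of the biadjacency matrix.

The 0/1 side-effect x drug matrix Y is approximated as Y ~ S D^T with
S (m x r) and D (n x r) elementwise nonnegative, by minimising the squared
Frobenius error ||Y - S D^T||_F^2 with Lee-Seung multiplicative updates.
The reconstruction S D^T replaces Y wholesale: every cell, observed or not,
receives a real-valued association score, and each reconstructed row later
seeds one heat-diffusion run over the drug similarity graph.

Zeros of Y are treated as weak observed zeros (plain NMF over the full
matrix), not as missing cells, so sparsity itself carries signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import BipartiteAdjacency

#: floating-point slack allowed when asserting the monotone objective trace
TRACE_SLACK = 1e-10


@dataclass
class NMFConfig:
    rank: int = 10
    max_iter: int = 500
    rel_tol: float = 1e-6
    epsilon: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0 or self.epsilon <= 0:
            raise ValueError("rel_tol and epsilon must be positive")


@dataclass
class FactorPair:
    """Factors of Y ~ S D^T with fit diagnostics.

    ``objective_trace[t]`` is ||Y - S D^T||_F^2 after t full update sweeps
    (index 0 is the initialization); multiplicative updates make it
    non-increasing up to floating-point slack.
    """

    S: np.ndarray
    D: np.ndarray
    rank: int
    objective_trace: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.S < 0) or np.any(self.D < 0):
            raise ValueError("factors must be nonnegative")
        if self.S.shape[1] != self.rank or self.D.shape[1] != self.rank:
            raise ValueError("factor widths do not match rank")


def _objective(Y: np.ndarray, S: np.ndarray, D: np.ndarray) -> float:
    R = Y - S @ D.T
    return float(np.sum(R * R))


def factorize(Y: BipartiteAdjacency, cfg: NMFConfig) -> FactorPair:
    """Fit Y ~ S D^T by multiplicative updates from a seeded uniform start.

    Initial entries are uniform(0, 1) scaled by sqrt(mean(Y)/r) so the
    initial product matches Y's scale. Stops at ``max_iter`` sweeps or when
    the relative objective decrease falls below ``rel_tol``. Deterministic
    for a fixed seed.
    """
    m, n = Y.m, Y.n
    r = cfg.rank
    if not (1 <= r <= min(m, n)):
        raise ValueError(f"rank {r} out of range [1, {min(m, n)}]")
    Yd = Y.toarray()
    if Y.nnz == 0:
        raise ValueError("cannot factorize an all-zero matrix")

    rng = np.random.default_rng(cfg.seed)
    scale = np.sqrt(Yd.mean() / r)
    S = rng.uniform(size=(m, r)) * scale
    D = rng.uniform(size=(n, r)) * scale

    eps = cfg.epsilon
    trace = [_objective(Yd, S, D)]
    for _ in range(cfg.max_iter):
        S *= (Yd @ D) / (S @ (D.T @ D) + eps)
        D *= (Yd.T @ S) / (D @ (S.T @ S) + eps)
        obj = _objective(Yd, S, D)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < cfg.rel_tol:
            break
    return FactorPair(S=S, D=D, rank=r, objective_trace=trace, seed=cfg.seed)


def complete(
    fp: FactorPair,
    row_labels: list[str],
    col_labels: list[str],
) -> BipartiteAdjacency:
    """Reconstruct the full matrix: y_hat_ij = s_i . d_j for every cell.

    Observed cells are replaced by their reconstructed scores too — the
    completed matrix supersedes the 0/1 matrix as the diffusion seed source.
    """
    if fp.S.shape[0] != len(row_labels) or fp.D.shape[0] != len(col_labels):
        raise ValueError("factor shapes do not match labels")
    return BipartiteAdjacency(list(row_labels), list(col_labels), fp.S @ fp.D.T)


def select_rank(
    Y: BipartiteAdjacency,
    candidate_ranks: list[int],
    inner_folds: int,
    cfg: NMFConfig,
    restarts: int = 5,
    tie_tol: float = 0.01,
) -> int:
    """Choose the NMF rank by edge-masking cross-validation within Y.

    Observed entries are partitioned into ``inner_folds`` groups; for each
    group the factorization is fit on the remaining entries (held-out cells
    zeroed) and the held-out links are scored against an equal-count sample
    of never-observed cells by AUPR. Each inner fit takes the best of
    ``restarts`` seeded random initializations by final objective —
    multiplicative updates are local-optimum prone on structured matrices,
    and a single bad fit at the true rank would masquerade as evidence for
    a larger one.

    Held-out AUPR plateaus at and above the sufficient rank, so the strict
    argmax wanders over the plateau by CV noise; ranks whose mean AUPR is
    within ``tie_tol`` of the best are therefore treated as tied and the
    smallest tied rank wins (a one-standard-error-style parsimony rule).
    Only the training matrix should be passed here — the outer evaluation's
    test links must not leak in.
    """
    from .evaluation import aupr  # deferred: evaluation imports this module's sibling

    ranks = sorted(set(candidate_ranks))
    if not ranks:
        raise ValueError("candidate_ranks is empty")
    for r in ranks:
        if not (1 <= r <= min(Y.m, Y.n)):
            raise ValueError(f"candidate rank {r} out of range [1, {min(Y.m, Y.n)}]")
    if inner_folds < 2:
        raise ValueError("inner_folds must be >= 2")
    if len(ranks) == 1:
        return ranks[0]

    rng = np.random.default_rng(cfg.seed)
    obs = Y.observed_pairs()
    if len(obs) < inner_folds:
        raise ValueError("fewer observed links than inner folds")
    perm = rng.permutation(len(obs))
    fold_of = perm % inner_folds

    Yd = Y.toarray()
    zero_cells = np.argwhere(Yd == 0)

    mean_aupr = {}
    fold_scores: dict[int, list[float]] = {r: [] for r in ranks}
    for f in range(inner_folds):
        held = [obs[i] for i in np.where(fold_of == f)[0]]
        if not held:
            continue
        Ytr = Yd.copy()
        for i, j in held:
            Ytr[i, j] = 0.0
        Ytr_adj = BipartiteAdjacency(Y.row_labels, Y.col_labels, Ytr)
        neg_idx = rng.choice(len(zero_cells), size=min(len(held), len(zero_cells)),
                             replace=False)
        negs = [tuple(zero_cells[i]) for i in neg_idx]
        for r in ranks:
            fits = [
                factorize(Ytr_adj, NMFConfig(rank=r, max_iter=cfg.max_iter,
                                             rel_tol=cfg.rel_tol,
                                             epsilon=cfg.epsilon,
                                             seed=cfg.seed + 101 * t))
                for t in range(restarts)
            ]
            fp = min(fits, key=lambda f_: f_.objective_trace[-1])
            Yhat = fp.S @ fp.D.T
            scores = [Yhat[i, j] for i, j in held] + [Yhat[i, j] for i, j in negs]
            labels = [1] * len(held) + [0] * len(negs)
            fold_scores[r].append(aupr(scores, labels).aupr)
    for r in ranks:
        mean_aupr[r] = float(np.mean(fold_scores[r]))
    best = max(mean_aupr.values())
    return min(r for r in ranks if mean_aupr[r] >= best - tie_tol)
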