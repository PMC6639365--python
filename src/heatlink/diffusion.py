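"""Heat diffusion on the drug-drug similarity graph.

Association weight ("heat") placed on drugs by a side effect is transported
along similarity edges by the kernel e^{alpha H}, where H is the heat matrix
of the undirected weighted graph:

    H_ij = w_ji / d_j          for an edge (v_j, v_i), d_j the weighted degree,
    H_ii = -tau_i              (tau_i = 1 iff node i has an incident edge),
    H_ij = 0                   otherwise.

With d the *weighted* degree, every column of H belonging to a non-isolated
node sums to zero, so total heat is conserved exactly: what a node loses
(-tau_i on the diagonal) is exactly what its neighbours gain. The exact
kernel costs O(N^3) and is kept as a small-graph oracle; the production path
is the discrete approximation (I + alpha/M H)^M applied as M sparse
matrix-vector products, with error O(1/M).

alpha is the thermal conductivity (how fast heat spreads), M the iteration
count; the defaults alpha=1, M=30 are the practical optimum for this family
of kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm

from .graph_io import BipartiteAdjacency, ScoreMatrix, SimilarityGraph

logger = logging.getLogger(__name__)

#: relative tolerance for the per-call heat-conservation check
CONSERVATION_RTOL = 1e-9

#: largest graph the dense matrix-exponential oracle will accept
DEFAULT_EXACT_CAP = 2000


@dataclass
class DiffusionParams:
    """Thermal conductivity alpha and discrete iteration count M.

    alpha <= M guarantees the propagation matrix I + (alpha/M) H is
    entrywise nonnegative (its diagonal is 1 - alpha/M * tau >= 0), so
    nonnegative seeds stay nonnegative.
    """

    alpha: float = 1.0
    M: int = 30

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.M < 1:
            raise ValueError("M must be a positive integer")
        if self.alpha > self.M:
            raise ValueError(
                f"alpha={self.alpha} > M={self.M}: propagation matrix would "
                "have a negative diagonal"
            )


@dataclass
class HeatMatrix:
    H: sp.csr_matrix
    node_order: list[str]

    @property
    def n(self) -> int:
        return self.H.shape[0]


def build_heat_matrix(G: SimilarityGraph, degree: str = "weighted") -> HeatMatrix:
    """Assemble the heat matrix H from a similarity graph.

    ``degree="weighted"`` (default) uses d_j = sum of incident weights, which
    makes non-isolated columns sum to zero and heat conservation exact.
    ``degree="unweighted"`` uses the incident edge count instead; conservation
    then only holds approximately on non-uniform weights.
    """
    if degree not in ("weighted", "unweighted"):
        raise ValueError("degree must be 'weighted' or 'unweighted'")
    n = G.n
    if not G.edges:
        logger.warning("similarity graph has no edges; heat matrix is zero")
        return HeatMatrix(sp.csr_matrix((n, n)), list(G.node_labels))

    W = G.adjacency()
    wdeg = G.weighted_degree()
    if degree == "weighted":
        d = wdeg
    else:
        d = np.asarray((W > 0).sum(axis=0)).ravel().astype(float)
    tau = (wdeg > 0).astype(float)

    inv_d = np.zeros(n)
    nz = d > 0
    inv_d[nz] = 1.0 / d[nz]
    # off-diagonal: column j scaled by 1/d_j; diagonal: -(tau_j/d_j) * wdeg_j
    H = (W @ sp.diags(inv_d)).tolil()
    diag = -tau * wdeg * inv_d
    H.setdiag(diag)
    return HeatMatrix(H.tocsr(), list(G.node_labels))


def _check_conservation(f0: np.ndarray, f1: np.ndarray) -> None:
    s0, s1 = float(f0.sum()), float(f1.sum())
    tol = CONSERVATION_RTOL * max(abs(s0), 1.0)
    if abs(s0 - s1) > tol:
        raise RuntimeError(
            f"heat not conserved: sum(f0)={s0!r}, sum(f1)={s1!r}"
        )


def diffuse_exact(
    Hm: HeatMatrix,
    f0: np.ndarray,
    alpha: float,
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> np.ndarray:
    """f(1) = e^{alpha H} f(0) via the dense matrix exponential.

    O(N^3): intended as the oracle for small graphs; refuses graphs larger
    than ``exact_cap`` nodes (use :func:`diffuse_discrete` there).
    """
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != (Hm.n,):
        raise ValueError("seed vector length does not match graph size")
    if np.any(f0 < 0):
        raise ValueError("seed vector must be nonnegative")
    if Hm.n > exact_cap:
        raise ValueError(
            f"graph has {Hm.n} > {exact_cap} nodes; use diffuse_discrete"
        )
    f1 = expm(alpha * Hm.H.toarray()) @ f0
    _check_conservation(f0, f1)
    return f1


def diffuse_discrete(
    Hm: HeatMatrix,
    f0: np.ndarray,
    p: DiffusionParams,
) -> np.ndarray:
    """f(1) = (I + alpha/M H)^M f(0) by M sparse matrix-vector products.

    The dense power is never formed, so the cost is O(M |E|) per seed vector.
    """
    f = np.asarray(f0, dtype=float).copy()
    if f.shape != (Hm.n,):
        raise ValueError("seed vector length does not match graph size")
    if np.any(f < 0):
        raise ValueError("seed vector must be nonnegative")
    step = p.alpha / p.M
    for _ in range(p.M):
        f = f + step * (Hm.H @ f)
    _check_conservation(np.asarray(f0, dtype=float), f)
    return f


def propagate_all(
    Yhat: BipartiteAdjacency,
    G: SimilarityGraph,
    p: DiffusionParams = DiffusionParams(),
    method_tag: str = "",
) -> ScoreMatrix:
    """Diffuse every side effect's completed row over the similarity graph.

    Row i of ``Yhat`` is the seed vector f(0) for side effect i; the output
    row is the diffused f(1). All rows are propagated together: the M sparse
    products are applied to the whole n x m seed block at once.
    """
    if Yhat.col_labels != G.node_labels:
        raise ValueError("biadjacency columns and similarity nodes misaligned")
    Hm = build_heat_matrix(G)
    F = Yhat.toarray()  # m x n, rows are seed vectors
    T = F.T.copy()      # n x m
    step = p.alpha / p.M
    for _ in range(p.M):
        T = T + step * (Hm.H @ T)
    out = T.T
    # conservation, checked per side-effect row
    s0, s1 = F.sum(axis=1), out.sum(axis=1)
    bad = np.abs(s0 - s1) > CONSERVATION_RTOL * np.maximum(np.abs(s0), 1.0)
    if np.any(bad):
        raise RuntimeError(f"heat not conserved for rows {np.where(bad)[0][:5]}")
    tag = method_tag or f"heat_diffusion(alpha={p.alpha}, M={p.M})"
    return ScoreMatrix(Yhat.row_labels, Yhat.col_labels, out, tag)
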