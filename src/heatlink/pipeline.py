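"""End-to-end scorers: each maps a training biadjacency plus the similarity
graph to a full m x n score matrix.

The method under study is ``nmf_diffusion``: complete Y by NMF, then diffuse
each completed row over the drug similarity graph. Its two ablations
(``nmf_only``, ``diffusion_only``) and the baseline scorers share the same
interface so the evaluation machinery can compare them fold for fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .baselines import (
    CombinedGraph,
    KatzParams,
    PPRParams,
    katz_score_matrix,
    neighborhood_score_matrix,
    ppr_score_matrix,
)
from .diffusion import DiffusionParams, propagate_all
from .graph_io import BipartiteAdjacency, ScoreMatrix, SimilarityGraph
from .nmf import NMFConfig, complete, factorize


@dataclass
class NMFDiffusionScorer:
    """NMF completion followed by heat diffusion (the full method).

    ``seed_known_only`` zeroes the reconstructed scores of unobserved cells
    before diffusion, seeding only cells with a known link; the default seeds
    with the full completed row.
    """

    nmf: NMFConfig = field(default_factory=lambda: NMFConfig(rank=3))
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    seed_known_only: bool = False
    name: str = "nmf_diffusion"

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        fp = factorize(Y, replace(self.nmf, seed=seed))
        Yhat = complete(fp, Y.row_labels, Y.col_labels)
        if self.seed_known_only:
            mask = (Y.toarray() > 0).astype(float)
            Yhat = BipartiteAdjacency(Y.row_labels, Y.col_labels, Yhat.toarray() * mask)
        tag = (f"{self.name}(rank={fp.rank}, alpha={self.diffusion.alpha}, "
               f"M={self.diffusion.M})")
        return propagate_all(Yhat, G, self.diffusion, method_tag=tag)


@dataclass
class NMFOnlyScorer:
    """Matrix completion alone: the reconstructed score is the prediction."""

    nmf: NMFConfig = field(default_factory=lambda: NMFConfig(rank=3))
    name: str = "nmf_only"

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        fp = factorize(Y, replace(self.nmf, seed=seed))
        Yhat = complete(fp, Y.row_labels, Y.col_labels)
        return ScoreMatrix(Y.row_labels, Y.col_labels, Yhat.toarray(),
                           f"{self.name}(rank={fp.rank})")


@dataclass
class DiffusionOnlyScorer:
    """Heat diffusion seeded directly with the observed 0/1 links."""

    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    name: str = "diffusion_only"

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        sm = propagate_all(Y, G, self.diffusion,
                           method_tag=f"{self.name}(alpha={self.diffusion.alpha}, "
                                      f"M={self.diffusion.M})")
        return sm


@dataclass
class NeighborhoodScorer:
    """One of the four node-based proximity metrics on the combined graph."""

    metric: str = "common_neighbors"

    @property
    def name(self) -> str:
        return self.metric

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        g = CombinedGraph(Y, G)
        return ScoreMatrix(Y.row_labels, Y.col_labels,
                           neighborhood_score_matrix(g, self.metric), self.metric)


@dataclass
class KatzScorer:
    params: KatzParams = field(default_factory=KatzParams)
    weighted: bool = False
    name: str = "katz"

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        g = CombinedGraph(Y, G)
        scores = katz_score_matrix(g, self.params, weighted=self.weighted)
        return ScoreMatrix(Y.row_labels, Y.col_labels, scores,
                           f"katz(beta={self.params.beta}, l_max={self.params.l_max})")


@dataclass
class PPRScorer:
    params: PPRParams = field(default_factory=PPRParams)
    weighted: bool = False
    name: str = "ppr"

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        g = CombinedGraph(Y, G)
        scores = ppr_score_matrix(g, self.params, weighted=self.weighted)
        return ScoreMatrix(Y.row_labels, Y.col_labels, scores,
                           f"ppr(restart={self.params.restart})")


@dataclass
class RandomScorer:
    """Seeded uniform(0,1) score per cell — the floor every method must beat."""

    name: str = "random"

    def __call__(self, Y: BipartiteAdjacency, G: SimilarityGraph, seed: int) -> ScoreMatrix:
        rng = np.random.default_rng(seed)
        return ScoreMatrix(Y.row_labels, Y.col_labels,
                           rng.uniform(size=(Y.m, Y.n)), "random")


DEFAULT_METHODS = {
    "nmf_diffusion": NMFDiffusionScorer,
    "nmf_only": NMFOnlyScorer,
    "diffusion_only": DiffusionOnlyScorer,
    "common_neighbors": lambda: NeighborhoodScorer("common_neighbors"),
    "jaccard": lambda: NeighborhoodScorer("jaccard"),
    "adamic_adar": lambda: NeighborhoodScorer("adamic_adar"),
    "resource_allocation": lambda: NeighborhoodScorer("resource_allocation"),
    "katz": KatzScorer,
    "ppr": PPRScorer,
    "random": RandomScorer,
}


def make_scorer(name: str, **kwargs):
    """Instantiate a scorer by its method name."""
    try:
        factory = DEFAULT_METHODS[name]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; known: {sorted(DEFAULT_METHODS)}")
    return factory(**kwargs) if kwargs else factory()
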