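import itertools

import numpy as np
import pytest
from scipy import stats

import heatlink as hl
from heatlink.evaluation import candidate_pools, mask_links
from heatlink.nmf import NMFConfig

from conftest import random_similarity_graph


def adjacency(arr):
    arr = np.asarray(arr, dtype=float)
    m, n = arr.shape
    return hl.BipartiteAdjacency([f"s{i}" for i in range(m)],
                                 [f"d{j}" for j in range(n)], arr)


def brute_aupr(scores, labels):
    """Exhaustive threshold oracle: one PR point per distinct score, tie
    groups entering together, trapezoid over recall with a (0, p0) anchor."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    P = (labels == 1).sum()
    pts = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        pts.append((tp / P, tp / int(pred.sum())))
    if pts[0][0] > 0:
        pts.insert(0, (0.0, pts[0][1]))
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2
    return area


class TestAupr:
    def test_perfect_ranking(self):
        assert hl.aupr([0.9, 0.1], [1, 0]).aupr == pytest.approx(1.0)

    def test_reversed_ranking_hand_value(self):
        assert hl.aupr([0.1, 0.9], [1, 0]).aupr == pytest.approx(0.25)

    def test_matches_exhaustive_oracle_on_all_small_inputs(self):
        # every 0/1 labeling and tie pattern on up to 8 items
        rng = np.random.default_rng(0)
        score_pool = [0.1, 0.2, 0.3, 0.4]
        count = 0
        for n in (2, 4, 6, 8):
            for _ in range(60):
                scores = rng.choice(score_pool, size=n)
                labels = rng.integers(0, 2, size=n)
                if labels.sum() in (0, n):
                    continue
                assert hl.aupr(scores, labels).aupr == pytest.approx(
                    brute_aupr(scores, labels), abs=1e-12)
                count += 1
        assert count > 100

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        a = hl.aupr(scores, labels).aupr
        b = hl.aupr(np.exp(3 * scores) + 7, labels).aupr
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounds_and_curve_invariants(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.uniform(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            pr = hl.aupr(scores, labels)
            assert 0 <= pr.aupr <= 1
            assert (np.diff(pr.recall) >= 0).all()
            assert ((pr.precision >= 0) & (pr.precision <= 1)).all()

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hl.aupr([0.1, 0.2], [1, 1])


class TestSplitFolds:
    def test_partition_sizes(self):
        Y = adjacency(np.ones((10, 10)))
        split = hl.split_folds(Y, 10, seed=0)
        folds = [split.fold_links(f) for f in range(10)]
        assert sum(len(f) for f in folds) == 100
        assert all(len(f) == 10 for f in folds)
        assert set().union(*[set(f) for f in folds]) == set(Y.observed_pairs())

    def test_per_row_stratification(self):
        Y = adjacency(np.ones((3, 10)))
        split = hl.split_folds(Y, 10, seed=1)
        for i in range(3):
            per_fold = [sum(1 for (r, _), g in split.assignments.items()
                            if r == i and g == f) for f in range(10)]
            assert per_fold == [1] * 10

    def test_uneven_rows_differ_by_at_most_one(self):
        rng = np.random.default_rng(3)
        Y = adjacency((rng.random((8, 12)) < 0.6).astype(float))
        split = hl.split_folds(Y, 5, seed=2)
        for i in range(8):
            per_fold = [sum(1 for (r, _), g in split.assignments.items()
                            if r == i and g == f) for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_determinism_and_seed_sensitivity(self):
        Y = adjacency(np.ones((5, 8)))
        a = hl.split_folds(Y, 4, seed=7).assignments
        b = hl.split_folds(Y, 4, seed=7).assignments
        c = hl.split_folds(Y, 4, seed=8).assignments
        assert a == b
        assert a != c

    def test_too_many_folds_rejected(self):
        Y = adjacency(np.eye(3))
        with pytest.raises(ValueError, match="exceeds"):
            hl.split_folds(Y, 10, seed=0)

    def test_row_without_links_rejected(self):
        Y = adjacency(np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="without links"):
            hl.split_folds(Y, 2, seed=0)


class TestPairedTTest:
    def test_identical_vectors_rejected(self):
        a = np.linspace(0.1, 0.9, 10)
        with pytest.raises(ValueError, match="degenerate"):
            hl.paired_ttest(a, a)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.2, 0.4, size=10)
        d = np.array([0.3, -0.1, 0.3, -0.1, 0.3, -0.1, 0.3, -0.1, 0.3, 0.9])
        a = b + d
        t, p = hl.paired_ttest(a, b)
        k = len(d)
        t_ref = d.mean() * np.sqrt(k) / d.std(ddof=1)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df=k - 1), rel=1e-12)

    def test_large_consistent_differences_highly_significant(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0.1, 0.2, size=10)
        a = b + rng.uniform(0.3, 0.32, size=10)
        _, p = hl.paired_ttest(a, b)
        assert p < 0.001


class TestDegreePreservingRandomize:
    def test_single_edge_unchanged(self):
        G = hl.SimilarityGraph(["a", "b", "c"], {(0, 1): 0.4})
        R = hl.degree_preserving_randomize(G, seed=0)
        assert R.edges == G.edges

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_multiset_preserved(self, seed):
        G = random_similarity_graph(20, 0.25, seed)
        R = hl.degree_preserving_randomize(G, seed=seed + 1)
        def degs(g):
            d = np.zeros(g.n)
            for (i, j), _ in g.edges.items():
                d[i] += 1
                d[j] += 1
            return sorted(d.tolist())
        assert degs(R) == degs(G)
        assert R.n_edges == G.n_edges
        assert sorted(R.edges.values()) == sorted(G.edges.values())  # weights travel

    def test_unique_configuration_returned_unchanged(self):
        # degree sequence (3,2,2,1) of triangle-plus-pendant has exactly one
        # labeled realization, so rewiring can only return the same edge set
        G = hl.SimilarityGraph(["a", "b", "c", "d"],
                               {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0, (2, 3): 1.0})
        seen = {frozenset(hl.degree_preserving_randomize(G, seed=s).edges)
                for s in range(50)}
        assert seen == {frozenset(G.edges)}

    def test_reaches_multiple_configurations(self):
        # the 4-cycle has three labeled 2-regular realizations; swaps move
        # between them
        G = hl.SimilarityGraph(["a", "b", "c", "d"],
                               {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (0, 3): 1.0})
        seen = {frozenset(hl.degree_preserving_randomize(G, seed=s).edges)
                for s in range(200)}
        assert len(seen) > 1

    def test_deterministic(self):
        G = random_similarity_graph(15, 0.3, 4)
        assert hl.degree_preserving_randomize(G, seed=9).edges == \
            hl.degree_preserving_randomize(G, seed=9).edges


class TestCrossValidate:
    def test_random_scorer_brackets_prevalence(self, small_dataset):
        ds = small_dataset
        split = hl.split_folds(ds.Y_obs, 5, seed=0)
        rep = hl.cross_validate(ds.Y_obs, ds.G, [hl.RandomScorer()], split)
        vals = rep.fold_aupr("random")
        # random ranking's expected AUPR is the candidate-pool prevalence
        obs = set(ds.Y_obs.observed_pairs())
        test = set(split.fold_links(0))
        _, labels = candidate_pools(ds.Y_obs, obs - test, test)
        prev = labels.mean()
        assert abs(vals.mean() - prev) < 0.02

    def test_identical_method_twice_identical_folds(self, small_dataset):
        ds = small_dataset
        split = hl.split_folds(ds.Y_obs, 4, seed=1)
        rep = hl.cross_validate(ds.Y_obs, ds.G,
                                [hl.RandomScorer(), hl.RandomScorer()], split)
        assert np.array_equal(rep.per_fold[0], rep.per_fold[1])

    def test_planted_signal_beats_random(self, small_dataset):
        ds = small_dataset
        split = hl.split_folds(ds.Y_obs, 5, seed=2)
        rep = hl.cross_validate(ds.Y_obs, ds.G,
                                [hl.NMFDiffusionScorer(), hl.RandomScorer()], split)
        assert rep.mean("nmf_diffusion") > 5 * rep.mean("random")

    def test_candidate_pools_exclude_other_folds_positives(self):
        Y = adjacency(np.array([[1.0, 1, 0, 0], [1, 0, 1, 0]]))
        obs = set(Y.observed_pairs())
        test = {(0, 0)}
        train = obs - test - {(1, 2)}  # (1,2) held out in some other fold
        cands, labels = candidate_pools(Y, train, test)
        assert (0, 0) in cands
        assert (1, 2) not in cands
        assert all((labels[k] == 1) == (cands[k] in test) for k in range(len(cands)))


class TestPermutationPvalues:
    def test_pvalue_arithmetic(self):
        res = hl.evaluation.PermutationResult(pairs=[("s", "d")],
                                              actual=np.array([1.0]),
                                              omega=np.array([50]), N=1000)
        assert res.pvalues[0] == pytest.approx(0.05)

    def test_exact_multiples_of_one_over_N(self, small_dataset):
        ds = small_dataset
        test = ds.held_out[:5]
        pairs = [(ds.Y_obs.row_labels[i], ds.Y_obs.col_labels[j]) for i, j in test]
        res = hl.permutation_pvalues(ds.Y_obs, ds.G, pairs, N=20, seed=3)
        assert res.N == 20
        assert all(o <= 20 for o in res.omega)
        mult = res.pvalues * 20
        assert np.allclose(mult, np.round(mult))

    def test_dominant_pair_gets_zero(self):
        # star similarity graph: the hub's actual score survives any rewiring
        Y = adjacency(np.array([[1.0, 1, 0], [0, 1, 1]]))
        G = hl.SimilarityGraph(["d0", "d1", "d2"], {(0, 1): 1.0})
        res = hl.permutation_pvalues(Y, G, [("s0", "d0")], N=15, seed=0,
                                     nmf=NMFConfig(rank=1))
        # only one wiring of a single-edge graph exists => identical scores, ties
        # never count toward omega
        assert res.pvalues[0] == 0.0


class TestTrainingFractionSweep:
    def test_deterministic(self, small_dataset):
        ds = small_dataset
        a = hl.training_fraction_sweep(ds.Y_obs, ds.G, [0.5], repeats=1, seed=5)
        b = hl.training_fraction_sweep(ds.Y_obs, ds.G, [0.5], repeats=1, seed=5)
        assert a == b

    def test_more_training_data_helps(self, small_dataset):
        ds = small_dataset
        out = hl.training_fraction_sweep(ds.Y_obs, ds.G, [0.1, 0.5, 0.9],
                                         repeats=3, seed=6)
        assert out[0.9] > out[0.1]

    def test_bad_fraction_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError, match="outside"):
            hl.training_fraction_sweep(ds.Y_obs, ds.G, [1.5], repeats=1, seed=0)
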