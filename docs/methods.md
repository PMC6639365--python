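# Methods

## The model

`heatlink` predicts missing links between side effects and drugs on a
heterogeneous graph built from two parts:

1. a **bipartite graph**: the m x n biadjacency matrix Y, with Y_ij = 1 when
   side effect i is a reported reaction to drug j, and 0 otherwise;
2. an undirected, weighted **drug–drug similarity graph** G = (V, E, W),
   with weights w_ij > 0 — typically cosine similarities between drug
   embeddings, or any supplied nonnegative similarity.

Prediction is a two-stage pipeline.

**Stage 1 — NMF completion.** Y is factorized as Y ≈ S Dᵀ with S (m x r) and
D (n x r) elementwise nonnegative, minimising ‖Y − S Dᵀ‖²_F by Lee–Seung
multiplicative updates. The reconstruction ŷ_ij = s_iᵀ d_j replaces the 0/1
matrix wholesale: observed cells get real-valued scores too, and each
reconstructed row is the heat seed vector f(0) for one side effect. Zeros of
Y are treated as weak observed zeros (plain NMF over the full matrix), not
as missing entries, so the sparsity pattern itself carries signal. A
`seed_known_only` switch instead zeroes the reconstructed values of
unobserved cells before diffusion, for users who want only known links to
inject heat.

**Stage 2 — heat diffusion.** Each seed vector is propagated over the
similarity graph by the heat kernel

    f(1) = e^{αH} f(0),

where the heat matrix H has off-diagonal entries H_ij = w_ji / d_j for each
edge (v_j, v_i) and diagonal H_ii = −τ_i (τ_i = 1 iff node i has an incident
edge). We interpret d_j as the **weighted** degree Σ_k w_jk. Under that
reading every non-isolated column of H sums to zero, so total heat is
conserved exactly — what a node emits is exactly what its neighbours absorb —
and the package asserts conservation (relative tolerance 1e−9) on every
diffusion call. A `degree="unweighted"` switch exposes the edge-count
reading, under which conservation is only approximate on non-uniform
weights.

The exact kernel costs O(N³) and is retained only as a small-graph oracle
(default cap 2000 nodes). The production path is the discrete approximation

    f(1) ≈ (I + (α/M) H)^M f(0),

applied as M sparse matrix–vector products (cost O(M|E|) per seed; the dense
power is never formed). The approximation error is O(1/M); with the defaults
it is below 0.05 in the infinity norm on every random test graph, and the
error decreases strictly in M. The constraint α ≤ M keeps the propagation
matrix entrywise nonnegative, so nonnegative seeds stay nonnegative.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | thermal conductivity (diffusion rate), dimensionless | 1.0 | the practical optimum reported for this kernel family; higher α spreads heat further |
| M | discrete iteration count | 30 | error O(1/M); must satisfy α ≤ M |
| r | NMF rank | 3 (scorers), or inner-CV selected | r ≪ min(m, n) |
| max_iter / rel_tol | NMF stopping rule | 500 / 1e−6 | relative objective decrease |
| ε | NMF denominator guard | 1e−12 | |
| Katz β, l_max | attenuation, walk-length cutoff | 0.005, 4 | walks, not simple paths; warn if β · max degree ≥ 1 |
| PPR restart | random-walk restart probability | 0.15 | distinct from the diffusion α |
| folds k | outer cross-validation folds | 10 | t-tests then have k−1 = 9 df |
| N | permutation randomizations | 1000 | p = Ω/N, strict exceedance |

## Rank selection

`select_rank` runs edge-masking cross-validation inside the training
matrix: the observed entries are split into inner folds, each fold is
zeroed in turn, the factorization is refit, and held-out links are scored
against an equal-count sample of never-observed cells by AUPR. Two
numerical choices matter:

* **Multi-start fits.** Multiplicative updates descend monotonically but
  are local; on block-structured matrices a single seeded start can lock
  onto the wrong factor support. Each inner fit therefore keeps the best of
  5 seeded initializations by final objective.
* **Parsimony tie rule.** Held-out AUPR plateaus at and above the smallest
  sufficient rank, so a strict argmax wanders over the plateau by CV noise.
  Ranks whose mean AUPR lies within `tie_tol = 0.01` of the best are
  treated as tied and the smallest wins (the 1-SE rule familiar from
  penalized regression).

With these choices the planted rank of an exactly-rank-3 block matrix
(45 x 36) is recovered in most seeds (typically 6–9 of 10 across seed
batches). When selection misses it always *over*-estimates: masking entries
raises the effective rank of the training matrix, and the extra component
of a rank-4 fit can genuinely improve held-out ranking — a known mild bias
of predictive rank selection, preferable to under-estimation for a
completion task. Note also that the rank of a *binarized* latent-factor
matrix is not identifiable this way at all: thresholding a rank-3 product
yields a 0/1 matrix whose predictive AUPR does not peak at 3, so
rank-recovery claims are only meaningful on real-valued low-rank input.

## Evaluation protocol

* **Folds** partition the observed *links* (not side-effect rows), dealt
  round-robin per side effect so each row keeps ≈ (k−1)/k of its links in
  every training matrix. Partitioning rows wholesale would zero entire seed
  vectors and make the NMF stage vacuous for test rows.
* **Candidates** per fold: for each side effect, every drug without a
  training link; positives are that fold's held-out links; negatives are
  never-observed pairs. Links held out in *other* folds are excluded.
* **AUPR** is computed with one PR point per distinct score threshold (tie
  groups enter as a unit), trapezoidal integration over recall, and a
  (0, p₀) anchor when the first point has positive recall. AUPR is
  preferred to ROC-AUC because positives are ~1–2% of candidate cells.
* **Method comparison** uses a two-sided paired t-test on the per-fold AUPR
  vectors (df = k−1). Identical vectors raise an error rather than
  reporting p = NaN.
* **Permutation significance**: the drug graph is rewired by seeded double
  edge swaps (weights travel with their rewired edges), which preserve the
  unweighted degree multiset exactly; the same NMF seeds are rediffused on
  each of N rewired graphs, and p = Ω/N counts strict exceedances of the
  actual score. p-values are exact multiples of 1/N.
* **Training-fraction sweep**: keep a random fraction f of links for
  training, test on the rest, average over repeats.

## The synthetic benchmark

`synthetic.generate` plants exactly the structure the method assumes:
nonnegative factors S* (m x r), D* (n x r) with exponential(1) entries,
Y_true = S* D*ᵀ; the top ⌊density · m · n⌋ cells become positive links
(each row's top cell is always included so every side effect has at least
one link); 10% of positives are hidden as recovery targets; and the drug
similarity graph is the cosine similarity of the rows of D* perturbed by
symmetrized Gaussian noise of s.d. `sim_noise`, with non-positive weights
dropped. Defaults (m=50, n=40, r=3, density=0.12, noise=0) give 240
positive links and a candidate-pool prevalence near 0.013.

Properties of this construction worth knowing before interpreting results:

* Cosines of all-positive factor vectors are uniformly high, so the
  **noiseless similarity graph is complete**. Two consequences: diffusion at
  α=1 mixes nearly uniformly (so the diffusion-only scorer is weak), and the
  degree-preserving null is degenerate on the noiseless graph (a complete
  graph is the unique realization of its degree sequence). Calibration
  studies of the permutation test therefore use a sparse similarity graph.
* `sim_noise` primarily **sparsifies** the graph (edges with true cosine C
  survive with probability Φ(C/σ)); moderate noise can therefore *improve*
  the diffusion-only scorer by thinning an uninformative dense graph, and
  the noise response is non-monotone by construction.
* On this benchmark the combined NMF+diffusion scorer beats the random
  floor by more than an order of magnitude and beats diffusion-only by a
  wide margin, but its edge over NMF-only is small (a few percent of AUPR,
  seed-dependent in sign) — the similarity graph derives from the same
  factors as Y, so diffusion contributes mostly redundant smoothing here.
  Passing ordering tests on this generator demonstrate internal
  consistency, not field performance on curated pharmacovigilance data,
  where the two information sources are genuinely complementary.
* `synthetic.planted_low_rank` provides the real-valued, structurally
  sparse, exactly-low-rank matrices used for factorization recovery and
  rank-selection studies.

Problem sizes used throughout the test suite and the acceptance script
(50 x 40 benchmark matrices, graphs of up to 50 nodes, N = 200
randomizations in calibration runs, 10 seeds per repetition study) were
chosen so the full suite runs in well under a minute of CPU while keeping
every assertion statistically meaningful at its stated tolerance.

## Numerical edge cases

* Empty similarity graph → zero heat matrix; diffusion is the identity.
* Isolated drugs keep their seed heat (zero row/column in H).
* Adamic/Adar terms with shared-neighbor degree ≤ 1 contribute 0 (ln 1 = 0
  would divide by zero); a warning is logged.
* PPR redistributes dangling-node mass to the restart node so the
  stationary vector always sums to 1.
* Conflicting duplicate weights in similarity input are an error;
  non-positive weights and self-loops are dropped with logged counts.
* Negative embedding cosines never become edges (dropped, not clipped):
  the heat matrix presupposes nonnegative conductance.
* Prediction output orders ties by ascending drug label so files are
  byte-reproducible.

## Known limitations

* The generator does not imitate the heavy-tailed degree distributions,
  reporting biases, or vocabulary-matching noise of real drug/side-effect
  databases.
* Scores are per side effect; the model cannot represent interactions
  between co-administered drugs (polypharmacy).
* Word2vec input is the text format only; binary-format parsing is out of
  scope.
* Baseline scorers operate on the binarized combined graph by default; a
  `weighted` flag switches Katz/PPR to cosine-weighted walks.
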