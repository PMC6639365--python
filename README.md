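# heatlink

Link prediction between **drug side effects and drugs** by NMF-seeded heat
diffusion on a heterogeneous graph.

Adverse drug reactions are expensive to verify in the lab, so ranking
plausible but unreported (side effect, drug) associations computationally is
a standard triage step in pharmacovigilance. `heatlink` implements a
two-stage propagation method for this task, together with the classic
link-prediction baselines and a complete evaluation protocol, all runnable
offline on synthetic benchmark data.

## The method

Inputs are two graphs over a shared drug set:

* the bipartite graph of known associations, as a biadjacency matrix
  Y ∈ {0,1}^{m×n} (side effects × drugs);
* an undirected weighted drug–drug similarity graph, either supplied as an
  edge list or built from word2vec-style embeddings (edge weight = cosine
  similarity; non-positive cosines are dropped).

**Stage 1 (completion).** Factorize Y ≈ S Dᵀ with S, D ≥ 0 by minimizing
‖Y − S Dᵀ‖²_F (Lee–Seung multiplicative updates). The reconstructed row
ŷ_i = Ds_i assigns every drug a nonnegative association score for side
effect i.

**Stage 2 (diffusion).** Treat ŷ_i as heat f(0) on the drug graph and
propagate it through the heat kernel

    f(1) = e^{αH} f(0),     H_ij = w_ji/d_j (edges),  H_ii = −τ_i,

with d_j the weighted degree and τ_i the has-edges flag; in production the
kernel is approximated by (I + (α/M)H)^M as M sparse mat-vec products
(defaults α = 1, M = 30). Columns of H sum to zero, so total heat is
conserved — the package asserts this on every call. The diffused vector
f(1) is the final ranking of drugs for that side effect.

Baselines for comparison: common neighbors, Jaccard, Adamic/Adar, resource
allocation, truncated Katz, personalized PageRank, and a random floor — all
on the combined bipartite + similarity graph. Evaluation machinery:
stratified link-level k-fold cross-validation with AUPR, paired t-tests,
degree-preserving permutation p-values (p = Ω/N), and a training-fraction
sweep. A planted-latent-factor generator makes everything testable without
any external database. See `docs/methods.md` for the full model account.

## Worked example

Generate a small planted dataset, rank candidate drugs, and compare methods
by cross-validated AUPR:

```sh
heatlink simulate --m 30 --n 20 --rank 3 --density 0.15 --noise 0.5 \
    --seed 7 --outdir demo
# wrote synthetic dataset (81 observed links, 9 held out, 185 similarity edges) to demo

heatlink predict --bipartite demo/bipartite.tsv --similarity demo/similarity.tsv \
    --rank 3 --top-k 3 --out demo/pred.tsv
head -4 demo/pred.tsv
# # side_effect  drug     score                rank
# se000          drug010  0.3911895567527285   1
# se000          drug004  0.11200048601382222  2
# se000          drug017  0.0938323195069362   3

heatlink evaluate --bipartite demo/bipartite.tsv --similarity demo/similarity.tsv \
    --methods nmf_diffusion,nmf_only,diffusion_only,random --folds 5 --rank 3 --seed 0 \
    | tail -8
# nmf_diffusion   mean    0.423799
# nmf_diffusion   sd      0.077114
# nmf_only        mean    0.291151
# nmf_only        sd      0.073412
# diffusion_only  mean    0.398853
# diffusion_only  sd      0.067826
# random          mean    0.061333
# random          sd      0.035891
```

The prediction file ranks drugs per side effect by diffused heat; scores are
conserved heat mass, so a row's scores sum to the row's seed heat. In the
evaluation report, the mean column is the 5-fold mean AUPR for recovering
held-out links: here the combined method (0.42) clearly beats the random
floor (0.06, ≈ the candidate-pool prevalence) and both of its ablations.
`heatlink permtest` adds per-pair permutation p-values against a
degree-preserving rewiring null.

The same functionality is available as a library:

```python
import heatlink as hl

ds = hl.generate(hl.SyntheticSpec(m=50, n=40, r_true=3, link_density=0.12, seed=0))
split = hl.split_folds(ds.Y_obs, 10, seed=0)
report = hl.cross_validate(ds.Y_obs, ds.G,
                           [hl.NMFDiffusionScorer(), hl.RandomScorer()], split)
print(report.mean("nmf_diffusion"), report.ttest("nmf_diffusion", "random"))
```

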