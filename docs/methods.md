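# Methods

## Generative model and objective U_n

Counts `x_ig` follow a ZINB observation model conditioned on a biological
latent `z_i ∈ R^{d_z}` (prior `N(0, I)`), a log-library latent `l_i` (prior
`N(l_μ[s_i], l_σ[s_i])` with per-batch empirical mean and *unbiased* (n−1)
variance of log total counts), and the one-hot batch label `s_i`. The
decoder maps `(z, s)` to per-cell gene proportions `ε` (softmax head over
genes, with a 1e−10 floor folded into the normalization so extreme logits
cannot underflow a proportion to exactly zero) and dropout logits (sigmoid
head); the gene-wise inverse dispersion `c` is a free parameter `exp(log_c)`
optimized jointly, the scVI convention. The Gamma–Poisson–Bernoulli
hierarchy marginalizes to the ZINB pmf with NB mean `μ = exp(l)·ε`:

```
NB(x; μ, c) = Γ(x+c) / (Γ(c) x!) · (c/(c+μ))^c · (μ/(c+μ))^x
ZINB(x)     = π·1{x=0} + (1−π)·NB(x)
```

computed in log space with log-sum-exp at x = 0. The encoder takes
`log1p(counts)` (raw counts always feed the likelihood) through one hidden
ReLU layer into four heads: means and log-variances for `q(z|x)` (diagonal
Gaussian) and `q(l|x)` (scalar Gaussian). U_n is the minibatch-mean negative
ELBO with one reparameterized latent sample for the reconstruction
expectation and analytic Gaussian KL terms. The sampled `l` is clipped to
`[min l_μ − 10, max l_μ + 10]` before exponentiation — inactive in ordinary
training, it prevents overflow when a batch-collapsed encoder is paired
with a fresh decoder.

Architecture defaults follow the scVI convention (one hidden layer of 128
units, d_z = 10) and are configurable; the experiments in the test suite
use 32-unit layers and d_z = 8.

## Batch-effect measures V_n

**MINE.** `V = mean_i f_ψ(z_i, s_i) − log mean_i exp f_ψ(z_i, s'_i)` with
`s'` a fresh uniform shuffle of the labels per minibatch and per evaluation
pass. Default statistics network: 10 fully connected ELU layers of 128
units, weights initialized N(0, 0.02); the test-scale experiments use 3×32.
The latent entering `f_ψ` is always standardized (per batch of draws, zero
mean/unit SD per dimension): mutual information is invariant under affine
maps, and bounded inputs keep both the adversarial game and the de-novo
evaluation fit numerically stable. The standardization constants are
treated as stop-gradients.

**MMD.** Square root (clamped at zero first; gradient guarded near zero) of
the biased V-statistic under a mixture of five Gaussian kernels
`k(a,b) = (1/5) Σ exp(−‖a−b‖²·√d_z / (2 b_i²))`, default bandwidths
(1, 2, 5, 8, 10), on the standardized latent. With B > 2 batches the value
is the mean over unordered batch pairs (the two-batch estimator is the
stated case; the extension is this package's choice).

**kNN MI (evaluation only).** The digamma-form Ross estimator for
continuous `z` vs discrete `s` (k = 3, distances to the k-th within-class
neighbor, KD-tree radius counts, estimate clamped at zero). It is not
differentiable and is never used in training.

## Standardization and bounds

U bounds are the min/max per-minibatch U_n observed across all epochs of a
plain generative pretraining run. V bounds come from an analogous run that
minimizes V alone over the encoder, with two departures from a literal
from-scratch run, made once after observing that desk-scale models start
with posterior variances that swamp the batch signal: (1) the V run
warm-starts from the U-pretrained model, so its trace spans the meaningful
range from the generative fit's batch dependence down to the collapsed
encoder; (2) with MINE, the statistics network first gets a frozen-encoder
warm-up (`mine_warmup_epochs`) and is then re-maximized for one full pass
before *every* encoder step — minimizing a stale lower bound is unbounded
below and diverges. Standardized objectives `(x − lo)/(hi − lo)` are not
clamped to [0, 1].

## Pareto MTL and scalarization

Preference vectors `c_k = (cos((k−1)π/(2(K−1))), sin((k−1)π/(2(K−1))))`,
k = 1..K (K = 10 in full runs). Subproblem k constrains
`g_j = (c_j − c_k)ᵀ (U̅, V̅) ≤ 0` for all j; the ε-active set uses
ε = 0.01 on the standardized scale. Each step computes ∇U̅ and ∇V̅ on a
shared minibatch (one backward pass per objective; constraint gradients are
their linear combinations, with standardized values recomputed per
minibatch) and descends the min-norm element of the convex hull of the
active gradients: constraint gradients only during the initialization
epochs, objectives plus constraints afterwards. Identically zero gradients
(the own-constraint ∇g_k) are excluded from the solve; if every vector is
zero the step is a stationary no-op.

The min-norm subproblem is solved analytically for one or two vectors and
by exact KKT support enumeration (all subsets, equality-constrained solve,
feasibility check) up to 16 vectors — every system the trainers produce has
at most K+2. A Frank–Wolfe fallback with away steps exists for larger
systems. Plain Frank–Wolfe alone was tried first and could not reliably
reach the 1e−4 agreement with a grid oracle within its iteration budget;
the enumeration is exact and deterministic.

Updates feed the composite direction to Adam (lr from the config,
denominator ε = 0.01 for the VAE — the published stability choice; 1e−8
for MINE, whose gradients are orders of magnitude smaller). A plain-SGD
mode exists for exact unit tests. Scalarization minimizes
`λU̅ + (1−λ)V̅` over the grid λ ∈ {1/(K+1), …, K/(K+1)} with the same
adversarial schedule. Per-candidate base seed is `seed + k`; MINE shuffle
seeds advance with the step counter.

**Extremes.** The U-extreme is the generative fit alone; the V-extreme
minimizes V over the encoder (adversarially for MINE) and then fits the
decoder with the encoder frozen. Both use raw objectives (no
standardization). `run_experiment` reuses the bounds-recording pretraining
runs as the two extremes — they are the same single-objective problems,
trained once.

**Evaluation.** U_n is the full-split mean negative ELBO. With MMD, V_n is
deterministic given the latent sample and seed. With MINE, a de-novo
statistics network is trained to convergence at the frozen encoder and the
bound is averaged over 25 fresh shuffles (`eval_shuffles`) to suppress
permutation noise. Evaluation never mutates candidate weights.

## Front metrics

Culling keeps exactly the non-dominated points (minimization convention;
coordinate-duplicates of a non-dominated point are all retained), via a
sorted sweep. Percentage = |non-dominated| / |candidates|. Hypervolume is
the rectangle-union area against a reference point that must weakly cover
every point; the default shared reference is the component-wise max plus 1%
of each range. NDC counts occupied μ×μ half-open grid cells among
non-dominated points; default μ = (largest component range)/10 with the
origin at the component-wise min. Reference and grid are shared across any
compared methods.

## Surrogate metrics

Batch entropy: mean natural-log entropy of batch composition among each
anchor cell's 50 Euclidean nearest neighbors, over 50 sampled pools of 100
anchors (all configurable). ASW: silhouette of the latent under the
*annotated* cell types (single-member types contribute silhouette 0, with a
log message). ARI/NMI/UCA compare seeded k-means (k = number of annotated
types) to the annotation; UCA uses optimal one-to-one Hungarian matching;
NMI uses arithmetic-mean normalization. The trade-off table negates
ASW/NMI/ARI/UCA/BE so every column is lower-is-better.

## Synthetic data

`simulate_zinb_dataset` draws counts from the model's own hierarchy: type
loadings `N(0, scale²)` per gene, a batch effect adding ±strength to the
pre-softmax log-mean of a random gene subset (default 30%), gene inverse
dispersions LogNormal(log 5, 0.7), per-batch log-normal libraries (default
log-mean log 2000, SD 0.3), and dropout either constant or logistic in the
log NB mean (default base rate 0.1). A `type_batch_confounding` parameter
tilts cell-type proportions linearly across batches. It exists because an
unconfounded simulation yields a degenerate, L-shaped trade-off — batch
information can be removed at almost no generative cost, so intermediate
Pareto candidates tie in V — whereas real integrated datasets (protocols
with different cell-composition sampling) couple type identity to batch.
The ordering and smoke experiments use strength 2.5 on 50% of genes with
confounding 0.95 as their study condition. The generator does not emulate
lineage trajectories, doublets, or ambient RNA; passing tests show the
method's internal consistency on data matching its own assumptions, not
robustness to real-data violations of them.

`simulate_mi_pairs` provides Gaussian class-conditional latents whose true
mutual information comes from 1-D quadrature (the class means are collinear
by construction; a Monte-Carlo cross-check is included). `toy_front` builds
quarter-circle fronts — `(1−cos t, 1−sin t)` is convex (every front point
supported by a scalarization), `(cos t, sin t)` is not — plus dominated
noise.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale, chosen
once: ordering experiment n = 1250 cells × 40 genes (K = 10, 32-unit
networks, 80/60/80 pretrain/adversarial/main epochs), smoke experiment
n = 1200 × 50 at K = 4, recovery n = 2000 × 60, MI fixtures n = 5000.
Objectives and weights are float64 throughout. Degenerate inputs: constant
latent dimensions are centered only (logged); a batch with fewer than two
cells, a zero-total cell, or a zero-width standardization range are errors;
λ outside [0, 1], non-positive μ (NDC), or a reference point that fails to
cover a front point are rejected with the offending value named.

## Known limitations

Minibatch MINE values are noisy at m = 128, so recorded V_min can be
slightly negative and standardized V̅ values can exceed [0, 1]; this is
inherent to the published bounds-recording rule. Candidate ordering in V̅
is statistically fragile for intermediate candidates whose true batch MI
differs by less than evaluation noise (~0.02 nats). MMD bandwidths are
fixed (no median heuristic by default); hypervolume is 2-D only. The
adversarial game inherits the usual instability of lower-bound
minimization: the per-step re-maximization schedule is the mitigation, not
a guarantee.
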