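# Methods

## Model

FeatureDCA models an aligned protein family jointly with a low-dimensional
conditioning vector per sequence.  A sequence `a = (a_1 … a_L)` over a
q-state alphabet (20 amino acids + gap, q = 21 by default) and a feature
vector `y ∈ R^d` are assigned the probability

    P(a, y) = P(y) · Π_k P(a_k | a_<k, y),

an exact autoregressive factorization.  Each per-site conditional is a
Boltzmann distribution over the energy

    H(a_k | a_<k, y) = − Σ_{i<k} J_ki(a_k, a_i) − h_k(a_k) − y · G_k(a_k),

i.e. a softmax over the q symbols with logits built from pairwise couplings
`J` to the already-placed sites, local fields `h`, and a per-symbol feature
embedding `G` contracted with `y`.  The parameter count is
`L(L−1)q²/2 + L(q + dq)`.  Setting d = 0 removes the `G` block and recovers
plain unconditioned autoregressive DCA (ArDCA); this reduction is enforced
by tests against an independent loop-based implementation.

In this package the conditioning features are the sequence's coordinates on
the top-d principal axes of the one-hot encoded training alignment
(dimension L·q, gap state included).  Any user-supplied real-valued feature
table can be used instead; nothing in the model core assumes PCA.

### Site ordering

The autoregressive factorization requires an ordering of the L columns.
The default is the natural left-to-right alignment order, which is the
simplest reproducible convention.  An "entropic" alternative (ranks sorted
by increasing single-site entropy), common in autoregressive DCA practice,
is available via `TrainingConfig(ordering_mode="entropic")`.  The ordering
is stored in the model archive, so scoring and sampling always use the
ordering the model was trained with.

### The feature density P(y)

`P(y)` is modeled as a single full-covariance Gaussian fitted to the
training projections, with shrinkage `Σ ← (1−s)Σ + s·(tr Σ/d)·I`
(default s = 0.01) so the covariance stays positive definite even for
small or collinear projection sets.  `P(y)` carries no sequence parameters:
it does not influence training or conditional sampling, and only enters
the joint probability used by the mutational score.  Because its exact form
is a modeling choice, the mutational scanner exposes
`include_density_term=False` to drop it and compare conditional
probabilities only.

## Training

Maximum-likelihood training decomposes into L independent convex
multinomial-logistic problems, one per rank: the rank-k problem sees the
one-hot prefix of earlier ranks plus `y` as covariates.  Each problem is
solved by L-BFGS with analytic gradients from a zero start (the uniform
model); convexity makes the optimum independent of initialization and of
data order, which the tests verify.  The objective is the *weighted mean*
of −log P(a|y) plus L2 penalties `λ_J‖J‖² + λ_h‖h‖² + λ_G‖G‖²` applied per
rank and **not** scaled by M.

Defaults, chosen to follow common autoregressive-DCA practice and fully
configurable:

| parameter | default | meaning |
|---|---|---|
| λ_J | 1e-2 | coupling penalty |
| λ_h | 1e-4 | field penalty |
| λ_G | 1e-4 | feature-embedding penalty |
| gradient tolerance | 1e-5 | L-BFGS projected-gradient stop |
| max iterations | 500 | per rank |
| similarity threshold | 0.8 | sequence reweighting identity cutoff |

Sequence reweighting (w_m = 1 / neighborhood size at fractional identity ≥
0.8, gap–gap positions counting as matches) is ON by default inside the
training objective, matching classical DCA; it is irrelevant and disabled
in tests whose data are i.i.d. model samples.  For parameter-recovery
experiments (fitting data drawn from a known unregularized model) the tests
use λ = 1e-5 and no reweighting — the principled configuration when the
ground truth itself is unregularized and the data exchangeable.

The reported per-rank NLL diagnostics include the L2 penalty (it is the
optimized objective); `negative_log_likelihood` exposes the same quantity
for arbitrary parameter values together with analytic gradients per block.

Numerical care: logits are max-shifted before exponentiation, all sequence
probabilities are accumulated in log space, and a non-finite objective
aborts training naming the offending rank.

## Sampling

Sequences are drawn ancestrally: at rank k the conditional softmax given
the already-drawn prefix and `y` is sampled by inverse transform using one
uniform variate per site from a seeded `numpy` Generator.  Sampling is
vectorized over sequences and bit-reproducible given the seed.  Generated
FASTA headers carry the conditioning vector and seed
(`>gen_<i>|y=<v1,…>|seed=<s>`).

## Evaluation metrics

* **Correlation fidelity** — Pearson correlation between the flattened
  two-site connected correlations `C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)`
  (all pairs i<j, gap state included by default, pseudocount 0) of the
  natural and generated alignments.  Natural statistics are reweighted;
  generated statistics use uniform weights (generated sets carry no
  phylogeny); both are configurable.
* **Sinkhorn divergence** — debiased entropic optimal transport
  `S(α,β) = OT_ε(α,β) − ½OT_ε(α,α) − ½OT_ε(β,β)` between PC-projection
  clouds, squared-Euclidean cost, uniform weights.  Implemented as
  stabilized Sinkhorn scaling (multiplicative updates on the Gibbs kernel
  with periodic absorption of the potentials, so the iterations remain
  exact in log space while running as matrix-vector products).  Default
  ε = 0.05 × mean pairwise squared distance of the pooled clouds, which
  makes the metric invariant to the overall scale of the embedding; clouds
  above 20 000 points are subsampled with a stated seed.  Convergence is
  declared when the L1 row-marginal violation of the implied plan falls
  below 1e-6 (checked every 5 iterations, up to 5000); non-convergence is
  recorded in the result and warned, never silently discarded.  The
  implementation is validated against an exact linear-programming /
  assignment oracle on small clouds and against the closed form for Dirac
  pairs.
* **Effective depth** — Meff/M of a generated set at identity threshold
  0.8, a diversity measure (memorizing generators collapse it toward the
  training set's value).
* **Conditioned-sampling report** — per-target mean/sd Hamming fraction,
  mean Euclidean distance of reprojected samples to the target `y` (first
  two components and full d), and the cross-target Hamming matrix.

## Mutational scanning

`ΔE(a_i→b_i) = −log [P(mutant, ỹ) / P(wild type, y)]` where ỹ is the
reprojection of the mutant (the mutation moves the sequence slightly in
feature space).  Identity substitutions are exactly 0; the antisymmetry
`ΔE(a→b) + ΔE(b→a) = 0` holds by construction and is tested.  Scans cover
the 19 non-wild-type amino acids per column by default (no gap
substitutions, matching experimental scans); lower ΔE predicts higher
fitness, and benchmark rank correlations are computed between −ΔE and
experimental scores after mapping mutations from ungapped reference
numbering onto alignment columns.

## Synthetic data generator

`make_cluster_msa` emulates the statistical structure the model is designed
to exploit, not biological realism:

* each cluster has its own per-column categorical profile, interpolated
  between a shared base profile and a cluster-specific Dirichlet draw by
  `profile_divergence` — this creates the separated PC-space clusters that
  stand in for a family's structural subclasses;
* a chosen fraction of disjoint column pairs is "coupled": a per-sequence
  fair-coin switch selects one of two product profiles for the pair,
  inducing nonzero connected correlation within a cluster without building
  a full Potts sampler.

It does **not** emulate phylogenetic correlations between sequences, gap
patterns, indel structure, or the length/conservation profiles of real
Pfam families.  Consequently, passing tests demonstrate the correctness of
the machinery and its behavior under controlled cluster/coupling structure,
not performance on real protein data.

Enumerable tiny models (q^L ≤ 4096) with i.i.d. normal parameters provide
brute-force oracles for normalization, sampling accuracy and ΔE; the exact
OT oracle is capped at 64 points so every oracle runs in well under a
second.

## Problem sizes used by the test and acceptance pipelines

Chosen as the package's own desk-scale study conditions:

* generativity / conditioning control: two clusters of 2500 (M = 5000),
  L = 30, q = 8, profile divergence 0.8, coupled fraction 0.2; d = 2 vs
  d = 0; Sinkhorn on 2000-point subsamples.
* memorization trend: two clusters of 200 (M = 400), L = 25, q = 6, with
  d swept over {0, 2, 8, 32, full rank}; at full rank the projection
  determines the one-hot encoding exactly, so the trained model can (and
  does) reproduce its conditioning sequence almost deterministically.
* recovery: L = 5, q = 3, d = 1 ground truth, M = 20 000 samples.
* sampling accuracy: 200 000 draws against an 81-state enumeration.

## Known limitations

* Training materializes the M × (L·q) one-hot matrix densely; families with
  very long alignments and deep MSAs need batching that is not implemented.
* The Gaussian P(y) is unimodal while PC projections of clustered families
  are multimodal; this only affects the density term of ΔE (off by a flag),
  not training or sampling.
* PCA is unweighted by default (a sequence-weighted variant is behind a
  flag); with heavily redundant MSAs the leading axes can be dominated by
  overrepresented subfamilies.
* The Sinkhorn divergence at very small ε converges slowly; the default
  scale-relative ε is meant for comparing clouds, not for approximating
  exact OT.
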