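# Methods

## Model

The package assumes a weighted undirected gene/protein association network
`G` with confidence weights `w_ij ∈ (0, 1]` (STRING-style 0–1000 scores are
divided by 1000 at load time), and that the causal gene of a phenotype sits
inside a *disrupted expression module*: its network neighbors are
differentially expressed between affected and control samples even when its
own transcript responds weakly. All strategies operationalize "neighborhood"
through matrices derived from `G`: the combinatorial Laplacian `L = D − A`
(symmetric, PSD) for the graph kernels, and the random-walk operator
`W = D⁻¹A` (row-stochastic, generally non-symmetric on weighted graphs) for
the diffusion strategies.

Self-loops are discarded at load (the Laplacian and transition formulations
assume none); duplicate edge records collapse to the maximum weight
(strongest evidence wins); degree-zero nodes get a unit self-row in `W`, so
isolation is absorbing: an isolated gene keeps its own expression signal
under diffusion and can still rank highly on that signal alone. Benchmark
genes absent from a sparse network are added as isolated nodes rather than
dropped, for the same reason.

Network statistics use the directed-record convention (each undirected edge
counts twice), matching how interaction databases report their sizes; the
average node degree is records per gene.

## Kernels and the similarity network

Three kernels are available for kernel ridge regression:

| kernel | formula | default α | constraint |
|---|---|---|---|
| Laplacian exponential diffusion | `e^{−αL}` | 0.5 | dense, n ≤ cap |
| regularized Laplacian | `(I + αL)⁻¹` | 1.0 | always PD |
| regularized commute time | `(D − αA)⁻¹` | 0.9 | α ∈ (0,1), no isolated nodes |

The diffusion kernel uses the *negative* exponent: diffusion must decay
with distance, and `e^{−αL}` is the PSD random-walk kernel (its rows sum to
1 because `L·1 = 0`). It is computed by symmetric eigendecomposition of
`L`, which is exact and preserves symmetry/PSD-ness; the test suite checks
it against `scipy.linalg.expm` as an independent oracle. Dense computation
is guarded by a configurable node cap (default 3,000); beyond it the
matrix-free Arnoldi strategy is the intended path (no Nyström or low-rank
approximation is attempted).

A kernel becomes the *similarity network* by cosine normalization
`K_N[i,j] = K[i,j]/√(K[i,i]K[j,j])` followed by double-centering
`K_C = K_N − (1/n)J K_N − (1/n)K_N J + (1/n²)(1ᵀK_N 1)J`. Normalization is
applied first, centering second. Centering necessarily produces negative
entries and destroys the unit diagonal — a centered "similarity" is a
covariance-like quantity, not a probability — which is why neighborhood
selection (below) filters on positive centered similarity.

## Kernel ridge regression ranking

A candidate's neighborhood is the candidate itself plus its most similar
other genes under `K_C`, at most `nn = 50` genes in total and never fewer
than two. Only strictly positive centered similarities qualify as
neighbors; if fewer than two genes qualify, the two most similar genes are
used regardless of sign. Including the candidate in its own regression set
is deliberate: a gene is always its own most similar gene, and it keeps the
smoothed value responsive to the candidate's own expression — without it,
erasing a candidate's own differential expression would not change its
score at all, contradicting the observed dependence of every strategy on
the causal gene's own signal (see the sensitivity analysis below).

With `K` the neighborhood-restricted kernel, `Y` the neighborhood's
differential expression and `K_x` the candidate's similarities to the
neighborhood, the smoothed value is `ŷ = K_xᵀ (K + λI)⁻¹ Y` (default
`λ = 1`). `ŷ` is linear in `Y`, shrinks to 0 as `λ → ∞`, and for a single
unit-similarity neighbor reduces to `y/(1 + λ)`.

## Diffusion strategies

**Heat kernel.** The preference vector `p₀` (by default scenario 3: every
gene's differential expression) is row-iterated N times through
`I − (α/N)(I − W)`, a first-order discretization of `p₀ e^{−α(I−W)}`
(defaults `α = 0.5`, `N = 2`). Convergence is first order — the sup-norm
error against the exact operator exponential roughly halves when N doubles
— but ranking quality saturates at very small N, which is why N = 2 is the
default. Only sparse matrix–vector products are used. Four preference
scenarios are implemented: binary candidate membership, candidate
expression only, all expression (default), and binary significance
(p < 0.05).

**Arnoldi.** The same diffusion approximated in an m-dimensional Krylov
subspace: Arnoldi iteration with one re-orthogonalization pass builds
`V_m`, `H_m` from the start vector `v` (the full expression vector), and
`u = ‖v‖ V_m e^{αH_m} e₁`. Happy breakdown before m steps uses the achieved
subspace (the result is then exact); `m = n` reproduces the dense operator
exponential to floating-point accuracy, and the approximation error is
non-increasing in m. Because the heat strategy multiplies a *row* vector
into the operator while a Krylov method acts on columns, the Arnoldi
operator is the adjoint `−(I − W)ᵀ` by default, making the two strategies
agree as m grows on any (also non-symmetric) `W`; flags expose the
untransposed operator and the growing sign `e^{+α(I−W)}` for comparison.
An all-zero expression vector is an error ("no signal to diffuse") rather
than a silent uniform ranking.

**Direct neighborhood.** `x̂ᵢ = a·|xᵢ| + (1−a)·mean{|xⱼ| : w_ij > ε}` over
direct neighbors (defaults `a = 0.5`, `ε = 0.15`; the threshold is strict).
At `a = 1` this reduces exactly to the baseline. Genes without surviving
neighbors score `a·|xᵢ|`.

**Score orientation.** All rankings sort on |score| by default. Knockout
(and many disease) genes are down-regulated; ranking literally by
descending signed value would place the strongest positives first and the
knockouts last. A `signed` flag restores literal ordering. Ties break
lexicographically by gene identifier, so all five strategies are
deterministic and permutation-equivariant in gene labels.

## Differential expression measures

* `log2_ratio`: `log2(mean(case)/mean(control))` on linear-scale
  intensities (probe-level preprocessing is upstream of this package).
* `t_stat`: regularized t in the CyberT style. Per arm, each gene's sample
  variance is shrunk toward a background `s₀²` — the mean within-arm
  variance over a sliding window of `window = 101` genes adjacent in mean
  intensity rank — with `prior_df = 10` pseudo-observations:
  `s̃² = (prior_df·s₀² + (r−1)s²)/(prior_df + r − 1)`. The statistic is a
  Welch-style t on shrunken variances; two-sided p-values use
  `(prior_df + r_case − 1) + (prior_df + r_ctrl − 1)` degrees of freedom,
  crediting the background estimate with its pseudo-observations. With
  `prior_df = 0` and ≥ 2 replicates this is exactly Welch's t. For
  single-replicate arms the windowed spread of single measurements across
  intensity-adjacent genes supplies the variance, so the measure stays
  defined. Under a seeded global null the realized false-positive rate at
  p < 0.05 is 3–5%, i.e. mildly conservative, as expected from shrinkage.
* `sig_log2_ratio`: the log2 ratio where p < 0.05 (strict), else 0. No
  multiple-testing correction is applied — the gate is a raw-p filter by
  design, not an inference procedure.

Window size and prior degrees of freedom follow CyberT's defaults and are
configurable; whether the original tool's paired/pooled design conventions
match is not recoverable, so both knobs are exposed.

## Synthetic benchmark

`SyntheticSpec` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1,000 | network size |
| network_model | preferential attachment, m = 3 | hub-rich, right-skewed degrees |
| weight_range | U(0.15, 1] | association confidences |
| module_depth | 2 | graph radius of the planted module |
| delta0 | 3.0 | log2-scale module effect at distance 0 |
| decay | 0.5 | effect multiplier per distance step |
| self_attenuation | 0.75 | planted gene keeps 25% of its own effect |
| replicates | 4 + 4 | per-arm array replicates |
| noise_sigma | 0.3 | log2-scale replicate noise SD |
| baseline | log2 ~ N(7, 1) | lognormal linear intensities |
| n_candidates / n_cases | 100 / 40 | benchmark shape |

Per case, a center gene of degree ≥ 3 is drawn, genes within the module
radius get a *negative* log2 shift `−delta0·decay^d` (knockouts are
down-regulated), the center's own shift is attenuated to
`−delta0·(1 − self_attenuation)`, and candidates are the center plus 99
genes drawn uniformly from the rest. Uniform sampling means some candidates
land inside the planted module by chance and out-respond the attenuated
center — exactly the failure mode of the expression-only baseline that
network smoothing is meant to fix. The attenuation parameter also supports
the sensitivity analysis: setting the center's own signal to zero after
measure computation strictly worsens its mean rank for every strategy.

The generator is fully deterministic: the spec seed fans out through named
`SeedSequence` streams (network, per-case), and benchmark directories are
byte-identical across runs of the same spec. What the generator does *not*
emulate: probe-level artifacts, correlated replicate noise,
intensity-dependent variance beyond lognormality, alias/orthology mapping
noise, or the topology of any specific interaction database release.
Passing tests therefore show the strategies behave correctly *given* the
disrupted-module model, not that any particular database/chip combination
will reach a particular AUC.

## Numerical choices

* Kernel solves use `scipy.linalg.solve` with symmetric/positive hints;
  systems are PD by construction (`I + αL`, `K_C + λI` with `λ > 0`,
  `D − αA` for α < 1 on isolated-free graphs). Conditioning above 1e12 is
  logged, never silently ignored.
* The Arnoldi breakdown tolerance is `1e−12·‖v‖`; symmetrization
  `(K + Kᵀ)/2` is applied after dense kernel computation to scrub
  round-off asymmetry.
* Edge thresholding is strictly `w > ε`, keeps the node set (nodes may
  become isolated), and is monotone in ε.
* Top-k% counts include the boundary rank `ceil(fraction·n)`.
* Pooled ROC sweeps a common rank threshold k = 0..max(nᵈ); each case
  contributes one positive and `n_d − 1` negatives. For a single case the
  pooled AUC equals the Mann–Whitney probability `(n − r)/(n − 1)`.
  Per-case-averaged AUC is also provided; pooling is the default.

## Problem sizes

The default test and acceptance runs use 1,000-gene networks with 40
planted cases (200 for the null calibration), sizes at which every
strategy, including the dense-kernel ridge path, completes in seconds
while still exhibiting the skewed-degree, sparse-module structure the
method targets. Property tests run on graphs of 5–30 nodes where dense
operator exponentials serve as exact oracles.

## Known limitations

* No correction for degree bias: diffusion favors highly connected genes;
  a randomization-based baseline adjustment is out of scope.
* Exact string identifier matching only — no alias or orthology mapping.
* The centered similarity network is not a probability ("values between 0
  and 1" holds for the normalized kernel, not after centering); downstream
  code treats negative centered similarity as non-neighborhood.
* Pooled vs averaged ROC conventions differ when candidate-list sizes vary
  across cases; with equal sizes (the benchmark default) rankings of
  strategies are unaffected.
* An isolated gene can only be ranked on its own signal; a strongly
  responding neighborhood elsewhere will dominate it.
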