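# netprio

Network-based candidate gene prioritization from differential expression.

## The problem

Genetic studies of constitutional disorders routinely end with a list of
~100 positional candidate genes and no prior knowledge — no known disease
genes, no annotated pathway — to pick the promising ones. When case/control
expression data for the relevant tissue exists, the standard genetic
procedure ranks candidates by their own differential expression. That
baseline fails whenever the causal gene's own transcript barely responds
while its *downstream neighbors* do: the signature of a disrupted module
around the causal gene in a functional association or protein–protein
interaction network.

`netprio` scores a candidate gene by how differentially expressed its
network neighborhood is. It implements four network-aware strategies plus
the expression-only baseline, a knockout-benchmark evaluator, and a seeded
synthetic benchmark generator, for bioinformaticians who have an edge-list
association network (e.g. STRING-style confidence scores), case/control
expression matrices, and a candidate list.

## Strategies

With adjacency `A`, degree diagonal `D`, combinatorial Laplacian
`L = D − A` and random-walk matrix `W = D⁻¹A`:

1. **Kernel ridge regression ranking** — build a graph kernel
   (Laplacian exponential diffusion `K_LED = e^{−αL}`, regularized
   Laplacian `(I + αL)⁻¹`, or regularized commute time `(D − αA)⁻¹`),
   normalize and center it into a similarity network, then smooth each
   candidate's differential expression over its ≤ 50 most similar genes:
   `ŷ = K_xᵀ (K + λI)⁻¹ Y`.
2. **Heat kernel diffusion ranking** — iterate a preference vector holding
   all expression values through `p ← p (I − (α/N)(I − W))`, a discrete
   N-step approximation of `p₀ e^{−α(I−W)}`; `N = 2` already ranks well.
3. **Arnoldi diffusion ranking** — approximate the same diffusion's action
   on the expression vector in an m-dimensional Krylov subspace
   (`u ≈ ‖v‖ V_m e^{αH_m} e₁`), matrix-free, so it scales to networks far
   beyond dense-kernel reach.
4. **Direct neighborhood ranking** — no diffusion: `x̂ᵢ = a·|xᵢ| +
   (1−a)·mean{|xⱼ| : w_ij > ε}` over direct neighbors.
5. **Simple expression ranking** — the baseline: the candidate's own
   differential expression.

Differential expression comes as the log2 ratio, a CyberT-style regularized
t statistic (intensity-windowed Bayesian variance shrinkage), or the
significant log2 ratio (log2 ratio gated at p < 0.05). Rankings sort by
score magnitude — knockout and disease genes are typically down-regulated —
with lexicographic tie-breaks for determinism.

Evaluation follows the knockout-benchmark protocol: the experimentally
deleted gene is the known positive among its candidates; reported metrics
are per-case rank, pooled ROC/AUC over rank thresholds, top-10%/top-20%
counts, and the error reduction `100·(x_new − x_base)/(x_max − x_base)`
versus the baseline.

## Worked example

```python
from netprio import (SyntheticSpec, generate_network, plant_knockout_case,
                     build_matrices, compute_measure,
                     simple_expression_ranking, heat_kernel_diffusion_ranking)

spec = SyntheticSpec(n_genes=500, n_cases=1, seed=11)
net = generate_network(spec)
case, ds = plant_knockout_case(net, spec, case_seed=2024, case_id="demo")
de = compute_measure(ds, "sig_log2_ratio")
mats = build_matrices(net)

baseline = simple_expression_ranking(de, case.candidates)
heat = heat_kernel_diffusion_ranking(mats, de, case.candidates)
print(f"knockout gene: {case.knockout}")
print(f"baseline rank: {baseline.rank_of(case.knockout)} / {len(baseline)}")
print(f"heat-kernel rank: {heat.rank_of(case.knockout)} / {len(heat)}")
for rank, gene, score in heat.to_frame().head(3).itertuples(index=False):
    print(f"  {rank}  {gene}  {score:.3f}")
```

prints

```
knockout gene: G00120
baseline rank: 2 / 100
heat-kernel rank: 1 / 100
  1  G00120  1.647
  2  G00057  1.574
  3  G00077  0.738
```

The planted knockout's own response is attenuated to 25% of the module
effect, so the baseline ranks a strongly responding downstream gene above
it; the diffusion recovers the knockout at rank 1 because its *entire*
neighborhood responds. The score column is the magnitude of the diffused
expression signal at each candidate's node.

The same pipeline is available from the shell:

```sh
netprio simulate --seed 5 --out bench/
netprio de --case bench/cases/case001.case.tsv \
           --control bench/cases/case001.control.tsv \
           --measure sig_log2_ratio --out case001.de.tsv
netprio rank --strategy heat --network bench/network.tsv \
             --de case001.de.tsv \
             --candidates bench/cases/case001.candidates.txt \
             --out case001.heat.tsv
netprio evaluate --rankings rankings/ --truth bench/truth.tsv \
                 --out report.json
netprio stats --network bench/network.tsv
```

Every command writes a `.provenance.json` sidecar (tool version, config
hash, input hashes); identical config and seed give byte-identical output.

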