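# grnsim

Simulation of gene regulatory network (GRN) structure and function, built
for studying how network architecture shapes the outcome of large-scale
perturbation experiments such as genome-wide Perturb-seq screens.

The package answers questions of the form: *if a regulatory network is
sparse, modular, and has master regulators, what should a systematic
knockout screen see — and what can coexpression alone recover?* It is aimed
at computational biologists benchmarking GRN-inference methods, designing
perturbation experiments, or exploring the parameter space of plausible
regulatory architectures.

## What it implements

**Network generator.** Directed scale-free graphs with pre-specified group
structure, grown by preferential attachment. Five knobs control the
architecture: sparsity `p` (mean regulators per gene ≈ `1/p`), number of
groups `k`, within-group affinity `w` (within-group edge fraction ≈
`w/(w+k−1)`), and degree-uniformity terms `δin`, `δout` (larger values
flatten the in-/out-degree distributions; small `δout` yields master
regulators).

**Expression model.** A stochastic differential equation per gene,
integrated with the Euler–Maruyama scheme:

    x' = x + Δt·(σ(α + βᵀx) − ℓ·x) + 𝒩(0, Δt·s²·diag(x))

with σ the logistic sigmoid, `α` innate transcription, `ℓ` decay, `β` the
signed regulator→target weights (nonzero exactly on network edges,
|β| ≥ 1), and `s` the intrinsic noise magnitude. Steady states
`x* = σ(α + βᵀx*)/ℓ` are found by forward simulation with a running-mean
convergence criterion, and their linear stability is read off the
eigenvalues of the Jacobian `J = βᵀ·diag(σ') − diag(ℓ)`.

**In-silico screens and analyses.** Systematic single-gene knockouts
(`β`-row nullification, re-equilibration, effects as
`log2FC = log2(x̄_ko) − log2(x̄_base)`), hub statistics, distance- and
module-stratified effect distributions, single-"cell" sampling and
coexpression, effect-degree distributions with fixed-discovery-rate
thresholding and Kolmogorov–Smirnov matching against empirical significance
tables, a logit regression of hub fractions on generator parameters,
truncated-SVD gene programs, and canonical correlations between program
spaces.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Generate a 500-gene network with 5 groups and strong modularity, run the
full knockout screen, and summarize:

```sh
grnsim generate --n 500 --p 0.25 --k 5 --w 40 --delta-in 30 --delta-out 3 \
    --seed 1 --out runs/net1
grnsim screen --network runs/net1 --seed 1 --out runs/net1
cat runs/net1/summary.json
```

which prints (numbers from this exact invocation):

```
INFO generated n=500 edges=2159 mean_in=4.32 within=0.898
```

```json
{
 "converged": true,
 "stable": true,
 "leading_eigenvalue_real_part": -0.7900148516254129,
 "n_hub_ko": 0,
 "n_hub_target": 0,
 "n_expressed": 499
}
```

Reading the output: the generator delivered a mean in-degree of 4.32 ≈
`1/p = 4` and a within-group edge fraction of 0.898 ≈ `w/(w+k−1) = 40/44`;
the expression model reached a converged, linearly stable equilibrium
(leading Jacobian eigenvalue real part −0.79 < 0); 499 of 500 genes are
expressed above the noise floor; and the screen found no hub knockouts or
hub targets — no gene whose removal shifts at least 100 other genes by more
than 0.1 log2 units — the signature of a sparse, modular architecture that
confines perturbation effects.

The same pipeline is available as a library:

```python
import numpy as np, grnsim as g

gp = g.GeneratorParams(n=500, p=0.25, k=5, w=40, delta_in=30, delta_out=3, seed=1)
grn = g.generate_network(gp)
rng = np.random.default_rng(1)
params = g.sample_expression_params(grn, rng)      # α, ℓ, β, s=1e-4
state = g.find_steady_state(params, rng=rng)       # burn-in + convergence
effects = g.ko_screen(grn, params, state, rng=rng) # 500 knockouts, batched
print(g.hub_summary(effects))
```

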