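# timedhn

Timed hazard networks: continuous-time Markov chain inference of the
dependency graph behind irreversible genetic-event accumulation in cancer
progression, from cross-sectional binary profiles.

## The problem

Cross-sectional tumour cohorts record which genetic events (driver
mutations, copy-number changes) each sample has accumulated, but not when.
Oncogenetic graph methods infer a directed graph over events — an edge
`i → j` meaning event `i` raises the rate of event `j` — from those
profiles alone.  `timedhn` models the accumulation as a continuous-time
Markov chain on the `2^n` binary profiles, parameterized by an `n × n`
hazard matrix `R` (diagonal: spontaneous rates; off-diagonal `R[i,j]`: the
extra rate on `j` once `i` has occurred, competing exponential clocks), and
treats each sample's unknown progression time as an explicit variable:

    P(x, t) = (e^{tQ})_{1, dec(x)},      Q built from R on the hypercube

    maximize over R, t:   (1/|D|) Σᵢ log P(xᵢ, tᵢ) − λ‖R‖₁
    subject to            R ≥ 0,  t ≥ 0,  ‖t‖₁ = c.

Times may be fixed to externally supplied pseudo-times or inferred jointly
with the network.  Likelihood and exact gradients are computed in the
`2^k`-state sub-hypercube below each observed profile (`k` = events
accumulated), so cost scales with profile sparsity, not with `n`; the
gradient of the matrix-exponential entry comes from one exponential of a
doubled block matrix (the Fréchet derivative trick).  After fitting, edges
below `0.1·max(R)` are pruned, samples can be ranked by the conditional
expected progression time `E(t|x)`, and each profile's maximum-likelihood
accumulation order is found by brute force over permutations.

Audience: computational biologists studying cancer progression or any
irreversible cumulative process with cross-sectional binary observations.

## Worked example

```python
import numpy as np
from timedhn import TimedHazardNetwork, SimulationConfig, generate_dataset

# simulate a cohort from a random 8-event forest-structured hazard network
data, truth = generate_dataset(
    SimulationConfig(n=8, topology="forest", sample_size=500, seed=7)
)

est = TimedHazardNetwork(
    lam=1e-2, optimizer="adam", learning_rate=0.05, max_iter=400, tol=0.0,
    random_state=7,
).fit(data.matrix())

print("inferred edges:", sorted((int(i), int(j)) for i, j in zip(*np.nonzero(est.adjacency_))))
print("true edges:    ", sorted((int(i), int(j)) for i, j in zip(*np.nonzero(truth.adjacency))))
print("pseudo-time of first 3 samples:", est.predict(data.matrix()[:3]).round(2))
```

```
inferred edges: [(1, 5), (3, 1), (3, 2), (7, 1)]
true edges:     [(1, 0), (1, 5), (1, 7), (3, 1), (3, 2)]
pseudo-time of first 3 samples: [2.66 2.13 0.67]
```

Three of the five true inter-event dependencies are recovered exactly; one
deep edge (`1 → 7`) comes back reversed and one (`1 → 0`) is absorbed into
a spontaneous rate — the expected behaviour at this scale, see the caveat
on small-`n` benchmarks in `docs/methods.md`.  The pseudo-times are in the
fitted gauge (mean sample time 1): the third sample is much earlier in
progression than the first two.

The same pipeline is scriptable from the shell:

```bash
timedhn simulate --n 8 --topology forest --samples 500 --seed 7 --out-prefix sim
timedhn fit --data sim.profiles.tsv --optimizer adam --lr 0.05 --max-iter 400 --out fit.json
timedhn threshold --fit fit.json --frac 0.1 --out pruned.tsv --dot graph.dot
timedhn evaluate --truth sim.truth.tsv --inferred pruned.tsv --out metrics.json
timedhn pseudotime --fit fit.json --data sim.profiles.tsv --out pt.tsv
```

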