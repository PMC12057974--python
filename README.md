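# traitnet

Leaf trait networks along an environmental gradient: construction, topology,
variability, and climate/soil variance partitioning.

## The problem

Leaf functional traits do not vary independently: morphology, stoichiometry
and anatomy are coordinated, and the *structure* of that coordination shifts
with the environment. A leaf trait network (LTN) makes the coordination
explicit — nodes are traits, and an edge joins two traits whose Pearson
correlation satisfies |r| > 0.2 with p < 0.05. Comparing LTN topology across
sites then asks an ecological question directly: does climate or soil shape
how tightly a species' leaf traits are integrated?

`traitnet` implements that analysis end to end for a multi-site survey
design (the motivating case: *Populus euphratica*, 20 sites × 15 trees × 27
traits along a desert river):

1. **netbuild** — pairwise Pearson correlations (pairwise-complete, exact
   t-distribution p-values) thresholded into one network per site plus a
   pooled network; negative correlations form edges like positive ones, the
   sign is an attribute.
2. **netmetrics** — whole-network parameters on the binary adjacency:
   edge density 2E/N(N−1), diameter and average path length over reachable
   pairs, average local clustering coefficient, and Newman modularity
   Q = Σ_c (e_cc/m − (d_c/2m)²) of a deterministic greedy (CNM) partition;
   node parameters: degree, Wasserman–Faust closeness, Brandes betweenness.
3. **variability** — coefficients of variation (100·sd/mean) per trait, per
   functional category, and per network parameter across sites.
4. **env_assoc** — correlation-matrix PCA of the climate (BIO1–BIO19) and
   soil tables, greedy |loading| representative selection, parameter–factor
   correlations, and Ward clustering of sites.
5. **varpart** — two-block variance partitioning: adjusted-R² fractions
   unique to climate, unique to soil, and shared (inclusion–exclusion over
   climate-only / soil-only / combined OLS fits), with 999-permutation
   significance tests per block.
6. **synth** — a seed-deterministic generator of complete synthetic studies
   with planted trait modules, an environmental gradient that modulates
   within-module correlation strength, and block-structured climate/soil
   tables, so every stage has testable ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_build_networks.py
python analysis/03_trait_variability.py
python analysis/04_environment_association.py
python analysis/05_variance_partition.py --seed 1
```

From `03_trait_variability.py`:

```
network-parameter variability across sites (CV %):
parameter
diameter                          33.89
edge_density                      30.17
average_path_length               25.99
modularity                        24.63
average_clustering_coefficient    19.29
```

Diameter varies most across sites and the average clustering coefficient
least: long geodesics appear and vanish as site networks gain or lose a few
bridging edges, while local triangle density is buffered by the persistent
within-module correlation. From `05_variance_partition.py`:

```
climate fraction exceeds soil fraction for 5/5 parameters
```

which is exactly what the generator plants (the gradient that drives
network structure is carried by the climate factor block; soil only echoes
it weakly) — the pipeline recovers the dominant driver.

The same run is available as one call:

```python
from traitnet import run_pipeline, RunConfig
from traitnet.synth import generate_study

traits, climate, soil, truth = generate_study(seed=1)
report = run_pipeline(traits, climate, soil, RunConfig(rng_seed=1))
print(report.param_cvs)          # spread of the five parameters across sites
print(report.varpart)            # climate/soil fractions + permutation p
```

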