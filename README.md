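# bcti

Stage-wise Bayesian-network inference of gene regulatory networks (GRNs)
with critical-transition detection from the trajectory of the network
score.

## The problem

Complex diseases and developmental programs progress through an ordered
sequence of stages. Just before an abrupt shift between stable system
states, a core group of genes shows two tell-tale changes — sharply
increased expression fluctuation and strongly coordinated co-variation
(the *dynamic network biomarker* signature). `bcti` detects this
pre-transition ("critical") stage while simultaneously reconstructing the
directed regulatory network at every stage, so the early-warning signal
comes with a causal-structure read-out instead of a bare statistic.

Intended users: computational biologists with a genes × samples
expression matrix per stage (tumor stages, developmental time points, a
swept control parameter) who want both per-stage GRNs and a principled
call of the tipping-point stage.

## Method

For each stage, with expression matrix of m genes over n samples:

1. **Skeleton (CBN).** Pairwise Gaussian mutual information
   `I(i,j) = -½ ln(1 − ρ²ᵢⱼ + ε)` (ε = 10⁻⁵ guards the log); gene pairs
   with `I ≥ T` (default T = 0.1 nats, i.e. |ρ| ≳ 0.43) form the
   undirected *correlation basis network* that constrains the search.
2. **Scoring.** Each gene is a linear structural-equation model (SEM) of
   its parents on mean-centered data. A DAG G is scored by the
   MDL/BIC-style

       H(G) = Σₛ [ Fₛ + λ·|Pa(Xₛ)|·ln n ],

   where Fₛ is the least-squares residual sum of squares of gene s on
   its parents (minimum-norm solution under collinearity). Lower is
   better.
3. **Search.** Restart hill-climbing over DAGs: add / delete / reverse
   moves restricted to the skeleton, best improving move accepted until
   none improves, I seeded restarts (default 10), minimum-H restart wins.
4. **Detection.** The stage score S(t) is the H of stage t's optimal
   network. Because a node with no useful parents is scored by its
   centered sum of squares, S(t) rises with expression variance. Stage t
   is called critical when a one-sample t-test finds the history
   S(1..t−1) significantly different from S(t) (default two-sided,
   α = 0.05). Structural instability — TPR against a reference network
   and agreement among restart networks — is reported as corroboration.

The package also ships two benchmark generators: a Michaelis–Menten SDE
circuit swept through a saddle-node bifurcation by a control parameter q
(critical slowing down inflates endpoint variance as q → 0), and a
stage-wise sampler with a planted critical stage (exact variance
inflation plus a shared latent factor across a core subnetwork), plus
direction-sensitive confusion-count evaluation against gold standards.

## Worked example

```python
import numpy as np
from bcti import (
    PlantedTransitionConfig, SearchParams, compute_bcti_series,
    detect_critical_state, generate_planted_transition,
)

config = PlantedTransitionConfig(seed=7)     # 20 genes, 6 stages, critical at 4
data, gold = generate_planted_transition(config)
series = compute_bcti_series(data, search_params=SearchParams(seed=3))
stage, p_values = detect_critical_state(series)
print("scores:", [round(s, 1) for s in series.scores_S])
print("p:", [round(p, 4) for p in p_values[2:]])
print("critical stage:", stage)
```

prints

```
scores: [1028.1, 991.5, 979.6, 1789.3, 1044.6, 936.6]
p: [0.3469, 0.0003, 0.4967, 0.2147]
critical stage: stage4
```

S(t) is flat (~1000) over the first three stages, surges ~80 % at the
planted stage 4 (p = 0.0003 against its history — the only stage below
α = 0.05), and relaxes afterwards: the transition is called at stage 4,
exactly where the generator planted the inflated-variance,
inflated-correlation core.

The same pipeline from the shell:

```bash
bcti simulate planted --seed 3 --out-prefix run1
bcti detect --expr run1_expr.tsv --stages run1_stage_map.tsv \
     --stage-order stage1,stage2,stage3,stage4,stage5,stage6 \
     --seed 5 --reference run1_gold.tsv --out series.json
bcti evaluate --predicted net.tsv --gold run1_gold.tsv
```

## Layout

- `bcti.core_io` — containers (ExpressionMatrix, StagedDataset, networks)
  and TSV/CSV readers/writers
- `bcti.cbn` — Gaussian mutual information and the skeleton
- `bcti.scoring` — SEM fits and the H score
- `bcti.search` — restart hill-climbing, exhaustive oracle
- `bcti.detection` — score trajectory, t-test, instability read-outs
- `bcti.simulator` — SDE bifurcation benchmark, planted-transition sampler
- `bcti.evaluation` — confusion counts, TPR, accuracy
- `bcti.cli` — the `bcti` command

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
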