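# Methods

## Model

Each stage of an ordered progression is modeled independently as a
linear-Gaussian Bayesian network over the m genes: a DAG G in which every
gene s is an intercept-free linear combination of its parents plus
Gaussian noise (a structural equation model, SEM). Expression rows are
mean-centered within the stage before fitting, which stands in for the
missing intercept; they are deliberately **not** scaled to unit variance,
because the detection signal lives in the variance (below).

Structure learning is score-based. The score of a DAG is

    H(G) = Σₛ [ Fₛ + λ · |Pa(Xₛ)| · ln n ],

with Fₛ the residual sum of squares of gene s regressed on its parents
and the penalty counting one ln n per estimated coefficient (number of
parents). H decomposes over nodes, so a single-edge move changes only the
touched nodes' terms; the search exploits this with exact incremental
rescoring (verified move-by-move against full rescoring in the tests).
Natural logarithms are used throughout — in the penalty and in the
mutual-information threshold — so both are in nats and λ = 1 reduces the
penalty to the familiar BIC form. λ is exposed (`--lambda`) because no
single value suits every noise regime; center_genes is exposed for data
already centered upstream.

Two properties of H carry the biology:

* **Variance monotonicity.** A parent-free node scores its centered sum
  of squares, (n−1)·sample variance; scaling the data by c > 1 strictly
  increases H for any fixed DAG with a nonzero residual. Hence the
  per-stage score S(t) = H(optimal DAG at t) rises when a gene group's
  fluctuation inflates — the early-warning signal.
* **Collinearity sensitivity.** Strongly co-varying parents make the
  per-node regression ill-conditioned. Fits use minimum-norm least
  squares (SVD); no ridge term is added, because regularizing the
  collinearity away would suppress exactly the instability that marks
  the pre-transition state. The residual stays well-defined; which
  parent set wins becomes unstable, which is measured, not hidden.

## Skeleton

The undirected correlation basis network keeps gene pairs whose Gaussian
mutual information −½·ln(1 − ρ² + ε) reaches T. Defaults ε = 10⁻⁵ (guards
the log as |ρ| → 1) and T = 0.1 nats, equivalent to an absolute-correlation
cutoff √(1 − e^(−2T) + ε) ≈ 0.426. Zero-variance genes have undefined ρ and
are treated as independent with a logged warning. A discrete/binned MI
estimator is intentionally out of scope: under the Gaussian assumption
the closed form is exact and estimator-free. Skeletons are built per
stage (each stage's data may imply different adjacency); pooling across
stages would blur exactly the rewiring the method tracks.

## Search

Restart hill-climbing. An initial DAG draws a uniform random topological
order and keeps each skeleton edge with probability 0.5 oriented along
that order — acyclic by construction, skeleton-consistent, and diverse
across restarts. Moves are add / delete / reverse, with additions and
reversals restricted to skeleton pairs and vetted by a DFS reachability
check. Per iteration the best candidate in each move class is formed and
the overall best accepted iff it lowers H by more than 10⁻⁹ (guards
against float churn). Ties break lexicographically (add < delete <
reverse, then source, then target index) and the lowest restart index
wins ties across restarts, so the whole inference is a pure function of
(data, parameters, seed). Default 10 restarts; on 4-gene systems the
search matches brute-force enumeration over all skeleton-consistent DAGs
in 100/100 seeded trials (the enumeration is kept in the package as
`exhaustive_search`, scored by the non-incremental path on purpose).

Local scores are memoised by (child, parent-set), shared across restarts
of the same stage — the dominant cost saving, since restarts revisit the
same local structures.

## Detection

S(t) is tested against its own history with a one-sample t-test: the
history (S(1), …, S(t−1)) is the sample, S(t) the hypothesized mean,
t−2 degrees of freedom. The first testable stage is the third (two
history points give the first sample SD). Two-sided by default; a
one-sided `greater` option exists since theory predicts a rise. A
zero-variance history degenerates to p = 1 on equality (|Δ| ≤ 10⁻¹²)
else p = 0. The earliest stage with p < α is called critical.

Raw H scales with n, so stages with unequal sample sizes are not directly
comparable; scores are reported raw by default (faithful to the score's
definition) and `--equalize-n` subsamples every stage to the smallest
stage size with a fixed seed when comparability matters.

Structural instability is reported alongside the call, never as a gate:
TPR of the stage network against a reference (when one exists) and the
mean pairwise edge-set Jaccard among the restart networks. Seeds derive
from one master seed (stage j: (seed·10007 + j) mod 2³¹; restart k of a
stage: SeedSequence([stage_seed, k])).

## Benchmark generators

**Planted transition.** m genes (default 20), of which a core (default 8)
follows a linear SEM over a known DAG (coefficient 0.8, noise SD 1 —
child–parent correlations ≈ 0.6, comfortably above the skeleton cutoff);
the rest are independent noise. At the designated critical stage each
core gene g gains extra fluctuation sized by its theoretical SEM variance
v_g: a shared latent factor with loading √(boost·inflation·v_g) plus
private noise making the total variance exactly inflation·v_g. Every core
gene's variance multiplies by exactly `variance_inflation` (default 4)
and every core pair's correlation is at least `correlation_boost`
(default 0.6) — the collective-fluctuation signature of a dominant gene
group near a tipping point. The construction requires boost ≤ 1 −
1/inflation (the shared part must fit in the added variance). Defaults
(6 stages, critical stage 4, n = 50/stage) define the standard test
conditions. What this fixture does *not* emulate: counts-like noise,
library-size effects, stage-to-stage drift of the baseline network, or
confounded batch structure — passing on it shows the detector works when
the DNB signature is present, not that real data always carry it.

**SDE circuit.** A 16-node signed network (a regulatory ring, three hub
activations, three inhibitory cross-links — feedback intentional) evolves
under Euler–Maruyama with reflection at 0. Each node has cooperative
self-activation V·x²/(K² + x²) with V = 2K (K = 4), first-order decay,
Michaelis–Menten inputs from its regulators, and an additive drift shift
q_coupling·q (default coupling −1). With V = 2K and unit decay the
uncoupled node has a saddle-node exactly at x = K, so the occupied
high-expression branch exists for q < 0 and annihilates at q = 0; as
q → 0⁻ the branch's eigenvalue −√(2·|q|/K)·K/… tends to 0 and endpoint
variance across replicates inflates (critical slowing down). Per-node
basal terms subtract each node's regulator input at the reference state
so coupling does not displace the fold. Landscape scale K = 4 keeps the
σ = 0.5 basin escape gradual; defaults dt = 0.01, 2000 steps per q
(horizon 20 time units ≫ the slowest relaxation in the sweep), 50
replicates per q (200 in the acceptance run).

Known limitation: the default inter-node coupling (V = 0.2) is weak
relative to the self-dynamics, so the circuit's edges are barely visible
in stationary fluctuations and far-from-fold network recovery against the
gold standard is poor. Couplings strong enough for edge recovery deform
the engineered fold (the collective transition fires mid-sweep), so the
default favors clean bifurcation physics; `coupling_vmax` is exposed for
reconstruction-oriented experiments.

## Evaluation

Confusion counts over all m(m−1) ordered gene pairs of a declared
universe, direction-sensitive (a reversed edge is one FP plus one FN);
TPR = TP/(TP+FN); accuracy = (TP+TN)/total, with a precision-style
alternative behind a flag. The ordered-pair universe is what makes
per-stage counts across a fixed gene set comparable.

## Numerical choices and degenerate inputs

- Minimum-norm least squares via SVD (`lstsq`) for all fits, including
  p ≥ n and duplicated-parent designs.
- ε inside the MI log; |ρ| beyond 1 by > 10⁻¹² is an error, smaller
  overshoot is clipped.
- Acyclicity: Kahn's algorithm on containers, incremental DFS during
  search.
- Missing values are a hard loader error (the residual score is undefined
  on them); no silent imputation.
- Whether expression should be log-transformed upstream is left to the
  caller; the loader is unit-agnostic.
- SDE states are reflected at 0 (abundances); non-finite or exploding
  states raise with the offending q and step; dt·decay > 0.5 is rejected.

## Known limitations

- Restart agreement under this deterministic greedy search tracks signal
  strength: at a high-variance critical stage the per-move score deltas
  dwarf the λ·ln n penalty and all restarts funnel toward the same dense
  optimum, so the Jaccard consistency read-out does not reliably *drop*
  at the critical stage under the default fixture conditions (it
  fragments only when the shared-variance fraction approaches ~0.9,
  which the variance budget caps at 0.75 when inflation = 4). The
  instability signature that is robust in this setting is the TPR drop
  against the reference network (≈ 0.9 pre-transition vs ≈ 0.5–0.7 at
  the critical stage on the default fixture).
- Per-stage networks are estimated independently; no smoothness prior
  links consecutive stages.
- The t-test treats the score history as i.i.d.; with very short
  histories (2–3 points) the test is conservative in spread but can fire
  on any sharp excursion, in either direction, under the two-sided
  default.
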