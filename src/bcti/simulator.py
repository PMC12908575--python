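"""Benchmark data generators: a Michaelis-Menten SDE swept through a
bifurcation, and stage-wise expression with a planted critical stage.

SDE benchmark
-------------
Each node carries a cooperative self-activation (Hill coefficient 2) that
creates a saddle-node fold, first-order degradation, Michaelis-Menten
coupling terms from its regulators (activation ``V x^h/(K^h+x^h)``,
inhibition ``V K^h/(K^h+x^h)``), and an additive shift proportional to
the swept control parameter q.  With the default coupling sign the
occupied high-expression branch exists for q < 0 and annihilates at
q = 0: as q approaches 0 from below the branch's restoring eigenvalue
goes to zero, so stochastic trajectories relax ever more slowly and the
endpoint variance across replicates inflates -- critical slowing down,
the signature a score-based early-warning detector should pick up.
Integration is Euler-Maruyama with reflection at 0 (abundances stay
nonnegative); one simulated "stage" per q value, replicate endpoints as
samples.

Planted-transition fixture
--------------------------
Stage-wise expression in which a core gene subset follows a linear SEM
over a known edge list.  At one designated critical stage each core gene
receives extra fluctuation sized so its variance multiplies by exactly
``variance_inflation``; a fraction ``correlation_boost`` of the inflated
variance is carried by one latent factor shared across the whole core --
the collective fluctuation of a dominant gene group near a tipping
point.  The core therefore shows both inflated variance and pairwise
correlation at least ``correlation_boost`` (the dynamic-network-
biomarker signature), and the common factor makes the core genes
severely collinear, which is what destabilizes per-node regression fits
there.  Background genes stay independent noise throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core_io import DirectedNetwork, ExpressionMatrix, StagedDataset

ACTIVATION = 1
INHIBITION = -1


@dataclass
class SdeConfig:
    """Configuration of the Michaelis-Menten SDE sweep.

    network : signed regulatory network (cycles allowed); ``signs`` maps
        each edge to +1 (activation) or -1 (inhibition).
    q_grid : control-parameter values, one simulated stage per value
        (default sweep -0.3 ... 0.3; the fold sits at q = 0).
    sigma_noise : diffusion strength of the driving Wiener terms.
    dt, n_steps_per_q : Euler-Maruyama step and horizon (the horizon
        doubles as burn-in; endpoints are the recorded samples).
    n_replicates : independent trajectories per q = samples per stage.
    self_vmax, self_km : the fold-generating auto-activation.
    coupling_vmax, coupling_km, hill : regulator input terms.
    degradation : first-order decay rate per node.
    q_coupling : drift shift per unit q (default -1: positive q pushes
        the high branch over its fold).
    balance_inputs : subtract each node's regulator input evaluated at
        the reference high state, so couplings do not displace the fold.
    """

    network: DirectedNetwork
    signs: dict[tuple[str, str], int]
    q_grid: Sequence[float] = (-0.3, -0.2, -0.1, -0.05, -0.01)
    sigma_noise: float = 0.5
    dt: float = 0.01
    n_steps_per_q: int = 2000
    n_replicates: int = 50
    seed: int = 0
    self_vmax: float = 8.0
    self_km: float = 4.0
    coupling_vmax: float = 0.2
    coupling_km: float = 4.0
    hill: float = 2.0
    degradation: float = 1.0
    q_coupling: float = -1.0
    balance_inputs: bool = True

    def __post_init__(self) -> None:
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps_per_q < 1 or self.n_replicates < 1:
            raise ValueError("n_steps_per_q and n_replicates must be >= 1")
        for c in (self.self_vmax, self.self_km, self.coupling_km,
                  self.degradation):
            if c <= 0:
                raise ValueError("kinetic constants must be positive")
        missing = set(self.network.edges) - set(self.signs)
        if missing:
            raise ValueError(f"edges without a sign: {sorted(missing)}")


def default_16_node_network() -> tuple[DirectedNetwork, dict]:
    """A 16-node signed benchmark circuit (synthetic default fixture).

    A regulatory ring with hub activations and three inhibitory
    cross-links; feedback loops are intentional.  This is the package's
    own documented stand-in for a small published-style benchmark
    circuit, not a parameter-exact reproduction of any specific model.
    """
    genes = [f"G{i:02d}" for i in range(1, 17)]
    edges: dict[tuple[str, str], int] = {}
    for i in range(16):
        edges[(genes[i], genes[(i + 1) % 16])] = ACTIVATION
    for hub_target in ("G05", "G09", "G13"):
        edges[("G01", hub_target)] = ACTIVATION
    edges[("G04", "G10")] = INHIBITION
    edges[("G08", "G14")] = INHIBITION
    edges[("G12", "G02")] = INHIBITION
    network = DirectedNetwork(genes, set(edges), require_acyclic=False)
    return network, edges


def _uncoupled_high_state(config: SdeConfig, shift: float) -> float:
    """High fixed point of one uncoupled node at drift shift ``shift``."""
    V, K, d, h = (
        config.self_vmax, config.self_km, config.degradation, config.hill,
    )
    f = lambda x: V * x**h / (K**h + x**h) - d * x + shift
    hi = 2 * (V / d + abs(shift))
    # the high branch lies above the fold point x = K (for h = 2)
    return brentq(f, K, hi, xtol=1e-12)


def _drift(
    x: np.ndarray,
    q: float,
    config: SdeConfig,
    parent_idx: list[list[int]],
    parent_sign: list[list[int]],
    basal: np.ndarray,
) -> np.ndarray:
    V, K, h = config.self_vmax, config.self_km, config.hill
    xh = x**h
    out = V * xh / (K**h + xh) - config.degradation * x
    out += config.q_coupling * q + basal[:, None]
    wh = config.coupling_km**h
    act = config.coupling_vmax * xh / (wh + xh)
    inh = config.coupling_vmax * wh / (wh + xh)
    for i, (idxs, signs) in enumerate(zip(parent_idx, parent_sign)):
        for j, s in zip(idxs, signs):
            out[i] += act[j] if s > 0 else inh[j]
    return out


def simulate_mm_sde(
    config: SdeConfig,
) -> tuple[StagedDataset, DirectedNetwork]:
    """Euler-Maruyama sweep over ``q_grid``; one stage per q value.

    Every trajectory starts on the deterministic high branch.  Replicate
    endpoints form the stage's sample columns.  Returns the staged
    dataset and the gold-standard network (the configured circuit).
    """
    genes = config.network.gene_ids
    m = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    parent_idx: list[list[int]] = [[] for _ in range(m)]
    parent_sign: list[list[int]] = [[] for _ in range(m)]
    for (u, v), s in sorted(config.signs.items()):
        parent_idx[idx[v]].append(idx[u])
        parent_sign[idx[v]].append(s)

    # reference operating point: the q farthest from the fold, i.e. the
    # largest positive drift shift in the sweep
    ref_shift = max(config.q_coupling * q for q in config.q_grid)
    if ref_shift <= 0:
        raise ValueError(
            "no q in the grid puts the system on the high branch "
            "(q_coupling * q must be positive somewhere in the sweep)"
        )
    x_ref = _uncoupled_high_state(config, ref_shift)
    basal = np.zeros(m)
    if config.balance_inputs:
        wh = config.coupling_km**config.hill
        xh = x_ref**config.hill
        act_ref = config.coupling_vmax * xh / (wh + xh)
        inh_ref = config.coupling_vmax * wh / (wh + xh)
        for i in range(m):
            basal[i] = -sum(
                act_ref if s > 0 else inh_ref for s in parent_sign[i]
            )

    if config.dt * config.degradation > 0.5:
        raise ValueError(
            "dt too large for the configured degradation rate "
            f"(dt*deg = {config.dt * config.degradation:.2f})"
        )

    sqrt_dt = np.sqrt(config.dt)
    stage_labels = [f"q={q:+.3f}" for q in config.q_grid]
    blocks: dict[str, ExpressionMatrix] = {}
    for qi, q in enumerate(config.q_grid):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % 2**31, qi])
        )
        x = np.full((m, config.n_replicates), x_ref, dtype=float)
        for step in range(config.n_steps_per_q):
            drift = _drift(x, q, config, parent_idx, parent_sign, basal)
            x = x + drift * config.dt
            if config.sigma_noise > 0:
                x = x + config.sigma_noise * sqrt_dt * rng.standard_normal(
                    x.shape
                )
            np.abs(x, out=x)  # reflecting boundary at 0
            if not np.all(np.isfinite(x)) or np.any(x > 1e9):
                raise FloatingPointError(
                    f"state exploded at q={q} step={step}; reduce dt"
                )
        samples = [f"rep{r + 1}" for r in range(config.n_replicates)]
        blocks[stage_labels[qi]] = ExpressionMatrix(genes, samples, x)
    return StagedDataset(stage_labels, blocks), config.network


# ---------------------------------------------------------------------------
# planted-transition fixture


def default_core_network(core_genes: Sequence[str]) -> set[tuple[str, str]]:
    """A small converging/diverging DAG over the core genes: the first
    two genes regulate a middle layer that feeds a downstream chain."""
    g = list(core_genes)
    k = len(g)
    if k < 3:
        raise ValueError("core needs at least 3 genes")
    edges = {(g[0], g[2]), (g[1], g[2])}
    for i in range(2, k - 1):
        edges.add((g[i], g[i + 1]))
    if k >= 5:
        edges.add((g[0], g[4]))
    return edges


@dataclass
class PlantedTransitionConfig:
    """Stage-wise synthetic expression with one designated critical stage.

    Core genes follow an intercept-free linear SEM (coefficient
    ``edge_coefficient`` on every true edge, Gaussian noise sd
    ``noise_sd``).  At ``critical_stage`` (1-based) each core gene g
    gains a shared-latent term a_g * z plus private noise e_g * eta,
    with loadings fixed by the gene's theoretical SEM variance v_g:

        a_g^2 = correlation_boost * variance_inflation * v_g
        e_g^2 = (variance_inflation - 1 - correlation_boost
                 * variance_inflation) * v_g

    so every core gene's variance multiplies by exactly
    ``variance_inflation`` while a ``correlation_boost`` fraction of it
    is collective, giving pairwise core correlations of at least
    ``correlation_boost``.  This requires ``correlation_boost <= 1 -
    1/variance_inflation`` (the shared part must fit inside the added
    variance).  Background genes are independent noise at every stage.
    """

    m_genes: int = 20
    n_samples_per_stage: int = 50
    n_stages: int = 6
    critical_stage: int = 4
    n_core: int = 8
    core_edges: set[tuple[str, str]] | None = None
    variance_inflation: float = 4.0
    correlation_boost: float = 0.6
    noise_sd: float = 1.0
    edge_coefficient: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.critical_stage <= self.n_stages:
            raise ValueError(
                "critical_stage must lie in [3, n_stages] so the score "
                "trajectory has a testable history"
            )
        if not self.n_core or self.n_core > self.m_genes:
            raise ValueError("core must be a nonempty subset of the genes")
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        if not 0 <= self.correlation_boost < 1:
            raise ValueError("correlation_boost must be in [0, 1)")
        budget = 1.0 - 1.0 / self.variance_inflation
        if self.correlation_boost > budget + 1e-12:
            raise ValueError(
                "correlation_boost must be <= 1 - 1/variance_inflation "
                f"(= {budget:.3f}): the shared variance has to fit inside "
                "the inflation budget"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:02d}" for i in range(1, self.m_genes + 1)]

    @property
    def core_genes(self) -> list[str]:
        return self.gene_ids[: self.n_core]


def generate_planted_transition(
    config: PlantedTransitionConfig,
) -> tuple[StagedDataset, DirectedNetwork]:
    """Draw the staged dataset and return it with the gold-standard DAG."""
    genes = config.gene_ids
    core = config.core_genes
    edges = (
        set(config.core_edges)
        if config.core_edges is not None
        else default_core_network(core)
    )
    gold = DirectedNetwork(genes, edges)  # validates acyclicity/universe
    parents: dict[str, list[str]] = {g: [] for g in core}
    for u, v in sorted(edges):
        parents[v].append(u)
    from .core_io import topological_order

    order = topological_order(core, edges)
    assert order is not None

    # theoretical per-gene SEM variances: x = (I - A)^-1 eps with
    # A[child, parent] = edge_coefficient, Var(eps) = noise_sd^2 I
    k = len(core)
    pos = {g: i for i, g in enumerate(core)}
    coef_matrix = np.zeros((k, k))
    for child, pars in parents.items():
        for p in pars:
            coef_matrix[pos[child], pos[p]] = config.edge_coefficient
    mixing = np.linalg.inv(np.eye(k) - coef_matrix)
    sem_var = config.noise_sd**2 * (mixing**2).sum(axis=1)

    inflation = config.variance_inflation
    boost = config.correlation_boost
    shared_sd = np.sqrt(boost * inflation * sem_var)
    private_sd = np.sqrt((inflation - 1.0 - boost * inflation) * sem_var)

    n = config.n_samples_per_stage
    stage_labels = [f"stage{t}" for t in range(1, config.n_stages + 1)]
    blocks: dict[str, ExpressionMatrix] = {}
    for t, label in enumerate(stage_labels, start=1):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % 2**31, t])
        )
        critical = t == config.critical_stage
        values = np.zeros((len(genes), n))
        col = {g: i for i, g in enumerate(genes)}
        for g in order:
            row = config.noise_sd * rng.standard_normal(n)
            for p in parents[g]:
                row = row + config.edge_coefficient * values[col[p]]
            values[col[g]] = row
        if critical and inflation > 1:
            latent = rng.standard_normal(n)
            for g in core:
                extra = shared_sd[pos[g]] * latent
                extra = extra + private_sd[pos[g]] * rng.standard_normal(n)
                values[col[g]] = values[col[g]] + extra
        for g in genes[config.n_core:]:
            values[col[g]] = config.noise_sd * rng.standard_normal(n)
        samples = [f"{label}_s{v + 1}" for v in range(n)]
        blocks[label] = ExpressionMatrix(genes, samples, values)
    return StagedDataset(stage_labels, blocks), gold
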