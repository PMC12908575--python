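"""Restart hill-climbing over DAGs constrained to the CBN skeleton.

The search minimizes the MDL network score H by greedy local moves --
add-edge, delete-edge, reverse-edge -- where additions and reversals may
only use gene pairs present in the undirected skeleton and must keep the
graph acyclic.  Each iteration forms the best candidate in each move
category, accepts the overall best if it strictly improves H, and stops
at the first iteration with no improving move.  Because H decomposes over
nodes, a move is scored by recomputing only the nodes whose parent sets it
touches; local scores are cached by (child, parent set), so repeated
evaluations across iterations and restarts are free.

A single greedy climb can stall in a local minimum, so the optimizer runs
I independently seeded restarts from random skeleton-consistent initial
DAGs and keeps the restart with the lowest H.  The spread of the restart
results doubles as a stability diagnostic: near a critical transition,
collinearity among co-varying genes makes many parent sets score almost
identically and the restarts stop agreeing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cbn import MiParams, build_cbn
from .core_io import (
    DirectedNetwork,
    ExpressionMatrix,
    ScoredNetwork,
    UndirectedNetwork,
)
from .scoring import ScoreParams

logger = logging.getLogger(__name__)

_KIND_ORDER = {"add": 0, "delete": 1, "reverse": 2}


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the restart hill-climber.

    n_restarts_I : number of independent restarts.
    init_edge_prob : probability that a skeleton edge is included in a
        random initial DAG.
    max_iterations : hard cap on climb iterations (a warning is logged if
        hit; in practice convergence is far earlier).
    improvement_tol : minimum absolute H decrease counted as improvement,
        guarding against floating-point churn.
    seed : master seed; restart k draws from SeedSequence([seed, k]).
    """

    n_restarts_I: int = 10
    init_edge_prob: float = 0.5
    max_iterations: int = 1000
    improvement_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts_I < 1:
            raise ValueError("n_restarts_I must be >= 1")
        if not 0 <= self.init_edge_prob <= 1:
            raise ValueError("init_edge_prob must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.improvement_tol <= 0:
            raise ValueError("improvement_tol must be positive")


@dataclass(frozen=True)
class Move:
    """One local edit: kind in {add, delete, reverse}, edge = (parent, child)
    in the pre-move orientation."""

    kind: str
    edge: tuple[str, str]


@dataclass
class InferenceResult:
    """Best-of-restarts network plus per-restart diagnostics."""

    best: ScoredNetwork
    restart_scores: list[float]
    restart_networks: list[DirectedNetwork]
    cbn: UndirectedNetwork

    @property
    def network(self) -> DirectedNetwork:
        return self.best.network

    @property
    def h_score(self) -> float:
        return self.best.h_score

    @property
    def local_scores(self) -> dict[str, float]:
        return self.best.local_scores


# ---------------------------------------------------------------------------
# cached node-wise scorer (index-based for speed)


class _Scorer:
    """Local-score evaluator over gene indices with memoisation."""

    def __init__(self, expr: ExpressionMatrix, params: ScoreParams):
        values = np.asarray(expr.values, dtype=float)
        if params.center_genes:
            values = values - values.mean(axis=1, keepdims=True)
        self.values = values
        self.penalty = params.lambda_reg * np.log(expr.n_samples)
        self._cache: dict[tuple[int, frozenset], float] = {}

    def local(self, child: int, parents: frozenset) -> float:
        key = (child, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        y = self.values[child]
        if parents:
            design = self.values[sorted(parents), :]
            theta, _, _, _ = np.linalg.lstsq(design.T, y, rcond=None)
            resid = y - theta @ design
            rss = float(resid @ resid)
        else:
            rss = float(y @ y)
        score = rss + self.penalty * len(parents)
        self._cache[key] = score
        return score


class _DagState:
    """Mutable index-based DAG: parent sets + child adjacency for cycle
    checks, plus per-node local scores."""

    def __init__(self, m: int, scorer: _Scorer):
        self.m = m
        self.scorer = scorer
        self.parents: list[set[int]] = [set() for _ in range(m)]
        self.children: list[set[int]] = [set() for _ in range(m)]
        self.local: np.ndarray = np.array(
            [scorer.local(v, frozenset()) for v in range(m)]
        )

    @classmethod
    def from_edges(
        cls, m: int, edges: Iterable[tuple[int, int]], scorer: _Scorer
    ) -> "_DagState":
        state = cls(m, scorer)
        for u, v in edges:
            state.parents[v].add(u)
            state.children[u].add(v)
        state.local = np.array(
            [scorer.local(v, frozenset(state.parents[v])) for v in range(m)]
        )
        return state

    @property
    def h(self) -> float:
        return float(self.local.sum())

    def edges(self) -> set[tuple[int, int]]:
        return {(u, v) for v in range(self.m) for u in self.parents[v]}

    def has_path(self, src: int, dst: int, skip_edge=None) -> bool:
        """DFS reachability src -> dst, optionally ignoring one edge."""
        stack = [src]
        seen = {src}
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            for nxt in self.children[node]:
                if skip_edge is not None and (node, nxt) == skip_edge:
                    continue
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def apply(self, kind: str, u: int, v: int) -> None:
        if kind == "add":
            self.parents[v].add(u)
            self.children[u].add(v)
            self.local[v] = self.scorer.local(v, frozenset(self.parents[v]))
        elif kind == "delete":
            self.parents[v].discard(u)
            self.children[u].discard(v)
            self.local[v] = self.scorer.local(v, frozenset(self.parents[v]))
        elif kind == "reverse":
            self.parents[v].discard(u)
            self.children[u].discard(v)
            self.parents[u].add(v)
            self.children[v].add(u)
            self.local[v] = self.scorer.local(v, frozenset(self.parents[v]))
            self.local[u] = self.scorer.local(u, frozenset(self.parents[u]))
        else:  # pragma: no cover
            raise ValueError(kind)


def _candidate_moves(
    state: _DagState, skeleton_pairs: set[frozenset]
) -> dict[str, list[tuple[int, int]]]:
    """Legal moves by category over index pairs.

    Additions and reversals are restricted to skeleton pairs and filtered
    by an incremental reachability check so every move keeps acyclicity.
    """
    adds: list[tuple[int, int]] = []
    for pair in skeleton_pairs:
        i, j = sorted(pair)
        occupied = j in state.parents[i] or i in state.parents[j]
        if occupied:
            continue
        # adding u -> v creates a cycle iff v already reaches u
        if not state.has_path(j, i):
            adds.append((i, j))
        if not state.has_path(i, j):
            adds.append((j, i))
    current = sorted(state.edges())
    deletes = list(current)
    reverses = [
        (u, v)
        for u, v in current
        if not state.has_path(u, v, skip_edge=(u, v))
    ]
    return {"add": adds, "delete": deletes, "reverse": reverses}


def _move_delta(state: _DagState, kind: str, u: int, v: int) -> float:
    scorer = state.scorer
    if kind == "add":
        new = scorer.local(v, frozenset(state.parents[v] | {u}))
        return new - state.local[v]
    if kind == "delete":
        new = scorer.local(v, frozenset(state.parents[v] - {u}))
        return new - state.local[v]
    new_v = scorer.local(v, frozenset(state.parents[v] - {u}))
    new_u = scorer.local(u, frozenset(state.parents[u] | {v}))
    return (new_v - state.local[v]) + (new_u - state.local[u])


class _NullScorer:
    """Structure-only stand-in: every local score is 0."""

    def local(self, child: int, parents: frozenset) -> float:
        return 0.0


_NULL_SCORER = _NullScorer()


# ---------------------------------------------------------------------------
# public operations


def random_initial_dag(
    cbn: UndirectedNetwork,
    init_edge_prob: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> DirectedNetwork:
    """Random DAG whose skeleton is a subset of the CBN.

    A uniformly random node permutation serves as topological order; each
    skeleton edge is kept independently with ``init_edge_prob`` and
    oriented low -> high in that order, so acyclicity holds by
    construction and different seeds explore different orientations.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genes = cbn.gene_ids
    order = {g: r for g, r in zip(genes, rng.permutation(len(genes)))}
    edges: set[tuple[str, str]] = set()
    for pair in sorted(tuple(sorted(e)) for e in cbn.edges):
        if rng.random() < init_edge_prob:
            a, b = pair
            edges.add((a, b) if order[a] < order[b] else (b, a))
    return DirectedNetwork(genes, edges)


def enumerate_moves(
    dag: DirectedNetwork, cbn: UndirectedNetwork
) -> tuple[set[Move], set[Move], set[Move]]:
    """The three legal move sets (additions, deletions, reversals)."""
    genes = dag.gene_ids
    idx = {g: i for i, g in enumerate(genes)}
    if not dag.skeleton() <= {frozenset(e) for e in cbn.edges}:
        raise ValueError("DAG skeleton is not contained in the CBN")
    skeleton = {frozenset((idx[a], idx[b])) for a, b in map(tuple, cbn.edges)}
    state = _DagState.from_edges(
        len(genes), {(idx[u], idx[v]) for u, v in dag.edges}, _NULL_SCORER
    )
    cand = _candidate_moves(state, skeleton)
    to_move = lambda kind, pairs: {
        Move(kind, (genes[u], genes[v])) for u, v in pairs
    }
    return (
        to_move("add", cand["add"]),
        to_move("delete", cand["delete"]),
        to_move("reverse", cand["reverse"]),
    )


def _climb(
    state: _DagState,
    skeleton_pairs: set[frozenset],
    params: SearchParams,
    trajectory: list[float] | None = None,
) -> None:
    """Greedy descent in place until no move improves H."""
    if trajectory is not None:
        trajectory.append(state.h)
    for _ in range(params.max_iterations):
        candidates = _candidate_moves(state, skeleton_pairs)
        best = None  # (delta, kind_rank, u, v, kind)
        for kind in ("add", "delete", "reverse"):
            for u, v in candidates[kind]:
                delta = _move_delta(state, kind, u, v)
                key = (delta, _KIND_ORDER[kind], u, v)
                if best is None or key < best[:4]:
                    best = (*key, kind)
        if best is None or best[0] >= -params.improvement_tol:
            return
        _, _, u, v, kind = best
        state.apply(kind, u, v)
        if trajectory is not None:
            trajectory.append(state.h)
    logger.warning("hill climb hit max_iterations=%d", params.max_iterations)


def hill_climb(
    initial: DirectedNetwork,
    cbn: UndirectedNetwork,
    expr: ExpressionMatrix,
    score_params: ScoreParams = ScoreParams(),
    search_params: SearchParams = SearchParams(),
    trajectory: list[float] | None = None,
    _scorer: _Scorer | None = None,
) -> ScoredNetwork:
    """Greedy descent from ``initial``; returns the local optimum reached.

    Pass a list as ``trajectory`` to collect the H value after every
    accepted move (the sequence is non-increasing by construction).
    """
    genes = expr.gene_ids
    if initial.gene_ids != genes:
        raise ValueError("initial DAG and data must share the gene list")
    if not initial.skeleton() <= {frozenset(e) for e in cbn.edges}:
        raise ValueError("initial DAG skeleton is not contained in the CBN")
    idx = {g: i for i, g in enumerate(genes)}
    scorer = _scorer if _scorer is not None else _Scorer(expr, score_params)
    state = _DagState.from_edges(
        len(genes), {(idx[u], idx[v]) for u, v in initial.edges}, scorer
    )
    skeleton_pairs = {
        frozenset((idx[a], idx[b])) for a, b in map(tuple, cbn.edges)
    }
    _climb(state, skeleton_pairs, search_params, trajectory)
    dag = DirectedNetwork(
        genes, {(genes[u], genes[v]) for u, v in state.edges()}
    )
    locals_ = {g: float(state.local[idx[g]]) for g in genes}
    return ScoredNetwork(dag, float(state.h), locals_)


def infer_global_optimum(
    expr: ExpressionMatrix,
    mi_params: MiParams = MiParams(),
    score_params: ScoreParams = ScoreParams(),
    search_params: SearchParams = SearchParams(),
    cbn: UndirectedNetwork | None = None,
) -> InferenceResult:
    """Best network over ``n_restarts_I`` seeded hill climbs.

    The CBN is built once (or supplied); each restart starts from a fresh
    random initial DAG.  Ties on the minimal H break on the lowest restart
    index, so the result is a pure function of (data, params, seed).
    """
    if cbn is None:
        cbn = build_cbn(expr, mi_params)
    scorer = _Scorer(expr, score_params)
    results: list[ScoredNetwork] = []
    for k in range(search_params.n_restarts_I):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(search_params.seed) % 2**31, k])
        )
        initial = random_initial_dag(cbn, search_params.init_edge_prob, rng)
        results.append(
            hill_climb(
                initial, cbn, expr, score_params, search_params,
                _scorer=scorer,
            )
        )
    scores = [r.h_score for r in results]
    best_k = int(np.argmin(scores))  # argmin takes the first minimum
    return InferenceResult(
        best=results[best_k],
        restart_scores=scores,
        restart_networks=[r.network for r in results],
        cbn=cbn,
    )


def exhaustive_search(
    expr: ExpressionMatrix,
    cbn: UndirectedNetwork,
    score_params: ScoreParams = ScoreParams(),
    max_pairs: int = 12,
) -> ScoredNetwork:
    """Brute-force minimum-H DAG over every CBN-consistent structure.

    Enumerates all 3^E orientation assignments (absent / forward /
    backward per skeleton pair), filters acyclic graphs, and scores each
    from scratch with :func:`bcti.scoring.h_score` -- deliberately not
    the incremental scorer, so this doubles as an independent check of
    the search.  Only feasible for a handful of skeleton pairs.
    """
    from itertools import product

    from .core_io import topological_order
    from .scoring import h_score as full_h_score

    pairs = sorted(tuple(sorted(e)) for e in cbn.edges)
    if len(pairs) > max_pairs:
        raise ValueError(
            f"{len(pairs)} skeleton pairs is too many to enumerate"
        )
    genes = expr.gene_ids
    best: ScoredNetwork | None = None
    for assignment in product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (a, b), state in zip(pairs, assignment):
            if state == 1:
                edges.add((a, b))
            elif state == 2:
                edges.add((b, a))
        if topological_order(genes, edges) is None:
            continue
        scored = full_h_score(
            DirectedNetwork(genes, edges), expr, score_params
        )
        if best is None or scored.h_score < best.h_score:
            best = scored
    assert best is not None  # the empty DAG is always admissible
    return best
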