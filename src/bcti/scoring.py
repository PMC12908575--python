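"""Structural-equation fit and the MDL-style network score H.

Each gene is modelled as an intercept-free linear combination of its
parents plus Gaussian noise (a linear SEM on mean-centered data).  The
score of a DAG G is

    H(G) = sum_s [ F_s + lambda * |Pa(s)| * ln n ],

where F_s is the least-squares residual sum of squares of gene s on its
parents and the penalty charges ln n per estimated coefficient.  Lower is
better; the search minimizes H.  H decomposes over nodes, which is what
makes incremental rescoring during the search exact.

Two properties of this score carry the downstream biology:

* with no parents, a node's score is its centered sum of squares, i.e.
  (n-1) times its sample variance -- H grows with expression variance, the
  early-warning signal near a critical transition;
* near-collinear parents (strongly co-varying genes) make the fit
  ill-conditioned.  The minimum-norm least-squares solution keeps F
  well-defined, but which parent set wins becomes unstable -- the
  structural-instability signal.  No ridge term is added: regularizing the
  collinearity away would mask exactly that signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core_io import DirectedNetwork, ExpressionMatrix, ScoredNetwork


@dataclass(frozen=True)
class ScoreParams:
    """lambda_reg weights the complexity penalty (BIC-like at 1.0);
    center_genes mean-centers each gene within the stage before fitting
    (the SEM has no intercept)."""

    lambda_reg: float = 1.0
    center_genes: bool = True

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")


@dataclass(frozen=True)
class SemFit:
    """Least-squares fit of a child on its parents.

    theta_hat : coefficients, one per parent (minimum-norm solution when
        the design is rank-deficient, e.g. duplicated parents or p >= n).
    rss : residual sum of squares; equals the centered sum of squares of
        the child when there are no parents.
    """

    theta_hat: np.ndarray
    rss: float


def fit_sem(child: np.ndarray, parents: np.ndarray) -> SemFit:
    """Minimum-norm least squares of ``child`` (n,) on ``parents`` (p, n)."""
    child = np.asarray(child, dtype=float)
    parents = np.asarray(parents, dtype=float)
    if child.ndim != 1:
        raise ValueError("child must be a 1-D vector")
    if parents.size and parents.ndim != 2:
        raise ValueError("parents must be a p x n matrix")
    p = parents.shape[0] if parents.ndim == 2 else 0
    if p == 0:
        return SemFit(np.empty(0), float(child @ child))
    if parents.shape[1] != child.shape[0]:
        raise ValueError(
            f"parents have {parents.shape[1]} samples, child has "
            f"{child.shape[0]}"
        )
    # lstsq (SVD) returns the minimum-norm solution for rank-deficient
    # designs, which is exactly what a collinear parent set needs.
    theta, _, _, _ = np.linalg.lstsq(parents.T, child, rcond=None)
    resid = child - theta @ parents
    return SemFit(theta, float(resid @ resid))


def local_score(
    child_gene: str,
    parent_set: Iterable[str],
    expr: ExpressionMatrix,
    params: ScoreParams = ScoreParams(),
) -> float:
    """Score of one local subnetwork: rss + lambda * |parents| * ln(n)."""
    parent_set = list(parent_set)
    if child_gene in parent_set:
        raise ValueError(f"{child_gene!r} cannot be its own parent")
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    values = expr.values
    if params.center_genes:
        values = values - values.mean(axis=1, keepdims=True)
    child = values[idx[child_gene]]
    parents = values[[idx[g] for g in parent_set], :]
    fit = fit_sem(child, parents)
    n = expr.n_samples
    return fit.rss + params.lambda_reg * len(parent_set) * np.log(n)


def h_score(
    dag: DirectedNetwork,
    expr: ExpressionMatrix,
    params: ScoreParams = ScoreParams(),
) -> ScoredNetwork:
    """Total MDL score of a DAG: the sum of per-node local scores."""
    if set(dag.gene_ids) != set(expr.gene_ids):
        raise ValueError("DAG and expression matrix cover different genes")
    if not dag.is_acyclic():  # defensive; DirectedNetwork already checks
        raise ValueError("network must be acyclic")
    parents: dict[str, list[str]] = {g: [] for g in dag.gene_ids}
    for u, v in dag.edges:
        parents[v].append(u)
    locals_: dict[str, float] = {
        g: local_score(g, sorted(parents[g]), expr, params)
        for g in dag.gene_ids
    }
    return ScoredNetwork(dag, float(sum(locals_.values())), locals_)
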