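"""Correlation basis network (CBN) from pairwise Gaussian mutual information.

Under a bivariate-Gaussian assumption the mutual information between two
genes reduces to a closed form of their Pearson correlation,

    I(X_i, X_j) = -1/2 * ln(1 - rho_ij^2 + eps),

where the small guard ``eps`` keeps the logarithm finite as |rho| -> 1.
Gene pairs with I >= T form the undirected skeleton that constrains the
directed search: only skeleton pairs may ever carry a directed edge.

Natural logarithm is used throughout, so the default threshold T = 0.1 is
in nats; it corresponds to an absolute-correlation cutoff of
sqrt(1 - exp(-2T) + eps) ~ 0.426.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix, UndirectedNetwork

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-5
DEFAULT_THRESHOLD = 0.1


@dataclass(frozen=True)
class MiParams:
    """Parameters of the mutual-information skeleton.

    epsilon : numerical guard inside the logarithm (> 0).
    threshold_T : minimum mutual information (nats) for an edge (>= 0).
    """

    epsilon: float = DEFAULT_EPSILON
    threshold_T: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.threshold_T < 0:
            raise ValueError("threshold_T must be >= 0")


def gaussian_mutual_information(rho, epsilon: float = DEFAULT_EPSILON):
    """Closed-form Gaussian MI, ``-1/2 ln(1 - rho**2 + epsilon)``.

    Accepts scalars or arrays; symmetric in the sign of ``rho``.  Values of
    |rho| beyond 1 by more than 1e-12 are rejected; tiny overshoot from
    floating-point correlation estimates is clipped.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    rho = np.clip(rho, -1.0, 1.0)
    out = -0.5 * np.log(1.0 - rho**2 + epsilon)
    return float(out) if out.ndim == 0 else out


def mi_threshold_correlation(params: MiParams) -> float:
    """|rho| above which a pair passes the MI threshold (analytic inverse)."""
    rho2 = 1.0 - np.exp(-2.0 * params.threshold_T) + params.epsilon
    return float(np.sqrt(min(max(rho2, 0.0), 1.0)))


def pairwise_mi(
    expr: ExpressionMatrix, params: MiParams = MiParams()
) -> np.ndarray:
    """Symmetric m x m Gaussian-MI matrix; diagonal fixed at 0.

    Genes with zero variance have no defined correlation; they are treated
    as independent of everything (rho = 0) and a warning is logged.
    """
    values = expr.values
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        names = [g for g, c in zip(expr.gene_ids, constant) if c]
        logger.warning(
            "constant-expression genes treated as independent: %s", names
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(values)
    rho[np.isnan(rho)] = 0.0
    mi = gaussian_mutual_information(rho, params.epsilon)
    np.fill_diagonal(mi, 0.0)
    return mi


def build_cbn(
    expr: ExpressionMatrix, params: MiParams = MiParams()
) -> UndirectedNetwork:
    """Threshold the pairwise MI matrix into the undirected skeleton."""
    mi = pairwise_mi(expr, params)
    m = expr.n_genes
    edges = {
        frozenset((expr.gene_ids[i], expr.gene_ids[j]))
        for i in range(m)
        for j in range(i + 1, m)
        if mi[i, j] >= params.threshold_T
    }
    return UndirectedNetwork(expr.gene_ids, edges)
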