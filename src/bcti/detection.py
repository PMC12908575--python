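"""Critical-transition detection from the network-score trajectory.

The score of a stage, S(t), is the H score of that stage's optimal
network.  Because a node with no useful parents is scored by its centered
sum of squares, H rises with expression variance -- and sharply increased
fluctuation of a core gene group is the classic early-warning signature
of an approaching tipping point.  A stage t is called critical when a
one-sample t-test finds the history (S(1), ..., S(t-1)) significantly
different from the current score S(t).

The second, corroborating signature is structural: enhanced co-variation
among the core genes makes the per-node regressions collinear, so network
reconstruction becomes unstable.  Two instability read-outs are provided:
the true-positive rate against a reference network (when one exists) and
the agreement among restart networks (mean pairwise edge-set Jaccard).
Instability is reported alongside the t-test call, not used as a gate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cbn import MiParams
from .core_io import DirectedNetwork, ScoredNetwork, StagedDataset
from .evaluation import confusion_counts, tpr
from .scoring import ScoreParams
from .search import InferenceResult, SearchParams, infer_global_optimum


@dataclass(frozen=True)
class DetectionParams:
    """alpha: significance level; sided: 'two' or 'greater' (theory
    predicts a score increase); min_history: history points required
    before a stage becomes testable (2 -> first testable stage is the
    third)."""

    alpha: float = 0.05
    sided: str = "two"
    min_history: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sided not in ("two", "greater"):
            raise ValueError("sided must be 'two' or 'greater'")
        if self.min_history < 2:
            raise ValueError("min_history must be >= 2")


@dataclass
class BctiSeries:
    """Per-stage scores, p-values and diagnostics along the progression.

    p_values[t] tests S(t) against the preceding history; stages with too
    little history carry NaN.  restart_consistency and (optionally) tpr
    hold the structural-stability read-outs.
    """

    stage_labels: list[str]
    scores_S: list[float]
    p_values: list[float]
    networks: list[ScoredNetwork]
    restart_consistency: list[float] = field(default_factory=list)
    tpr_vs_reference: list[float] | None = None
    results: list[InferenceResult] = field(default_factory=list)


def ttest_pvalue(
    history: Sequence[float], current: float, sided: str = "two"
) -> float:
    """One-sample t-test of the score history against the current score.

    The history is the sample, the current score the hypothesized mean;
    with t history points the statistic has t-1 ... n-1 = len(history)-1
    degrees of freedom.  ``sided='greater'`` asks whether the current
    score exceeds the history mean.  A zero-variance history degenerates
    to p = 1 when the current score equals the history mean (within
    1e-12) and p = 0 otherwise.
    """
    history = np.asarray(history, dtype=float)
    if history.size < 2:
        raise ValueError("need at least 2 history points for a t-test")
    if history.std(ddof=1) == 0:
        return 1.0 if abs(current - history.mean()) <= 1e-12 else 0.0
    alternative = {"two": "two-sided", "greater": "less"}[sided]
    # 'greater' means current > mean(history), i.e. the history sample
    # sits below the hypothesized mean -> scipy alternative='less'.
    res = stats.ttest_1samp(history, popmean=current, alternative=alternative)
    return float(res.pvalue)


def restart_consistency(networks: Sequence[DirectedNetwork]) -> float:
    """Mean pairwise Jaccard similarity of restart edge sets (1 = all
    restarts found the same network); two empty networks count as 1."""
    if len(networks) < 2:
        raise ValueError("need at least 2 restart networks")
    sims = []
    for a, b in itertools.combinations(networks, 2):
        ea, eb = set(a.edges), set(b.edges)
        union = ea | eb
        sims.append(len(ea & eb) / len(union) if union else 1.0)
    return float(np.mean(sims))


def structural_instability(
    network_t: DirectedNetwork,
    reference: DirectedNetwork,
    gene_universe: Sequence[str] | None = None,
) -> float:
    """TPR of a stage network against a reference; low values near a
    transition signal unstable reconstruction."""
    if not reference.edges:
        raise ValueError("reference network has no edges; TPR undefined")
    return tpr(confusion_counts(network_t, reference, gene_universe))


def compute_bcti_series(
    data: StagedDataset,
    mi_params: MiParams = MiParams(),
    score_params: ScoreParams = ScoreParams(),
    search_params: SearchParams = SearchParams(),
    detection_params: DetectionParams = DetectionParams(),
    reference: DirectedNetwork | None = None,
) -> BctiSeries:
    """One optimal-network inference per stage, then the score trajectory.

    Each stage gets its own CBN and its own set of seeded restarts; the
    seed of stage index j is derived from the master seed as
    ``(seed * 10007 + j) mod 2**31`` so stages are independent but the
    whole series is reproducible from (data, params, seed).
    """
    scores: list[float] = []
    networks: list[ScoredNetwork] = []
    consistency: list[float] = []
    tprs: list[float] | None = [] if reference is not None else None
    results: list[InferenceResult] = []
    for j, (label, block) in enumerate(data):
        stage_seed = (int(search_params.seed) * 10007 + j) % 2**31
        sp = SearchParams(
            n_restarts_I=search_params.n_restarts_I,
            init_edge_prob=search_params.init_edge_prob,
            max_iterations=search_params.max_iterations,
            improvement_tol=search_params.improvement_tol,
            seed=stage_seed,
        )
        result = infer_global_optimum(block, mi_params, score_params, sp)
        results.append(result)
        scores.append(result.h_score)
        networks.append(result.best)
        if len(result.restart_networks) >= 2:
            consistency.append(restart_consistency(result.restart_networks))
        else:
            consistency.append(math.nan)
        if tprs is not None:
            tprs.append(
                structural_instability(result.network, reference, data.gene_ids)
            )
    p_values = [math.nan] * len(scores)
    for t in range(detection_params.min_history, len(scores)):
        p_values[t] = ttest_pvalue(
            scores[:t], scores[t], detection_params.sided
        )
    return BctiSeries(
        stage_labels=list(data.stage_labels),
        scores_S=scores,
        p_values=p_values,
        networks=networks,
        restart_consistency=consistency,
        tpr_vs_reference=tprs,
        results=results,
    )


def detect_critical_state(
    series: BctiSeries, params: DetectionParams = DetectionParams()
) -> tuple[str | None, list[float]]:
    """Earliest stage whose score breaks significantly from its history.

    Returns (stage_label_or_None, per-stage p-values).  Only stages with
    at least ``min_history`` preceding scores are testable, so the first
    candidate is the third stage under the defaults.
    """
    if len(series.scores_S) < 3:
        raise ValueError("need at least 3 stages to test for a transition")
    p_values = list(series.p_values)
    for t, p in enumerate(p_values):
        if not math.isnan(p) and p < params.alpha:
            return series.stage_labels[t], p_values
    return None, p_values


def instability_corroborates(
    series: BctiSeries, stage_label: str
) -> bool | None:
    """Whether the restart-consistency read-out supports a call at the
    given stage (consistency there below the mean over earlier stages).
    None when no earlier consistency values exist."""
    t = series.stage_labels.index(stage_label)
    earlier = [
        c for c in series.restart_consistency[:t] if not math.isnan(c)
    ]
    if not earlier or math.isnan(series.restart_consistency[t]):
        return None
    return series.restart_consistency[t] < float(np.mean(earlier))
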