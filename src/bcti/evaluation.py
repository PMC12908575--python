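"""Confusion counts, TPR and accuracy against a gold-standard network.

Evaluation is over all ordered gene pairs (u, v), u != v, of a declared
gene universe of size m, so tp + fp + fn + tn = m*(m-1).  Matching is
direction-sensitive: predicting b -> a when the gold standard says a -> b
scores one false positive (the wrong pair) and one false negative (the
missed pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import DirectedNetwork


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    predicted: DirectedNetwork,
    gold: DirectedNetwork,
    gene_universe: Sequence[str] | None = None,
) -> ConfusionCounts:
    """Direction-sensitive confusion counts over ordered gene pairs."""
    if gene_universe is None:
        gene_universe = gold.gene_ids
    universe = set(gene_universe)
    for name, net in (("predicted", predicted), ("gold", gold)):
        stray = {g for e in net.edges for g in e} - universe
        if stray:
            raise ValueError(
                f"{name} network has edges outside the universe: "
                f"{sorted(stray)}"
            )
    m = len(universe)
    pred = set(predicted.edges)
    true = set(gold.edges)
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    tn = m * (m - 1) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def tpr(counts: ConfusionCounts) -> float:
    """Recall of gold edges, tp / (tp + fn)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("TPR undefined: gold standard has no edges")
    return counts.tp / (counts.tp + counts.fn)


def accuracy(counts: ConfusionCounts, style: str = "overall") -> float:
    """Fraction of ordered pairs classified correctly.

    ``style='overall'`` is (tp + tn) / total; ``style='precision'`` is the
    positive predictive value tp / (tp + fp), for comparisons that only
    consider predicted edges.
    """
    if style == "overall":
        if counts.total == 0:
            raise ValueError("accuracy undefined on an empty universe")
        return (counts.tp + counts.tn) / counts.total
    if style == "precision":
        if counts.tp + counts.fp == 0:
            raise ValueError("precision undefined: no predicted edges")
        return counts.tp / (counts.tp + counts.fp)
    raise ValueError(f"unknown accuracy style {style!r}")
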