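"""Domain containers and plain-text readers/writers.

The package works on stage-wise expression data: a genes x samples real
matrix per stage of an ordered progression (tumor stages, developmental
time points, values of a swept control parameter).  Everything downstream
-- the mutual-information skeleton, the structural-equation scoring, the
DAG search -- consumes these containers.

File formats are deliberately minimal and text-only:

* expression matrix: TSV/CSV, header row = sample ids, first column = gene
  ids (genes as rows is canonical; a flag transposes on load),
* stage map: two-column TSV ``sample_id<TAB>stage_label``,
* networks: two-column TSV edge lists ``source<TAB>target``; whether the
  file is directed is declared by the caller, never inferred.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """A genes x samples block of real-valued expression for one stage.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (m, n)
        Expression values in arbitrary units; no missing entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        if m < 2:
            raise ValidationError(f"need at least 2 genes, got {m}")
        if n < 3:
            raise ValidationError(f"need at least 3 samples, got {n}")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)}")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            g, s = bad[0]
            raise ValidationError(
                "missing/non-finite value at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, idx]
        )


@dataclass
class StagedDataset:
    """Ordered stages, each holding one :class:`ExpressionMatrix`.

    All blocks share the identical gene list and order; the stage order is
    the time axis along which the network-score trajectory is computed.
    """

    stage_labels: list[str]
    blocks: dict[str, ExpressionMatrix]

    def __post_init__(self) -> None:
        self.stage_labels = list(self.stage_labels)
        if len(self.stage_labels) < 2:
            raise ValidationError("need at least 2 stages")
        if set(self.stage_labels) != set(self.blocks):
            raise ValidationError("stage_labels and blocks disagree")
        genes0 = self.blocks[self.stage_labels[0]].gene_ids
        for label in self.stage_labels:
            if self.blocks[label].gene_ids != genes0:
                raise ValidationError(
                    f"stage {label!r} has a different gene list/order"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.blocks[self.stage_labels[0]].gene_ids

    def __iter__(self):
        return ((label, self.blocks[label]) for label in self.stage_labels)


@dataclass
class UndirectedNetwork:
    """Undirected skeleton over a fixed gene universe (the CBN)."""

    gene_ids: list[str]
    edges: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        universe = set(self.gene_ids)
        norm = set()
        for e in self.edges:
            pair = frozenset(e)
            if len(pair) != 2:
                raise ValidationError(f"self-loop or malformed edge: {set(e)}")
            if not pair <= universe:
                raise ValidationError(f"edge outside gene universe: {set(e)}")
            norm.add(pair)
        self.edges = norm

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DirectedNetwork:
    """A directed network over the gene universe: edges are (parent, child).

    Search states and inference results must be DAGs, which is the default
    (``require_acyclic=True``).  Gold-standard networks of dynamical
    systems legitimately contain feedback loops; construct those with
    ``require_acyclic=False``.
    """

    gene_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    require_acyclic: bool = True

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        universe = set(self.gene_ids)
        self.edges = set(map(tuple, self.edges))
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if u not in universe or v not in universe:
                raise ValidationError(f"edge outside gene universe: {(u, v)}")
        if self.require_acyclic and not self.is_acyclic():
            raise ValidationError("directed network contains a cycle")

    def parents(self, gene: str) -> set[str]:
        return {u for (u, v) in self.edges if v == gene}

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def is_acyclic(self) -> bool:
        return topological_order(self.gene_ids, self.edges) is not None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ScoredNetwork:
    """A DAG together with its H score and per-node local scores."""

    network: DirectedNetwork
    h_score: float
    local_scores: dict[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.local_scores.values()))
        scale = max(abs(total), abs(self.h_score), 1.0)
        if abs(total - self.h_score) > 1e-9 * scale:
            raise ValidationError(
                f"h_score {self.h_score} != sum of local scores {total}"
            )


def topological_order(
    nodes: Iterable[str], edges: Iterable[tuple[str, str]]
) -> list[str] | None:
    """Kahn's algorithm; returns None if the graph has a cycle."""
    nodes = list(nodes)
    indeg = {v: 0 for v in nodes}
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in edges:
        indeg[v] += 1
        children[u].append(v)
    queue = [v for v in nodes if indeg[v] == 0]
    order: list[str] = []
    while queue:
        v = queue.pop()
        order.append(v)
        for w in children[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return order if len(order) == len(nodes) else None


# ---------------------------------------------------------------------------
# readers / writers


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    # TSV is the default dialect; fall back to comma when the header has
    # commas but no tabs.
    if "\t" not in header and "," in header:
        return ","
    return "\t"


def read_expression(
    path: str | Path, samples_as_rows: bool = False
) -> ExpressionMatrix:
    """Load an expression matrix from TSV/CSV.

    Canonical orientation is genes as rows (header = sample ids, first
    column = gene ids); ``samples_as_rows=True`` transposes on load.
    Missing or non-numeric cells are a hard error: the downstream residual
    score is undefined on missing entries and silent imputation would bias
    the variance signal the method relies on.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if samples_as_rows:
        df = df.T
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]
    ]
    if len(non_numeric):
        raise ValidationError(
            f"non-numeric values in column(s) {list(non_numeric)}"
        )
    try:
        return ExpressionMatrix(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(dtype=float),
        )
    except ValidationError:
        raise


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_stage_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>stage_label`` -> dict."""
    path = Path(path)
    sep = _sniff_sep(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter=sep):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValidationError(f"malformed stage-map row: {row}")
            sample, stage = row[0].strip(), row[1].strip()
            if sample in mapping:
                raise ValidationError(f"sample {sample!r} mapped twice")
            mapping[sample] = stage
    return mapping


def write_stage_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, stage in mapping.items():
            fh.write(f"{sample}\t{stage}\n")


def split_by_stage(
    expr: ExpressionMatrix,
    stage_map: Mapping[str, str],
    stage_order: Sequence[str],
) -> StagedDataset:
    """Partition the samples of one pooled matrix into per-stage blocks.

    Every sample must be mapped, every mapped stage must appear in
    ``stage_order``, and every stage needs at least three samples (a
    Pearson correlation on fewer is meaningless).  Gene order is preserved
    in every block; the partition depends only on the stage map, not on
    the column order of the input.
    """
    stage_order = list(stage_order)
    by_stage: dict[str, list[str]] = {s: [] for s in stage_order}
    for sample in expr.sample_ids:
        if sample not in stage_map:
            raise ValidationError(f"sample {sample!r} has no stage mapping")
        stage = stage_map[sample]
        if stage not in by_stage:
            raise ValidationError(
                f"sample {sample!r} mapped to unknown stage {stage!r}"
            )
        by_stage[stage].append(sample)
    blocks: dict[str, ExpressionMatrix] = {}
    for stage in stage_order:
        samples = by_stage[stage]
        if len(samples) < 3:
            raise ValidationError(
                f"stage {stage!r} has {len(samples)} samples; need >= 3"
            )
        blocks[stage] = expr.subset_samples(samples)
    return StagedDataset(stage_order, blocks)


def read_edge_list(
    path: str | Path,
    directed: bool,
    gene_ids: Sequence[str] | None = None,
    require_acyclic: bool = True,
) -> UndirectedNetwork | DirectedNetwork:
    """Read a two-column edge list; a third column, if present, is ignored.

    When ``gene_ids`` is given it defines the universe and unknown
    endpoints are an error; otherwise the universe is the sorted set of
    endpoints seen in the file.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter=sep):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValidationError(f"malformed edge row: {row}")
            u, v = row[0].strip(), row[1].strip()
            if u == v:
                raise ValidationError(f"self-loop on {u!r} in {path.name}")
            pairs.append((u, v))
    if gene_ids is None:
        gene_ids = sorted({g for e in pairs for g in e})
    else:
        universe = set(gene_ids)
        for u, v in pairs:
            if u not in universe or v not in universe:
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) references unknown gene"
                )
    if directed:
        return DirectedNetwork(list(gene_ids), set(pairs), require_acyclic)
    return UndirectedNetwork(
        list(gene_ids), {frozenset(p) for p in pairs}
    )


def write_edge_list(
    network: UndirectedNetwork | DirectedNetwork, path: str | Path
) -> None:
    """Write edges as sorted two-column TSV (deterministic byte output)."""
    if isinstance(network, DirectedNetwork):
        rows = sorted(network.edges)
    else:
        rows = sorted(tuple(sorted(e)) for e in network.edges)
    with open(path, "w") as fh:
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")
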