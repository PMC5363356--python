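"""Expression-level filtering, target-overlap counting and clustering.

Implements the downstream selection applied to per-condition transcriptome
tables after miRNA/isomiR overexpression: a gene counts as down-regulated in
a condition when its log2 fold change versus the control is at most -0.9 and
its average expression exceeds log2 CPM 3.  Down-regulated sets are then
intersected with predicted-target sets per variant (Venn-style overlap
counts), and the filtered genes are clustered on correlation distance.

Differential-expression modelling (dispersion estimation, exact tests) is
out of scope: real edgeR outputs can be imported directly, and synthetic
tables carry log2 CPM from which fold changes are plain column differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class FilterThresholds:
    """Down-regulation selection thresholds (log2 scale)."""

    fc_max: float = -0.9
    cpm_min_log2: float = 3.0

    def __post_init__(self) -> None:
        if self.fc_max >= 0:
            raise ValueError(f"fc_max must be negative, got {self.fc_max}")


@dataclass
class ExpressionMatrix:
    """Genes x conditions log2 CPM table with a designated control column."""

    data: pd.DataFrame
    control: str

    def __post_init__(self) -> None:
        if self.control not in self.data.columns:
            raise ValueError(f"control column {self.control!r} not in matrix")
        if not np.all(np.isfinite(self.data.to_numpy(float))):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.data.columns if c != self.control]

    def average_log2cpm(self) -> pd.Series:
        """Mean log2 CPM across all samples (edgeR's logCPM convention)."""
        return self.data.mean(axis=1)


def log2fc(matrix: ExpressionMatrix, condition: str, control: Optional[str] = None) -> pd.Series:
    """Per-gene log2 fold change: condition minus control (both log2 CPM)."""
    control = control if control is not None else matrix.control
    for col in (condition, control):
        if col not in matrix.data.columns:
            raise KeyError(f"unknown condition {col!r}")
    return matrix.data[condition] - matrix.data[control]


def fold_change_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2 FC versus control for every non-control condition."""
    return pd.DataFrame({c: log2fc(matrix, c) for c in matrix.conditions})


@dataclass
class DownFilterResult:
    per_condition: dict[str, set[str]]
    union: set[str]


def down_filter(
    matrix: ExpressionMatrix,
    fc_table: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> DownFilterResult:
    """Genes down-regulated per condition and their union.

    A gene is retained in a condition iff log2 FC <= ``fc_max`` and its
    average log2 CPM across all samples exceeds ``cpm_min_log2``.
    """
    avg = matrix.average_log2cpm()
    expressed = avg > thresholds.cpm_min_log2
    per_condition: dict[str, set[str]] = {}
    for cond in fc_table.columns:
        mask = (fc_table[cond] <= thresholds.fc_max) & expressed
        per_condition[cond] = set(fc_table.index[mask])
    union: set[str] = set().union(*per_condition.values()) if per_condition else set()
    return DownFilterResult(per_condition=per_condition, union=union)


@dataclass(frozen=True)
class OverlapCounts:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_a, self.n_b):
            raise ValueError("intersection larger than one of the sets")


def overlap_counts(
    down_sets: Mapping[str, set[str]],
    predicted: Mapping[str, set[str]],
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
) -> list[OverlapCounts]:
    """Venn-style overlap of down-regulated predicted targets.

    Each requested pair is ((condition_a, variant_a), (condition_b,
    variant_b)); reported are the sizes of predicted_a ∩ down_a, predicted_b
    ∩ down_b and their intersection.
    """
    out: list[OverlapCounts] = []
    for (cond_a, var_a), (cond_b, var_b) in pairs:
        for cond in (cond_a, cond_b):
            if cond not in down_sets:
                raise KeyError(f"unknown condition {cond!r}")
        for var in (var_a, var_b):
            if var not in predicted:
                raise KeyError(f"unknown variant {var!r}")
        set_a = predicted[var_a] & down_sets[cond_a]
        set_b = predicted[var_b] & down_sets[cond_b]
        out.append(
            OverlapCounts(
                label_a=f"{var_a}|{cond_a}",
                label_b=f"{var_b}|{cond_b}",
                n_a=len(set_a),
                n_b=len(set_b),
                n_both=len(set_a & set_b),
            )
        )
    return out


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    gene_order: list[str]
    scaled: pd.DataFrame


def scale_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each gene row to mean 0, unit variance (ddof=1)."""
    values = data.to_numpy(float)
    sd = values.std(axis=1, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance gene(s) cannot be scaled: {list(data.index[zero][:5])}"
        )
    scaled = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(scaled, index=data.index, columns=data.columns)


def cluster_genes(data: pd.DataFrame, linkage: str = "complete") -> ClusterResult:
    """Hierarchical clustering of genes on Pearson correlation distance.

    Rows are centered and scaled per gene; distance is 1 - Pearson r;
    agglomeration uses the configured linkage (complete by default, average
    available).  Leaf order is deterministic given the inputs.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 conditions to cluster")
    scaled = scale_rows(data)
    dist = pdist(scaled.to_numpy(float), metric="correlation")
    Z = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage_matrix=Z,
        gene_order=[str(g) for g in scaled.index[order]],
        scaled=scaled,
    )
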