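"""Two-group expression matrices: normalization diagnostics and DEG selection.

The container is a log2-scale genes x samples matrix with a two-group design
(e.g. tumour grade II vs grade III biopsies).  Differential expression is
ranked by a two-sample t-test on the log2 values — pooled-variance by
default, which is exactly calibrated at the tiny group sizes (n = 3) such
designs have; Welch's unequal-variance form is available as an option.  The
selection step keeps the top-N most significant genes and then applies
symmetric linear fold-change thresholds (keep FC < 0.5 or FC > 2 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEGRecord",
    "median_center",
    "boxplot_stats",
    "fold_change",
    "rank_genes",
    "filter_degs",
    "drop_uncharacterized",
]


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes in rows, samples in columns, two-group design.

    Parameters
    ----------
    values
        DataFrame of log2 intensities indexed by gene id with sample ids as
        columns.
    groups
        Series mapping each sample id to one of exactly two group labels.
        The lexicographically smaller label is treated as the baseline
        (denominator) group in fold-change computations.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        self.groups = pd.Series(self.groups)
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.values.columns)]
        labels = sorted(set(self.groups))
        if len(labels) != 2:
            raise ValueError(f"expected exactly two group labels, got {labels}")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def group_labels(self) -> tuple:
        """(baseline, test) labels, baseline = lexicographically smaller."""
        a, b = sorted(set(self.groups))
        return a, b

    def samples_in(self, label) -> list:
        return [s for s in self.values.columns if self.groups[s] == label]


@dataclass(frozen=True)
class DEGRecord:
    """One ranked gene: linear fold change (test vs baseline) and Welch p."""

    gene: str
    fold_change: float
    p_value: float
    rank: int

    @property
    def log2_fold_change(self) -> float:
        return float(np.log2(self.fold_change))


def _require_nonempty(matrix: ExpressionMatrix) -> None:
    if matrix.values.size == 0:
        raise ValueError("expression matrix is empty")


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample column's median so every column has median 0.

    Idempotent; gene and sample order are preserved.
    """
    _require_nonempty(matrix)
    centered = matrix.values - matrix.values.median(axis=0)
    return ExpressionMatrix(values=centered, groups=matrix.groups.copy())


def boxplot_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample five-number summary (min, Q1, median, Q3, max).

    Quartiles use linear interpolation, matching the whisker-free box plots
    used to check that samples are comparable after median centering.
    """
    _require_nonempty(matrix)
    q = matrix.values.quantile([0.0, 0.25, 0.5, 0.75, 1.0], axis=0).T
    q.columns = ["min", "q1", "median", "q3", "max"]
    q.index.name = "sample"
    return q


def fold_change(matrix: ExpressionMatrix) -> pd.Series:
    """Linear fold change per gene: 2^(mean_test - mean_baseline) of log2 values.

    Means on the log2 scale correspond to geometric means on the linear
    scale, the standard microarray convention.  Strictly positive.
    """
    base, test = matrix.group_labels
    cols_a = matrix.samples_in(base)
    cols_b = matrix.samples_in(test)
    if not cols_a or not cols_b:
        raise ValueError("both groups must have at least one sample")
    diff = matrix.values[cols_b].mean(axis=1) - matrix.values[cols_a].mean(axis=1)
    fc = np.power(2.0, diff)
    fc.name = "fold_change"
    return fc


def _ttest_pvalues(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sample t-test p-values with a zero-variance convention.

    When both groups have zero variance the t statistic is 0/0; we call
    p = 1 if the group means agree and p = 0 if they differ, preserving the
    obvious inference without dividing by zero.
    """
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # flat genes trigger scipy's catastrophic-cancellation warning; their
        # p-values are overridden by the convention below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def rank_genes(matrix: ExpressionMatrix, equal_var: bool = True) -> list[DEGRecord]:
    """Rank all genes by two-sample t-test p-value (ascending).

    The default pooled-variance (Student) test is exactly calibrated under
    a common noise scale, which matters at microarray group sizes of 2-3
    where Welch's approximate degrees of freedom make the test noticeably
    conservative; pass ``equal_var=False`` for Welch's form.  Ties are
    broken by |log2 fold change| descending, then gene id lexicographically,
    so the ranking is a deterministic permutation of the genes.  Requires at
    least two samples per group.
    """
    base, test = matrix.group_labels
    cols_a = matrix.samples_in(base)
    cols_b = matrix.samples_in(test)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    p = _ttest_pvalues(a, b, equal_var)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    order = sorted(
        range(len(matrix.values.index)),
        key=lambda i: (p[i], -abs(log2fc[i]), str(matrix.values.index[i])),
    )
    return [
        DEGRecord(
            gene=str(matrix.values.index[i]),
            fold_change=float(2.0 ** log2fc[i]),
            p_value=float(p[i]),
            rank=r,
        )
        for r, i in enumerate(order, start=1)
    ]


def filter_degs(
    records: list[DEGRecord],
    top_n: int = 250,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
) -> list[DEGRecord]:
    """Keep the top-N ranked records whose fold change passes the thresholds.

    The thresholds are strict: a record survives only if FC < ``fc_low`` or
    FC > ``fc_high``; FC exactly at a boundary is removed.  Order (and the
    original ranks) are preserved, so the operation is idempotent.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    head = sorted(records, key=lambda r: r.rank)[:top_n]
    return [r for r in head if r.fold_change < fc_low or r.fold_change > fc_high]


def drop_uncharacterized(
    records: list[DEGRecord], characterized: set
) -> list[DEGRecord]:
    """Keep only records whose gene id is in the characterized set."""
    characterized = set(characterized)
    return [r for r in records if r.gene in characterized]
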