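"""Two-group differential expression.

Fold change is defined on the log2 scale: the difference of group mean log2
intensities, reported linearly as ``2**|delta|`` (a geometric-mean ratio) with
the direction ("up" when the case group mean exceeds the control mean) carried
separately.  Significance is a two-sided two-sample t-test (pooled-variance
Student's t by default, Welch available); selection keeps probes with
``fold_change >= fc_min`` and ``p_raw < p_max``.  Benjamini-Hochberg adjusted
p-values are reported alongside but never used as the filter.

Everything is deterministic: tables sort by regulation (up before down), then
descending fold change, then ascending raw p, then probe id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import DesignError, ExpressionMatrix

__all__ = [
    "fold_change_and_direction",
    "two_group_t_test",
    "bh_adjust",
    "select_differential",
    "DifferentialTable",
    "chromosome_distribution",
    "hierarchical_cluster_order",
    "correlation_distance",
    "average_linkage_merges",
    "top_n",
    "volcano_table",
]

_SORT_REG = {"up": 0, "down": 1}


def _group_arrays(
    m: ExpressionMatrix, case_group: str, control_group: str
) -> tuple[np.ndarray, np.ndarray]:
    case = m.values[m.samples_in_group(case_group)].to_numpy(dtype=float)
    ctrl = m.values[m.samples_in_group(control_group)].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise DesignError("need at least 2 samples per group")
    return case, ctrl


def fold_change_and_direction(
    m: ExpressionMatrix, case_group: str, control_group: str
) -> pd.DataFrame:
    """Per-probe linear fold change (always >= 1) and regulation direction.

    Returns a DataFrame indexed by probe with columns ``fold_change``,
    ``regulation``, ``log2_fc`` (signed case minus control), the two group
    means, and ``tie`` flagging exactly-equal means (direction defaults to
    "up" there by convention).
    """
    case, ctrl = _group_arrays(m, case_group, control_group)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    delta = mean_case - mean_ctrl
    tie = delta == 0
    regulation = np.where(delta >= 0, "up", "down")
    return pd.DataFrame(
        {
            "fold_change": np.exp2(np.abs(delta)),
            "regulation": regulation,
            "log2_fc": delta,
            "mean_log2_case": mean_case,
            "mean_log2_control": mean_ctrl,
            "tie": tie,
        },
        index=m.values.index,
    )


def two_group_t_test(
    m: ExpressionMatrix,
    case_group: str,
    control_group: str,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Two-sided two-sample t-test per probe.

    ``variant="pooled"`` is the classical Student's t with pooled variance;
    ``"welch"`` drops the equal-variance assumption.  Probes with zero
    variance in both groups are degenerate for the t statistic: they get
    p = 1 when the group means are equal (constant probe) and p = 0 when they
    differ, and are flagged in the ``zero_variance`` column.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    case, ctrl = _group_arrays(m, case_group, control_group)
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    diff = m1 - m2
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full_like(se, float(n1 + n2 - 2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    with np.errstate(invalid="ignore"):
        p = np.where(zero_var, np.where(diff == 0, 1.0, 0.0), p)
        t = np.where(zero_var, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    return pd.DataFrame(
        {"t": t, "p_raw": p, "zero_variance": zero_var}, index=m.values.index
    )


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialTable:
    """Selected differential records plus the thresholds that produced them."""

    records: pd.DataFrame
    fc_min: float
    p_max: float

    def __len__(self) -> int:
        return len(self.records)


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    # lexsort: last key is primary (regulation, -fold, p, probe id)
    order = np.lexsort(
        (
            df.index.to_numpy(),
            df["p_raw"].to_numpy(),
            -df["fold_change"].to_numpy(),
            df["regulation"].map(_SORT_REG).to_numpy(),
        )
    )
    return df.iloc[order]


def select_differential(
    fold: pd.DataFrame,
    pvals: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> DifferentialTable:
    """Keep probes with ``fold_change >= fc_min`` and ``p_raw < p_max``.

    ``fold`` and ``pvals`` are the outputs of :func:`fold_change_and_direction`
    and :func:`two_group_t_test`, aligned on probe ids.
    """
    if not fold.index.equals(pvals.index):
        raise ValueError("fold-change and p-value tables are not aligned")
    df = fold.join(pvals[["p_raw"]])
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    kept = df[(df["fold_change"] >= fc_min) & (df["p_raw"] < p_max)]
    return DifferentialTable(records=_sort_records(kept.copy()), fc_min=fc_min, p_max=p_max)


def chromosome_distribution(
    table: DifferentialTable, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Counts of selected probes per (chromosome, regulation).

    ``annotation`` is indexed by probe with a ``chromosome`` column; probes
    missing from the annotation (or with an empty chromosome) land in the
    ``unplaced`` bucket.  Counts sum to the table size.
    """
    recs = table.records
    chroms = []
    for probe in recs.index:
        c = None
        if probe in annotation.index:
            c = annotation.loc[probe, "chromosome"]
        if c is None or (isinstance(c, float) and math.isnan(c)) or c == "":
            c = "unplaced"
        chroms.append(c)
    df = pd.DataFrame({"chromosome": chroms, "regulation": recs["regulation"].to_numpy()})
    counts = (
        df.groupby(["chromosome", "regulation"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


# ---------------------------------------------------------------------------
# hierarchical clustering (1 - Pearson distance, average linkage)
# ---------------------------------------------------------------------------

def correlation_distance(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise 1 - Pearson distance between the rows of X.

    Zero-variance rows cannot be correlated; their distance to everything is
    defined as 1 and they are flagged in the returned boolean mask.
    """
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    Z = centered / safe[:, None]
    D = 1.0 - Z @ Z.T
    D[flat, :] = 1.0
    D[:, flat] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0), flat


def average_linkage_merges(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Agglomerative average-linkage (UPGMA) merge sequence on distance D.

    Returns merges as (cluster_a, cluster_b, height); leaves are 0..n-1 and
    the i-th merge creates cluster n+i.  Ties are broken deterministically by
    the smallest original leaf index contained in each candidate cluster.
    """
    n = D.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    min_idx: dict[int, int] = {i: i for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = float(D[np.ix_(members[a], members[b])].mean())
                lo, hi = sorted((min_idx[a], min_idx[b]))
                key = (d, lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        key, a, b = best
        if min_idx[b] < min_idx[a]:
            a, b = b, a
        merges.append((a, b, key[0]))
        members[next_id] = members[a] + members[b]
        min_idx[next_id] = min(min_idx[a], min_idx[b])
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return merges


def _leaf_order(merges: list[tuple[int, int, float]], n: int) -> list[int]:
    if n == 1:
        return [0]
    children: dict[int, tuple[int, int]] = {}
    min_idx: dict[int, int] = {i: i for i in range(n)}
    node = n
    for a, b, _h in merges:
        children[node] = (a, b)
        min_idx[node] = min(min_idx[a], min_idx[b])
        node += 1
    order: list[int] = []

    def walk(c: int) -> None:
        if c < n:
            order.append(c)
            return
        a, b = children[c]
        first, second = (a, b) if min_idx[a] <= min_idx[b] else (b, a)
        walk(first)
        walk(second)

    walk(node - 1)
    return order


def hierarchical_cluster_order(m: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """Deterministic heatmap row (probe) and column (sample) leaf orders.

    Agglomerative average-linkage clustering on 1 - Pearson distance; tie
    breaks favour the smallest original index so the result is reproducible.
    """
    X = m.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 probes to cluster")
    D_rows, flat_rows = correlation_distance(X)
    if flat_rows.any():
        warnings.warn(f"{int(flat_rows.sum())} zero-variance rows; distance set to 1")
    row_order = _leaf_order(average_linkage_merges(D_rows), X.shape[0])
    D_cols, _ = correlation_distance(X.T)
    col_order = _leaf_order(average_linkage_merges(D_cols), X.shape[1])
    return (
        [m.values.index[i] for i in row_order],
        [m.values.columns[i] for i in col_order],
    )


def top_n(table: DifferentialTable, n: int) -> DifferentialTable:
    """Top ceil(n/2) upregulated and floor(n/2) downregulated by fold change.

    Mirrors a "top 20" report listing 10 up and 10 down.  If a side has fewer
    records than requested, all of them are returned with a warning.
    """
    recs = table.records
    up = recs[recs["regulation"] == "up"]
    down = recs[recs["regulation"] == "down"]
    want_up = math.ceil(n / 2)
    want_down = n // 2
    if len(up) < want_up or len(down) < want_down:
        warnings.warn("fewer records than requested in top_n; returning all available")
    out = pd.concat([up.head(want_up), down.head(want_down)])
    return DifferentialTable(records=out, fc_min=table.fc_min, p_max=table.p_max)


def volcano_table(fold: pd.DataFrame, pvals: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano columns: signed log2 fold change vs -log10 p."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pvals["p_raw"].to_numpy())
    return pd.DataFrame(
        {"log2_fc": fold["log2_fc"], "neg_log10_p": neglog}, index=fold.index
    )
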