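"""ceRNA (miRNA sponge) triplet inference.

A circRNA is called a candidate sponge for an mRNA when (a) some miRNA has at
least one perfect seed site on both the circRNA and the mRNA 3'UTR, and (b)
the circRNA and mRNA expression profiles are strongly positively correlated
across all samples (both groups pooled).  The correlation screen is the
Pearson product-moment coefficient with its exact t-transform p-value
(n - 2 degrees of freedom).  Sponge logic implies positive co-expression, so
negative correlations never qualify by default; an absolute-value mode is
available for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import DesignError, ExpressionMatrix
from .seedmatch import SeedMatch

__all__ = [
    "CeRNATriplet",
    "pairwise_pearson",
    "build_triplets",
    "triplet_table",
    "export_network",
    "to_graphml",
]


@dataclass(frozen=True)
class CeRNATriplet:
    """One circRNA--miRNA--mRNA candidate sponge interaction."""

    circ_id: str
    mirna_id: str
    mrna_id: str
    pearson_r: float
    r_pvalue: float
    circ_sites: int
    mrna_sites: int


def pairwise_pearson(
    circ_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix
) -> pd.DataFrame:
    """Pearson r and p for every (circRNA probe, mRNA probe) pair.

    Both matrices must carry the same samples in the same order; r is computed
    across all samples pooled.  p comes from the exact t transform
    ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 df.  Zero-variance series are
    skipped (their correlation is undefined) and counted in the
    ``skipped_zero_variance`` DataFrame attribute.
    """
    if list(circ_expr.values.columns) != list(mrna_expr.values.columns):
        raise DesignError("circRNA and mRNA matrices must share samples in order")
    n = circ_expr.values.shape[1]
    if n < 3:
        raise DesignError("need at least 3 samples for a correlation p-value")

    def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        flat = norms == 0
        Z = centered / np.where(flat, 1.0, norms)[:, None]
        return Z, flat

    Xc = circ_expr.values.to_numpy(dtype=float)
    Xm = mrna_expr.values.to_numpy(dtype=float)
    Zc, flat_c = _standardize(Xc)
    Zm, flat_m = _standardize(Xm)
    R = np.clip(Zc @ Zm.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(t), n - 2)
    P = np.where(np.abs(R) >= 1.0, 0.0, P)

    keep_c = ~flat_c
    keep_m = ~flat_m
    circ_ids = np.asarray(circ_expr.values.index)[keep_c]
    mrna_ids = np.asarray(mrna_expr.values.index)[keep_m]
    R = R[np.ix_(keep_c, keep_m)]
    P = P[np.ix_(keep_c, keep_m)]
    out = pd.DataFrame(
        {
            "circ": np.repeat(circ_ids, len(mrna_ids)),
            "mrna": np.tile(mrna_ids, len(circ_ids)),
            "r": R.ravel(),
            "p": P.ravel(),
        }
    )
    out.attrs["skipped_zero_variance"] = int(flat_c.sum() + flat_m.sum())
    return out


def build_triplets(
    target_map: Mapping[str, Mapping[str, list[SeedMatch]]],
    correlations: pd.DataFrame,
    r_min: float = 0.9,
    r_p_max: float = 0.05,
    use_abs: bool = False,
) -> list[CeRNATriplet]:
    """Emit (circ, miRNA, mRNA) triplets passing both evidence gates.

    A triplet requires the miRNA to target both the circRNA and the mRNA in
    ``target_map`` (>= 1 perfect seed site each) and the circ--mRNA Pearson r
    to reach ``r_min`` (signed by default) with p < ``r_p_max``.  Output is
    deduplicated and sorted by (circ, descending r, mirna, mrna).
    """
    corr = {
        (c, g): (r, p)
        for c, g, r, p in zip(
            correlations["circ"], correlations["mrna"],
            correlations["r"], correlations["p"],
        )
    }
    triplets: dict[tuple[str, str, str], CeRNATriplet] = {}
    for mirna_id, targets in target_map.items():
        circs = [(t, s) for t, s in targets.items() if s[0].target_class == "circRNA"]
        mrnas = [(t, s) for t, s in targets.items() if s[0].target_class == "mRNA_3utr"]
        for c_id, c_sites in circs:
            for g_id, g_sites in mrnas:
                pair = corr.get((c_id, g_id))
                if pair is None:
                    continue
                r, p = pair
                stat = abs(r) if use_abs else r
                if stat >= r_min and p < r_p_max:
                    triplets[(c_id, mirna_id, g_id)] = CeRNATriplet(
                        circ_id=c_id,
                        mirna_id=mirna_id,
                        mrna_id=g_id,
                        pearson_r=float(r),
                        r_pvalue=float(p),
                        circ_sites=len(c_sites),
                        mrna_sites=len(g_sites),
                    )
    return sorted(
        triplets.values(),
        key=lambda t: (t.circ_id, -t.pearson_r, t.mirna_id, t.mrna_id),
    )


def triplet_table(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ": t.circ_id,
                "mirna": t.mirna_id,
                "mrna": t.mrna_id,
                "pearson_r": t.pearson_r,
                "r_pvalue": t.r_pvalue,
                "circ_sites": t.circ_sites,
                "mrna_sites": t.mrna_sites,
            }
            for t in triplets
        ],
        columns=["circ", "mirna", "mrna", "pearson_r", "r_pvalue", "circ_sites", "mrna_sites"],
    )


def export_network(
    triplets: Sequence[CeRNATriplet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (circ->miRNA, miRNA->mRNA) and node table with classes."""
    edges: dict[tuple[str, str, str], None] = {}
    nodes: dict[str, str] = {}
    for t in triplets:
        edges[(t.circ_id, t.mirna_id, "circ-mirna")] = None
        edges[(t.mirna_id, t.mrna_id, "mirna-mrna")] = None
        nodes[t.circ_id] = "circRNA"
        nodes[t.mirna_id] = "miRNA"
        nodes[t.mrna_id] = "mRNA"
    edge_df = pd.DataFrame(
        sorted(edges), columns=["source", "target", "edge_type"]
    )
    node_df = pd.DataFrame(
        sorted(nodes.items()), columns=["node", "node_class"]
    )
    return edge_df, node_df


def to_graphml(triplets: Sequence[CeRNATriplet], path) -> None:
    """Optional GraphML export for network viewers."""
    import networkx as nx

    edge_df, node_df = export_network(triplets)
    G = nx.DiGraph()
    for _, row in node_df.iterrows():
        G.add_node(row["node"], node_class=row["node_class"])
    for _, row in edge_df.iterrows():
        G.add_edge(row["source"], row["target"], edge_type=row["edge_type"])
    nx.write_graphml(G, path)
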