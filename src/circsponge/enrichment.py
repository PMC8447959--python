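"""Hypergeometric term enrichment (GO-like and pathway-like gene sets).

For a gene list of size n drawn from a background of N genes, a term covering
K background genes and hitting k list genes is scored with the upper-tail
hypergeometric probability P[X >= k] (enrichment only, never depletion).
Fold enrichment is (k/n)/(K/N) and the reporting score is -log10 p, the usual
bar-chart ranking quantity.  Benjamini-Hochberg adjustment is applied across
the tested terms within each category (BP/CC/MF/pathway).

Terms with no hit in the list (k = 0) are omitted from the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "Term",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrich",
    "select_enriched",
    "rank_terms",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# TermGeneMap = dict[term_id, Term]


def read_gmt(path: str | Path) -> dict[str, Term]:
    """Read a GMT file; the description column encodes ``category|name``."""
    terms: dict[str, Term] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, desc = fields[0], fields[1]
            category, _, name = desc.partition("|")
            if term_id in terms:
                raise ValueError(f"duplicate term id {term_id}")
            terms[term_id] = Term(
                term_id=term_id,
                name=name or term_id,
                category=category if category in CATEGORIES else "BP",
                genes=frozenset(g for g in fields[2:] if g),
            )
    return terms


def write_gmt(terms: Mapping[str, Term], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            t = terms[term_id]
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.category}|{t.name}\t{genes}\n")


def hypergeometric_enrich(
    gene_list: Iterable[str],
    terms: Mapping[str, Term],
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` in every term.

    Genes outside the background are dropped with a warning.  Returns one row
    per term with at least one hit: term metadata, the (k, K, n, N) counts,
    p, BH-adjusted p within category, fold enrichment and -log10 p score.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    genes = set(gene_list)
    outside = genes - bg
    if outside:
        warnings.warn(f"{len(outside)} list genes outside background; dropped")
    genes &= bg
    N = len(bg)
    n = len(genes)
    rows = []
    for term_id in sorted(terms):
        t = terms[term_id]
        term_genes = t.genes & bg
        K = len(term_genes)
        k = len(term_genes & genes)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        fe = (k / n) / (K / N)
        rows.append(
            {
                "term_id": term_id,
                "name": t.name,
                "category": t.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "fold_enrichment": fe,
                "score": float(-np.log10(p)) if p > 0 else np.inf,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term_id", "name", "category", "k", "K", "n", "N", "p",
                 "fold_enrichment", "score"],
    )
    if len(df):
        df["p_adj"] = np.nan
        for cat, idx in df.groupby("category").groups.items():
            df.loc[idx, "p_adj"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df


def select_enriched(
    results: pd.DataFrame, fe_min: float = 2.0, p_max: float = 0.05
) -> pd.DataFrame:
    """Keep terms with fold_enrichment >= fe_min and p < p_max."""
    return results[
        (results["fold_enrichment"] >= fe_min) & (results["p"] < p_max)
    ].copy()


def rank_terms(
    results: pd.DataFrame, n: int = 10, per_category: bool = False
) -> pd.DataFrame:
    """Top terms by descending -log10 p score, ties broken by term id."""
    ordered = results.sort_values(
        ["score", "term_id"], ascending=[False, True], kind="stable"
    )
    if per_category:
        return (
            ordered.groupby("category", group_keys=False, sort=True)
            .head(n)
            .copy()
        )
    return ordered.head(n).copy()
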