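"""Function-focused candidate selection: angiogenesis, proliferation, migration.

The final maneuver of the pipeline: pick differentially expressed mRNAs
annotated to vascular-endothelial keyword terms at stricter thresholds
(strictly >2-fold, p < 0.01), then walk the ceRNA triplets backwards to label
differentially expressed circRNAs with the biological functions of the mRNAs
they may de-repress.  Keyword terms are data (a plain TSV shipped with the
package, editable), seeded with the standard mouse angiogenesis GO ids
(e.g. GO:0001525 angiogenesis, GO:0045766 positive regulation of
angiogenesis) and the angiogenesis-relevant KEGG pathways (mmu04370 VEGF
signaling, mmu04151 PI3K-Akt, mmu04014 Ras, mmu04512 ECM-receptor
interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cerna import CeRNATriplet
from .diffexp import DifferentialTable
from .enrichment import Term

__all__ = [
    "FUNCTIONS",
    "KeywordTermSet",
    "load_default_keywords",
    "select_functional_mrnas",
    "map_mrnas_to_circrnas",
    "summarize_candidates",
    "candidate_set_algebra",
]

FUNCTIONS = ("proliferation", "migration", "angiogenesis")


@dataclass
class KeywordTermSet:
    """function -> set of term ids, with each term's source (GO vs pathway)."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)  # term_id -> GO|pathway
    name_patterns: dict[str, set[str]] = field(default_factory=dict)

    def functions_of_term(self, term_id: str) -> set[str]:
        return {f for f, ids in self.terms.items() if term_id in ids}

    def all_term_ids(self, source: str | None = None) -> set[str]:
        ids = set().union(*self.terms.values()) if self.terms else set()
        if source is None:
            return ids
        return {t for t in ids if self.source.get(t) == source}

    def restricted_to(self, source: str) -> "KeywordTermSet":
        keep = self.all_term_ids(source)
        return KeywordTermSet(
            terms={f: ids & keep for f, ids in self.terms.items()},
            source={t: s for t, s in self.source.items() if t in keep},
            name_patterns=dict(self.name_patterns),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordTermSet":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        ks = cls()
        for _, row in df.iterrows():
            for f in row["functions"].split(","):
                f = f.strip()
                if f not in FUNCTIONS:
                    raise ValueError(f"unknown function {f!r}")
                ks.terms.setdefault(f, set()).add(row["term_id"])
            ks.source[row["term_id"]] = row["source"]
        return ks


def load_default_keywords() -> KeywordTermSet:
    """The packaged keyword term set (editable text in circsponge/data)."""
    path = resources.files("circsponge.data") / "keyword_terms.tsv"
    return KeywordTermSet.from_tsv(str(path))


@dataclass
class LabeledMRNA:
    gene: str
    probe: str
    fold_change: float
    regulation: str
    p_raw: float
    flags: frozenset[str]
    evidence_terms: dict[str, set[str]]  # function -> supporting term ids


def select_functional_mrnas(
    mrna_diff: DifferentialTable,
    terms: Mapping[str, Term],
    keywords: KeywordTermSet,
    gene_of: Mapping[str, str],
    fc_min: float = 2.0,
    p_max: float = 0.01,
    match_names: bool = False,
) -> list[LabeledMRNA]:
    """mRNAs with fold change strictly > fc_min, p < p_max, and membership in
    at least one keyword term; each gets a function label with evidence.

    ``gene_of`` maps mRNA probe id to gene symbol.  ``match_names`` adds
    name-substring matching (e.g. any term whose name contains
    "angiogenesis") on top of the explicit id lists.
    """
    labeled: list[LabeledMRNA] = []
    for probe, rec in mrna_diff.records.iterrows():
        if not (rec["fold_change"] > fc_min and rec["p_raw"] < p_max):
            continue
        gene = gene_of.get(probe, "")
        if not gene:
            continue
        evidence: dict[str, set[str]] = {}
        for term_id in keywords.all_term_ids():
            term = terms.get(term_id)
            if term is None or gene not in term.genes:
                continue
            for f in keywords.functions_of_term(term_id):
                evidence.setdefault(f, set()).add(term_id)
        if match_names:
            for term_id, term in terms.items():
                if gene not in term.genes:
                    continue
                lowered = term.name.lower()
                for f, patterns in keywords.name_patterns.items():
                    if any(p in lowered for p in patterns):
                        evidence.setdefault(f, set()).add(term_id)
        if evidence:
            labeled.append(
                LabeledMRNA(
                    gene=gene,
                    probe=probe,
                    fold_change=float(rec["fold_change"]),
                    regulation=rec["regulation"],
                    p_raw=float(rec["p_raw"]),
                    flags=frozenset(evidence),
                    evidence_terms=evidence,
                )
            )
    return labeled


@dataclass
class CircCandidate:
    circ_id: str
    fold_change: float
    regulation: str
    flags: frozenset[str]
    chains: list[tuple[str, str]]  # (mirna, mrna gene) supporting chains


def map_mrnas_to_circrnas(
    labeled_mrnas: Sequence[LabeledMRNA],
    triplets: Sequence[CeRNATriplet],
    circ_diff: DifferentialTable,
    mrna_gene_of: Mapping[str, str] | None = None,
) -> list[CircCandidate]:
    """circRNA candidates: differentially expressed AND sponging at least one
    labeled mRNA through a ceRNA triplet.

    The candidate's function label is the union over its supporting mRNAs;
    output is sorted by descending fold change (ties by circ id).
    """
    by_gene: dict[str, LabeledMRNA] = {}
    for lm in labeled_mrnas:
        by_gene.setdefault(lm.gene, lm)
    de_circ = circ_diff.records
    candidates: dict[str, CircCandidate] = {}
    for t in triplets:
        if t.circ_id not in de_circ.index:
            continue
        gene = (mrna_gene_of or {}).get(t.mrna_id, t.mrna_id)
        lm = by_gene.get(gene)
        if lm is None:
            continue
        cand = candidates.get(t.circ_id)
        if cand is None:
            rec = de_circ.loc[t.circ_id]
            cand = CircCandidate(
                circ_id=t.circ_id,
                fold_change=float(rec["fold_change"]),
                regulation=rec["regulation"],
                flags=frozenset(),
                chains=[],
            )
            candidates[t.circ_id] = cand
        cand.flags = cand.flags | lm.flags
        chain = (t.mirna_id, gene)
        if chain not in cand.chains:
            cand.chains.append(chain)
    return sorted(candidates.values(), key=lambda c: (-c.fold_change, c.circ_id))


def summarize_candidates(
    candidates: Sequence[CircCandidate], n: int = 10
) -> pd.DataFrame:
    """Long-format report of the top-n candidates by fold change: one row per
    supporting (miRNA, target gene) chain."""
    rows = []
    for cand in candidates[:n]:
        flags = "/".join(f.capitalize() for f in FUNCTIONS if f in cand.flags)
        for mirna, gene in cand.chains:
            rows.append(
                {
                    "circRNA": cand.circ_id,
                    "fold_change": cand.fold_change,
                    "regulation": cand.regulation,
                    "miRNA": mirna,
                    "target_gene": gene,
                    "functions": flags,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["circRNA", "fold_change", "regulation", "miRNA", "target_gene", "functions"],
    )


def candidate_set_algebra(
    go_candidates: Iterable[str], pathway_candidates: Iterable[str]
) -> dict[str, int]:
    """Report the GO-derived and pathway-derived candidate circRNA sets under
    every set reading: each count, the naive sum (double-counts the overlap),
    the union, and the intersection."""
    go = set(go_candidates)
    kegg = set(pathway_candidates)
    return {
        "go_count": len(go),
        "pathway_count": len(kegg),
        "sum_with_overlap": len(go) + len(kegg),
        "union": len(go | kegg),
        "intersection": len(go & kegg),
    }
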