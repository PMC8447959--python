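"""Function-labelled mRNA selection and candidate circRNA mapping."""

import numpy as np
import pandas as pd
import pytest

from circsponge import fixtures
from circsponge.cerna import CeRNATriplet
from circsponge.diffexp import DifferentialTable, _sort_records
from circsponge.enrichment import Term
from circsponge.functional import (
    KeywordTermSet,
    candidate_set_algebra,
    load_default_keywords,
    map_mrnas_to_circrnas,
    select_functional_mrnas,
    summarize_candidates,
)


def _diff(rows):
    """rows: (probe, fold, regulation, p)"""
    df = pd.DataFrame(
        {
            "fold_change": [r[1] for r in rows],
            "regulation": [r[2] for r in rows],
            "p_raw": [r[3] for r in rows],
        },
        index=[r[0] for r in rows],
    )
    return DifferentialTable(records=_sort_records(df), fc_min=2.0, p_max=0.05)


def _term(tid, cat, genes):
    return Term(tid, tid.lower(), cat, frozenset(genes))


KEYWORDS = KeywordTermSet(
    terms={"angiogenesis": {"GO:0001525"}, "proliferation": {"mmu04151"}},
    source={"GO:0001525": "GO", "mmu04151": "pathway"},
)
TERMS = {
    "GO:0001525": _term("GO:0001525", "BP", ["GeneA", "GeneB"]),
    "mmu04151": _term("mmu04151", "pathway", ["GeneB", "GeneC"]),
    "TERM:1": _term("TERM:1", "MF", ["GeneD"]),
}
GENE_OF = {"m1": "GeneA", "m2": "GeneB", "m3": "GeneC", "m4": "GeneD"}


class TestSelectFunctionalMrnas:
    def test_rule_application_and_flags(self):
        diff = _diff([("m1", 3.0, "up", 0.005), ("m4", 5.0, "up", 0.001)])
        labeled = select_functional_mrnas(diff, TERMS, KEYWORDS, GENE_OF)
        assert [lm.gene for lm in labeled] == ["GeneA"]
        assert labeled[0].flags == frozenset({"angiogenesis"})
        assert labeled[0].evidence_terms["angiogenesis"] == {"GO:0001525"}

    def test_p_gate_strict(self):
        diff = _diff([("m1", 3.0, "up", 0.02)])
        assert select_functional_mrnas(diff, TERMS, KEYWORDS, GENE_OF, p_max=0.01) == []

    def test_fold_gate_strict(self):
        diff = _diff([("m1", 2.0, "up", 0.001)])
        assert select_functional_mrnas(diff, TERMS, KEYWORDS, GENE_OF, fc_min=2.0) == []

    def test_exhaustive_agreement_with_hand_enumeration(self, rng):
        genes = [f"G{i}" for i in range(60)]
        terms = {
            "GO:0001525": _term("GO:0001525", "BP", list(rng.choice(genes, 15, replace=False))),
            "mmu04151": _term("mmu04151", "pathway", list(rng.choice(genes, 15, replace=False))),
        }
        gene_of = {f"m{i}": genes[i] for i in range(60)}
        rows = [
            (f"m{i}", float(rng.uniform(1, 6)), "up", float(rng.uniform(0, 0.05)))
            for i in range(60)
        ]
        diff = _diff(rows)
        labeled = {lm.probe for lm in select_functional_mrnas(diff, terms, KEYWORDS, gene_of)}
        keyword_genes = terms["GO:0001525"].genes | terms["mmu04151"].genes
        expected = {
            p for p, f, _reg, pv in rows
            if f > 2.0 and pv < 0.01 and gene_of[p] in keyword_genes
        }
        assert labeled == expected

    def test_monotone_in_keyword_set(self):
        diff = _diff([("m1", 3.0, "up", 0.005), ("m3", 4.0, "up", 0.002)])
        small = KeywordTermSet(terms={"angiogenesis": {"GO:0001525"}},
                               source={"GO:0001525": "GO"})
        bigger = KEYWORDS
        got_small = {lm.gene for lm in select_functional_mrnas(diff, TERMS, small, GENE_OF)}
        got_big = {lm.gene for lm in select_functional_mrnas(diff, TERMS, bigger, GENE_OF)}
        assert got_small <= got_big


class TestMapToCircRNAs:
    def _triplet(self, c, m, g):
        return CeRNATriplet(c, m, g, 0.95, 0.01, 1, 1)

    def test_label_propagation_with_chain(self):
        circ_diff = _diff([("c1", 6.0, "up", 0.01)])
        mrna_diff = _diff([("m1", 3.0, "up", 0.005)])
        labeled = select_functional_mrnas(mrna_diff, TERMS, KEYWORDS, GENE_OF)
        cands = map_mrnas_to_circrnas(
            labeled, [self._triplet("c1", "mirX", "m1")], circ_diff,
            mrna_gene_of=GENE_OF,
        )
        assert len(cands) == 1
        assert cands[0].flags == frozenset({"angiogenesis"})
        assert cands[0].chains == [("mirX", "GeneA")]

    def test_unlabeled_targets_excluded(self):
        circ_diff = _diff([("c1", 6.0, "up", 0.01)])
        cands = map_mrnas_to_circrnas(
            [], [self._triplet("c1", "mirX", "m1")], circ_diff, mrna_gene_of=GENE_OF
        )
        assert cands == []

    def test_non_differential_circ_excluded(self):
        circ_diff = _diff([("other", 6.0, "up", 0.01)])
        mrna_diff = _diff([("m1", 3.0, "up", 0.005)])
        labeled = select_functional_mrnas(mrna_diff, TERMS, KEYWORDS, GENE_OF)
        cands = map_mrnas_to_circrnas(
            labeled, [self._triplet("c1", "mirX", "m1")], circ_diff, mrna_gene_of=GENE_OF
        )
        assert cands == []

    def test_published_topology_summary(self):
        # rebuild the published candidate table shape from the fixtures:
        # top candidate circRNA.7079 reaches Lgals3 via two distinct miRNAs
        t3 = fixtures.typed_table3()
        circ_diff = fixtures.table1_differential()
        triplets = [
            CeRNATriplet(row["circRNA"], row["miRNA"], row["target_gene"], 0.95, 0.01, 1, 1)
            for _, row in t3.iterrows()
        ]
        terms = {"GO:0001525": _term("GO:0001525", "BP", sorted(set(t3["target_gene"])))}
        keywords = KeywordTermSet(terms={"angiogenesis": {"GO:0001525"}},
                                  source={"GO:0001525": "GO"})
        gene_of = {g: g for g in set(t3["target_gene"])}
        mrna_diff = _diff([(g, 4.0, "up", 0.001) for g in sorted(set(t3["target_gene"]))])
        labeled = select_functional_mrnas(mrna_diff, terms, keywords, gene_of)
        cands = map_mrnas_to_circrnas(labeled, triplets, circ_diff, mrna_gene_of=gene_of)
        assert cands[0].circ_id == "circRNA.7079"
        assert ("mmu-miR-761", "Lgals3") in cands[0].chains
        assert ("mmu-miR-1907", "Lgals3") in cands[0].chains
        summary = summarize_candidates(cands, n=10)
        assert summary["circRNA"].iloc[0] == "circRNA.7079"
        # long format: one row per chain for a multi-chain candidate
        assert (summary["circRNA"] == "circRNA.7079").sum() == len(cands[0].chains)

    def test_candidates_sorted_by_fold(self):
        circ_diff = _diff([("c1", 3.0, "up", 0.01), ("c2", 9.0, "up", 0.01)])
        mrna_diff = _diff([("m1", 3.0, "up", 0.005)])
        labeled = select_functional_mrnas(mrna_diff, TERMS, KEYWORDS, GENE_OF)
        cands = map_mrnas_to_circrnas(
            labeled,
            [self._triplet("c1", "x", "m1"), self._triplet("c2", "y", "m1")],
            circ_diff, mrna_gene_of=GENE_OF,
        )
        assert [c.circ_id for c in cands] == ["c2", "c1"]


class TestSetAlgebra:
    def test_union_bounds(self, rng):
        for _ in range(20):
            go = set(rng.choice(50, size=rng.integers(0, 20), replace=False).tolist())
            kegg = set(rng.choice(50, size=rng.integers(0, 20), replace=False).tolist())
            out = candidate_set_algebra(go, kegg)
            assert max(out["go_count"], out["pathway_count"]) <= out["union"]
            assert out["union"] <= out["sum_with_overlap"]
            assert out["union"] + out["intersection"] == out["sum_with_overlap"]

    def test_default_keywords_load(self):
        ks = load_default_keywords()
        assert {"proliferation", "migration", "angiogenesis"} <= set(ks.terms)
        assert "GO:0001525" in ks.terms["angiogenesis"]
        assert ks.source["mmu04370"] == "pathway"
        go_only = ks.restricted_to("GO")
        assert go_only.all_term_ids() == ks.all_term_ids("GO")
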