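"""Generator contracts: determinism, planted-site integrity, calibration."""

import io

import numpy as np
import pytest

from circsponge import synthetic
from circsponge.matrix import DesignError
from circsponge.seedmatch import find_seed_matches, write_fasta
from circsponge.synthetic import (
    IdentifierError,
    generate_annotations,
    generate_expression,
    generate_sequences,
)


def _fasta_bytes(records, tmp_path, name):
    path = tmp_path / name
    write_fasta(records, path)
    return path.read_bytes()


class TestGenerateSequences:
    def test_planted_site_is_exact_reverse_complement(self):
        plan = [("miR1", "circ1", 1)]
        records, truth = generate_sequences(2, 2, 2, site_plan=plan, rng_seed=5)
        by_id = {r.id: r for r in records}
        (mirna_id, target_id, pos) = next(iter(truth.planted_sites))
        hits = find_seed_matches(by_id[mirna_id], by_id[target_id], kinds=("7mer_m8",))
        assert pos in {h.start for h in hits}

    def test_empty_plan_records_no_sites(self):
        _records, truth = generate_sequences(2, 2, 2, site_plan=[], rng_seed=5)
        assert truth.planted_sites == set()

    def test_deterministic_fasta_bytes(self, tmp_path):
        a, _ = generate_sequences(3, 4, 4, site_plan=[("miR1", "circ2", 2)], rng_seed=9)
        b, _ = generate_sequences(3, 4, 4, site_plan=[("miR1", "circ2", 2)], rng_seed=9)
        assert _fasta_bytes(a, tmp_path, "a.fasta") == _fasta_bytes(b, tmp_path, "b.fasta")
        c, _ = generate_sequences(3, 4, 4, site_plan=[("miR1", "circ2", 2)], rng_seed=10)
        assert _fasta_bytes(a, tmp_path, "a2.fasta") != _fasta_bytes(c, tmp_path, "c.fasta")

    def test_unknown_ids_rejected(self):
        with pytest.raises(IdentifierError):
            generate_sequences(1, 1, 1, site_plan=[("nope", "circ1", 1)], rng_seed=0)
        with pytest.raises(IdentifierError):
            generate_sequences(1, 1, 1, site_plan=[("miR1", "nope", 1)], rng_seed=0)

    def test_all_planted_sites_recovered(self):
        # site-integrity invariant: the matcher finds 100% of planted sites
        plan = [("miR1", "circ1", 2), ("miR2", "utr1", 1), ("miR3", "circ2", 3)]
        records, truth = generate_sequences(4, 3, 3, site_plan=plan, rng_seed=21)
        by_id = {r.id: r for r in records}
        for mirna_id, target_id, pos in truth.planted_sites:
            hits = find_seed_matches(
                by_id[mirna_id], by_id[target_id], kinds=("7mer_m8",)
            )
            assert pos in {h.start for h in hits}


class TestGenerateExpression:
    def test_noise_free_limit_recovers_planted_fold(self):
        probes = ["a", "b", "c"]
        m, _ = generate_expression(
            probes, de_plan=[("a", "up", 4.0)], noise_sd=1e-9, rng_seed=0
        )
        vals = np.log2(m.values.to_numpy())
        realized = 2 ** (vals[0, 3:].mean() - vals[0, :3].mean())
        assert realized == pytest.approx(4.0, rel=1e-6)

    def test_degenerate_correlation_limit(self):
        probes = ["c", "g"]
        m, _ = generate_expression(
            probes, triplet_plan=[("c", "g", 1.0)], noise_sd=1e-6, rng_seed=0,
            baseline_sd=0.0,
        )
        vals = np.log2(m.values.to_numpy())
        r = np.corrcoef(vals[0], vals[1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_mean_realized_fold_calibrated(self):
        # Monte-Carlo mean of realized log2 fold against the planted effect
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(5)]
        plan = [(p, "up", 3.0) for p in probes]
        realized = []
        for _ in range(200):
            m, _ = generate_expression(
                probes, de_plan=plan, noise_sd=0.25,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            vals = np.log2(m.values.to_numpy())
            realized.extend(vals[:, 3:].mean(axis=1) - vals[:, :3].mean(axis=1))
        assert np.mean(realized) == pytest.approx(np.log2(3.0), abs=0.1)
        # and within 3 standard errors of the plan
        se = np.std(realized, ddof=1) / np.sqrt(len(realized))
        assert abs(np.mean(realized) - np.log2(3.0)) < 3 * se + 1e-12

    def test_planted_latent_correlation_calibrated(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(300):
            m, _ = generate_expression(
                ["c", "g"], triplet_plan=[("c", "g", 0.9)], noise_sd=0.25,
                rng_seed=int(rng.integers(0, 2**31 - 1)), baseline_sd=0.0,
            )
            vals = np.log2(m.values.to_numpy())
            rs.append(np.corrcoef(vals[0], vals[1])[0, 1])
        # small-sample Pearson r is biased low; Fisher-z mean should sit near
        # atanh(0.9) (exact small-n mean is slightly below; wide tolerance)
        assert np.mean(rs) == pytest.approx(0.9, abs=0.07)

    def test_intensities_positive_and_deterministic(self):
        m1, _ = generate_expression(["a", "b"], rng_seed=3)
        m2, _ = generate_expression(["a", "b"], rng_seed=3)
        assert (m1.values.to_numpy() > 0).all()
        assert np.array_equal(m1.values.to_numpy(), m2.values.to_numpy())

    def test_design_and_plan_validation(self):
        with pytest.raises(DesignError):
            generate_expression(["a"], n_per_group=1)
        with pytest.raises(IdentifierError):
            generate_expression(["a"], de_plan=[("zz", "up", 2.0)])
        with pytest.raises(ValueError):
            generate_expression(["a"], de_plan=[("a", "up", -1.0)])
        with pytest.raises(ValueError):
            generate_expression(["a", "b"], triplet_plan=[("a", "b", 1.5)])


class TestGenerateAnnotations:
    def test_fields_complete_and_reproducible(self, tmp_path):
        probes = [f"p{i}" for i in range(50)]
        ann1, terms1 = generate_annotations(probes, n_terms=10, rng_seed=4)
        ann2, terms2 = generate_annotations(probes, n_terms=10, rng_seed=4)
        assert ann1.equals(ann2)
        assert set(ann1.columns) == {"host_gene", "chromosome", "strand"}
        assert set(ann1["strand"]) <= {"+", "-"}
        assert all(c.startswith("chr") for c in ann1["chromosome"])
        from circsponge.enrichment import write_gmt

        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(terms1, p1)
        write_gmt(terms2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_some_probes_missing_host_gene(self):
        probes = [f"p{i}" for i in range(200)]
        ann, _ = generate_annotations(probes, n_terms=5, rng_seed=4,
                                      missing_host_fraction=0.1)
        assert (ann["host_gene"] == "").sum() > 0

    def test_angio_terms_included_with_expected_categories(self):
        probes = [f"p{i}" for i in range(30)]
        angio = ["GO:0001525", "mmu04370"]
        _, terms = generate_annotations(probes, n_terms=8, angio_terms=angio, rng_seed=1)
        assert terms["GO:0001525"].category == "BP"
        assert terms["mmu04370"].category == "pathway"
        assert all(len(t.genes) >= 1 for t in terms.values())

    def test_saturated_single_term_enriches_to_p_one(self):
        from circsponge.enrichment import Term, hypergeometric_enrich

        genes = [f"G{i}" for i in range(20)]
        term = Term("ALL", "everything", "BP", frozenset(genes))
        res = hypergeometric_enrich(genes[:6], {"ALL": term}, genes)
        assert res["p"].iloc[0] == pytest.approx(1.0)
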