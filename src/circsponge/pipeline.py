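"""End-to-end orchestration: simulate -> preprocess -> differential expression
-> seed matching -> ceRNA triplets -> enrichment -> functional subset.

``run_pipeline`` drives every stage from a validated :class:`RunConfig`,
writes each stage's tables atomically under the output directory, and records
a manifest (seed, thresholds, row counts, output checksums).  Re-running with
the same configuration reproduces identical outputs (manifest timestamps
aside).

The simulate stage builds the packaged demo study: a two-group (sham vs SCI,
n = 3 each) array with planted sponge triplets -- injury-induced circRNAs and
mRNAs sharing a miRNA seed site and co-fluctuating through a latent factor --
among background probes, decoy differential probes and low-intensity probes,
with annotation linking planted mRNA genes to angiogenesis keyword terms.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cerna, diffexp, enrichment, functional, preprocess, seedmatch, synthetic
from .matrix import ExpressionMatrix

__all__ = ["RunConfig", "SimulatedStudy", "PipelineResult", "simulate_study", "run_pipeline"]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_mirna": 20,
        "n_circ": 90,
        "n_mrna": 90,
        "n_planted_triplets": 10,
        "planted_fold": 8.0,
        "planted_r": 0.9,
        "n_decoy_de_circ": 15,
        "n_decoy_de_mrna": 10,
        "decoy_fold": 4.0,
        "n_low_intensity": 10,
        "noise_sd": 0.25,
        "n_terms": 40,
        "n_per_group": 3,
        "group_labels": ["sham", "SCI"],
    },
    "preprocess": {"log2_offset": 1.0, "quantile_cut": 0.2, "min_samples": 3},
    "diffexp": {"fc_min": 2.0, "p_max": 0.05, "t_variant": "pooled"},
    "seedmatch": {"kinds": ["7mer_m8", "8mer"], "min_sites": 1, "circular": True},
    "cerna": {"r_min": 0.9, "r_p_max": 0.05, "use_abs": False},
    "enrichment": {"fe_min": 2.0, "p_max": 0.05},
    "functional": {"fc_min": 2.0, "p_max": 0.01},
}


@dataclass
class RunConfig:
    """Validated stage parameters; unknown keys are rejected."""

    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = copy.deepcopy(_DEFAULTS)
        for key, value in self.params.items():
            if key not in merged:
                raise ValueError(f"unknown config section {key!r}")
            if isinstance(merged[key], dict):
                for sub, v in value.items():
                    if sub not in merged[key]:
                        raise ValueError(f"unknown config key {key}.{sub}")
                    merged[key][sub] = v
            else:
                merged[key] = value
        for section in ("diffexp", "enrichment", "functional"):
            if merged[section]["fc_min" if "fc_min" in merged[section] else "fe_min"] <= 0:
                raise ValueError(f"{section} threshold must be positive")
        self.params = merged

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(params=raw)


@dataclass
class SimulatedStudy:
    sequences: list[seedmatch.SequenceRecord]
    expression: ExpressionMatrix  # raw scale, circ + mRNA probes
    annotation: pd.DataFrame  # host_gene, chromosome, strand, molecule_class
    terms: dict[str, enrichment.Term]
    truth: synthetic.TruthTable
    gene_of: dict[str, str]


def simulate_study(sim: Mapping[str, Any], seed: int) -> SimulatedStudy:
    """Build the demo study under the configured conditions."""
    rng = np.random.default_rng(seed)
    n_trip = sim["n_planted_triplets"]
    site_plan = [(f"miR{i+1}", f"circ{i+1}", 1) for i in range(n_trip)] + [
        (f"miR{i+1}", f"utr{i+1}", 1) for i in range(n_trip)
    ]
    sequences, seq_truth = synthetic.generate_sequences(
        n_mirna=sim["n_mirna"],
        n_circ=sim["n_circ"],
        n_mrna=sim["n_mrna"],
        site_plan=site_plan,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )

    circ_probes = [f"circ{i+1}" for i in range(sim["n_circ"])]
    mrna_probes = [f"utr{i+1}" for i in range(sim["n_mrna"])]
    probes = circ_probes + mrna_probes

    fold = sim["planted_fold"]
    de_plan = [(f"circ{i+1}", "up", fold * (1 + i % 3)) for i in range(n_trip)]
    de_plan += [(f"utr{i+1}", "up", fold) for i in range(n_trip)]
    # decoy differential probes without sponge structure, mixed directions
    for j in range(sim["n_decoy_de_circ"]):
        de_plan.append(
            (f"circ{n_trip + j + 1}", "up" if j % 2 == 0 else "down", sim["decoy_fold"] + j % 4)
        )
    for j in range(sim["n_decoy_de_mrna"]):
        de_plan.append(
            (f"utr{n_trip + j + 1}", "up" if j % 2 == 0 else "down", sim["decoy_fold"] + j % 3)
        )
    triplet_plan = [(f"circ{i+1}", f"utr{i+1}", sim["planted_r"]) for i in range(n_trip)]
    low = {
        p: 2.0
        for p in (circ_probes[-sim["n_low_intensity"] :] + mrna_probes[-sim["n_low_intensity"] :])
    }
    expression, expr_truth = synthetic.generate_expression(
        probe_ids=probes,
        de_plan=de_plan,
        triplet_plan=triplet_plan,
        noise_sd=sim["noise_sd"],
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        group_labels=tuple(sim["group_labels"]),
        n_per_group=sim["n_per_group"],
        baseline_overrides=low,
    )
    expr_truth.planted_triplets = {
        (c, f"miR{i+1}", g) for i, (c, g, _r) in enumerate(triplet_plan)
    }

    gene_of = {p: f"G{p}" for p in probes}
    angio = ["GO:0001525", "GO:0045766", "GO:0001935", "GO:0043542", "mmu04370", "mmu04151"]
    forced = []
    for i in range(n_trip):
        gene = gene_of[f"utr{i+1}"]
        forced.append((angio[i % len(angio)], gene))
        forced.append(("GO:0001525", gene))
        # host genes of the injury-induced circRNAs share pathway annotation,
        # so the enrichment stage has real signal to find
        forced.append(("mmu04151", gene_of[f"circ{i+1}"]))
        forced.append(("GO:0045766", gene_of[f"circ{i+1}"]))
    annotation, terms = synthetic.generate_annotations(
        probes=probes,
        n_terms=sim["n_terms"],
        angio_terms=angio,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        gene_of=gene_of,
        missing_host_fraction=0.05,
        forced_memberships=forced,
    )
    # planted functional genes must keep their annotation
    for i in range(n_trip):
        annotation.loc[f"utr{i+1}", "host_gene"] = gene_of[f"utr{i+1}"]
        annotation.loc[f"circ{i+1}", "host_gene"] = gene_of[f"circ{i+1}"]
    annotation["molecule_class"] = ["circRNA"] * len(circ_probes) + ["mRNA_3utr"] * len(
        mrna_probes
    )
    return SimulatedStudy(
        sequences=sequences,
        expression=expression,
        annotation=annotation,
        terms=terms,
        truth=seq_truth.merged_with(expr_truth),
        gene_of=gene_of,
    )


@dataclass
class PipelineResult:
    manifest: dict[str, Any]
    study: SimulatedStudy
    normalized: ExpressionMatrix
    circ_diff: diffexp.DifferentialTable
    mrna_diff: diffexp.DifferentialTable
    triplets: list[cerna.CeRNATriplet]
    enrichment_results: pd.DataFrame
    candidates: list[functional.CircCandidate]
    set_algebra: dict[str, int]


def _write_atomic(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=index, lineterminator="\n")
    os.replace(tmp, path)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Run all stages, writing stage outputs and a manifest under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    counts: dict[str, int] = {}
    files: list[Path] = []

    # stage 1: simulate ---------------------------------------------------
    study = simulate_study(p["simulate"], seed=p["seed"])
    seedmatch.write_fasta(study.sequences, out / "sequences.fasta")
    study.expression.to_tsv(out / "expression_raw.tsv")
    study.expression.groups_to_tsv(out / "groups.tsv")
    study.truth.to_tsv(out / "truth.tsv")
    ann = study.annotation.copy()
    ann.index.name = "probe"
    _write_atomic(ann, out / "annotation.tsv", index=True)
    enrichment.write_gmt(study.terms, out / "terms.gmt")
    files += [out / f for f in
              ["sequences.fasta", "expression_raw.tsv", "groups.tsv", "truth.tsv",
               "annotation.tsv", "terms.gmt"]]
    counts["simulate_probes"] = len(study.expression.probe_ids)

    # stage 2: preprocess -------------------------------------------------
    logm = preprocess.log2_transform(study.expression, offset=p["preprocess"]["log2_offset"])
    norm = preprocess.quantile_normalize(logm)
    filtered = preprocess.filter_low_intensity(
        norm,
        quantile_cut=p["preprocess"]["quantile_cut"],
        min_samples=p["preprocess"]["min_samples"],
    )
    filtered.to_tsv(out / "expression_normalized.tsv")
    files.append(out / "expression_normalized.tsv")
    counts["preprocess_probes_kept"] = len(filtered.probe_ids)

    # stage 3: differential expression ------------------------------------
    sham, case = tuple(p["simulate"]["group_labels"])
    fold = diffexp.fold_change_and_direction(filtered, case_group=case, control_group=sham)
    pvals = diffexp.two_group_t_test(
        filtered, case_group=case, control_group=sham, variant=p["diffexp"]["t_variant"]
    )
    de = diffexp.select_differential(
        fold, pvals, fc_min=p["diffexp"]["fc_min"], p_max=p["diffexp"]["p_max"]
    )
    de_out = de.records.copy()
    de_out.index.name = "probe"
    _write_atomic(de_out, out / "diffexp.tsv", index=True)
    chrom = diffexp.chromosome_distribution(de, study.annotation)
    _write_atomic(chrom, out / "chromosome_distribution.tsv")
    _write_atomic(
        diffexp.volcano_table(fold, pvals).reset_index(names="probe"),
        out / "volcano.tsv",
    )
    files += [out / "diffexp.tsv", out / "chromosome_distribution.tsv", out / "volcano.tsv"]
    counts["diffexp_selected"] = len(de)

    classes = study.annotation["molecule_class"]
    circ_mask = [classes.get(pr) == "circRNA" for pr in de.records.index]
    circ_diff = diffexp.DifferentialTable(
        records=de.records[circ_mask], fc_min=de.fc_min, p_max=de.p_max
    )
    mrna_diff = diffexp.DifferentialTable(
        records=de.records[[not m for m in circ_mask]], fc_min=de.fc_min, p_max=de.p_max
    )
    counts["diffexp_circ"] = len(circ_diff)
    counts["diffexp_mrna"] = len(mrna_diff)

    # stage 4: seed matching ----------------------------------------------
    mirnas = [s for s in study.sequences if s.molecule_class == "miRNA"]
    targets = [s for s in study.sequences if s.molecule_class != "miRNA"]
    target_map = seedmatch.build_target_map(
        mirnas,
        targets,
        kinds=p["seedmatch"]["kinds"],
        min_sites=p["seedmatch"]["min_sites"],
        circular=p["seedmatch"]["circular"],
    )
    _write_atomic(seedmatch.target_map_edges(target_map), out / "target_map.tsv")
    _write_atomic(seedmatch.site_table(target_map), out / "seed_sites.tsv")
    files += [out / "target_map.tsv", out / "seed_sites.tsv"]
    counts["seedmatch_pairs"] = sum(len(t) for t in target_map.values())

    # stage 5: ceRNA network ----------------------------------------------
    circ_ids = [pr for pr in circ_diff.records.index if pr in filtered.values.index]
    mrna_ids = [pr for pr in mrna_diff.records.index if pr in filtered.values.index]
    circ_expr = filtered.with_values(filtered.values.loc[circ_ids])
    mrna_expr = filtered.with_values(filtered.values.loc[mrna_ids])
    correlations = cerna.pairwise_pearson(circ_expr, mrna_expr)
    triplets = cerna.build_triplets(
        target_map,
        correlations,
        r_min=p["cerna"]["r_min"],
        r_p_max=p["cerna"]["r_p_max"],
        use_abs=p["cerna"]["use_abs"],
    )
    _write_atomic(cerna.triplet_table(triplets), out / "triplets.tsv")
    edges, nodes = cerna.export_network(triplets)
    _write_atomic(edges, out / "network_edges.tsv")
    _write_atomic(nodes, out / "network_nodes.tsv")
    files += [out / "triplets.tsv", out / "network_edges.tsv", out / "network_nodes.tsv"]
    counts["cerna_triplets"] = len(triplets)
    counts["network_nodes"] = len(nodes)
    counts["network_edges"] = len(edges)

    # stage 6: enrichment --------------------------------------------------
    background = sorted(
        {
            study.annotation.loc[pr, "host_gene"]
            for pr in filtered.values.index
            if study.annotation.loc[pr, "host_gene"]
        }
    )
    circ_hosts = sorted(
        {
            study.annotation.loc[pr, "host_gene"]
            for pr in circ_diff.records.index
            if study.annotation.loc[pr, "host_gene"]
        }
    )
    enr = enrichment.hypergeometric_enrich(circ_hosts, study.terms, background)
    _write_atomic(enr, out / "enrichment.tsv")
    _write_atomic(
        enrichment.rank_terms(enr, n=10, per_category=True), out / "enrichment_top.tsv"
    )
    files += [out / "enrichment.tsv", out / "enrichment_top.tsv"]
    counts["enrichment_terms_tested"] = len(enr)

    # stage 7: functional subset -------------------------------------------
    keywords = functional.load_default_keywords()
    mrna_gene_of = {
        pr: study.annotation.loc[pr, "host_gene"]
        for pr in study.annotation.index
        if study.annotation.loc[pr, "molecule_class"] == "mRNA_3utr"
    }
    labeled = functional.select_functional_mrnas(
        mrna_diff,
        study.terms,
        keywords,
        gene_of=mrna_gene_of,
        fc_min=p["functional"]["fc_min"],
        p_max=p["functional"]["p_max"],
    )
    candidates = functional.map_mrnas_to_circrnas(
        labeled, triplets, circ_diff, mrna_gene_of=mrna_gene_of
    )
    go_cands = functional.map_mrnas_to_circrnas(
        functional.select_functional_mrnas(
            mrna_diff, study.terms, keywords.restricted_to("GO"), gene_of=mrna_gene_of,
            fc_min=p["functional"]["fc_min"], p_max=p["functional"]["p_max"],
        ),
        triplets, circ_diff, mrna_gene_of=mrna_gene_of,
    )
    kegg_cands = functional.map_mrnas_to_circrnas(
        functional.select_functional_mrnas(
            mrna_diff, study.terms, keywords.restricted_to("pathway"), gene_of=mrna_gene_of,
            fc_min=p["functional"]["fc_min"], p_max=p["functional"]["p_max"],
        ),
        triplets, circ_diff, mrna_gene_of=mrna_gene_of,
    )
    algebra = functional.candidate_set_algebra(
        (c.circ_id for c in go_cands), (c.circ_id for c in kegg_cands)
    )
    summary = functional.summarize_candidates(candidates, n=10)
    _write_atomic(summary, out / "candidate_summary.tsv")
    cand_rows = pd.DataFrame(
        [
            {
                "circRNA": c.circ_id,
                "fold_change": c.fold_change,
                "regulation": c.regulation,
                "functions": ",".join(sorted(c.flags)),
                "n_chains": len(c.chains),
            }
            for c in candidates
        ],
        columns=["circRNA", "fold_change", "regulation", "functions", "n_chains"],
    )
    _write_atomic(cand_rows, out / "candidates.tsv")
    files += [out / "candidate_summary.tsv", out / "candidates.tsv"]
    counts["functional_mrnas"] = len(labeled)
    counts["candidate_circrnas"] = len(candidates)

    manifest = {
        "package": "circsponge",
        "seed": p["seed"],
        "thresholds": {
            "de": [p["diffexp"]["fc_min"], p["diffexp"]["p_max"]],
            "functional": [p["functional"]["fc_min"], p["functional"]["p_max"]],
            "enrichment": [p["enrichment"]["fe_min"], p["enrichment"]["p_max"]],
            "cerna": [p["cerna"]["r_min"], p["cerna"]["r_p_max"]],
        },
        "stages": [
            "simulate", "preprocess", "diffexp", "seedmatch", "cerna",
            "enrich", "subset",
        ],
        "counts": counts,
        "set_algebra": algebra,
        "checksums": {f.name: _checksum(f) for f in sorted(set(files))},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, out / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        study=study,
        normalized=filtered,
        circ_diff=circ_diff,
        mrna_diff=mrna_diff,
        triplets=triplets,
        enrichment_results=enr,
        candidates=candidates,
        set_algebra=algebra,
    )
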