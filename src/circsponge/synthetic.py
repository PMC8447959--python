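"""Synthetic two-group microarray study generator with a planted truth table.

The generator emulates the design the pipeline targets: two groups of three
arrays, log-normal probe intensities, >= 2-fold planted differential effects,
miRNA seed sites planted verbatim into circRNA/3'UTR sequences, and
circRNA--mRNA pairs co-fluctuating through a shared latent factor so that the
noise component of the pair has an exact expected Pearson correlation.

All randomness flows through ``numpy.random.default_rng(rng_seed)``; identical
seeds give byte-identical serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import Term
from .matrix import DesignError, ExpressionMatrix
from .seedmatch import SequenceRecord, site_pattern

__all__ = [
    "TruthTable",
    "IdentifierError",
    "generate_sequences",
    "generate_expression",
    "generate_annotations",
]

_BASES = np.array(list("ACGT"))


class IdentifierError(KeyError):
    """A plan referenced an id that does not exist."""


@dataclass
class TruthTable:
    """Ground truth for recovery tests.

    de_probes: (probe id, direction, planted linear fold)
    planted_triplets: (circ id, mirna id, mrna id)
    planted_sites: (mirna id, target id, position)
    """

    de_probes: set[tuple[str, str, float]] = field(default_factory=set)
    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    planted_sites: set[tuple[str, str, int]] = field(default_factory=set)

    def merged_with(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            de_probes=self.de_probes | other.de_probes,
            planted_triplets=self.planted_triplets | other.planted_triplets,
            planted_sites=self.planted_sites | other.planted_sites,
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = (
            [("de_probe", p, d, str(f)) for p, d, f in sorted(self.de_probes)]
            + [("triplet", c, m, g) for c, m, g in sorted(self.planted_triplets)]
            + [("site", m, t, str(pos)) for m, t, pos in sorted(self.planted_sites)]
        )
        pd.DataFrame(rows, columns=["kind", "a", "b", "c"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_sequences(
    n_mirna: int,
    n_circ: int,
    n_mrna: int,
    site_plan: Sequence[tuple[str, str, int]] = (),
    rng_seed: int = 0,
    mirna_length: int = 22,
    circ_length: int = 250,
    mrna_length: int = 400,
    seed_kind: str = "7mer_m8",
) -> tuple[list[SequenceRecord], TruthTable]:
    """Random sequences with planted seed sites.

    ids are ``miR1..``, ``circ1..``, ``utr1..``.  ``site_plan`` entries
    (mirna_id, target_id, n_sites) plant exactly that many non-overlapping
    perfect sites of class ``seed_kind`` at recorded positions.  Chance sites
    arising in the random background are left in place but unrecorded, so
    recovery tests assert recall on planted sites, not precision.
    """
    rng = np.random.default_rng(rng_seed)
    mirnas = [
        SequenceRecord(f"miR{i+1}", "miRNA", _random_seq(rng, mirna_length))
        for i in range(n_mirna)
    ]
    targets = [
        SequenceRecord(f"circ{i+1}", "circRNA", _random_seq(rng, circ_length))
        for i in range(n_circ)
    ] + [
        SequenceRecord(f"utr{i+1}", "mRNA_3utr", _random_seq(rng, mrna_length))
        for i in range(n_mrna)
    ]
    mirna_by_id = {m.id: m for m in mirnas}
    target_idx = {t.id: i for i, t in enumerate(targets)}
    target_seqs = {t.id: list(t.sequence) for t in targets}
    occupied: dict[str, list[tuple[int, int]]] = {t.id: [] for t in targets}
    sites: set[tuple[str, str, int]] = set()

    for mirna_id, target_id, n_sites in site_plan:
        if mirna_id not in mirna_by_id:
            raise IdentifierError(f"unknown miRNA id {mirna_id!r} in site plan")
        if target_id not in target_idx:
            raise IdentifierError(f"unknown target id {target_id!r} in site plan")
        pattern = site_pattern(mirna_by_id[mirna_id].sequence, seed_kind)
        plen = len(pattern)
        seq = target_seqs[target_id]
        if plen > len(seq):
            raise ValueError(f"site does not fit in target {target_id}")
        for _ in range(n_sites):
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(0, len(seq) - plen + 1))
                span = (start, start + plen)
                if all(span[1] <= a or span[0] >= b for a, b in occupied[target_id]):
                    seq[span[0] : span[1]] = list(pattern)
                    occupied[target_id].append(span)
                    sites.add((mirna_id, target_id, start))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place {n_sites} non-overlapping sites in {target_id}"
                )

    records = mirnas + [
        SequenceRecord(t.id, t.molecule_class, "".join(target_seqs[t.id]))
        for t in targets
    ]
    return records, TruthTable(planted_sites=sites)


def generate_expression(
    probe_ids: Sequence[str],
    de_plan: Sequence[tuple[str, str, float]] = (),
    triplet_plan: Sequence[tuple[str, str, float]] = (),
    noise_sd: float = 0.25,
    rng_seed: int = 0,
    group_labels: tuple[str, str] = ("sham", "SCI"),
    n_per_group: int = 3,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    baseline_overrides: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Two-group raw intensity matrix with planted effects.

    Log2 intensities are Gaussian around per-probe baselines.  ``de_plan``
    entries (probe, "up"/"down", linear_fold) shift the second (case) group
    mean by +/- log2(fold).  ``triplet_plan`` entries (circ_probe, mrna_probe,
    r) give the pair's noise a shared standard-normal factor with loading
    sqrt(|r|) (sign on the mRNA side), so the noise component has expected
    Pearson correlation exactly r; when both members also carry planted group
    effects the pooled-sample correlation exceeds the plan (between-group
    covariance adds to it).

    Returns the raw-scale matrix (2**log2) and the truth table.
    """
    if n_per_group < 2:
        raise DesignError("t-test undefined with fewer than 2 samples per group")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    probe_ids = list(probe_ids)
    if len(set(probe_ids)) != len(probe_ids):
        raise ValueError("duplicate probe ids")
    idx = {p: i for i, p in enumerate(probe_ids)}
    for probe, direction, fold in de_plan:
        if probe not in idx:
            raise IdentifierError(f"unknown probe {probe!r} in de_plan")
        if fold <= 0:
            raise ValueError("planted folds must be positive")
        if direction not in ("up", "down"):
            raise ValueError(f"bad direction {direction!r}")
    for circ, mrna, r in triplet_plan:
        if circ not in idx or mrna not in idx:
            raise IdentifierError("unknown probe in triplet_plan")
        if abs(r) > 1:
            raise ValueError("|planned correlation| must be <= 1")

    rng = np.random.default_rng(rng_seed)
    n_probes = len(probe_ids)
    n_samples = 2 * n_per_group
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)
    if baseline_overrides:
        for probe, value in baseline_overrides.items():
            baseline[idx[probe]] = value

    # group means: columns 0..n-1 control, n..2n-1 case
    means = np.tile(baseline[:, None], (1, n_samples))
    for probe, direction, fold in de_plan:
        delta = np.log2(fold)
        half = delta / 2 if direction == "up" else -delta / 2
        i = idx[probe]
        means[i, :n_per_group] -= half
        means[i, n_per_group:] += half

    noise = rng.standard_normal((n_probes, n_samples))
    for circ, mrna, r in triplet_plan:
        f = rng.standard_normal(n_samples)
        a = np.sqrt(abs(r))
        b = np.sqrt(1.0 - abs(r))
        noise[idx[circ]] = a * f + b * rng.standard_normal(n_samples)
        noise[idx[mrna]] = np.sign(r) * a * f + b * rng.standard_normal(n_samples)

    log2_vals = means + noise_sd * noise
    sample_ids = [f"{group_labels[0]}{j+1}" for j in range(n_per_group)] + [
        f"{group_labels[1]}{j+1}" for j in range(n_per_group)
    ]
    groups = {s: (group_labels[0] if j < n_per_group else group_labels[1])
              for j, s in enumerate(sample_ids)}
    values = pd.DataFrame(np.exp2(log2_vals), index=probe_ids, columns=sample_ids)
    truth = TruthTable(
        de_probes={(p, d, float(f)) for p, d, f in de_plan},
        planted_triplets=set(),
    )
    matrix = ExpressionMatrix(values=values, scale="raw", groups=groups)
    return matrix, truth


def generate_annotations(
    probes: Sequence[str],
    n_terms: int,
    angio_terms: Sequence[str] = (),
    rng_seed: int = 0,
    gene_of: dict[str, str] | None = None,
    missing_host_fraction: float = 0.05,
    forced_memberships: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, dict[str, Term]]:
    """Probe annotation table and a term -> gene-set map.

    Every probe gets a host gene (a small fraction recorded as missing, the
    "n/a" case), a chromosome among chr1-chr19/chrX/chrY, and a strand.
    Terms named in ``angio_terms`` are included among the generated terms
    (GO-style ids get category BP, pathway-style ids category "pathway");
    ``forced_memberships`` (term_id, gene) pins genes into terms so planted
    functional structure survives the random assignment.
    """
    rng = np.random.default_rng(rng_seed)
    probes = list(probes)
    chromosomes = [f"chr{i}" for i in range(1, 20)] + ["chrX", "chrY"]
    if gene_of is None:
        gene_of = {p: f"G{i+1}" for i, p in enumerate(probes)}
    host = []
    for p in probes:
        if rng.random() < missing_host_fraction:
            host.append("")
        else:
            host.append(gene_of.get(p, ""))
    annotation = pd.DataFrame(
        {
            "host_gene": host,
            "chromosome": rng.choice(chromosomes, size=len(probes)),
            "strand": rng.choice(["+", "-"], size=len(probes)),
        },
        index=pd.Index(probes, name="probe"),
    )

    genes = sorted({g for g in gene_of.values() if g})
    term_ids = list(angio_terms) + [
        f"TERM:{i+1:05d}" for i in range(max(0, n_terms - len(angio_terms)))
    ]
    if len(set(term_ids)) != len(term_ids):
        raise ValueError("duplicate term ids")
    forced: dict[str, set[str]] = {}
    for term_id, gene in forced_memberships:
        if term_id not in term_ids:
            raise IdentifierError(f"forced membership for unknown term {term_id}")
        forced.setdefault(term_id, set()).add(gene)
    terms: dict[str, Term] = {}
    for term_id in term_ids:
        size = int(rng.integers(3, max(4, min(25, len(genes)))))
        members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        members |= forced.get(term_id, set())
        if term_id.startswith(("mmu", "PATH")):
            category = "pathway"
        elif term_id.startswith("GO:"):
            category = "BP"
        else:
            category = ("BP", "CC", "MF")[int(rng.integers(0, 3))]
        name = term_id.replace(":", "_").lower()
        terms[term_id] = Term(term_id=term_id, name=name, category=category,
                              genes=frozenset(members))
    return annotation, terms
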