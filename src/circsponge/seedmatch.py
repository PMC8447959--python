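"""Perfect miRNA seed-site detection in circRNA and 3'UTR sequences.

A miRNA recognises a target through Watson-Crick pairing of its seed --
nucleotides 2-7 (6mer) or 2-8 (7mer-m8) counted from the miRNA 5' end -- to an
antisense site on the target.  Reading the target 5'->3', a site is the
reverse complement of the seed, optionally followed by an adenosine opposite
miRNA position 1 (the 7mer-A1 and 8mer classes).  Matching is purely
sequence-based: every perfect occurrence is reported, overlapping occurrences
included, with no thermodynamic or context scoring.

circRNAs are covalently closed, so by default their sequence is scanned
circularly: the string is extended by its first ``site_length - 1``
nucleotides to catch sites spanning the back-splice junction.  Coordinates of
junction-spanning sites run past the linear length (start < L <= end).

Sequences are normalized internally to the DNA alphabet (U -> T), so RNA and
DNA inputs can be mixed freely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SEED_KINDS",
    "DEFAULT_KINDS",
    "SequenceRecord",
    "SeedMatch",
    "normalize_sequence",
    "seed_region",
    "site_pattern",
    "find_seed_matches",
    "build_target_map",
    "target_map_edges",
    "site_table",
    "write_fasta",
    "read_fasta",
]

SEED_KINDS = ("6mer", "7mer_m8", "7mer_A1", "8mer")
#: "perfect seed matching" defaults to the stringent classes
DEFAULT_KINDS = ("7mer_m8", "8mer")

_DNA = set("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with its molecule class."""

    id: str
    molecule_class: str  # miRNA | circRNA | mRNA_3utr
    sequence: str

    def __post_init__(self) -> None:
        if self.molecule_class not in ("miRNA", "circRNA", "mRNA_3utr"):
            raise ValueError(f"unknown molecule class {self.molecule_class!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")


@dataclass(frozen=True)
class SeedMatch:
    """One perfect seed-complementary site on a target sequence.

    ``start``/``end`` are 0-based half-open coordinates on the (possibly
    circularly extended) target; ``site_sequence`` is the matched substring.
    """

    mirna_id: str
    target_id: str
    target_class: str
    seed_kind: str
    start: int
    end: int
    site_sequence: str


def normalize_sequence(seq: str) -> str:
    """Uppercase, RNA->DNA (U->T), validated against the ACGT alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def seed_region(mirna_sequence: str, seed_kind: str) -> str:
    """The miRNA-side seed slice for a site class.

    6mer and 7mer-A1 pair through miRNA positions 2-7; 7mer-m8 and 8mer pair
    through positions 2-8 (1-based from the miRNA 5' end).  The supplementary
    target-side adenosine of the A1/8mer classes is a requirement on the
    target, not part of the returned slice.
    """
    if seed_kind not in SEED_KINDS:
        raise ValueError(f"unknown seed kind {seed_kind!r}")
    s = normalize_sequence(mirna_sequence)
    if len(s) < 8:
        raise ValueError("miRNA shorter than 8 nt has no defined seed")
    if seed_kind in ("6mer", "7mer_A1"):
        return s[1:7]
    return s[1:8]


def site_pattern(mirna_sequence: str, seed_kind: str) -> str:
    """Target-side site written 5'->3': revcomp(seed) [+ A for A1/8mer]."""
    core = _revcomp(seed_region(mirna_sequence, seed_kind))
    if seed_kind in ("7mer_A1", "8mer"):
        return core + "A"
    return core


def find_seed_matches(
    mirna: SequenceRecord,
    target: SequenceRecord,
    kinds: Iterable[str] = DEFAULT_KINDS,
    circular: bool = True,
) -> list[SeedMatch]:
    """All perfect seed sites of ``mirna`` on ``target``, sorted by start.

    ``circular`` applies only to circRNA targets: the scan wraps across the
    back-splice junction.  Overlapping sites (and sites of different classes
    at the same locus) are all reported.
    """
    tseq = normalize_sequence(target.sequence)
    L = len(tseq)
    matches: list[SeedMatch] = []
    for kind in kinds:
        pattern = site_pattern(mirna.sequence, kind)
        plen = len(pattern)
        wrap = circular and target.molecule_class == "circRNA" and L >= plen
        search = tseq + tseq[: plen - 1] if wrap else tseq
        # starts beyond L - 1 would duplicate sites already found at start - L
        last_start = min(len(search) - plen, L - 1) if wrap else len(search) - plen
        pos = search.find(pattern)
        while 0 <= pos <= last_start:
            matches.append(
                SeedMatch(
                    mirna_id=mirna.id,
                    target_id=target.id,
                    target_class=target.molecule_class,
                    seed_kind=kind,
                    start=pos,
                    end=pos + plen,
                    site_sequence=pattern,
                )
            )
            pos = search.find(pattern, pos + 1)
    matches.sort(key=lambda s: (s.start, SEED_KINDS.index(s.seed_kind)))
    return matches


def build_target_map(
    mirnas: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    kinds: Iterable[str] = DEFAULT_KINDS,
    min_sites: int = 1,
    circular: bool = True,
) -> dict[str, dict[str, list[SeedMatch]]]:
    """miRNA -> {target id -> seed-site evidence}, keeping pairs with at
    least ``min_sites`` perfect sites."""
    kinds = tuple(kinds)
    out: dict[str, dict[str, list[SeedMatch]]] = {}
    for mi in mirnas:
        hits: dict[str, list[SeedMatch]] = {}
        for t in targets:
            sites = find_seed_matches(mi, t, kinds=kinds, circular=circular)
            if len(sites) >= min_sites:
                hits[t.id] = sites
        if hits:
            out[mi.id] = hits
    return out


def target_map_edges(target_map: Mapping[str, Mapping[str, list[SeedMatch]]]) -> pd.DataFrame:
    """Flatten a target map into a (mirna, target, target_class, n_sites) table."""
    rows = [
        {
            "mirna": mi,
            "target": t,
            "target_class": sites[0].target_class,
            "n_sites": len(sites),
        }
        for mi, targets in sorted(target_map.items())
        for t, sites in sorted(targets.items())
    ]
    return pd.DataFrame(rows, columns=["mirna", "target", "target_class", "n_sites"])


def site_table(target_map: Mapping[str, Mapping[str, list[SeedMatch]]]) -> pd.DataFrame:
    """Flatten all seed-site evidence into a TSV-ready table."""
    rows = [
        {
            "mirna": s.mirna_id,
            "target": s.target_id,
            "target_class": s.target_class,
            "kind": s.seed_kind,
            "start": s.start,
            "end": s.end,
            "site": s.site_sequence,
        }
        for mi, targets in sorted(target_map.items())
        for t, sites in sorted(targets.items())
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["mirna", "target", "target_class", "kind", "start", "end", "site"]
    )


def site_table_to_map(df: pd.DataFrame) -> dict[str, dict[str, list[SeedMatch]]]:
    """Inverse of :func:`site_table`: rebuild a target map from a site TSV."""
    out: dict[str, dict[str, list[SeedMatch]]] = {}
    for row in df.itertuples(index=False):
        match = SeedMatch(
            mirna_id=row.mirna,
            target_id=row.target,
            target_class=row.target_class,
            seed_kind=row.kind,
            start=int(row.start),
            end=int(row.end),
            site_sequence=row.site,
        )
        out.setdefault(row.mirna, {}).setdefault(row.target, []).append(match)
    return out


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Plain FASTA output (60-column wrap), deterministic."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.molecule_class}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_fasta(path: str | Path, molecule_class: str | None = None) -> list[SequenceRecord]:
    """Read FASTA written by :func:`write_fasta` (class taken from the header
    description unless overridden)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = molecule_class
        if cls is None:
            parts = rec.description.split()
            cls = parts[1] if len(parts) > 1 else "mRNA_3utr"
        records.append(SequenceRecord(id=rec.id, molecule_class=cls, sequence=str(rec.seq)))
    return records
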