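"""Packaged transcriptions of the published result tables.

Three small TSVs ship with the package: the top-20 differential circRNA table
(T1), the qRT-PCR primer table (T2), and the top-10 functional sponge
candidate table with its (miRNA, target gene) chains (T3).  They are used as
validation inputs: parsing plus rule application on these rows must reproduce
the printed extrema and counts.  Integrity is enforced by SHA-256 checksums;
ids are opaque strings (the printed tables mix several id styles) and are
never parsed for meaning.
"""

from __future__ import annotations

import hashlib
import io
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "FixtureIntegrityError",
    "load_fixture",
    "typed_table1",
    "typed_table3",
    "serialize_fixture",
    "validate_fixture_against_rules",
]

_FILES = {"T1": "table1.tsv", "T2": "table2.tsv", "T3": "table3.tsv"}
_SHA256 = {
    "T1": "657ddf834c25652c522514f4022489dbbb4a844e8d8a511f0dde43d271e6ee01",
    "T2": "44bb4e260a6e923cf08c38e816d400f81fd166b42b93bedc2c3c7000d08bf773",
    "T3": "699bb7f0e50ceb891d3eb77d3e63ce8cfc4ba690bb79dadeb2fd62556f8aeab3",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture bytes do not match the recorded checksum."""


def _fixture_bytes(table_id: str) -> bytes:
    if table_id not in _FILES:
        raise KeyError(f"unknown fixture table {table_id!r}")
    data = (resources.files("circsponge.data") / _FILES[table_id]).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _SHA256[table_id]:
        raise FixtureIntegrityError(
            f"{_FILES[table_id]}: checksum {digest} != recorded {_SHA256[table_id]}"
        )
    return data


def load_fixture(table_id: str) -> pd.DataFrame:
    """Raw string view of a fixture table (verbatim cells, blanks preserved)."""
    data = _fixture_bytes(table_id)
    return pd.read_csv(
        io.BytesIO(data), sep="\t", dtype=str, keep_default_na=False
    )


def serialize_fixture(df: pd.DataFrame) -> bytes:
    """Serialize a raw fixture view; round-trips the packaged bytes."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    return buf.getvalue().encode("utf-8")


def typed_table1() -> pd.DataFrame:
    """T1 with numeric fold change / p-value, normalized regulation and
    strand, and missing host genes ("n/a") as empty strings."""
    df = load_fixture("T1").copy()
    df["fold_change"] = df["fold_change"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    df["regulation"] = df["regulation"].str.lower()
    df["strand"] = df["strand"].str.replace("−", "-", regex=False)
    df["host_gene"] = df["host_gene"].replace("n/a", "")
    return df


def typed_table3() -> pd.DataFrame:
    """T3 with continuation rows forward-filled and numeric fold change."""
    df = load_fixture("T3").copy()
    for col in ("circRNA", "fold_change", "regulation"):
        df[col] = df[col].replace("", pd.NA)
        df[col] = df[col].ffill()
    df["fold_change"] = df["fold_change"].astype(float)
    df["regulation"] = df["regulation"].str.lower()
    return df


def table1_differential():
    """T1 as a :class:`~circsponge.diffexp.DifferentialTable` (records indexed
    by circRNA id with fold_change/regulation/p_raw and annotation columns),
    ready for rule application, ranking and chromosome summaries."""
    from .diffexp import DifferentialTable, _sort_records

    df = typed_table1()
    records = pd.DataFrame(
        {
            "fold_change": df["fold_change"].to_numpy(),
            "regulation": df["regulation"].to_numpy(),
            "p_raw": df["p_value"].to_numpy(),
            "chromosome": df["chromosome"].to_numpy(),
            "strand": df["strand"].to_numpy(),
            "host_gene": df["host_gene"].to_numpy(),
        },
        index=pd.Index(df["circRNA"], name="probe"),
    )
    return DifferentialTable(records=_sort_records(records), fc_min=2.0, p_max=0.05)


def validate_fixture_against_rules(
    rows: pd.DataFrame, fc_min: float, p_max: float
) -> tuple[int, pd.DataFrame]:
    """Apply the differential-selection rule (fold >= fc_min, p < p_max) to a
    typed T1 view; returns (surviving count, violating rows)."""
    ok = (rows["fold_change"] >= fc_min) & (rows["p_value"] < p_max)
    return int(ok.sum()), rows[~ok]
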