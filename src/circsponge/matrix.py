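"""Probe-by-sample expression container for the two-group array design.

The whole pipeline operates on :class:`ExpressionMatrix`: a pandas DataFrame of
intensities (probes as rows, samples as columns) plus a sample -> group map and
an explicit scale tag (``raw`` linear intensities vs ``log2``).  The study
design is two groups (e.g. sham vs injured); validation enforces exactly two
distinct group labels and a complete, NaN-free matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DesignError",
    "ValidationError",
    "read_matrix_tsv",
    "read_groups_tsv",
]


class ValidationError(ValueError):
    """Raised when an input matrix violates the container invariants."""


class DesignError(ValueError):
    """Raised when the sample/group design cannot support the analysis."""


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids.
    scale
        ``"raw"`` (non-negative linear intensities) or ``"log2"``.
    groups
        Mapping from sample id to group label; exactly two distinct labels.
    """

    values: pd.DataFrame
    scale: str
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValidationError("missing values in expression matrix")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)}")
        labels = {self.groups[s] for s in self.values.columns}
        if len(labels) != 2:
            raise DesignError(
                f"two-group design required, got labels {sorted(labels)}"
            )
        if self.scale == "raw" and (self.values.to_numpy() < 0).any():
            raise ValidationError("raw intensities must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return (seen[0], seen[1])

    def samples_in_group(self, label: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == label]
        if not cols:
            raise DesignError(f"unknown group label {label!r}")
        return cols

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a copy of self carrying new values (same samples/groups)."""
        return ExpressionMatrix(
            values=values, scale=self.scale if scale is None else scale,
            groups=dict(self.groups),
        )

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "probe"
        df.to_csv(path, sep="\t", lineterminator="\n")

    def groups_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample": self.sample_ids,
             "group": [self.groups[s] for s in self.sample_ids]}
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_matrix_tsv(
    path: str | Path, groups: Mapping[str, str], scale: str = "raw"
) -> ExpressionMatrix:
    """Load a probe x sample TSV (first column = probe id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, scale=scale, groups=dict(groups))


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["group"]))
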