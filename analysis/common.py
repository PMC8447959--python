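"""Shared paths and loaders for the numbered analysis drivers.

Each driver reads the previous stage's tables from ``results/`` and writes its
own there, so the chain can be re-run stage by stage:

    python analysis/01_simulate.py [--seed N]
    python analysis/02_preprocess.py
    ...
    python analysis/07_functional_subset.py
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"


def stage_args(description: str, seed_default: int = 0) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=seed_default,
                    help="simulation seed (only used by 01_simulate)")
    return ap.parse_args()


def load_groups() -> dict[str, str]:
    from circsponge.matrix import read_groups_tsv

    return read_groups_tsv(DATA / "groups.tsv")


def load_matrix(path: Path, scale: str):
    from circsponge.matrix import read_matrix_tsv

    return read_matrix_tsv(path, load_groups(), scale=scale)


def load_annotation() -> pd.DataFrame:
    return pd.read_csv(DATA / "annotation.tsv", sep="\t", index_col=0,
                       keep_default_na=False)


def load_diff_table(path: Path):
    from circsponge.diffexp import DifferentialTable

    records = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    for col in ("fold_change", "p_raw"):
        records[col] = records[col].astype(float)
    return DifferentialTable(records=records, fc_min=2.0, p_max=0.05)


def load_truth():
    from circsponge.synthetic import TruthTable

    df = pd.read_csv(DATA / "truth.tsv", sep="\t", dtype=str)
    truth = TruthTable()
    for row in df.itertuples(index=False):
        if row.kind == "de_probe":
            truth.de_probes.add((row.a, row.b, float(row.c)))
        elif row.kind == "triplet":
            truth.planted_triplets.add((row.a, row.b, row.c))
        elif row.kind == "site":
            truth.planted_sites.add((row.a, row.b, int(row.c)))
    return truth


def write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
    print(f"  wrote {path.relative_to(ROOT)} ({len(df)} rows)")
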