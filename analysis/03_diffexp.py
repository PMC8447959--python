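"""Two-group differential expression: fold change from log2 group means,
pooled Student's t, selection at fold >= 2 and p < 0.05, plus the summary
tables behind the usual figures (volcano columns, chromosome distribution,
heatmap row/column orders)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_annotation, load_matrix, stage_args, write

from circsponge import diffexp


def main() -> None:
    stage_args(__doc__)
    m = load_matrix(RESULTS / "expression_normalized.tsv", scale="log2")
    fold = diffexp.fold_change_and_direction(m, case_group="SCI", control_group="sham")
    pvals = diffexp.two_group_t_test(m, "SCI", "sham", variant="pooled")
    table = diffexp.select_differential(fold, pvals, fc_min=2.0, p_max=0.05)

    ann = load_annotation()
    out = table.records.join(ann[["host_gene", "chromosome", "strand", "molecule_class"]])
    out.index.name = "probe"
    write(out, RESULTS / "diffexp.tsv", index=True)
    write(diffexp.chromosome_distribution(table, ann), RESULTS / "chromosome_distribution.tsv")
    write(diffexp.volcano_table(fold, pvals).reset_index(names="probe"), RESULTS / "volcano.tsv")

    selected = m.with_values(m.values.loc[table.records.index])
    rows, cols = diffexp.hierarchical_cluster_order(selected)
    write(pd.DataFrame({"probe": rows}), RESULTS / "heatmap_row_order.tsv")
    write(pd.DataFrame({"sample": cols}), RESULTS / "heatmap_col_order.tsv")

    up = (table.records["regulation"] == "up").sum()
    down = len(table) - up
    print(f"{len(table)} probes differential at (fold >= 2, p < 0.05): "
          f"{up} up, {down} down")
    top = diffexp.top_n(table, 10)
    print("top records by fold change:")
    print(top.records[["fold_change", "regulation", "p_raw"]].to_string())


if __name__ == "__main__":
    main()
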