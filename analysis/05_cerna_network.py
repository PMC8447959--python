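"""Build candidate sponge triplets: a miRNA with perfect seed sites on both a
differential circRNA and a differential mRNA, whose expression profiles are
strongly positively correlated (Pearson r >= 0.9, p < 0.05 across all six
samples).  Exports the triplet table and the circRNA-miRNA-mRNA network."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_annotation, load_diff_table, load_matrix, stage_args, write

from circsponge import cerna, seedmatch


def main() -> None:
    stage_args(__doc__)
    m = load_matrix(RESULTS / "expression_normalized.tsv", scale="log2")
    diff = load_diff_table(RESULTS / "diffexp.tsv")
    ann = load_annotation()
    classes = ann["molecule_class"]
    circ_ids = [p for p in diff.records.index if classes.get(p) == "circRNA"]
    mrna_ids = [p for p in diff.records.index if classes.get(p) == "mRNA_3utr"]
    sites = pd.read_csv(RESULTS / "seed_sites.tsv", sep="\t")
    tmap = seedmatch.site_table_to_map(sites)

    circ_expr = m.with_values(m.values.loc[circ_ids])
    mrna_expr = m.with_values(m.values.loc[mrna_ids])
    corr = cerna.pairwise_pearson(circ_expr, mrna_expr)
    triplets = cerna.build_triplets(tmap, corr, r_min=0.9, r_p_max=0.05)
    write(cerna.triplet_table(triplets), RESULTS / "triplets.tsv")
    edges, nodes = cerna.export_network(triplets)
    write(edges, RESULTS / "network_edges.tsv")
    write(nodes, RESULTS / "network_nodes.tsv")
    cerna.to_graphml(triplets, RESULTS / "network.graphml")

    print(f"screened {len(corr)} differential circRNA-mRNA pairs "
          f"({len(circ_ids)} circ x {len(mrna_ids)} mRNA)")
    print(f"{len(triplets)} sponge triplets over {len(nodes)} nodes / {len(edges)} edges")


if __name__ == "__main__":
    main()
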