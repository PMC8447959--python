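"""Hypergeometric enrichment of the host genes of differential circRNAs
against the measured-gene background, ranked by -log10(p) within each GO
category and pathway set (the bar-plot / bubble-plot tables)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS, load_annotation, load_diff_table, load_matrix, stage_args, write

from circsponge import enrichment


def main() -> None:
    stage_args(__doc__)
    terms = enrichment.read_gmt(DATA / "terms.gmt")
    ann = load_annotation()
    diff = load_diff_table(RESULTS / "diffexp.tsv")
    kept = load_matrix(RESULTS / "expression_normalized.tsv", scale="log2").probe_ids
    background = sorted({ann.loc[p, "host_gene"] for p in kept if ann.loc[p, "host_gene"]})
    circ_de = [p for p in diff.records.index if ann.loc[p, "molecule_class"] == "circRNA"]
    hosts = sorted({ann.loc[p, "host_gene"] for p in circ_de if ann.loc[p, "host_gene"]})
    skipped = len(circ_de) - len([p for p in circ_de if ann.loc[p, "host_gene"]])

    res = enrichment.hypergeometric_enrich(hosts, terms, background)
    write(res, RESULTS / "enrichment.tsv")
    sig = enrichment.select_enriched(res, fe_min=2.0, p_max=0.05)
    top = enrichment.rank_terms(res, n=10, per_category=True)
    write(top, RESULTS / "enrichment_top.tsv")

    print(f"{len(hosts)} host genes of differential circRNAs "
          f"({skipped} probes lacked a host gene) against {len(background)} background genes")
    print(f"{len(res)} terms tested, {len(sig)} pass (fold enrichment >= 2, p < 0.05)")
    if len(top):
        print("top terms by enrichment score:")
        print(top[["term_id", "category", "k", "K", "p", "score"]].head(8).to_string(index=False))


if __name__ == "__main__":
    main()
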