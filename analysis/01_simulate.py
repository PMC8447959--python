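"""Generate the synthetic two-group spinal-cord-injury-style array study.

Two groups of three arrays (sham vs SCI), ~180 probes: ten planted sponge
triplets (injury-induced circRNA + mRNA sharing a miRNA seed site and
co-fluctuating, planned Pearson r = 0.9), decoy differential probes without
sponge structure, low-intensity probes destined for the background filter,
and random background.  Writes the raw matrix, sequences, annotation, term
sets and the truth table under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, stage_args

from circsponge.enrichment import write_gmt
from circsponge.pipeline import RunConfig, simulate_study
from circsponge.seedmatch import write_fasta


def main() -> None:
    args = stage_args(__doc__)
    cfg = RunConfig({"seed": args.seed})
    study = simulate_study(cfg["simulate"], seed=cfg["seed"])
    DATA.mkdir(parents=True, exist_ok=True)
    write_fasta(study.sequences, DATA / "sequences.fasta")
    study.expression.to_tsv(DATA / "expression_raw.tsv")
    study.expression.groups_to_tsv(DATA / "groups.tsv")
    ann = study.annotation.copy()
    ann.index.name = "probe"
    ann.to_csv(DATA / "annotation.tsv", sep="\t", lineterminator="\n")
    write_gmt(study.terms, DATA / "terms.gmt")
    study.truth.to_tsv(DATA / "truth.tsv")

    n_de = len(study.truth.de_probes)
    print(f"simulated {len(study.expression.probe_ids)} probes x "
          f"{len(study.expression.sample_ids)} samples (seed {cfg['seed']})")
    print(f"planted: {n_de} differential probes, "
          f"{len(study.truth.planted_triplets)} sponge triplets, "
          f"{len(study.truth.planted_sites)} seed sites")
    print(f"outputs under {DATA}")


if __name__ == "__main__":
    main()
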