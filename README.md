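# circsponge

Candidate "miRNA sponge" discovery from a two-group circRNA/mRNA expression
experiment.  The pipeline reimplements, as tested and reusable code, the
inference chain used in small-animal injury microarray studies: quantile
normalization and low-intensity filtering of probe intensities, two-group
differential expression, miRNA seed-site matching on circRNA and mRNA 3'UTR
sequences, a Pearson-correlation ceRNA screen that combines both evidence
types into circRNA–miRNA–mRNA triplets, hypergeometric term enrichment of
host genes, and a final keyword-driven selection of candidate circRNAs tied
to vascular endothelial proliferation, migration and angiogenesis.

A synthetic-data generator with a planted truth table stands in for the
deposited arrays, so every stage is verifiable at desk scale: the generator
plants ≥2-fold differential effects, perfect seed sites at recorded
positions, and latent-factor co-expression between sponge partners, and the
tests measure how much of that planted structure each stage recovers.

## The model in brief

* **Fold change** is computed on the log2 scale: `FC = 2^|mean₂ − mean₁|`
  (a geometric-mean ratio), with direction reported separately; selection
  keeps probes with `FC ≥ 2` and Student's-t `p < 0.05` (raw p, with
  Benjamini–Hochberg values reported alongside).
* **Seed matching** is antisense and exact: a site is the reverse complement
  of miRNA positions 2–7 (6mer) or 2–8 (7mer-m8), optionally followed by an
  A opposite position 1 (7mer-A1 / 8mer).  circRNAs are covalently closed,
  so their sequence is scanned circularly across the back-splice junction.
* **ceRNA triplets** `(circRNA, miRNA, mRNA)` require the miRNA to have ≥ 1
  perfect site on both transcripts and the circ–mRNA Pearson correlation
  across all samples to reach `r ≥ 0.9` with `p < 0.05` (exact t transform,
  n − 2 df).  Sponge logic implies positive co-expression, so negative r
  never qualifies by default.
* **Enrichment** is the one-sided hypergeometric upper tail
  `P[X ≥ k]` for a term with K background genes hit k times by an n-gene
  list from an N-gene background; fold enrichment is `(k/n)/(K/N)` and terms
  are ranked by `−log10 p`.
* **Functional candidates**: mRNAs with fold strictly > 2 and `p < 0.01`
  annotated to angiogenesis/proliferation/migration keyword terms (GO ids
  and KEGG pathway ids shipped as editable data) are walked back through the
  triplets to label differentially expressed circRNAs.

## Worked example

The numbered drivers under `analysis/` run the chain stage by stage on the
simulated study (~180 probes, sham vs SCI, n = 3 each, ten planted sponge
triplets) and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_diffexp.py
python analysis/04_seedmatch.py
python analysis/05_cerna_network.py
python analysis/06_enrichment.py
python analysis/07_functional_subset.py
```

Output of the final stages for seed 1:

```
20 miRNAs x 180 targets -> 83 miRNA-target pairs with >= 1 perfect site
planted-site recall: 20/20
...
screened 546 differential circRNA-mRNA pairs (26 circ x 21 mRNA)
16 sponge triplets over 33 nodes / 26 edges
...
15 functional mRNAs at (fold > 2, p < 0.01) with keyword-term evidence
11 candidate sponge circRNAs (GO-derived 11, pathway-derived 8, union 11, sum-with-overlap 19)
planted sponge circRNA recall: 10/10 (1.00)
```

Reading: every planted seed site was found, the correlation screen emitted
16 triplets (the 10 planted ones plus a handful of chance associations,
which is expected at n = 6), and all 10 planted sponge circRNAs came back
out of the final keyword-driven selection.  The same chain is available as a
single call, `circsponge.pipeline.run_pipeline(RunConfig({"seed": 1}), out)`,
which also writes a manifest with thresholds, row counts and output
checksums (re-running with the same seed reproduces identical outputs).

The package also ships machine-readable transcriptions of the published
result tables (top-20 differential circRNAs, qRT-PCR primers, top-10
functional sponge candidates) under `circsponge.fixtures`; applying the
pipeline's selection rules to them reproduces the printed counts and extrema
exactly, which the test suite asserts.

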