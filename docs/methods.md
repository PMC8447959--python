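# Methods

This note documents the statistical procedures, the synthetic study the
package simulates, the defaults and why they were chosen, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and data model

The pipeline targets a one-color microarray comparison of two groups of
three arrays (sham vs injured spinal cord).  Its central container is a
probe × sample matrix with a sample → group map and an explicit scale tag
(`raw` linear intensities vs `log2`).  Exactly two group labels are
enforced; matrices must be complete (no missing values).  Probe ids are
opaque strings throughout — published circRNA tables mix several id styles,
so ids are never parsed for meaning.

## Preprocessing

1. **log2 transform**, `log2(x + offset)` with `offset = 1.0` by default to
   protect zero intensities (configurable; use 0 for strictly positive
   data).
2. **Quantile normalization** on the log2 scale: every column is mapped onto
   the cross-column mean of order statistics.  Ties within a column receive
   the mean of the reference values at their tied ranks, which makes the
   operation deterministic and idempotent (both asserted to 1e-9 in tests).
3. **Low-intensity filter**: keep probes whose value exceeds the per-sample
   `q`-quantile in at least `k` samples, defaults `q = 0.2`, `k = 3`.  The
   vendor's exact rule is not published; this rule was chosen because it is
   scale-free and design-aware (a probe present in one full group of three
   arrays survives).  `q ≤ 0` is an explicit keep-everything short-circuit,
   since the strict "exceeds" comparison would otherwise drop the column
   minimum even at the vacuous threshold.

Filtering is applied **after** normalization; the pipeline test asserts this
order by recomputing the full-matrix normalization and checking the written
subset against it.

## Differential expression

Fold change is defined from the difference of group mean log2 intensities
(`FC = 2^|Δ|`, a geometric-mean ratio) rather than the ratio of arithmetic
means, for consistency with the log2 analysis scale; direction is carried
separately ("up" iff the case mean exceeds the control mean, with
exactly-equal means flagged and broken toward "up").  Significance is the
classical pooled-variance Student's t (two-sided); Welch is available by
configuration.  Probes with zero variance in both groups are degenerate for
the t statistic: they receive p = 1 when the group means are equal and p = 0
otherwise, and are flagged.  The published analysis filters on raw p
(fold ≥ 2, p < 0.05, fold inclusive, p strict); Benjamini–Hochberg adjusted
values are reported alongside for transparency but never used as the filter.
Tables sort by regulation (up before down), descending fold, ascending raw
p, then probe id, so every output is deterministic.

Hierarchical clustering for heatmap ordering uses 1 − Pearson distance with
average (UPGMA) linkage, implemented in-package so tie-breaks are pinned to
the smallest original index; a brute-force n = 3 oracle and a scipy
average-linkage height comparison cross-check it.  Zero-variance rows have
no defined correlation; their distance is set to 1 and flagged.

## Seed matching

Site classes follow standard target-prediction taxonomy: 6mer (miRNA
positions 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 plus target-side A opposite
position 1), 8mer (2–8 plus A).  The published text requires "perfect
seed-matching" without defining the seed, so the stringent classes
{7mer-m8, 8mer} are the default; all four are available.  Matching is
antisense (the site is the reverse complement of the seed read 5'→3' on the
target), exact, and reports every occurrence including overlaps.  Sequences
are normalized to the DNA alphabet internally (U ≡ T).  Because circRNAs
are covalently closed, their sequence is extended by the first
`site length − 1` nucleotides so junction-spanning sites are found;
coordinates of such sites run past the linear length.  A brute-force
scan of every substring is the oracle: the matcher must agree exactly on
100 random miRNA/target pairs across all four classes.

## ceRNA screen

Pearson correlation between every differential circRNA and mRNA probe is
computed across all six samples pooled (per-group n = 3 has essentially no
power; a per-group mode exists).  The p-value is the exact t transform
`t = r·sqrt((n−2)/(1−r²))` with n − 2 df.  A triplet (circ, miRNA, mRNA)
is emitted when the miRNA has ≥ 1 perfect site on both transcripts and
`r ≥ r_min` with `p < 0.05`.  "High related coefficient" is not quantified
in the published text; `r_min = 0.9` is the default, and the screen is
restricted to positive r because sponge logic predicts positive circ–mRNA
co-expression (an |r| mode exists for exploration).  The published
"regression model" is interpreted as this correlation screen; no
multivariate regression is fitted.

## Enrichment

One-sided hypergeometric upper tail per term, BH-adjusted within each
category (BP/CC/MF/pathway); terms without hits are omitted.  The background
is the set of genes hosting any probe that survives the low-intensity
filter — a measured-gene background is self-contained and statistically
defensible, though annotation-universe backgrounds are common; it is
configurable.  circRNAs enter enrichment through their host genes; probes
without a host gene ("n/a") are excluded with a logged count.  DAVID-style
tools actually use a modified Fisher (EASE) score; the plain hypergeometric
is implemented here because the published text does not specify the
statistic, and the difference (subtracting one hit) is conservative only
for very small k.

## Functional subset

The final selection uses the stricter printed gates deliberately encoded as
printed: differential selection is `fold ≥ 2`, the functional mRNA gate is
`fold strictly > 2` with `p < 0.01`.  Keyword terms are data, not code
(`circsponge/data/keyword_terms.tsv`): the angiogenesis GO ids
(GO:0001525, GO:0045765/66, GO:0010573/74, GO:0002040), endothelial
proliferation/migration GO ids (GO:0001935/38, GO:0043542, GO:0043536) and
the relevant KEGG pathways (mmu04512, mmu04014, mmu04151, mmu04370), each
mapped to one or more function flags.  Name-substring matching
("angiogenesis", …) is an optional mode because published term lists are
rarely complete.  Candidate circRNAs must be differentially expressed and
reach a labelled mRNA through at least one triplet; their function label is
the union over supporting mRNAs, and every candidate carries re-checkable
(miRNA, mRNA) chains.  Because published counts of GO-derived vs
pathway-derived candidates are sometimes summed with overlap, the pipeline
reports all set readings explicitly: both counts, the union, the
intersection, and the naive sum.

## Synthetic data generator

The generator emulates the study conditions, not the vendor's platform:

* **Expression**: per-probe baselines ~ N(8, 1.5) on the log2 scale,
  i.i.d. Gaussian noise with `noise_sd = 0.25` (a typical within-group
  log2 SD for replicate arrays), exponentiated to raw intensities.
  Differential probes shift the case-group mean by ±log2(fold)/2 around the
  baseline, so the planted linear fold is exact in expectation; planted
  folds are ≥ 2 by design, ≥ 4 in the recovery benchmarks.
* **Co-expression**: a sponge pair shares a standard-normal latent factor
  with loading √|r| and idiosyncratic component √(1−|r|), giving the noise
  component an expected Pearson correlation of exactly r.  When both
  members also carry planted group effects, the pooled-sample correlation
  exceeds the plan — between-group covariance adds to it.  That is
  intentional in the sponge benchmark: candidate sponge transcripts in a
  two-group injury study are by construction differentially expressed, and
  the pooled screen sees both components.
* **Sequences**: uniform random ACGT backgrounds (miRNA 22 nt, circRNA
  250 nt, 3'UTR 400 nt by default) with planted sites embedded verbatim at
  recorded non-overlapping positions.  Chance seed sites in the background
  are left in place and unrecorded — scrubbing them would bias base
  composition — so recovery tests assert recall on planted sites, never
  precision.
* **Annotation**: every probe gets a host gene (a small fraction recorded
  as missing, mirroring "n/a" rows), a chromosome among chr1–chr19/X/Y and
  a strand; term sets are random gene subsets with the angiogenesis keyword
  ids included and planted functional genes pinned into them.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical serialized outputs (asserted byte-wise in tests).

What the generator does **not** emulate: probe cross-hybridization, dye and
spatial artifacts, background correction, miRNA expression levels (the
assay measures none), and realistic genomic sequence composition.  Passing
recovery tests therefore demonstrate correctness of the inference chain
under the stated noise model, not performance on real arrays.

## Validation benchmarks and problem sizes

Chosen to keep the full suite in the seconds range while leaving ample
statistical resolution:

* Type-I error: 10,000 null probes, 3 vs 3 pooled t — rejection at 0.05
  must lie in [0.040, 0.060] (Monte-Carlo SE ≈ 0.002).
* Differential recovery: 50 simulations × 500 probes with 50 planted
  ≥ 4-fold effects at noise 0.25 — recall ≥ 95%, false-call rate ≤ 7%.
* Sponge recovery: 20 simulations of 20 planted triplets (both members
  4-fold differential, alternating direction, latent r = 0.9, 8mer sites)
  among 200 site-sharing decoy pairs with independent null expression —
  recall ≥ 0.9, precision ≥ 0.8.  The target map holds exactly the designed
  pair universe (each designated miRNA–target pair scanned for its real
  sites); an all-vs-all scan of random sequences would add a comparable
  number of chance site-sharing pairs and change the decoy count the
  benchmark states.  Note the inherent limit of a pooled-correlation screen
  at n = 6: P(sample r ≥ 0.9 | ρ = 0.9) ≈ 0.5, so purely latent pairs
  without a differential component cannot be recovered reliably at the
  default gate, and co-directionally differential decoy pairs would be
  false-called; the per-group correlation mode is the mitigation, at the
  cost of n = 3 power.
* Oracles: exact rational-arithmetic hypergeometric enumeration for every
  configuration with N ≤ 30 (agreement to 1e-9; plus literal subset
  enumeration at tiny N), and exhaustive substring scanning for seed sites.

## Known limitations

* Student's t with n = 3 per group is what the published analysis states;
  limma's moderated t would be more powerful and is deliberately out of
  scope.  Published per-probe p-values of the kind transcribed in the
  fixture tables are consistent with raw-p filtering, not FDR control.
* The correlation screen cannot distinguish co-regulation from shared
  group response (see above); it reproduces the published inference, not a
  causal sponge test (no partial-correlation/SPONGE-style conditioning, no
  miRNA expression conditioning — none was measured).
* Seed matching is purely combinatorial: no thermodynamics, conservation
  or context scores.
* Enrichment ignores GO graph topology (no elim/weight decorrelation).
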