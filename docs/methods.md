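# Methods

## Domain-rule classification

A gene's TCS class is a pure function of its set of canonical Pfam
accessions. The HATPase catalytic domain family identifies histidine kinases
because it is better conserved than the phosphoacceptor domain and retrieves
kinase sets comparable to curated surveys; the receiver (REC) domain PF00072
identifies response regulators; a gene carrying both is a hybrid kinase.
Default rule sets:

| set | accessions | role |
|---|---|---|
| hatpase | PF02518, PF13581, PF13589, PF14501, PF07536, PF07730 | HPK evidence |
| receiver | PF00072 | RR evidence |
| exclusion | PF00204, PF00183, PF13941 | gyrase B / HSP90 / MutL decoys |

Design choices that were genuinely open:

- **Exclusion precedence.** The decoy domains share the HATPase fold; a gene
  carrying one is removed even when it also carries PF00072. This is the
  conservative reading of "removed from the analysis" — decoy evidence taints
  the whole gene call, and the false-positive cost of keeping a gyrase
  dominates the false-negative cost of dropping a rare genuine fusion.
- **HATPase set membership.** Published HPK identification lists sometimes
  use HWE-family kinase domains (PF07536) and sometimes HisKA_3 (PF07730) in
  the hybrid rule; both are included by default and the sets are fully
  configurable (YAML / `PfamRuleSet.from_config`), so either narrower
  convention is one config away.
- **Set semantics.** Multiple copies of a domain on one gene count once:
  the census counts genes, not domain copies.

The counting contract — hybrids tallied on both the HPK and RR sides —
makes n_HPK + n_RR − n_hybrid equal the number of distinct TCS genes, an
invariant the tests enforce.

## Orphan rule

Distance is start-to-start on the linearized contig (no circular
wraparound), threshold = multiplier × mean protein-coding gene length,
default multiplier 4, strict inequality at the boundary. A contig's sole
TCS gene has infinite nearest-neighbor distance and is an orphan. Start
points rather than nearest edges are used because gene starts are what a
number-line depiction of the genome plots, and because the choice only
shifts the effective threshold by ~one gene length, well inside the
multiplier's own arbitrariness; the multiplier is exposed on the CLI for
sensitivity analysis. The production scan sorts starts per contig and
compares each gene with its two sorted neighbors (sufficient on a line);
tests verify it against a quadratic all-pairs oracle.

## Repertoire statistics

- HPK density = 100 × n_HPK / n_protein_coding. The denominator comes from
  the annotation's protein-coding flags, delegated to the input (whether
  pseudogenes count is an upstream annotation-pipeline decision).
- RR/HPK and % hybrid are undefined when their denominators are zero and are
  carried as missing values. Zero-HPK/zero-RR genomes are excluded from
  ratio-based analyses only; they keep contributing to count-based ones.
- t tests are Student's pooled-variance, two-sided by default; one-tailed
  reporting halves the two-sided p in the direction of the observed
  difference and is a parameter because directional hypotheses (copiotrophs
  richer in sensors) are natural here.
- ANOVA reports the standard (k−1, N−k) degrees of freedom. All-constant
  groups make F 0/0; it is reported missing with a warning.
- Bootstrap CIs: percentile method on the resampled mean, 10,000 replicates
  by default, seed required. The percentile method was chosen over BCa for
  transparency; for the n ≥ 30 cohorts it is used on, the difference is well
  under the interval's own Monte-Carlo noise.
- No multiple-testing correction is applied; the comparisons are few and
  pre-specified.

## Clustering

Features are (HPK per 100 genes, genome size in bp). "Unit normalization"
of two features six orders of magnitude apart admits several readings;
per-feature min-max to [0, 1] is the default because it exactly removes the
scale mismatch without changing either feature's shape, with z-score and
per-sample unit-norm selectable for sensitivity analysis. K-means uses
k-means++ initialization, 10 restarts, fixed seed; k is searched over 2–10
(the search ceiling is comfortably above the 3–5 clusters such surveys
report) and selected by maximal mean silhouette with ties to the smaller k
(parsimony). Silhouette uses the Euclidean metric; singleton clusters score
0 by convention (scikit-learn's convention, matched by the brute-force
oracle in the tests).

## Power-law fit

y = a·x^b is fit by OLS of ln y on ln x: the multiplicative (lognormal)
error model is the natural one for spectral counts spanning decades, and it
makes the fit scale-equivariant (y → cy maps a → ca, leaves b and r²
unchanged) and inversion-antisymmetric (x → 1/x negates b), both tested.
Nonpositive x or y pairs are dropped and counted, never offset — adding a
pseudocount would bias b at exactly the low-phosphate end where the signal
lives. r² is canonical in log space; an original-space r² is also reported
for sensitivity. No sign constraint is placed on b; inverse abundance–
nutrient relationships simply come out with b < 0. At least 3 positive
pairs are required for the 2-parameter fit.

## Synthetic-data generator

What it emulates: annotated bacterial genomes as a TCS census sees them —
gene coordinate tables plus per-gene Pfam assignments. Paired systems are
adjacent genes (operon-like); planted orphans are isolated behind filler
buffers sized to exceed the orphan threshold with a 2× safety margin even
under worst-case gene-length draws; hybrids attach to pair blocks when any
exist (standalone hybrids are legitimately orphans); decoys carry
HATPase + gyrase-B domains; filler genes draw from a dummy accession pool
(PF90000–PF90019) disjoint from every rule set. Gene lengths are truncated
normal (mean 1,000 bp, sd 12%, clipped to ±50%) — real length
distributions are right-skewed, but only the mean enters any downstream
computation. Intergenic gaps are constant (200 bp). The realized layout is
re-checked against the orphan rule with an independent quadratic scan
before emission; an unsatisfiable blueprint raises rather than silently
bending the planted truth.

Cohorts: per-lifestyle HPK densities are drawn from normal distributions —
copiotrophs 1.4, oligotrophs 0.8 per 100 genes, sd 0.2, 40 genomes per
group by default, the planted contrast the statistical tests are exercised
on — and converted to integer counts against sampled protein-coding gene
totals (oligotrophs ~1,700 genes, copiotrophs ~4,000, mirroring the
streamlined-vs-large genome contrast), so realized densities carry genuine
integer-rounding granularity. Transects: phosphate log-spaced over
0.01–3 µM (surface-to-nutricline range), counts y = a·x^b·exp(N(0, σ)),
defaults a = 3, b = −0.8, σ = 0.1, n = 50.

What the generator does **not** emulate: nucleotide sequence, operon
transcription, phylogenetic covariance among genomes, annotation error in
the Pfam assignments themselves, or right-skewed gene-length tails.
Passing round-trip tests therefore shows the pipeline's bookkeeping and
rules are exact, and the statistical tests behave as advertised under
clean sampling assumptions — not that domain annotations of real draft
genomes are error-free inputs.

## Numerical and degenerate-input conventions

- Pfam accessions are normalized case-insensitively, version suffixes
  stripped, digits zero-padded to five; normalization is idempotent.
- Coordinates are 1-based inclusive internally (GFF3 convention); BED
  export converts to 0-based half-open. Strand is carried but unused.
- Flat power-law response (constant y): b = 0, a = y, r² = 0.
- Constant feature columns make min-max/z-score scaling ill-defined and
  raise, naming the column; identical-point K-means warns about collapsed
  clusters rather than failing.
- Equal constant groups: t = 0, p = 1 (t test); F missing with a warning
  (ANOVA).
- All stochastic stages take explicit seeds; the pipeline refuses to run
  stochastic stages without one, and re-running an identical config and
  seed reproduces every report byte for byte.

## Problem sizes in the test and acceptance runs

The self-checks run at desk scale, chosen as the smallest sizes at which
the measured rates are statistically meaningful: 100 planted genomes of
150–300 genes for round-trip recovery, 1,000 random genomes for the orphan
oracle, 100 cohort seeds for power and 400–600 for type-I rates, 1,000
bootstrap replications at 1,000 resamples, 75 blob configurations for k
recovery, and 100 transect seeds for exponent recovery.

## Known limitations

- Orphan detection treats contigs independently; on fragmented drafts,
  genes near contig edges can be mis-flagged as orphans because their true
  neighbor fell on another contig.
- The HPK/RR identification inherits whatever Pfam annotation pipeline
  produced the input; hybrid detection in particular depends on both
  domains having been annotated on the same gene model.
- Replicating published survey-level statistics for real genome
  collections requires the corresponding per-genome supplementary tables
  as TSV exports (`data/supplementary/tableS1.tsv`, `tableS2.tsv`); the
  repository ships none, and the acceptance test for that replication
  fails explicitly when they are absent.
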