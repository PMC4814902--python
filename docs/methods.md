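# Methods

## The model and its assumptions

`drugprior` treats a pharmacogenomic screen as a response table of IC50
values (μM, positive, possibly missing) over cell lines × drugs, plus up to
four feature matrices over cell lines × genes: binary mutation and
variation indicators, log2 RMA expression, and log2 copy-number ratios.
Because real panels assay different cell-line subsets per data type, every
(feature type, drug) pair is analysed on the lexicographically ordered
*intersection* of lines carrying both that feature type and an IC50 for
that drug; nothing is imputed, and empty intersections are flagged
unusable rather than fabricated.

**Dichotomization.** A line is *sensitive* to a drug iff IC50 ≤ 0.5 μM and
*resistant* otherwise. The boundary is inclusive on the sensitive side and
the threshold is a parameter everywhere it appears. Lines without an IC50
for the drug are excluded, not labelled.

**Bias statistic.** For a binary gene feature,
`diff = f_res − f_sen` with `f_res = mut_res / n_res` and
`f_sen = mut_sen / n_sen`, the fractions of resistant and sensitive lines
carrying the alteration. Fractions are exact rationals of counts, so the
statistic is deterministic and order-invariant; internal values keep full
precision. The display convention rounds each fraction to 3 decimals and
takes the difference *of the rounded fractions* — that is the convention
under which the bundled 24-drug reference table is internally consistent
(e.g. 0.216 − 0.109 = 0.107, where the full-precision difference would
round to 0.108). Drug-class pooling applies the same statistic to (cell
line, drug) pairs pooled across the class, so one line contributes once per
class member.

**Group tests.** The mutant-vs-wild signature test compares IC50 between
lines with and without a gene alteration, two-sided. The default is the
Mann–Whitney U test on the μM values (rank-based, hence robust to the
heavy-tailed IC50 scale and invariant to the log transform); Welch's t on
log10 IC50 is available via `test="welch"`. Groups smaller than 2, or a
pooled sample with zero spread, leave the p-value NaN ("untestable") —
never 0 or 1. The same convention holds for Pearson correlations of
zero-variance vectors: undefined is NaN, not 0 (except inside CFS, where a
zero-variance feature's correlation is defined as 0 with a warning so the
search can proceed).

## Gene selection

**CFS.** Subset quality is Hall's merit
`k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`, where `r̄_cf` is the mean absolute
Pearson correlation of subset features with the target (log10 IC50) and
`r̄_ff` the mean absolute pairwise feature correlation. Binary features
enter numerically, i.e. as point-biserial correlations. Search is
best-first from the empty set with single-feature expansions, a visited-set
cut, and termination after 5 consecutive expansions that fail to improve
the best merit (the search tool's customary stopping rule). On instances
with ≤ 6 features the search provably has time to enumerate everything
reachable, and tests hold it to exact agreement with exhaustive
enumeration. Determinism follows from the fixed column order and an
insertion-order tie-break in the priority queue.

**F-stepping.** One sweep over the selected genes in descending
single-gene |r| with the target; each gene is dropped when the evaluator
score without it is *equal or better*, ties removing. The evaluator is the
seeded cross-validated Pearson correlation of the SVR (below). Because
that score is a continuous, noisy quantity, "equal" is operationalized as
agreement at reported precision: scores are compared rounded to 3 decimals
(`score_decimals=3`; `None` restores strict float comparison). Measured
paired score changes from removing a pure-noise gene are ~1e-4 with either
sign — far below reportable precision — so under strict comparison such
genes are kept or dropped by luck, while at reported precision they are
reliably dropped and genuinely predictive genes (whose removal costs
≳ 0.01 PCC) are reliably kept. The compared (rounded) score never
decreases during a sweep. A flag iterates sweeps to a fixpoint; the
default is one pass.

**Light selectors.** `top_correlated` ranks genes by |r| sign-blind (ties
lexicographic, zero-variance genes last). `significant_genes` keeps genes
whose mutant-vs-wild test reaches p < α (default 0.05) in at least
`min_drugs` drugs (default 7); untestable pairs count as non-significant.

## Per-drug models

Epsilon-SVR with a linear kernel, C = 1, ε = 0.1 (the common defaults; RBF
and other settings via `ModelConfig`). The regression target is log10 IC50
by default: potencies span orders of magnitude and a fixed ε tube is only
meaningful on the log scale; `target_transform="identity"` restores raw μM.
Training requires ≥ 10 usable lines and rejects constant targets or
constant gene columns as unlearnable. Evaluation is k-fold (default 5)
cross-validation with shuffled, seeded folds; out-of-fold predictions are
pooled and a single Pearson r against the observed (transformed) values is
returned, so the score is reproducible given (data, config, seed).

Hybrid features concatenate ≥ 2 feature types over their shared lines,
standardizing continuous blocks to zero mean/unit variance (constant
columns dropped with a warning) and leaving binary blocks 0/1; columns are
prefixed by type to keep symbols unique.

Prediction applies the inverse transform, so outputs are positive μM.
The missing-gene policy at prediction is strict by default (error naming
the genes); `missing_policy="fill"` substitutes training-set column means
(continuous) or 0 (binary). Prioritization sorts drugs by ascending
predicted IC50 with ties broken by drug name; models that cannot score the
profile are listed as unscored rather than dropped. The drug calculator is
deliberately model-free: it sums stored (f_res, f_sen) pairs over the
query's altered genes per drug, which stays usable when the query covers
only a few genes.

## Variant ingestion

VCF 4.x rows (via cyvcf2) are split per alternate allele; by default only
FILTER = PASS/'.' rows are used. ANNOVAR-style rows are 1-based inclusive
(chrom, start, end, ref, alt[, gene]). Gene assignment prefers the
record's own gene annotation, else a user-supplied interval map (BED
input, 0-based half-open, converted to 1-based inclusive — a variant at a
gene's exact start or end is contained). The SNP exclusion list matches
exactly on rsID or (chrom, pos, ref, alt); *mutation* mode filters against
it, *variation* mode does not, so the mutation vector is element-wise ≤
the variation vector by construction. Records mapping to no gene are
counted and returned, never silently dropped. No liftover and no
functional-consequence filtering are attempted: any qualifying variant in
a gene sets the indicator.

## The synthetic panel generator

The generator emulates a CCLE-shaped panel at test scale: a few hundred
cell lines, cyclically assigned tissue labels, Bernoulli(0.1) mutation
indicators with variations a superset (mutations plus additional benign
polymorphisms), N(7, 2²) log2 expression and N(0, 0.5²) log2 copy ratios.
Each feature type keeps an independent random ~90% subset of lines, so the
partial-overlap alignment path is always exercised. Per drug, `n_causal`
genes (default 5, drawn from the configured causal feature types) define
log10 IC50 as a ±1-weighted sum of their standardized values plus
N(0, noise_sd²) noise (default 0.3), affinely rescaled to mean log10(0.5)
and unit spread so both resistant and sensitive lines exist. Planted
identities and coefficients are recorded for recovery tests, and the same
seed reproduces the panel bit for bit.

What the generator does *not* emulate: correlated gene blocks
(co-expression, copy-number segments spanning neighbouring genes),
tissue-driven response structure, non-linear or epistatic gene effects,
censoring at the maximum tested dose, and assay noise that varies by
compound. Tests passing on these panels therefore demonstrate that the
machinery recovers planted linear signal under honest noise and missing
data — not that comparable correlations are attainable on any particular
real panel.

## Numerical choices and degenerate inputs

* Display rounding is 3 decimals; `round()` half-even, which the reference
  table itself follows (0.0625 → 0.062).
* All orderings are total: bias tables sort by full-precision diff with
  lexicographic gene tie-breaks; rankings break prediction ties by drug
  name; alignments are lexicographic.
* Undefined statistics (empty group, zero variance) surface as NaN plus a
  flag, or as a raised `DataError` naming the offending group/gene.
* Sizes used by the test and acceptance runs — e.g. 6-feature instances
  for exhaustive CFS enumeration, n = 200–300 lines with 60–200 genes and
  20 seeds for recovery/null simulations, 1000 pairs for test calibration —
  keep every statistical check comfortably powered while the whole suite
  runs in well under a minute.

## Known limitations

Reported cross-validated correlations on synthetic panels (~0.99 under the
default planted-signal settings) are upper bounds tied to the generator's
linear world; real panels carry structure the generator omits (above).
CFS best-first search is exact only on small instances; on larger ones it
is a well-behaved heuristic. The F-stepping equality-at-reported-precision
rule trades a bounded (< 5e-4 per removal) raw-score slack for reliable
pruning of uninformative genes. Wrapper selection shares data with the
subsequent cross-validated evaluation, so pipeline CV scores carry the
usual selection optimism; the permutation-null measurement quantifies the
honest baseline for a fixed gene set.
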