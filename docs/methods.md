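# Methods

## The insertion mechanism the simulator encodes

LINE-1 copies itself by target-primed reverse transcription: an endonuclease
makes staggered nicks at the target site, and reverse transcription of the L1
transcript starts at its 3' poly(A) and extends a variable distance toward
the 5' end. Repair duplicates the sequence between the nicks, so the
haplotype around an insertion reads

    [target site] [inserted cassette] [target site duplicate]

with the duplicate length equal to the nick stagger (the TSD). The cassette,
in sense orientation, is

    [inverted 5' fragment?] [3'-anchored L1 segment] [transduction?] [poly(A)]

- **Truncation** — `inserted_len` < consensus length anchors the segment at
  the 3' end; the 5' end is missing.
- **Twin priming** — a second priming event on the opposite strand reverse
  transcribes the 5'-ward part of the transcript onto the other strand, so
  the realized cassette carries that fragment reverse complemented relative
  to the 3' fragment. The junction coordinate is the second-priming position.
- **3' transduction** — read-through transcripts carry unique genomic
  sequence downstream of the source element; it appears between the L1 3'
  end and the poly(A) and allows source attribution.
- **Minus-strand insertions** are the reverse complement of the whole
  cassette, so the reference top strand shows poly(T) 5'-ward.

The simulator embeds full-length consensus copies (plus-strand) into a random
background genome as transduction sources, records each source's unique
downstream flank, and materializes haplotypes with an explicit piecewise map
from haplotype coordinates to reference/consensus/transduction/poly(A)
provenance.

## Oracle alignments

Reads are simulated with uniform fragment starts, Normal fragment lengths
truncated at twice the read length, FR mate orientation, constant Q30
qualities and independent substitution errors. Because provenance is exact,
the package emits the alignment a correct local aligner would produce
against the unmodified reference: junction-spanning reads are soft-clipped at
the true breakpoint, cassette-interior reads are placed on a genomic source
copy (with hard-clipped supplementary records for clipped L1 tails of
anchored reads), transduced-interval reads map to the source flank, and
poly(A)-only reads are emitted unmapped with a mapped mate. Pairs in which
either mate is clipped, placed in L1/transduced sequence, or unmapped are
flagged discordant.

The oracle places clips at the exact simulated junction rather than
left-shifting through homopolymer ambiguity; real aligners jitter by a few
bases at such junctions, which is why every breakpoint comparison in tests
uses a ±5 bp tolerance. The read simulator has no indel or PCR model, never
marks duplicates (duplicate filtering is exercised on hand-built records),
and base quality is constant — so passing tests demonstrate correctness of
the calling logic, not robustness to real-world base-quality or alignment
artifacts.

## Caller parameters

| parameter | default | rationale |
|---|---|---|
| `min_clip` | 20 nt | shortest tail that maps reliably; also the floor for realignment |
| clip scoring | +2/−2, gap −4/−1 | standard local-alignment regime for 20–150 nt tails |
| score threshold | 0.6 × (2 × clip length) | rejects random tails (empirically ~0 false hits at 60 nt) |
| identity floor | 0.85 | tolerates 0.1–1% sequencing error plus divergence |
| cluster window | 50 bp | matches the call-intersection window |
| `max_tsd` | 30 bp | junction pairing span; negative offsets ≤5 bp recorded as target-site deletions |
| poly tract | ≥8 nt, purity 0.8 | terminal tract test is a total function |
| min support | 2 clips, or 1 clip + 2 discordant | conservative defaults, configurable |
| transduction search | 10 kb downstream of each source 3' end | transductions are short-range read-through products |
| source grouping | 1 kb | sources closer than this are indistinguishable |
| L1 mask margin | 500 bp | calls inside/near annotated L1 copies are repeat artifacts |
| normal coverage floor | 8× | below this, somatic vs germline is undecidable → `unresolved` |

Clip realignment uses a banded whole-query edit-distance search (edlib,
infix mode) for the common case of tails fully embedded in the consensus and
falls back to Smith–Waterman local alignment for chimeric tails
(transduction + L1, residual poly(A)). Orientation ties between strands are
treated as ambiguous and discarded.

Inversion calls report the second-priming coordinate (the only quantity a
single junction determines) and a length lower bound from the two fragments'
combined extents; the inserted length itself is left unresolved, since clips
cannot see the unsequenced middle of the cassette.

## QC metrics and adjustment

Per-sample metrics are computed after removing unpaired reads, duplicates,
mapping-quality-zero reads and records with inconsistent sequence/quality
lengths: chimeric read fraction (unexpected orientation or insert > 100 kb),
clipped base fraction, mean read length, mean base quality, and coverage.
Coverage is filtered aligned bases over a configured genome length — the
denominator is a package choice and is reported in output metadata. Pairs
are dropped when chimeric fraction exceeds 2% in either sample, tumor depth
is below 50×, or normal depth below 20×.

Adjustment is OLS residualization of log2(value + 0.5): RNA against intronic
rate (tumor and normal fitted jointly), RT against the ten WGS metrics. The
log2 transform precedes residualization — residuals can be negative, so the
reverse order would be incoherent. Residualization is idempotent and
invariant to affine rescaling of covariates.

## Locus models

The activity matrix holds per-tumor-type means of log2-adjusted locus RNA
and TRT; global locus means average the per-type means unweighted, so each
tumor type contributes equally regardless of cohort composition. Loci are
clustered by two average-linkage Euclidean dendrograms (RNA and TRT
profiles; flat cut at 0.7 × maximum linkage distance by default, tunable)
plus a low-TRT flag (< 0.0018 log2-adjusted TRTs per sample); loci sharing
all three annotations form one final cluster.

The efficiency model fits one OLS over all sample × locus rows with a
per-locus RNA slope and shared tumor-type/p53/intercept terms. Its
permutation background refits the model after randomly permuting locus
labels (multiset preserved), pooling `n_resamplings × n_loci` slopes.
Empirical tail probabilities use the (r+1)/(N+1) estimator; categorization
multiplies the one-sided min-tail p by the number of hypotheses (Bonferroni)
at threshold 0.05, with non-significant values outside the background IQR
labeled slightly high/low. Under a shared-efficiency null the one-sided
empirical p is uniform (measured false-positive rate 0.049 over 1200 null
loci at 200 resamplings).

The total-RT models are independent per-locus simple regressions of log2
total burden on log2 locus RNA; their background resamples observations with
replacement and permutes the locus assignment before refitting. The cluster
model regresses total burden on per-sample sums of log2-adjusted locus RNA
within each cluster, so the cluster sums conserve the total per-sample
signal when clusters partition the loci.

## Cohort generator

Per sample and locus: log2 RNA is Normal(baseline + type effect + α·p53,
dispersion); TRT counts are Poisson(e_i · RNA · exp(τ′·p53)); total burden
sums the locus counts plus a Poisson background. Effects are log-linear so
OLS on log2 scales recovers them; α defaults to 1.0 log2 units (the scale of
p53-stratified expression differences in large tumor cohorts) and locus
efficiencies default to log-uniform over [0.01, 0.3], giving per-locus mean
TRT counts between roughly 0.2 and 5 at the default baseline. A pseudocount
of 0.5 precedes every log2 of counts. Gene-mutation flags with planted RNA/RT
shifts, stratum-restricted, support the association tests. The generator
makes no attempt to mimic empirical marginal distributions of any real
cohort; its parameters are explicit and user-set.

The p53 regulation scenarios are Gaussian structural equations directly on
the log2-adjusted scale (so planted coefficients are exact OLS estimands):
`expression_only` forces τ′ = 0; `rt_selection` forces α = τ′ = 0 and
removes wild-type-p53 samples whose RT exceeds the 99th percentile of the
wild-type distribution, redrawing to preserve n; `dual` keeps both (α = 1.0,
β′ = 0.8, τ′ = 0.8, noise SDs 1.0/1.5). The survival threshold is
deliberately in the extreme tail: selection against high-RT cells induces a
small spurious p53–RNA association through the RNA–RT correlation, and the
scenario is meant to encode "no expression regulation", so the selection
strength is set weak enough that this induced association stays within
sampling noise at n = 2000 (analytically, the induced mean shift is ~0.01 of
an RNA SD). Censoring only ever removes wild-type samples.

## Mediation and cohort tests

The five-equation decomposition is fitted by OLS; τ − τ′ = αβ′ holds to
machine precision because equations 1, 3 and 4 share the same data.
Standardized coefficients multiply by sd(predictor)/sd(outcome) — the
conventional, rescaling-invariant direction; the reversed ratio is available
via `quoted_standardization=True` for comparison. Bootstrap CIs are
percentile intervals over samples drawn with replacement (default 1000
resamples), computed vectorized; the significance of the mediated effect
uses the delta-method (Sobel) standard error. The p53 indicator is the 0/1
altered/wild-type dichotomy; no continuous mutation score is modeled.

Quintile tests split samples into five equal RNA strata (sizes differ by at
most one) and compare RT between p53 groups by two-sided Mann–Whitney U,
Bonferroni-corrected over the five strata. The LFS comparison draws, per
tumor type, as many non-LFS p53-mutant samples (with replacement) as the LFS
set contains, 10,000 times by default, and t-tests the bootstrap mean
distribution against the LFS values. Gene tests run mutant-vs-wild-type
rank tests for RNA and RT per gene, then p53-stratified tests for all genes
other than TP53, Bonferroni-corrected within the full family; a comparison
passes at corrected p < 0.01 with a median shift of at least one cohort SD.
The normal-tissue model is a linear probability model of tumor p53 status on
normal RNA with categorical tumor type; types with uniform outcomes are
dropped.

## Problem sizes used in tests and the acceptance script

Caller benchmarks use a 2 Mb genome with 200 insertions at 30× (0.1% error),
a 600 kb error-free run for length/transduction inference, and a 1 Mb run
with 50 germline + 50 somatic events for status labels. Statistical
calibrations use 100 replicates per scenario at n = 2000 for mediation, and
40 loci × 500 samples (recovery) / 300 samples × 20 null cohorts × 200
permutations (calibration) for the efficiency model. These sizes keep every
quantity's Monte Carlo error small relative to its acceptance band while the
full suite completes in minutes.

## Known limitations

- The oracle aligner is not a real aligner: mappability, low-complexity
  regions, multi-mapping ambiguity and alignment-score ties are absent, so
  measured recall/precision are upper bounds on real-data performance.
- Support thresholds and masking are explicit stand-ins; production use on
  real BAMs would require tuning against validated call sets.
- Tumor purity and subclonality are not modeled; every somatic insertion is
  present on the (single) simulated tumor haplotype.
- Only L1 is modeled — no Alu/SVA/ERV, no long-read support, no genotype
  likelihoods, no germline allele frequencies beyond the pseudo-germline
  label.
- The count-based cohort generator defines "efficiency" multiplicatively on
  the natural scale while the efficiency model estimates log2-scale slopes;
  recovery is monotone and tight at the default parameter spread (Pearson
  r ≈ 0.95) but the estimand is not numerically identical to the generative
  parameter.
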