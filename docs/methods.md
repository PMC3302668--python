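# Methods

## Scope and data model

`parclip` analyses PAR-CLIP libraries after alignment: its inputs are
ungapped, mismatch-annotated alignments (SAM/BAM with MD tags, or a
reference FASTA to derive mismatches), a reference sequence, and optional
transcript annotation, repeat intervals, expression tables and miRNA
lists. Running the aligner, adapter discovery, quality trimming and
duplicate collapsing are out of scope; adapter stripping and the length/
ambiguity filters are provided for raw read strings. Coordinates are
0-based half-open internally and in BED output; human-readable tables are
1-based closed.

A T=>C conversion is always defined in transcript orientation: reference T
read as C on a '+' alignment, reference A read as G (plus-strand view) on
a '-' alignment. Reads are kept only when exactly one reported location
has zero mismatches after conversion subtraction, and when the aligner
reported at most 10 candidate locations; reads with indels are rejected
(the consumed mapping mode is mismatch-only, default 2 mismatches, a
lenient 3-mismatch mode is reachable by parameter). Read groups are
connected components of the ≥1-nt-overlap relation, computed per
(chromosome, strand). Grouping is strand-separated by design: crosslink
chemistry is transcript-strand specific and annotation is stranded.
Annotation category is resolved by any-overlap with the fixed priority
3' UTR > CDS > 5' UTR > miRNA > intron > intergenic.

## The kernel-density classifier

For each read group with ≥ `min_reads` (5) reads and ≥
`min_conversion_locations` (2) distinct conversion offsets, conversion and
non-conversion events at transcript-sense thymines are tallied per offset.
Both classes are smoothed with a Gaussian kernel and renormalized over the
group, so any constant kernel prefactor cancels; we therefore compute
`exp(-(i-j)^2 / (2*lambda^2))` with no prefactor. `lambda` is the kernel
bandwidth (SD) in nucleotides; its default 3 reflects the locality of
crosslink-induced conversions, and planted-site recovery on simulations is
stable for lambda in 2..5 (checked in the test suite).

Classification takes offsets where the conversion density strictly exceeds
the non-conversion density; ties classify as background. The read-depth
floor (`min_depth` = 5) is enforced at classification time rather than
during frequency estimation; counts are tallied at all offsets. When a
group has no non-conversion events at all, every depth-qualified offset is
classified signal (the k_TT -> 0 limit) and the case is logged. A relaxed
variant (`per_position_depth=False`) keeps the per-group read floor but
drops the per-position depth requirement.

Maximal runs of signal offsets become candidate sites. Two extension
strategies are provided, chosen by the crosslinking behaviour of the
assayed protein: `fixed5` grows each side by up to 5 nt (suited to RBPs
that crosslink directly at the motif), `by_read` grows to the most distal
ends of conversion-bearing reads overlapping the core by ≥1 nt (suited to
proteins, such as Argonaute, whose bound element is protected from
conversion). Both halt where depth falls below the floor. `by_read`
considers reads overlapping the initial core only (single pass, not
iterated). Extended spans that overlap are merged by pure interval union —
the depth floor is not re-checked after merging — and site statistics
(conversions, conversion locations, reads, evidence) are recomputed on the
merged span. A span whose merged extent contains no conversion event is
dropped. Site evidence is log2 of the conversion count; log2 read count is
available for CLIP-seq-style inputs without conversions.

## Motif and seed matching

IUPAC scanning reports all, possibly overlapping, offsets; T and U are
equivalent and matching is on transcript-sense sequence (minus-strand
genomic regions must be reverse-complemented first). Motif presets for
PUM2 (UGUANAUA), QKI (AUUAAY, ACUAAY) and IGF2BP1 (CAUU, CUUU) are
configuration entries in `MOTIF_PRESETS`.

miRNA target sites use the seven canonical seed-match types in preference
order 8mer-m1, 8mer-A1, 7mer-m1, 7mer-A1, 7mer-m8, 6mer2-7, 6mer3-8; the
*-A1 types place an adenine at the site position opposite miRNA position 1
(replacing the position-1 pairing). Non-redundant scanning is greedy:
longer seed types claim positions first, and at equal type the more highly
expressed miRNA wins, so each nucleotide is credited at most once.
Composition profiles count each match location once regardless of read
depth; conversion-likelihood profiles pool all reads covering an offset
(P(T=>C | reference T)), with the background computed over every reference
T of the profiled regions.

## Enrichment statistics

Signal-to-noise is (foreground matches / foreground nucleotides) /
(background matches / background nucleotides); backgrounds are built from
genes called expressed on a companion microarray — probe replicates
averaged, gene value the maximum over its probes, threshold the 80th
percentile (linear interpolation, strict >) of background-probe values —
using the longest transcript (or longest 3' UTR) per gene. Display
rounding is half-even at 2 decimals, the precision of the reference
tables. 3' UTR positional analysis places the site midpoint on a UTR
normalized to 100% (one annotated poly-adenylation site) or 200% (two or
more); rank-resolved signal-to-noise curves use a centered 21-rank moving
average of log2 ratios, with edge windows shrunk to the available ranks
and a window wider than the list collapsing to the global mean.

## Evidence-ranked discovery

Evidence y* is mean-centered across the region set before any scoring.
For a motif with target set size n_j out of n regions, the enrichment
score is S = A_j · e_j / sqrt(sigma^2 / n_j) with e_j the mean centered
evidence over targets and sigma^2 the unbiased sample variance of all
evidence. The adjustment A_j is implemented as sqrt(1 − n_j/n) — it tends
to 1 for small target sets, penalizes near-universal motifs, and is
pluggable (`adjustment=` argument) since other definitions are defensible.
The search enumerates all 4^7 non-degenerate 7-mers with a target set of
at least 5% of regions, expands the 50 best by best-first hill climbing
over single-symbol IUPAC substitutions and single-position extensions or
contractions (lengths 6–10, at most 3 degenerate symbols), and accepts
strict score improvements only; score ties rank toward the less degenerate,
shorter pattern. The exact move set is a design choice of this package.

The miRNA seed-enrichment regression fits, per seed type, ordinary least
squares of centered evidence on a seed-presence indicator plus 16
overlapping dinucleotide counts (mean-centered, unit sample SD) with no
intercept. The indicator column is mean-centered like every other column:
with a centered response, an uncentered binary indicator in a no-intercept
fit attenuates the coefficient by the target fraction, whereas centering
makes the fit equivalent to a with-intercept fit, so the coefficient is an
unbiased effect estimate while the t-score is essentially unchanged for
small target fractions. The per-type score is the indicator coefficient
over its standard error; the miRNA score is the mean over positively
scoring types (0 if none are positive); seed types matching no region (or
all regions) are excluded as undefined. Zero-variance covariates are
dropped with a warning, and a singular design falls back to the
pseudo-inverse. Significance permutes the evidence vector jointly for all
seed types (one permutation stream per replicate, default B = 100), fits a
Gaussian to the null scores, declares significance above mean + 3 SD, and
reports the upper Gaussian tail as the p-value; a zero-variance null is
flagged and degenerates to a mean comparison. Ranked miRNAs are clustered
greedily: the top scorer founds the first cluster and each miRNA joins the
first cluster center whose canonical 8-mer site shares an identical
substring of ≥ 7 nt, else founds a new one. Scores are computed per miRNA
and clustered afterwards.

OLS is implemented directly in numpy (the permutation loop makes per-fit
model-object overhead prohibitive) and is cross-checked against
statsmodels in the unit tests.

## The simulator

The generator emulates the features the analysis depends on: transcripts
with labeled 5' UTR / CDS / 3' UTR segments (defaults 50–120 / 200–400 /
150–300 nt, ~30% on the minus strand and stored reverse-complemented so
both alignment orientations are exercised); planted 3' UTR sites — a bare
crosslink, an IUPAC motif instance, or in Argonaute mode an 8mer-m1 seed
match of a configured miRNA with the crosslink T directly upstream and
conversions forbidden inside the seed; per-read conversion draws (50% at
the crosslink T, 25% at other Ts within ±2 nt of it or within a
non-protected bound element, 0.1% elsewhere), so per-position conversion
fractions are binomial, matching the estimator the profiles assume. Each
planted site carries more than one potential conversion location because
the caller's two-location filter would otherwise exclude genuine sites by
construction. Read lengths default to Uniform(20, 35) nt (configurable
down to the 13-nt minimum), 20 reads per planted site plus 200 uniform
background reads. Optional knobs add RNase-T1-style G-biased fragment ends
and AU-rich site flanks. All randomness derives from one integer seed;
generation is loop-ordered with no order-dependent accumulation, so output
is byte-identical across runs and platforms.

Not emulated: sequencing base-call errors, PCR duplication, multimapping,
RNA secondary structure, expression-driven coverage heterogeneity, and
real genomic repeat content. Passing simulation tests therefore show that
the algorithms behave as specified under the stated statistical model, not
that biological libraries meet that model.

The 41-nt crosslink-centered window baseline (window centered on the
offset with the highest conversion fraction) is implemented inside the
simulator benchmarks only, as a comparison point — not as a supported
caller.

## Problem sizes and determinism

Validation runs at desk scale by design: oracle comparisons use ≥100
random profiles of length ≤200; caller recovery uses 50 transcripts with
30 planted sites at depth 20; motif recovery uses 500 regions; regression
recovery uses 2,000 regions with 100 permutations. The published raw match
counts and per-miRNA score tables derive from multi-library deep-sequencing
data, a full genome and a specific annotation release, and are not
recomputable at this scale; the package instead validates the statistical
machinery on simulations and reproduces the published ratio arithmetic
exactly from its component counts.

## Known limitations

- `by_read` extension is single-pass; reads that overlap only the extended
  (not the initial) core do not extend further.
- Merged sites are not re-checked against the depth floor.
- The A_j adjustment is one reasonable choice among several; scores with
  different adjustments are not comparable across runs.
- The permutation null is fit parametrically (Gaussian); very small B or
  heavy-tailed null score distributions will distort tail p-values.
- Seed clustering is greedy and rank-dependent; exact ties in miRNA scores
  make cluster membership depend on input order (stable for distinct
  scores).
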