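# Methods

## The tolerance model

`gtbkit` computes, for each genomic base and each prediction algorithm, a
single value in [0, 1] summarizing how tolerant that base is predicted to
be to mutation, oriented so that higher = less tolerant.

For a base with reference allele `r`, the three substitutions `r→a`
(`a ≠ r`) are considered; the reference allele itself is never scored.
Each substitution may carry several raw scores, one per transcript
overlapping the position. A raw score `x` from an algorithm with bounds
`[min, max]` is first clamped into the bounds, then min–max normalized,

    u = (x − min) / (max − min),

and inverted (`1 − u`) when the algorithm reports damage with low scores
(SIFT, FATHMM, PROVEAN). The per-base tolerance is a two-stage unweighted
mean: transcript scores are averaged within each substitution, then the
substitution means are averaged. The two-stage form gives every
substitution event equal weight regardless of how many transcripts it
touches; a flat mean would let transcript-rich isoforms dominate.
Substitutions with no score are excluded from the outer mean, never
imputed as zero. A position scored for only one or two of its three
substitutions is still reported by default; `min_permutations`
(CLI `--min-permutations`) masks such thinly covered positions when set
above 1.

Clamping before normalization matters only for algorithms without a
closed native scale (see below); it guarantees the [0, 1] contract
without rejecting real data that exceeds a published observed range.

## The registry: bounds and directions

The normalization needs `min`, `max` and a damaging direction per
algorithm. These are data, not code: the built-in registry ships one
entry per supported track (31 entries across four categories — generic
non-synonymous, cancer-specific, genome-wide, conservation), and any
entry can be overridden or extended from a user TSV/JSON file. Scores
defined on a closed interval (probability-like outputs: SIFT,
PolyPhen-2, FATHMM-MKL, DANN, fitCons, PhastCons, …) carry
`bounds_kind=theoretical` with their exact bounds. Open-ended scores
(GERP++, PhyloP, SiPhy, MutationAssessor, FATHMM, PROVEAN, MetaSVM,
TransFIC) carry `bounds_kind=empirical` with published observed ranges —
e.g. GERP++ [−12.3, 6.17], PhyloP [−20, 10], CADD's phred scale clamped
to [0, 99]. Empirical bounds are defensible defaults, not properties of
the algorithms; anyone with better ranges for their data should override
them. PolyPhen-2's HumDiv and HumVar models, FATHMM's weighted and
unweighted variants and the three PhyloP lineages are separate entries
because they are separate tracks. Categorical predictors
(MutationTaster2) are represented through their continuous converted
score; labels are ignored, since the normalization operates on reals.

## Coordinates and input dialects

Score tables use the dbNSFP conventions: 1-based positions, `.` for
missing, `;`-separated multi-transcript cells that must align
field-for-field with a transcript-id cell (misaligned cells are skipped
with a warning — the upstream alignment policy for unaligned sub-fields
is unknowable from the data, so we require explicit alignment). VCF input
takes numeric INFO fields, expanding multi-allelic records per ALT.
Internally everything is 0-based half-open; the conversion happens at
exactly one place (region binning), which prevents off-by-one drift.
Chromosome names are taken verbatim — no silent `chr`-prefix
normalization, because silent renaming corrupts joins. Parse problems
skip the offending field, not the row, and warnings aggregate as counts
rather than per-record log lines, since realistic inputs are exome-scale.

Track output (BedGraph, bigWig, BED6) is 0-based half-open; CLI `--region`
arguments are 1-based inclusive, matching how biologists quote
coordinates, and are converted during argument parsing only. Missing
bases are encoded as absent intervals, never as a sentinel value — 0 is a
meaningful tolerance score. BedGraph values are written with six decimal
places, so round trips preserve values to 5·10⁻⁷; bigWig stores
float32, good to ~10⁻⁷ on [0, 1]. Adjacent equal values (within 10⁻⁹)
merge into single intervals, which changes no per-base value.

## Concordance and region detection

Pairwise agreement between tracks is computed over the bases both score:
Pearson r, Spearman ρ, and mean absolute difference. Spearman is the
statistic we quote first, because native score scales are non-linearly
related across methods and rank agreement is the fairer comparison.
Correlations are reported as undefined (not 0) when fewer than two bases
are shared or either restricted vector is constant.

The consensus profile is the unweighted per-base mean across the methods
scoring that base, masked where fewer than `min_methods` methods score
it. It is a convenience aggregate of this package — deliberately labelled
`consensus` and nothing else — not a score any upstream method defines;
weighting schemes are future work.

The intolerant-region detector is a plain run scanner over the consensus:
maximal runs of bases with consensus ≥ `threshold`, allowing
interruptions of at most `max_gap` consecutive sub-threshold-or-missing
bases (default 0; small gaps accommodate positions absent from input
tables), kept when the run spans ≥ `min_length` bases and trimmed to
qualifying bases at both ends. Reported regions carry the mean consensus
over their qualifying bases and the minimum per-base method count as a
support measure. No statistical significance is attached to region calls;
the detector is a screening aid, not a test.

## The synthetic generator

The generator exists so the entire pipeline is testable without any
external download. It plants a known latent intolerance profile
(background level plus rectangular blocks) and emits a dbNSFP-style
table by running the normalization backwards: per (base, substitution,
transcript, method), target = clamp(latent + noise, 0, 1) on the
normalized scale, then mapped to the method's native scale by inverting
the min–max formula, direction inversion included. Noise is Gaussian
with standard deviation `noise_sd` on the normalized scale — injected
there, not on native scales, so one noise knob is comparable across
methods with different bounds. A single shared noise draw per (base,
substitution, transcript), mixed with method-private draws in variance
proportion `c : 1 − c`, gives an expected inter-method correlation of
about `c` (clamping attenuates this slightly near the interval ends).
Generation clamps exactly as the pipeline clamps, so the zero-noise,
zero-missingness round trip is exact to floating-point, which is the
generator's core invariant and the basis of the end-to-end recovery test.

Default conditions: a 1 kb region, the four default tracks, background
tolerance 0.1 with one block of level 0.9 over the middle fifth of the
region, `noise_sd` 0.05, inter-method correlation 0.8, one transcript
per site, 2 % missingness — a small, plausibly sized locus with a strong
planted signal and realistic nuisance levels. Raw values are written with
`repr`, i.e. shortest exact decimal, so tables re-read to the exact
floats generated and identical configs yield byte-identical tables.

What the generator does **not** emulate: gene structure (exons, codons,
reading frames), the actual behaviour of any predictor, correlated
missingness (coding-only methods missing entire non-coding stretches),
or dbNSFP's full column schema. Passing tests therefore demonstrate that
the pipeline's arithmetic and I/O are correct and self-consistent — not
that any real algorithm's scores behave like the simulation.

## Numerical choices and edge cases

- Tolerance values are float64 throughout; missingness is NaN.
- Duplicate records for the same (position, alt, transcript, algorithm):
  the last one wins, with a warning tally — deterministic and detectable.
- `site_tolerance` on an empty group set, and normalization of non-finite
  raws, raise domain errors; stream-level validation instead silently
  drops bad records with a tally, because filtering is the right
  behaviour at scale.
- Interval merging tolerance 10⁻⁹; BedGraph/bigWig round-trip contract
  10⁻⁶; profile-builder oracle agreement 10⁻¹²; zero-noise recovery
  10⁻⁹.
- Problem sizes in the behavioural test suite: 200 random instances of up
  to 1,000 records for oracle equivalence; a 10 kb region with 5 methods
  and 3 transcripts/site for exact recovery; 20 seeds at 10,000 positions
  for correlation recovery; 100 random profiles for format round trips.
  These sizes exercise every code path at comfortable desk scale.

## Known limitations

Indels and multi-nucleotide variants are out of scope, as is any
gain- vs loss-of-function distinction — the upstream predictors this
package summarizes are SNV-only in that sense. Genome-build liftover,
parsing the full dbNSFP column schema, automatic bound discovery from
data, statistical testing of region calls, and attribution of
inter-method differences to genomic annotations (chromatin state,
binding sites) are all explicitly not attempted. The per-base tolerance
is a summary of existing predictions, not a new predictor.
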