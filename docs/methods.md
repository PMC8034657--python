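# Methods

## IR quantification

The unit of measurement is one intron in one sample.  Intronic abundance is
the trimmed-median per-base depth over the intron's *measurable region*:
the inter-exon gap minus the union of all annotated exons of any transcript
overlapping it, so exonic signal from alternative isoforms never counts as
intronic.  Positions are sorted by depth, ⌊0.3 n⌋ are discarded from each
end, and the median of the remainder is taken; per-base depth is already a
length-normalized quantity (reads per base), commensurate with the spliced
junction count, which is a point feature.  The IR ratio is
intronic/(intronic + spliced); with both zero the measurement is flagged
undefined and excluded downstream.

Trimming rationale and its limits.  Discarding the top and bottom 30% of
positions makes the statistic exactly immune to coverage spikes when the
central quantile span of the profile is flat — the realistic scenario of
uniform intronic coverage with localized artifacts (repeats, mismapped
fragments).  For arbitrary profiles exact invariance does not hold
(replacing a below-median value with a spike shifts the symmetric trim
window by one rank), but influence is bounded: the statistic stays between
the 30th-percentile order statistic of the original profile and the
(n − ⌊0.3n⌋ − 1 + m)-th, for m spiked positions.  The test suite asserts
both properties separately.

Reliability follows the two-warning scheme: LowCover unless
flanking-junction reads + intron reads > 10, LowSplicing unless
flanking-junction reads > 4; an event is clean only with neither warning,
and "reliable retained" means clean with IR > 0.1 (strict).  Intron reads
are recovered from depth as round(depth × measurable length / read length),
read length 100 by default.  Multi-mapping-read exclusion is an upstream
contract: coverage inputs are assumed pre-filtered, and the package does
not re-implement alignment-level filters.

## Differential IR and the exact count test

Replicates are pooled (counts summed) within each condition; one
Audic–Claverie test per intron compares pooled intron reads against pooled
intron + spliced totals, and ΔIR is the difference of the pooled abundance
ratios (condition minus reference).  Significance is called at p < 0.05
uncorrected — the convention for this analysis — with BH q-values emitted
alongside for users who want them.  Direction summaries count significant
events with ΔIR < 0 versus > 0 (exact ties excluded from both) and test
the ΔIR distribution against zero with a one-sample t and a Wilcoxon
signed-rank test.

The test itself: given x from a library of size N₁, y from a library of
size N₂, y | x is negative binomial with x + 1 successes and success
probability 1/(1 + N₂/N₁); tails are evaluated through the regularized
incomplete beta function (scipy's `nbinom`), so extreme p-values keep full
relative accuracy, and the two-sided p doubles the smaller tail (capped at
1).  The doubled-tail formula is not label-symmetric when N₁ ≠ N₂ — the
conditional masses of (y | x) and (x | y) differ by the factor r — so the
implementation canonicalizes argument order (the lexicographically smaller
(count, total) pair conditions the test) before computing tails, which
makes p(x,N₁,y,N₂) ≡ p(y,N₂,x,N₁) bit-exact.

Calibration.  As a two-library count comparison with per-intron biological
abundance shared across the contrast (pooled counts marginally negative
binomial with mean 100 and dispersion 0.1, variance μ + αμ²), the test's
empirical type-I error at α = 0.05 is ≈ 0.042–0.046 — slightly conservative,
as expected for a discrete doubled-tail test.  Applied in the ratio form the
differential pipeline uses (x = intron reads, N = intron + spliced), the
test is substantially more conservative (≈ 0.01–0.02 at totals near 100):
first, the binomial variance of a within-library ratio is (1 − θ) times the
Poisson variance the test assumes; second, the trimmed-median intronic
estimate has far smaller sampling variance than a raw count of the same
magnitude.  Both effects push rejection below nominal — the test remains
valid (type-I error controlled) but power-limited at low counts, which is
the right failure mode for a screening statistic.  Power is nonetheless
high where it matters: a retention drop of 0.3 at pooled totals of a few
hundred is detected for essentially every affected intron.

## Intron features

GC content is computed over A/C/G/T with N excluded from numerator and
denominator.  Conservation is consumed as a user-supplied per-base track
([0, 1] scores); the mean over covered bases is flagged unreliable below
50% coverage.  Crosslink enrichment is length-normalized by default —
(events/kb in retained introns) / (events/kb in non-retained introns of the
same genes) — because raw event proportions confound intron length; the
raw-proportion variant is available behind a flag.

Splice-site strength uses the field's window convention: 9 bases for the
donor (last 3 exonic + first 6 intronic) and 23 for the acceptor (last 20
intronic + first 3 exonic), extracted in transcription orientation
(minus-strand windows reverse-complemented).  The default model is a
position-weight log₂-odds score: per-position foreground base frequencies
with pseudocount 1, against the position-independent base frequencies of a
supplied background, scored as Σ log₂ P_fg − log₂ P_bg.  This first-order
model replaces maximum-entropy parameter tables so no third-party model
files are bundled; a loader for externally supplied per-window score tables
preserves the same window contract for users who have them.  Ambiguous
bases contribute zero (foreground falls back to background at that
position).

NMD prediction is the deterministic 50-nt rule in place of a trained
classifier: the transcript sequence is rebuilt with the intron retained,
translated from the annotated start (or the longest open reading frame when
none is supplied), and the call is positive iff a stop codon ends more than
50 nt upstream of the last exon–exon junction of the retained transcript.
The distance is emitted so users can re-threshold; retention of the final
intron can never trigger the rule, and transcripts with no ORF are flagged
undefined rather than called.

Feature comparisons between IR-down and IR-up event sets use two-sided
rank-sum tests with BH adjustment across the feature family; a feature
constant in both groups reports p = 1.

## Expression integration and set statistics

Expression fold changes come from median-of-ratios size factors and
log₂((mean_A + 0.5)/(mean_B + 0.5)) on normalized counts — a deliberately
simple estimator; externally computed fold-change tables (e.g. from a
shrinkage-based differential-expression fit) are accepted verbatim by the
same integration operation.  Per-gene mean ΔIR is length-weighted over the
gene's events; quadrants follow the sign pair (genes with a zero on either
axis stay unclassified); the ΔIR-versus-log₂FC Pearson correlation is
reported both per event and per gene, since the two differ and the
event-level variant matches how such scatters are usually drawn.

Overlap tests are implemented once as the hypergeometric upper tail
(equivalent to Fisher's exact on the 2×2); the background gene universe
must be supplied explicitly and is recorded in the output.  The three-set
overlap is tested as a continuity-corrected 1-df chi-squared goodness of
fit of the observed triple overlap against its independence expectation
N·Π(nᵢ/N), with an exact Poisson upper tail substituted (and flagged) when
the expectation falls below 1.  Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum (weight = |score|, exponent 1), gene-set
permutations for the null, NES = ES / mean |ES| of same-sign permutations,
and a +1-corrected permutation p; when the number of distinct same-size
subsets is at most `n_perm` the null is enumerated exhaustively, making the
p-value exact on small universes.  Gene-set over-representation over a GMT
collection is hypergeometric with BH adjustment.  The reactivity marker
panels (pan/A1/A2) ship as an editable YAML file, never hard-coded.

## Compartment analysis

Detection overlap between fractions counts reliable retained introns
(clean, IR > 0.1 in ≥ 1 sample of the fraction) in nuclear-only,
cytoplasmic-only and both, with percentages against the whole-cell set.
Per-fraction differential IR reuses the condition contrast within each
fraction and compares the two significant-ΔIR distributions by rank-sum.
Confinement contrasts cytoplasm against nucleus within one condition
(replicates pooled per fraction, no per-sample pairing): ΔIR = cytoplasmic
− nuclear, so negative means nuclear-enriched, and an intron is nuclear
confined when the fraction contrast is significant with ΔIR < 0; the
confined fraction is reported over significant events.

## The synthetic generator

What it emulates.  Two-condition bulk RNA-seq with 3 replicates per
condition by default, optional nuclear/cytoplasmic fractionation, gene
expression lognormal (σ = 0.5 log-units), junction-depth scale 100 reads,
and negative-binomial noise (dispersion 0.05) implemented as a gamma
expression multiplier per gene × sample shared between the intronic and
spliced signal — totals are overdispersed while the IR ratio stays
calibrated, which is how biological replicate noise behaves.  Retention
levels: a retained class (~50% of introns, θ ~ Beta(4, 6)) and a
non-retained class (θ ~ Beta(1, 40)); condition effects either additive in
θ (default −0.25 on 30% of retained introns, 80% decreases) or
multiplicative on retention odds, which is direction-symmetric across
compartments.  A configurable fraction of genes carries coupled effects
(retention down, expression up 1.5 log₂ units); alternatively a bivariate
mode draws (Δθ, log₂FC) jointly with a configured correlation,
orthogonalized so the realized ensemble correlation equals the target
exactly.  Sequences are built codon-wise in phase 0 with GT…AG intron
boundaries; PTC-bearing introns carry an in-frame TAA and PTC-free introns
contain no in-frame stop, so the NMD rule's truth is exact by construction.
Compartments scale retention odds up in the nucleus (×3) and down in the
cytoplasm (×0.3), guaranteeing nuclear θ ≥ cytoplasmic θ; the cytoplasmic
PTC decay factor models *mutant-enhanced* NMD — in the mutant cytoplasm the
retention odds of PTC-bearing introns are divided by the factor, control
cytoplasm is untouched.  A condition-independent decay could only compress
cytoplasmic differences and could not produce the observed pattern of a
cytoplasmic percent-decrease exceeding the nuclear one.  Conservation
tracks are class-dependent constants plus small noise; crosslink events are
Poisson with a class-dependent rate ratio.  Flanking-junction counts
emulate spliced support at each flanking junction (mean e·(1−θ) per side),
matching the reliability warnings' intent of flagging events with weak
spliced evidence.

What it does not emulate: read-level artifacts (FASTQ simulation,
alignment, mappability, GC bias of library prep), positional
autocorrelation of read coverage (per-base depths are independent Poisson,
so the trimmed-median estimate is *less* noisy than real coverage of equal
depth — pipeline power on real data will be somewhat lower than on
synthetic data of the same depth), isoform-level transcript structure
beyond one transcript per gene, and overlapping genes.  Passing the
recovery tests therefore demonstrates correctness of the estimators and
calibration of the tests under the stated noise model, not performance on
any particular real library.

## Study-condition choices for the verification experiments

These problem sizes are the package's reference experiment designs; each
keeps the nuisance noise subdominant to the effect being verified.

* Retention recovery: θ grid {0.05, 0.1, 0.3, 0.5}, 200 introns, deep
  coverage (junction-depth 3000, mean spliced ≈ 1500–2850, Poisson noise) —
  at the 0.02 tolerance the binding noise source is the spliced count, so
  the design sits well above the minimum depth at which the tolerance is
  statistically marginal.
* Differential power: Δθ = −0.3 from θ = 0.5, 100 introns, pooled totals
  ≈ 500 per condition.
* Null calibration: 2,000 introns, pooled counts marginally NB(100, 0.1)
  with abundance shared across the contrast (see the calibration note
  above).
* Correlation recovery: 2,000 single-intron genes, target R = −0.2,
  Δθ spread 0.08, log₂FC spread 1.0 (replicate noise ≈ 0.26 log₂ units
  stays subdominant); the measured event-level R runs ≈ −0.17…−0.19 —
  attenuation by measurement noise of roughly 0.9, the same attenuation any
  real estimate of such a correlation carries.
* Coupled-gene sensitivity: 300 genes, 30% coupled (Δθ = −0.25,
  log₂FC = +1.5), junction depth 50.
* Compartment direction: 250 genes, fractionation-only design, PTC
  probability 0.5, mutant cytoplasmic decay ×3, and a direction-balanced
  genotype effect on the odds scale (50% decreases) — balancing the
  genotype effect isolates the decay channel as the only systematic source
  of excess cytoplasmic decreases; an additive-θ genotype effect would
  itself skew the two fractions asymmetrically through the odds mapping.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; GTF/GFF3 convert at the I/O
boundary.  Intron identity is (gene, start, end, strand) — identical gaps
shared by transcripts collapse to one intron, and alternative 5′/3′
variants of a gap are distinct introns.  Undefined measurements (no
signal), undefined ratios (zero denominators), all-N sequences, empty
conservation coverage and empty gene-set intersections are flagged rather
than silently zeroed.  Retention levels are clipped to [0.005, 0.95] in the
generator so odds transforms stay finite.  GSEA with all-zero scores falls
back to unweighted steps.  The exact-test p is capped at 1; values can fall
within one ulp of 1 for symmetric inputs.  All stochastic code takes an
explicit seed, recorded in the run manifest; identical configs reproduce
byte-identical outputs.

## Known limitations

* The ratio-form exact test is conservative at low counts (see
  Calibration); interpret non-significance at shallow depth as
  insufficient evidence, not absence of change.
* The position-weight splice-site model ignores dependencies between
  positions that maximum-entropy models capture; scores are comparable
  within one trained model, not across models or with published
  maximum-entropy score scales.
* The 50-nt rule is a deterministic approximation to NMD commitment;
  genuinely rule-violating substrates (long 3′ UTR triggers, uORFs) are
  out of scope.
* Overlap-test p-values depend strongly on the background universe, which
  the caller must choose and supply; outputs record it.
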