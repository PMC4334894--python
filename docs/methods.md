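# Methods

## Coordinates and interval algebra

All genomic coordinates are 0-based, half-open base-pair integers; megabase
values (two decimals, round-half-up) exist only at the reporting layer.
Overlapping *and abutting* intervals merge during consolidation — under the
half-open convention `end == start` adjacency is unambiguous. The default
chromosome sizes are the six cb4 *C. briggsae* assembly sizes
(I 15.45, II 16.62, III 14.57, IV 17.48, V 19.49, X 21.54 Mb, stored as bp).
Aggregate landscape rows (Autosomal, Overall) are sums of the stored
per-chromosome sizes; published aggregates computed from unrounded assembly
sizes can differ from these sums by ~0.01 Mb, which propagates to ≤0.01
percentage points in coverage — within reporting precision but worth knowing
when comparing tables.

## The XX/XO Mendelian engine

Sex determination is XX/XO: males produce X-bearing and nullo-X sperm at
exactly 1/2 each, and an X-linked locus is hemizygous in males. The engine
tracks one biallelic locus (`G` = GFP-linked donor allele, dominant for
expression; `+` = recipient allele) through a single cross: gamete
distributions are enumerated per parent, combined with sex determination,
and per-(genotype, sex) survival probabilities are applied and renormalised
to give the post-selection distribution observed progeny are drawn from.

All probabilities are `fractions.Fraction`s, so the design's expected ratios
are exact: 3/4 GFP overall and among males for an autosomal het × het cross;
1/2 of males GFP for an X-linked carrier female × wild male; 1/3 of
survivors GFP when G hemizygous males are inviable; 1/4 of progeny lost to a
fully penetrant recessive lethal; 1/8 joint probability of the
(homozygous, male) class; 1/9 chance a random GFP × GFP plate from het × het
F1 breeds true. The engine is single-locus by design — the crossing schemes
it models select on one marker — and parent sterility is a per-class flag
that makes a cross raise rather than return an empty distribution.

Segregation distortion (biased X vs nullo-X transmission) is deliberately
*not* in the analytic engine; the synthetic generator exposes it as an
optional perturbation (`male_x_transmission`) so distorted datasets can be
produced while the null expectations stay Mendelian.

## PCR boundary calling

Markers are donor-specific primer pairs ordered by amplicon midpoint; the
midpoint is each marker's point position (the convention is configurable in
principle — midpoints are the natural point estimate of an amplicon).
For one strain and chromosome:

1. NA calls are transparent: skipped when building runs, never flagged.
2. **Exception rule**: a maximal run of ≤ `exception_max_run` (default 1)
   identical calls, flanked on both sides by ≥ `min_consensus` (default 2;
   1 when the flanking run sits at the panel edge) markers of the opposite
   call, contradicts the local consensus. Such markers are flagged as
   candidate assembly errors — a primer whose annotated position belongs
   elsewhere in the genome produces exactly this signature — and excluded.
3. **Boundaries**: the *inner* interval spans the outermost surviving POS
   midpoints (amplicon span for a single-marker run); the *outer* interval
   runs from the nearest surviving NEG midpoint on each side, falling back
   to the chromosome end when the POS run reaches the terminal marker. The
   outer interval is the reported introgression size.
4. Multiple disjoint POS runs are a first-class multi-segment result with a
   warning (secondary insertion or assembly error), not an error.

Zygosity is never inferred from PCR — donor-specific primers amplify in
heterozygotes and homozygotes alike — it is an annotation from crossing
records.

Known limitation: an introgression covering exactly one interior marker is
indistinguishable from an isolated assembly error, and the consensus rule
removes it ("no introgression detected"). Detection therefore requires the
segment to span ≥ 2 markers of the panel, i.e. resolution is bounded by
marker spacing.

## Coverage-based calling

Input is a per-window (default 10 kb) mean-depth track; alignment is out of
scope. Depths can be normalised to per-Gb-sequenced units so libraries of
different size are comparable; the caller itself is scale-invariant.

The enrichment rule — an introgression shows several-fold deeper coverage
than its flanks when a recipient-background strain is aligned to the donor
assembly — is operationalised as seed-and-extend with hysteresis:

- **Baseline** ("flanking" depth): chromosome-wide median, re-estimated once
  with candidate enriched windows excluded so a large introgression does not
  inflate its own reference. A local-flank variant (median of the nearest
  20 windows each side) is available for narrow insertions.
- **Seeds**: windows with depth ≥ `fold` × baseline (default 5).
- **Extension**: runs grow over contiguous windows ≥ `extend_fold` ×
  baseline (default `fold`/2) and bridge ≤ `gap_windows` (default 1) windows
  below that.
- **Acceptance**: a run needs ≥ `min_windows` (default 3) seeds and a mean
  depth satisfying the fold rule.

A single hard per-window threshold fragments under realistic multiplicative
noise (at 5.5× signal with lognormal σ = 0.2, roughly a third of true
windows fall below 5× baseline), whereas flank windows essentially never
reach the extension threshold; hysteresis therefore recovers planted
segments with window-level boundary accuracy while every reported run is
still fold-enriched in the mean. A uniformly elevated track (whole
chromosome introgressed) has no flanking contrast and is correctly
uncallable. A zero baseline with positive windows is floored at a small
epsilon with a warning.

## Phenotype statistics and HI classification

Per replicate, embryonic lethality Emb = unhatched/eggs and larval arrest
Lva = (L1 − adults)/L1; brood size is total eggs over a fixed window.
Replicates with zero denominators are excluded with a warning.

- **Rate contrasts** (Emb, Lva, brood size) use one-way ANOVA across groups
  followed by Tukey's HSD against the control, on replicate-level rates.
  With exactly two groups Tukey's HSD reduces algebraically to the pooled
  two-sample t-test (q = √2·|t|, identical p), and that closed form is used;
  ≥3 groups use the studentized-range distribution. All-zero-variance
  groups short-circuit to exact equality comparison.
- **Ratio tests** (percentage of males; GFP segregation) use Pearson χ²
  without continuity correction on pooled counts, against the engine-derived
  scheme expectation (75 % GFP autosomal het × het; 50 % of males GFP
  X-linked viable; 33.3 % of survivors GFP X-linked male-inviable; 50 %
  males for homozygous lines). Counts, not percentages, enter the test.
- **Dominance**: a heterozygous line is dominant for Emb when its rate
  exceeds the control rate plus the 25 % expected from fully penetrant
  recessive lethality of homozygotes (strict inequality); the same rule is
  mirrored for Lva. A dominant call presupposes a significantly elevated
  rate.
- **Categorical flags**: male sterility = no progeny from the
  male-direction cross with progeny in the reciprocal; male inviability
  (X-linked) = zero GFP males with GFP females present (and it pre-empts the
  sterility label — there are no males to assay); homozygous inviability =
  five failed homozygosing attempts.
- Significance tiers are p < 0.05 (`*`) and p < 0.01 (`**`). No
  multiple-testing correction is applied across lines beyond Tukey's
  within-ANOVA adjustment; output metadata says so.

Directional flags (`emb_elevated`, `fertility_reduced`, …) fire only when
the deviation is in the named direction *and* the two-sided test rejects,
so under the null each fires at about half the nominal level; the raw
two-sided contrasts are kept on the call (`emb_test`, `lva_test`,
`fertility_test`) and it is those whose type-I rate is calibrated at
0.05 ± 0.02 in the test suite. Calibration draws an independent control per
simulated line: type-I error is a property of replications of the whole
experiment, and reusing one control correlates all comparisons.

## Locus refinement

Severity is ordered male_inviable > male_sterile > male_fertile and
homozygous_inviable > homozygous_viable. For overlapping introgressions
*a* (severe) and *b* (milder), the responsible locus lies in `a \ b`; the
candidate carries the capability class the milder strain retains ("male
viability" for inviable-vs-sterile or inviable-vs-fertile contrasts, "male
fertility" for sterile-vs-fertile, "homozygous viability" for the
homozygote family). Identical intervals localise nothing; disjoint
intervals are uninformative and raise.

A nested introgression *more* severe than the larger one containing it
cannot be explained by locus content and suggests a linked suppressor in
`superset \ subset`; the quantitative severity metric (lower = more severe,
e.g. percent GFP males) must differ by more than a configurable margin
(default 20 percentage points, chosen so only contrasts of the magnitude
seen in real nested pairs — single-digit vs ~50 % — trigger). The check is
asymmetric by construction.

`minimal_locus_map` computes all informative pairwise contrasts, intersects
overlapping concordant candidates of the same class (tightest support), and
reports severe-nested-in-mild pairs as discordant rather than resolving
them. The per-class lower bound on locus count is the size of a maximum set
of mutually disjoint candidates (greedy interval scheduling per
chromosome) — exact for interval scheduling, hence a true lower bound.

## Synthetic data: what it emulates

The generator reproduces the statistical structure of the serial-backcross
design so that every pipeline claim can be scored against planted truth.

**Backcross simulator.** The donor chromosome enters whole; each generation
one meiosis of the carrier recombines it (crossover count Poisson on the
genetic map, positions uniform in genetic distance, no interference) and a
GFP-carrying recombinant is selected, so the retained donor segment is the
running intersection of nearest-crossover windows around the GFP locus.
The trajectory is nested, non-increasing and always contains the marker.
Defaults: 15 generations; 50 cM per chromosome, uniform cM/bp — a
*Caenorhabditis*-like one-crossover-per-meiosis map. True interspecies map
lengths and the suppression landscape are unknown; recombination
suppression is modelled as per-interval rate multipliers rather than a
fitted map. Under a uniform map the retained one-side genetic length after
*t* generations is the minimum of *t* Exp(1) draws truncated at the map
distance *L* to the chromosome end, with mean (1 − e^{−tL})/t Morgans; the
simulator agrees with this closed form within Monte-Carlo error, which the
acceptance suite checks at t ∈ {7, 10, 15} over 5,000 replicates.

**Progeny counts.** Eggs per replicate are allocated to (genotype, sex)
classes by a multinomial draw from the engine's pre-selection distribution;
planted-class deaths occur at the configured stage (embryonic or larval);
independent baseline embryonic and larval deaths apply on top; survivors
are tallied into male/female × GFP/non-GFP adults. Baselines default to
0.141 for larval arrest — the magnitude characteristic of the inbred
recipient strain, which is itself far from perfectly viable — and the same
0.141 for embryonic lethality (the two baseline rates are of comparable
magnitude; no separate figure distinguishes them).
Brood sizes are Normal(150, 25) truncated at 1, a realistic recipient-strain
scale; fertility-shift loci scale the mean. Study-scale defaults: 5
replicates × 200 eggs.

**Planted HI models.** Loci carry an effect (emb_lethal, larval_arrest,
male_sterile, male_inviable, fertility_shift), penetrance and dominance.
Recessive effects express only in homozygous/hemizygous state — so an
autosomal recessive lethal shows as the het × het cross's 25 % loss and an
unobtainable homozygous line, while X-linked effects are fully penetrant
through hemizygous males. Truth flags per line enable recovery scoring.

**What the generator does not emulate:** real marker panels' irregular
spacing and failure patterns, linked multi-locus epistasis, inbreeding-
depression genetics beyond the baseline rates, parent-of-origin effects,
and read-level sequencing artefacts. Passing recovery tests therefore show
the *analysis* is correct under the design's own statistical assumptions,
not that real data meet those assumptions.

## Numerical and reporting choices

Exact rational arithmetic in the engine; float conversion at interfaces.
Percentages print to two decimals, p-values to three significant figures.
BED (0-based half-open, sorted) for all interval output; marker panels are
read 1-based inclusive (the convention primer coordinates are reported in)
and converted at the boundary. Pipeline outputs are deterministic given
inputs, config and seed.

## Problem sizes in the test suite

The stochastic guarantees are exercised at: 5,000 backcross replicates per
generation count for the analytic-oracle check; 2,000 simulated null lines
(independent controls) for type-I calibration; 150 targeted lines
(≥ 100 planted-flag checks) for ≥ 95 % recovery; 1,000 random marker-panel
fixtures for the boundary round trip; 100 seeds for coverage-caller
boundary accuracy. The full suite runs in well under a minute on one CPU.
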