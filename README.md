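# himap

Genome-wide hybrid-incompatibility (HI) mapping from marker-assisted
introgressions between *Caenorhabditis briggsae* (donor) and *C. nigoni*
(recipient).

## The problem

*C. briggsae* and *C. nigoni* are sister nematode species that mate and
produce hybrids, but the hybrids suffer pervasive sterility, lethality and
developmental arrest. A systematic way to dissect this is to backcross
GFP-marked *C. briggsae* chromosomal fragments into an otherwise *C. nigoni*
background for ≥15 generations, producing near-isogenic introgression lines,
then score each line's phenotypes against Mendelian expectations. `himap`
implements the complete analysis side of that design for researchers mapping
HI loci in XX/XO species:

- **Boundary calling** of introgressed segments from ordered
  species-specific PCR markers (consensus rule with assembly-error
  flagging) and from windowed read-depth enrichment (the 5-fold rule with
  seed-and-extend hysteresis).
- **Exact Mendelian expectations** for XX/XO crossing schemes with
  per-(genotype, sex) viability models, in rational arithmetic. For an
  autosomal cross G/+ × G/+ with a dominant GFP marker, the expected
  GFP-expressing fraction is 3/4; for an X-linked cross X<sup>G</sup>/X<sup>+</sup> ×
  X<sup>+</sup>/O it is 1/2 of males, falling to 1/3 of all survivors when
  G hemizygous males are inviable.
- **HI classification**: embryonic lethality Emb = unhatched/eggs, larval
  arrest Lva = (L1 − adults)/L1, brood size, sex and GFP segregation.
  Rates are tested against a control strain (one-way ANOVA + Tukey HSD on
  replicate rates), ratios against engine expectations (Pearson χ² on
  pooled counts), dominance by the control + 25 % rule, and the categorical
  definitions of male sterility, male inviability and homozygous
  inviability.
- **Locus refinement** by interval contrasts: overlapping introgressions
  with discordant phenotypes localise loci to set differences; nested pairs
  with inverted severity flag linked suppressors; all pairwise contrasts
  condense into a minimal locus map with per-class lower bounds.
- **Landscape statistics**: consolidated genome-wide coverage of
  introgressions per chromosome and viability category.
- **A synthetic-data generator** producing every pipeline input with
  planted ground truth: Poisson-crossover backcross simulation on a genetic
  map, multinomial progeny counts under planted viability models, PCR call
  matrices with planted assembly errors, noisy coverage tracks.

## Worked example

```sh
python examples/01_mendelian_expectations.py
```

```
autosomal het x het:
  GFP-expressing progeny overall: 75.0%
  GFP among males:                75.0%
  P(male and homozygous G/G):     12.5%
X-linked carrier female x wild male (GFP males viable):
  GFP among males:                50.0%
same cross, GFP hemizygous males inviable:
  GFP among survivors:            33.3%
double-homozygote plate probability (het x het F1): 1/9 (~1 plate in 9)
```

These are the null ratios every segregation test in the pipeline uses: a
significant deficit of GFP progeny against the 75 % (autosomal) or 50 %/33.3 %
(X-linked) expectation indicates HI acting on the marked class, the 12.5 %
figure is the chance an F1 male is a (potentially sterile) homozygote, and
1/9 is the per-plate success probability when homozygosing a line.

The other examples each demonstrate one capability end to end:

```sh
python examples/02_marker_boundary_calling.py   # PCR boundary calling + assembly errors
python examples/03_coverage_calling.py          # read-depth interval calling
python examples/04_phenotype_classification.py  # HI flags for a male-inviable line
python examples/05_locus_refinement.py          # 490-kb viability interval, suppressors
python examples/06_full_pipeline.py             # simulate -> call -> classify -> landscape
```

Example 05 reproduces the canonical X-chromosome contrast: an inviable
introgression reaching 15.11 Mb against a sterile one ending at 14.62 Mb
localises a 0.49 Mb interval required for male viability.

A thin CLI mirrors the stages (`himap call-pcr`, `call-coverage`, `expect`,
`classify`, `refine`, `landscape`, `simulate`, `run`); the importable
modules are the primary interface.

## Layout

- `src/himap/genome_core.py` — coordinates, interval algebra, landscape stats
- `src/himap/marker_genotyping.py` — PCR boundary calling, assembly-error flags
- `src/himap/coverage_mapping.py` — windowed depth-enrichment calling
- `src/himap/cross_engine.py` — exact XX/XO Mendelian engine
- `src/himap/hi_stats.py` — rates, tests, HI classification
- `src/himap/locus_refinement.py` — interval contrasts, suppressors, locus map
- `src/himap/synthetic_data.py` — simulators with planted ground truth
- `src/himap/cli_io.py`, `src/himap/cli.py` — file formats, pipeline, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
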