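"""Synthetic inputs with the statistical structure the analysis assumes.

This module generates every input the pipeline consumes, with planted ground
truth for recovery scoring:

* serial-backcross introgression intervals (Poisson crossover meiosis on a
  genetic map, with marker-assisted selection each generation),
* progeny count tables under planted viability/sterility models (multinomial
  sampling from the exact Mendelian engine, binomial Emb/Lva events),
* PCR genotype call matrices with optional per-call error and planted
  assembly-error markers,
* windowed coverage tracks with lognormal multiplicative noise.

Defaults emulate the study conditions of the source crossing design:
15 generations of backcrossing, a 50-cM uniform genetic map per chromosome,
single-carrier selection each generation, recipient-strain baseline rates of
~14% for both embryonic lethality and larval arrest (the inbred recipient
is itself far from perfectly viable), egg lays of ~200 eggs per replicate
and five replicates per strain.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cross_engine as ce
from .coverage_mapping import CoverageTrack, DEFAULT_WINDOW
from .genome_core import CB4, ChromosomeMap, GenomicInterval
from .hi_stats import PhenotypeRecord, ReplicateCounts
from .marker_genotyping import NA, NEG, POS, GenotypeMatrix, Marker, MarkerPanel

__all__ = [
    "BackcrossConfig",
    "PlantedLocus",
    "PlantedHIModel",
    "AssemblyErrorSpec",
    "simulate_backcross",
    "simulate_progeny_counts",
    "simulate_genotype_matrix",
    "simulate_coverage",
    "simulate_hi_dataset",
    "uniform_panel",
    "SimulatedLine",
    "HIDataset",
]

#: Default chromosome-wide genetic length (Morgans): 50 cM, Caenorhabditis-like.
DEFAULT_GENETIC_LENGTH = 0.5

#: Recipient-strain (inbred C. nigoni-like) baseline phenotype rates.
BASELINE_LVA = 0.141
BASELINE_EMB = 0.141

#: Baseline brood-size distribution (normal, truncated at 1).
BROOD_MEAN = 150.0
BROOD_SD = 25.0

DEFAULT_GENERATIONS = 15
DEFAULT_REPLICATES = 5
DEFAULT_EGGS_PER_REPLICATE = 200


# --------------------------------------------------------------------------
# Backcross simulator
# --------------------------------------------------------------------------

@dataclass
class BackcrossConfig:
    """Configuration of the serial-backcross introgression simulator.

    The donor chromosome enters as a whole; each generation one meiosis of
    the carrier parent recombines it against the recipient homolog
    (crossovers Poisson on the genetic map, no interference) and a single
    GFP-carrying recombinant is selected to continue the line, so the donor
    segment containing the GFP locus shrinks monotonically.  Recombination
    suppression is modelled by per-interval rate multipliers.
    """

    chromosome: str = "X"
    gfp_position: int = 10_000_000
    generations: int = DEFAULT_GENERATIONS
    chrom: ChromosomeMap = field(default_factory=lambda: CB4)
    genetic_length: float = DEFAULT_GENETIC_LENGTH
    rate_multipliers: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.genetic_length < 0:
            raise ValueError("genetic length must be >= 0")
        length = self.chrom.length(self.chromosome)
        if not 0 <= self.gfp_position < length:
            raise ValueError("GFP position outside the chromosome")
        for iv, mult in self.rate_multipliers:
            if iv.chromosome != self.chromosome:
                raise ValueError("rate multiplier interval on the wrong chromosome")
            if mult < 0:
                raise ValueError("rate multipliers must be >= 0")

    @property
    def linkage(self) -> str:
        return ce.X_LINKED if self.chromosome == "X" else ce.AUTOSOMAL


def _genetic_map(cfg: BackcrossConfig) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant map: bp breakpoints and cumulative Morgans at each."""
    length = cfg.chrom.length(cfg.chromosome)
    cuts = {0, length}
    for iv, _ in cfg.rate_multipliers:
        cuts.add(iv.start)
        cuts.add(iv.end)
    bp = np.array(sorted(cuts), dtype=float)
    base_rate = cfg.genetic_length / length  # Morgans per bp
    rates = np.full(len(bp) - 1, base_rate)
    for iv, mult in cfg.rate_multipliers:
        seg = (bp[:-1] >= iv.start) & (bp[1:] <= iv.end)
        rates[seg] = base_rate * mult
    cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(bp))])
    return bp, cum


def simulate_backcross(
    cfg: BackcrossConfig, rng: np.random.Generator | None = None
) -> list[GenomicInterval]:
    """Simulate the introgression interval across backcross generations.

    Returns one interval per generation (1..t).  The trajectory is nested and
    non-increasing, and every interval contains the GFP position: selection
    on the marker each generation makes losing it impossible.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    bp, cum = _genetic_map(cfg)
    total_morgans = float(cum[-1])
    length = cfg.chrom.length(cfg.chromosome)

    seg_start, seg_end = 0, length  # current donor segment (contains GFP)
    trajectory: list[GenomicInterval] = []
    for _ in range(cfg.generations):
        n_co = rng.poisson(total_morgans) if total_morgans > 0 else 0
        if n_co:
            u = rng.uniform(0.0, total_morgans, size=n_co)
            positions = np.interp(u, cum, bp)  # genetic -> physical
            left = positions[positions <= cfg.gfp_position]
            right = positions[positions > cfg.gfp_position]
            co_left = float(left.max()) if left.size else 0.0
            co_right = float(right.min()) if right.size else float(length)
            seg_start = max(seg_start, int(np.ceil(co_left)))
            seg_end = min(seg_end, int(np.floor(co_right)))
            seg_end = max(seg_end, cfg.gfp_position + 1)
            seg_start = min(seg_start, cfg.gfp_position)
        trajectory.append(GenomicInterval(cfg.chromosome, seg_start, seg_end))
    return trajectory


# --------------------------------------------------------------------------
# Progeny count simulator
# --------------------------------------------------------------------------

def simulate_progeny_counts(
    mother: ce.ParentGenotype,
    father: ce.ParentGenotype,
    locus: ce.LocusSpec,
    model: ce.ViabilityFertilityModel = ce.FULL_VIABILITY,
    n_eggs: int = DEFAULT_EGGS_PER_REPLICATE,
    replicates: int = DEFAULT_REPLICATES,
    baseline_emb: float = BASELINE_EMB,
    baseline_lva: float = BASELINE_LVA,
    lethal_stage: str = "embryonic",
    male_x_transmission: float = 0.5,
    seed: int | np.random.Generator | None = None,
    strain: str = "sim",
    zygosity: str = "heterozygous",
) -> PhenotypeRecord:
    """Multinomial progeny counts for one strain under a viability model.

    Each replicate lays ``n_eggs`` eggs whose (genotype, sex) classes are a
    multinomial draw from the engine's pre-selection distribution.  Class
    deaths (survival < 1 under ``model``) occur at ``lethal_stage``
    ("embryonic" or "larval"); independent baseline embryonic and larval
    deaths at the recipient-strain rates apply on top.  Survivors are
    tallied into male/female x GFP/non-GFP adult counts.

    ``male_x_transmission`` perturbs the X : nullo-X sperm ratio away from
    the Mendelian 1/2 (X-linked locus only), emulating size-dependent
    segregation distortion in male meiosis; the analytic engine never does
    this.
    """
    if n_eggs <= 0:
        raise ValueError("n_eggs must be positive")
    if lethal_stage not in ("embryonic", "larval"):
        raise ValueError("lethal_stage must be 'embryonic' or 'larval'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dist = ce.expected_progeny(mother, father, locus, model)
    classes = list(dist.pre)
    probs = np.array([float(dist.pre[c]) for c in classes])
    if locus.linkage == ce.X_LINKED and male_x_transmission != 0.5:
        # Reweight by sex: male classes arise from nullo-X sperm.
        w = np.array(
            [
                (1 - male_x_transmission) * 2 if c.sex == ce.MALE else male_x_transmission * 2
                for c in classes
            ]
        )
        probs = probs * w
        probs = probs / probs.sum()
    survival = np.array([float(model.survival_of(c)) for c in classes])

    reps: list[ReplicateCounts] = []
    for _ in range(replicates):
        counts = rng.multinomial(n_eggs, probs)
        hi_deaths = rng.binomial(counts, 1.0 - survival)
        alive = counts - hi_deaths
        emb_deaths_base = rng.binomial(alive, baseline_emb)
        alive_l1 = alive - emb_deaths_base
        lva_deaths = rng.binomial(alive_l1, baseline_lva)
        adults = alive_l1 - lva_deaths

        unhatched = int(emb_deaths_base.sum())
        l1 = int(alive_l1.sum())
        if lethal_stage == "embryonic":
            unhatched += int(hi_deaths.sum())
        else:
            l1 += int(hi_deaths.sum())
            lva_deaths = lva_deaths + hi_deaths

        rep = ReplicateCounts(
            eggs=n_eggs,
            unhatched=unhatched,
            l1=l1,
            adults=int(adults.sum()),
        )
        for cls, n_adult in zip(classes, adults):
            if cls.sex == ce.MALE and cls.gfp:
                rep.males_gfp += int(n_adult)
            elif cls.sex == ce.MALE:
                rep.males_nongfp += int(n_adult)
            elif cls.gfp:
                rep.females_gfp += int(n_adult)
            else:
                rep.females_nongfp += int(n_adult)
        reps.append(rep)

    return PhenotypeRecord(
        strain=strain,
        replicates=reps,
        zygosity=zygosity,
        linkage=locus.linkage,
    )


# --------------------------------------------------------------------------
# Genotype matrix simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyErrorSpec:
    """Relocate a marker's truth source: its calls reflect ``true_position``
    (the marker's real genomic home) rather than its annotated panel span."""

    marker: str
    true_position: int | None = None  # None: the marker's true home is off-interval


def uniform_panel(
    chromosome: str,
    n_markers: int,
    chrom: ChromosomeMap = CB4,
    amplicon: int = 400,
    prefix: str | None = None,
) -> MarkerPanel:
    """Evenly spaced marker panel across one chromosome."""
    length = chrom.length(chromosome)
    prefix = prefix or chromosome
    mids = np.linspace(length / (n_markers + 1), length * n_markers / (n_markers + 1), n_markers)
    markers = []
    for i, mid in enumerate(mids, 1):
        start = max(0, int(mid) - amplicon // 2)
        markers.append(Marker(f"{prefix}-{i}", chromosome, start, start + amplicon))
    return MarkerPanel(markers)


def simulate_genotype_matrix(
    true_interval: GenomicInterval,
    panel: MarkerPanel,
    call_error_rate: float = 0.0,
    assembly_errors: Sequence[AssemblyErrorSpec] = (),
    na_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    strain: str = "sim",
) -> GenotypeMatrix:
    """PCR call matrix for one strain given its true introgression interval.

    A marker is truly POS iff its amplicon midpoint lies in the interval.
    Assembly-error specs override a marker's truth source with a foreign
    position (emulating a mis-assembled primer locus); per-call flips then
    occur at ``call_error_rate`` and calls drop to NA at ``na_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    relocated = {s.marker: s for s in assembly_errors}
    calls: dict[str, str] = {}
    for marker in panel.on(true_interval.chromosome):
        if marker.name in relocated:
            spec = relocated[marker.name]
            truth = (
                spec.true_position is not None
                and true_interval.contains_position(spec.true_position)
            )
        else:
            truth = true_interval.contains_position(marker.midpoint)
        call = POS if truth else NEG
        if call_error_rate > 0 and rng.random() < call_error_rate:
            call = NEG if call == POS else POS
        if na_rate > 0 and rng.random() < na_rate:
            call = NA
        calls[marker.name] = call
    return GenotypeMatrix({strain: calls}, panel)


# --------------------------------------------------------------------------
# Coverage track simulator
# --------------------------------------------------------------------------

def simulate_coverage(
    true_interval: GenomicInterval,
    window: int = DEFAULT_WINDOW,
    baseline_depth: float = 1.0,
    fold: float = 5.5,
    sigma: float = 0.2,
    chrom: ChromosomeMap = CB4,
    seed: int | np.random.Generator | None = None,
) -> CoverageTrack:
    """Windowed depth track with the introgression elevated ``fold``-fold.

    Depth per window is ``baseline_depth`` (times ``fold`` inside the true
    interval) under multiplicative lognormal noise of parameter ``sigma``.
    A window counts as inside when its centre falls in the interval.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = chrom.length(true_interval.chromosome)
    n_windows = length // window
    centers = (np.arange(n_windows) + 0.5) * window
    inside = (centers >= true_interval.start) & (centers < true_interval.end)
    mean = np.where(inside, baseline_depth * fold, baseline_depth)
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=n_windows) if sigma > 0 else 1.0
    return CoverageTrack(
        chromosome=true_interval.chromosome,
        depths=mean * noise,
        window=window,
    )


# --------------------------------------------------------------------------
# End-to-end HI dataset simulator
# --------------------------------------------------------------------------

EFFECTS = ("emb_lethal", "larval_arrest", "male_sterile", "male_inviable", "fertility_shift")


@dataclass(frozen=True)
class PlantedLocus:
    """One planted HI locus: where it sits, what it does, how strongly."""

    interval: GenomicInterval
    effect: str
    penetrance: float = 1.0
    dominance: str = "recessive"  # recessive | dominant

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.dominance not in ("recessive", "dominant"):
            raise ValueError("dominance must be 'recessive' or 'dominant'")


@dataclass
class PlantedHIModel:
    """Planted loci plus the recipient-strain baselines they act on."""

    loci: list[PlantedLocus] = field(default_factory=list)
    baseline_emb: float = BASELINE_EMB
    baseline_lva: float = BASELINE_LVA
    brood_mean: float = BROOD_MEAN
    brood_sd: float = BROOD_SD
    fertility_shift_factor: float = 0.5  # brood-mean multiplier for fertility_shift loci


@dataclass
class SimulatedLine:
    """One simulated introgression line with its planted ground truth."""

    strain: str
    introgression: GenomicInterval
    linkage: str
    record: PhenotypeRecord
    genotypes: GenotypeMatrix
    truth_effects: list[str]
    truth_flags: dict[str, bool]


@dataclass
class HIDataset:
    """Bundle of simulated lines plus the shared control record and panel."""

    lines: list[SimulatedLine]
    control: PhenotypeRecord
    panels: dict[str, MarkerPanel]
    model: PlantedHIModel


def simulate_control_record(
    model: PlantedHIModel,
    seed: int | np.random.Generator | None = None,
    strain: str = "control",
    replicates: int = DEFAULT_REPLICATES,
    n_eggs: int = DEFAULT_EGGS_PER_REPLICATE,
) -> PhenotypeRecord:
    """An independent recipient-strain control record (baseline rates only).

    Each call is one control experiment; calibration studies should draw a
    fresh control per simulated line so comparisons are independent, as they
    would be across independently replicated experiments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _baseline_record(model, rng, strain, replicates, n_eggs)


def _baseline_record(
    model: PlantedHIModel,
    rng: np.random.Generator,
    strain: str,
    replicates: int,
    n_eggs: int,
) -> PhenotypeRecord:
    """Recipient-strain-style record: baseline deaths only, 1:1 sex ratio."""
    reps = []
    for _ in range(replicates):
        unhatched = int(rng.binomial(n_eggs, model.baseline_emb))
        l1 = n_eggs - unhatched
        arrested = int(rng.binomial(l1, model.baseline_lva))
        adults = l1 - arrested
        males = int(rng.binomial(adults, 0.5))
        reps.append(
            ReplicateCounts(
                eggs=n_eggs,
                unhatched=unhatched,
                l1=l1,
                adults=adults,
                males_nongfp=males,
                females_nongfp=adults - males,
            )
        )
    broods = np.maximum(1, np.round(rng.normal(model.brood_mean, model.brood_sd, replicates)))
    return PhenotypeRecord(
        strain=strain, replicates=reps, brood_sizes=[int(b) for b in broods],
        zygosity="homozygous",
    )


def simulate_hi_dataset(
    model: PlantedHIModel,
    n_lines: int = 20,
    replicates: int = DEFAULT_REPLICATES,
    n_eggs: int = DEFAULT_EGGS_PER_REPLICATE,
    generations: int = DEFAULT_GENERATIONS,
    markers_per_chromosome: int = 20,
    chrom: ChromosomeMap = CB4,
    seed: int | np.random.Generator | None = None,
    gfp_loci: Sequence[tuple[str, int]] | None = None,
) -> HIDataset:
    """Full pipeline input bundle with planted ground truth.

    Each line gets a random GFP insertion point, a backcross-simulated
    introgression interval, a PCR genotype matrix, and phenotype counts whose
    planted effects are those of the model loci its introgression covers
    (recessive effects express only in the homozygous/hemizygous state, so
    autosomal recessive lethality shows as the het x het cross's 25%
    homozygote loss, while X-linked male effects are fully penetrant through
    hemizygous males).  Truth labels per line enable recovery scoring.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chromosomes = list(chrom.lengths)
    panels = {
        c: uniform_panel(c, markers_per_chromosome, chrom=chrom) for c in chromosomes
    }
    control = _baseline_record(model, rng, "control", replicates, n_eggs)

    lines: list[SimulatedLine] = []
    for i in range(n_lines):
        if gfp_loci:
            # Targeted insertion sites (cycled), e.g. to guarantee coverage
            # of planted loci in recovery studies.
            chromosome, gfp_pos = gfp_loci[i % len(gfp_loci)]
        else:
            chromosome = chromosomes[int(rng.integers(len(chromosomes)))]
            length = chrom.length(chromosome)
            gfp_pos = int(rng.integers(int(0.05 * length), int(0.95 * length)))
        cfg = BackcrossConfig(
            chromosome=chromosome,
            gfp_position=gfp_pos,
            generations=generations,
            chrom=chrom,
        )
        introgression = simulate_backcross(cfg, rng)[-1]
        linkage = cfg.linkage

        covered = [
            locus
            for locus in model.loci
            if locus.interval.chromosome == chromosome
            and locus.interval.overlaps(introgression)
        ]
        effects = [locus.effect for locus in covered]

        line = _simulate_line_phenotypes(
            strain=f"line{i:04d}",
            introgression=introgression,
            linkage=linkage,
            covered=covered,
            model=model,
            replicates=replicates,
            n_eggs=n_eggs,
            rng=rng,
        )
        line.genotypes = simulate_genotype_matrix(
            introgression, panels[chromosome], seed=rng, strain=line.strain
        )
        line.truth_effects = effects
        lines.append(line)

    return HIDataset(lines=lines, control=control, panels=panels, model=model)


def _simulate_line_phenotypes(
    strain: str,
    introgression: GenomicInterval,
    linkage: str,
    covered: list[PlantedLocus],
    model: PlantedHIModel,
    replicates: int,
    n_eggs: int,
    rng: np.random.Generator,
) -> SimulatedLine:
    """Phenotype record and truth flags for one line given its covered loci."""
    locus = ce.LocusSpec(linkage)
    if linkage == ce.X_LINKED:
        mother = ce.parse_genotype("G/+", ce.FEMALE, ce.X_LINKED)
        father = ce.parse_genotype("+/O", ce.MALE, ce.X_LINKED)
    else:
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)

    survival: dict[tuple[str, str], float] = {}
    lethal_stage = "embryonic"
    truth_flags = {
        "male_sterile": False,
        "male_inviable": False,
        "homozygous_inviable": False,
        "emb_elevated": False,
        "lva_elevated": False,
        "fertility_reduced": False,
    }
    brood_mean = model.brood_mean
    male_cross_progeny: int | None = None
    reciprocal_cross_progeny: int | None = None
    attempts_failed: int | None = None

    def _expressed_keys(locus_obj: PlantedLocus) -> list[tuple[str, str]]:
        """(genotype, sex) classes in which the planted effect expresses."""
        if linkage == ce.X_LINKED:
            # Hemizygous males always express; het females only for dominant.
            keys = [("G/O", ce.MALE)]
            if locus_obj.dominance == "dominant":
                keys.append(("+/G", ce.FEMALE))
            return keys
        if locus_obj.dominance == "dominant":
            return [
                ("+/G", ce.FEMALE), ("+/G", ce.MALE),
                ("G/G", ce.FEMALE), ("G/G", ce.MALE),
            ]
        return [("G/G", ce.FEMALE), ("G/G", ce.MALE)]

    for planted in covered:
        if planted.effect in ("emb_lethal", "larval_arrest"):
            for key in _expressed_keys(planted):
                prev = survival.get(key, 1.0)
                survival[key] = prev * (1 - planted.penetrance)
            if planted.effect == "larval_arrest":
                lethal_stage = "larval"
                truth_flags["lva_elevated"] = True
            else:
                truth_flags["emb_elevated"] = True
            if linkage == ce.AUTOSOMAL:
                # A recessive lethal makes the homozygous line unobtainable.
                truth_flags["homozygous_inviable"] = planted.penetrance >= 1.0 or truth_flags["homozygous_inviable"]
        elif planted.effect == "male_inviable":
            if linkage == ce.X_LINKED:
                survival[("G/O", ce.MALE)] = survival.get(("G/O", ce.MALE), 1.0) * (
                    1 - planted.penetrance
                )
                if planted.penetrance >= 1.0:
                    truth_flags["male_inviable"] = True
        elif planted.effect == "male_sterile":
            if linkage == ce.X_LINKED and planted.penetrance >= 1.0:
                truth_flags["male_sterile"] = True
                male_cross_progeny = 0
                reciprocal_cross_progeny = int(rng.poisson(100)) + 1
        elif planted.effect == "fertility_shift":
            brood_mean = brood_mean * (
                1 - planted.penetrance * (1 - model.fertility_shift_factor)
            )
            truth_flags["fertility_reduced"] = True

    if truth_flags["male_inviable"]:
        # Inviability pre-empts sterility (no males to assay), matching the
        # classifier's label-set invariant.
        truth_flags["male_sterile"] = False
        male_cross_progeny = None
        reciprocal_cross_progeny = None
    if truth_flags["homozygous_inviable"]:
        attempts_failed = 5
    if (
        linkage == ce.X_LINKED
        and male_cross_progeny is None
        and not truth_flags["male_inviable"]
    ):
        # Fertile-male assay: progeny present in both directions.  Inviable
        # lines yield no GFP males to set up the male-direction cross with.
        male_cross_progeny = int(rng.poisson(100)) + 1
        reciprocal_cross_progeny = int(rng.poisson(100)) + 1

    vmodel = ce.ViabilityFertilityModel(survival=survival)
    record = simulate_progeny_counts(
        mother,
        father,
        locus,
        model=vmodel,
        n_eggs=n_eggs,
        replicates=replicates,
        baseline_emb=model.baseline_emb,
        baseline_lva=model.baseline_lva,
        lethal_stage=lethal_stage,
        seed=rng,
        strain=strain,
        zygosity="heterozygous",
    )
    broods = np.maximum(1, np.round(rng.normal(brood_mean, model.brood_sd, replicates)))
    record.brood_sizes = [int(b) for b in broods]
    record.male_cross_progeny = male_cross_progeny
    record.reciprocal_cross_progeny = reciprocal_cross_progeny
    record.homozygosing_attempts_failed = attempts_failed

    return SimulatedLine(
        strain=strain,
        introgression=introgression,
        linkage=linkage,
        record=record,
        genotypes=None,  # filled by the caller
        truth_effects=[],
        truth_flags=truth_flags,
    )
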