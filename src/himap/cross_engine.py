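"""Exact Mendelian expectation engine for XX/XO nematode crosses.

*Caenorhabditis* uses XX/XO sex determination: females (or hermaphrodites)
carry two X chromosomes, males carry one X and no Y, and male spermatogenesis
yields X-bearing and nullo-X sperm in equal proportion.  An oocyte fertilised
by an X sperm becomes an XX female; by a nullo-X sperm, an XO male.

A single biallelic locus is tracked: ``G`` marks the GFP-linked donor
introgression, ``+`` the recipient (wild) allele.  The locus is either
autosomal (diploid in both sexes) or X-linked (diploid in females, hemizygous
in males).  GFP expression is dominant: any genotype carrying at least one
``G`` expresses.

All probabilities are computed with :class:`fractions.Fraction`, so expected
segregation ratios (3/4, 1/2, 1/3, 1/8, 1/9, ...) are exact; they are
converted to float only at the reporting surface.  Per-class survival
probabilities model inviability: applying them and renormalising over
survivors gives the post-selection distribution that observed progeny are
drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping

__all__ = [
    "AUTOSOMAL",
    "X_LINKED",
    "FEMALE",
    "MALE",
    "LocusSpec",
    "ParentGenotype",
    "ViabilityFertilityModel",
    "ProgenyClass",
    "ProgenyDistribution",
    "parse_genotype",
    "enumerate_gametes",
    "expected_progeny",
    "expected_fraction",
    "homozygosing_success_probability",
]

AUTOSOMAL = "autosomal"
X_LINKED = "X-linked"
FEMALE = "female"
MALE = "male"

#: Sentinel allele for the nullo-X gamete / missing X in XO males.
NULLO = "O"

HALF = Fraction(1, 2)


@dataclass(frozen=True)
class LocusSpec:
    """A single biallelic marker locus, autosomal or X-linked."""

    linkage: str = AUTOSOMAL

    def __post_init__(self) -> None:
        if self.linkage not in (AUTOSOMAL, X_LINKED):
            raise ValueError(f"linkage must be {AUTOSOMAL!r} or {X_LINKED!r}")


def _canonical(alleles: tuple[str, ...]) -> tuple[str, ...]:
    # Sort so G/+ and +/G are the same genotype; "+" sorts before "G".
    return tuple(sorted(alleles))


@dataclass(frozen=True)
class ParentGenotype:
    """Sex plus allele multiset, consistent with linkage and XX/XO sex.

    Autosomal parents of either sex are diploid at the locus.  X-linked
    females are diploid; X-linked males are hemizygous (a single allele).
    """

    sex: str
    alleles: tuple[str, ...]
    linkage: str = AUTOSOMAL

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE!r} or {MALE!r}")
        if self.linkage not in (AUTOSOMAL, X_LINKED):
            raise ValueError(f"bad linkage {self.linkage!r}")
        object.__setattr__(self, "alleles", _canonical(tuple(self.alleles)))
        n = len(self.alleles)
        if self.linkage == X_LINKED and self.sex == MALE:
            if n != 1:
                raise ValueError("an X-linked XO male genotype is hemizygous (one allele)")
        elif n != 2:
            raise ValueError(f"expected a diploid genotype, got {self.alleles}")
        for a in self.alleles:
            if a == NULLO:
                raise ValueError("nullo-X is not an allele; XO males carry a single X allele")

    @property
    def gfp(self) -> bool:
        return "G" in self.alleles

    def __str__(self) -> str:
        if self.linkage == X_LINKED and self.sex == MALE:
            return f"{self.alleles[0]}/O"
        return "/".join(self.alleles)


def parse_genotype(text: str, sex: str, linkage: str = AUTOSOMAL) -> ParentGenotype:
    """Parse ``"G/+"``-style genotype strings; ``"G/O"`` is an X-linked male."""
    parts = [p.strip() for p in text.split("/")]
    if any(p not in ("G", "+", NULLO) for p in parts):
        raise ValueError(f"unrecognised alleles in genotype {text!r}")
    alleles = tuple(p for p in parts if p != NULLO)
    return ParentGenotype(sex=sex, alleles=alleles, linkage=linkage)


@dataclass(frozen=True)
class ProgenyClass:
    """One (genotype, sex) progeny class."""

    sex: str
    alleles: tuple[str, ...]
    linkage: str = AUTOSOMAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", _canonical(tuple(self.alleles)))

    @property
    def gfp(self) -> bool:
        return "G" in self.alleles

    @property
    def homozygous(self) -> bool:
        return len(self.alleles) == 2 and self.alleles[0] == self.alleles[1]

    @property
    def hemizygous(self) -> bool:
        return len(self.alleles) == 1

    def genotype_str(self) -> str:
        if self.hemizygous:
            return f"{self.alleles[0]}/O"
        return "/".join(self.alleles)

    def __str__(self) -> str:
        return f"{self.genotype_str()} {self.sex}"


@dataclass
class ViabilityFertilityModel:
    """Survival probability and fertility per (genotype string, sex).

    ``survival`` maps ``("G/G", "male")``-style keys to probabilities in
    [0, 1]; unlisted classes survive with probability 1.  ``sterile`` lists
    (genotype, sex) classes that are viable but cannot reproduce.  The sex
    ratio at conception defaults to the Mendelian 1/2 : 1/2 delivered by
    X vs nullo-X sperm.
    """

    survival: dict[tuple[str, str], Fraction | float] = field(default_factory=dict)
    sterile: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], Fraction] = {}
        for key, p in self.survival.items():
            p = Fraction(p).limit_denominator(10**9) if not isinstance(p, Fraction) else p
            if not 0 <= p <= 1:
                raise ValueError(f"survival probability {p} for {key} outside [0, 1]")
            clean[key] = p
        self.survival = clean

    def survival_of(self, cls: ProgenyClass) -> Fraction:
        return self.survival.get((cls.genotype_str(), cls.sex), Fraction(1))

    def is_fertile(self, genotype: str, sex: str) -> bool:
        return (genotype, sex) not in self.sterile


FULL_VIABILITY = ViabilityFertilityModel()


def enumerate_gametes(parent: ParentGenotype, locus: LocusSpec) -> dict[str, Fraction]:
    """Equal-frequency gamete distribution for one parent.

    Autosomal gametes carry one allele each at probability 1/2 (or 1 for a
    homozygote).  X-linked female gametes carry one X allele each at 1/2;
    X-linked XO males produce X-bearing and nullo-X gametes at exactly 1/2
    each, the nullo gamete tagged ``"O"``.
    """
    if parent.linkage != locus.linkage:
        raise ValueError(
            f"parent linkage {parent.linkage!r} inconsistent with locus {locus.linkage!r}"
        )
    out: dict[str, Fraction] = {}
    if locus.linkage == X_LINKED and parent.sex == MALE:
        out[parent.alleles[0]] = HALF
        out[NULLO] = out.get(NULLO, Fraction(0)) + HALF
        return out
    for allele in parent.alleles:
        out[allele] = out.get(allele, Fraction(0)) + HALF
    return out


@dataclass
class ProgenyDistribution:
    """Pre- and post-selection probabilities over (genotype, sex) classes.

    ``pre`` sums to 1 exactly.  ``post`` is ``pre`` with each class weighted
    by its survival probability and renormalised over survivors; it also sums
    to 1 when any class survives.  ``survival_mass`` is the expected surviving
    fraction, so ``1 - survival_mass`` is the expected inviable fraction.
    """

    pre: dict[ProgenyClass, Fraction]
    post: dict[ProgenyClass, Fraction]
    survival_mass: Fraction

    def classes(self) -> list[ProgenyClass]:
        return list(self.pre)


def expected_progeny(
    mother: ParentGenotype,
    father: ParentGenotype,
    locus: LocusSpec,
    model: ViabilityFertilityModel = FULL_VIABILITY,
) -> ProgenyDistribution:
    """Exact progeny class distribution of a single-locus XX/XO cross.

    The cross-product of parental gamete distributions is combined with
    XX/XO sex determination: for an autosomal locus, sex is independent of
    the locus and splits 1/2 female : 1/2 male; for an X-linked locus, sex is
    determined by whether the paternal gamete carries an X (daughter) or is
    nullo-X (son), and sons are hemizygous for the maternal allele.

    Survival probabilities are applied per class and renormalised to give the
    post-selection distribution.  A parent flagged sterile under the model
    raises ``ValueError``.
    """
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("expected a female mother and male father")
    for parent in (mother, father):
        if not model.is_fertile(str(parent), parent.sex):
            raise ValueError(f"cross yields no progeny: parent {parent} is sterile")

    pre: dict[ProgenyClass, Fraction] = {}

    def add(cls: ProgenyClass, p: Fraction) -> None:
        pre[cls] = pre.get(cls, Fraction(0)) + p

    egg = enumerate_gametes(mother, locus)
    sperm = enumerate_gametes(father, locus)
    if locus.linkage == AUTOSOMAL:
        for ea, ep in egg.items():
            for sa, sp in sperm.items():
                for sex in (FEMALE, MALE):
                    add(ProgenyClass(sex=sex, alleles=(ea, sa), linkage=AUTOSOMAL), ep * sp * HALF)
    else:
        for ea, ep in egg.items():
            for sa, sp in sperm.items():
                if sa == NULLO:
                    add(ProgenyClass(sex=MALE, alleles=(ea,), linkage=X_LINKED), ep * sp)
                else:
                    add(ProgenyClass(sex=FEMALE, alleles=(ea, sa), linkage=X_LINKED), ep * sp)

    assert sum(pre.values()) == 1

    weighted = {cls: p * model.survival_of(cls) for cls, p in pre.items()}
    mass = sum(weighted.values(), Fraction(0))
    if mass == 0:
        raise ValueError("no viable progeny class under the given model")
    post = {cls: w / mass for cls, w in weighted.items() if w > 0}
    return ProgenyDistribution(pre=pre, post=post, survival_mass=mass)


def expected_fraction(
    dist: ProgenyDistribution,
    predicate: Callable[[ProgenyClass], bool],
    given: Callable[[ProgenyClass], bool] | None = None,
    pre_selection: bool = False,
) -> Fraction:
    """Conditional class probability under the progeny distribution.

    ``predicate`` selects the event; ``given`` (optional) the conditioning
    event.  By default probabilities are over the post-selection (surviving)
    distribution; ``pre_selection=True`` uses the at-conception distribution,
    e.g. for joint probabilities like P(homozygous and male).
    """
    probs = dist.pre if pre_selection else dist.post
    if given is None:
        return sum((p for cls, p in probs.items() if predicate(cls)), Fraction(0))
    denom = sum((p for cls, p in probs.items() if given(cls)), Fraction(0))
    if denom == 0:
        raise ValueError("conditioning event has zero probability")
    num = sum((p for cls, p in probs.items() if predicate(cls) and given(cls)), Fraction(0))
    return num / denom


def gfp(cls: ProgenyClass) -> bool:
    """Predicate: class expresses the dominant GFP marker."""
    return cls.gfp


def is_male(cls: ProgenyClass) -> bool:
    return cls.sex == MALE


def is_female(cls: ProgenyClass) -> bool:
    return cls.sex == FEMALE


def homozygosing_success_probability(
    mother: ParentGenotype,
    father: ParentGenotype,
    locus: LocusSpec,
    model: ViabilityFertilityModel = FULL_VIABILITY,
) -> Fraction:
    """Probability that two GFP progeny picked at random are both homozygous.

    Models the homozygosing step: one GFP-expressing female and one
    GFP-expressing male are drawn from the progeny of the given cross and
    mated; the plate breeds true only if both are homozygous (females) or
    homozygous/hemizygous-G (males).  For the canonical autosomal het x het
    cross this is ``(1/3)^2 = 1/9`` — one plate in nine.
    """
    dist = expected_progeny(mother, father, locus, model)

    def hom_g(cls: ProgenyClass) -> bool:
        if cls.hemizygous:
            return cls.alleles == ("G",)
        return cls.alleles == ("G", "G")

    p_f = expected_fraction(dist, hom_g, given=lambda c: c.gfp and c.sex == FEMALE)
    p_m = expected_fraction(dist, hom_g, given=lambda c: c.gfp and c.sex == MALE)
    return p_f * p_m
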