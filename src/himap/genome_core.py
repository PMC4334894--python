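"""Coordinate conventions, interval algebra and genome-wide landscape statistics.

All coordinates are 0-based, half-open base-pair integers.  Megabase values
with two decimals appear only at the reporting layer; interval arithmetic is
exact integer arithmetic throughout, which keeps set operations (union,
difference, coverage) free of floating-point drift.

The default :class:`ChromosomeMap` carries the six chromosome sizes of the
*C. briggsae* "cb4" genome assembly, the coordinate system in which the
genotyping markers and introgression boundaries of this package are
expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CB4_CHROMOSOME_SIZES_BP",
    "AUTOSOMES",
    "ChromosomeMap",
    "GenomicInterval",
    "IntervalSet",
    "LandscapeTable",
    "interval_length",
    "mb",
    "consolidate",
    "coverage_fraction",
    "build_landscape",
]

#: cb4 chromosome sizes in bp (printed as Mb to two decimals in reports).
CB4_CHROMOSOME_SIZES_BP: dict[str, int] = {
    "I": 15_450_000,
    "II": 16_620_000,
    "III": 14_570_000,
    "IV": 17_480_000,
    "V": 19_490_000,
    "X": 21_540_000,
}

AUTOSOMES: tuple[str, ...] = ("I", "II", "III", "IV", "V")


def mb(bp: int | float) -> float:
    """Render a bp length in Mb, rounded half-up to two decimals."""
    return float((Decimal(bp) / Decimal(1_000_000)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChromosomeMap:
    """Chromosome name -> length (bp), with optional genetic lengths (Morgans)."""

    lengths: Mapping[str, int] = field(default_factory=lambda: dict(CB4_CHROMOSOME_SIZES_BP))
    genetic_lengths: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.genetic_lengths is not None:
            for name in self.genetic_lengths:
                if name not in self.lengths:
                    raise ValueError(f"genetic length given for unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def genetic_length(self, name: str) -> float:
        if self.genetic_lengths is None or name not in self.genetic_lengths:
            raise KeyError(f"no genetic length for chromosome {name!r}")
        return self.genetic_lengths[name]

    @classmethod
    def from_tsv(cls, path) -> "ChromosomeMap":
        """Read a two-column (name, length-bp) TSV, FASTA-index style."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
                name, length = parts[0], int(parts[1])
                if name in lengths:
                    raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
                lengths[name] = length
        return cls(lengths=lengths)


#: Default cb4 map shared across the package.
CB4 = ChromosomeMap()


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return mb(self.length)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chromosome, max(self.start, other.start), min(self.end, other.end)
        )

    def difference(self, other: "GenomicInterval") -> list["GenomicInterval"]:
        """``self \\ other`` as 0, 1 or 2 intervals (2 when other is interior)."""
        if self.chromosome != other.chromosome or not self.overlaps(other):
            return [self]
        out: list[GenomicInterval] = []
        if self.start < other.start:
            out.append(GenomicInterval(self.chromosome, self.start, other.start))
        if other.end < self.end:
            out.append(GenomicInterval(self.chromosome, other.end, self.end))
        return out

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.intersection(other)
        if inter is None:
            return 0.0
        union = self.length + other.length - inter.length
        return inter.length / union


def interval_length(iv: GenomicInterval) -> int:
    """Length of an interval in bp (``end - start``)."""
    return iv.length


class IntervalSet:
    """An ordered, per-chromosome set of non-overlapping, non-abutting intervals.

    Construction consolidates the input: overlapping or abutting intervals are
    merged (the half-open convention makes ``end == start`` adjacency
    unambiguous), so membership is a canonical union.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chromosome, []).append(iv)
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for chrom in sorted(by_chrom):
            merged: list[list[int]] = []
            for iv in sorted(by_chrom[chrom], key=lambda v: (v.start, v.end)):
                if merged and iv.start <= merged[-1][1]:  # overlap or abut
                    merged[-1][1] = max(merged[-1][1], iv.end)
                else:
                    merged.append([iv.start, iv.end])
            self._by_chrom[chrom] = [GenomicInterval(chrom, s, e) for s, e in merged]

    def __iter__(self):
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __repr__(self) -> str:
        return f"IntervalSet({list(self)!r})"

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def on(self, chromosome: str) -> list[GenomicInterval]:
        return list(self._by_chrom.get(chromosome, ()))

    def total_length(self, chromosome: str | None = None) -> int:
        if chromosome is not None:
            return sum(iv.length for iv in self._by_chrom.get(chromosome, ()))
        return sum(iv.length for iv in self)


def consolidate(intervals: Iterable[GenomicInterval]) -> IntervalSet:
    """Merge a collection of intervals into its minimal sorted union.

    Redundant (overlapping or abutting) parts are consolidated; intervals on
    different chromosomes are grouped per chromosome and never merged across.
    Idempotent: ``consolidate(consolidate(S)) == consolidate(S)``.
    """
    return IntervalSet(intervals)


def coverage_fraction(
    ivset: IntervalSet, chrom: ChromosomeMap, chromosome: str
) -> float:
    """Percentage of a chromosome covered by a consolidated interval set.

    Raises ``KeyError`` for an unknown chromosome id.
    """
    length = chrom.length(chromosome)
    covered = ivset.total_length(chromosome)
    if covered > length:
        raise ValueError(
            f"consolidated length {covered} exceeds chromosome {chromosome} length {length}"
        )
    return 100.0 * covered / length


# Landscape categories for introgression viability status.
CATEGORY_HOM_VIABLE = "homozygous-viable"
CATEGORY_HOM_INVIABLE = "homozygous-inviable"
CATEGORY_HETEROZYGOUS = "heterozygous"
LANDSCAPE_CATEGORIES = (CATEGORY_HOM_VIABLE, CATEGORY_HOM_INVIABLE, CATEGORY_HETEROZYGOUS)


@dataclass
class LandscapeRow:
    """One chromosome (or aggregate) row of the introgression landscape."""

    name: str
    size_bp: int
    covered_bp: dict[str, int]  # per category plus "all"

    def coverage_pct(self, category: str = "all") -> float:
        return 100.0 * self.covered_bp.get(category, 0) / self.size_bp

    def covered_mb(self, category: str = "all") -> float:
        return mb(self.covered_bp.get(category, 0))


@dataclass
class LandscapeTable:
    """Per-chromosome and aggregate coverage of introgressions by viability category."""

    rows: dict[str, LandscapeRow]

    def row(self, name: str) -> LandscapeRow:
        return self.rows[name]

    def to_records(self) -> list[dict]:
        out = []
        for row in self.rows.values():
            rec = {"linkage_group": row.name, "size_mb": mb(row.size_bp)}
            for cat in ("all",) + LANDSCAPE_CATEGORIES:
                rec[f"{cat}_mb"] = row.covered_mb(cat)
                rec[f"{cat}_pct"] = round(row.coverage_pct(cat), 2)
            out.append(rec)
        return out


def build_landscape(
    introgressions: Sequence[tuple[GenomicInterval, str]],
    chrom: ChromosomeMap | None = None,
) -> LandscapeTable:
    """Tabulate consolidated introgression coverage per chromosome and category.

    Parameters
    ----------
    introgressions:
        ``(outer interval, category)`` pairs with category one of
        ``homozygous-viable``, ``homozygous-inviable``, ``heterozygous``.
    chrom:
        Chromosome sizes; defaults to the cb4 assembly sizes.

    The table carries one row per chromosome plus an autosomal aggregate
    ("Autosomal") and a genome aggregate ("Overall"); the "all" category
    consolidates every introgression regardless of category.
    """
    chrom = chrom or CB4
    for iv, cat in introgressions:
        if iv.chromosome not in chrom:
            raise KeyError(f"introgression on unknown chromosome {iv.chromosome!r}")
        if cat not in LANDSCAPE_CATEGORIES:
            raise ValueError(f"unknown landscape category {cat!r}")

    rows: dict[str, LandscapeRow] = {}
    per_cat_sets = {
        cat: consolidate(iv for iv, c in introgressions if c == cat)
        for cat in LANDSCAPE_CATEGORIES
    }
    all_set = consolidate(iv for iv, _ in introgressions)

    for name, size in chrom.lengths.items():
        covered = {"all": all_set.total_length(name)}
        for cat, s in per_cat_sets.items():
            covered[cat] = s.total_length(name)
        rows[name] = LandscapeRow(name=name, size_bp=size, covered_bp=covered)

    def aggregate(label: str, names: Iterable[str]) -> LandscapeRow:
        names = [n for n in names if n in rows]
        size = sum(rows[n].size_bp for n in names)
        covered: dict[str, int] = {}
        for cat in ("all",) + LANDSCAPE_CATEGORIES:
            covered[cat] = sum(rows[n].covered_bp[cat] for n in names)
        return LandscapeRow(name=label, size_bp=size, covered_bp=covered)

    # Every chromosome except "X" counts as autosomal (cb4 and custom maps alike).
    autosomes = [n for n in chrom.lengths if n != "X"]
    rows["Autosomal"] = aggregate("Autosomal", autosomes)
    rows["Overall"] = aggregate("Overall", chrom.lengths)
    return LandscapeTable(rows=rows)
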