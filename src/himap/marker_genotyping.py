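"""Introgression boundary calling from ordered species-specific PCR markers.

A marker panel is a set of donor-specific (*C. briggsae*) primer pairs at
known cb4 positions.  Genotyping a strain with the panel yields, per marker,
POS (product amplified: donor allele present), NEG (no product) or NA
(reaction failed).  Because the primers amplify in heterozygotes and
homozygotes alike, zygosity is never inferred here; it is an annotation from
crossing records.

An introgressed segment appears as a run of POS calls.  The *inner* boundary
interval spans the outermost POS markers and is the minimal segment
consistent with the calls; the *outer* interval extends to the nearest
flanking NEG markers (or the chromosome ends) and is the maximal — and
reported — segment size.

Isolated calls contradicting a surrounding consensus run (e.g. a single NEG
inside a long POS run whose flanking markers both amplified) are flagged as
candidate genome assembly errors — the primer's annotated position likely
belongs elsewhere — and excluded from boundary computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_core import ChromosomeMap, GenomicInterval

__all__ = [
    "POS",
    "NEG",
    "NA",
    "Marker",
    "MarkerPanel",
    "GenotypeMatrix",
    "IntrogressionCall",
    "NoIntrogressionError",
    "call_boundaries",
    "flag_assembly_errors",
    "compare_callsets",
    "ConcordanceReport",
]

POS = "+"
NEG = "-"
NA = "NA"
_VALID_CALLS = (POS, NEG, NA)


@dataclass(frozen=True)
class Marker:
    """One genotyping primer pair: name and amplicon span (0-based half-open)."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"marker {self.name}: invalid span {self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        """Amplicon midpoint — the marker's point position on the chromosome."""
        return (self.start + self.end) // 2


class MarkerPanel:
    """Ordered collection of markers, sorted per chromosome by amplicon midpoint."""

    def __init__(self, markers: Iterable[Marker]) -> None:
        self._by_chrom: dict[str, list[Marker]] = {}
        names: set[str] = set()
        for m in markers:
            if m.name in names:
                raise ValueError(f"duplicate marker name {m.name!r}")
            names.add(m.name)
            self._by_chrom.setdefault(m.chromosome, []).append(m)
        for chrom, ms in self._by_chrom.items():
            ms.sort(key=lambda m: m.midpoint)
            mids = [m.midpoint for m in ms]
            if len(set(mids)) != len(mids):
                raise ValueError(f"markers on chromosome {chrom} have duplicate midpoints")
        self._by_name = {m.name: m for ms in self._by_chrom.values() for m in ms}

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def marker(self, name: str) -> Marker:
        return self._by_name[name]

    def on(self, chromosome: str) -> list[Marker]:
        """Markers on one chromosome in midpoint order."""
        return list(self._by_chrom.get(chromosome, ()))


class GenotypeMatrix:
    """Strain x marker PCR call matrix with calls in {+, -, NA}."""

    def __init__(self, calls: Mapping[str, Mapping[str, str]], panel: MarkerPanel) -> None:
        self.panel = panel
        self._calls: dict[str, dict[str, str]] = {}
        for strain, row in calls.items():
            clean: dict[str, str] = {}
            for marker, call in row.items():
                if marker not in panel:
                    raise ValueError(f"strain {strain}: call for unknown marker {marker!r}")
                if call not in _VALID_CALLS:
                    raise ValueError(
                        f"strain {strain}, marker {marker}: invalid call {call!r} "
                        f"(expected one of {_VALID_CALLS})"
                    )
                clean[marker] = call
            self._calls[strain] = clean

    @property
    def strains(self) -> list[str]:
        return list(self._calls)

    def calls_for(self, strain: str, chromosome: str) -> list[tuple[Marker, str]]:
        """(marker, call) pairs for one strain on one chromosome, in panel order."""
        row = self._calls[strain]
        return [(m, row.get(m.name, NA)) for m in self.panel.on(chromosome)]

    def call(self, strain: str, marker: str) -> str:
        return self._calls[strain].get(marker, NA)


class NoIntrogressionError(ValueError):
    """Raised when a strain shows no POS marker call on the chromosome."""


@dataclass
class IntrogressionCall:
    """Boundary intervals inferred for one strain on one chromosome.

    ``inner`` spans the outermost consensus POS markers (minimal segment);
    ``outer`` extends to the flanking consensus NEG midpoints or chromosome
    ends (maximal segment — the reported introgression size).  Additional
    disjoint POS runs, if any, are carried in ``extra_segments`` with a
    warning (possible assembly error or secondary insertion).
    """

    strain: str
    chromosome: str
    inner: GenomicInterval
    outer: GenomicInterval
    exception_markers: list[str] = field(default_factory=list)
    assembly_error_candidates: list[str] = field(default_factory=list)
    zygosity: str = "unknown"
    extra_segments: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.outer.contains(self.inner):
            raise ValueError("inner boundary interval must lie within the outer interval")

    @property
    def size_bp(self) -> int:
        """Reported introgression size: the outer interval length."""
        return self.outer.length


def _runs(calls: Sequence[tuple[int, str]]) -> list[tuple[str, list[int]]]:
    """Group (index, call) pairs into maximal runs of identical calls."""
    runs: list[tuple[str, list[int]]] = []
    for idx, call in calls:
        if runs and runs[-1][0] == call:
            runs[-1][1].append(idx)
        else:
            runs.append((call, [idx]))
    return runs


def flag_assembly_errors(
    calls: Sequence[str],
    panel_markers: Sequence[Marker],
    exception_max_run: int = 1,
    min_consensus: int = 2,
) -> list[str]:
    """Markers whose call contradicts a flanking consensus on both sides.

    A maximal run of identical calls of length <= ``exception_max_run``,
    flanked on each side by >= ``min_consensus`` markers of the opposite call
    (>= 1 when the flanking run sits at the panel edge), is an exception: the
    odd marker out of an otherwise consistent consensus, the signature of a
    primer whose annotated genomic position is wrong (assembly error) or of a
    sporadic PCR failure.  NA calls are transparent: they are skipped when
    building runs and are never flagged.
    """
    if len(calls) != len(panel_markers):
        raise ValueError("calls and panel markers must align")
    informative = [(i, c) for i, c in enumerate(calls) if c != NA]
    runs = _runs(informative)
    flagged: list[str] = []
    for k, (call, idxs) in enumerate(runs):
        if len(idxs) > exception_max_run:
            continue
        if k == 0 or k == len(runs) - 1:
            continue  # needs consensus on both sides
        left_call, left_idxs = runs[k - 1]
        right_call, right_idxs = runs[k + 1]
        if left_call != right_call or left_call == call:
            continue
        need_left = min_consensus if k - 1 > 0 else 1
        need_right = min_consensus if k + 1 < len(runs) - 1 else 1
        if len(left_idxs) >= need_left and len(right_idxs) >= need_right:
            flagged.extend(panel_markers[i].name for i in idxs)
    return flagged


def call_boundaries(
    calls: Sequence[str],
    panel_markers: Sequence[Marker],
    chrom: ChromosomeMap,
    strain: str = "",
    zygosity: str = "unknown",
    exception_max_run: int = 1,
    min_consensus: int = 2,
) -> IntrogressionCall:
    """Infer introgression boundary intervals from one strain's ordered calls.

    Parameters
    ----------
    calls:
        Per-marker calls (``+``/``-``/``NA``) aligned with ``panel_markers``.
    panel_markers:
        Markers of one chromosome in midpoint order (``MarkerPanel.on``).

    Exceptions (see :func:`flag_assembly_errors`) are excluded before the
    boundary rule is applied.  The reported size is the outer interval:
    from the midpoint of the nearest non-amplifying marker left of the POS
    run (or the chromosome start when the run reaches the first marker) to
    its counterpart on the right (or the chromosome end).

    Raises :class:`NoIntrogressionError` when no POS call survives exception
    removal.  When several disjoint POS runs survive, the largest-outer one
    is primary and the rest are attached as ``extra_segments`` with a warning.
    """
    if len(calls) != len(panel_markers):
        raise ValueError("calls and panel markers must align")
    if not panel_markers:
        raise NoIntrogressionError("empty marker panel for chromosome")
    chromosome = panel_markers[0].chromosome
    if any(m.chromosome != chromosome for m in panel_markers):
        raise ValueError("panel markers span multiple chromosomes")
    chrom_len = chrom.length(chromosome)

    exceptions = flag_assembly_errors(
        calls, panel_markers, exception_max_run=exception_max_run, min_consensus=min_consensus
    )
    dropped = set(exceptions)

    informative = [
        (i, c)
        for i, c in enumerate(calls)
        if c != NA and panel_markers[i].name not in dropped
    ]
    pos_idx = [i for i, c in informative if c == POS]
    if not pos_idx:
        raise NoIntrogressionError(
            f"no introgression detected for strain {strain!r} on chromosome {chromosome}"
        )

    runs = _runs(informative)
    pos_runs = [idxs for call, idxs in runs if call == POS]
    warnings: list[str] = []
    if len(pos_runs) > 1:
        warnings.append(
            f"{len(pos_runs)} disjoint POS runs on chromosome {chromosome}: "
            "possible assembly error or secondary insertion"
        )

    neg_positions = [i for i, c in informative if c == NEG]

    def segment(idxs: list[int]) -> tuple[GenomicInterval, GenomicInterval]:
        left_mid = panel_markers[idxs[0]].midpoint
        right_mid = panel_markers[idxs[-1]].midpoint
        if left_mid < right_mid:
            inner = GenomicInterval(chromosome, left_mid, right_mid)
        else:  # single-marker run: fall back to the amplicon span
            m = panel_markers[idxs[0]]
            inner = GenomicInterval(chromosome, m.start, m.end)
        left_negs = [i for i in neg_positions if i < idxs[0]]
        right_negs = [i for i in neg_positions if i > idxs[-1]]
        outer_start = panel_markers[max(left_negs)].midpoint if left_negs else 0
        outer_end = panel_markers[min(right_negs)].midpoint if right_negs else chrom_len
        outer = GenomicInterval(chromosome, outer_start, outer_end)
        return inner, outer

    segments = [segment(idxs) for idxs in pos_runs]
    segments.sort(key=lambda s: s[1].length, reverse=True)
    inner, outer = segments[0]

    return IntrogressionCall(
        strain=strain,
        chromosome=chromosome,
        inner=inner,
        outer=outer,
        exception_markers=list(exceptions),
        assembly_error_candidates=list(exceptions),
        zygosity=zygosity,
        extra_segments=segments[1:],
        warnings=warnings,
    )


@dataclass
class ConcordanceReport:
    """Agreement between a PCR boundary call and an independent reference interval."""

    jaccard: float
    left_offset_bp: int
    right_offset_bp: int
    same_chromosome: bool
    warnings: list[str] = field(default_factory=list)


def compare_callsets(
    pcr: IntrogressionCall, reference: GenomicInterval
) -> ConcordanceReport:
    """Compare a PCR outer interval against a reference (e.g. NGS) interval.

    Jaccard overlap of the two intervals, plus signed boundary offsets
    (PCR minus reference) in bp.  Calls on different chromosomes yield
    concordance 0 with a warning.
    """
    if pcr.chromosome != reference.chromosome:
        return ConcordanceReport(
            jaccard=0.0,
            left_offset_bp=0,
            right_offset_bp=0,
            same_chromosome=False,
            warnings=[
                f"PCR call on {pcr.chromosome} but reference on {reference.chromosome}"
            ],
        )
    return ConcordanceReport(
        jaccard=pcr.outer.jaccard(reference),
        left_offset_bp=pcr.outer.start - reference.start,
        right_offset_bp=pcr.outer.end - reference.end,
        same_chromosome=True,
    )
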