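"""Introgression detection from windowed read-depth enrichment.

When short reads from an introgression strain (recipient *C. nigoni*
background carrying a donor *C. briggsae* segment) are aligned to the donor
assembly, only the introgressed segment recruits reads at full depth; the
rest of the donor genome attracts a background of cross-mapping reads.  The
introgression therefore shows as a block of windows several-fold deeper than
its flanks.  The caller operationalises the enrichment rule as: a window is
enriched when its depth is at least ``fold`` (default 5) times a robust
baseline; runs of at least ``min_windows`` enriched windows, bridged across
at most ``gap_windows`` sub-threshold windows, are reported as intervals.

The baseline ("flanking region" depth) defaults to the chromosome-wide
median excluding candidate enriched windows, re-estimated once after an
initial pass; a local-flank variant (median of the nearest windows each
side) is available through the config.  Alignment itself is out of scope:
the module consumes per-window depth tracks (bedGraph-style) or simulated
tracks.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_core import GenomicInterval

__all__ = [
    "CoverageTrack",
    "CoverageCallConfig",
    "normalize_track",
    "call_coverage_introgression",
]

DEFAULT_WINDOW = 10_000


@dataclass
class CoverageTrack:
    """Per-window mean depth along one chromosome.

    Window ``i`` covers ``[i * window, (i + 1) * window)`` bp; windows tile
    the chromosome in order.  ``normalization`` records the total bases
    sequenced the track has been normalized by (None if raw).
    """

    chromosome: str
    depths: np.ndarray
    window: int = DEFAULT_WINDOW
    normalization: float | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if np.any(self.depths < 0):
            raise ValueError("window depths must be non-negative")
        if self.window <= 0:
            raise ValueError("window size must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.depths)

    def window_interval(self, i: int, j: int | None = None) -> GenomicInterval:
        """Genomic interval covered by windows ``i..j`` inclusive."""
        j = i if j is None else j
        return GenomicInterval(self.chromosome, i * self.window, (j + 1) * self.window)


def normalize_track(track: CoverageTrack, total_bases: float) -> CoverageTrack:
    """Scale window depths to depth per Gb sequenced.

    Each depth is divided by ``total_bases / 1e9`` so tracks from libraries
    of different size are comparable.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    scale = total_bases / 1e9
    return CoverageTrack(
        chromosome=track.chromosome,
        depths=track.depths / scale,
        window=track.window,
        normalization=total_bases,
    )


@dataclass
class CoverageCallConfig:
    """Parameters of the fold-enrichment interval caller.

    Calling is seed-and-extend with hysteresis: windows at depth >=
    ``fold x baseline`` seed a call; the call extends over contiguous windows
    at depth >= ``extend_fold x baseline`` and bridges up to ``gap_windows``
    windows below that.  A call needs at least ``min_windows`` seed windows
    and a mean depth satisfying the fold rule, so every reported run is
    ``fold``-enriched over the baseline even though single noisy windows
    inside it may dip below the seed threshold.
    """

    fold: float = 5.0
    extend_fold: float | None = None  # default: fold / 2
    min_windows: int = 3
    gap_windows: int = 1
    baseline: str = "global-median"  # or "local-flank"
    local_flank_windows: int = 20
    baseline_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold threshold must exceed 1")
        if self.extend_fold is None:
            self.extend_fold = self.fold / 2.0
        if not 1 <= self.extend_fold <= self.fold:
            raise ValueError("extend_fold must lie in [1, fold]")
        if self.min_windows < 1:
            raise ValueError("min_windows must be >= 1")
        if self.gap_windows < 0:
            raise ValueError("gap_windows must be >= 0")
        if self.baseline not in ("global-median", "local-flank"):
            raise ValueError(f"unknown baseline estimator {self.baseline!r}")


def _seed_extend_runs(
    depths: np.ndarray,
    seed_mask: np.ndarray,
    extend_mask: np.ndarray,
    fold_threshold: float,
    min_windows: int,
    gap: int,
) -> list[tuple[int, int]]:
    """Seed-and-extend run finding with gap bridging.

    Runs grow from seed windows over contiguous extend-mask windows; runs
    separated by <= ``gap`` non-extend windows merge.  A run survives when it
    contains >= ``min_windows`` seeds and its mean depth >= ``fold_threshold``.
    """
    idx = np.flatnonzero(extend_mask)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 <= gap:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    out: list[tuple[int, int]] = []
    for s, e in runs:
        if int(seed_mask[s : e + 1].sum()) < min_windows:
            continue
        if float(depths[s : e + 1].mean()) >= fold_threshold:
            out.append((s, e))
    return out


def _baseline_global(depths: np.ndarray, exclude: np.ndarray | None) -> float:
    keep = depths if exclude is None else depths[~exclude]
    if keep.size == 0:
        keep = depths
    return float(np.median(keep))


def call_coverage_introgression(
    track: CoverageTrack, cfg: CoverageCallConfig | None = None
) -> list[GenomicInterval]:
    """Call introgressed intervals as runs of fold-enriched windows.

    The baseline is estimated, candidate enriched windows are masked out and
    the baseline re-estimated once (so a large introgression does not inflate
    its own reference level), then maximal enriched runs are emitted as
    0-based half-open intervals.  A zero baseline with positive windows is
    floored at ``cfg.baseline_epsilon`` and the call emitted with a warning.
    """
    cfg = cfg or CoverageCallConfig()
    depths = track.depths
    if len(depths) < 2 * cfg.min_windows:
        raise ValueError(
            f"track too short: {len(depths)} windows < 2 x min_windows ({cfg.min_windows})"
        )

    if cfg.baseline == "local-flank":
        folds = _local_fold(depths, cfg)
        runs = _seed_extend_runs(
            folds, folds >= cfg.fold, folds >= cfg.extend_fold,
            cfg.fold, cfg.min_windows, cfg.gap_windows,
        )
        return [track.window_interval(s, e) for s, e in runs]

    baseline = _final_baseline(depths, cfg)
    if baseline is None:
        return []  # all-zero track
    runs = _seed_extend_runs(
        depths,
        depths >= cfg.fold * baseline,
        depths >= cfg.extend_fold * baseline,
        cfg.fold * baseline,
        cfg.min_windows,
        cfg.gap_windows,
    )
    return [track.window_interval(s, e) for s, e in runs]


def _final_baseline(depths: np.ndarray, cfg: CoverageCallConfig) -> float | None:
    """Global-median baseline: initial pass, then one re-estimation with
    candidate enriched windows excluded.  None for an all-zero track."""
    baseline = _baseline_global(depths, None)
    for _ in range(2):
        if baseline <= 0:
            if np.any(depths > 0):
                _warnings.warn(
                    "zero baseline with positive windows; flooring at epsilon",
                    stacklevel=3,
                )
                baseline = cfg.baseline_epsilon
            else:
                return None
        mask = depths >= cfg.extend_fold * baseline
        new_baseline = _baseline_global(depths, mask)
        if new_baseline == baseline:
            break
        baseline = new_baseline
    if baseline <= 0:
        if not np.any(depths > 0):
            return None
        _warnings.warn("zero baseline with positive windows; flooring at epsilon", stacklevel=3)
        baseline = cfg.baseline_epsilon
    return baseline


def _local_fold(depths: np.ndarray, cfg: CoverageCallConfig) -> np.ndarray:
    """Per-window fold over the median of the nearest flanking windows."""
    n = len(depths)
    k = cfg.local_flank_windows
    out = np.empty(n)
    for i in range(n):
        left = depths[max(0, i - k) : i]
        right = depths[i + 1 : i + 1 + k]
        flank = np.concatenate([left, right])
        base = float(np.median(flank)) if flank.size else 0.0
        if base <= 0:
            base = cfg.baseline_epsilon
        out[i] = depths[i] / base
    return out


def fold_values(track: CoverageTrack, cfg: CoverageCallConfig | None = None) -> np.ndarray:
    """Per-window fold enrichment over the caller's final baseline."""
    cfg = cfg or CoverageCallConfig()
    if cfg.baseline == "local-flank":
        return _local_fold(track.depths, cfg)
    baseline = _final_baseline(track.depths, cfg)
    if baseline is None:
        return np.zeros_like(track.depths)
    return track.depths / baseline
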