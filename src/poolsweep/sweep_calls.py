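"""Sweep calling: fold-reduction classification and interval merging.

A window is flagged when the chromosome-mean diversity divided by the window
diversity reaches a cutoff: >= 100-fold is a "major" sweep window, >= 90- but
< 100-fold a "minor" one.  Flagged windows are labelled by their start on the
step grid and runs of abutting labels are merged into reported intervals,
numbered in genome order within each tier.  A window of exactly zero
diversity is the strongest possible signal and passes any cutoff (infinite
fold reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DataError
from .window_scan import WindowStat, chrom_mean

MAJOR_FOLD = 100.0
MINOR_FOLD = 90.0

TIER_MAJOR = "major"
TIER_MINOR = "minor"


@dataclass
class FlaggedWindow:
    """A flagged window's reported span on the step grid, with its pi."""

    chrom: str
    start: int
    end: int
    tier: str
    pi: float | None = None


@dataclass
class SweepInterval:
    """A merged run of flagged windows reported as one sweep interval."""

    id: int
    chrom: str
    start: int
    end: int
    tier: str
    member_windows: list[tuple[int, float | None]]


def fold_reduction(window_pi: float, chrom_mean_pi: float) -> float:
    """Chromosome-mean pi over window pi; +inf when the window pi is zero."""
    if window_pi < 0 or chrom_mean_pi <= 0:
        raise ValueError("fold_reduction needs window_pi >= 0 and chrom_mean_pi > 0")
    if window_pi == 0:
        return math.inf
    return chrom_mean_pi / window_pi


def classify_windows(
    stats: Sequence[WindowStat],
    major_cut: float = MAJOR_FOLD,
    minor_cut: float = MINOR_FOLD,
    mean_pi: float | None = None,
) -> list[tuple[WindowStat, str | None]]:
    """Assign each pi window of one chromosome a sweep tier (or None).

    The chromosome mean is computed from the defined windows unless passed
    explicitly.  "na" windows are never flagged.
    """
    stats = list(stats)
    if mean_pi is None:
        mean_pi = chrom_mean(stats)
    if mean_pi is None or mean_pi <= 0:
        raise DataError("chromosome mean pi undefined; cannot classify windows")
    out: list[tuple[WindowStat, str | None]] = []
    for w in stats:
        if w.value is None:
            out.append((w, None))
            continue
        fold = fold_reduction(w.value, mean_pi)
        if fold >= major_cut:
            out.append((w, TIER_MAJOR))
        elif fold >= minor_cut:
            out.append((w, TIER_MINOR))
        else:
            out.append((w, None))
    return out


def flag_windows(
    classified: Iterable[tuple[WindowStat, str | None]], step: int
) -> list[FlaggedWindow]:
    """Report each flagged window as its step-grid anchor span [start, start+step)."""
    return [
        FlaggedWindow(w.chrom, w.start, w.start + step, tier, w.value)
        for w, tier in classified
        if tier is not None
    ]


def merge_intervals(flagged: Iterable[FlaggedWindow]) -> list[SweepInterval]:
    """Merge abutting or overlapping same-tier windows into numbered intervals.

    Windows merge when they share a chromosome and tier and the next span
    starts at or before the previous end.  IDs run 1..k in (chrom, start)
    order within each tier; tiers never merge with each other.
    """
    out: list[SweepInterval] = []
    by_tier: dict[str, list[FlaggedWindow]] = {}
    for fw in flagged:
        if fw.end <= fw.start:
            raise ValueError(f"empty flagged span {fw.chrom}:{fw.start}-{fw.end}")
        by_tier.setdefault(fw.tier, []).append(fw)
    for tier in sorted(by_tier):
        windows = sorted(by_tier[tier], key=lambda f: (f.chrom, f.start, f.end))
        current: SweepInterval | None = None
        intervals: list[SweepInterval] = []
        for fw in windows:
            if (
                current is not None
                and fw.chrom == current.chrom
                and fw.start <= current.end
            ):
                current.end = max(current.end, fw.end)
                current.member_windows.append((fw.start, fw.pi))
            else:
                current = SweepInterval(0, fw.chrom, fw.start, fw.end, tier, [(fw.start, fw.pi)])
                intervals.append(current)
        for i, iv in enumerate(intervals, start=1):
            iv.id = i
        out.extend(intervals)
    return out


def call_sweeps(
    stats: Sequence[WindowStat],
    step: int,
    major_cut: float = MAJOR_FOLD,
    minor_cut: float = MINOR_FOLD,
    chrom_means: dict[str, float] | None = None,
) -> list[SweepInterval]:
    """End-to-end caller over pi windows of one or more chromosomes."""
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in stats:
        if w.metric != "pi":
            raise DataError("sweep calling runs on pi windows")
        by_chrom.setdefault(w.chrom, []).append(w)
    flagged: list[FlaggedWindow] = []
    for chrom in sorted(by_chrom):
        mean_pi = None if chrom_means is None else chrom_means.get(chrom)
        classified = classify_windows(by_chrom[chrom], major_cut, minor_cut, mean_pi)
        flagged.extend(flag_windows(classified, step))
    return merge_intervals(flagged)
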