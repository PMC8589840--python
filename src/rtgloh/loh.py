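"""LOH segmentation, classification, coordinates and clone summaries.

Stretches of consecutive markers with the same homozygous genotype are
grouped into LOH segments. Two coordinate systems are attached to every
segment:

* ``first``/``last`` — the positions of the first and last markers of the
  event itself;
* ``start``/``end`` — the midpoints between those markers and the nearest
  informative marker outside the segment, clamped to the terminal marker at
  a chromosome end where no flanking marker exists.

A segment is *terminal* when it reaches the last non-masked informative
marker of a chromosome arm (the telomere-proximal extent of the callable
region), *interstitial* when heterozygous markers flank it on both sides.
MISSING calls are transparent: they neither break nor support a run, and a
run consisting only of MISSING markers is no event. Masked (subtelomeric)
markers are excluded from calling and from terminal-extent determination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats as st

from .markers import (
    HET,
    HOM_P1,
    HOM_P2,
    MISSING,
    GenomeLayout,
    GenotypeTrack,
    MarkerMap,
    ValidationError,
)

__all__ = [
    "LOHSegment",
    "LOHSummary",
    "BreakpointRegion",
    "call_loh",
    "segment_coordinates",
    "summarize_clone",
    "breakpoint_regions",
    "inter_marker_distances",
    "reciprocity",
    "compare_clone_sets",
]


@dataclass(frozen=True)
class LOHSegment:
    chrom: str
    parent: int  # HOM_P1 | HOM_P2
    first: int  # bp position of the first marker of the event
    last: int
    start: int  # midpoint coordinates (see module docstring)
    end: int
    n_markers: int
    terminal: bool
    spans_centromere: bool = False
    whole_chromosome: bool = False

    @property
    def kind(self) -> str:
        return "terminal" if self.terminal else "interstitial"

    def __post_init__(self) -> None:
        if not (self.start <= self.first <= self.last <= self.end):
            raise ValidationError("segment coordinate ordering violated")
        if self.n_markers < 1:
            raise ValidationError("segment with no supporting marker")


@dataclass(frozen=True)
class LOHSummary:
    clone: str
    n_interstitial: int
    n_terminal: int
    frac_markers: float  # markers inside LOH / non-masked markers
    frac_p1: float
    frac_p2: float
    frac_genome: float  # bp in LOH (start/end extent) / genome length


@dataclass(frozen=True)
class BreakpointRegion:
    """Interval between the outermost homozygous marker of a segment and the
    nearest informative marker outside it, plus the marker window around the
    breakpoint (<= k heterozygous and <= k homozygous markers)."""

    chrom: str
    start: int
    end: int
    segment: LOHSegment
    side: str  # "left" | "right"
    het_positions: np.ndarray
    hom_positions: np.ndarray


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def call_loh(
    track: GenotypeTrack,
    marker_map: MarkerMap,
    layout: GenomeLayout,
    max_gap: int | None = None,
) -> list[LOHSegment]:
    """Segment a genotype track into LOH events.

    ``max_gap``: optional maximum bp distance between consecutive supporting
    markers of a run; a larger (e.g. MISSING-bridged) gap splits the run.
    Default unlimited.
    """
    track.check_against(marker_map)
    segments: list[LOHSegment] = []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        calls = track.calls[sl]
        keep = (~marker_map.masked(chrom)) & (calls != MISSING)
        if not keep.any():
            continue
        pos = marker_map.positions(chrom)[keep]
        g = calls[keep]
        cs, ce = layout.centromere(chrom) if chrom in layout.lengths else (0, 0)
        if chrom not in layout.lengths:
            raise ValidationError(f"chromosome {chrom!r} absent from layout")
        # boundaries where the informative call changes
        change = np.flatnonzero(np.r_[True, g[1:] != g[:-1], True])
        for a, b in zip(change[:-1], change[1:]):
            if g[a] == HET:
                continue
            # optional gap-splitting of a single homozygous run
            for lo, hi in _gap_split(pos, a, b, max_gap):
                segments.append(
                    _build_segment(chrom, int(g[a]), pos, lo, hi, cs, ce)
                )
    return segments


def _gap_split(pos: np.ndarray, a: int, b: int, max_gap: int | None):
    if max_gap is None:
        yield a, b
        return
    lo = a
    for i in range(a + 1, b):
        if pos[i] - pos[i - 1] > max_gap:
            yield lo, i
            lo = i
    yield lo, b


def _build_segment(
    chrom: str, parent: int, pos: np.ndarray, a: int, b: int, cs: int, ce: int
) -> LOHSegment:
    first, last = int(pos[a]), int(pos[b - 1])
    start = first if a == 0 else int((pos[a - 1] + first) // 2)
    end = last if b == pos.size else int((last + pos[b]) // 2)
    terminal = a == 0 or b == pos.size
    return LOHSegment(
        chrom=chrom,
        parent=parent,
        first=first,
        last=last,
        start=start,
        end=end,
        n_markers=int(b - a),
        terminal=terminal,
        spans_centromere=bool(first < cs and last > ce),
        whole_chromosome=bool(a == 0 and b == pos.size),
    )


def segment_coordinates(
    segment: LOHSegment, marker_map: MarkerMap
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Recompute ((first, last), (start, end)) of a segment from the map.

    start is the mean of the first segment marker and the nearest preceding
    marker outside the segment; end symmetric; both clamp to the terminal
    marker position where the segment reaches a chromosome end.
    """
    pos = marker_map.positions(segment.chrom)
    pos = pos[~marker_map.masked(segment.chrom)]
    before = pos[pos < segment.first]
    after = pos[pos > segment.last]
    start = int((before[-1] + segment.first) // 2) if before.size else segment.first
    end = int((segment.last + after[0]) // 2) if after.size else segment.last
    return (segment.first, segment.last), (start, end)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_clone(
    clone: str,
    segments: Sequence[LOHSegment],
    marker_map: MarkerMap,
    layout: GenomeLayout,
) -> LOHSummary:
    """Per-clone LOH summary: event counts by class and LOH fractions."""
    n_unmasked = marker_map.n_unmasked()
    n_markers = sum(s.n_markers for s in segments)
    n_p1 = sum(s.n_markers for s in segments if s.parent == HOM_P1)
    n_p2 = sum(s.n_markers for s in segments if s.parent == HOM_P2)
    bp = sum(s.end - s.start + 1 for s in segments)
    return LOHSummary(
        clone=clone,
        n_interstitial=sum(1 for s in segments if not s.terminal),
        n_terminal=sum(1 for s in segments if s.terminal),
        frac_markers=n_markers / n_unmasked if n_unmasked else 0.0,
        frac_p1=n_p1 / n_unmasked if n_unmasked else 0.0,
        frac_p2=n_p2 / n_unmasked if n_unmasked else 0.0,
        frac_genome=bp / layout.total_length(),
    )


def breakpoint_regions(
    segments: Sequence[LOHSegment],
    track: GenotypeTrack,
    marker_map: MarkerMap,
    k: int = 5,
) -> list[BreakpointRegion]:
    """Breakpoint regions of LOH segments.

    One region per segment side that has an informative flanking marker:
    two for an interstitial segment, one for a terminal segment (its distal
    side reaches the arm end). Each region spans from the outermost
    homozygous marker of the segment to the nearest flanking marker outside
    it and carries the <= k nearest heterozygous and <= k nearest homozygous
    marker positions around the breakpoint.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    track.check_against(marker_map)
    regions: list[BreakpointRegion] = []
    for seg in segments:
        sl = marker_map.chrom_slice(seg.chrom)
        calls = track.calls[sl]
        keep = (~marker_map.masked(seg.chrom)) & (calls != MISSING)
        pos = marker_map.positions(seg.chrom)[keep]
        g = calls[keep]
        a = int(np.searchsorted(pos, seg.first))
        b = int(np.searchsorted(pos, seg.last, side="right"))
        hom_pos = pos[a:b]
        for side, exists in (("left", a > 0), ("right", b < pos.size)):
            if not exists:
                continue
            if side == "left":
                flank = int(pos[a - 1])
                het = pos[max(0, a - k) : a]
                hom = hom_pos[:k]
                start, end = flank, seg.first
            else:
                flank = int(pos[b])
                het = pos[b : b + k]
                hom = hom_pos[-k:]
                start, end = seg.last, flank
            regions.append(
                BreakpointRegion(
                    chrom=seg.chrom,
                    start=start,
                    end=end,
                    segment=seg,
                    side=side,
                    het_positions=np.asarray(het, dtype=np.int64),
                    hom_positions=np.asarray(hom, dtype=np.int64),
                )
            )
    return regions


def inter_marker_distances(
    obj: MarkerMap | Iterable[BreakpointRegion],
) -> np.ndarray:
    """Distances between consecutive markers (bp).

    For a :class:`MarkerMap`: genome-wide per-chromosome consecutive
    differences over non-masked markers. For breakpoint regions: the
    consecutive differences within each region's marker window.
    """
    if isinstance(obj, MarkerMap):
        out = []
        for chrom in obj.chromosomes:
            pos = obj.positions(chrom)[~obj.masked(chrom)]
            if pos.size >= 2:
                out.append(np.diff(pos))
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)
    out = []
    for region in obj:
        window = np.sort(
            np.concatenate([region.het_positions, region.hom_positions])
        )
        if window.size >= 2:
            out.append(np.diff(window))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def reciprocity(
    mother: GenotypeTrack, daughter: GenotypeTrack, marker_map: MarkerMap
) -> int:
    """Count non-reciprocal markers between an RTG mother/daughter pair.

    A marker is reciprocal when the combined parental allele dosage over the
    pair is 2 P1 + 2 P2 (HET contributes 1+1, a homozygous call 2+0).
    Markers with a MISSING call in either cell, and masked markers, are not
    evaluated.
    """
    mother.check_against(marker_map)
    daughter.check_against(marker_map)
    usable = (
        (mother.calls != MISSING)
        & (daughter.calls != MISSING)
        & (~marker_map.table["masked"].to_numpy())
    )
    p1 = _p1_dosage(mother.calls) + _p1_dosage(daughter.calls)
    return int((p1[usable] != 2).sum())


def _p1_dosage(calls: np.ndarray) -> np.ndarray:
    d = np.ones(calls.shape, dtype=np.int8)  # HET -> 1
    d[calls == HOM_P1] = 2
    d[calls == HOM_P2] = 0
    return d


def compare_clone_sets(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "ranksum",
    alternative: str = "greater",
) -> tuple[float, float]:
    """Compare a summary metric between two clone sets.

    ``test='ranksum'``: Wilcoxon rank-sum (Mann-Whitney U with continuity
    correction), one- or two-tailed. ``test='fligner'``: Fligner-Killeen
    variance-homogeneity test (two-tailed). Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 clones per set")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("degenerate comparison: all values tied; p = 1")
        return float("nan"), 1.0
    if test == "ranksum":
        res = st.mannwhitneyu(
            a, b, alternative=alternative, use_continuity=True, method="asymptotic"
        )
    elif test == "fligner":
        res = st.fligner(a, b)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
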