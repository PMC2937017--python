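"""Pre-analysis filters for segmented profiles.

Three stages: derivation of common copy-number-polymorphism (CNP) intervals
from a normal cohort and their exclusion, absorption of unreliably small
segments into the nearest-valued neighbour, and thresholded per-segment
aberration calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genome_io import CopyNumberProfile, Region, Segment


@dataclass(frozen=True)
class CallThresholds:
    """Universal log2 calling thresholds.

    Gains/losses are called past +/-0.3 with strict inequalities; higher
    amplitude gain tiers at 0.6/0.8/1.0 and homozygous deletion below -1.
    """

    gain: float = 0.3
    loss: float = -0.3
    high_tiers: tuple[float, ...] = (0.6, 0.8, 1.0)
    hd: float = -1.0
    min_probes: dict = field(default_factory=lambda: {"snp6": 10, "500k": 5})

    def __post_init__(self):
        if not (self.gain < min(self.high_tiers)):
            raise ValueError("gain threshold must lie below the high tiers")
        if list(self.high_tiers) != sorted(self.high_tiers):
            raise ValueError("high tiers must be increasing")
        if not (self.hd < self.loss):
            raise ValueError("hd threshold must lie below the loss threshold")


@dataclass(frozen=True)
class SegmentCall:
    state: str  # neutral | gain | loss
    gain_06: bool
    gain_08: bool
    gain_10: bool
    hd: bool


@dataclass
class CnpIntervalSet:
    """Per-chromosome non-overlapping CNP intervals (merged on construction)."""

    intervals: list[Region]
    source: str = ""

    def __post_init__(self):
        merged: list[Region] = []
        for r in sorted(self.intervals, key=lambda r: (r.chrom, r.start)):
            if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
                prev = merged.pop()
                merged.append(replace(prev, end=max(prev.end, r.end)))
            else:
                merged.append(replace(r, provenance="cnp"))
        self.intervals = merged

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            r.chrom == chrom and r.start < end and start < r.end
            for r in self.intervals
        )

    def by_chrom(self, chrom: str) -> list[Region]:
        return [r for r in self.intervals if r.chrom == chrom]


def derive_cnp_intervals(
    normals: Sequence[CopyNumberProfile],
    freq_threshold: float = 0.05,
    call_threshold: float = 0.3,
) -> CnpIntervalSet:
    """Intervals aberrant (|log2| > call_threshold) in > freq_threshold of normals.

    Works on the breakpoint-union partition of the normal cohort; the fraction
    comparison is strict, per the exclusion rule this implements.
    """
    if not normals:
        raise ValueError("cannot derive CNPs without normals")
    n = len(normals)
    chroms: dict[str, None] = {}
    for p in normals:
        for c in p.chromosomes():
            chroms.setdefault(c, None)
    out: list[Region] = []
    for chrom in chroms:
        points: set[int] = set()
        events: list[tuple[int, int]] = []
        for p in normals:
            for seg in p.by_chrom(chrom):
                points.update((seg.start, seg.end))
                if abs(seg.log2) > call_threshold:
                    events.append((seg.start, seg.end))
        if not events:
            continue
        pts = np.array(sorted(points))
        starts, ends = pts[:-1], pts[1:]
        counts = np.zeros(len(starts), dtype=int)
        for ev_start, ev_end in events:
            i = np.searchsorted(pts, ev_start)
            j = np.searchsorted(pts, ev_end)
            counts[i:j] += 1
        keep = counts / n > freq_threshold
        i = 0
        while i < len(keep):
            if not keep[i]:
                i += 1
                continue
            j = i
            # merge adjacent qualifying, contiguous intervals
            while j + 1 < len(keep) and keep[j + 1] and ends[j] == starts[j + 1]:
                j += 1
            out.append(
                Region(
                    chrom=chrom,
                    start=int(starts[i]),
                    end=int(ends[j]),
                    aber_type="gain",  # placeholder type; CNPs are untyped masks
                    label=f"cnp_{chrom}_{int(starts[i])}",
                    provenance="cnp",
                )
            )
            i = j + 1
    return CnpIntervalSet(out, source=f"{n} normals")


def mask_cnp_regions(
    regions: Iterable[Region], cnp_set: CnpIntervalSet
) -> list[Region]:
    """Drop regions overlapping a CNP interval by >= 1 bp."""
    return [
        r for r in regions if not cnp_set.overlaps(r.chrom, r.start, r.end)
    ]


def mask_cnp_profile(
    profile: CopyNumberProfile, cnp_set: CnpIntervalSet
) -> CopyNumberProfile:
    """Intersect segments with the complement of CNP intervals.

    Segments are split where a CNP lies inside them; probe counts are prorated
    by retained length and floored at 1.
    """
    if not len(cnp_set):
        return profile
    new_segments: list[Segment] = []
    for seg in profile.segments:
        cnps = [
            (r.start, r.end)
            for r in cnp_set.by_chrom(seg.chrom)
            if r.start < seg.end and seg.start < r.end
        ]
        if not cnps:
            new_segments.append(seg)
            continue
        pieces: list[tuple[int, int]] = []
        pos = seg.start
        for c_start, c_end in sorted(cnps):
            if c_start > pos:
                pieces.append((pos, c_start))
            pos = max(pos, c_end)
        if pos < seg.end:
            pieces.append((pos, seg.end))
        for p_start, p_end in pieces:
            frac = (p_end - p_start) / seg.length
            new_segments.append(
                replace(
                    seg,
                    start=p_start,
                    end=p_end,
                    n_probes=max(1, round(seg.n_probes * frac)),
                )
            )
    return CopyNumberProfile(profile.sample_id, new_segments)


def mask_cnp(obj, cnp_set: CnpIntervalSet):
    """Dispatch CNP masking for a profile or a region list."""
    if isinstance(obj, CopyNumberProfile):
        return mask_cnp_profile(obj, cnp_set)
    return mask_cnp_regions(obj, cnp_set)


def merge_small_segments(
    profile: CopyNumberProfile, min_probes: int
) -> CopyNumberProfile:
    """Absorb segments with fewer than ``min_probes`` probes into the adjacent
    same-chromosome segment of closest log2.

    The absorbing neighbour keeps its own log2, extends its coordinates over
    the absorbed interval and gains its probe count.  Iteration is
    smallest-probe-count first (ties to the leftmost segment) so the result is
    order-independent; a neighbour tie absorbs leftward.  A chromosome reduced
    to a single segment is left as is.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in profile.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    merged: list[Segment] = []
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        while len(segs) > 1:
            small = [
                (s.n_probes, i) for i, s in enumerate(segs) if s.n_probes < min_probes
            ]
            if not small:
                break
            _, i = min(small)
            target = segs[i]
            candidates = []
            if i > 0:
                candidates.append((abs(segs[i - 1].log2 - target.log2), 0, i - 1))
            if i + 1 < len(segs):
                candidates.append((abs(segs[i + 1].log2 - target.log2), 1, i + 1))
            _, _, j = min(candidates)  # tie -> leftward (secondary key 0 < 1)
            absorber = segs[j]
            segs[j] = replace(
                absorber,
                start=min(absorber.start, target.start),
                end=max(absorber.end, target.end),
                n_probes=absorber.n_probes + target.n_probes,
            )
            del segs[i]
        merged.extend(segs)
    return CopyNumberProfile(profile.sample_id, merged)


def call_segment(log2: float, thresholds: CallThresholds) -> SegmentCall:
    t06, t08, t10 = thresholds.high_tiers
    if log2 > thresholds.gain:
        state = "gain"
    elif log2 < thresholds.loss:
        state = "loss"
    else:
        state = "neutral"
    return SegmentCall(
        state=state,
        gain_06=log2 > t06,
        gain_08=log2 > t08,
        gain_10=log2 > t10,
        hd=log2 < thresholds.hd,
    )


def call_states(
    profile: CopyNumberProfile, thresholds: CallThresholds | None = None
) -> list[SegmentCall]:
    """Per-segment neutral/gain/loss labels with amplitude-tier flags.

    Strict inequalities throughout: a segment at exactly +0.3 is neutral.
    """
    thresholds = thresholds or CallThresholds()
    return [call_segment(seg.log2, thresholds) for seg in profile.segments]
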