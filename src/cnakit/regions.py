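"""Frequency tracks on the breakpoint-union partition, tiered region calling,
the binary sample-by-region aberration matrix, and the pre-association
region-pair filters."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import CopyNumberProfile, Region
from .preprocess import CallThresholds, CnpIntervalSet


@dataclass
class ChromTrack:
    starts: np.ndarray  # partition interval starts
    ends: np.ndarray
    counts: np.ndarray  # samples aberrant past the threshold on each interval

    def fractions(self, n_samples: int) -> np.ndarray:
        return self.counts / n_samples


@dataclass
class FrequencyTrack:
    """Per-interval aberrant-sample counts on the union of all breakpoints."""

    direction: str  # gain | loss
    amplitude: float
    n_samples: int
    chroms: dict[str, ChromTrack]

    def to_bedgraph(self, path, comments: Sequence[str] = ()) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for comment in comments:
                fh.write(f"# {comment}\n")
            for chrom, track in self.chroms.items():
                for s, e, c in zip(track.starts, track.ends, track.counts):
                    fh.write(f"{chrom}\t{s}\t{e}\t{c / self.n_samples:.6g}\n")


@dataclass(frozen=True)
class TierRule:
    """One amplitude tier: a log2 threshold plus a frequency and/or count bar.

    When both a fraction and a count are given they combine with OR semantics
    (used for homozygous deletions, which have an absolute-count bar).
    """

    direction: str
    amplitude: float
    min_fraction: float | None = None
    min_count: int | None = None

    def __post_init__(self):
        if self.min_fraction is None and self.min_count is None:
            raise ValueError("tier rule needs min_fraction and/or min_count")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be gain or loss")

    def required_count(self, n_samples: int) -> int:
        candidates = []
        if self.min_fraction is not None:
            # a sample count must be integral; "at least" semantics -> ceiling
            candidates.append(math.ceil(self.min_fraction * n_samples))
        if self.min_count is not None:
            candidates.append(self.min_count)
        return min(candidates)


def default_tier_rules() -> list[TierRule]:
    """Default tiers: gains >0.3 at 30%, >0.6 at 10%, >0.8 at 5%, >1 at 2.5%;
    losses <-0.3 at 30%; homozygous deletions <-1 in at least 4 samples."""
    return [
        TierRule("gain", 0.3, min_fraction=0.30),
        TierRule("gain", 0.6, min_fraction=0.10),
        TierRule("gain", 0.8, min_fraction=0.05),
        TierRule("gain", 1.0, min_fraction=0.025),
        TierRule("loss", -0.3, min_fraction=0.30),
        TierRule("loss", -1.0, min_count=4),
    ]


def frequency_track(
    profiles: Sequence[CopyNumberProfile], direction: str, amplitude: float
) -> FrequencyTrack:
    """Count, on each breakpoint-union interval, the samples whose covering
    segment passes the strict amplitude threshold."""
    if not profiles:
        raise ValueError("cannot build a frequency track from an empty cohort")
    if direction == "gain" and amplitude <= 0:
        raise ValueError("gain track needs a positive amplitude")
    if direction == "loss" and amplitude >= 0:
        raise ValueError("loss track needs a negative amplitude")
    chroms: dict[str, None] = {}
    for p in profiles:
        for c in p.chromosomes():
            chroms.setdefault(c, None)
    out: dict[str, ChromTrack] = {}
    for chrom in chroms:
        points: set[int] = set()
        events: list[tuple[int, int]] = []
        for p in profiles:
            for seg in p.by_chrom(chrom):
                points.update((seg.start, seg.end))
                passes = (
                    seg.log2 > amplitude
                    if direction == "gain"
                    else seg.log2 < amplitude
                )
                if passes:
                    events.append((seg.start, seg.end))
        pts = np.array(sorted(points))
        starts, ends = pts[:-1], pts[1:]
        counts = np.zeros(len(starts), dtype=int)
        for ev_start, ev_end in events:
            i = np.searchsorted(pts, ev_start)
            j = np.searchsorted(pts, ev_end)
            counts[i:j] += 1
        out[chrom] = ChromTrack(starts=starts, ends=ends, counts=counts)
    return FrequencyTrack(
        direction=direction,
        amplitude=amplitude,
        n_samples=len(profiles),
        chroms=out,
    )


def tier_regions(
    tracks: Sequence[FrequencyTrack],
    rules: Sequence[TierRule],
    n_samples: int | None = None,
) -> list[Region]:
    """Maximal qualifying intervals per tier rule, as typed Regions.

    Each Region carries the tier amplitude and a peak-summit annotation
    (the argmax interval of the run).
    """
    by_key = {(t.direction, t.amplitude): t for t in tracks}
    regions: list[Region] = []
    for rule in rules:
        key = (rule.direction, rule.amplitude)
        if key not in by_key:
            raise ValueError(f"no frequency track for tier rule {key}")
        track = by_key[key]
        n = n_samples if n_samples is not None else track.n_samples
        need = rule.required_count(n)
        for chrom, ct in track.chroms.items():
            keep = ct.counts >= need
            i = 0
            while i < len(keep):
                if not keep[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < len(keep) and keep[j + 1] and ct.ends[j] == ct.starts[j + 1]:
                    j += 1
                summit = i + int(np.argmax(ct.counts[i : j + 1]))
                sign = "+" if rule.direction == "gain" else ""
                regions.append(
                    Region(
                        chrom=chrom,
                        start=int(ct.starts[i]),
                        end=int(ct.ends[j]),
                        aber_type=rule.direction,
                        label=(
                            f"{chrom}:{int(ct.starts[i])}-{int(ct.ends[j])}"
                            f":{rule.direction}{sign}{rule.amplitude:g}"
                        ),
                        provenance="tier",
                        amplitude=rule.amplitude,
                        peak=(int(ct.starts[summit]), int(ct.ends[summit])),
                    )
                )
                i = j + 1
    return regions


@dataclass
class AberrationMatrix:
    """Binary samples-by-regions matrix X."""

    sample_ids: list[str]
    regions: list[Region]
    X: np.ndarray  # shape (n_samples, n_regions), dtype int8

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.shape != (len(self.sample_ids), len(self.regions)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("aberration matrix must be binary")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels")

    @property
    def region_labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X, index=self.sample_ids, columns=self.region_labels
        )

    def to_tsv(self, path, comments: Sequence[str] = ()) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for comment in comments:
                fh.write(f"# {comment}\n")
            self.to_frame().rename_axis("sample_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path, regions: Sequence[Region] | None = None):
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        if regions is None:
            # synthesize placeholder region objects from column labels
            regions = [
                Region("chr0", i * 2 + 1, i * 2 + 2, "gain", label, "external_peak")
                for i, label in enumerate(df.columns)
            ]
        else:
            if [r.label for r in regions] != list(df.columns):
                raise ValueError("region labels do not match matrix columns")
        return cls(
            sample_ids=[str(s) for s in df.index],
            regions=list(regions),
            X=df.to_numpy(),
        )


def build_matrix(
    profiles: Sequence[CopyNumberProfile],
    regions: Sequence[Region],
    thresholds: CallThresholds | None = None,
    use_tier_amplitude: bool = False,
) -> AberrationMatrix:
    """X[t,i] = 1 iff sample t has a segment overlapping region i by >= 1 bp
    whose state matches the region's type at the base +/-0.3 threshold.

    Gain regions score gains only and loss regions losses only.  With
    ``use_tier_amplitude`` a region's own tier amplitude replaces the base
    threshold (sensitivity analysis).
    """
    if not regions:
        raise ValueError("no regions to score")
    thresholds = thresholds or CallThresholds()
    X = np.zeros((len(profiles), len(regions)), dtype=np.int8)
    for t, profile in enumerate(profiles):
        for i, region in enumerate(regions):
            if region.aber_type == "gain":
                cut = (
                    region.amplitude
                    if use_tier_amplitude and region.amplitude is not None
                    else thresholds.gain
                )
            else:
                cut = (
                    region.amplitude
                    if use_tier_amplitude and region.amplitude is not None
                    else thresholds.loss
                )
            for seg in profile.by_chrom(region.chrom):
                if seg.start >= region.end:
                    break
                if seg.end <= region.start:
                    continue
                passes = (
                    seg.log2 > cut if region.aber_type == "gain" else seg.log2 < cut
                )
                if passes:
                    X[t, i] = 1
                    break
    return AberrationMatrix(
        sample_ids=[p.sample_id for p in profiles],
        regions=list(regions),
        X=X,
    )


def filter_region_pairs(
    regions: Sequence[Region],
    broad_regions: Sequence[Region] = (),
    cnp_set: CnpIntervalSet | None = None,
) -> list[tuple[int, int]]:
    """All unordered region-index pairs except those invalidated before testing:
    both regions inside the same broad region (physical linkage), or either
    region overlapping a CNP interval by >= 1 bp."""
    cnp_flag = [
        cnp_set.overlaps(r.chrom, r.start, r.end) if cnp_set is not None else False
        for r in regions
    ]
    broad_of = []
    for r in regions:
        containing = {
            b_idx
            for b_idx, b in enumerate(broad_regions)
            if b.chrom == r.chrom and b.start <= r.start and r.end <= b.end
        }
        broad_of.append(containing)
    pairs: list[tuple[int, int]] = []
    for i in range(len(regions)):
        if cnp_flag[i]:
            continue
        for j in range(i + 1, len(regions)):
            if cnp_flag[j]:
                continue
            if broad_of[i] & broad_of[j]:
                continue
            pairs.append((i, j))
    return pairs
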