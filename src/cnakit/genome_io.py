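"""Genomic coordinate model and readers/writers for the tab-delimited formats
used throughout the pipeline.

All coordinates are held internally as 0-based half-open intervals.  SEG files
in the wild are usually 1-based inclusive, so the SEG reader/writer take an
explicit ``dialect`` argument rather than guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SEG_DIALECTS = ("one_based_inclusive", "zero_based_half_open")
ABER_TYPES = ("gain", "loss")
PROVENANCES = ("tier", "external_peak", "broad", "cnp")

SEG_HEADER = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]

_COLUMN_SYNONYMS = {
    "sample": "sample", "sample_id": "sample", "id": "sample",
    "chromosome": "chrom", "chrom": "chrom", "chr": "chrom",
    "start": "start", "loc.start": "start", "start_position": "start",
    "end": "end", "loc.end": "end", "end_position": "end",
    "num_probes": "n_probes", "num.mark": "n_probes", "probes": "n_probes",
    "num_markers": "n_probes",
    "segment_mean": "log2", "seg.mean": "log2", "log2": "log2", "mean": "log2",
}


def normalize_chrom(name: str, aliases: dict[str, str] | None = None) -> str:
    """Canonical chromosome naming: "chr"-prefixed, e.g. "1" -> "chr1"."""
    name = name.strip()
    if aliases and name in aliases:
        name = aliases[name]
    if not name.lower().startswith("chr"):
        name = "chr" + name
    return "chr" + name[3:]


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names with lengths in base pairs."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"no length for chromosome {name}")
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name}")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeBuild":
        return cls(names=tuple(lengths), lengths=dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number interval of one sample (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    log2: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberProfile:
    """Sorted, per-chromosome non-overlapping segments of one sample."""

    sample_id: str
    segments: list[Segment]

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        self.validate()

    def validate(self) -> None:
        prev = None
        for seg in self.segments:
            if seg.sample_id != self.sample_id:
                raise ValueError(
                    f"segment sample {seg.sample_id!r} != profile {self.sample_id!r}"
                )
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"overlapping segments in {self.sample_id} on {seg.chrom}: "
                    f"[{prev.start},{prev.end}) and [{seg.start},{seg.end})"
                )
            prev = seg

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chrom, None)
        return list(seen)

    def by_chrom(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]


@dataclass(frozen=True)
class Region:
    """A typed genomic interval used as an aberration locus."""

    chrom: str
    start: int
    end: int
    aber_type: str
    label: str
    provenance: str = "external_peak"
    amplitude: float | None = None  # tier amplitude that defined the region
    peak: tuple[int, int] | None = None  # frequency-summit interval, if known

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.label}: start >= end")
        if self.aber_type not in ABER_TYPES:
            raise ValueError(
                f"region {self.label}: aber_type {self.aber_type!r} "
                f"not in {ABER_TYPES}"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"region {self.label}: unknown provenance")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region | Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_MISSING = (None, "", "na", "nan", "none", "null", ".")


@dataclass
class SampleAnnotation:
    sample_id: str
    cohort: str | None = None
    subtype: str | None = None
    grade: str | None = None
    stage: str | None = None
    os_time: float | None = None
    os_event: int | None = None
    pfs_time: float | None = None
    pfs_event: int | None = None

    def __post_init__(self):
        for name in ("os_time", "pfs_time"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: negative {name}")
        for name in ("os_event", "pfs_event"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{self.sample_id}: {name} must be 0/1, got {v!r}")


# ---------------------------------------------------------------------------
# coordinate conversion

def to_one_based_inclusive(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


def from_one_based_inclusive(start: int, end: int) -> tuple[int, int]:
    return start - 1, end


# ---------------------------------------------------------------------------
# SEG

def _resolve_columns(header: Sequence[str]) -> dict[str, int]:
    cols: dict[str, int] = {}
    for i, raw in enumerate(header):
        key = _COLUMN_SYNONYMS.get(raw.strip().lower())
        if key is not None and key not in cols:
            cols[key] = i
    for required in ("sample", "chrom", "start", "end", "log2"):
        if required not in cols:
            raise ValueError(f"SEG header is missing a {required!r} column: {header}")
    return cols


def read_seg(
    path,
    dialect: str = "one_based_inclusive",
    build: GenomeBuild | None = None,
    chrom_aliases: dict[str, str] | None = None,
) -> list[CopyNumberProfile]:
    """Read a tab-delimited SEG file into per-sample profiles.

    Coordinates are converted to the internal 0-based half-open convention.
    A missing probe-count column defaults to 1 (with a warning), so externally
    segmented files without marker counts remain usable.
    """
    if dialect not in SEG_DIALECTS:
        raise ValueError(f"unknown SEG dialect {dialect!r}; use one of {SEG_DIALECTS}")
    by_sample: dict[str, list[Segment]] = {}
    with open(path, encoding="utf-8") as fh:
        header = None
        warned_probes = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = _resolve_columns(fields)
                continue
            try:
                sample = fields[header["sample"]].strip()
                chrom = normalize_chrom(fields[header["chrom"]], chrom_aliases)
                start = int(fields[header["start"]])
                end = int(fields[header["end"]])
                log2 = float(fields[header["log2"]])
                if "n_probes" in header:
                    n_probes = int(fields[header["n_probes"]])
                else:
                    if not warned_probes:
                        logger.warning(
                            "%s: no probe-count column; defaulting to 1", path
                        )
                        warned_probes = True
                    n_probes = 1
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed SEG row at line {lineno}: {exc}")
            if dialect == "one_based_inclusive":
                start, end = from_one_based_inclusive(start, end)
            if build is not None and chrom not in build:
                raise ValueError(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                )
            try:
                seg = Segment(sample, chrom, start, end, n_probes, log2)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}")
            by_sample.setdefault(sample, []).append(seg)
        if header is None:
            raise ValueError(f"{path}: empty SEG file (no header)")
    return [CopyNumberProfile(sample, segs) for sample, segs in by_sample.items()]


def write_seg(
    profiles: Iterable[CopyNumberProfile],
    path,
    dialect: str = "one_based_inclusive",
    comments: Sequence[str] = (),
) -> None:
    if dialect not in SEG_DIALECTS:
        raise ValueError(f"unknown SEG dialect {dialect!r}; use one of {SEG_DIALECTS}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(SEG_HEADER) + "\n")
        for profile in profiles:
            for seg in profile.segments:
                start, end = seg.start, seg.end
                if dialect == "one_based_inclusive":
                    start, end = to_one_based_inclusive(start, end)
                fh.write(
                    f"{seg.sample_id}\t{seg.chrom}\t{start}\t{end}"
                    f"\t{seg.n_probes}\t{seg.log2:.8g}\n"
                )


# ---------------------------------------------------------------------------
# regions (BED6-like: chrom, start, end, label, aber_type, provenance[, amplitude])

def read_regions(path, build: GenomeBuild | None = None) -> list[Region]:
    regions: list[Region] = []
    seen_labels: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 columns")
            chrom = normalize_chrom(fields[0])
            if build is not None and chrom not in build:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            label = fields[3]
            # duplicated labels are disambiguated deterministically by suffix
            n = seen_labels.get(label, 0)
            seen_labels[label] = n + 1
            if n:
                label = f"{label}_{n + 1}"
            amplitude = float(fields[6]) if len(fields) > 6 and fields[6] else None
            try:
                regions.append(
                    Region(
                        chrom=chrom,
                        start=int(fields[1]),
                        end=int(fields[2]),
                        label=label,
                        aber_type=fields[4].strip().lower(),
                        provenance=fields[5].strip().lower(),
                        amplitude=amplitude,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}")
    return regions


def write_regions(
    regions: Iterable[Region], path, comments: Sequence[str] = ()
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        for r in regions:
            amp = "" if r.amplitude is None else f"\t{r.amplitude:.8g}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}"
                f"\t{r.aber_type}\t{r.provenance}{amp}\n"
            )


# ---------------------------------------------------------------------------
# sample annotations

_ANNOT_FIELDS = (
    "sample_id", "cohort", "subtype", "grade", "stage",
    "os_time", "os_event", "pfs_time", "pfs_event",
)


def _parse_cell(raw: str | None, kind: str):
    if raw is None or raw.strip().lower() in _MISSING:
        return None
    raw = raw.strip()
    if kind == "float":
        return float(raw)
    if kind == "event":
        value = int(raw)
        return value
    return raw


def read_annotations(path) -> list[SampleAnnotation]:
    records: list[SampleAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if "sample_id" not in header:
                    raise ValueError(f"{path}: header must include sample_id")
                continue
            row = dict(zip(header, fields))
            try:
                rec = SampleAnnotation(
                    sample_id=row["sample_id"].strip(),
                    cohort=_parse_cell(row.get("cohort"), "str"),
                    subtype=_parse_cell(row.get("subtype"), "str"),
                    grade=_parse_cell(row.get("grade"), "str"),
                    stage=_parse_cell(row.get("stage"), "str"),
                    os_time=_parse_cell(row.get("os_time"), "float"),
                    os_event=_parse_cell(row.get("os_event"), "event"),
                    pfs_time=_parse_cell(row.get("pfs_time"), "float"),
                    pfs_event=_parse_cell(row.get("pfs_event"), "event"),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}")
            if rec.sample_id in seen:
                raise ValueError(f"{path}: duplicated sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            records.append(rec)
    return records


def write_annotations(records: Iterable[SampleAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_ANNOT_FIELDS) + "\n")
        for rec in records:
            cells = []
            for name in _ANNOT_FIELDS:
                v = getattr(rec, name)
                if v is None:
                    cells.append("NA")
                elif isinstance(v, float):
                    cells.append(f"{v:.8g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
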