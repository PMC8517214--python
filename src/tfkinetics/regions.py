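"""Genomic interval primitives, BED I/O, merging, consensus ROIs, and read counting.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; any 1-based format must be converted at the boundary.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def feature_id(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class StrandedRead:
    """A sequencing read interval; strand must be '+' or '-'."""

    interval: GenomicInterval
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("read strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """5' end position (last covered base for minus-strand reads)."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class ROI:
    """A region of interest with a designated center (origin or summit)."""

    interval: GenomicInterval
    center: int
    support: int = 1

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.center < self.interval.end):
            raise ValueError(
                f"center {self.center} outside [{self.interval.start}, {self.interval.end})"
            )
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def roi_id(self) -> str:
        return self.interval.feature_id


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str = ""
    replicate: int = 1


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer counts."""

    features: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def columns_for(self, sample_ids: Sequence[str]) -> list[int]:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return [index[s] for s in sample_ids]

    def samples_for_condition(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = None
    score = None
    strand = "."
    if len(fields) >= 4 and fields[3] != ".":
        name = fields[3]
    if len(fields) >= 5 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-numeric score") from exc
    if len(fields) >= 6:
        strand = fields[5]
    try:
        return GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6 intervals in file order.

    Lines starting with '#', 'track' or 'browser' and blank lines are skipped.
    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_bed_line(line, lineno))
    return intervals


def _format_score(score: float) -> str:
    text = f"{score:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (no annotation) or BED6 lines.

    Round-trips through :func:`read_bed` field-for-field, provided names are
    not the literal "." and scores carry at most six decimals.
    """
    with open(path, "w") as handle:
        for iv in intervals:
            if iv.name is None and iv.score is None and iv.strand == ".":
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = _format_score(iv.score) if iv.score is not None else "."
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_bed_reads(path: str | Path, sample_id: str = "") -> list[StrandedRead]:
    """Read a BED6 file of stranded reads."""
    return [StrandedRead(iv, sample_id=sample_id) for iv in read_bed(path)]


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union intervals on the same chromosome separated by <= gap bases.

    Strand is ignored; annotation fields are dropped. Output is sorted by
    (chrom, start). Idempotent and input-order invariant.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ordered[0].chrom, ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def consensus_rois(
    roi_sets: Sequence[tuple[str, Sequence[ROI]]], gap: int = 0
) -> list[ROI]:
    """Merge per-sample ROI calls into consensus ROIs.

    Calls across samples whose intervals overlap or lie within ``gap`` bases
    are unioned. The consensus center is the support-weighted mean of member
    centers rounded down (ties toward the lower coordinate); support is the
    total number of contributing calls.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    members: list[ROI] = [roi for _sample, rois in roi_sets for roi in rois]
    if not members:
        return []
    members.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    out: list[ROI] = []
    cluster: list[ROI] = [members[0]]
    cur_chrom = members[0].interval.chrom
    cur_end = members[0].interval.end

    def _flush(group: list[ROI]) -> ROI:
        start = min(r.interval.start for r in group)
        end = max(r.interval.end for r in group)
        chrom = group[0].interval.chrom
        support = sum(r.support for r in group)
        center = int(sum(r.center * r.support for r in group) // support)
        center = min(max(center, start), end - 1)
        return ROI(GenomicInterval(chrom, start, end), center=center, support=support)

    for roi in members[1:]:
        iv = roi.interval
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cluster.append(roi)
            cur_end = max(cur_end, iv.end)
        else:
            out.append(_flush(cluster))
            cluster = [roi]
            cur_chrom, cur_end = iv.chrom, iv.end
    out.append(_flush(cluster))
    return out


def count_reads_in_regions(
    reads_by_sample: Mapping[str, Sequence[StrandedRead]],
    regions: Sequence[GenomicInterval],
    sample_conditions: Mapping[str, str] | None = None,
    stranded: bool = False,
) -> CountMatrix:
    """Count reads overlapping each region by >= 1 base.

    Both strands are pooled by default (``stranded=False``); with
    ``stranded=True`` only reads matching the region strand are counted.
    A read overlapping several regions counts toward each. Reads on
    chromosomes absent from the region set contribute zero (warning logged).
    """
    sample_conditions = sample_conditions or {}
    region_chroms = {r.chrom for r in regions}
    features = [r.feature_id for r in regions]
    sample_ids = list(reads_by_sample.keys())
    counts = np.zeros((len(regions), len(sample_ids)), dtype=np.int64)

    for j, sample in enumerate(sample_ids):
        reads = reads_by_sample[sample]
        # sorted starts/ends per (chrom, strand-key) for O(log n) counting
        by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        unknown: set[str] = set()
        for read in reads:
            iv = read.interval
            if iv.chrom not in region_chroms:
                unknown.add(iv.chrom)
                continue
            key = (iv.chrom, iv.strand if stranded else ".")
            starts_ends = by_key.setdefault(key, ([], []))
            starts_ends[0].append(iv.start)
            starts_ends[1].append(iv.end)
        if unknown:
            logger.warning(
                "sample %s: reads on chromosomes %s not in region set; counted as zero",
                sample,
                sorted(unknown),
            )
        for key in by_key:
            by_key[key][0].sort()
            by_key[key][1].sort()
        for i, region in enumerate(regions):
            key = (region.chrom, region.strand if stranded else ".")
            if key not in by_key:
                continue
            starts, ends = by_key[key]
            n = len(starts)
            # disjoint exclusions: start >= region.end, or end <= region.start
            after = n - bisect_left(starts, region.end)
            before = bisect_right(ends, region.start)
            counts[i, j] = n - after - before

    samples = [
        SampleInfo(sample_id=s, condition=sample_conditions.get(s, ""))
        for s in sample_ids
    ]
    return CountMatrix(features=features, samples=samples, counts=counts)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into {chrom: sequence} (uppercased)."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks).upper()
    return genome


# ---------------------------------------------------------------------------
# Count-matrix I/O (TSV + YAML sample sidecar)
# ---------------------------------------------------------------------------

def write_count_matrix(
    matrix: CountMatrix, counts_path: str | Path, samples_path: str | Path
) -> None:
    with open(counts_path, "w") as handle:
        handle.write("# feature\t" + "\t".join(matrix.sample_ids) + "\n")
        for feature, row in zip(matrix.features, matrix.counts):
            handle.write(feature + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    meta = [
        {"sample_id": s.sample_id, "condition": s.condition, "replicate": s.replicate}
        for s in matrix.samples
    ]
    with open(samples_path, "w") as handle:
        yaml.safe_dump({"samples": meta}, handle, sort_keys=False)


def read_count_matrix(
    counts_path: str | Path, samples_path: str | Path
) -> CountMatrix:
    with open(counts_path) as handle:
        header = handle.readline().lstrip("#").strip().split("\t")
        sample_ids = header[1:]
        features: list[str] = []
        rows: list[list[int]] = []
        for line in handle:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            features.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    with open(samples_path) as handle:
        meta = yaml.safe_load(handle)["samples"]
    by_id = {m["sample_id"]: m for m in meta}
    samples = [
        SampleInfo(
            sample_id=s,
            condition=by_id[s].get("condition", ""),
            replicate=int(by_id[s].get("replicate", 1)),
        )
        for s in sample_ids
    ]
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(samples)), dtype=np.int64)
    return CountMatrix(features=features, samples=samples, counts=counts)
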