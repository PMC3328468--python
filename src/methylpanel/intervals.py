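"""Genomic interval model, BED I/O and the overlap engine.

Coordinates are 0-based half-open (BED native) everywhere: an interval
``(chrom, start, end)`` covers positions ``start .. end-1``.  A single
convention at every module seam avoids off-by-one errors when peak sets,
CpG-island tracks and promoter windows are intersected.

Chromosome names are matched by exact string equality; no ``chr`` prefix
normalisation is attempted.  Callers that need to reconcile naming schemes
should rename before loading.
"""

from __future__ import annotations

import bisect
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "AnnotationSet",
    "ANNOTATION_TRACKS",
    "read_bed",
    "read_annotation",
    "write_bed",
    "overlap_length",
    "overlaps",
    "overlap_flags",
    "intersect_any",
    "Partition",
]

#: Valid annotation track names.  ``promoter`` is produced by
#: :func:`methylpanel.dmr.make_promoters` from a TSS track.
ANNOTATION_TRACKS = frozenset({"CGI", "gene_body", "TSS", "promoter"})

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """One BED record.

    ``rest`` holds columns 4+ verbatim so that reading and re-writing a
    well-formed BED file is byte-identical.  ``name``, ``score`` and
    ``strand`` are parsed views of those columns.
    """

    chrom: str
    start: int
    end: int
    rest: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("start and end must be integers")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    @classmethod
    def make(
        cls,
        chrom: str,
        start: int,
        end: int,
        *,
        name: str | None = None,
        score: float | str | None = None,
        strand: str | None = None,
    ) -> "GenomicInterval":
        """Build an interval from keyword fields instead of raw BED columns."""
        rest: list[str] = []
        if strand is not None and strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if name is not None or score is not None or strand is not None:
            rest.append("." if name is None else name)
        if score is not None or strand is not None:
            rest.append("0" if score is None else str(score))
        if strand is not None:
            rest.append(strand)
        return cls(chrom, start, end, tuple(rest))

    @property
    def name(self) -> str | None:
        return self.rest[0] if self.rest else None

    @property
    def score(self) -> float | None:
        if len(self.rest) < 2:
            return None
        try:
            return float(self.rest[1])
        except ValueError:
            return None

    @property
    def strand(self) -> str:
        """'+' or '-' when annotated, '.' otherwise."""
        if len(self.rest) >= 3 and self.rest[2] in _STRANDS:
            return self.rest[2]
        return "."

    def __len__(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def to_bed_line(self) -> str:
        return "\t".join((self.chrom, str(self.start), str(self.end)) + self.rest)


@dataclass
class PeakSet:
    """An ordered collection of peaks from one sequencing library.

    Duplicate intervals are retained (peak callers can emit them) but
    surface through :attr:`n_duplicates` so upstream issues are visible.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    skipped_lines: int = 0

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def n_duplicates(self) -> int:
        seen: set[tuple] = set()
        dups = 0
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end, iv.rest)
            if key in seen:
                dups += 1
            seen.add(key)
        return dups

    def sorted_intervals(self) -> list[GenomicInterval]:
        return sorted(self.intervals, key=GenomicInterval.sort_key)


@dataclass
class AnnotationSet:
    """A genomic annotation track (CpG islands, gene bodies, TSS, promoters)."""

    track_name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.track_name not in ANNOTATION_TRACKS:
            raise ValueError(
                f"track_name must be one of {sorted(ANNOTATION_TRACKS)}, "
                f"got {self.track_name!r}"
            )
        if self.track_name == "TSS":
            for iv in self.intervals:
                if iv.end != iv.start + 1:
                    raise ValueError(
                        "TSS records must be single-position intervals "
                        f"(end == start + 1); got [{iv.start}, {iv.end})"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Input order is preserved.  ``track``/``browser``/comment lines are
    skipped and counted.  Malformed records raise ``ValueError`` naming the
    offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                skipped += 1
                continue
            if stripped.startswith(("track", "browser", "#")):
                skipped += 1
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"({fields[1]!r}, {fields[2]!r})"
                ) from exc
            try:
                iv = GenomicInterval(fields[0], start, end, tuple(fields[3:]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    if not intervals:
        warnings.warn(f"{path}: no BED records found", stacklevel=2)
    return PeakSet(name=name or path.stem, intervals=intervals, skipped_lines=skipped)


def read_annotation(path: str | Path, track_name: str) -> AnnotationSet:
    """Read a BED file as an annotation track."""
    peaks = read_bed(path, name=track_name)
    return AnnotationSet(track_name=track_name, intervals=peaks.intervals)


def write_bed(
    records: PeakSet | AnnotationSet | Iterable[GenomicInterval],
    path: str | Path,
) -> None:
    ivs = records.intervals if isinstance(records, (PeakSet, AnnotationSet)) else records
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(iv.to_bed_line() + "\n")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 or negative when disjoint."""
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases.

    Symmetric; half-open adjacency (``end_a == start_b``) never counts.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    return a.chrom == b.chrom and overlap_length(a, b) >= min_bp


class _ChromIndex(NamedTuple):
    intervals: list[GenomicInterval]
    starts: list[int]
    prefix_max_end: list[int]


def _build_index(subject: Iterable[GenomicInterval]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    index: dict[str, _ChromIndex] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        starts = [iv.start for iv in ivs]
        pme = list(itertools.accumulate((iv.end for iv in ivs), max))
        index[chrom] = _ChromIndex(ivs, starts, pme)
    return index


def overlap_flags(
    query: Iterable[GenomicInterval],
    subject: Iterable[GenomicInterval],
    min_bp: int = 1,
) -> list[bool]:
    """Per-query flag: does it overlap any subject interval by >= min_bp?

    Sorted-sweep implementation: subjects are indexed per chromosome by
    start with a running maximum of ends, so each query scans only
    candidates that can still reach it.  Contract is set-equality with the
    naive all-pairs answer.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    index = _build_index(subject)
    flags: list[bool] = []
    for q in query:
        entry = index.get(q.chrom)
        hit = False
        if entry is not None:
            ivs, starts, pme = entry
            # candidates must start at or before q.end - min_bp
            i = bisect.bisect_right(starts, q.end - min_bp) - 1
            lo_end = q.start + min_bp
            while i >= 0 and pme[i] >= lo_end:
                s = ivs[i]
                if min(s.end, q.end) - max(s.start, q.start) >= min_bp:
                    hit = True
                    break
                i -= 1
        flags.append(hit)
    return flags


class Partition(NamedTuple):
    hitting: PeakSet
    non_hitting: PeakSet


def intersect_any(query: PeakSet, subject: PeakSet, min_bp: int = 1) -> Partition:
    """Partition ``query`` into peaks that do / do not overlap ``subject``.

    Every query interval lands in exactly one output part; input order is
    preserved within each part.
    """
    flags = overlap_flags(query.intervals, subject.intervals, min_bp=min_bp)
    hit = [iv for iv, f in zip(query.intervals, flags) if f]
    miss = [iv for iv, f in zip(query.intervals, flags) if not f]
    return Partition(
        hitting=PeakSet(name=f"{query.name}:hitting", intervals=hit),
        non_hitting=PeakSet(name=f"{query.name}:non_hitting", intervals=miss),
    )
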