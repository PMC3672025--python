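"""Tag and mappability input, strand-specific count tracks, and windowed
candidate-region selection.

A "tag" is one mapped read; its location is the leftmost genomic coordinate of
the alignment on either strand.  Forward-strand tags are "left" tags, reverse
strand "right" (their densities peak upstream and downstream of the site,
respectively).  Supported dialects: BED (3+ or 6 columns), SAM text (via
pysam), and Bowtie default output.  BED and Bowtie files may be gzipped.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pysam

from .model import RegionTags

__all__ = [
    "TagRecord",
    "MappabilityTrack",
    "Region",
    "TagTracks",
    "read_mapped_tags",
    "read_mappability",
    "select_regions",
    "filter_unmappable_tags",
    "extract_region_tags",
]

LEFT = "left"
RIGHT = "right"
_STRAND_FROM_SYMBOL = {"+": LEFT, "-": RIGHT}


class TagRecord(NamedTuple):
    """One mapped tag: chromosome, leftmost coordinate (1-based), strand
    ('left' = forward, 'right' = reverse)."""

    chrom: str
    pos: int
    strand: str


class TagFileError(ValueError):
    """Malformed tag file; carries the offending line number."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_bed(path) -> Iterator[TagRecord]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom = fields[0]
                start0 = int(fields[1])
                strand = _STRAND_FROM_SYMBOL[fields[5]] if len(fields) >= 6 else LEFT
            except (IndexError, ValueError, KeyError) as exc:
                raise TagFileError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            yield TagRecord(chrom, start0 + 1, strand)


def _iter_bowtie(path) -> Iterator[TagRecord]:
    # Bowtie default output: read, strand (+/-), reference, 0-based offset, ...
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                strand = _STRAND_FROM_SYMBOL[fields[1]]
                chrom = fields[2]
                offset0 = int(fields[3])
            except (IndexError, ValueError, KeyError) as exc:
                raise TagFileError(
                    f"{path}: malformed Bowtie line {lineno}: {line!r}"
                ) from exc
            yield TagRecord(chrom, offset0 + 1, strand)


def _iter_sam(path) -> Iterator[TagRecord]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            strand = RIGHT if aln.is_reverse else LEFT
            yield TagRecord(aln.reference_name, aln.reference_start + 1, strand)


_READERS = {"bed": _iter_bed, "bowtie": _iter_bowtie, "sam": _iter_sam}


def read_mapped_tags(path, format: str = "bed") -> Iterator[TagRecord]:
    """Stream TagRecords from a mapped-tag location file.

    ``format`` is one of 'bed', 'sam', 'bowtie'.  BED positions are the
    0-based start converted to 1-based; SAM skips unmapped records and takes
    the leftmost aligned coordinate; Bowtie default text gives the 0-based
    offset in column 4.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown tag format {format!r}; expected bed, sam or bowtie")
    return reader(path)


class MappabilityTrack:
    """Per-chromosome set of unmappable genomic positions, stored as merged
    1-based inclusive intervals with O(log n) membership queries."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in (intervals or {}).items():
            self._set_chrom(chrom, ivs)

    def _set_chrom(self, chrom: str, ivs) -> None:
        merged: list[list[int]] = []
        for s, e in sorted((int(s), int(e)) for s, e in ivs):
            if s < 1 or e < s:
                raise ValueError(f"invalid interval [{s}, {e}] on {chrom}")
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
        self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def is_unmappable(self, chrom: str, pos) -> np.ndarray:
        """Vectorized membership query for 1-based position(s)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if np.any(pos < 1):
            raise ValueError("positions must be >= 1")
        starts = self._starts.get(chrom)
        if starts is None or starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ends = self._ends[chrom]
        return (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])

    def mask(self, chrom: str, start: int, width: int) -> np.ndarray:
        """Boolean unmappable mask for positions start .. start+width-1."""
        return self.is_unmappable(chrom, np.arange(start, start + width))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)


def read_mappability(path, invert: bool = False, chrom_sizes: dict[str, int] | None = None) -> MappabilityTrack:
    """Read a BED file of unmappable intervals into a MappabilityTrack.

    BED intervals are 0-based half-open; [10, 20) marks 1-based positions
    11..20 unmappable.  Overlapping intervals merge silently.  With
    ``invert=True`` the BED lists *mappable* intervals and ``chrom_sizes`` is
    required to complement them.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                chrom, s0, e0 = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise TagFileError(
                    f"{path}: malformed BED line {lineno}: {line!r}"
                ) from exc
            if s0 < 0:
                raise ValueError(f"{path}: negative coordinate at line {lineno}")
            if e0 > s0:
                raw.setdefault(chrom, []).append((s0 + 1, e0))
    if not invert:
        return MappabilityTrack(raw)
    if chrom_sizes is None:
        raise ValueError("invert=True requires chrom_sizes")
    track = MappabilityTrack(raw)  # merged mappable intervals
    complement: dict[str, list[tuple[int, int]]] = {}
    for chrom, size in chrom_sizes.items():
        cur = 1
        ivs = []
        starts = track._starts.get(chrom, np.empty(0, dtype=np.int64))
        ends = track._ends.get(chrom, np.empty(0, dtype=np.int64))
        for s, e in zip(starts, ends):
            if s > cur:
                ivs.append((cur, int(s) - 1))
            cur = max(cur, int(e) + 1)
        if cur <= size:
            ivs.append((cur, size))
        complement[chrom] = ivs
    return MappabilityTrack(complement)


@dataclass(frozen=True)
class Region:
    """A candidate region (1-based inclusive) with its pooled tag count."""

    chrom: str
    start: int
    end: int
    total_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class TagTracks:
    """Strand-specific sorted tag-position arrays per chromosome."""

    def __init__(self) -> None:
        self._pos: dict[str, dict[str, np.ndarray]] = {}
        self.n_tags = 0

    @classmethod
    def from_records(cls, records: Iterable[TagRecord]) -> "TagTracks":
        buf: dict[str, dict[str, list[int]]] = {}
        n = 0
        for rec in records:
            buf.setdefault(rec.chrom, {LEFT: [], RIGHT: []})[rec.strand].append(rec.pos)
            n += 1
        tracks = cls()
        tracks.n_tags = n
        for chrom, by_strand in buf.items():
            tracks._pos[chrom] = {
                strand: np.sort(np.asarray(positions, dtype=np.int64))
                for strand, positions in by_strand.items()
            }
        return tracks

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        return self._pos.get(chrom, {}).get(strand, np.empty(0, dtype=np.int64))

    def pooled(self, chrom: str) -> np.ndarray:
        """Sorted positions of both strands combined."""
        return np.sort(
            np.concatenate([self.positions(chrom, LEFT), self.positions(chrom, RIGHT)])
        )


def filter_unmappable_tags(
    records: Iterable[TagRecord], track: MappabilityTrack | None
) -> Iterator[TagRecord]:
    """Drop (with a warning) tags whose position lies in the unmappable set —
    such tags contradict the mappability input."""
    n_dropped = 0
    for rec in records:
        if track is not None and bool(track.is_unmappable(rec.chrom, rec.pos)[0]):
            n_dropped += 1
            continue
        yield rec
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} tag(s) located at unmappable positions",
            RuntimeWarning,
        )


def select_regions(
    tracks: TagTracks, window: int = 150, min_count: int = 15
) -> list[Region]:
    """Select candidate regions by windowed tag counts.

    The genome is tiled with non-overlapping ``window``-bp windows (both
    strands pooled); a window with at least ``min_count`` tags qualifies, and
    runs of neighboring qualifying windows merge into one region.  Region
    lengths are therefore multiples of ``window``, from the minimum length
    ``window`` upward; an isolated tag pileup yields exactly one
    minimum-length region.
    """
    if window < 1 or min_count < 1:
        raise ValueError("window and min_count must be >= 1")
    regions: list[Region] = []
    for chrom in tracks.chroms:
        pos = tracks.pooled(chrom)
        if pos.size == 0:
            continue
        bins = (pos - 1) // window  # window b covers [b*window + 1, (b+1)*window]
        counts = np.bincount(bins)
        q = np.nonzero(counts >= min_count)[0]
        if q.size == 0:
            continue
        breaks = np.nonzero(np.diff(q) > 1)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [q.size - 1]])
        for a, b in zip(run_starts, run_ends):
            s = int(q[a]) * window + 1
            e = (int(q[b]) + 1) * window
            total = int(
                np.searchsorted(pos, e, side="right") - np.searchsorted(pos, s, side="left")
            )
            regions.append(Region(chrom=chrom, start=s, end=e, total_count=total))
    return regions


def extract_region_tags(
    region: Region, tracks: TagTracks, mappability: MappabilityTrack | None = None
) -> RegionTags:
    """Per-position strand counts and unmappable masks for one region."""
    w = region.length
    counts = {}
    for strand in (LEFT, RIGHT):
        p = tracks.positions(region.chrom, strand)
        inside = p[(p >= region.start) & (p <= region.end)]
        counts[strand] = np.bincount(inside - region.start, minlength=w)
    if mappability is not None:
        mask = mappability.mask(region.chrom, region.start, w)
    else:
        mask = np.zeros(w, dtype=bool)
    return RegionTags(
        start=region.start,
        counts_left=counts[LEFT],
        counts_right=counts[RIGHT],
        unmappable_left=mask.copy(),
        unmappable_right=mask.copy(),
        chrom=region.chrom,
    )
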