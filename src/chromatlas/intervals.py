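"""Genomic interval data model and bedtools-style interval algebra.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based formats (GTF) are converted on read.  The primitives here
(merge, segment intersect, overlap counting, masked shuffling) reproduce the
default semantics of the corresponding bedtools operations and are the
foundation every downstream stage builds on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomeInterval",
    "PeakSet",
    "GenomeTable",
    "BedParseError",
    "IntervalValidationError",
    "EmptySetError",
    "PlacementError",
    "read_bed",
    "write_bed",
    "read_genome_table",
    "write_genome_table",
    "merge_intervals",
    "intersect_regions",
    "count_overlapping",
    "overlaps_any",
    "shuffle_set",
    "complement",
]

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A BED/broadPeak line could not be parsed."""


class IntervalValidationError(ValueError):
    """An interval violates 0 <= start < end or falls off its chromosome."""


class EmptySetError(ValueError):
    """A rate/percent is undefined because the denominator set is empty."""


class PlacementError(RuntimeError):
    """Randomized placement failed repeatedly for one interval."""


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise IntervalValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def _sort_key(iv: GenomeInterval):
    return (iv.chrom, iv.start, iv.end, iv.name or "")


class PeakSet:
    """An ordered collection of intervals for one (species, tissue, replicate).

    Intervals are kept sorted by (chrom, start, end, name).  Raw peak-caller
    output may contain overlapping intervals; merged sets are guaranteed
    non-overlapping by :func:`merge_intervals`.
    """

    __slots__ = ("species", "tissue", "replicate", "_intervals", "_by_chrom")

    def __init__(
        self,
        intervals: Iterable[GenomeInterval] = (),
        species: str | None = None,
        tissue: str | None = None,
        replicate: str | None = None,
    ) -> None:
        self.species = species
        self.tissue = tissue
        self.replicate = replicate
        self._intervals: tuple[GenomeInterval, ...] = tuple(
            sorted(intervals, key=_sort_key)
        )
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomeInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomeInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [(iv.chrom, iv.start, iv.end) for iv in self] == [
            (iv.chrom, iv.start, iv.end) for iv in other
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "/".join(str(x) for x in (self.species, self.tissue, self.replicate) if x)
        return f"PeakSet({tag or 'unlabelled'}, n={len(self)})"

    @property
    def intervals(self) -> tuple[GenomeInterval, ...]:
        return self._intervals

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self._intervals], dtype=np.int64)

    def total_bp(self) -> int:
        """Sum of interval widths (equals covered bases only if disjoint)."""
        return int(self.widths().sum()) if len(self) else 0

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, start-sorted."""
        if self._by_chrom is None:
            out: dict[str, list[list[int]]] = {}
            for iv in self._intervals:
                out.setdefault(iv.chrom, [[], []])
                out[iv.chrom][0].append(iv.start)
                out[iv.chrom][1].append(iv.end)
            self._by_chrom = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in out.items()
            }
        return self._by_chrom

    def relabel(self, **kw) -> "PeakSet":
        ps = PeakSet(
            self._intervals,
            species=kw.get("species", self.species),
            tissue=kw.get("tissue", self.tissue),
            replicate=kw.get("replicate", self.replicate),
        )
        return ps


class GenomeTable:
    """Chromosome lengths (bedtools 'genome file' abstraction)."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        for chrom, n in lengths.items():
            if n <= 0:
                raise IntervalValidationError(f"chromosome {chrom} length {n} <= 0")
        self.lengths: dict[str, int] = dict(lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    @property
    def total_size(self) -> int:
        return sum(self.lengths.values())

    def validate(self, ps: PeakSet | Iterable[GenomeInterval]) -> None:
        for iv in ps:
            if iv.chrom not in self.lengths:
                raise IntervalValidationError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > self.lengths[iv.chrom]:
                raise IntervalValidationError(
                    f"{iv} exceeds chromosome length {self.lengths[iv.chrom]}"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, dialect: str = "bed3+", **labels) -> PeakSet:
    """Read a BED3+/BED6/broadPeak file into a sorted PeakSet.

    ``dialect`` is ``"bed3+"`` (first three columns used, extra columns
    name/score/strand if present) or ``"broadPeak"`` (ENCODE 9-column; name
    and score preserved).  Coordinates are taken verbatim (0-based half-open).
    """
    if dialect not in ("bed3+", "broadPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    path = Path(path)
    ivs: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 0 or start >= end:
                raise IntervalValidationError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = "."
            if len(fields) > 5 and fields[5] in STRANDS:
                strand = fields[5]
            ivs.append(GenomeInterval(chrom, start, end, strand, name, score))
    return PeakSet(ivs, **labels)


def write_bed(ps: PeakSet, path: str | Path, dialect: str = "bed3+") -> None:
    """Write intervals as tab-separated BED (no header).

    ``bed3+`` emits 3 columns plus name/score/strand when any interval
    carries them; ``broadPeak`` emits the ENCODE 9-column layout with
    placeholder statistics columns.
    """
    path = Path(path)
    has_meta = any(iv.name or iv.score is not None or iv.strand != "." for iv in ps)
    with open(path, "w") as fh:
        for iv in ps:
            if dialect == "broadPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{int(iv.score) if iv.score is not None else 0}\t{iv.strand}\t"
                    f"0\t-1\t-1\n"
                )
            elif has_meta:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genome_table(path: str | Path) -> GenomeTable:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, n = line.split("\t")[:2]
            lengths[chrom] = int(n)
    return GenomeTable(lengths)


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, n in genome.lengths.items():
            fh.write(f"{chrom}\t{n}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(ps: PeakSet, max_gap: int = 0) -> PeakSet:
    """Collapse intervals whose gap is <= ``max_gap`` (bedtools merge).

    ``max_gap=0`` (the bedtools default) merges overlapping AND book-ended
    intervals.  Output is sorted and non-overlapping; strand/name metadata is
    dropped (merged regions are anonymous, as with bedtools).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    merged: list[GenomeInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in ps:  # already sorted by (chrom, start, end)
        if iv.chrom != cur_chrom or iv.start > cur_end + max_gap:
            if cur_chrom is not None:
                merged.append(GenomeInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    if cur_chrom is not None:
        merged.append(GenomeInterval(cur_chrom, cur_start, cur_end))
    return PeakSet(merged, species=ps.species, tissue=ps.tissue, replicate=ps.replicate)


def _candidate_range(
    b_starts: np.ndarray, b_prefix_max_end: np.ndarray, start: int, end: int
) -> tuple[int, int]:
    """Index range [i, j) of b intervals possibly overlapping [start, end)."""
    j = int(np.searchsorted(b_starts, end, side="left"))
    i = int(np.searchsorted(b_prefix_max_end, start, side="right"))
    return i, j


def intersect_regions(a: PeakSet, b: PeakSet) -> PeakSet:
    """Overlap segments [max(starts), min(ends)) for every overlapping pair.

    This is ``bedtools intersect`` default output: one segment per
    overlapping (a, b) pair, so an a-interval crossing two b-intervals
    yields two segments.
    """
    segments: list[GenomeInterval] = []
    b_chrom = b.by_chrom()
    for chrom, (a_starts, a_ends) in a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        b_starts, b_ends = b_chrom[chrom]
        prefix_max = np.maximum.accumulate(b_ends)
        for s, e in zip(a_starts, a_ends):
            i, j = _candidate_range(b_starts, prefix_max, s, e)
            if i >= j:
                continue
            bs, be = b_starts[i:j], b_ends[i:j]
            mask = be > s  # starts already < e by construction
            for os_, oe in zip(np.maximum(bs[mask], s), np.minimum(be[mask], e)):
                segments.append(GenomeInterval(chrom, int(os_), int(oe)))
    return PeakSet(segments, species=a.species, tissue=a.tissue)


def overlaps_any(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean vector: does each a-interval overlap any b-interval >= min_bp bp."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    hits = np.zeros(len(a), dtype=bool)
    b_chrom = merge_intervals(b).by_chrom() if min_bp == 1 else b.by_chrom()
    idx_by_chrom: dict[str, list[int]] = {}
    for k, iv in enumerate(a):
        idx_by_chrom.setdefault(iv.chrom, []).append(k)
    for chrom, (a_starts, a_ends) in a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        idx = np.asarray(idx_by_chrom[chrom])
        b_starts, b_ends = b_chrom[chrom]
        if min_bp == 1:
            # merged b: disjoint & sorted, O(log n) per query
            pos = np.searchsorted(b_ends, a_starts, side="right")
            ok = pos < len(b_starts)
            safe = np.minimum(pos, len(b_starts) - 1)
            hit = ok & (b_starts[safe] < a_ends)
            hits[idx] = hit
        else:
            prefix_max = np.maximum.accumulate(b_ends)
            for local, (s, e) in enumerate(zip(a_starts, a_ends)):
                i, j = _candidate_range(b_starts, prefix_max, s, e)
                if i >= j:
                    continue
                ol = np.minimum(b_ends[i:j], e) - np.maximum(b_starts[i:j], s)
                if ol.size and int(ol.max()) >= min_bp:
                    hits[idx[local]] = True
    return hits


def count_overlapping(a: PeakSet, b: PeakSet, min_bp: int = 1) -> tuple[int, float]:
    """(count, percent) of a-intervals overlapping any b-interval by >= min_bp.

    Each a-interval counts once no matter how many b-intervals it touches;
    percent is 100 * count / |a| rounded to one decimal (reporting precision
    of replicate-concordance tables).  Raises :class:`EmptySetError` if |a| = 0.
    """
    if len(a) == 0:
        raise EmptySetError("percent overlapping undefined for an empty set")
    count = int(overlaps_any(a, b, min_bp=min_bp).sum())
    return count, round(100.0 * count / len(a), 1)


def complement(genome: GenomeTable, ps: PeakSet) -> PeakSet:
    """Genome minus the (merged) intervals of ``ps``."""
    merged = merge_intervals(ps)
    by_chrom = merged.by_chrom()
    out: list[GenomeInterval] = []
    for chrom, length in genome.lengths.items():
        pos = 0
        for s, e in zip(*by_chrom.get(chrom, (np.array([]), np.array([])))):
            if s > pos:
                out.append(GenomeInterval(chrom, pos, int(s)))
            pos = max(pos, int(e))
        if pos < length:
            out.append(GenomeInterval(chrom, pos, length))
    return PeakSet(out)


def shuffle_set(
    ps: PeakSet,
    genome: GenomeTable,
    excluded: PeakSet | None = None,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1000,
) -> PeakSet:
    """Randomly relocate each interval, preserving its width (bedtools shuffle).

    The chromosome is drawn with probability proportional to its length and
    the start uniformly in [0, chrom_len - width]; a placement overlapping
    the ``excluded`` mask by >= 1 bp is redrawn, up to ``max_attempts`` per
    interval.  Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(genome.lengths)
    chrom_lens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    cum = np.cumsum(chrom_lens / chrom_lens.sum())
    excl = merge_intervals(excluded).by_chrom() if excluded is not None else {}

    n = len(ps)
    widths = ps.widths()
    out_chrom = np.zeros(n, dtype=np.int64)
    out_start = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    # redraw failed placements in vectorized rounds (equivalent to per-peak
    # rejection sampling with a shared stream, still deterministic by seed)
    for _ in range(max_attempts):
        if pending.size == 0:
            break
        k = pending.size
        ci = np.searchsorted(cum, rng.random(k), side="right")
        room = chrom_lens[ci] - widths[pending]
        start = np.floor(rng.random(k) * np.maximum(room + 1, 1)).astype(np.int64)
        ok = room >= 0
        for ci_val in np.unique(ci):
            chrom = chroms[ci_val]
            if chrom not in excl:
                continue
            sel = ci == ci_val
            xs, xe = excl[chrom]
            s = start[sel]
            e = s + widths[pending[sel]]
            pos = np.searchsorted(xe, s, side="right")
            safe = np.minimum(pos, len(xs) - 1)
            hit = (pos < len(xs)) & (xs[safe] < e)
            bad = np.zeros(k, dtype=bool)
            bad[sel] = hit
            ok &= ~bad
        out_chrom[pending[ok]] = ci[ok]
        out_start[pending[ok]] = start[ok]
        pending = pending[~ok]
    if pending.size:
        iv = ps[int(pending[0])]
        raise PlacementError(
            f"could not place {iv} after {max_attempts} attempts "
            "(excluded mask too dense?)"
        )
    placed = [
        GenomeInterval(chroms[out_chrom[i]], int(out_start[i]),
                       int(out_start[i]) + int(widths[i]), name=ps[i].name)
        for i in range(n)
    ]
    return PeakSet(placed, species=ps.species, tissue=ps.tissue, replicate=ps.replicate)
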