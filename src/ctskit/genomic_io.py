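"""Readers, writers and core genomic primitives.

All coordinates are 0-based half-open (BED convention). narrowPeak summit
offsets are converted to absolute positions at parse time; everything
downstream works with absolute summits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, TextIO

import numpy as np
from Bio import SeqIO

log = logging.getLogger("ctskit")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class MalformedRecordError(ValueError):
    """A record in a tabular genomic file violates the format contract."""


class UnknownChromosomeError(KeyError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak with its summit (base of maximal enrichment)."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class Tag:
    """A single-base sequencing-tag position (5' end of an aligned read)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("tag position must be >= 0")


class TagLibrary:
    """A collection of tags held as sorted per-chromosome position arrays.

    ``total`` is the library size used for tags-per-10-million normalization.
    """

    def __init__(self, positions: Mapping[str, np.ndarray] | None = None):
        self._pos: dict[str, np.ndarray] = {}
        if positions:
            for chrom, arr in positions.items():
                a = np.asarray(arr, dtype=np.int64)
                self._pos[chrom] = np.sort(a)

    @classmethod
    def from_tags(cls, tags: Iterable[Tag]) -> "TagLibrary":
        bych: dict[str, list[int]] = {}
        for t in tags:
            bych.setdefault(t.chrom, []).append(t.pos)
        return cls({c: np.array(v) for c, v in bych.items()})

    @property
    def total(self) -> int:
        return int(sum(len(a) for a in self._pos.values()))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        a = self.positions(chrom)
        return int(np.searchsorted(a, end) - np.searchsorted(a, start))

    def tags(self) -> Iterator[Tag]:
        for chrom in self.chroms:
            for p in self._pos[chrom]:
                yield Tag(chrom, int(p))

    def concat(self, other: "TagLibrary") -> "TagLibrary":
        chroms = set(self._pos) | set(other._pos)
        return TagLibrary(
            {
                c: np.concatenate([self.positions(c), other.positions(c)])
                for c in chroms
            }
        )


class ScoreTrack:
    """Per-base score track with bedGraph semantics.

    Within a chromosome the intervals are non-overlapping and sorted; bases
    not covered by any record have value 0 (coverage semantics).
    """

    def __init__(self):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}

    @classmethod
    def from_arrays(
        cls, chrom: str, starts, ends, values
    ) -> "ScoreTrack":
        t = cls()
        t.add_chrom(chrom, starts, ends, values)
        return t

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=float)
        if not (len(s) == len(e) == len(v)):
            raise ValueError("starts/ends/values length mismatch")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(e <= s):
            raise ValueError("empty or inverted interval in score track")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")
        if not np.all(np.isfinite(v)):
            raise ValueError("score values must be finite")
        self._starts[chrom], self._ends[chrom], self._values[chrom] = s, e, v

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def records(self, chrom: str):
        return (
            self._starts.get(chrom, np.empty(0, np.int64)),
            self._ends.get(chrom, np.empty(0, np.int64)),
            self._values.get(chrom, np.empty(0, float)),
        )

    def values_over(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0.

        Positions before 0 are clipped off the chromosome and returned as 0.
        """
        if end <= start:
            return np.empty(0, dtype=float)
        out = np.zeros(end - start, dtype=float)
        s, e, v = self.records(chrom)
        if len(s) == 0:
            return out
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start)
            b = min(int(e[i]), end)
            if a < b:
                out[a - start : b - start] = v[i]
        return out


class Genome:
    """Uppercase genome sequences over {A,C,G,T,N} keyed by chromosome."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seq = {c: s.upper() for c, s in sequences.items()}
        self.lengths = {c: len(s) for c, s in self._seq.items()}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._seq)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    def sequence(self, chrom: str) -> str:
        try:
            return self._seq[chrom]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence over [start, end); out-of-bounds positions padded with N."""
        seq = self.sequence(chrom)
        n = len(seq)
        left = "N" * max(0, -start)
        right = "N" * max(0, end - n)
        return left + seq[max(0, start) : min(n, end)] + right


def extract_window(
    genome: Genome, chrom: str, center: int, flank: int, strand: str = "+"
) -> str:
    """Sequence of length 2*flank+1 centered on ``center``.

    Minus strand returns the reverse complement; positions off the
    chromosome are padded with N.
    """
    seq = genome.fetch(chrom, center - flank, center + flank + 1)
    if strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# parsing


def _open(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source)


def parse_intervals(source, dialect: str = "bed6") -> list[Peak]:
    """Parse peaks from a BED6 or ENCODE narrowPeak stream or path.

    BED6 records (and narrowPeak records with summit offset -1) get
    summit = floor((start+end)/2); narrowPeak column 10 gives the summit as
    an offset from start. narrowPeak score is column 7 (signalValue) when
    positive, else column 5.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    peaks: list[Peak] = []
    fh = _open(source)
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        except (IndexError, ValueError) as exc:
            raise MalformedRecordError(f"line {lineno}: {exc}") from None
        if start >= end:
            raise MalformedRecordError(
                f"line {lineno}: start {start} >= end {end}"
            )
        name = f[3] if len(f) > 3 and f[3] else "."
        score = 0.0
        if len(f) > 4 and f[4] not in (".", ""):
            score = float(f[4])
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
        summit = (start + end) // 2
        if dialect == "narrowPeak":
            if len(f) < 10:
                raise MalformedRecordError(
                    f"line {lineno}: narrowPeak needs 10 columns, got {len(f)}"
                )
            signal = float(f[6])
            if signal > 0:
                score = signal
            offset = int(f[9])
            if offset >= 0:
                summit = start + offset
                if not (start <= summit < end):
                    raise MalformedRecordError(
                        f"line {lineno}: summit offset {offset} outside peak"
                    )
        peaks.append(
            Peak(GenomicInterval(chrom, start, end, strand), summit, score, name)
        )
    return peaks


def write_peaks(dest, peaks: Iterable[Peak], dialect: str = "bed6") -> None:
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        for p in peaks:
            base = (
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                f"{p.score:g}\t{p.interval.strand}"
            )
            if dialect == "narrowPeak":
                offset = p.summit - p.start
                base += f"\t{p.score:g}\t-1\t-1\t{offset}"
            dest.write(base + "\n")
    finally:
        if close:
            dest.close()


def read_tags(source, shift: int = 0) -> TagLibrary:
    """Read tags from BED3/BED6 read intervals.

    The tag is the read's 5' end (start for +, end-1 for -) plus ``shift``
    toward 3'. BED3 records are treated as + strand.
    """
    bych: dict[str, list[int]] = {}
    fh = _open(source)
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        except (IndexError, ValueError) as exc:
            raise MalformedRecordError(f"line {lineno}: {exc}") from None
        if start >= end:
            raise MalformedRecordError(f"line {lineno}: start >= end")
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
        pos = (start + shift) if strand == "+" else (end - 1 - shift)
        bych.setdefault(chrom, []).append(max(0, pos))
    return TagLibrary({c: np.array(v) for c, v in bych.items()})


def write_tags(dest, lib: TagLibrary) -> None:
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        for chrom in lib.chroms:
            for p in lib.positions(chrom):
                dest.write(f"{chrom}\t{p}\t{p + 1}\n")
    finally:
        if close:
            dest.close()


def read_bedgraph(source) -> ScoreTrack:
    bych: dict[str, list[tuple[int, int, float]]] = {}
    fh = _open(source)
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        try:
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        except (IndexError, ValueError) as exc:
            raise MalformedRecordError(f"line {lineno}: {exc}") from None
        bych.setdefault(chrom, []).append((start, end, value))
    track = ScoreTrack()
    for chrom, recs in bych.items():
        s, e, v = zip(*recs)
        track.add_chrom(chrom, s, e, v)
    return track


def write_bedgraph(dest, track: ScoreTrack, precision: int = 6) -> None:
    """Write a track, merging adjacent intervals with equal values."""
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        for chrom in track.chroms:
            s, e, v = track.records(chrom)
            i = 0
            while i < len(s):
                j = i
                while (
                    j + 1 < len(s)
                    and s[j + 1] == e[j]
                    and round(v[j + 1], precision) == round(v[i], precision)
                ):
                    j += 1
                dest.write(
                    f"{chrom}\t{s[i]}\t{e[j]}\t{round(float(v[i]), precision):g}\n"
                )
                i = j + 1
    finally:
        if close:
            dest.close()


def read_fasta(source) -> Genome:
    fh = _open(source)
    return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")})


def write_fasta(dest, genome: Genome, width: int = 80) -> None:
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        for chrom in genome.chroms:
            dest.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                dest.write(seq[i : i + width] + "\n")
    finally:
        if close:
            dest.close()
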