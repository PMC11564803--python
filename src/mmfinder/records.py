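"""Core record types: aligned fragments, mismatches, filter configuration,
interval sets and the germline variant store.

Coordinate conventions: read/BAM parsing is 0-based half-open internally;
every user-facing position (``Mismatch.pos``, VCF output, germline store
keys) is 1-based.  BED interval files are 0-based half-open, as usual.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

SBS = "SBS"
DBS = "DBS"
INS = "INS"
DEL = "DEL"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MissingTagError(ValueError):
    """An alignment record lacks a required tag (typically MD)."""


class MalformedRecordError(ValueError):
    """MD and CIGAR of a record are mutually inconsistent."""


@dataclass(slots=True)
class ReadRecord:
    """One mate of an aligned fragment.

    ``start`` is the 0-based leftmost reference position.  ``quals`` are
    Phred scores, one per sequenced base.
    """

    chrom: str
    start: int
    cigar: str
    md: Optional[str]
    seq: str
    quals: Sequence[int]
    mapq: int = 60
    is_reverse: bool = False
    is_secondary: bool = False
    is_duplicate: bool = False
    is_proper_pair: bool = True
    _alen: int = -1  # cached reference span; computed lazily

    def aligned_length(self) -> int:
        """Number of reference bases consumed by the alignment (M/D/N/=/X)."""
        if self._alen < 0:
            c = self.cigar
            if c[-1] == "M" and c[:-1].isdigit():
                self._alen = int(c[:-1])
            else:
                self._alen = sum(
                    n for n, op in parse_cigar(c) if op in "MDN=X")
        return self._alen

    @property
    def end(self) -> int:
        """0-based exclusive reference end of the alignment."""
        return self.start + self.aligned_length()

    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if len(self.quals) else 0.0


@dataclass(slots=True)
class FragmentRecord:
    """A sequenced cfDNA fragment: one or two mates plus the template length.

    ``tlen`` is the signed outer span of a properly paired fragment
    (0 for unpaired reads, mirroring the BAM TLEN field).
    """

    name: str
    r1: ReadRecord
    r2: Optional[ReadRecord] = None
    tlen: int = 0

    @property
    def fragment_length(self) -> int:
        return abs(self.tlen)

    def overlap_interval(self) -> tuple[int, int]:
        """0-based half-open reference interval where the mates overlap.

        Returns (0, 0) when the fragment is unpaired, the mates map to
        different chromosomes, or their alignments do not overlap.
        """
        if self.r2 is None or self.r1.chrom != self.r2.chrom:
            return (0, 0)
        lo = max(self.r1.start, self.r2.start)
        hi = min(self.r1.end, self.r2.end)
        if hi <= lo:
            return (0, 0)
        return (lo, hi)


@dataclass(slots=True, frozen=True)
class Mismatch:
    """One candidate somatic event carried by one fragment (or, after
    aggregation, by ``support`` distinct fragments).

    ``pos`` is 1-based.  For substitutions ``ref``/``alt`` are the reference
    and read alleles.  Indels are stored gap-style until VCF anchoring:
    insertions with ``ref == ""`` (``pos`` = base after which the sequence is
    inserted), deletions with ``alt == ""`` (``pos`` = first deleted base).
    ``bq`` is the combined Phred quality (summed inside read-pair overlaps);
    ``read_quals`` keeps the per-read components that produced it.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    klass: str
    bq: int
    mapq: int = 60
    fragment_length: int = 0
    in_overlap: bool = False
    read_quals: tuple[int, ...] = ()
    support: int = 1
    read_pos: int = -1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(slots=True)
class FilterConfig:
    """Thresholds of the mismatch filter stack.

    All quality thresholds are inclusive (an event at exactly the threshold
    is retained).  ``min_bq`` applies to the combined quality: the sum of
    both mates' base qualities for an agreeing overlap mismatch, the single
    read's quality outside overlaps.  ``min_per_read_bq`` additionally
    requires every contributing read quality to reach the bound (the
    "high-BQ strict consensus" regime).  ``fragment_windows`` are inclusive
    [min, max] template-length intervals in bp; a fragment must fall in one
    of them when any are given.
    """

    min_mapq: int = 20
    min_bq: int = 65
    min_avg_bq: float = 25.0
    min_mismatches: int = 1
    max_mismatches: int = 15
    min_per_read_bq: int = 0
    fragment_windows: Optional[list[tuple[int, int]]] = None
    consensus: bool = True
    only_overlap: bool = False
    strict_overlap: bool = False
    whitelist: Optional["GenomicIntervals"] = None
    blacklist: Optional["GenomicIntervals"] = None
    min_support: int = 1
    germline: Optional["GermlineStore"] = None

    def __post_init__(self) -> None:
        if self.min_mismatches > self.max_mismatches:
            raise ValueError("min_mismatches must be <= max_mismatches")
        for name in ("min_mapq", "min_bq", "min_per_read_bq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_avg_bq < 0:
            raise ValueError("min_avg_bq must be >= 0")
        if self.fragment_windows is not None:
            for lo, hi in self.fragment_windows:
                if lo > hi:
                    raise ValueError(f"fragment window [{lo}, {hi}] has min > max")
        if self.strict_overlap and not self.only_overlap:
            # strict consensus is defined on top of the overlap-only regime
            self.only_overlap = True

    def evolve(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)

    def fragment_length_ok(self, length: int) -> bool:
        if not self.fragment_windows:
            return True
        return any(lo <= length <= hi for lo, hi in self.fragment_windows)


class GenomicIntervals:
    """A set of genomic intervals (whitelist/blacklist) with point queries.

    Built from 0-based half-open intervals (BED convention); queries use
    1-based positions to match :class:`Mismatch`.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if end <= start:
                continue
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
        self.n_intervals = n

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicIntervals":
        opener = gzip.open if str(path).endswith(".gz") else open
        ivals = []
        with opener(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                ivals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(ivals)

    def contains(self, chrom: str, pos: int) -> bool:
        """True when 1-based ``pos`` lies inside any interval on ``chrom``."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def __len__(self) -> int:
        return self.n_intervals


class GermlineStore:
    """Allele-specific lookup of known (germline) variants to exclude.

    Keys are ``(chrom, pos, ref, alt)`` with 1-based positions and alleles
    as written on the reference forward strand, i.e. VCF-style.  Sources: a
    4-column TSV (chrom, pos, ref, alt) or a VCF (one key per ALT allele).
    """

    def __init__(self, keys: Iterable[tuple[str, int, str, str]] = (),
                 source: str = "in-memory") -> None:
        self._keys = {(c, int(p), r.upper(), a.upper()) for c, p, r, a in keys}
        self.source = source

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GermlineStore":
        opener = gzip.open if str(path).endswith(".gz") else open
        keys = []
        with opener(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
                keys.append((chrom, int(pos), ref, alt))
        return cls(keys, source=str(path))

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GermlineStore":
        import pysam

        keys = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    keys.append((rec.chrom, rec.pos, rec.ref, alt))
        return cls(keys, source=str(path))

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self._keys)


_CIGAR_OPS = set("MIDNSHP=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples."""
    out: list[tuple[int, str]] = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        elif ch in _CIGAR_OPS:
            if num == 0:
                raise MalformedRecordError(f"zero-length CIGAR op in {cigar!r}")
            out.append((num, ch))
            num = 0
        else:
            raise MalformedRecordError(f"bad CIGAR character {ch!r} in {cigar!r}")
    if num:
        raise MalformedRecordError(f"trailing number in CIGAR {cigar!r}")
    return out
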