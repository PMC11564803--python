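"""BAM and FASTA adapters between on-disk alignments and the in-memory
fragment records the extraction and simulation code works on."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from mmfinder.mdtools import compute_md
from mmfinder.records import FragmentRecord, MissingTagError, ReadRecord


def write_fasta(genome: dict[str, str], path: str | Path,
                line_width: int = 70) -> None:
    """Write a genome dict as FASTA and build the .fai index."""
    path = str(path)
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    pysam.faidx(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def _nm_from_md_cigar(md: str, cigar: str) -> int:
    subs = len(re.sub(r"\^[A-Za-z]+|\d+", "",
                      re.sub(r"\^([A-Za-z]+)", "", md)))
    dels = sum(len(g) for g in re.findall(r"\^([A-Za-z]+)", md))
    ins = sum(int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
              if op == "I")
    return subs + dels + ins


def fragments_to_bam(
    fragments: Iterable[FragmentRecord],
    contigs: dict[str, int],
    path: str | Path,
    sort: bool = True,
) -> None:
    """Write fragments as a coordinate-sorted, indexed BAM with MD/NM tags."""
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contigs.items()],
    }
    tmp = path + ".unsorted.bam" if sort else path
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        tid = {c: i for i, c in enumerate(contigs)}
        for frag in fragments:
            mates = [frag.r1] + ([frag.r2] if frag.r2 is not None else [])
            for i, r in enumerate(mates):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = frag.name
                a.reference_id = tid[r.chrom]
                a.reference_start = r.start
                a.cigarstring = r.cigar
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.quals))
                a.mapping_quality = r.mapq
                flag = 0
                if len(mates) == 2:
                    other = mates[1 - i]
                    flag |= 0x1  # paired
                    if r.is_proper_pair:
                        flag |= 0x2
                    flag |= 0x40 if i == 0 else 0x80
                    if r.is_reverse:
                        flag |= 0x10
                    if other.is_reverse:
                        flag |= 0x20
                    a.next_reference_id = tid[other.chrom]
                    a.next_reference_start = other.start
                    a.template_length = frag.tlen if i == 0 else -frag.tlen
                else:
                    if r.is_reverse:
                        flag |= 0x10
                if r.is_secondary:
                    flag |= 0x100
                if r.is_duplicate:
                    flag |= 0x400
                a.flag = flag
                if r.md is not None:
                    a.set_tag("MD", r.md)
                    a.set_tag("NM", _nm_from_md_cigar(r.md, r.cigar))
                bam.write(a)
    if sort:
        pysam.sort("-o", path, tmp)
        Path(tmp).unlink()
    pysam.index(path)


def fragments_from_bam(
    path: str | Path,
    fasta: Optional[str | Path] = None,
    counters: Optional[dict] = None,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a BAM, pairing mates by read name.

    Unmapped, secondary and supplementary records are skipped (tallied in
    ``counters``).  Records without an MD tag raise
    :class:`MissingTagError` unless ``fasta`` is given, in which case MD is
    recomputed from the reference.
    """
    fetch = None
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), sequence_always_upper=True)

        def fetch(chrom: str, start0: int, end0: int) -> str:
            return str(fa[chrom][start0:end0])

    def _tally(key: str):
        if counters is not None:
            counters[key] = counters.get(key, 0) + 1

    def _to_record(aln: pysam.AlignedSegment) -> ReadRecord:
        try:
            md = aln.get_tag("MD")
        except KeyError:
            if fetch is None:
                raise MissingTagError(
                    f"read {aln.query_name} has no MD tag (supply the "
                    f"reference FASTA to recompute it)")
            window = fetch(aln.reference_name, aln.reference_start,
                           aln.reference_end)
            md = compute_md(aln.query_sequence, aln.cigarstring, window,
                            aln.reference_start, aln.reference_start)
        return ReadRecord(
            chrom=aln.reference_name,
            start=aln.reference_start,
            cigar=aln.cigarstring,
            md=str(md),
            seq=aln.query_sequence.upper(),
            quals=bytes(aln.query_qualities),
            mapq=aln.mapping_quality,
            is_reverse=aln.is_reverse,
            is_secondary=aln.is_secondary,
            is_duplicate=aln.is_duplicate,
            is_proper_pair=aln.is_proper_pair,
        )

    pending: dict[str, tuple[pysam.AlignedSegment, ReadRecord]] = {}
    with pysam.AlignmentFile(str(path)) as bam:
        for aln in bam:
            if aln.is_unmapped:
                _tally("unmapped")
                continue
            if aln.is_supplementary or aln.is_secondary:
                _tally("secondary_or_supplementary")
                continue
            if not aln.is_paired:
                yield FragmentRecord(name=aln.query_name, r1=_to_record(aln),
                                     tlen=0)
                continue
            prev = pending.pop(aln.query_name, None)
            if prev is None:
                pending[aln.query_name] = (aln, _to_record(aln))
            else:
                prev_aln, prev_rec = prev
                rec = _to_record(aln)
                first, second = ((prev_rec, rec) if prev_aln.is_read1
                                 else (rec, prev_rec))
                tlen = abs(prev_aln.template_length)
                yield FragmentRecord(name=aln.query_name, r1=first,
                                     r2=second, tlen=tlen)
    for aln, rec in pending.values():
        _tally("unpaired_mate")
        yield FragmentRecord(name=aln.query_name, r1=rec, tlen=0)
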