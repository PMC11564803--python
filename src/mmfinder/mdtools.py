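"""Reconstruction of read/reference mismatches from MD and CIGAR tags.

The reference sequence under an alignment is fully determined by the read
sequence plus the MD and CIGAR tags, so mismatches (substitutions,
insertions, deletions) can be recovered without touching the reference
FASTA.  This module performs that reconstruction and is the first stage of
the extraction pipeline; everything downstream (consensus, filtering,
classification) consumes its output.
"""

from __future__ import annotations

import re
from typing import Optional

from mmfinder.records import (
    DBS,
    DEL,
    INS,
    SBS,
    MalformedRecordError,
    Mismatch,
    MissingTagError,
    ReadRecord,
    parse_cigar,
)

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


def _md_tokens(md: str):
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise MalformedRecordError(f"unparseable MD tag {md!r}")
        pos = m.end()
        if m.group(1) is not None:
            yield ("=", int(m.group(1)))
        elif m.group(2) is not None:
            yield ("^", m.group(2).upper())
        else:
            yield ("X", m.group(3).upper())
    if pos != len(md):
        raise MalformedRecordError(f"unparseable MD tag {md!r}")


def reconstruct_mismatches(
    read: ReadRecord,
    reference_window: Optional[str] = None,
    window_start: Optional[int] = None,
    merge_dbs: bool = True,
    counters: Optional[dict] = None,
) -> list[Mismatch]:
    """Recover every mismatch of one aligned mate from its MD/CIGAR tags.

    Substitutions are emitted per position; with ``merge_dbs`` (default) two
    adjacent substitutions on the same read merge into one DBS event (the
    combined quality is the smaller of the two base qualities) and runs of
    three or more adjacent substitutions are discarded as likely artefacts.
    Insertions/deletions are emitted gap-style (see :class:`Mismatch`).
    Soft-clipped and padded segments contribute nothing; substituted bases
    read as ``N`` are skipped.

    ``reference_window``/``window_start`` optionally give the reference
    sequence covering the alignment span (0-based start); when provided the
    MD-derived reference bases are cross-checked against it.

    Raises :class:`MissingTagError` when MD is absent and
    :class:`MalformedRecordError` when MD and CIGAR disagree.
    """
    if read.md is None:
        raise MissingTagError(f"read at {read.chrom}:{read.start + 1} has no MD tag")

    n = len(read.seq)
    # fast path: gapless perfect match
    if read.md == str(n) and read.cigar == f"{n}M":
        return []

    ops = parse_cigar(read.cigar)
    seq = read.seq.upper()
    quals = read.quals

    subs: list[tuple[int, str, str, int, int]] = []  # (ref0, refbase, alt, qual, read_i)
    indels: list[Mismatch] = []

    # segments the MD tag walks through, in order: M blocks and D blocks
    segments: list[tuple[str, int, int, int]] = []  # (kind, read_i, ref_i, length)
    read_i = 0
    ref_i = read.start
    for length, op in ops:
        if op in "M=X":
            segments.append(("M", read_i, ref_i, length))
            read_i += length
            ref_i += length
        elif op == "I":
            ins_seq = seq[read_i:read_i + length]
            q = min(quals[read_i:read_i + length])
            if "N" not in ins_seq:
                indels.append(Mismatch(
                    chrom=read.chrom, pos=ref_i, ref="", alt=ins_seq,
                    klass=INS, bq=q, mapq=read.mapq, read_quals=(q,),
                    read_pos=read_i,
                ))
            read_i += length
        elif op == "D":
            segments.append(("D", read_i, ref_i, length))
            ref_i += length
        elif op == "N":
            ref_i += length
        elif op == "S":
            read_i += length
        # H and P consume neither
    if read_i != n:
        raise MalformedRecordError(
            f"CIGAR {read.cigar!r} consumes {read_i} read bases, sequence has {n}")

    seg_idx = 0
    seg_off = 0  # offset within the current M segment

    def _advance_to_m():
        nonlocal seg_idx, seg_off
        while seg_idx < len(segments):
            kind_, _, _, length_ = segments[seg_idx]
            if kind_ == "M":
                if seg_off < length_:
                    return
                seg_idx += 1
                seg_off = 0
            else:  # a match/sub MD token landing on a D segment
                raise MalformedRecordError(
                    f"MD tag {read.md!r} missing deletion for CIGAR {read.cigar!r}")

    for kind, payload in _md_tokens(read.md):
        if kind == "=":
            remaining = payload
            while remaining > 0:
                _advance_to_m()
                if seg_idx >= len(segments):
                    raise MalformedRecordError(
                        f"MD tag {read.md!r} runs past CIGAR {read.cigar!r}")
                _, s_read, s_ref, s_len = segments[seg_idx]
                step = min(remaining, s_len - seg_off)
                seg_off += step
                remaining -= step
                if seg_off >= s_len:
                    seg_idx += 1
                    seg_off = 0
        elif kind == "X":
            _advance_to_m()
            if seg_idx >= len(segments):
                raise MalformedRecordError(
                    f"MD tag {read.md!r} runs past CIGAR {read.cigar!r}")
            _, s_read, s_ref, s_len = segments[seg_idx]
            ri = s_read + seg_off
            rp = s_ref + seg_off
            alt = seq[ri]
            if alt != "N" and alt != payload:
                subs.append((rp, payload, alt, quals[ri], ri))
            seg_off += 1
            if seg_off >= s_len:
                seg_idx += 1
                seg_off = 0
        else:  # deletion "^SEQ"
            # must line up with a D segment boundary
            if seg_idx < len(segments) and segments[seg_idx][0] == "M" \
                    and seg_off >= segments[seg_idx][3]:
                seg_idx += 1
                seg_off = 0
            if seg_idx >= len(segments) or segments[seg_idx][0] != "D" \
                    or seg_off != 0 or segments[seg_idx][3] != len(payload):
                raise MalformedRecordError(
                    f"MD deletion ^{payload} inconsistent with CIGAR {read.cigar!r}")
            _, s_read, s_ref, s_len = segments[seg_idx]
            qs = []
            if s_read > 0:
                qs.append(quals[s_read - 1])
            if s_read < n:
                qs.append(quals[s_read])
            q = min(qs) if qs else 0
            indels.append(Mismatch(
                chrom=read.chrom, pos=s_ref + 1, ref=payload, alt="",
                klass=DEL, bq=q, mapq=read.mapq, read_quals=(q,),
                read_pos=s_read,
            ))
            seg_idx += 1
            seg_off = 0

    # MD must have consumed every M and D segment exactly
    if seg_idx < len(segments):
        if not (seg_idx == len(segments) - 1 and segments[seg_idx][0] == "M"
                and seg_off == segments[seg_idx][3]):
            raise MalformedRecordError(
                f"MD tag {read.md!r} too short for CIGAR {read.cigar!r}")

    if reference_window is not None and window_start is not None:
        for rp, refbase, _alt, _q, _ri in subs:
            off = rp - window_start
            if 0 <= off < len(reference_window) and \
                    reference_window[off].upper() not in (refbase, "N"):
                raise MalformedRecordError(
                    f"MD reference base {refbase} at {read.chrom}:{rp + 1} "
                    f"contradicts the supplied reference window")

    events: list[Mismatch] = []
    if merge_dbs and subs:
        i = 0
        while i < len(subs):
            j = i + 1
            while j < len(subs) and subs[j][0] == subs[j - 1][0] + 1:
                j += 1
            run = subs[i:j]
            if len(run) == 1:
                rp, rb, ab, q, ri = run[0]
                events.append(Mismatch(
                    chrom=read.chrom, pos=rp + 1, ref=rb, alt=ab, klass=SBS,
                    bq=q, mapq=read.mapq, read_quals=(q,), read_pos=ri))
            elif len(run) == 2:
                (rp1, rb1, ab1, q1, ri1), (_rp2, rb2, ab2, q2, _ri2) = run
                q = min(q1, q2)
                events.append(Mismatch(
                    chrom=read.chrom, pos=rp1 + 1, ref=rb1 + rb2, alt=ab1 + ab2,
                    klass=DBS, bq=q, mapq=read.mapq, read_quals=(q,), read_pos=ri1))
            else:
                if counters is not None:
                    counters["multi_substitution_runs_discarded"] = \
                        counters.get("multi_substitution_runs_discarded", 0) + 1
            i = j
    else:
        for rp, rb, ab, q, ri in subs:
            events.append(Mismatch(
                chrom=read.chrom, pos=rp + 1, ref=rb, alt=ab, klass=SBS,
                bq=q, mapq=read.mapq, read_quals=(q,), read_pos=ri))

    events.extend(indels)
    events.sort(key=lambda m: m.pos)
    return events


def compute_md(seq: str, cigar: str, reference_window: str, window_start: int,
               ref_start: int) -> str:
    """Compute the MD tag for an alignment given the reference sequence.

    ``reference_window`` must cover the alignment span; ``window_start`` is
    its 0-based origin and ``ref_start`` the 0-based leftmost aligned
    position.  Utility for records whose aligner omitted MD.
    """
    out: list[str] = []
    match_run = 0
    read_i = 0
    ref_i = ref_start
    seq = seq.upper()
    last_was_del = False

    def flush(force: bool = False):
        nonlocal match_run, last_was_del
        if match_run or force or last_was_del:
            out.append(str(match_run))
        match_run = 0
        last_was_del = False

    for length, op in parse_cigar(cigar):
        if op in "M=X":
            for k in range(length):
                rb = reference_window[ref_i - window_start + k].upper()
                qb = seq[read_i + k]
                if rb == qb:
                    match_run += 1
                else:
                    flush(force=True)
                    out.append(rb)
            read_i += length
            ref_i += length
        elif op == "I":
            read_i += length
        elif op == "S":
            read_i += length
        elif op in "DN":
            if op == "D":
                flush(force=True)
                deleted = reference_window[
                    ref_i - window_start:ref_i - window_start + length].upper()
                out.append("^" + deleted)
                last_was_del = True
            ref_i += length
    out.append(str(match_run))
    # MD grammar requires a number between a deletion and a following base,
    # which the explicit flushes above already guarantee
    return "".join(out)
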