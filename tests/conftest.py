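"""Shared fixtures and the alignment fuzzer used by the oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

from mmfinder.mdtools import compute_md
from mmfinder.records import DBS, DEL, INS, SBS, Mismatch, ReadRecord
from mmfinder.signatures_synthetic import synthetic_sbs_catalogue
from mmfinder.workbench import make_fixture_genome

BASES = "ACGT"


@pytest.fixture(scope="session")
def sbs_catalogue():
    return synthetic_sbs_catalogue()


@pytest.fixture(scope="session")
def small_genome():
    genome, whitelist = make_fixture_genome(length=1_000_000, seed=11)
    return genome, whitelist


def random_alignment(rng: np.random.Generator, chrom: str = "chr1",
                     with_indels: bool = True):
    """Build one random gapped alignment with known ground truth.

    Returns ``(read_record, reference, truth)`` where ``truth`` is the list
    of alignment columns actually applied: ('S', refpos0, refbase, altbase,
    qual), ('I', anchor_refpos0, seq, qual), ('D', refpos0, seq, qual).
    The MD tag is derived from the reference so the reconstruction under
    test never sees the truth directly.
    """
    ref = "".join(rng.choice(list(BASES), size=260))
    start = int(rng.integers(10, 30))
    target_len = int(rng.integers(60, 110))

    read_chars: list[str] = []
    quals: list[int] = []
    cigar: list[tuple[int, str]] = []
    truth: list[tuple] = []

    def push_op(length: int, op: str) -> None:
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + length, op)
        else:
            cigar.append((length, op))

    ref_i = start
    last_was_indel = True  # forbid an indel as the first op
    while len(read_chars) < target_len and ref_i < len(ref) - 20:
        roll = rng.random()
        remaining = target_len - len(read_chars)
        if roll < 0.06 and remaining > 3:
            # substitution (possibly part of an adjacent run)
            rb = ref[ref_i]
            alt = BASES[(BASES.index(rb) + int(rng.integers(1, 4))) % 4]
            q = int(rng.integers(10, 41))
            read_chars.append(alt)
            quals.append(q)
            truth.append(("S", ref_i, rb, alt, q))
            push_op(1, "M")
            ref_i += 1
            last_was_indel = False
        elif with_indels and roll < 0.08 and remaining > 5 and not last_was_indel:
            ins = "".join(rng.choice(list(BASES),
                                     size=int(rng.integers(1, 4))))
            q = int(rng.integers(10, 41))
            truth.append(("I", ref_i - 1, ins, q))
            for b in ins:
                read_chars.append(b)
                quals.append(q)
            push_op(len(ins), "I")
            last_was_indel = True
        elif with_indels and roll < 0.10 and not last_was_indel and \
                ref_i + 5 < len(ref) - 20:
            dlen = int(rng.integers(1, 4))
            truth.append(("D", ref_i, ref[ref_i:ref_i + dlen],
                          min(quals[-1] if quals else 30, 30)))
            push_op(dlen, "D")
            ref_i += dlen
            last_was_indel = True
        else:
            read_chars.append(ref[ref_i])
            quals.append(int(rng.integers(10, 41)))
            push_op(1, "M")
            ref_i += 1
            last_was_indel = False
    # alignment must end on M
    if cigar[-1][1] != "M":
        read_chars.append(ref[ref_i])
        quals.append(30)
        push_op(1, "M")
        ref_i += 1

    cigar_str = "".join(f"{n}{op}" for n, op in cigar)
    seq = "".join(read_chars)
    md = compute_md(seq, cigar_str, ref, 0, start)
    record = ReadRecord(chrom=chrom, start=start, cigar=cigar_str, md=md,
                        seq=seq, quals=bytes(quals))
    return record, ref, truth


def oracle_events(truth, chrom: str = "chr1") -> set[tuple]:
    """Independent expectation: turn known alignment columns into events,
    merging adjacent substitutions (pairs -> DBS, runs of 3+ dropped)."""
    subs = sorted([t for t in truth if t[0] == "S"], key=lambda t: t[1])
    events: set[tuple] = set()
    i = 0
    while i < len(subs):
        j = i + 1
        while j < len(subs) and subs[j][1] == subs[j - 1][1] + 1:
            j += 1
        run = subs[i:j]
        if len(run) == 1:
            _, p, rb, ab, q = run[0]
            events.add((p + 1, rb, ab, SBS, q))
        elif len(run) == 2:
            (_, p1, rb1, ab1, q1), (_, _p2, rb2, ab2, q2) = run
            events.add((p1 + 1, rb1 + rb2, ab1 + ab2, DBS, min(q1, q2)))
        i = j
    for t in truth:
        if t[0] == "I":
            _, anchor0, ins, _q = t
            events.add((anchor0 + 1, "", ins, INS, None))
        elif t[0] == "D":
            _, p0, dseq, _q = t
            events.add((p0 + 1, dseq, "", DEL, None))
    return events


def as_comparable(mismatches: list[Mismatch], with_qual: bool = True
                  ) -> set[tuple]:
    out = set()
    for m in mismatches:
        q = m.bq if (with_qual and m.klass in (SBS, DBS)) else None
        out.add((m.pos, m.ref, m.alt, m.klass, q))
    return out
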