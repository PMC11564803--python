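"""Mismatch extraction: read-pair consensus, the filter stack, site-level
aggregation and VCF output.

The pipeline runs per fragment: reconstruct mismatches from each mate's
MD/CIGAR tags, reconcile the mates inside their overlap (agreeing calls sum
their base qualities, disagreeing ones keep the higher-quality base with a
penalty), apply fragment- and mismatch-level filters, then collapse
identical events across fragments into site records carrying the number of
distinct supporting fragments (the MULTI field).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional

from mmfinder.mdtools import reconstruct_mismatches
from mmfinder.records import (
    DBS,
    DEL,
    INS,
    SBS,
    FilterConfig,
    FragmentRecord,
    GermlineStore,
    MalformedRecordError,
    Mismatch,
    ReadRecord,
    parse_cigar,
)


def _qual_at(read: ReadRecord, ref_pos0: int) -> Optional[int]:
    """Base quality of ``read`` at 0-based reference position, or None when
    the position is not covered by an aligned (M) base of the read."""
    read_i = 0
    ref_i = read.start
    for length, op in parse_cigar(read.cigar):
        if op in "M=X":
            if ref_i <= ref_pos0 < ref_i + length:
                return read.quals[read_i + (ref_pos0 - ref_i)]
            read_i += length
            ref_i += length
        elif op in "IS":
            read_i += length
        elif op in "DN":
            if op == "D" and ref_i <= ref_pos0 < ref_i + length:
                return None
            ref_i += length
    return None


def _other_mate_ref_quality(event: Mismatch, other: ReadRecord) -> Optional[int]:
    pos0 = event.pos - 1
    if event.klass == DBS:
        q1 = _qual_at(other, pos0)
        q2 = _qual_at(other, pos0 + 1)
        if q1 is None or q2 is None:
            return None
        return min(q1, q2)
    if event.klass == INS:
        return _qual_at(other, pos0)
    return _qual_at(other, pos0)


def consensus_merge(
    events1: list[Mismatch],
    events2: list[Mismatch],
    overlap: tuple[int, int],
    read1: Optional[ReadRecord] = None,
    read2: Optional[ReadRecord] = None,
    only_overlap: bool = False,
    strict_overlap: bool = False,
) -> list[Mismatch]:
    """Reconcile the two mates' mismatches inside their overlap interval.

    ``overlap`` is the 0-based half-open reference interval shared by both
    alignments ((0, 0) when the mates do not overlap).  Inside it, agreeing
    mismatches merge with combined quality = sum of both base qualities;
    where the mates disagree (different event, or one mate reads the
    reference) the higher-quality base wins and, if it is the mismatch, its
    quality is reduced by half the losing quality.  Outside the overlap,
    mismatches pass through unchanged.  ``only_overlap`` drops non-overlap
    mismatches; ``strict_overlap`` additionally drops every disagreement.

    ``read1``/``read2`` provide the mates' alignments so the quality of a
    reference-agreeing base can be looked up; without them a lone-mate
    overlap mismatch is treated as unopposed.
    """
    lo, hi = overlap
    if read1 is not None and read2 is not None and hi > lo:
        if not (read1.start <= lo and read2.start <= lo
                and hi <= max(read1.end, read2.end)):
            raise MalformedRecordError(
                "overlap interval inconsistent with mate coordinates")

    def in_ov(e: Mismatch) -> bool:
        return lo <= e.pos - 1 < hi

    out: list[Mismatch] = []
    for e in events1 + events2:
        if not in_ov(e):
            if not only_overlap:
                out.append(e)

    ov1 = {(e.pos, e.klass): e for e in events1 if in_ov(e)}
    ov2 = {(e.pos, e.klass): e for e in events2 if in_ov(e)}

    for key, e1 in ov1.items():
        e2 = ov2.get(key)
        if e2 is not None:
            if (e1.ref, e1.alt) == (e2.ref, e2.alt):
                out.append(replace(
                    e1, bq=e1.bq + e2.bq, in_overlap=True,
                    read_quals=(e1.bq, e2.bq),
                    mapq=min(e1.mapq, e2.mapq)))
            elif not strict_overlap:
                hi_e, lo_e = (e1, e2) if e1.bq >= e2.bq else (e2, e1)
                out.append(replace(
                    hi_e, bq=hi_e.bq - lo_e.bq // 2, in_overlap=True,
                    read_quals=(hi_e.bq,),
                    mapq=min(e1.mapq, e2.mapq)))
        else:
            if strict_overlap:
                continue
            q_other = None
            if read2 is not None:
                q_other = _other_mate_ref_quality(e1, read2)
            if q_other is None:
                out.append(replace(e1, in_overlap=True))
            elif e1.bq > q_other:
                out.append(replace(
                    e1, bq=e1.bq - q_other // 2, in_overlap=True))
            # else the reference base wins: no mismatch

    for key, e2 in ov2.items():
        if key in ov1:
            continue
        if strict_overlap:
            continue
        q_other = None
        if read1 is not None:
            q_other = _other_mate_ref_quality(e2, read1)
        if q_other is None:
            out.append(replace(e2, in_overlap=True))
        elif e2.bq > q_other:
            out.append(replace(e2, bq=e2.bq - q_other // 2, in_overlap=True))

    out.sort(key=lambda m: m.pos)
    return out


# rejection reason labels used in the run report
R_DUPLICATE = "duplicate_or_secondary"
R_MAPQ = "mapping_quality"
R_MEAN_BQ = "mean_base_quality"
R_MM_COUNT = "mismatch_count_per_read"
R_FRAG_SIZE = "fragment_size"
R_BQ = "combined_base_quality"
R_PER_READ_BQ = "per_read_base_quality"
R_WHITELIST = "outside_whitelist"
R_BLACKLIST = "blacklisted"
R_NON_OVERLAP = "outside_overlap"


def apply_fragment_filters(
    fragment: FragmentRecord,
    mismatches: list[Mismatch],
    config: FilterConfig,
    per_read_counts: Optional[tuple[int, ...]] = None,
    counters: Optional[dict] = None,
) -> tuple[list[Mismatch], Optional[str]]:
    """Apply the fragment- and mismatch-level filters after consensus.

    Returns ``(retained mismatches, rejection reason)``; the reason is set
    (and the retained list empty) when the whole fragment was rejected.
    Individual mismatch rejections are tallied in ``counters``.
    ``per_read_counts`` gives the raw mismatch count of each mate for the
    per-read count bounds; it defaults to the consensus list length.
    """
    reads = [r for r in (fragment.r1, fragment.r2) if r is not None]

    def _tally(reason: str, n: int = 1):
        if counters is not None:
            counters[reason] = counters.get(reason, 0) + n

    if any(r.is_duplicate or r.is_secondary for r in reads):
        _tally(R_DUPLICATE)
        return [], R_DUPLICATE
    if any(r.mapq < config.min_mapq for r in reads):
        _tally(R_MAPQ)
        return [], R_MAPQ
    total_q = sum(sum(r.quals) for r in reads)
    total_n = sum(len(r.quals) for r in reads)
    if total_n == 0 or total_q / total_n < config.min_avg_bq:
        _tally(R_MEAN_BQ)
        return [], R_MEAN_BQ
    counts = per_read_counts if per_read_counts is not None else (len(mismatches),)
    for c in counts:
        if c > config.max_mismatches or 0 < c < config.min_mismatches:
            _tally(R_MM_COUNT)
            return [], R_MM_COUNT
    if config.fragment_windows and not config.fragment_length_ok(
            fragment.fragment_length):
        _tally(R_FRAG_SIZE)
        return [], R_FRAG_SIZE

    retained: list[Mismatch] = []
    for m in mismatches:
        if m.bq < config.min_bq:
            _tally(R_BQ)
            continue
        if config.min_per_read_bq and any(
                q < config.min_per_read_bq for q in m.read_quals):
            _tally(R_PER_READ_BQ)
            continue
        if config.whitelist is not None and not config.whitelist.contains(
                m.chrom, m.pos):
            _tally(R_WHITELIST)
            continue
        if config.blacklist is not None and config.blacklist.contains(
                m.chrom, m.pos):
            _tally(R_BLACKLIST)
            continue
        retained.append(m)
    return retained, None


def filter_germline(
    mismatches: list[Mismatch], store: Optional[GermlineStore]
) -> list[Mismatch]:
    """Remove mismatches whose (chrom, pos, ref, alt) key is in the store.

    The lookup is allele-specific; order is preserved and the operation is
    idempotent.  ``store=None`` or an empty store is the identity.
    """
    if store is None or len(store) == 0:
        return list(mismatches)
    return [m for m in mismatches if m.key not in store]


def aggregate_support(mismatches: Iterable[Mismatch],
                      min_support: int = 1) -> list[Mismatch]:
    """Collapse identical events across fragments into site records.

    MULTI (``support``) counts distinct fragments; the site record carries
    the best combined quality and mapping quality among its supporters.
    Records below ``min_support`` are dropped (the optional read-depth
    filter).  Output is sorted by (chrom, pos, ref, alt).
    """
    sites: dict[tuple, Mismatch] = {}
    for m in mismatches:
        k = (m.chrom, m.pos, m.ref, m.alt, m.klass)
        prev = sites.get(k)
        if prev is None:
            sites[k] = replace(m, support=1)
        else:
            sites[k] = replace(
                prev,
                support=prev.support + 1,
                bq=max(prev.bq, m.bq),
                mapq=max(prev.mapq, m.mapq),
                in_overlap=prev.in_overlap or m.in_overlap,
            )
    out = [m for m in sites.values() if m.support >= min_support]
    out.sort(key=lambda m: (m.chrom, m.pos, m.ref, m.alt))
    return out


def left_align_indel(m: Mismatch, ref_base: Callable[[str, int], str]) -> Mismatch:
    """Left-align a gap-style indel against the reference.

    ``ref_base(chrom, pos1)`` returns the reference base at a 1-based
    position.  Substitutions pass through unchanged.
    """
    if m.klass == DEL:
        pos, seq = m.pos, m.ref
        while pos > 1 and ref_base(m.chrom, pos - 1).upper() == seq[-1]:
            seq = ref_base(m.chrom, pos - 1).upper() + seq[:-1]
            pos -= 1
        return replace(m, pos=pos, ref=seq)
    if m.klass == INS:
        pos, seq = m.pos, m.alt  # pos = base before the insertion
        while pos >= 1 and ref_base(m.chrom, pos).upper() == seq[-1]:
            seq = ref_base(m.chrom, pos).upper() + seq[:-1]
            pos -= 1
        return replace(m, pos=pos, alt=seq)
    return m


def anchor_indel(m: Mismatch, ref_base: Callable[[str, int], str]) -> Mismatch:
    """Convert a gap-style indel to its anchored VCF representation.

    Deletions become ``POS = first deleted base − 1`` with the anchor base
    prepended to REF and as ALT; insertions anchor on the base they follow.
    Left-align first.
    """
    if m.klass == DEL:
        if m.pos <= 1:
            anchor_pos = m.pos + len(m.ref)
            anchor = ref_base(m.chrom, anchor_pos).upper()
            return replace(m, pos=m.pos, ref=m.ref + anchor, alt=anchor)
        anchor = ref_base(m.chrom, m.pos - 1).upper()
        return replace(m, pos=m.pos - 1, ref=anchor + m.ref, alt=anchor)
    if m.klass == INS:
        pos = max(m.pos, 1)
        anchor = ref_base(m.chrom, pos).upper()
        return replace(m, pos=pos, ref=anchor, alt=anchor + m.alt)
    return m


@dataclass
class ExtractionResult:
    """Site records plus the run report of an extraction."""

    sites: list[Mismatch]
    report: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.sites:
            out[m.klass] = out.get(m.klass, 0) + 1
        return out


def extract_mismatches(
    fragments: Iterable[FragmentRecord],
    config: Optional[FilterConfig] = None,
    reference: Optional[Callable[[str, int], str]] = None,
) -> ExtractionResult:
    """Run the full extraction over a stream of fragments.

    ``reference`` is an optional ``(chrom, 1-based pos) -> base`` accessor
    used to left-align and anchor indels; without it indels stay gap-style
    and skip germline lookup.  The report tallies fragments seen/kept,
    rejections per filter reason, retained per-fragment mismatches, the
    number of bases surviving the fragment-level filters (the error-rate
    denominator) and site/class counts.
    """
    if config is None:
        config = FilterConfig()
    counters: dict[str, int] = {}
    report: dict = {
        "fragments_seen": 0,
        "fragments_kept": 0,
        "filtered_bases": 0,
        "retained_fragment_mismatches": 0,
        "rejections": counters,
    }
    kept: list[Mismatch] = []

    for frag in fragments:
        report["fragments_seen"] += 1
        r1, r2 = frag.r1, frag.r2

        mm1 = reconstruct_mismatches(r1, counters=counters)
        mm2 = reconstruct_mismatches(r2, counters=counters) if r2 is not None else []
        lo, hi = frag.overlap_interval()
        if config.consensus:
            merged = consensus_merge(
                mm1, mm2, (lo, hi), read1=r1, read2=r2,
                only_overlap=config.only_overlap,
                strict_overlap=config.strict_overlap,
            )
        else:  # raw mode: every per-read mismatch stands on its own
            merged = sorted(mm1 + mm2, key=lambda m: m.pos)
        per_read_counts = (len(mm1), len(mm2)) if r2 is not None else (len(mm1),)
        retained, reason = apply_fragment_filters(
            frag, merged, config, per_read_counts=per_read_counts,
            counters=counters)
        if reason is not None:
            continue
        report["fragments_kept"] += 1
        ov_len = hi - lo
        total = r1.aligned_length() + (r2.aligned_length() if r2 else 0)
        if config.only_overlap:
            report["filtered_bases"] += ov_len
        elif config.consensus:
            report["filtered_bases"] += total - ov_len  # overlap counted once
        else:
            report["filtered_bases"] += total  # raw mode: per sequenced base
        kept.extend(retained)

    report["retained_fragment_mismatches"] = len(kept)

    if reference is not None:
        kept = [anchor_indel(left_align_indel(m, reference), reference)
                if m.klass in (INS, DEL) else m for m in kept]
    kept = filter_germline(kept, config.germline)
    report["retained_after_germline"] = len(kept)

    sites = aggregate_support(kept, min_support=config.min_support)
    result = ExtractionResult(sites=sites, report=report)
    report["site_records"] = len(sites)
    report["class_counts"] = result.class_counts()
    return result


def write_vcf(
    sites: list[Mismatch],
    sample_name: str,
    path: str | Path,
    contigs: dict[str, int],
) -> None:
    """Write site records as a VCF v4.2 file with the MULTI INFO field.

    Records must be sorted by chromosome then position and carry VCF-style
    (anchored) alleles; duplicate (chrom, pos, ref, alt) keys are an error.
    """
    import pysam

    keys = [(m.chrom, m.pos, m.ref, m.alt) for m in sites]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (chrom, pos, ref, alt) keys in site records")
    by_chrom: dict[str, int] = {}
    for m in sites:
        if m.chrom in by_chrom and m.pos < by_chrom[m.chrom]:
            raise ValueError("site records are not position-sorted")
        by_chrom[m.chrom] = m.pos

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("MULTI", number=1, type="Integer",
                    description="Number of distinct fragments supporting the mismatch")
    header.info.add("CBQ", number=1, type="Integer",
                    description="Best combined base quality among supporting fragments")
    header.info.add("CLASS", number=1, type="String",
                    description="Event class (SBS, DBS, INS, DEL)")
    header.add_sample(sample_name)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m in sites:
            rec = vf.new_record(
                contig=m.chrom, start=m.pos - 1,
                alleles=(m.ref, m.alt), qual=None)
            rec.info["MULTI"] = int(m.support)
            rec.info["CBQ"] = int(m.bq)
            rec.info["CLASS"] = m.klass
            vf.write(rec)


def read_vcf(path: str | Path) -> list[Mismatch]:
    """Read a VCF written by :func:`write_vcf` back into site records.

    Anchored indel alleles are converted back to the internal gap-style
    representation.
    """
    import pysam

    out: list[Mismatch] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                support = int(rec.info.get("MULTI", 1))
                bq = int(rec.info.get("CBQ", 0))
                if len(ref) == len(alt):
                    klass = SBS if len(ref) == 1 else DBS
                    out.append(Mismatch(
                        chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                        klass=klass, bq=bq, support=support))
                elif len(ref) > len(alt) and ref.startswith(alt):
                    out.append(Mismatch(
                        chrom=rec.chrom, pos=rec.pos + len(alt),
                        ref=ref[len(alt):], alt="", klass=DEL, bq=bq,
                        support=support))
                elif len(alt) > len(ref) and alt.startswith(ref):
                    out.append(Mismatch(
                        chrom=rec.chrom, pos=rec.pos + len(ref) - 1,
                        ref="", alt=alt[len(ref):], klass=INS, bq=bq,
                        support=support))
                else:  # complex allele: keep as-is, classified by length
                    klass = DEL if len(ref) > len(alt) else INS
                    out.append(Mismatch(
                        chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                        klass=klass, bq=bq, support=support))
    return out
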