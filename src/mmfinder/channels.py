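"""Mutation-channel classification and catalogue construction.

Implements the three standard COSMIC channel schemes:

* SBS96 — single-base substitutions in trinucleotide context, strand-
  collapsed so the central reference base is a pyrimidine (the reverse
  complement is taken when it is a purine);
* DBS78 — doublet-base substitutions, strand-collapsed onto the ten
  canonical reference doublets;
* ID83 — insertions/deletions classified by type, length, homopolymer or
  tandem-repeat content, and (for non-repetitive deletions >=2 bp)
  flanking microhomology.

Channel label strings match COSMIC file headers byte-for-byte so catalogues
join directly onto downloaded signature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from mmfinder.records import DBS, DEL, INS, SBS, Mismatch, revcomp

_PYRIMIDINES = ("C", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# ---------------------------------------------------------------------------
# channel label enumerations (canonical ordering)

_SBS_SUBS = [("C", "A"), ("C", "G"), ("C", "T"),
             ("T", "A"), ("T", "C"), ("T", "G")]


def sbs96_labels() -> list[str]:
    """The 96 SBS channel labels, substitution-major order."""
    return [f"{five}[{ref}>{alt}]{three}"
            for ref, alt in _SBS_SUBS
            for five in "ACGT"
            for three in "ACGT"]


_DBS_CANONICAL_REFS = ["AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT"]


def dbs78_labels() -> list[str]:
    """The 78 DBS channel labels in alphabetical (COSMIC file) order."""
    labels = []
    for ref in _DBS_CANONICAL_REFS:
        palindromic = revcomp(ref) == ref
        seen = set()
        for a0 in "ACGT":
            for a1 in "ACGT":
                if a0 == ref[0] or a1 == ref[1]:
                    continue
                alt = a0 + a1
                if palindromic:
                    alt = min(alt, revcomp(alt))
                if alt not in seen:
                    seen.add(alt)
                    labels.append(f"{ref}>{alt}")
    return sorted(labels)


def id83_labels() -> list[str]:
    """The 83 ID channel labels in COSMIC file order."""
    labels = []
    for base in "CT":
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for length in range(2, 6):
        labels += [f"{length}:Del:R:{i}" for i in range(6)]
    for length in range(2, 6):
        labels += [f"{length}:Ins:R:{i}" for i in range(6)]
    for length in range(2, 6):
        max_mh = 5 if length >= 5 else length - 1
        labels += [f"{length}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return labels


SCHEME_LABELS: dict[str, Callable[[], list[str]]] = {
    "SBS96": sbs96_labels,
    "DBS78": dbs78_labels,
    "ID83": id83_labels,
}


# ---------------------------------------------------------------------------
# classification

def classify_sbs(mismatch: Mismatch, context: str) -> Optional[str]:
    """SBS96 channel of a substitution given its reference trinucleotide.

    ``context`` is the reference base flanked by one base on each side.
    Returns ``None`` (caller tallies the exclusion) when the context or the
    alternate allele contains a base outside A/C/G/T.
    """
    if len(context) != 3:
        raise ValueError("SBS context must be exactly 3 bases")
    context = context.upper()
    alt = mismatch.alt.upper()
    if any(b not in "ACGT" for b in context) or alt not in "ACGT":
        return None
    if context[1] != mismatch.ref.upper():
        raise ValueError(
            f"context central base {context[1]} does not match the reference "
            f"allele {mismatch.ref}")
    if context[1] not in _PYRIMIDINES:
        context = revcomp(context)
        alt = _COMP[alt]
    return f"{context[0]}[{context[1]}>{alt}]{context[2]}"


def classify_dbs(mismatch: Mismatch) -> Optional[str]:
    """DBS78 channel of a doublet substitution (strand-collapsed)."""
    ref = mismatch.ref.upper()
    alt = mismatch.alt.upper()
    if len(ref) != 2 or len(alt) != 2:
        raise ValueError("DBS events must carry 2-base alleles")
    if any(b not in "ACGT" for b in ref + alt):
        return None
    if ref not in _DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if revcomp(ref) == ref:
        alt = min(alt, revcomp(alt))
    return f"{ref}>{alt}"


@dataclass(slots=True)
class MicrohomologyAnnotation:
    """Microhomology/repeat annotation of a deletion (or repeat content of
    an insertion).  ``mh_length`` is the longest exact match between the
    deleted sequence's prefix and the 3' flank or its suffix and the 5'
    flank; ``repeat_units`` counts tandem copies of the indel sequence at
    the site (including the deleted copy for deletions)."""

    event: Mismatch
    mh_length: int = 0
    repeat_units: int = 1

    def labelled(self, min_length: int = 1) -> bool:
        """Standalone microhomology-deletion label (length >= threshold)."""
        return self.event.klass == DEL and self.mh_length >= min_length


class FlankTooSmallError(ValueError):
    """The supplied reference window does not cover enough flank."""


def _count_copies_right(seq: str, flank: str) -> int:
    n, L = 0, len(seq)
    while flank[n * L:(n + 1) * L] == seq and (n + 1) * L <= len(flank):
        n += 1
    return n


def _count_copies_left(seq: str, flank: str) -> int:
    n, L = 0, len(seq)
    while n * L + L <= len(flank) and \
            flank[len(flank) - (n + 1) * L:len(flank) - n * L] == seq:
        n += 1
    return n


def _mh_length(seq: str, left: str, right: str) -> int:
    pre = 0
    while pre < len(seq) and pre < len(right) and seq[pre] == right[pre]:
        pre += 1
    suf = 0
    while suf < len(seq) and suf < len(left) and \
            seq[len(seq) - 1 - suf] == left[len(left) - 1 - suf]:
        suf += 1
    return min(max(pre, suf), len(seq) - 1)


def classify_indel(
    mismatch: Mismatch,
    reference_window: str,
    window_start: int,
) -> tuple[Optional[str], MicrohomologyAnnotation]:
    """ID83 channel and microhomology annotation of a left-aligned indel.

    ``reference_window`` (0-based origin ``window_start``) must extend at
    least 6x the event length on both sides of the event.  Deletions are
    classed by repeat-unit count at the site; deletions >=2 bp that are not
    part of a tandem repeat but share flanking microhomology fall into the
    microhomology classes.
    """
    if mismatch.klass not in (INS, DEL):
        raise ValueError("classify_indel requires an INS or DEL event")
    win = reference_window.upper()
    is_del = mismatch.klass == DEL
    seq = (mismatch.ref if is_del else mismatch.alt).upper()
    L = len(seq)
    need = 6 * L
    # event span in window coordinates
    if is_del:
        ev_start = mismatch.pos - 1 - window_start
        ev_end = ev_start + L
    else:
        ev_start = mismatch.pos - window_start  # insertion sits after pos
        ev_end = ev_start
    if ev_start < need or len(win) - ev_end < need:
        raise FlankTooSmallError(
            f"need >= {need} bp of flank on both sides of the event; enlarge "
            f"the reference window")
    if any(b not in "ACGT" for b in seq):
        return None, MicrohomologyAnnotation(mismatch)
    left = win[:ev_start]
    right = win[ev_end:]

    right_copies = _count_copies_right(seq, right)
    left_copies = _count_copies_left(seq, left)
    if is_del:
        units = 1 + right_copies + left_copies
    else:
        units = right_copies + left_copies

    # deletions count the deleted copy, so units >= 1 there; insertions
    # may legitimately have zero pre-existing copies
    ann = MicrohomologyAnnotation(mismatch, repeat_units=units)

    if L == 1:
        base = seq if seq in "CT" else _COMP[seq]
        if is_del:
            sub = min(units, 6) - 1
            label = f"1:Del:{base}:{sub}"
        else:
            sub = min(units, 5)
            label = f"1:Ins:{base}:{sub}"
        return label, ann

    size = min(L, 5)
    if is_del:
        if units == 1:
            mh = _mh_length(seq, left, right)
            ann.mh_length = mh
            if mh >= 1:
                cap = 5 if L >= 5 else L - 1
                return f"{size}:Del:M:{min(mh, cap)}", ann
        sub = min(units, 6) - 1
        return f"{size}:Del:R:{sub}", ann
    sub = min(units, 5)
    return f"{size}:Ins:R:{sub}", ann


# ---------------------------------------------------------------------------
# catalogues

@dataclass
class MutationCatalogue:
    """Per-scheme channel count vectors for one sample."""

    sample: str
    counts: dict[str, pd.Series] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scheme, make in SCHEME_LABELS.items():
            if scheme not in self.counts:
                labels = make()
                self.counts[scheme] = pd.Series(
                    0, index=pd.Index(labels, name="Type"), dtype=int,
                    name=self.sample)

    def total(self, scheme: str) -> int:
        return int(self.counts[scheme].sum())

    def to_tsv(self, path: str | Path, scheme: str) -> None:
        """Write one scheme as a COSMIC-orientation TSV (channels as rows)."""
        self.counts[scheme].to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: str) -> "MutationCatalogue":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sample = str(df.columns[0])
        cat = cls(sample=sample)
        cat.counts[scheme] = df.iloc[:, 0].reindex(
            SCHEME_LABELS[scheme](), fill_value=0).astype(int)
        cat.counts[scheme].index.name = "Type"
        cat.counts[scheme].name = sample
        return cat


def build_catalogue(
    mismatches: Iterable[Mismatch],
    fetch: Callable[[str, int, int], str],
    sample: str = "sample",
    per_fragment: bool = False,
    indel_flank: int = 60,
) -> MutationCatalogue:
    """Classify retained mismatches into SBS96/DBS78/ID83 catalogues.

    ``fetch(chrom, start0, end0)`` returns reference sequence for a 0-based
    half-open interval.  Each mismatch contributes one count (or its
    supporting-fragment count with ``per_fragment``) to exactly one channel
    of exactly one scheme, or is tallied under ``excluded``.
    """
    cat = MutationCatalogue(sample=sample)
    sbs = cat.counts["SBS96"]
    dbs = cat.counts["DBS78"]
    ind = cat.counts["ID83"]
    for m in mismatches:
        w = m.support if per_fragment else 1
        if m.klass == SBS:
            ctx = fetch(m.chrom, m.pos - 2, m.pos + 1)
            label = classify_sbs(m, ctx) if len(ctx) == 3 else None
            if label is None:
                cat.excluded["SBS96"] = cat.excluded.get("SBS96", 0) + w
            else:
                sbs[label] += w
        elif m.klass == DBS:
            label = classify_dbs(m)
            if label is None:
                cat.excluded["DBS78"] = cat.excluded.get("DBS78", 0) + w
            else:
                dbs[label] += w
        elif m.klass in (INS, DEL):
            L = max(len(m.ref), len(m.alt))
            flank = max(indel_flank, 6 * L + 5)
            start0 = max(m.pos - 1 - flank, 0)
            end0 = m.pos - 1 + L + flank
            win = fetch(m.chrom, start0, end0)
            try:
                label, _ann = classify_indel(m, win, start0)
            except FlankTooSmallError:
                label = None
            if label is None:
                cat.excluded["ID83"] = cat.excluded.get("ID83", 0) + w
            else:
                ind[label] += w
    return cat


def fasta_fetcher(path: str | Path) -> Callable[[str, int, int], str]:
    """0-based half-open sequence accessor backed by an indexed FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)

    def fetch(chrom: str, start0: int, end0: int) -> str:
        return str(fa[chrom][max(start0, 0):end0])

    return fetch


def dict_fetcher(genome: dict[str, str]) -> Callable[[str, int, int], str]:
    """Sequence accessor over an in-memory {chrom: sequence} genome."""

    def fetch(chrom: str, start0: int, end0: int) -> str:
        return genome[chrom][max(start0, 0):end0]

    return fetch
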