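"""Simulation of cell-free DNA sequencing data for validating limits of
detection.

Four generators cover the validation designs used throughout the package:

* error-only paired reads, where every deviation from the reference is a
  sequencing error drawn from a parametric per-base quality profile;
* signature-faithful spike-ins: somatic variants planned so their
  pyrimidine-normalised trinucleotide contexts follow a target SBS96
  profile, injected into reads at a constant allele fraction;
* depth downsampling via a per-fragment Bernoulli keep decision;
* tumour-purity admixtures that replace source (tumour-bearing) fragments
  with healthy-donor fragments at matched depth.

The sizing arithmetic is exposed as pure functions before any I/O use:

    n_vars     = r_m / 1e6 * n_genome
    f          = n_genome * depth_t / (len_read * n_reads)
    f_tumour   = p_t / p_s
    f_normal   = (1 - f_tumour) * n_s / n_d

Reads are emitted as already-aligned records with correct CIGAR and MD tags
by construction, so extraction needs no external aligner.  Indel sequencing
errors are not simulated; substitution error rates are the quantity of
interest for error-only data.  Every operation is reproducible bit-for-bit
given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from mmfinder.records import FragmentRecord, Mismatch, ReadRecord, revcomp

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# sizing equations (pure)

def spike_in_variant_count(r_m: float, n_genome: int) -> int:
    """Number of variants to spike for a target mutation rate.

    ``r_m`` is in mutations per megabase, so n_vars = r_m / 1e6 * n_genome
    (about 300 variants at r_m = 0.1 on a 3 Gb genome, 300,000 at
    r_m = 100).
    """
    if r_m < 0 or n_genome <= 0:
        raise ValueError("r_m must be >= 0 and n_genome positive")
    return int(round(r_m / 1e6 * n_genome))


def downsample_fraction(n_genome: int, depth_t: float, len_read: int,
                        n_reads: int) -> float:
    """Subsampling fraction reaching a target depth:
    f = n_genome * depth_t / (len_read * n_reads)."""
    if min(n_genome, len_read, n_reads) <= 0 or depth_t <= 0:
        raise ValueError("all sizing quantities must be positive")
    f = (n_genome * depth_t) / (len_read * n_reads)
    if f > 1.0:
        raise ValueError(
            f"target depth {depth_t} is unattainable: it needs subsampling "
            f"fraction {f:.3f} > 1")
    return f


def tumour_read_fraction(p_t: float, p_s: float) -> float:
    """Fraction of source reads kept to dilute purity p_s down to p_t."""
    if not (0 < p_s <= 1) or not (0 <= p_t <= 1):
        raise ValueError("purities must lie in (0, 1]")
    if p_t > p_s:
        raise ValueError("target purity cannot exceed source purity")
    return p_t / p_s


def donor_fraction(f_tumour: float, n_s: int, n_d: int) -> float:
    """Fraction of donor reads replacing removed source reads:
    f_normal = (1 - f_tumour) * n_s / n_d."""
    if n_d <= 0 or n_s < 0:
        raise ValueError("read counts must be positive")
    f = (1.0 - f_tumour) * n_s / n_d
    if f > 1.0:
        raise ValueError(
            f"donor dataset too small: required fraction {f:.3f} > 1")
    return f


def measure_error_rate(retained_mismatches: int, filtered_bases: int) -> float:
    """Errors per base: retained mismatches over bases surviving the same
    fragment-level filters."""
    if filtered_bases <= 0:
        raise ValueError("error rate undefined: zero filtered bases")
    return retained_mismatches / filtered_bases


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class QualityProfile:
    """Per-base Phred quality distribution of the simulated sequencer.

    Base qualities are drawn i.i.d. from ``quals`` with ``probs``; a base
    of quality Q is sequenced wrongly with probability 10^(-Q/10) (the
    wrong base uniform over the three alternatives).  The default mixture
    mimics a modern Illumina run: mostly Q37 with minor Q32/Q22/Q12 tails
    (mean quality ~34.9, mean error rate ~2.4e-3).
    """

    quals: tuple[int, ...] = (12, 22, 32, 37)
    probs: tuple[float, ...] = (0.03, 0.05, 0.12, 0.80)
    zero_error: bool = False  # record the qualities but inject no errors

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.probs) or not self.quals:
            raise ValueError("quals and probs must be equal-length, non-empty")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")

    def error_rates(self) -> np.ndarray:
        if self.zero_error:
            return np.zeros(len(self.quals))
        return 10.0 ** (-np.asarray(self.quals, dtype=float) / 10.0)

    def expected_error_rate(self) -> float:
        """Analytic per-base substitution error rate of the profile."""
        return float(np.dot(self.probs, self.error_rates()))

    def mean_quality(self) -> float:
        return float(np.dot(self.probs, self.quals))

    @classmethod
    def error_free(cls) -> "QualityProfile":
        return cls(quals=(60,), probs=(1.0,), zero_error=True)


@dataclass
class ReadSimParams:
    """Fragment and read geometry of the simulator.

    Defaults model plasma cfDNA sequencing: 100 bp paired reads from
    fragments of Normal(166, 24) bp length truncated to
    [read_length, max_fragment].
    """

    read_length: int = 100
    fragment_mean: float = 166.0
    fragment_sd: float = 24.0
    max_fragment: int = 500
    profile: QualityProfile = field(default_factory=QualityProfile)
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.fragment_sd <= 0:
            raise ValueError("fragment_sd must be positive")
        if self.read_length > self.max_fragment:
            raise ValueError("read_length must not exceed max_fragment")


def _md_from_offsets(read_len: int, offsets: Sequence[int],
                     ref_bases: Sequence[str]) -> str:
    parts: list[str] = []
    prev = 0
    for off, rb in zip(offsets, ref_bases):
        parts.append(str(off - prev))
        parts.append(rb)
        prev = off + 1
    parts.append(str(read_len - prev))
    return "".join(parts)


def simulate_clean_reads(
    genome: dict[str, str],
    depth: float,
    params: Optional[ReadSimParams] = None,
    seed: int = 0,
    chunk_size: int = 20_000,
) -> Iterator[FragmentRecord]:
    """Generate error-only paired fragments to a target mean depth.

    Fragments are placed uniformly per contig; any read/reference
    difference is a substitution sequencing error injected per base at
    rate 10^(-Q/10) under the params' quality profile, with the drawn
    quality recorded.  Yields :class:`FragmentRecord` with correct
    CIGAR/MD, coordinate-ordered within each contig.
    """
    if params is None:
        params = ReadSimParams()
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rl = params.read_length
    qvals = np.asarray(params.profile.quals, dtype=np.uint8)
    qcum = np.cumsum(params.profile.probs)
    err_by_q = params.profile.error_rates()

    frag_counter = 0
    for chrom in sorted(genome):
        seq_str = genome[chrom]
        L = len(seq_str)
        if L < params.max_fragment:
            raise ValueError(
                f"contig {chrom} ({L} bp) shorter than max fragment "
                f"{params.max_fragment}")
        n_frags = int(round(L * depth / (2 * rl)))
        done = 0
        while done < n_frags:
            n = min(chunk_size, n_frags - done)
            done += n
            flens = np.clip(
                np.rint(rng.normal(params.fragment_mean, params.fragment_sd,
                                   size=n)),
                rl, min(params.max_fragment, L)).astype(np.int64)
            starts = (rng.random(n) * (L - flens + 1)).astype(np.int64)
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            flens = flens[order]

            # qualities for both mates: (n, 2, rl)
            qidx = np.searchsorted(qcum, rng.random((n, 2, rl)),
                                   side="right").clip(max=len(qvals) - 1)
            quals = qvals[qidx]
            errs = rng.random((n, 2, rl)) < err_by_q[qidx]
            err_fi, err_mi, err_off = np.nonzero(errs)
            alt_pick = rng.integers(0, 3, size=err_fi.size)
            err_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
            for k in range(err_fi.size):
                err_map.setdefault(
                    (int(err_fi[k]), int(err_mi[k])), []).append(
                        (int(err_off[k]), int(alt_pick[k])))

            for i in range(n):
                start = int(starts[i])
                flen = int(flens[i])
                r2_start = start + flen - rl
                mates = []
                for mi, (mstart, is_rev) in enumerate(
                        ((start, False), (r2_start, True))):
                    ref_slice = seq_str[mstart:mstart + rl]
                    errors = err_map.get((i, mi))
                    if errors:
                        errors.sort()
                        chars = list(ref_slice)
                        offsets, refbases = [], []
                        for off, pick in errors:
                            rb = chars[off]
                            alts = [b for b in _BASES if b != rb]
                            chars[off] = alts[pick]
                            offsets.append(off)
                            refbases.append(rb)
                        read_seq = "".join(chars)
                        md = _md_from_offsets(rl, offsets, refbases)
                    else:
                        read_seq = ref_slice
                        md = str(rl)
                    mates.append(ReadRecord(
                        chrom=chrom, start=mstart, cigar=f"{rl}M", md=md,
                        seq=read_seq, quals=quals[i, mi].tobytes(),
                        mapq=params.mapq, is_reverse=is_rev))
                yield FragmentRecord(
                    name=f"frag{frag_counter}", r1=mates[0], r2=mates[1],
                    tlen=flen)
                frag_counter += 1


# ---------------------------------------------------------------------------
# spike-ins

@dataclass
class SpikeInPlan:
    """A set of somatic variants whose contexts replicate a target SBS96
    profile, to be injected at a constant allele fraction."""

    signature: str
    r_m: float
    n_genome: int
    n_vars: int
    variants: list[tuple[str, int, str, str]]  # (chrom, pos 1-based, ref, alt)
    allele_frequency: float = 0.1
    seed: int = 0

    def positions_by_chrom(self) -> dict[str, dict[int, tuple[str, str]]]:
        out: dict[str, dict[int, tuple[str, str]]] = {}
        for chrom, pos, ref, alt in self.variants:
            out.setdefault(chrom, {})[pos] = (ref, alt)
        return out

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.variants, columns=["chrom", "pos", "ref", "alt"])


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _context_index(genome: dict[str, str]) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome map: pyrimidine-normalised trinucleotide -> 0-based
    positions of the central base."""
    out: dict[str, dict[str, np.ndarray]] = {}
    # enumerate the 32 pyrimidine-centred contexts and code lookup
    code_to_ctx = np.full(64, -1, dtype=np.int16)
    ctx_labels: list[str] = []
    for mid in "CT":
        for five in _BASES:
            for three in _BASES:
                ctx = five + mid + three
                ctx_labels.append(ctx)
    ctx_id = {c: i for i, c in enumerate(ctx_labels)}
    for five in _BASES:
        for mid in _BASES:
            for three in _BASES:
                ctx = five + mid + three
                canon = ctx if mid in "CT" else revcomp(ctx)
                code = _CODE[five] * 16 + _CODE[mid] * 4 + _CODE[three]
                code_to_ctx[code] = ctx_id[canon]
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        base = np.full(arr.size, -1, dtype=np.int8)
        for b, v in _CODE.items():
            base[arr == ord(b)] = v
        codes = base[:-2] * 16 + base[1:-1] * 4 + base[2:]
        valid = (base[:-2] >= 0) & (base[1:-1] >= 0) & (base[2:] >= 0)
        ctx_of_mid = np.where(valid, code_to_ctx[codes.clip(min=0)], -1)
        chrom_map: dict[str, np.ndarray] = {}
        for ctx, cid in ctx_id.items():
            # element i is centred on 0-based position i+1
            chrom_map[ctx] = np.nonzero(ctx_of_mid == cid)[0] + 2
        out[chrom] = chrom_map
    return out


def _parse_sbs_label(label: str) -> tuple[str, str]:
    """SBS96 label -> (pyrimidine context, alt base)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, alt


def plan_spike_in(
    signature: pd.Series,
    r_m: float,
    genome: dict[str, str],
    seed: int = 0,
    allele_frequency: float = 0.1,
    signature_name: Optional[str] = None,
) -> SpikeInPlan:
    """Plan spike-in variants replicating an SBS96 signature profile.

    The variant count follows the mutation-rate formula; channels are drawn
    multinomially from the signature's probabilities and genome positions
    are sampled (without replacement) among sites whose pyrimidine-
    normalised context matches each channel — the spiked alternate allele
    is reverse-complemented where the genomic central base is a purine.
    Raises when a channel needs more positions than the genome offers.
    """
    n_genome = sum(len(s) for s in genome.values())
    n_vars = spike_in_variant_count(r_m, n_genome)
    name = signature_name or str(signature.name or "signature")
    rng = np.random.default_rng(seed)
    plan = SpikeInPlan(signature=name, r_m=r_m, n_genome=n_genome,
                       n_vars=n_vars, variants=[],
                       allele_frequency=allele_frequency, seed=seed)
    if n_vars == 0:
        return plan

    probs = signature.to_numpy(dtype=float)
    probs = probs / probs.sum()
    channel_counts = rng.multinomial(n_vars, probs)
    ctx_index = _context_index(genome)
    chroms = sorted(genome)

    # group channel demands by context so one draw per context guarantees
    # globally distinct positions
    by_ctx: dict[str, list[tuple[str, int]]] = {}
    for label, k in zip(signature.index, channel_counts):
        if k == 0:
            continue
        ctx, alt = _parse_sbs_label(str(label))
        by_ctx.setdefault(ctx, []).append((alt, int(k)))

    variants: list[tuple[str, int, str, str]] = []
    for ctx, demands in sorted(by_ctx.items()):
        pools = [(c, ctx_index[c][ctx]) for c in chroms]
        sizes = np.array([p.size for _, p in pools])
        total_need = sum(k for _, k in demands)
        if total_need > sizes.sum():
            raise ValueError(
                f"channel context {ctx} exhausted: need {total_need} "
                f"positions, genome offers {sizes.sum()}")
        flat = rng.choice(sizes.sum(), size=total_need, replace=False)
        flat.sort()
        bounds = np.cumsum(sizes)
        picked: list[tuple[str, int]] = []
        for idx in flat:
            ci = int(np.searchsorted(bounds, idx, side="right"))
            offset = idx - (bounds[ci - 1] if ci else 0)
            chrom = pools[ci][0]
            picked.append((chrom, int(pools[ci][1][offset])))
        rng.shuffle(picked)
        i = 0
        for alt, k in demands:
            for chrom, pos in picked[i:i + k]:
                ref = genome[chrom][pos - 1]
                actual_alt = alt if ref in "CT" else _COMP[alt]
                variants.append((chrom, pos, ref, actual_alt))
            i += k
    variants.sort()
    plan.variants = variants
    return plan


def _ref_from_md(seq: str, md: str) -> str:
    """Reference sequence under a gapless (M-only) alignment."""
    import re

    out = []
    i = 0
    for tok in re.finditer(r"(\d+)|([A-Za-z])", md):
        if tok.group(1):
            n = int(tok.group(1))
            out.append(seq[i:i + n])
            i += n
        else:
            out.append(tok.group(2).upper())
            i += 1
    return "".join(out)


def inject_variants(
    fragments: Iterable[FragmentRecord],
    plan: SpikeInPlan,
    seed: int = 0,
) -> tuple[list[FragmentRecord], dict]:
    """Inject planned variants into reads at the plan's allele fraction.

    Each fragment overlapping a planned site carries the alternate allele
    with probability ``allele_frequency`` — the decision is per fragment,
    so both mates are edited when both cover the site; MD tags are updated.
    Only gapless (M-only) reads are supported, matching the simulator's
    output.  Returns the edited fragment list and a stats dict including
    sites never covered by any fragment (``unrepresented``).
    """
    rng = np.random.default_rng(seed)
    sites = plan.positions_by_chrom()
    pos_arrays = {c: np.array(sorted(d), dtype=np.int64)
                  for c, d in sites.items()}
    covered: set[tuple[str, int]] = set()
    carried = 0
    out: list[FragmentRecord] = []

    for frag in fragments:
        chrom = frag.r1.chrom
        d = sites.get(chrom)
        if d is None:
            out.append(frag)
            continue
        arr = pos_arrays[chrom]
        reads = [r for r in (frag.r1, frag.r2) if r is not None]
        lo = min(r.start for r in reads) + 1
        hi = max(r.start + len(r.seq) for r in reads)
        i0 = int(np.searchsorted(arr, lo, side="left"))
        i1 = int(np.searchsorted(arr, hi, side="right"))
        if i1 <= i0:
            out.append(frag)
            continue
        edits: list[int] = []
        for pos in arr[i0:i1]:
            pos = int(pos)
            if any(r.start < pos <= r.start + len(r.seq) for r in reads):
                covered.add((chrom, pos))
                if rng.random() < plan.allele_frequency:
                    edits.append(pos)
        if not edits:
            out.append(frag)
            continue
        carried += len(edits)
        new_reads = []
        for r in reads:
            seq = r.seq
            md = r.md
            touched = False
            for pos in edits:
                off = pos - 1 - r.start
                if 0 <= off < len(seq):
                    if r.cigar != f"{len(seq)}M":
                        raise ValueError(
                            "variant injection supports gapless reads only")
                    ref_seq = _ref_from_md(seq, md)
                    alt = d[pos][1]
                    seq = seq[:off] + alt + seq[off + 1:]
                    offsets = [k for k in range(len(seq))
                               if seq[k] != ref_seq[k]]
                    md = _md_from_offsets(
                        len(seq), offsets, [ref_seq[k] for k in offsets])
                    touched = True
            if touched:
                new_reads.append(ReadRecord(
                    chrom=r.chrom, start=r.start, cigar=r.cigar, md=md,
                    seq=seq, quals=r.quals, mapq=r.mapq,
                    is_reverse=r.is_reverse, is_secondary=r.is_secondary,
                    is_duplicate=r.is_duplicate,
                    is_proper_pair=r.is_proper_pair))
            else:
                new_reads.append(r)
        out.append(FragmentRecord(
            name=frag.name, r1=new_reads[0],
            r2=new_reads[1] if len(new_reads) > 1 else None, tlen=frag.tlen))

    all_sites = {(c, int(p)) for c, d in sites.items() for p in d}
    stats = {
        "planned_sites": len(all_sites),
        "covered_sites": len(covered),
        "unrepresented": len(all_sites - covered),
        "alleles_injected": carried,
    }
    return out, stats


# ---------------------------------------------------------------------------
# downsampling and admixture

@dataclass
class DownsampleSpec:
    """Depth-downsampling parameterisation; ``fraction`` follows the
    sizing formula and must not exceed 1."""

    depth_t: float
    len_read: int
    n_reads: int
    n_genome: int
    seed: int = 0
    replicates: int = 20
    fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.fraction = downsample_fraction(
            self.n_genome, self.depth_t, self.len_read, self.n_reads)


def downsample(fragments: Sequence[FragmentRecord],
               spec: DownsampleSpec) -> list[FragmentRecord]:
    """Per-fragment Bernoulli(f) keep decisions (mates kept or dropped
    together), reproducible from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    keep = rng.random(len(fragments)) < spec.fraction
    return [f for f, k in zip(fragments, keep) if k]


@dataclass
class AdmixtureSpec:
    """Tumour-purity dilution: keep Bernoulli(f_tumour) of source
    fragments and add Bernoulli(f_normal) of donor fragments so the
    expected total stays at the source count."""

    p_s: float
    p_t: float
    n_s: int
    n_d: int
    seed: int = 0
    replicates: int = 20
    f_tumour: float = field(init=False)
    f_normal: float = field(init=False)

    def __post_init__(self) -> None:
        self.f_tumour = tumour_read_fraction(self.p_t, self.p_s)
        self.f_normal = donor_fraction(self.f_tumour, self.n_s, self.n_d)


def admix(
    source: Sequence[FragmentRecord],
    donor: Sequence[FragmentRecord],
    spec: AdmixtureSpec,
) -> list[FragmentRecord]:
    """Mix source and donor fragments at the spec's fractions, sorted by
    coordinate.  Donor fragment names are prefixed to stay unique."""
    rng = np.random.default_rng(spec.seed)
    keep_s = rng.random(len(source)) < spec.f_tumour
    keep_d = rng.random(len(donor)) < spec.f_normal
    mixed = [f for f, k in zip(source, keep_s) if k]
    for f, k in zip(donor, keep_d):
        if k:
            mixed.append(FragmentRecord(
                name=f"donor_{f.name}", r1=f.r1, r2=f.r2, tlen=f.tlen))
    mixed.sort(key=lambda fr: (fr.r1.chrom, fr.r1.start))
    return mixed
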