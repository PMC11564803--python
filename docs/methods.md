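# Methods

## Mismatch reconstruction

The reference sequence under an alignment is fully determined by the read
plus its MD and CIGAR tags, so mismatches are recovered without touching
the FASTA (`mmfinder.mdtools`).  Substitutions, insertions and deletions
are emitted per read; soft-clipped and padded segments contribute
nothing.  Two adjacent substitutions on one read merge into a single
doublet (DBS) event whose quality is the *smaller* of the two base
qualities (the doublet is only as credible as its weaker base); runs of
three or more adjacent substitutions are discarded as likely alignment or
chemistry artefacts, since no standard channel scheme describes them.
MD/CIGAR inconsistencies raise a malformed-record error naming the read;
a missing MD raises a distinct error (the BAM reader can recompute MD
from the reference FASTA when supplied).

Indels are carried gap-style internally (deletion = deleted sequence at
its first deleted base; insertion = inserted sequence anchored on the
base it follows), left-aligned against the reference, and only converted
to anchored VCF alleles at the boundary.  Germline lookup happens after
left-alignment so representations match the store.

## Read-pair consensus

For each fragment the mates' overlap interval is computed from alignment
coordinates.  Inside it:

* both mates agree on a mismatch → one event, combined quality
  `BQ₁ + BQ₂` (both components retained for the per-read-quality filter);
* the mates disagree (different alternate bases, or one mate reads the
  reference) → the higher-quality base wins; if the winner is the
  mismatch it keeps quality `BQ_hi − ⌊BQ_lo/2⌋`, if the reference wins
  the event disappears.  An exact quality tie keeps mate 1's base (a
  deterministic rule whose penalty is symmetric in magnitude);
* indels must match in representation to count as agreement.

Outside the overlap mismatches pass through unchanged.  `only_overlap`
discards them; `strict_overlap` (implies `only_overlap`) additionally
discards every disagreement.  Four named presets expose the nested
regimes used by the error-rate benchmark — A: no filters, no consensus
(every per-read mismatch counts); B: consensus, overlap only;
C: strict consensus; D: strict consensus plus per-read BQ ≥ 32 — plus
`paper-default`, the standard configuration (MQ ≥ 20, combined BQ ≥ 65,
mean read-pair BQ ≥ 25, 1–15 mismatches per read).

All quality thresholds are inclusive (≥).  The combined-BQ threshold of
65 applies to the summed overlap quality; outside overlaps (when those
are kept) the single read's quality is compared unmodified — the
threshold is defined on overlap sums and the method is silent outside
them, so the raw quality is the only defensible choice.  The high-BQ
strict regime is expressed as a per-read bound (`min_per_read_bq = 32`)
rather than a summed bound, which matches its definition on both mates.

### Error-rate accounting

The error-rate denominator counts bases surviving the same
fragment-level filters as the numerator: in overlap-only regimes, the
overlap length per kept fragment (each consensus base counted once); in
consensus mode without overlap restriction, aligned bases with the
overlap counted once; in raw mode, every aligned base.  This makes the
regimes' rates comparable as "retained errors per examined base".

## Channel classification

SBS96/DBS78/ID83 follow the standard scheme definitions.  SBS channels
are pyrimidine-centred (reverse complement taken for purine reference
bases); DBS reference doublets are collapsed onto the ten canonical ones
with the lexicographically smaller alternate chosen for palindromic
references; label strings match COSMIC file headers byte-for-byte.
ID83 assigns type (Del/Ins), length class (1/2/3/4/5+), and a repeat
subtype: for 1 bp events the homopolymer length (including the deleted
base; insertions count pre-existing copies only), for longer events the
tandem repeat-unit count, and for non-repetitive deletions ≥ 2 bp the
flanking microhomology length — the longest exact match between the
deleted sequence's prefix and the 3′ flank or its suffix and the 5′
flank, capped at length − 1.  The microhomology annotation is also
exposed standalone with a configurable labelling threshold (default:
MH length ≥ 1).

A site record contributes one count per site by default; a
`per_fragment` flag weights by the MULTI count instead.  Events whose
context contains a non-ACGT base are tallied as excluded, preserving the
conservation identity `channel sums + exclusions = classified events`.

## Signature refitting

Exposures solve the quadratic program `min ‖c − S·e‖², e ≥ 0` via
Lawson–Hanson active-set NNLS on raw counts; no per-channel weighting is
applied by default (a Poisson inverse-variance variant sits behind
`poisson_weighted=True`).  Weights are exposures over their sum.
Artefact signatures (default: the COSMIC v3.2 "possible sequencing
artefact" list — SBS27, SBS43, SBS45–60; configurable) are then removed
and the remainder renormalised to sum to exactly 1; a sample whose
entire signal was artefactual is flagged `no_signal` with all-zero
weights.  GC-bias background correction, as performed by some refitting
packages, is deliberately not implemented: on the synthetic validation
data the sequencer model has no GC bias, and on real data the correction
belongs to the upstream fitting package's model, not to this method.
Cosine similarity over a signature subset (zero vectors map to 0, never
NaN) and additive signature grouping (e.g. SBS2+SBS13 → APOBEC) support
concordance analyses.

## Detection thresholds

Healthy plasma produces non-zero weights for most signatures (fitting
noise plus genuine clock-like somatic background), so detection is
defined against a healthy panel.  Per signature: drop the single highest
and lowest panel weights (one of each; a flag widens this to two of
each — the conservative trim dampens outliers), clamp values into
[10⁻⁶, 1−10⁻⁶] (exact zeros are common and beta moments are undefined at
the boundary; the shift is negligible at threshold scale), fit
Beta(α, β) by closed-form moment matching with population moments, and
set the threshold to the fitted 99th percentile.  Closed-form MME
replaces iterative refinement because the beta moment equations are
analytic; a fit is declared degenerate when the variance is zero or
within clamping distance of the Bernoulli bound `m(1−m)` (k ≤ 10⁻³), in
which case the threshold falls back to max(trimmed panel) + 0.01.
A signature is detected only on a *strict* exceedance: the threshold is
itself a quantile of "healthy", so equality is non-evidence.  At least
four panel samples are required (two trimmed, two remaining); no
multiple-testing correction is applied across signatures.

## Simulator

Fragments are placed uniformly per contig with lengths
Normal(166, 24) bp truncated to [read length, 500]; 100 bp mates are read
from each end.  Base qualities are drawn i.i.d. from a four-point
profile — Q37 (80%), Q32 (12%), Q22 (5%), Q12 (3%), mean quality ≈ 34.9 —
and a base of quality Q is mis-sequenced with probability 10^(−Q/10)
(uniform wrong base).  This emulates a modern Illumina quality mixture
without claiming any platform's exact per-cycle profile; the achieved
raw error rate (2.44 × 10⁻³/base) and the strict-consensus residual rate
are properties of the profile, so the 1-in-10⁷ benchmark is checked as a
bound, not an exact match.  Indel sequencing errors are not simulated
(substitution error is the quantity the clean-read analysis measures),
and spike-ins cover substitutions only.  Reads are emitted as aligned
records with correct CIGAR/MD by construction, so no aligner runs in the
loop; PCR duplicates and germline variants are likewise out of scope for
the generator.

Spike-in plans size the variant count as `n_vars = r_m/10⁶ · n_genome`,
draw channels multinomially from the target SBS96 profile and sample
matching genome positions (pyrimidine-normalised context, duplicates
forbidden, per-channel exhaustion is an error).  Injection decides
per fragment with the configured allele fraction (default 0.1) and edits
both mates when both cover the site, updating MD.  Downsampling keeps
whole fragments Bernoulli(f); admixture keeps Bernoulli(f_tumour) source
and Bernoulli(f_normal) donor fragments.  Every operation is
bit-reproducible from its seed.

## Desk-scale study designs

The validation experiments (`mmfinder.experiments`) run on a random
single-contig fixture genome (41% GC, the human genome-wide value).
Problem sizes were chosen once as follows:

* **Error-rate benchmark**: ≥ 10⁸ sequenced bases (34 Mb at 3×) in the
  test suite, ≥ 2 × 10⁸ in the acceptance script, so the 10⁻⁷ bound is
  measured with a denominator of ~2–4 × 10⁷ filtered bases.
* **Limit-of-detection designs**: 2 Mb genome at 3×.  Mutation burdens
  are absolute counts — 600 spiked tumour variants at allele fraction
  0.5, and a healthy "aging" background of 400 variants (30/70
  SBS1/SBS5 mixture) at allele fraction 0.1 — keeping per-sample
  catalogue sizes (tens to hundreds of events) in the range a 3 Gb
  genome yields at realistic per-megabase rates, since catalogue size is
  what drives fitting behaviour.  Panels use 8 healthy samples and
  ladders 4 replicates (a scaled-down analogue of 20-replicate designs);
  purity ladders span 1–10%, depth ladders 0.5–3× (the ladder source is
  simulated 10% above the top rung so each target is a genuine
  downsample).
* **Fragmentomics**: tumour fragments Normal(145, 22) vs donor
  Normal(166, 24), selection window 90–150 bp.  The empirical
  size-distribution shift of ctDNA is qualitative here; the experiment
  asserts the direction of the enrichment, not a particular fold-change.

What passing these tests shows — and does not.  The generator produces
ideal alignments: no mapping ambiguity, no indel sequencing error, no
GC-coverage bias, no germline variation, i.i.d. qualities.  Passing
therefore validates the algorithmic contracts (reconstruction,
consensus arithmetic, classification, fitting, thresholds, the
simulation equations) and the direction of the filter effects, but says
nothing about alignment artefacts or platform-specific error structure
in real plasma data, where whitelists and the germline store do the
corresponding work.

## Open design choices

* Germline lookup is allele-specific; a position-level exclusion can be
  emulated by storing all three alternates.  The store format is a VCF
  or 4-column TSV rather than a binary encoding — format compatibility
  is an optimisation, not part of the method.
* Fragment-size windows are explicit configuration (no hidden default in
  the standard config); the fragmentomics experiments use 90–150 bp.
* Catalogues count once per site by default (`per_fragment` available):
  at low coverage MULTI > 1 is rare, and site-level counting avoids
  double-weighting clonal events at higher depth.
* The synthetic signature catalogue emulates canonical process shapes
  (peaked APOBEC/UV columns, flat HRD-like and clock-like columns,
  artefact columns) without copying any published matrix; real
  COSMIC-format TSVs are the intended production input.
* Consensus disagreement quality uses integer floor division
  (`BQ_hi − ⌊BQ_lo/2⌋`); Phred scores are integers throughout.
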