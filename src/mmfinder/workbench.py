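"""End-to-end plumbing: named filter presets, fixture-genome generation,
the error-rate benchmark over nested filter regimes, and the chained
extract -> catalogue -> fit -> call pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from mmfinder.channels import MutationCatalogue, build_catalogue, dict_fetcher
from mmfinder.extract import ExtractionResult, extract_mismatches
from mmfinder.fitting import (
    SignatureCatalogue,
    SignatureWeights,
    drop_artefacts_renormalise,
    fit_weights,
)
from mmfinder.records import FilterConfig, FragmentRecord, GenomicIntervals
from mmfinder.simulate import (
    QualityProfile,
    ReadSimParams,
    measure_error_rate,
    simulate_clean_reads,
)
from mmfinder.thresholds import DetectionThreshold, call_detected


def _preset_none() -> FilterConfig:
    # panel A: no filters, every raw per-read mismatch retained
    return FilterConfig(min_mapq=0, min_bq=0, min_avg_bq=0.0,
                        min_mismatches=1, max_mismatches=10**9,
                        consensus=False)


def _preset_consensus() -> FilterConfig:
    # panel B: read-pair consensus, overlap mismatches only
    cfg = _preset_none()
    cfg.consensus = True
    cfg.only_overlap = True
    return cfg


def _preset_strict() -> FilterConfig:
    # panel C: strict consensus, both mates must agree
    cfg = _preset_consensus()
    cfg.strict_overlap = True
    return cfg


def _preset_strict_high_bq() -> FilterConfig:
    # panel D: strict consensus plus per-read base quality >= 32
    cfg = _preset_strict()
    cfg.min_per_read_bq = 32
    return cfg


def _preset_default() -> FilterConfig:
    return FilterConfig()


#: Named filter regimes; A-D form a strictly nested stack used by the
#: error-rate benchmark, "paper-default" is the tool's standard config.
FILTER_PRESETS: dict[str, Callable[[], FilterConfig]] = {
    "A": _preset_none,
    "B": _preset_consensus,
    "C": _preset_strict,
    "D": _preset_strict_high_bq,
    "paper-default": _preset_default,
}


def get_preset(name: str) -> FilterConfig:
    try:
        return FILTER_PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(FILTER_PRESETS)}")


_PYR_CONTEXTS = [f + m + t for m in "CT" for f in "ACGT" for t in "ACGT"]


def make_fixture_genome(
    length: int = 20_000_000,
    gc: float = 0.41,
    seed: int = 0,
    name: str = "chr1",
    margin: int = 1000,
) -> tuple[dict[str, str], GenomicIntervals]:
    """Random single-contig genome plus a whole-contig whitelist.

    Bases are i.i.d. with the requested GC fraction (default 41%, the
    human genome-wide value); the whitelist covers the contig minus
    ``margin`` bp on each end.  Lengths of 1 Mb and up guarantee all 32
    pyrimidine-centred trinucleotide contexts are represented.  Same seed,
    same genome.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    seq = arr.tobytes().decode("ascii")
    genome = {name: seq}
    whitelist = GenomicIntervals([(name, margin, length - margin)])
    return genome, whitelist


def reproduce_error_rate_table(
    genome: dict[str, str],
    depth: float = 3.0,
    seed: int = 0,
    params: Optional[ReadSimParams] = None,
    presets: Sequence[str] = ("A", "B", "C", "D"),
) -> pd.DataFrame:
    """Per-preset sequencing error rates on error-only simulated reads.

    Simulates one clean read set (re-generated identically per preset from
    the same seed) and reports, for each named filter regime, the retained
    mismatch count, the filtered-base denominator and their ratio.  With
    the nested presets A-D the rates are monotone non-increasing.
    """
    rows = []
    for preset in presets:
        cfg = get_preset(preset)
        frags = simulate_clean_reads(genome, depth, params=params, seed=seed)
        res = extract_mismatches(frags, cfg)
        retained = res.report["retained_fragment_mismatches"]
        bases = res.report["filtered_bases"]
        rows.append({
            "preset": preset,
            "retained_mismatches": retained,
            "filtered_bases": bases,
            "error_rate": measure_error_rate(retained, bases)
            if bases else float("nan"),
        })
    return pd.DataFrame(rows).set_index("preset")


@dataclass
class PipelineResult:
    """Outputs of one extract -> catalogue -> fit -> call run."""

    extraction: ExtractionResult
    catalogue: MutationCatalogue
    raw_weights: SignatureWeights
    weights: SignatureWeights
    calls: Optional[pd.DataFrame] = None
    report: dict = field(default_factory=dict)

    def detected(self) -> set[str]:
        if self.calls is None:
            return set()
        return set(self.calls.index[self.calls["detected"]])


def run_pipeline(
    fragments: Iterable[FragmentRecord],
    reference: dict[str, str] | Callable[[str, int, int], str],
    signatures: SignatureCatalogue,
    config: Optional[FilterConfig] = None,
    thresholds: Optional[dict[str, DetectionThreshold]] = None,
    sample: str = "sample",
    scheme: str = "SBS96",
    artefacts: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Chain extraction, channel classification, signature refitting with
    artefact renormalisation and (when panel thresholds are given)
    signature detection calls.

    ``reference`` is the genome as a {chrom: sequence} dict or a
    ``fetch(chrom, start0, end0)`` accessor.  The run report merges the
    extraction tallies with catalogue totals and fit diagnostics.
    """
    fetch = reference if callable(reference) else dict_fetcher(reference)

    def ref_base(chrom: str, pos1: int) -> str:
        return fetch(chrom, pos1 - 1, pos1)

    result = extract_mismatches(fragments, config=config, reference=ref_base)
    catalogue = build_catalogue(result.sites, fetch, sample=sample)
    raw = fit_weights(catalogue.counts[scheme], signatures, sample=sample)
    weights = drop_artefacts_renormalise(
        raw, artefacts if artefacts is not None else signatures.artefacts)
    calls = None
    if thresholds is not None:
        calls = call_detected(weights.weights, thresholds,
                              signatures=sorted(thresholds))
    report = dict(result.report)
    report.update({
        "sample": sample,
        "catalogue_totals": {s: catalogue.total(s) for s in catalogue.counts},
        "catalogue_excluded": dict(catalogue.excluded),
        "fitted_total": weights.fitted_total,
        "residual": weights.residual,
        "no_signal": weights.no_signal,
    })
    return PipelineResult(
        extraction=result, catalogue=catalogue, raw_weights=raw,
        weights=weights, calls=calls, report=report)
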