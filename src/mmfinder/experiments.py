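"""Desk-scale limit-of-detection experiment designs.

These functions wire the simulator, extraction and inference stages into
the validation experiments used throughout the package: a healthy-plasma
panel with its detection thresholds, tumour-purity dilution ladders,
sequencing-depth ladders and the fragment-size-selection comparison.

Scaling note: the experiments run on a miniature fixture genome (default
2 Mb) instead of a 3 Gb human genome.  Mutation burdens are therefore
specified as absolute variant counts chosen to keep per-sample *catalogue
sizes* realistic (hundreds of somatic events per genome), which is what
drives signature fitting; the per-megabase rates on the miniature genome
are correspondingly higher than any human tumour's.  Healthy plasma is
modelled as clean reads plus a low-frequency "aging" background (a 30/70
SBS1/SBS5 mixture at 10% allele fraction), since normal cfDNA carries
clock-like somatic mutations rather than none at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mmfinder.fitting import SignatureCatalogue
from mmfinder.records import FilterConfig, FragmentRecord
from mmfinder.signatures_synthetic import synthetic_sbs_catalogue
from mmfinder.simulate import (
    AdmixtureSpec,
    DownsampleSpec,
    ReadSimParams,
    admix,
    downsample,
    inject_variants,
    plan_spike_in,
    simulate_clean_reads,
)
from mmfinder.thresholds import DetectionThreshold, fit_thresholds
from mmfinder.workbench import make_fixture_genome, run_pipeline


@dataclass
class StudyDesign:
    """Shared parameters of the desk-scale validation experiments."""

    genome_length: int = 2_000_000
    depth: float = 3.0
    # healthy background: absolute variant count and allele fraction of the
    # clock-like (SBS1/SBS5) mixture present in normal cfDNA
    healthy_burden: int = 400
    healthy_af: float = 0.1
    # tumour signal: absolute spiked variant count and (clonal) allele
    # fraction in the pure-tumour source sample
    tumour_burden: int = 600
    tumour_af: float = 0.5
    panel_size: int = 8
    replicates: int = 4
    signatures: SignatureCatalogue = field(
        default_factory=synthetic_sbs_catalogue)
    config: FilterConfig = field(default_factory=FilterConfig)

    def genome(self, seed: int):
        return make_fixture_genome(length=self.genome_length, seed=seed)[0]

    def aging_profile(self) -> pd.Series:
        s = (0.3 * self.signatures.matrix["SBS1"]
             + 0.7 * self.signatures.matrix["SBS5"])
        s.name = "aging"
        return s

    def _spiked(self, genome, profile: pd.Series, n_vars: int, af: float,
                seed: int, params: Optional[ReadSimParams] = None,
                ) -> list[FragmentRecord]:
        frags = list(simulate_clean_reads(
            genome, self.depth, params=params, seed=seed))
        if n_vars == 0:
            return frags
        r_m = n_vars / sum(len(s) for s in genome.values()) * 1e6
        plan = plan_spike_in(profile, r_m, genome, seed=seed + 1,
                             allele_frequency=af)
        return inject_variants(frags, plan, seed=seed + 2)[0]

    def healthy_fragments(self, genome, seed: int,
                          params: Optional[ReadSimParams] = None,
                          ) -> list[FragmentRecord]:
        """One healthy-plasma read set: errors plus the aging background."""
        return self._spiked(genome, self.aging_profile(),
                            self.healthy_burden, self.healthy_af, seed,
                            params=params)

    def tumour_fragments(self, genome, signature: str, seed: int,
                         params: Optional[ReadSimParams] = None,
                         ) -> list[FragmentRecord]:
        """A pure-tumour source read set carrying one spiked signature."""
        return self._spiked(genome, self.signatures.matrix[signature],
                            self.tumour_burden, self.tumour_af, seed,
                            params=params)


def build_healthy_panel(
    design: StudyDesign,
    genome,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, DetectionThreshold]]:
    """Simulate the healthy panel, fit weights per sample, and derive
    per-signature detection thresholds."""
    rows = []
    for i in range(design.panel_size):
        frags = design.healthy_fragments(genome, seed + 101 * i)
        res = run_pipeline(frags, genome, design.signatures,
                           config=design.config, sample=f"healthy{i}")
        rows.append(res.weights.weights)
    panel = pd.DataFrame(rows)
    return panel, fit_thresholds(panel)


def purity_ladder(
    design: StudyDesign,
    genome,
    signature: str,
    thresholds: dict[str, DetectionThreshold],
    purities: Sequence[float] = (0.01, 0.03, 0.10),
    seed: int = 0,
    source_purity: float = 1.0,
) -> pd.DataFrame:
    """Detection frequency and weights of a spiked signature across
    tumour-purity admixtures at fixed depth.

    Returns one row per purity with the replicate weights, the detection
    frequency and the median weight.
    """
    source = design.tumour_fragments(genome, signature, seed + 11)
    donor = design.healthy_fragments(genome, seed + 23)
    rows = []
    for pi, p_t in enumerate(purities):
        weights, detected = [], 0
        for rep in range(design.replicates):
            spec = AdmixtureSpec(
                p_s=source_purity, p_t=p_t, n_s=len(source), n_d=len(donor),
                seed=seed + 1000 * pi + rep)
            mix = admix(source, donor, spec)
            res = run_pipeline(mix, genome, design.signatures,
                               config=design.config, thresholds=thresholds,
                               sample=f"p{p_t}_r{rep}")
            w = float(res.weights.weights[signature])
            weights.append(w)
            detected += int(signature in res.detected())
        rows.append({
            "purity": p_t,
            "detection_frequency": detected / design.replicates,
            "median_weight": float(np.median(weights)),
            "weights": weights,
        })
    return pd.DataFrame(rows).set_index("purity")


def depth_ladder(
    design: StudyDesign,
    genome,
    signature: str,
    thresholds: dict[str, DetectionThreshold],
    depths: Sequence[float] = (0.5, 1.5, 3.0),
    purity: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection frequency across sequencing depths at fixed purity.

    The source admixture is simulated 10% above the highest target depth
    so every rung is a genuine downsample, then reduced per target depth
    and replicate (fresh Bernoulli seed per replicate, as in repeated
    downsampling of one source dataset).
    """
    import dataclasses

    deep = dataclasses.replace(design, depth=max(depths) * 1.1)
    source = deep.tumour_fragments(genome, signature, seed + 11)
    donor = deep.healthy_fragments(genome, seed + 23)
    n_genome = sum(len(s) for s in genome.values())
    rows = []
    for di, depth_t in enumerate(depths):
        weights, detected = [], 0
        for rep in range(design.replicates):
            spec = AdmixtureSpec(
                p_s=1.0, p_t=purity, n_s=len(source), n_d=len(donor),
                seed=seed + 7000 + rep)
            mix = admix(source, donor, spec)
            n_reads = sum(2 if f.r2 is not None else 1 for f in mix)
            dspec = DownsampleSpec(
                depth_t=depth_t, len_read=100, n_reads=n_reads,
                n_genome=n_genome, seed=seed + 100 * di + rep)
            sub = downsample(mix, dspec)
            res = run_pipeline(sub, genome, design.signatures,
                               config=design.config, thresholds=thresholds,
                               sample=f"d{depth_t}_r{rep}")
            w = float(res.weights.weights[signature])
            weights.append(w)
            detected += int(signature in res.detected())
        rows.append({
            "depth": depth_t,
            "detection_frequency": detected / design.replicates,
            "median_weight": float(np.median(weights)),
            "weights": weights,
        })
    return pd.DataFrame(rows).set_index("depth")


def fragmentomics_comparison(
    design: StudyDesign,
    genome,
    signature: str,
    seed: int = 0,
    purity: float = 0.10,
    windows: Sequence[tuple[int, int]] = ((90, 150),),
    tumour_params: Optional[ReadSimParams] = None,
    donor_params: Optional[ReadSimParams] = None,
) -> pd.DataFrame:
    """Fitted target-signature weight with and without the fragment-size
    filter, on an admixture where tumour fragments are shorter.

    Tumour-derived cfDNA fragments run shorter than those of healthy
    cells; selecting size windows enriched for short fragments should
    therefore raise the fitted weight of the tumour signature.  Defaults:
    tumour fragments Normal(145, 22) bp, donor Normal(166, 24) bp, windows
    90-150 bp.
    """
    if tumour_params is None:
        tumour_params = ReadSimParams(fragment_mean=145.0, fragment_sd=22.0)
    if donor_params is None:
        donor_params = ReadSimParams()
    source = design.tumour_fragments(genome, signature, seed + 11,
                                     params=tumour_params)
    donor = design.healthy_fragments(genome, seed + 23, params=donor_params)
    rows = []
    for rep in range(design.replicates):
        spec = AdmixtureSpec(p_s=1.0, p_t=purity, n_s=len(source),
                             n_d=len(donor), seed=seed + 500 + rep)
        mix = admix(source, donor, spec)
        for filtered in (False, True):
            cfg = design.config.evolve(
                fragment_windows=list(windows) if filtered else None)
            res = run_pipeline(mix, genome, design.signatures, config=cfg,
                               sample=f"rep{rep}")
            rows.append({
                "replicate": rep,
                "size_filtered": filtered,
                "weight": float(res.weights.weights[signature]),
                "catalogue_total": res.catalogue.total("SBS96"),
            })
    return pd.DataFrame(rows)
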