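"""Synthetic signature catalogues for simulation and testing.

These matrices are *synthetic* stand-ins constructed in code: each column
emulates the qualitative shape of a well-known mutational process (APOBEC
deamination, UV dipyrimidine damage, the flat homologous-recombination-
deficiency profile, clock-like deamination, and a couple of library-
preparation artefact profiles) without reproducing any published matrix
entry-by-entry.  Column names follow the standard signature nomenclature
so that code written against these catalogues runs unchanged against a
real COSMIC-format TSV loaded with
:meth:`mmfinder.fitting.SignatureCatalogue.from_tsv`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmfinder.channels import dbs78_labels, id83_labels, sbs96_labels
from mmfinder.fitting import DEFAULT_ARTEFACTS, SignatureCatalogue


def _profile(labels: list[str], peaks: dict[str, float],
             background: float = 0.0, tilt: np.ndarray | None = None
             ) -> np.ndarray:
    """Column with ``peaks`` mass on named channels and the remainder
    spread (optionally tilted) over all channels."""
    idx = {c: i for i, c in enumerate(labels)}
    col = np.zeros(len(labels))
    for ch, w in peaks.items():
        col[idx[ch]] += w
    rest = 1.0 - sum(peaks.values())
    if rest > 0:
        base = np.ones(len(labels)) if tilt is None else tilt
        col += rest * base / base.sum()
    col += background
    return col / col.sum()


def synthetic_sbs_catalogue() -> SignatureCatalogue:
    """Synthetic SBS96 catalogue with peaked, flat and artefact columns."""
    labels = sbs96_labels()
    k = np.arange(96)

    def spread(chs: list[str], total: float) -> dict[str, float]:
        return {c: total / len(chs) for c in chs}

    cpg = [f"{f}[C>T]G" for f in "ACGT"]
    tcn_ct = [f"T[C>T]{t}" for t in "ACGT"]
    tcn_cg = [f"T[C>G]{t}" for t in "ACGT"]
    dipyr_ct = [f"{f}[C>T]{t}" for f in "CT" for t in "ACGT"]
    nca = [f"{f}[C>A]A" for f in "ACGT"] + [f"{f}[C>A]T" for f in "ACGT"]
    tta = [f"{f}[T>C]{t}" for f in "AT" for t in "ACGT"]

    cols = {
        # clock-like CpG deamination
        "SBS1": _profile(labels, spread(cpg, 0.80)),
        # APOBEC C>T at TpC
        "SBS2": _profile(labels, spread(tcn_ct, 0.85)),
        # flat HRD-like profile with gentle structure
        "SBS3": _profile(labels, {}, tilt=1.0 + 0.25 * np.sin(k / 5.0)),
        # flat clock-like profile, tilted differently from SBS3
        "SBS5": _profile(labels, spread(tta, 0.25),
                         tilt=1.0 + 0.3 * np.cos(k / 7.0)),
        # UV damage: C>T at dipyrimidines
        "SBS7a": _profile(labels, spread(dipyr_ct, 0.88)),
        # APOBEC C>G at TpC
        "SBS13": _profile(labels, spread(tcn_cg, 0.85)),
        # reactive-oxygen-like C>A
        "SBS18": _profile(labels, spread(nca, 0.65)),
        # artefact-like profiles (flagged via DEFAULT_ARTEFACTS)
        "SBS45": _profile(labels, spread([f"{f}[C>A]C" for f in "ACGT"], 0.7)),
        "SBS52": _profile(labels, spread([f"{f}[T>C]G" for f in "ACGT"], 0.6),
                          tilt=1.0 + 0.2 * np.sin(k / 3.0)),
    }
    df = pd.DataFrame(cols, index=pd.Index(labels, name="Type"))
    return SignatureCatalogue(matrix=df, artefacts=DEFAULT_ARTEFACTS)


def synthetic_dbs_catalogue() -> SignatureCatalogue:
    """Synthetic DBS78 catalogue (UV CC>TT, platinum-like CT>AA, flat)."""
    labels = dbs78_labels()
    cols = {
        "DBS1": _profile(labels, {"CC>TT": 0.85}),
        "DBS5": _profile(labels, {"CT>AA": 0.45, "CT>AC": 0.25}),
        "DBS_flat": _profile(labels, {}),
    }
    df = pd.DataFrame(cols, index=pd.Index(labels, name="Type"))
    return SignatureCatalogue(matrix=df, artefacts=())


def synthetic_id_catalogue() -> SignatureCatalogue:
    """Synthetic ID83 catalogue (slippage ID1/ID2, microhomology ID6)."""
    labels = id83_labels()
    mh = {c: 0.75 / 11 for c in labels if ":Del:M:" in c}
    cols = {
        "ID1": _profile(labels, {"1:Ins:T:4": 0.4, "1:Ins:T:5": 0.4}),
        "ID2": _profile(labels, {"1:Del:T:4": 0.4, "1:Del:T:5": 0.4}),
        "ID6": _profile(labels, mh),
        "ID_flat": _profile(labels, {}),
    }
    df = pd.DataFrame(cols, index=pd.Index(labels, name="Type"))
    return SignatureCatalogue(matrix=df, artefacts=())
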