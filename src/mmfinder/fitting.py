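"""Signature refitting: non-negative least squares against a fixed
catalogue, artefact removal with renormalisation, and signature-set
comparison utilities.

Given a channel count vector c and a column-stochastic signature matrix S,
exposures e solve min ||c - S e||^2 subject to e >= 0 (a quadratic
program, solved by Lawson-Hanson active-set NNLS).  Weights are exposures
normalised to sum to one; after removing signatures attributed to
sequencing/library-preparation artefacts the remaining weights are
renormalised so each sample again sums to one.

No per-channel variance weighting or GC-bias background correction is
applied: the fit is plain least squares on raw counts (a Poisson-weighted
variant is available via ``poisson_weighted=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

# COSMIC v3.2 signatures flagged as "possible sequencing artefact"
DEFAULT_ARTEFACTS: tuple[str, ...] = (
    "SBS27", "SBS43", "SBS45", "SBS46", "SBS47", "SBS48", "SBS49", "SBS50",
    "SBS51", "SBS52", "SBS53", "SBS54", "SBS55", "SBS56", "SBS57", "SBS58",
    "SBS59", "SBS60",
)


@dataclass
class SignatureCatalogue:
    """A channels x signatures reference matrix (each column sums to 1)."""

    matrix: pd.DataFrame
    artefacts: tuple[str, ...] = DEFAULT_ARTEFACTS

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy(dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("signature matrix has negative entries")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            bad = self.matrix.columns[np.abs(sums - 1.0) > 1e-8].tolist()
            raise ValueError(f"signature columns do not sum to 1: {bad}")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def channels(self) -> list[str]:
        return list(self.matrix.index)

    def artefact_names(self) -> list[str]:
        return [s for s in self.names if s in set(self.artefacts)]

    @classmethod
    def from_tsv(cls, path: str | Path,
                 artefacts: Sequence[str] = DEFAULT_ARTEFACTS,
                 ) -> "SignatureCatalogue":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.astype(float), artefacts=tuple(artefacts))

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t")


@dataclass
class SignatureWeights:
    """Per-sample non-negative signature exposure fractions.

    ``weights`` sum to 1 whenever any weight is positive; ``fitted_total``
    is the summed raw exposure (approximately the fitted mutation count);
    ``residual`` is the Euclidean norm of the unexplained counts.
    """

    sample: str
    weights: pd.Series
    fitted_total: float = 0.0
    residual: float = 0.0
    no_signal: bool = False

    def subset(self, names: Sequence[str]) -> np.ndarray:
        return self.weights.reindex(names, fill_value=0.0).to_numpy(dtype=float)


def fit_weights(
    counts: pd.Series,
    signatures: SignatureCatalogue,
    sample: Optional[str] = None,
    poisson_weighted: bool = False,
) -> SignatureWeights:
    """Fit non-negative signature exposures to a channel count vector.

    ``counts`` must be indexed by the same channel labels as the signature
    matrix (order-insensitive).  An all-zero catalogue yields all-zero
    weights flagged ``no_signal`` rather than an error.
    """
    S = signatures.matrix
    missing = S.index.difference(counts.index)
    if len(missing):
        raise ValueError(
            f"count vector lacks {len(missing)} channels, e.g. {missing[0]!r}")
    c = counts.reindex(S.index).to_numpy(dtype=float)
    name = sample if sample is not None else (counts.name or "sample")
    total = c.sum()
    if total <= 0:
        w = pd.Series(0.0, index=S.columns, name=name)
        return SignatureWeights(sample=str(name), weights=w, no_signal=True)
    A = S.to_numpy(dtype=float)
    b = c
    if poisson_weighted:
        # inverse-variance weighting under a Poisson error model
        sd = np.sqrt(np.maximum(c, 1.0))
        A = A / sd[:, None]
        b = c / sd
    exposures, rnorm = nnls(A, b)
    esum = exposures.sum()
    weights = exposures / esum if esum > 0 else exposures
    w = pd.Series(weights, index=S.columns, name=name)
    return SignatureWeights(
        sample=str(name), weights=w, fitted_total=float(esum),
        residual=float(rnorm), no_signal=bool(esum == 0))


def drop_artefacts_renormalise(
    fit: SignatureWeights,
    artefacts: Optional[Iterable[str]] = None,
) -> SignatureWeights:
    """Remove artefact-flagged signatures and renormalise to sum 1.

    When every remaining weight is zero the sample is flagged
    ``no_signal`` and all weights stay zero.
    """
    if artefacts is None:
        artefacts = DEFAULT_ARTEFACTS
    drop = [s for s in fit.weights.index if s in set(artefacts)]
    kept = fit.weights.drop(labels=drop)
    total = float(kept.sum())
    if total > 0:
        kept = kept / total
        no_signal = False
    else:
        kept = kept * 0.0
        no_signal = True
    return SignatureWeights(
        sample=fit.sample, weights=kept, fitted_total=fit.fitted_total,
        residual=fit.residual, no_signal=no_signal)


def cosine_similarity(a, b, subset: Optional[Sequence[str]] = None) -> float:
    """Cosine similarity between two weight vectors, 0.0 when either is
    all-zero (defined, never NaN).

    Accepts pandas Series (aligned on ``subset`` or on their common order)
    or plain arrays of equal length.
    """
    if subset is not None:
        a = pd.Series(a).reindex(subset, fill_value=0.0)
        b = pd.Series(b).reindex(subset, fill_value=0.0)
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("vectors must have equal length")
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def group_signatures(
    weights: pd.Series,
    grouping: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Sum member signatures into named groups (e.g. SBS2+SBS13 -> APOBEC).

    Signatures not covered by any group pass through unchanged; a signature
    in two groups is a configuration error.  Total weight is conserved.
    """
    seen: set[str] = set()
    for group, members in grouping.items():
        for m in members:
            if m in seen:
                raise ValueError(f"signature {m} appears in multiple groups")
            seen.add(m)
    out: dict[str, float] = {}
    for group, members in grouping.items():
        out[group] = float(weights.reindex(members, fill_value=0.0).sum())
    for name, value in weights.items():
        if name not in seen:
            out[str(name)] = float(value)
    return pd.Series(out, name=weights.name)


def write_weights_tsv(fits: Sequence[SignatureWeights], path: str | Path) -> None:
    """Sample x signature weight table with fitted-total/residual columns."""
    rows = []
    for f in fits:
        row = f.weights.to_dict()
        row["fitted_total"] = f.fitted_total
        row["residual"] = f.residual
        rows.append(pd.Series(row, name=f.sample))
    pd.DataFrame(rows).rename_axis("sample").to_csv(path, sep="\t")


def read_weights_tsv(path: str | Path) -> pd.DataFrame:
    """Read a sample x signature weight table (extra columns dropped)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.drop(columns=[c for c in ("fitted_total", "residual")
                            if c in df.columns])
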