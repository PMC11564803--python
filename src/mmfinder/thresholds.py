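"""Per-signature detection thresholds from a healthy-plasma panel.

Healthy cell-free DNA carries a background of every signature (fitting
noise plus normal somatic mutations), so a signature is only called in a
sample when its weight exceeds what healthy plasma can plausibly produce.
For each signature the panel's weights are trimmed of their single highest
and lowest values (a conservative fit that dampens outliers), a beta
distribution is fitted by closed-form moment matching, and the fitted
distribution's 99th percentile becomes the detection threshold.  A sample
weight strictly above the threshold is a detection; equality is treated as
non-evidence because the threshold itself is a quantile of "healthy".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

# weights are clamped away from {0, 1} before fitting: exact zeros are
# common and beta moments are undefined at the boundary
CLAMP = 1e-6
# additive floor over the panel maximum used when the moment fit degenerates
DEGENERATE_FLOOR = 0.01


class PanelTooSmallError(ValueError):
    """Fewer panel samples than the trimming scheme requires."""


class MissingThresholdError(KeyError):
    """A queried signature has no fitted threshold."""


@dataclass(slots=True)
class DetectionThreshold:
    """Fitted beta parameters and the 99th-quantile cut-off for one
    signature; ``degenerate`` marks fits that fell back to the empirical
    max-plus-floor rule."""

    signature: str
    alpha: float
    beta: float
    threshold: float
    n_panel: int
    degenerate: bool = False


def trim_panel(values: Sequence[float], n_trim_each: int = 1) -> np.ndarray:
    """Drop the ``n_trim_each`` highest and lowest panel weights.

    Default removes exactly one maximum and one minimum (two samples);
    ties are broken by first occurrence.  Requires at least
    ``2*n_trim_each + 2`` values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2 * n_trim_each + 2:
        raise PanelTooSmallError(
            f"need >= {2 * n_trim_each + 2} panel samples, got {vals.size}")
    keep = np.ones(vals.size, dtype=bool)
    order = np.argsort(vals, kind="stable")
    keep[order[:n_trim_each]] = False
    keep[order[-n_trim_each:]] = False
    return vals[keep]


def fit_beta_mme(values: Sequence[float],
                 clamp: float = CLAMP) -> tuple[float, float, bool]:
    """Closed-form moment-matching beta fit.

    With sample mean m and (population) variance v the estimates are
    ``alpha = m*k`` and ``beta = (1-m)*k`` where ``k = m(1-m)/v - 1``.
    Returns ``(alpha, beta, degenerate)``; the fit is degenerate when the
    variance is zero or ``k <= 0`` (variance at or beyond the Bernoulli
    bound m(1-m)).
    """
    vals = np.clip(np.asarray(values, dtype=float), clamp, 1.0 - clamp)
    m = float(vals.mean())
    v = float(vals.var())  # ddof=0: classical moment matching
    if v <= 0.0:
        return float("nan"), float("nan"), True
    k = m * (1.0 - m) / v - 1.0
    # k at (or within clamping distance of) the Bernoulli bound means the
    # data are two-point-like and no proper beta fits
    if k <= 1e-3:
        return float("nan"), float("nan"), True
    return m * k, (1.0 - m) * k, False


def threshold_q99(alpha: float, beta: float, q: float = 0.99) -> float:
    """Inverse regularised incomplete beta at the detection quantile."""
    if not (alpha > 0 and beta > 0):
        raise ValueError("beta shape parameters must be positive")
    return float(beta_dist.ppf(q, alpha, beta))


def fit_threshold(
    signature: str,
    panel_weights: Sequence[float],
    n_trim_each: int = 1,
    q: float = 0.99,
) -> DetectionThreshold:
    """Trim, fit and derive the detection threshold for one signature.

    Degenerate moment fits (zero or boundary variance) fall back to the
    empirical rule max(trimmed panel) + 0.01, capped below 1.
    """
    trimmed = trim_panel(panel_weights, n_trim_each=n_trim_each)
    alpha, b, degenerate = fit_beta_mme(trimmed)
    if degenerate:
        thr = min(float(np.max(trimmed)) + DEGENERATE_FLOOR, 1.0 - 1e-9)
        return DetectionThreshold(
            signature=signature, alpha=float("nan"), beta=float("nan"),
            threshold=thr, n_panel=trimmed.size, degenerate=True)
    return DetectionThreshold(
        signature=signature, alpha=alpha, beta=b,
        threshold=threshold_q99(alpha, b, q=q),
        n_panel=trimmed.size, degenerate=False)


def fit_thresholds(
    panel: pd.DataFrame,
    n_trim_each: int = 1,
    q: float = 0.99,
    signatures: Optional[Sequence[str]] = None,
) -> dict[str, DetectionThreshold]:
    """Fit detection thresholds for every signature column of a panel
    weight matrix (samples x signatures)."""
    names = list(signatures) if signatures is not None else list(panel.columns)
    return {s: fit_threshold(s, panel[s].to_numpy(), n_trim_each=n_trim_each,
                             q=q)
            for s in names}


def call_detected(
    sample_weights: pd.Series,
    thresholds: dict[str, DetectionThreshold],
    signatures: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Call signatures whose weight strictly exceeds the panel threshold.

    Returns a table (signature, weight, threshold, margin, detected).
    Querying a signature without a fitted threshold raises
    :class:`MissingThresholdError` rather than silently skipping it.
    """
    names = list(signatures) if signatures is not None else \
        list(sample_weights.index)
    rows = []
    for s in names:
        if s not in thresholds:
            raise MissingThresholdError(s)
        w = float(sample_weights.get(s, 0.0))
        thr = thresholds[s].threshold
        rows.append({"signature": s, "weight": w, "threshold": thr,
                     "margin": w - thr, "detected": w > thr})
    return pd.DataFrame(rows).set_index("signature")


def thresholds_to_tsv(thresholds: dict[str, DetectionThreshold],
                      path: str | Path) -> None:
    rows = [{"signature": t.signature, "alpha": t.alpha, "beta": t.beta,
             "q99": t.threshold, "n": t.n_panel, "degenerate": t.degenerate}
            for t in thresholds.values()]
    pd.DataFrame(rows).set_index("signature").to_csv(path, sep="\t")


def thresholds_from_tsv(path: str | Path) -> dict[str, DetectionThreshold]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {
        str(s): DetectionThreshold(
            signature=str(s), alpha=float(r["alpha"]), beta=float(r["beta"]),
            threshold=float(r["q99"]), n_panel=int(r["n"]),
            degenerate=bool(r["degenerate"]))
        for s, r in df.iterrows()
    }
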