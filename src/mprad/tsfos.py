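"""Tissue signature first-order statistics (TSFOS).

All channels' in-ROI intensities are pooled into one histogram (the tissue
signature histogram, TSH) of B equally spaced bins, from which histogram
features are computed.  Pooling across channels is what distinguishes TSFOS
from ordinary per-channel first-order radiomics: for series whose channels
share a physical scale (DWI b-values, DCE frames) the pooled histogram
captures the inter-parametric intensity relationship directly.

Two pooling modes are provided: ``raw`` bins the raw intensities over the
global pooled min–max (appropriate for intrinsically co-scaled series), and
``normalized`` first rescales each channel to [0, 1] over the ROI so
channels with incommensurate units contribute comparably.

All moments are computed on bin centers weighted by bin probabilities, so
every feature is strictly a function of the TSH.  Entropy uses log base 2.
Kurtosis is the plain (non-excess) fourth standardized moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MultiparametricVolume, ROIMask, _check_finite

__all__ = ["TSHistogram", "build_tsh", "tsfos_features"]


@dataclass(frozen=True)
class TSHistogram:
    """Pooled intensity histogram: B+1 equally spaced edges, B probabilities."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if len(edges) != len(probs) + 1:
            raise ValueError("need B+1 edges for B probabilities")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)

    @property
    def B(self) -> int:
        return len(self.probabilities)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_tsh(
    mpv: MultiparametricVolume,
    roi: ROIMask,
    B: int = 128,
    pooling: str = "raw",
) -> TSHistogram:
    """Pool all N * |ROI| intensity samples into one B-bin histogram.

    ``raw`` spans the global pooled min–max; ``normalized`` rescales each
    channel to [0, 1] over the ROI before pooling (edges span [0, 1]).
    A degenerate pooled range (all samples equal) yields a unit-width bin
    grid centered on the common value, with all mass in one bin.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    roi.require_nonempty()
    if roi.mask.shape != mpv.shape:
        raise ValueError("mask shape must equal channel shape")
    samples = []
    for ch in mpv.channels:
        _check_finite(ch)
        vals = ch[roi.mask].astype(float)
        if pooling == "normalized":
            lo, hi = vals.min(), vals.max()
            vals = np.zeros_like(vals) if hi <= lo else (vals - lo) / (hi - lo)
        elif pooling != "raw":
            raise ValueError(f"unknown pooling {pooling!r}")
        samples.append(vals)
    pooled = np.concatenate(samples)
    if pooling == "normalized":
        lo, hi = 0.0, 1.0
    else:
        lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(pooled, bins=B, range=(lo, hi))
    return TSHistogram(bin_edges=edges, probabilities=counts / counts.sum())


def tsfos_features(tsh: TSHistogram) -> dict[str, float]:
    """Histogram features of a TSH.

    Returns entropy (bits), uniformity, energy (alias of uniformity — both
    names are in common use for ``sum p**2`` and are reported once each),
    and the probability-weighted moments mean, variance, skewness and
    kurtosis on bin centers.  Zero-variance histograms report skewness and
    kurtosis of 0 by convention.
    """
    p = tsh.probabilities
    c = tsh.bin_centers
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    uniformity = float(np.sum(p * p))
    mean = float(np.sum(p * c))
    var = float(np.sum(p * (c - mean) ** 2))
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.sum(p * ((c - mean) / sd) ** 3))
        kurt = float(np.sum(p * ((c - mean) / sd) ** 4))
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "entropy": entropy,
        "uniformity": uniformity,
        "energy": uniformity,
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
    }
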