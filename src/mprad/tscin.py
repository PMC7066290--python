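"""Tissue signature complex-interaction network (TSCIN) features.

Where TSPM/TSCM compare signatures *between* voxels, TSCIN looks *within*
one voxel's signature — the length-N vector of intensities across channels:

* first-order TSCIN: any chosen statistic (entropy, mean, std, max, min,
  range, median, median absolute deviation, skewness, kurtosis) evaluated
  on the signature vector independently at each region voxel, producing a
  feature map;
* second-order TSCIN: the tissue signature relationship matrix (TSRM) —
  a within-voxel co-occurrence of quantized intensities at channel
  positions k and k + d, sensitive to the ordering of the series (DCE
  frames, b-values), from which the full Haralick set is extracted.

First-order statistics operate on [0, 1]-normalized intensities so max and
range are scale-free unit-interval quantities comparable across channels;
dispersion statistics use the population (1/N) convention and kurtosis is
the plain (non-excess) fourth standardized moment.  The TSRM is kept
*ordered* (not symmetrized) because parameter sequences are directional.
Feature maps are summarized to one scalar per region by mean, median, or
standard deviation.
"""

from __future__ import annotations

import numpy as np

from .core import (
    FeatureMapStack,
    MultiparametricVolume,
    ROIMask,
    TissueSignature,
)
from .tscm import CooccurrenceMatrix, haralick_features

__all__ = [
    "TSCIN_STATS",
    "tscin_first_order",
    "build_tsrm",
    "tsrm_features",
    "tsrm_feature_maps",
    "summarize_map",
]

TSCIN_STATS = (
    "entropy",
    "mean",
    "std",
    "max",
    "min",
    "range",
    "median",
    "median_abs_deviation",
    "skewness",
    "kurtosis",
)

_DISPERSION = {"std", "range", "median_abs_deviation", "skewness", "kurtosis",
               "entropy"}


def _signature_entropy(sig: np.ndarray, b_sig: int) -> np.ndarray:
    """Histogram entropy of each column of ``sig`` ((N, M) -> (M,)), bits."""
    n, m = sig.shape
    bins = np.clip((sig * b_sig).astype(np.int64), 0, b_sig - 1)
    flat = bins + b_sig * np.arange(m)[None, :]
    counts = np.bincount(flat.ravel(), minlength=b_sig * m).reshape(m, b_sig)
    p = counts / n
    safe = np.where(p > 0, p, 1.0)
    return -(p * np.log2(safe)).sum(axis=1)


def tscin_first_order(
    mpv_normalized: MultiparametricVolume,
    roi: ROIMask,
    stats: tuple[str, ...] = TSCIN_STATS,
    b_sig: int = 8,
) -> FeatureMapStack:
    """Per-voxel first-order statistics of the signature vector.

    ``mpv_normalized`` must hold [0, 1]-normalized channels (see
    :func:`mprad.core.normalize_channels`).  Entropy is computed on a
    fixed-bin histogram of the N signature values (``b_sig`` bins over
    [0, 1]), so it is bounded by ``log2(b_sig)``.  Voxels outside the
    region are set to 0 in every map.
    """
    roi.require_nonempty()
    if roi.mask.shape != mpv_normalized.shape:
        raise ValueError("mask shape must equal channel shape")
    n = mpv_normalized.n_channels
    bad = [s for s in stats if s not in TSCIN_STATS]
    if bad:
        raise ValueError(f"unknown TSCIN statistics: {bad}")
    if n < 2 and any(s in _DISPERSION for s in stats):
        raise ValueError("dispersion statistics require N >= 2 channels")
    sig = mpv_normalized.stack()[:, roi.mask]  # (N, M)
    if sig.size and (sig.min() < -1e-9 or sig.max() > 1 + 1e-9):
        raise ValueError("channels must be normalized to [0, 1] first")
    values: dict[str, np.ndarray] = {}
    mean = sig.mean(axis=0)
    if "mean" in stats:
        values["mean"] = mean
    if "std" in stats or "skewness" in stats or "kurtosis" in stats:
        centered = sig - mean
        var = np.mean(centered**2, axis=0)  # population convention
        std = np.sqrt(var)
        if "std" in stats:
            values["std"] = std
        if "skewness" in stats or "kurtosis" in stats:
            safe = np.where(std > 0, std, 1.0)
            z = centered / safe
            if "skewness" in stats:
                values["skewness"] = np.where(std > 0, np.mean(z**3, axis=0), 0.0)
            if "kurtosis" in stats:
                values["kurtosis"] = np.where(std > 0, np.mean(z**4, axis=0), 0.0)
    if "max" in stats:
        values["max"] = sig.max(axis=0)
    if "min" in stats:
        values["min"] = sig.min(axis=0)
    if "range" in stats:
        values["range"] = sig.max(axis=0) - sig.min(axis=0)
    if "median" in stats or "median_abs_deviation" in stats:
        med = np.median(sig, axis=0)
        if "median" in stats:
            values["median"] = med
        if "median_abs_deviation" in stats:
            values["median_abs_deviation"] = np.median(np.abs(sig - med), axis=0)
    if "entropy" in stats:
        values["entropy"] = _signature_entropy(sig, b_sig)
    maps = {}
    for name in stats:
        m = np.zeros(mpv_normalized.shape, dtype=float)
        m[roi.mask] = values[name]
        maps[name] = m
    return FeatureMapStack(
        maps=maps,
        provenance={"family": "tscin_first_order", "b_sig": b_sig, "N": n},
    )


def build_tsrm(
    signature: TissueSignature | np.ndarray,
    d: int,
    G: int,
    normalized: bool = False,
) -> CooccurrenceMatrix:
    """Tissue signature relationship matrix of one quantized signature.

    Cell ``(i, j)`` counts parameter positions k (k = 1..N-d) with level i
    at position k and level j at position k + d, so the total count is
    exactly ``N - d``.  Requires ``1 <= d < N``.
    """
    vals = np.asarray(
        signature.values if isinstance(signature, TissueSignature) else signature
    ).astype(int)
    n = len(vals)
    if d < 1:
        raise ValueError("inter-parameter distance d must be >= 1")
    if d >= n:
        raise ValueError("distance exceeds signature length")
    counts = np.zeros((G, G), dtype=float)
    np.add.at(counts, (vals[:-d] - 1, vals[d:] - 1), 1.0)
    com = CooccurrenceMatrix(counts, G, normalized=False, offset=("param", d))
    return com.normalize() if normalized else com


def tsrm_features(
    signature: TissueSignature | np.ndarray, d: int, G: int
) -> dict[str, float]:
    """The 22 Haralick features of the normalized TSRM of one signature."""
    return haralick_features(build_tsrm(signature, d, G, normalized=True))


def tsrm_feature_maps(
    field,
    d: int = 1,
    features: tuple[str, ...] = ("entropy", "energy", "maximum_probability"),
) -> FeatureMapStack:
    """Vectorized per-voxel TSRM maps for count-based features.

    Computes the TSRM of every region voxel in one pass and evaluates the
    subset of features expressible directly from the per-voxel pair
    distribution (entropy, energy, maximum_probability).  For the full
    22-feature set use :func:`tsrm_features` per voxel.
    """
    allowed = {"entropy", "energy", "maximum_probability"}
    bad = set(features) - allowed
    if bad:
        raise ValueError(f"tsrm_feature_maps supports {sorted(allowed)}, got {bad}")
    levels = field.levels  # (M, N)
    m_vox, n = levels.shape
    if d < 1 or d >= n:
        raise ValueError("distance exceeds signature length")
    g = field.G
    a = levels[:, :-d] - 1
    b = levels[:, d:] - 1
    pair = a * g + b + (g * g) * np.arange(m_vox)[:, None]
    counts = np.bincount(pair.ravel(), minlength=g * g * m_vox)
    counts = counts.reshape(m_vox, g * g).astype(float)
    p = counts / (n - d)
    maps: dict[str, np.ndarray] = {}
    vals: dict[str, np.ndarray] = {}
    if "entropy" in features:
        safe = np.where(p > 0, p, 1.0)
        vals["entropy"] = -(p * np.log2(safe)).sum(axis=1)
    if "energy" in features:
        vals["energy"] = (p * p).sum(axis=1)
    if "maximum_probability" in features:
        vals["maximum_probability"] = p.max(axis=1)
    for name in features:
        full = np.zeros(field.grid_shape, dtype=float)
        full[field.mask] = vals[name]
        maps[name] = full
    return FeatureMapStack(
        maps=maps, provenance={"family": "tsrm", "d": d, "G": g}
    )


def summarize_map(
    feature_map: np.ndarray, roi: ROIMask, reducer: str = "mean"
) -> float:
    """Reduce a feature map to one scalar over the region voxels."""
    roi.require_nonempty()
    if feature_map.shape != roi.mask.shape:
        raise ValueError("map shape must equal mask shape")
    vals = np.asarray(feature_map, dtype=float)[roi.mask]
    if reducer == "mean":
        return float(vals.mean())
    if reducer == "median":
        return float(np.median(vals))
    if reducer == "std":
        return float(vals.std())
    raise ValueError(f"unknown reducer {reducer!r}")
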