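"""Tissue signature co-occurrence matrix (TSCM) and Haralick-style features.

The TSCM generalizes the gray-level co-occurrence matrix (GLCM) to
multichannel data: for two tissue signatures ``S_i`` and ``S_j`` at voxels
separated by an offset ``(d, theta)``, pair counts are accumulated over the
*parameter* index r — cell ``(m, n)`` counts channels where
``S_i(r) = m`` and ``S_j(r) = n``.  Summing these per-pair counts over all
in-region voxel pairs at the offset (plus the reversed offset, i.e.
symmetric accumulation) and normalizing yields the TSCM.  With a single
channel this collapses exactly to the classical symmetric normalized GLCM.

The feature extractor computes 22 scalar statistics on any normalized G x G
co-occurrence matrix: the 14 classical Haralick features plus 8 widely used
extensions.  The same extractor serves the TSCM, the within-voxel
relationship matrix (TSRM) and the single-image GLCM baseline.

Angle convention: in-plane angles follow the Haralick compass with the
image y-axis pointing up — theta=0 pairs (row, col) with (row, col+d),
45 with (row-d, col+d), 90 with (row-d, col), 135 with (row-d, col-d).
Under symmetric accumulation each offset and its negation produce the same
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EmptyRegionError, SignatureField, TissueSignature

__all__ = [
    "CooccurrenceMatrix",
    "ANGLES_2D",
    "offset_vector",
    "signature_pair_glcm",
    "build_tscm",
    "haralick_features",
    "HARALICK_FEATURE_NAMES",
]

#: supported in-plane angles (degrees)
ANGLES_2D = (0, 45, 90, 135)

_EPS = 1e-12


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Square non-negative pair-count (or probability) matrix.

    ``matrix[m-1, n-1]`` holds the count/probability of the level pair
    ``(m, n)`` with 1-based levels.  ``offset`` records provenance:
    ``(d, theta)`` for spatial matrices, ``("param", d)`` for the TSRM.
    """

    matrix: np.ndarray
    G: int
    normalized: bool
    offset: tuple | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if m.shape[0] != self.G:
            raise ValueError("matrix side must equal G")
        if np.any(m < 0):
            raise ValueError("co-occurrence matrix must be non-negative")
        if self.normalized and abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("normalized matrix must sum to 1")
        object.__setattr__(self, "matrix", m)

    def normalize(self) -> "CooccurrenceMatrix":
        if self.normalized:
            return self
        total = self.matrix.sum()
        if total <= 0:
            raise EmptyRegionError("no co-occurring pairs: empty matrix")
        return CooccurrenceMatrix(self.matrix / total, self.G, True, self.offset)


def offset_vector(d: int, theta: int, ndim: int = 2) -> tuple[int, ...]:
    """(row, col[, slice]) displacement for distance ``d`` and angle ``theta``."""
    if d < 1:
        raise ValueError("distance d must be >= 1")
    table = {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}
    if theta not in table:
        raise ValueError(f"theta must be one of {ANGLES_2D}, got {theta}")
    off = table[theta]
    if ndim == 3:
        off = off + (0,)  # in-plane: slices processed independently
    elif ndim != 2:
        raise ValueError("only 2D/3D grids are supported")
    return off


def signature_pair_glcm(
    s_i: TissueSignature | np.ndarray,
    s_j: TissueSignature | np.ndarray,
    G: int,
) -> CooccurrenceMatrix:
    """Per-pair GLCM between two quantized signatures.

    Cell ``(m, n)`` counts parameter indices r with ``s_i(r) = m`` and
    ``s_j(r) = n``; the total count equals the signature length N.
    """
    a = np.asarray(s_i.values if isinstance(s_i, TissueSignature) else s_i)
    b = np.asarray(s_j.values if isinstance(s_j, TissueSignature) else s_j)
    if a.shape != b.shape:
        raise ValueError("signature lengths must match")
    counts = np.zeros((G, G), dtype=float)
    np.add.at(counts, (a.astype(int) - 1, b.astype(int) - 1), 1.0)
    return CooccurrenceMatrix(counts, G, normalized=False)


def build_tscm(
    field: SignatureField,
    d: int = 1,
    theta: int = 0,
    offset: tuple[int, ...] | None = None,
) -> CooccurrenceMatrix:
    """Normalized TSCM of a signature field at one spatial offset.

    Accumulates ``signature_pair_glcm`` over every in-region voxel pair at
    the offset and its reverse (symmetric accumulation), then normalizes.
    Pairs with either endpoint outside the region are skipped.  For 3D
    fields the in-plane angles act slice by slice; an explicit ``offset``
    tuple (e.g. an axial step) overrides ``(d, theta)``.
    """
    if field.n_voxels == 0:
        raise EmptyRegionError("empty region: cannot build TSCM")
    ndim = len(field.grid_shape)
    off = tuple(offset) if offset is not None else offset_vector(d, theta, ndim)
    if len(off) != ndim:
        raise ValueError("offset dimensionality must match the grid")
    mask = field.mask
    shape = field.grid_shape
    # slices selecting voxel p and its neighbor p+off, staying in bounds
    src, dst = [], []
    for o, n in zip(off, shape):
        if abs(o) >= n:
            raise EmptyRegionError("no co-occurring pairs: offset exceeds grid")
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    src, dst = tuple(src), tuple(dst)
    valid = mask[src] & mask[dst]
    if not valid.any():
        raise EmptyRegionError("no co-occurring pairs at this offset")
    G = field.G
    counts = np.zeros((G, G), dtype=float)
    for lm in field.level_maps:
        a = lm[src][valid].astype(int) - 1
        b = lm[dst][valid].astype(int) - 1
        np.add.at(counts, (a, b), 1.0)
    counts += counts.T  # symmetric accumulation: forward + reverse offsets
    return CooccurrenceMatrix(
        counts / counts.sum(), G, normalized=True, offset=(d, theta) if offset is None else off
    )


HARALICK_FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "information_measure_correlation_1",
    "information_measure_correlation_2",
    "maximal_correlation_coefficient",
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "dissimilarity",
    "maximum_probability",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _maximal_correlation_coefficient(p, px, py) -> float:
    # second-largest eigenvalue magnitude of Q(i,j) = sum_k p(i,k)p(j,k)/(px(i)py(k)),
    # restricted to occupied marginal levels; any numerical failure -> 0
    keep = (px > 0) & (py > 0)
    if keep.sum() < 2:
        return 0.0
    psub = p[np.ix_(keep, keep)]
    pxs, pys = px[keep], py[keep]
    try:
        q = (psub / pxs[:, None]) @ (psub / pys[:, None]).T
        ev = np.linalg.eigvals(q)
        mags = np.sort(np.abs(ev))[::-1]
        val = mags[1] if len(mags) > 1 else 0.0
        if not np.isfinite(val) or val < 0:
            return 0.0
        return float(np.sqrt(val))
    except np.linalg.LinAlgError:
        return 0.0


def haralick_features(com: CooccurrenceMatrix) -> dict[str, float]:
    """The 22-feature set on a normalized co-occurrence matrix.

    Fourteen classical Haralick features (energy / angular second moment,
    contrast, correlation, sum-of-squares variance, inverse difference
    moment, sum average, sum variance, sum entropy, entropy, difference
    variance, difference entropy, the two information measures of
    correlation, maximal correlation coefficient) plus eight common
    extensions (autocorrelation, cluster prominence / shade / tendency,
    dissimilarity, maximum probability, inverse difference normalized,
    inverse difference moment normalized).  Entropies are in bits.

    Degenerate denominators resolve to 0: correlation when a marginal
    standard deviation vanishes, the information measures when the
    conditioning marginal entropy vanishes, the maximal correlation
    coefficient on numerical failure.
    """
    if not com.normalized:
        raise ValueError("haralick_features requires a normalized matrix")
    p = com.matrix
    G = com.G
    levels = np.arange(1, G + 1, dtype=float)
    i = levels[:, None]
    j = levels[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(levels * px))
    mu_y = float(np.sum(levels * py))
    sd_x = float(np.sqrt(np.sum((levels - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((levels - mu_y) ** 2 * py)))

    # p_{x+y}(k), k = 2..2G and p_{|x-y|}(k), k = 0..G-1
    ksum = np.arange(2, 2 * G + 1, dtype=float)
    p_sum = np.zeros(2 * G - 1)
    kdiff = np.arange(0, G, dtype=float)
    p_diff = np.zeros(G)
    ii, jj = np.indices((G, G))
    np.add.at(p_sum, ii + jj, p)
    np.add.at(p_diff, np.abs(ii - jj), p)

    out: dict[str, float] = {}
    out["energy"] = float(np.sum(p * p))
    out["contrast"] = float(np.sum(p * (i - j) ** 2))
    if sd_x > _EPS and sd_y > _EPS:
        out["correlation"] = float(
            (np.sum(i * j * p) - mu_x * mu_y) / (sd_x * sd_y)
        )
    else:
        out["correlation"] = 0.0
    out["sum_of_squares_variance"] = float(np.sum(p * (i - mu_x) ** 2))
    out["inverse_difference_moment"] = float(np.sum(p / (1.0 + (i - j) ** 2)))
    sum_avg = float(np.sum(ksum * p_sum))
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(np.sum((ksum - sum_avg) ** 2 * p_sum))
    out["sum_entropy"] = _entropy_bits(p_sum)
    hxy = _entropy_bits(p)
    out["entropy"] = hxy
    diff_avg = float(np.sum(kdiff * p_diff))
    out["difference_variance"] = float(np.sum((kdiff - diff_avg) ** 2 * p_diff))
    out["difference_entropy"] = _entropy_bits(p_diff)

    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    outer = px[:, None] * py[None, :]
    nz = p > 0
    with np.errstate(divide="ignore"):
        hxy1 = float(-np.sum(p[nz] * np.log2(np.maximum(outer[nz], _EPS))))
        nzo = outer > 0
        hxy2 = float(-np.sum(outer[nzo] * np.log2(outer[nzo])))
    denom = max(hx, hy)
    out["information_measure_correlation_1"] = (
        (hxy - hxy1) / denom if denom > _EPS else 0.0
    )
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0) * np.log(2.0))
    out["information_measure_correlation_2"] = float(np.sqrt(max(arg, 0.0)))
    out["maximal_correlation_coefficient"] = _maximal_correlation_coefficient(
        p, px, py
    )

    out["autocorrelation"] = float(np.sum(i * j * p))
    dev = i + j - mu_x - mu_y
    out["cluster_prominence"] = float(np.sum(dev**4 * p))
    out["cluster_shade"] = float(np.sum(dev**3 * p))
    out["cluster_tendency"] = float(np.sum(dev**2 * p))
    out["dissimilarity"] = float(np.sum(p * np.abs(i - j)))
    out["maximum_probability"] = float(p.max())
    out["inverse_difference_normalized"] = float(
        np.sum(p / (1.0 + np.abs(i - j) / G))
    )
    out["inverse_difference_moment_normalized"] = float(
        np.sum(p / (1.0 + (i - j) ** 2 / G**2))
    )
    return out
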