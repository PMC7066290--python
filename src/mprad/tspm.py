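"""Tissue signature probability matrix (TSPM) features.

The TSPM is the joint distribution of quantized tissue signatures over a
region: an N-dimensional contingency table with one axis per channel and G
cells per axis, populated with the relative frequency of each signature.
Because only at most one cell per ROI voxel can be occupied, the table is
kept sparse — a dense ``G**N`` array is never allocated (G = 128, N = 10
would need more cells than atoms of RAM).

Features extracted here are the joint (Shannon) entropy in bits, the
uniformity (sum of squared cell probabilities, also called energy), and the
multivariate mutual information obtained by inclusion–exclusion over the
marginal entropies of every non-empty channel subset.  For two channels the
latter is the familiar ``I(X1; X2) = H(X1) + H(X2) - H(X1, X2) >= 0``; for
three or more channels the alternating sum (interaction information) may
legitimately be negative and is reported signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import EmptyRegionError, SignatureField

__all__ = [
    "SparseJointMatrix",
    "build_tspm",
    "tspm_entropy",
    "tspm_uniformity",
    "marginalize",
    "tspm_mutual_information",
    "tspm_features",
]


@dataclass(frozen=True)
class SparseJointMatrix:
    """Sparse N-dimensional probability table over quantized signatures.

    ``cells`` maps level tuples (each entry in ``1..G``) to probabilities
    summing to 1.  ``total_count`` records the number of voxels tallied.
    """

    cells: Mapping[tuple[int, ...], float]
    N: int
    G: int
    total_count: int

    def __post_init__(self):
        for key in self.cells:
            if len(key) != self.N:
                raise ValueError("cell key length must equal N")
            if any(not (1 <= k <= self.G) for k in key):
                raise ValueError("cell levels must lie in 1..G")
        total = sum(self.cells.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def probabilities(self) -> np.ndarray:
        return np.fromiter(self.cells.values(), dtype=float, count=len(self.cells))


def build_tspm(field: SignatureField) -> SparseJointMatrix:
    """Tally the signatures of a field into a normalized sparse joint matrix."""
    if field.n_voxels == 0:
        raise EmptyRegionError("empty region: cannot build TSPM from empty field")
    uniq, counts = np.unique(field.levels, axis=0, return_counts=True)
    total = field.n_voxels
    cells = {
        tuple(int(v) for v in row): float(c) / total for row, c in zip(uniq, counts)
    }
    return SparseJointMatrix(cells=cells, N=field.n_channels, G=field.G,
                             total_count=total)


def _entropy_bits(p: np.ndarray) -> float:
    # 0 * log2(0) := 0 by convention
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def tspm_entropy(tspm: SparseJointMatrix) -> float:
    """Joint entropy ``H = -sum p log2 p`` in bits."""
    return _entropy_bits(tspm.probabilities())


def tspm_uniformity(tspm: SparseJointMatrix) -> float:
    """Uniformity ``U = sum p**2`` (1 iff a single occupied cell)."""
    p = tspm.probabilities()
    return float(np.sum(p * p))


def marginalize(
    tspm: SparseJointMatrix, subset: Sequence[int]
) -> SparseJointMatrix:
    """Marginal joint matrix over an ordered subset of channel axes.

    ``subset`` holds 0-based channel indices; probabilities of the dropped
    axes are summed out.  Marginalizing onto all axes in order is the
    identity.
    """
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise ValueError("subset indices must be distinct")
    if any(not (0 <= i < tspm.N) for i in subset):
        raise ValueError(f"subset indices must lie in 0..{tspm.N - 1}")
    out: dict[tuple[int, ...], float] = {}
    for key, p in tspm.cells.items():
        sub = tuple(key[i] for i in subset)
        out[sub] = out.get(sub, 0.0) + p
    # guard against accumulated float drift
    total = sum(out.values())
    out = {k: v / total for k, v in out.items()}
    return SparseJointMatrix(cells=out, N=len(subset), G=tspm.G,
                             total_count=tspm.total_count)


def tspm_mutual_information(tspm: SparseJointMatrix) -> float:
    """Multivariate mutual information by inclusion–exclusion, in bits.

    ``MI = sum over non-empty subsets Y of (-1)**(|Y|+1) H(marginal on Y)``,
    so the N-way joint enters with sign ``(-1)**(N-1)``.  Reduces to
    ``H1 + H2 - H12`` for two channels; may be negative for N >= 3.
    """
    if tspm.N < 2:
        raise ValueError("mutual information undefined for one channel")
    mi = 0.0
    for size in range(1, tspm.N + 1):
        sign = (-1.0) ** (size + 1)
        for subset in combinations(range(tspm.N), size):
            mi += sign * tspm_entropy(marginalize(tspm, subset))
    return mi


def tspm_features(field: SignatureField) -> dict[str, float]:
    """Entropy, uniformity, and (for N >= 2) mutual information of a field."""
    m = build_tspm(field)
    out = {"entropy": tspm_entropy(m), "uniformity": tspm_uniformity(m)}
    if m.N >= 2:
        out["mutual_information"] = tspm_mutual_information(m)
    return out
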