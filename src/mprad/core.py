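"""Core domain types and quantization conventions.

Every feature family in this package operates on the *tissue signature*: the
vector of intensities observed at one voxel across all N co-registered
channels of a multiparametric volume.  This module defines the shared
containers (volume, ROI mask, quantization spec, signature field) and the
two primitive transforms every family relies on — intensity quantization to
integer gray levels and per-channel [0, 1] normalization.

Conventions
-----------
* Gray levels are 1-based integers in ``1..G``; bin edges are half-open
  ``[lo, hi)`` with the scope maximum assigned to level ``G`` so the top
  level is never empty.
* A channel that is constant within the quantization scope maps entirely
  to level 1.
* Voxel coordinates are 0-based numpy indices; masks and channels must
  share the same grid — no resampling is performed (inputs are assumed
  co-registered).
* Non-finite intensities are a hard error, never silently masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "MultiparametricVolume",
    "ROIMask",
    "QuantizationSpec",
    "TissueSignature",
    "SignatureField",
    "FeatureMapStack",
    "quantize_channel",
    "normalize_channels",
    "extract_signature_field",
]


class EmptyRegionError(ValueError):
    """Raised when a feature is requested on an empty region."""


class NonFiniteIntensityError(ValueError):
    """Raised when a channel contains NaN or infinite voxels."""


@dataclass(frozen=True)
class MultiparametricVolume:
    """N co-registered scalar channels on a common voxel grid.

    Parameters
    ----------
    channels : sequence of ndarray
        Scalar arrays, all with identical shape ``(X, Y)`` or ``(X, Y, Z)``.
    channel_names : sequence of str
        Unique names, positionally aligned with ``channels``.
    voxel_spacing : tuple of float, optional
        Physical spacing per axis in mm; metadata only.
    """

    channels: tuple[np.ndarray, ...]
    channel_names: tuple[str, ...]
    voxel_spacing: tuple[float, ...] | None = None

    def __init__(
        self,
        channels: Sequence[np.ndarray],
        channel_names: Sequence[str] | None = None,
        voxel_spacing: Sequence[float] | None = None,
    ):
        channels = tuple(np.asarray(c, dtype=float) for c in channels)
        if len(channels) < 1:
            raise ValueError("at least one channel is required")
        shape = channels[0].shape
        if any(c.shape != shape for c in channels):
            raise ValueError("all channels must have identical shape")
        if channel_names is None:
            channel_names = tuple(f"ch{i}" for i in range(len(channels)))
        else:
            channel_names = tuple(str(n) for n in channel_names)
        if len(channel_names) != len(channels):
            raise ValueError("channel_names must align with channels")
        if len(set(channel_names)) != len(channel_names):
            raise ValueError("channel_names must be unique")
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "channel_names", channel_names)
        object.__setattr__(
            self,
            "voxel_spacing",
            None if voxel_spacing is None else tuple(float(s) for s in voxel_spacing),
        )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.channels[0].shape

    def stack(self) -> np.ndarray:
        """Channels stacked into one ``(N, *grid)`` array."""
        return np.stack(self.channels, axis=0)

    def select(self, names: Sequence[str]) -> "MultiparametricVolume":
        """Sub-volume restricted to the named channels, in the given order."""
        idx = [self.channel_names.index(n) for n in names]
        return MultiparametricVolume(
            [self.channels[i] for i in idx], [self.channel_names[i] for i in idx],
            self.voxel_spacing,
        )


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask on the volume grid."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise EmptyRegionError(f"empty region: ROI '{self.label}' has no voxels")


@dataclass(frozen=True)
class QuantizationSpec:
    """Gray-level quantization parameters shared by all feature families.

    Parameters
    ----------
    G : int
        Gray levels for second-order / joint features (levels ``1..G``).
    B : int
        Bins for pooled first-order histograms.
    mode : {"per_channel_minmax", "global_minmax", "fixed_range"}
        How bin limits are chosen.  ``fixed_range`` requires ``fixed_range``.
    scope : {"roi", "volume"}
        Whether min/max are taken over the ROI only or the whole volume.
        ROI scope maximizes intra-ROI dynamic range; volume scope keeps
        sliding-window feature maps comparable across windows.
    fixed_range : (lo, hi), optional
        Explicit intensity limits for ``mode="fixed_range"``.
    """

    G: int = 8
    B: int = 128
    mode: str = "per_channel_minmax"
    scope: str = "roi"
    fixed_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.G < 2:
            raise ValueError("G must be >= 2")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.mode not in ("per_channel_minmax", "global_minmax", "fixed_range"):
            raise ValueError(f"unknown quantization mode {self.mode!r}")
        if self.scope not in ("roi", "volume"):
            raise ValueError(f"unknown quantization scope {self.scope!r}")
        if self.mode == "fixed_range" and self.fixed_range is None:
            raise ValueError("fixed_range mode requires explicit (lo, hi)")


@dataclass(frozen=True)
class TissueSignature:
    """The intensity (or level) vector at one voxel across all channels."""

    values: np.ndarray
    position: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values))
        object.__setattr__(self, "position", tuple(int(p) for p in self.position))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SignatureField:
    """All quantized tissue signatures of one ROI, array-backed.

    ``levels`` holds one row per in-ROI voxel (row order follows
    ``np.argwhere`` of the mask); ``level_maps`` keeps the full-grid
    quantized channels so spatially-aware consumers (co-occurrence at an
    offset, sliding windows) can look up neighbors.
    """

    levels: np.ndarray      # (M, N) int, entries in 1..G
    positions: np.ndarray   # (M, ndim) int
    level_maps: np.ndarray  # (N, *grid) int
    mask: np.ndarray        # bool, grid shape
    G: int

    @property
    def n_channels(self) -> int:
        return self.levels.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.levels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def __len__(self) -> int:
        return self.n_voxels

    def signatures(self) -> Iterator[TissueSignature]:
        for row, pos in zip(self.levels, self.positions):
            yield TissueSignature(row.copy(), tuple(pos))

    def signature_at(self, position: Sequence[int]) -> TissueSignature:
        pos = tuple(int(p) for p in position)
        if not self.mask[pos]:
            raise KeyError(f"position {pos} is outside the ROI")
        return TissueSignature(self.level_maps[(slice(None),) + pos], pos)


@dataclass
class FeatureMapStack:
    """Named per-voxel feature maps on the input grid, with provenance."""

    maps: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def __contains__(self, name: str) -> bool:
        return name in self.maps

    @property
    def names(self) -> list[str]:
        return list(self.maps)


def _check_finite(channel: np.ndarray) -> None:
    if not np.all(np.isfinite(channel)):
        raise NonFiniteIntensityError(
            "non-finite intensity: channel contains NaN or inf; pre-clean the input"
        )


def _scope_limits(
    channel: np.ndarray, roi: ROIMask | None, spec: QuantizationSpec
) -> tuple[float, float]:
    if spec.mode == "fixed_range":
        return float(spec.fixed_range[0]), float(spec.fixed_range[1])
    if spec.scope == "roi":
        if roi is None:
            raise ValueError("roi scope requires a mask")
        roi.require_nonempty()
        vals = channel[roi.mask]
    else:
        vals = channel
    return float(vals.min()), float(vals.max())


def quantize_channel(
    channel: np.ndarray, roi: ROIMask | None, spec: QuantizationSpec
) -> np.ndarray:
    """Quantize one channel to integer gray levels ``1..G``.

    Bins are linear and equally spaced between the scope minimum and
    maximum, half-open ``[lo, hi)`` with the maximum assigned to level
    ``G``.  A constant channel maps wholly to level 1.  The whole grid is
    quantized with the scope's limits (values outside are clipped into
    ``1..G``); consumers restrict to the ROI as needed.
    """
    channel = np.asarray(channel, dtype=float)
    _check_finite(channel)
    lo, hi = _scope_limits(channel, roi, spec)
    if hi <= lo:
        return np.ones_like(channel, dtype=np.int64)
    levels = np.floor((channel - lo) / (hi - lo) * spec.G).astype(np.int64) + 1
    np.clip(levels, 1, spec.G, out=levels)
    return levels


def normalize_channels(
    mpv: MultiparametricVolume,
    scope: str = "volume",
    roi: ROIMask | None = None,
) -> MultiparametricVolume:
    """Affinely rescale each channel to [0, 1] (min -> 0, max -> 1).

    Required before cross-channel first-order statistics so channels with
    arbitrary units become scale-comparable.  A channel constant within the
    scope maps to all zeros.
    """
    if scope not in ("roi", "volume"):
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for ch in mpv.channels:
        _check_finite(ch)
        if scope == "roi":
            if roi is None:
                raise ValueError("roi scope requires a mask")
            roi.require_nonempty()
            vals = ch[roi.mask]
        else:
            vals = ch
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            out.append(np.zeros_like(ch, dtype=float))
        else:
            out.append((ch - lo) / (hi - lo))
    return MultiparametricVolume(out, mpv.channel_names, mpv.voxel_spacing)


def extract_signature_field(
    mpv: MultiparametricVolume, roi: ROIMask, spec: QuantizationSpec
) -> SignatureField:
    """Quantize every channel and collect the signature of each ROI voxel.

    Entry order within each signature equals channel order; one signature
    per ROI voxel (conservation).
    """
    if roi.mask.shape != mpv.shape:
        raise ValueError("mask shape must equal channel shape")
    roi.require_nonempty()
    level_maps = np.stack(
        [quantize_channel(ch, roi, spec) for ch in mpv.channels], axis=0
    )
    positions = np.argwhere(roi.mask)
    idx = tuple(positions.T)
    levels = np.stack([lm[idx] for lm in level_maps], axis=1)
    return SignatureField(
        levels=levels,
        positions=positions,
        level_maps=level_maps,
        mask=roi.mask,
        G=spec.G,
    )
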