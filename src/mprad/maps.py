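"""Sliding-window radiomic feature maps.

A feature map assigns to every voxel the value of a texture feature
computed on the w x w in-plane neighborhood around it, treating the window
as the region.  The default preset follows a 5 x 5 neighborhood with 128
gray levels.  Quantization is *volume-scoped* — levels are fixed across
windows — so map values are spatially comparable; per-window
re-quantization would destroy spatial contrast.  Borders are handled by
mirror padding so the output grid matches the input, and 3D volumes are
mapped slice by slice in-plane.

Feature naming: ``"<family>_<feature>"`` with families ``tspm`` (entropy,
uniformity, mutual_information), ``tsfos`` (histogram features), and
``tscm`` (any of the 22 Haralick names, computed on the window TSCM at
offset ``(d, theta)``).  TSCIN maps are intrinsically voxelwise and come
from :mod:`mprad.tscin` instead.
"""

from __future__ import annotations

import numpy as np

from .core import (
    FeatureMapStack,
    MultiparametricVolume,
    QuantizationSpec,
    ROIMask,
    SignatureField,
)
from . import tsfos, tspm
from .tscm import HARALICK_FEATURE_NAMES, build_tscm, haralick_features

__all__ = ["mpmap", "single_glcm_map", "MAP_FEATURES"]

MAP_FEATURES = (
    ("tspm_entropy", "tspm_uniformity", "tspm_mutual_information")
    + ("tsfos_entropy", "tsfos_uniformity", "tsfos_mean", "tsfos_variance",
       "tsfos_skewness", "tsfos_kurtosis")
    + tuple(f"tscm_{n}" for n in HARALICK_FEATURE_NAMES)
)


def _window_field(levels_pad: np.ndarray, r: int, ci: int, cj: int, G: int
                  ) -> SignatureField:
    """Signature field of one (already padded) w x w window."""
    win = levels_pad[:, ci - r:ci + r + 1, cj - r:cj + r + 1]
    n, w, _ = win.shape
    mask = np.ones((w, w), dtype=bool)
    return SignatureField(
        levels=win.reshape(n, -1).T,
        positions=np.argwhere(mask),
        level_maps=win,
        mask=mask,
        G=G,
    )


def _feature_fn(feature: str, d: int, theta: int):
    """Resolve a map feature name to a window -> float callable."""
    if feature.startswith("tspm_"):
        stat = feature[len("tspm_"):]
        def fn(field, raw_win):
            m = tspm.build_tspm(field)
            if stat == "entropy":
                return tspm.tspm_entropy(m)
            if stat == "uniformity":
                return tspm.tspm_uniformity(m)
            if stat == "mutual_information":
                return tspm.tspm_mutual_information(m) if m.N >= 2 else 0.0
            raise ValueError(f"unknown feature {feature!r}")
        return fn
    if feature.startswith("tsfos_"):
        stat = feature[len("tsfos_"):]
        def fn(field, raw_win):  # noqa: ARG001 - histogram uses raw values
            counts = np.zeros(len(raw_win["edges"]) - 1)
            hist, _ = np.histogram(raw_win["values"], bins=raw_win["edges"])
            counts += hist
            tsh = tsfos.TSHistogram(raw_win["edges"], counts / counts.sum())
            feats = tsfos.tsfos_features(tsh)
            if stat not in feats:
                raise ValueError(f"unknown feature {feature!r}")
            return feats[stat]
        return fn
    if feature.startswith("tscm_"):
        stat = feature[len("tscm_"):]
        if stat not in HARALICK_FEATURE_NAMES:
            raise ValueError(f"unknown feature {feature!r}")
        def fn(field, raw_win):
            com = build_tscm(field, d=d, theta=theta)
            return haralick_features(com)[stat]
        return fn
    raise ValueError(
        f"unknown feature {feature!r}; valid names: {', '.join(MAP_FEATURES)}"
    )


def _map_slice(
    stack: np.ndarray,
    levels: np.ndarray,
    feature: str,
    w: int,
    spec: QuantizationSpec,
    d: int,
    theta: int,
    edges: np.ndarray,
) -> np.ndarray:
    r = w // 2
    pad = [(0, 0), (r, r), (r, r)]
    levels_pad = np.pad(levels, pad, mode="reflect")
    stack_pad = np.pad(stack, pad, mode="reflect")
    fn = _feature_fn(feature, d, theta)
    h, wid = stack.shape[1:]
    out = np.empty((h, wid), dtype=float)
    for ii in range(h):
        for jj in range(wid):
            ci, cj = ii + r, jj + r
            field = _window_field(levels_pad, r, ci, cj, spec.G)
            raw_win = {
                "values": stack_pad[:, ci - r:ci + r + 1, cj - r:cj + r + 1].ravel(),
                "edges": edges,
            }
            out[ii, jj] = fn(field, raw_win)
    return out


def mpmap(
    mpv: MultiparametricVolume,
    feature: str,
    window: tuple[int, int] = (5, 5),
    spec: QuantizationSpec | None = None,
    d: int = 1,
    theta: int = 0,
) -> FeatureMapStack:
    """Sliding-window multiparametric feature map.

    For each voxel the requested feature is computed on the w x w in-plane
    neighborhood (mirror-padded at borders) treated as the region, and
    assigned to the center voxel.  Window size must be odd and >= 3.
    """
    if spec is None:
        spec = QuantizationSpec(G=128, B=128, scope="volume")
    w = int(window[0])
    if window[0] != window[1]:
        raise ValueError("only square windows are supported")
    if w % 2 == 0 or w < 3:
        raise ValueError("window size must be odd and >= 3")
    vol_spec = QuantizationSpec(G=spec.G, B=spec.B, mode=spec.mode,
                                scope="volume", fixed_range=spec.fixed_range)
    full = ROIMask(np.ones(mpv.shape, dtype=bool), "volume")
    from .core import quantize_channel

    levels = np.stack(
        [quantize_channel(ch, full, vol_spec) for ch in mpv.channels], axis=0
    )
    stack = mpv.stack().astype(float)
    lo, hi = float(stack.min()), float(stack.max())
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, spec.B + 1)

    if stack.ndim == 3:  # (N, X, Y)
        out = _map_slice(stack, levels, feature, w, vol_spec, d, theta, edges)
    elif stack.ndim == 4:  # (N, X, Y, Z): slice-wise in-plane
        out = np.empty(mpv.shape, dtype=float)
        for z in range(mpv.shape[2]):
            out[:, :, z] = _map_slice(
                stack[:, :, :, z], levels[:, :, :, z], feature, w, vol_spec,
                d, theta, edges,
            )
    else:
        raise ValueError("only 2D or 3D volumes are supported")
    return FeatureMapStack(
        maps={feature: out},
        provenance={
            "feature": feature, "window": w, "G": spec.G, "B": spec.B,
            "d": d, "theta": theta, "quantization_scope": "volume",
        },
    )


def single_glcm_map(
    channel: np.ndarray,
    feature: str,
    window: tuple[int, int] = (5, 5),
    G: int = 128,
    d: int = 1,
    theta: int = 0,
) -> FeatureMapStack:
    """Single-image GLCM baseline map (the N = 1 case of :func:`mpmap`).

    ``feature`` is a bare Haralick name (e.g. ``"entropy"``).  Note that
    this is *not* equivalent to running :func:`mpmap` with the channel
    duplicated — duplicating a channel doubles the per-pair counts and
    changes nothing else only when the copies are identical, but a
    duplicated channel changes TSPM/TSFOS statistics.
    """
    mpv = MultiparametricVolume([np.asarray(channel, dtype=float)], ["ch0"])
    fs = mpmap(mpv, f"tscm_{feature}", window,
               QuantizationSpec(G=G, B=max(G, 2), scope="volume"), d, theta)
    return FeatureMapStack(
        maps={feature: fs.maps[f"tscm_{feature}"]},
        provenance={**fs.provenance, "family": "single_glcm"},
    )
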