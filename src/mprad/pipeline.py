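"""End-to-end feature extraction: one region -> one named feature vector.

Bundles the five multiparametric families (TSPM, TSFOS, TSCM, TSCIN
first-order, TSRM) plus the single-channel first-order baseline into a
flat ``{name: value}`` map per region, ready for a feature table.  TSCM
features are averaged over the four in-plane angles at distance 1 by
default (per-angle values are retrievable through :mod:`mprad.tscm`);
TSCIN maps are summarized over the region by the mean.
"""

from __future__ import annotations

import numpy as np

from . import tsfos, tspm
from .core import (
    MultiparametricVolume,
    QuantizationSpec,
    ROIMask,
    extract_signature_field,
    normalize_channels,
)
from .tscm import ANGLES_2D, build_tscm, haralick_features
from .tscin import TSCIN_STATS, summarize_map, tscin_first_order, tsrm_feature_maps

__all__ = ["extract_features", "single_channel_features"]


def single_channel_features(
    mpv: MultiparametricVolume, roi: ROIMask, B: int = 32
) -> dict[str, float]:
    """Per-channel first-order histogram features (the single-parameter
    baseline): ``single_<channel>_<stat>``."""
    out: dict[str, float] = {}
    for name in mpv.channel_names:
        sub = mpv.select([name])
        tsh = tsfos.build_tsh(sub, roi, B=B, pooling="raw")
        for stat, val in tsfos.tsfos_features(tsh).items():
            if stat == "energy":
                continue  # alias of uniformity
            out[f"single_{name}_{stat}"] = val
    return out


def extract_features(
    mpv: MultiparametricVolume,
    roi: ROIMask,
    spec: QuantizationSpec | None = None,
    d: int = 1,
    tsfos_pooling: str = "normalized",
    include_single: bool = True,
    prefix: str = "",
) -> dict[str, float]:
    """All mpRad feature families for one region of one volume.

    Returns a flat map with keys ``tspm_*``, ``tsfos_*``, ``tscm_*``
    (angle-averaged Haralick set), ``tscin_<stat>_mean`` and
    ``tsrm_<stat>_mean``, plus the per-channel ``single_*`` baseline when
    requested.  ``prefix`` is prepended to every key (e.g. a compartment
    name).
    """
    if spec is None:
        spec = QuantizationSpec()
    roi.require_nonempty()
    feats: dict[str, float] = {}

    field = extract_signature_field(mpv, roi, spec)
    for stat, val in tspm.tspm_features(field).items():
        feats[f"tspm_{stat}"] = val

    tsh = tsfos.build_tsh(mpv, roi, B=spec.B, pooling=tsfos_pooling)
    for stat, val in tsfos.tsfos_features(tsh).items():
        if stat == "energy":
            continue
        feats[f"tsfos_{stat}"] = val

    acc: dict[str, list[float]] = {}
    for theta in ANGLES_2D:
        com = build_tscm(field, d=d, theta=theta)
        for stat, val in haralick_features(com).items():
            acc.setdefault(stat, []).append(val)
    for stat, vals in acc.items():
        feats[f"tscm_{stat}"] = float(np.mean(vals))

    norm = normalize_channels(mpv, scope="roi", roi=roi)
    n = mpv.n_channels
    stats = TSCIN_STATS if n >= 2 else ("mean", "max", "min", "median")
    fmaps = tscin_first_order(norm, roi, stats=stats)
    for stat in stats:
        feats[f"tscin_{stat}_mean"] = summarize_map(fmaps[stat], roi, "mean")

    if n > d:
        tmaps = tsrm_feature_maps(field, d=d)
        for stat in tmaps.names:
            feats[f"tsrm_{stat}_mean"] = summarize_map(tmaps[stat], roi, "mean")

    if include_single:
        feats.update(single_channel_features(mpv, roi, B=min(spec.B, 32)))
    if prefix:
        feats = {f"{prefix}{k}": v for k, v in feats.items()}
    return feats
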