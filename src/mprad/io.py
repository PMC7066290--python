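"""Readers and writers: NIfTI volumes/masks/maps, CSV feature tables, JSON.

Channels are read from one NIfTI file per channel or a single 4D file;
all grids and affines must agree (inputs are assumed co-registered —
registration is never performed here).  Feature tables are written as
deterministic CSV (``subject_id, label, <sorted feature names>``) so the
same cohort always produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .classify import FeatureTable
from .core import FeatureMapStack, MultiparametricVolume, ROIMask

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_maps",
    "write_features",
    "read_features",
    "write_json",
]

_AFFINE_TOL = 1e-4


def read_volume(
    paths: Sequence[str | Path] | str | Path,
    channel_names: Sequence[str] | None = None,
) -> MultiparametricVolume:
    """Load co-registered channels from NIfTI file(s).

    One path to a 4D file yields one channel per frame; several paths to
    2D/3D files yield one channel each, in input order.  Shape or affine
    mismatch beyond 1e-4 raises a co-registration error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    imgs = [nib.load(str(p)) for p in paths]
    affine0 = imgs[0].affine
    channels: list[np.ndarray] = []
    for p, img in zip(paths, imgs):
        if not np.allclose(img.affine, affine0, atol=_AFFINE_TOL):
            raise ValueError(f"channels not co-registered: affine mismatch in {p}")
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim == 4:
            # frames become channels; a singleton third axis marks a 2D
            # grid written as (X, Y, 1, N) and is squeezed back out
            frames = [data[..., t] for t in range(data.shape[3])]
            if data.shape[2] == 1:
                frames = [f[:, :, 0] for f in frames]
            channels.extend(frames)
        else:
            channels.append(data)
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError("channels not co-registered: shape mismatch")
    if channel_names is None and len(paths) == len(channels):
        channel_names = [p.name.split(".")[0] for p in paths]
        if len(set(channel_names)) != len(channel_names):
            channel_names = None
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[: channels[0].ndim])
    return MultiparametricVolume(channels, channel_names, spacing)


def read_mask(path: str | Path, label: str = "roi") -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asarray(img.get_fdata()) > 0.5, label)


def _as_nifti(data: np.ndarray, affine: np.ndarray | None) -> nib.Nifti1Image:
    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)


def write_volume(
    mpv: MultiparametricVolume, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write a volume as one 4D NIfTI (channels along the last axis).

    A 2D grid is stored as (X, Y, 1, N) so the channel axis is always the
    NIfTI time dimension; :func:`read_volume` squeezes it back.
    """
    data = np.stack(mpv.channels, axis=-1)
    if data.ndim == 3:  # 2D grid + channel axis
        data = data[:, :, None, :]
    nib.save(_as_nifti(data, affine), str(path))


def write_maps(
    stack: FeatureMapStack,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
    prefix: str = "map",
) -> list[Path]:
    """Write each feature map as its own NIfTI, plus a provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(stack.maps):
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(_as_nifti(stack.maps[name], affine), str(p))
        written.append(p)
    write_json(dict(stack.provenance), out_dir / f"{prefix}_provenance.json")
    return written


def write_features(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as deterministic CSV.

    Header is ``subject_id, label, <feature names sorted>``; rows keep
    subject order.  An empty feature set is an error.
    """
    if len(table.feature_names) == 0:
        raise ValueError("feature table has no features")
    df = table.to_frame()
    cols = ["subject_id", "label"] + sorted(table.feature_names)
    df[cols].to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    return FeatureTable.from_frame(df)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
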