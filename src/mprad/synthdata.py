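"""Seedable multiparametric phantoms and cohort benchmarks.

Real multiparametric acquisitions of lesions are not redistributable, so
every test and benchmark in this package runs on procedurally generated
phantoms: N co-registered channels containing compartments of distinct,
controllable texture on a glandular-like textured background —

* a "benign-like" lesion: a smooth, homogeneous Gaussian random field
  (long correlation length);
* a "malignant-like" lesion: a heterogeneous field (short correlation
  length, slightly larger texture amplitude);
* an optional "cyst": constant intensity per channel (zero texture);
* a glandular background with intermediate texture, drawn identically for
  both classes (the contralateral-tissue analogue).

Textures are Gaussian random fields obtained by Gaussian-filtering white
noise (correlation length = filter sigma, in voxels) and re-standardizing
within the compartment, so the marginal intensity distribution is held
fixed while spatial heterogeneity varies.  Channels share one latent field
with weight ``coupling`` plus independent fields with weight
``sqrt(1 - coupling**2)``, which dials the inter-channel mutual information
without changing per-channel variance.  All randomness flows from the
mandatory integer seed; identical seeds give bit-identical phantoms.

The cohort generator draws class-conditional lesion textures, extracts the
full multiparametric + single-channel feature set per subject, and returns
a labeled feature table — the benchmark used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .classify import FeatureTable
from .core import MultiparametricVolume, QuantizationSpec, ROIMask
from .pipeline import extract_features

__all__ = ["TextureSpec", "Compartment", "PhantomSpec", "generate_phantom",
           "generate_cohort", "two_class_phantom_spec"]


@dataclass(frozen=True)
class TextureSpec:
    """Texture of one compartment.

    ``kind``: "constant" (zero texture), "grf" (Gaussian random field with
    ``correlation_length`` voxels and amplitude ``sd``), or "checkerboard"
    (alternating ±sd squares with ``period`` voxels).
    """

    kind: str = "grf"
    correlation_length: float = 2.0
    sd: float = 1.0
    period: int = 2

    def __post_init__(self):
        if self.kind not in ("constant", "grf", "checkerboard"):
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.kind == "grf" and self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


@dataclass(frozen=True)
class Compartment:
    """One region of the phantom: a disk or box with its own texture."""

    name: str
    shape: str  # "disk" | "box" | "background"
    center: tuple[float, ...] = ()
    size: float | tuple[float, ...] = 0.0
    texture: TextureSpec = TextureSpec()
    channel_offsets: tuple[float, ...] | None = None  # per-channel mean shift
    coupling: float | None = None  # overrides the phantom-level coupling

    def mask_on(self, grid_shape: tuple[int, ...]) -> np.ndarray:
        if self.shape == "background":
            return np.ones(grid_shape, dtype=bool)
        coords = np.indices(grid_shape).astype(float)
        if self.shape == "disk":
            r2 = sum((c - cc) ** 2 for c, cc in zip(coords, self.center))
            m = r2 <= float(self.size) ** 2
        elif self.shape == "box":
            half = (
                [float(self.size) / 2] * len(grid_shape)
                if np.isscalar(self.size)
                else [s / 2 for s in self.size]
            )
            m = np.ones(grid_shape, dtype=bool)
            for c, cc, h in zip(coords, self.center, half):
                m &= np.abs(c - cc) <= h
        else:
            raise ValueError(f"unknown compartment shape {self.shape!r}")
        if not m.any():
            raise ValueError(f"compartment {self.name!r} lies outside the grid")
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; ``seed`` is mandatory for reproducibility."""

    grid_shape: tuple[int, ...] = (48, 48)
    n_channels: int = 4
    compartments: tuple[Compartment, ...] = ()
    coupling: float = 0.7  # shared-latent-field weight in [0, 1]
    noise_sd: float = 0.05
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self):
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _grf(rng: np.random.Generator, shape, correlation_length: float) -> np.ndarray:
    """Unit-variance Gaussian random field via filtered white noise."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=correlation_length, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _texture_field(
    rng: np.random.Generator, shape, tex: TextureSpec
) -> np.ndarray:
    if tex.kind == "constant":
        return np.zeros(shape)
    if tex.kind == "checkerboard":
        coords = np.indices(shape) // tex.period
        return tex.sd * (2.0 * (coords.sum(axis=0) % 2) - 1.0)
    return tex.sd * _grf(rng, shape, tex.correlation_length)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MultiparametricVolume, dict[str, ROIMask], dict[str, str]]:
    """Render a phantom: volume, one ROI mask per compartment, labels.

    Deterministic given ``spec.seed``.  Within each compartment, channel k
    is ``offset_k + coupling * shared + sqrt(1 - coupling**2) * indep_k``
    (shared and independent fields drawn from the compartment's texture)
    plus iid Gaussian voxel noise of ``noise_sd``.  After per-compartment
    standardization the per-channel marginal amplitude equals the texture
    ``sd`` regardless of correlation length, so classes differing only in
    correlation length share first-order statistics by construction.
    Later compartments overwrite earlier ones; overlap between two
    non-background compartments is an error unless ``allow_overlap``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    n = spec.n_channels
    channels = [np.zeros(shape) for _ in range(n)]
    masks: dict[str, ROIMask] = {}
    labels: dict[str, str] = {}
    occupied = np.zeros(shape, dtype=bool)
    for comp in spec.compartments:
        coupling = spec.coupling if comp.coupling is None else comp.coupling
        if not (0.0 <= coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        w_shared = coupling
        w_indep = float(np.sqrt(max(0.0, 1.0 - coupling**2)))
        m = comp.mask_on(shape)
        if comp.shape != "background":
            if (occupied & m).any() and not spec.allow_overlap:
                raise ValueError(
                    f"compartment {comp.name!r} overlaps an earlier compartment"
                )
            occupied |= m
        shared = _texture_field(rng, shape, comp.texture)
        offsets = comp.channel_offsets or tuple([0.0] * n)
        if len(offsets) != n:
            raise ValueError("channel_offsets length must equal n_channels")
        for k in range(n):
            indep = _texture_field(rng, shape, comp.texture)
            tex = w_shared * shared + w_indep * indep
            if comp.texture.kind == "grf":
                # standardize within the compartment so the marginal
                # amplitude equals the texture sd irrespective of
                # correlation length (classes differing only in spatial
                # heterogeneity share first-order statistics)
                inside = tex[m]
                sd_in = inside.std()
                if sd_in > 0:
                    tex = (tex - inside.mean()) / sd_in * comp.texture.sd
            channels[k][m] = offsets[k] + tex[m]
        masks[comp.name] = ROIMask(m, comp.name)
        labels[comp.name] = comp.texture.kind
    for k in range(n):
        channels[k] = channels[k] + spec.noise_sd * rng.standard_normal(shape)
    mpv = MultiparametricVolume(channels, [f"ch{k}" for k in range(n)])
    return mpv, masks, labels


def two_class_phantom_spec(
    kind: str,
    seed: int,
    grid: tuple[int, int] = (36, 36),
    n_channels: int = 4,
    lesion_radius: float = 8.0,
    benign_corr_len: float = 3.0,
    effect_size: float = 1.0,
    coupling: float = 0.7,
    noise_sd: float = 0.05,
    with_cyst: bool = False,
) -> PhantomSpec:
    """Class-conditional lesion phantom on a glandular background.

    ``kind`` is "benign" (smooth lesion, correlation length
    ``benign_corr_len``, cross-channel coupling ``coupling``) or
    "malignant" (heterogeneous: correlation length divided by
    ``1 + 3 * effect_size`` — a 4:1 heterogeneity ratio at effect_size 1 —
    and lesion coupling reduced by ``0.4 * effect_size`` of its value, so
    the within-voxel spread across channels is larger).  Per-compartment
    standardization holds the first-order marginals of the two classes
    equal by construction: the class effect is purely in spatial and
    cross-channel structure.  ``effect_size = 0`` makes the two classes
    identically distributed.  The glandular background texture does not
    depend on class.
    """
    if kind not in ("benign", "malignant"):
        raise ValueError("kind must be 'benign' or 'malignant'")
    if kind == "malignant":
        corr = benign_corr_len / (1.0 + 3.0 * effect_size)
        lesion_coupling = coupling * (1.0 - 0.4 * effect_size)
    else:
        corr = benign_corr_len
        lesion_coupling = coupling
    sd = 1.0
    cx, cy = grid[0] / 2.0, grid[1] / 2.0
    comps = [
        Compartment(
            name="glandular",
            shape="background",
            texture=TextureSpec(kind="grf", correlation_length=2.0, sd=0.8),
            channel_offsets=tuple(0.5 * k for k in range(n_channels)),
        ),
        Compartment(
            name="lesion",
            shape="disk",
            center=(cx, cy),
            size=lesion_radius,
            texture=TextureSpec(kind="grf", correlation_length=corr, sd=sd),
            channel_offsets=tuple(1.0 + 0.5 * k for k in range(n_channels)),
            coupling=lesion_coupling,
        ),
    ]
    if with_cyst:
        comps.append(
            Compartment(
                name="cyst",
                shape="disk",
                center=(cx / 2.5, cy / 2.5),
                size=max(2.5, lesion_radius / 3.0),
                texture=TextureSpec(kind="constant"),
                channel_offsets=tuple(3.0 - 0.3 * k for k in range(n_channels)),
            )
        )
    return PhantomSpec(
        grid_shape=grid,
        n_channels=n_channels,
        compartments=tuple(comps),
        coupling=coupling,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_cohort(
    n_benign: int = 20,
    n_malignant: int = 20,
    effect_size: float = 1.0,
    seed: int = 0,
    spec: QuantizationSpec | None = None,
    grid: tuple[int, int] = (36, 36),
    n_channels: int = 4,
    include_background: bool = True,
    **phantom_kwargs,
) -> FeatureTable:
    """Simulated two-class cohort with full feature extraction.

    Draws ``n_benign + n_malignant`` lesion phantoms with class-conditional
    texture (see :func:`two_class_phantom_spec`), extracts every feature
    family from the lesion ROI (plus, optionally, the class-independent
    glandular background under a ``gland_`` prefix) and assembles a
    :class:`~mprad.classify.FeatureTable` with labels 0 = benign,
    1 = malignant.  Deterministic given ``seed``.
    """
    if n_benign < 5 or n_malignant < 5:
        raise ValueError("need at least 5 subjects per class")
    if spec is None:
        spec = QuantizationSpec(G=8, B=32)
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_benign + n_malignant)
    rows, ids, labels = [], [], []
    kinds = ["benign"] * n_benign + ["malignant"] * n_malignant
    for i, (kind, s) in enumerate(zip(kinds, sub_seeds)):
        pspec = two_class_phantom_spec(
            kind, int(s), grid=grid, n_channels=n_channels,
            effect_size=effect_size, **phantom_kwargs,
        )
        mpv, masks, _ = generate_phantom(pspec)
        feats = extract_features(mpv, masks["lesion"], spec=spec)
        if include_background:
            gland = masks["glandular"]
            gland_only = ROIMask(gland.mask & ~masks["lesion"].mask, "glandular")
            feats.update(
                extract_features(mpv, gland_only, spec=spec, prefix="gland_")
            )
        rows.append(feats)
        ids.append(f"subj{i:03d}")
        labels.append(0 if kind == "benign" else 1)
    df = pd.DataFrame(rows)
    return FeatureTable(tuple(ids), np.asarray(labels), df)
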