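"""Synthetic agricultural hyperspectral scenes.

Generates labeled reflectance cubes whose statistical shape mimics the
public crop benchmarks: smooth per-class mean spectra (sums of random
Gaussian bumps over the band axis), contiguous single-class fields laid
out on a rectangular grid or as Voronoi cells, spatially correlated
per-band noise, a fraction of unlabeled background pixels, and optional
"corrupted" bands overwritten with high-variance noise to emulate
water-vapor absorption channels.

A designated *confusable pair* of classes can be given nearly identical
mean spectra (mean-curve L2 distance delta) while occupying distinct
fields — the mechanism that defeats a pixelwise spectral classifier but
is rescued by spatial context, as with the notoriously confused
grapes/vineyard classes of the crop benchmark.

Everything is deterministic under the scene seed; each operation draws
from its own child stream so signatures, layout and noise can be
reproduced independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .hsi_io import BandRemovalSpec, GroundTruth, HSICube

__all__ = [
    "SceneConfig",
    "make_signatures",
    "make_scene",
    "render_cube",
    "make_confusable_pair_scene",
]

# child-stream tags, so each generation stage has an independent stream
_SIG, _SCENE, _CUBE = 11, 22, 33


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene.

    Defaults produce a 40×40 scene with 60 bands and 16 contiguous crop
    fields — the desk-scale stand-in for the ~200-band, 16-class public
    scenes.  ``noise_std`` may be a scalar or a per-class sequence;
    ``overlap_delta`` is the L2 distance between the mean spectra of the
    ``confusable_pair`` (None = leave the pair's signatures independent).
    """

    rows: int = 40
    cols: int = 40
    bands: int = 60
    classes: int = 16
    layout: str = "rect-grid"  # or "voronoi"
    n_bumps: int = 6
    bump_width: float = 0.08  # fraction of the band axis
    overlap_delta: Optional[float] = None
    confusable_pair: tuple[int, int] = (8, 15)
    noise_std: float | tuple[float, ...] = 0.05
    texture_length: int = 3  # correlation length of the noise field, pixels
    unlabeled_fraction: float = 0.1
    corrupt_bands: Optional[BandRemovalSpec] = None
    corrupt_noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.overlap_delta is not None and self.overlap_delta < 0:
            raise ValueError("overlap_delta must be >= 0")
        stds = np.atleast_1d(np.asarray(self.noise_std, dtype=float))
        if np.any(stds <= 0):
            raise ValueError("noise std must be positive")
        if stds.size not in (1, self.classes):
            raise ValueError("noise_std must be a scalar or one value per class")
        if self.overlap_delta is not None:
            a, b = self.confusable_pair
            if not (1 <= a <= self.classes and 1 <= b <= self.classes) or a == b:
                raise ValueError("confusable_pair must be two distinct class labels")

    def class_noise_std(self) -> np.ndarray:
        stds = np.atleast_1d(np.asarray(self.noise_std, dtype=float))
        if stds.size == 1:
            stds = np.full(self.classes, stds[0])
        return stds


def _rng(config: SceneConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _smooth_curve(rng: np.random.Generator, n_bands: int, n_bumps: int, width: float) -> np.ndarray:
    """A non-negative smooth spectrum: baseline plus random Gaussian bumps."""
    grid = np.arange(n_bands)
    curve = np.full(n_bands, 0.15)
    sigma = max(width * n_bands, 1.0)
    for _ in range(n_bumps):
        center = rng.uniform(0, n_bands)
        amp = rng.uniform(0.2, 1.0)
        curve += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return curve


def make_signatures(config: SceneConfig) -> np.ndarray:
    """Per-class smooth mean spectra, shape (M, bands), seed-reproducible.

    When ``overlap_delta`` is set, the second class of the confusable
    pair becomes the first class's signature plus a smooth perturbation
    of L2 norm exactly delta (delta = 0 → identical mean spectra).
    """
    rng = _rng(config, _SIG)
    sigs = np.stack(
        [_smooth_curve(rng, config.bands, config.n_bumps, config.bump_width)
         for _ in range(config.classes)]
    )
    if config.overlap_delta is not None:
        a, b = config.confusable_pair
        direction = _smooth_curve(rng, config.bands, max(config.n_bumps // 2, 2), config.bump_width)
        direction -= direction.mean()
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            direction = np.zeros(config.bands)
            direction[0] = 1.0
            norm = 1.0
        sigs[b - 1] = sigs[a - 1] + config.overlap_delta * direction / norm
    return sigs


def _rect_grid_labels(config: SceneConfig) -> np.ndarray:
    M = config.classes
    g_rows = int(np.ceil(np.sqrt(M)))
    g_cols = int(np.ceil(M / g_rows))
    if config.rows < g_rows or config.cols < g_cols:
        raise ValueError(
            f"{config.rows}x{config.cols} grid cannot hold {g_rows}x{g_cols} fields"
        )
    row_edges = np.linspace(0, config.rows, g_rows + 1).astype(int)
    col_edges = np.linspace(0, config.cols, g_cols + 1).astype(int)
    labels = np.zeros((config.rows, config.cols), dtype=int)
    for gi in range(g_rows):
        for gj in range(g_cols):
            region = gi * g_cols + gj
            labels[row_edges[gi]:row_edges[gi + 1], col_edges[gj]:col_edges[gj + 1]] = (
                region % M + 1
            )
    return labels


def _voronoi_labels(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    M = config.classes
    if config.rows * config.cols < M:
        raise ValueError("grid too small to hold one region per class")
    for _ in range(64):
        seeds = np.column_stack(
            [rng.uniform(0, config.rows, M), rng.uniform(0, config.cols, M)]
        )
        rr, cc = np.meshgrid(np.arange(config.rows), np.arange(config.cols), indexing="ij")
        d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
        labels = d2.argmin(axis=2) + 1
        if np.unique(labels).size == M:
            return labels
    raise RuntimeError("could not place a non-empty Voronoi cell for every class")


def make_scene(config: SceneConfig) -> GroundTruth:
    """A contiguous-field label raster with ~10% unlabeled background.

    Every class is guaranteed at least one labeled pixel even after the
    background mask is applied.
    """
    rng = _rng(config, _SCENE)
    if config.layout == "rect-grid":
        labels = _rect_grid_labels(config)
    elif config.layout == "voronoi":
        labels = _voronoi_labels(config, rng)
    else:
        raise ValueError(f"unknown layout {config.layout!r}")
    if config.unlabeled_fraction > 0:
        mask = rng.random(labels.shape) < config.unlabeled_fraction
        masked = labels.copy()
        masked[mask] = 0
        # restore one pixel for any class the mask wiped out entirely
        for cls in range(1, config.classes + 1):
            if not np.any(masked == cls):
                rr, cc = np.nonzero(labels == cls)
                masked[rr[0], cc[0]] = cls
        labels = masked
    names = [f"field-{i:02d}" for i in range(1, config.classes + 1)]
    return GroundTruth(labels, class_names=names)


def _correlated_field(
    rng: np.random.Generator, shape: tuple[int, int, int], length: int
) -> np.ndarray:
    """Unit-variance noise, spatially smoothed to the given correlation length."""
    white = rng.standard_normal(shape)
    if length <= 1:
        return white
    smoothed = uniform_filter(white, size=(length, length, 1), mode="reflect")
    std = smoothed.std()
    return smoothed / (std if std > 0 else 1.0)


def render_cube(
    gt: GroundTruth, signatures: np.ndarray, config: SceneConfig
) -> HSICube:
    """Reflectance cube: class signature + correlated field + white noise.

    Per-class noise scales follow ``config.noise_std``.  Unlabeled pixels
    get a dimmed soil-like background signature.  Bands listed in
    ``corrupt_bands`` are overwritten with high-variance noise to mimic
    water-vapor absorption channels.
    """
    signatures = np.asarray(signatures, dtype=float)
    M, N = signatures.shape
    if M != config.classes or N != config.bands:
        raise ValueError("signature matrix does not match the configuration")
    if gt.labels.shape != (config.rows, config.cols):
        raise ValueError("ground-truth shape does not match the configuration")
    rng = _rng(config, _CUBE)
    background = 0.5 * _smooth_curve(rng, N, config.n_bumps, config.bump_width)
    bank = np.vstack([background[None, :], signatures])  # row 0 = background
    base = bank[gt.labels]
    stds = config.class_noise_std()
    scale_bank = np.concatenate([[stds.mean()], stds])
    scale = scale_bank[gt.labels][..., None]
    shape = (config.rows, config.cols, N)
    correlated = _correlated_field(rng, shape, config.texture_length)
    white = rng.standard_normal(shape)
    values = base + scale * (np.sqrt(0.5) * correlated + np.sqrt(0.5) * white)
    if config.corrupt_bands is not None and len(config.corrupt_bands) > 0:
        idx = np.asarray(config.corrupt_bands.indices()) - 1
        if idx.max() >= N:
            raise ValueError("corrupt band index exceeds the band count")
        values[:, :, idx] = rng.normal(
            0.5, config.corrupt_noise_std, size=(config.rows, config.cols, idx.size)
        )
    return HSICube(values, scene_name=f"synthetic-{config.seed}")


def make_confusable_pair_scene(config: SceneConfig) -> tuple[HSICube, GroundTruth]:
    """A scene whose designated pair is spectrally indistinguishable.

    Forces ``overlap_delta`` to 0 when unset, so the pair's mean spectra
    coincide exactly: a pixelwise classifier can do no better than chance
    on the pair, while an R×R neighborhood (which sees the pair's
    different surrounding fields) can separate them.
    """
    if config.overlap_delta is None:
        config = replace(config, overlap_delta=0.0)
    signatures = make_signatures(config)
    gt = make_scene(config)
    cube = render_cube(gt, signatures, config)
    return cube, gt
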