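"""Input construction for the four classification pipelines.

Covers band removal and zero-masking, train/test pixel splitting, PCA on
pixel spectra, neighborhood-patch extraction, and the three network input
representations:

* the raw pixel spectrum (pixelwise 1D-CNN and BSCNN),
* the augmented spectral–spatial vector of length ``N + R*R*Q`` — the
  pixel's N-band spectrum concatenated with the vectorized first Q
  principal components of its R×R neighborhood,
* the 2D input layer stack (R × R × Q) fed to the 2D-CNN.

A fitted :class:`Preprocessor` packages everything needed to map a raw
pixel of a cube to a network-ready input, so trained models can be
serialized and reapplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA

from .hsi_io import BandRemovalSpec, GroundTruth, HSICube

__all__ = [
    "PCABasis",
    "SampleSplit",
    "PatchGeometry",
    "Standardizer",
    "Preprocessor",
    "remove_bands",
    "mask_bands",
    "split_train_test",
    "pca_fit",
    "pca_transform",
    "extract_patch",
    "build_augmented_vector",
    "build_input_layers",
    "make_batches",
]


# --------------------------------------------------------------------------
# Band removal and masking
# --------------------------------------------------------------------------

def remove_bands(cube: HSICube, spec: BandRemovalSpec) -> HSICube:
    """Drop the listed bands; survivors keep their original 1-based ids.

    Spec indices are matched against the cube's ``band_ids``, so removal
    composes correctly even on an already-reduced cube.
    """
    drop = spec.indices()
    if not drop:
        return HSICube(
            cube.values, cube.band_ids, cube.wavelengths_nm, cube.scene_name
        )
    present = set(cube.band_ids.tolist())
    missing = [i for i in drop if i not in present]
    if missing:
        raise ValueError(f"bands {missing} not present in cube (ids {cube.band_ids.min()}..{cube.band_ids.max()})")
    keep = ~np.isin(cube.band_ids, drop)
    wl = cube.wavelengths_nm[keep] if cube.wavelengths_nm is not None else None
    return HSICube(cube.values[:, :, keep], cube.band_ids[keep], wl, cube.scene_name)


def mask_bands(vector: np.ndarray, keep: Iterable[int]) -> np.ndarray:
    """Zero every entry outside ``keep`` (1-based positions); length unchanged.

    This is the BSCNN masking step: a subset of bands is evaluated by
    resetting the data in all other bands to zero while the input vector
    keeps its full dimension.  Works on a single vector or on a batch
    whose last axis is the band axis.  An empty ``keep`` yields zeros.
    """
    vector = np.asarray(vector, dtype=float)
    n = vector.shape[-1]
    keep_idx = np.asarray(sorted(set(int(k) for k in keep)), dtype=int)
    if keep_idx.size and (keep_idx.min() < 1 or keep_idx.max() > n):
        raise ValueError(f"keep indices must lie in 1..{n}")
    mask = np.zeros(n)
    mask[keep_idx - 1] = 1.0
    return vector * mask


# --------------------------------------------------------------------------
# Train/test splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSplit:
    """A reproducible train/test partition of the labeled pixels.

    ``train_pixels`` / ``test_pixels`` are (n, 3) int arrays of
    (row, col, label); label-0 pixels never appear.
    """

    train_pixels: np.ndarray
    test_pixels: np.ndarray
    fraction: float
    seed: int
    stratified: bool = False

    @property
    def n_train(self) -> int:
        return len(self.train_pixels)

    @property
    def n_test(self) -> int:
        return len(self.test_pixels)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(
    gt: GroundTruth,
    fraction: float,
    seed: int,
    stratified: bool = False,
) -> SampleSplit:
    """Randomly partition the labeled pixels into train and test sets.

    Simple mode draws ``round(fraction * n_labeled)`` training pixels
    uniformly over all labeled pixels (the benchmark protocol selects 50%
    of pixels at random); stratified mode applies the same rounding rule
    per class.  Deterministic for a given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    pixels = gt.labeled_pixels()
    if len(pixels) == 0:
        raise ValueError("ground truth has no labeled pixels")
    rng = np.random.default_rng(seed)
    if stratified:
        train_parts, test_parts = [], []
        for cls in np.unique(pixels[:, 2]):
            cls_pix = pixels[pixels[:, 2] == cls]
            order = rng.permutation(len(cls_pix))
            k = _round_half_up(fraction * len(cls_pix))
            train_parts.append(cls_pix[order[:k]])
            test_parts.append(cls_pix[order[k:]])
        train = np.concatenate(train_parts)
        test = np.concatenate(test_parts)
    else:
        order = rng.permutation(len(pixels))
        k = _round_half_up(fraction * len(pixels))
        train = pixels[order[:k]]
        test = pixels[order[k:]]
    return SampleSplit(train, test, fraction, seed, stratified)


# --------------------------------------------------------------------------
# PCA on pixel spectra
# --------------------------------------------------------------------------

@dataclass
class PCABasis:
    """Top-Q principal directions of the pixelwise spectral covariance.

    Components are rows of an orthonormal (Q, N) matrix, ordered by
    non-increasing explained variance; each component's sign is fixed so
    its largest-magnitude loading is positive (PCA sign is arbitrary and
    determinism requires a rule).
    """

    mean_spectrum: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.components.shape[1]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        """Project (n, N) spectra onto the components after mean-centering."""
        spectra = np.asarray(spectra, dtype=float)
        if spectra.shape[-1] != self.n_bands:
            raise ValueError(
                f"spectra have {spectra.shape[-1]} bands, basis expects {self.n_bands}"
            )
        return (spectra - self.mean_spectrum) @ self.components.T

    def inverse(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct spectra from component scores."""
        return np.asarray(scores, dtype=float) @ self.components + self.mean_spectrum


def pca_fit(
    cube: HSICube,
    Q: int,
    pixel_scope: str = "all",
    train_pixels: Optional[np.ndarray] = None,
) -> PCABasis:
    """Fit the top-Q PCA of the pixel spectra.

    ``pixel_scope="all"`` uses every pixel of the cube (PCA applied to all
    spectral bands of each pixel); ``"train-only"`` restricts the fit to
    the supplied (row, col, ...) training pixels for leakage-sensitive use.
    """
    n = cube.n_bands
    if not 1 <= Q <= n:
        raise ValueError(f"Q must lie in 1..{n}, got {Q}")
    if pixel_scope == "all":
        X = cube.spectra()
    elif pixel_scope == "train-only":
        if train_pixels is None:
            raise ValueError("train-only scope requires train_pixels")
        tp = np.asarray(train_pixels, dtype=int)
        X = cube.values[tp[:, 0], tp[:, 1], :].astype(float)
    else:
        raise ValueError(f"unknown pixel_scope {pixel_scope!r}")
    if X.shape[0] < Q:
        raise ValueError(f"need at least {Q} pixels to fit {Q} components")
    model = PCA(n_components=Q, svd_solver="full")
    model.fit(X)
    components = model.components_.copy()
    for q in range(Q):
        j = int(np.argmax(np.abs(components[q])))
        if components[q, j] < 0:
            components[q] = -components[q]
    return PCABasis(
        mean_spectrum=model.mean_.copy(),
        components=components,
        explained_variance=model.explained_variance_.copy(),
    )


def pca_transform(cube: HSICube, basis: PCABasis) -> np.ndarray:
    """Per-pixel component scores as a (rows, cols, Q) grid."""
    if cube.n_bands != basis.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands, basis expects {basis.n_bands}"
        )
    scores = basis.transform(cube.spectra())
    return scores.reshape(cube.rows, cube.cols, basis.n_components)


# --------------------------------------------------------------------------
# Patch extraction and the three input representations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchGeometry:
    """Neighborhood geometry: window side R (odd), components Q, bands N."""

    R: int
    Q: int
    N: int

    def __post_init__(self) -> None:
        if self.R < 1 or self.R % 2 == 0:
            raise ValueError(f"R must be an odd positive integer, got {self.R}")
        if self.Q < 1:
            raise ValueError(f"Q must be positive, got {self.Q}")
        if self.N < 1:
            raise ValueError(f"N must be positive, got {self.N}")

    @property
    def augmented_length(self) -> int:
        return self.N + self.R * self.R * self.Q


def _pad_grid(grid: np.ndarray, pad: int) -> np.ndarray:
    # mirror reflection at the border keeps patch statistics scene-like
    return np.pad(grid, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")


def extract_patch(grid: np.ndarray, pixel: tuple[int, int], R: int) -> np.ndarray:
    """The R×R×Q window centered on ``pixel`` of a (rows, cols, Q) grid.

    Out-of-image positions are filled by mirror reflection at the border,
    so the shape is always (R, R, Q) and every labeled pixel is usable.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("component grid must be (rows, cols, Q)")
    if R < 1 or R % 2 == 0:
        raise ValueError(f"R must be an odd positive integer, got {R}")
    pad = R // 2
    r, c = pixel
    if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
        raise ValueError(f"pixel {pixel} outside grid {grid.shape[:2]}")
    padded = _pad_grid(grid, pad)
    return padded[r : r + R, c : c + R, :].copy()


def extract_patches(grid: np.ndarray, pixels: np.ndarray, R: int) -> np.ndarray:
    """Vectorized :func:`extract_patch` for many pixels → (n, R, R, Q)."""
    grid = np.asarray(grid)
    if R < 1 or R % 2 == 0:
        raise ValueError(f"R must be an odd positive integer, got {R}")
    pad = R // 2
    padded = _pad_grid(grid, pad)
    windows = sliding_window_view(padded, (R, R), axis=(0, 1))  # (rows, cols, Q, R, R)
    pixels = np.asarray(pixels, dtype=int)
    picked = windows[pixels[:, 0], pixels[:, 1]]  # (n, Q, R, R)
    return np.ascontiguousarray(picked.transpose(0, 2, 3, 1))


def build_augmented_vector(
    spectrum: np.ndarray,
    patch: np.ndarray,
    spectrum_standardizer: "Standardizer | None" = None,
    patch_standardizer: "Standardizer | None" = None,
) -> np.ndarray:
    """Concatenate a pixel spectrum with its vectorized PCA patch.

    The first N entries are the (optionally standardized) spectrum; the
    remaining R·R·Q entries are the patch vectorized row-major with the
    component index fastest.  Output length is ``N + R*R*Q``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    patch = np.asarray(patch, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("spectrum must be a 1D vector")
    if patch.ndim != 3 or patch.shape[0] != patch.shape[1] or patch.shape[0] % 2 == 0:
        raise ValueError(f"patch must be (R, R, Q) with odd R, got {patch.shape}")
    if spectrum_standardizer is not None:
        spectrum = spectrum_standardizer.transform(spectrum)
    if patch_standardizer is not None:
        patch = patch_standardizer.transform(patch)
    return np.concatenate([spectrum, patch.reshape(-1)])


def build_input_layers(grid: np.ndarray, pixel: tuple[int, int], R: int) -> np.ndarray:
    """The 2D-CNN input: the R×R neighborhood of the Q-component grid.

    Returned as (R, R, Q); Q is the channel count.
    """
    return extract_patch(grid, pixel, R)


# --------------------------------------------------------------------------
# Mini-batching
# --------------------------------------------------------------------------

def make_batches(
    n_samples: int,
    batch_size: int,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """A random permutation of sample indices cut into mini-batches.

    The last short batch is kept, except that a trailing batch of size 1
    is merged into the previous one (mini-batch statistics are undefined
    for a single sample), e.g. 33 samples at size 16 → batches of 16, 17.
    """
    if batch_size < 2:
        raise ValueError(f"batch_size must be >= 2, got {batch_size}")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    batches = [order[i : i + batch_size] for i in range(0, n_samples, batch_size)]
    if len(batches) > 1 and len(batches[-1]) == 1:
        tail = batches.pop()
        batches[-1] = np.concatenate([batches[-1], tail])
    return batches


# --------------------------------------------------------------------------
# Feature standardization
# --------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature zero-mean / unit-variance scaling from training data.

    Features with (near-)zero spread pass through uncentered-scale 1 to
    avoid blowing up constant bands.
    """

    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float).reshape(-1, np.asarray(X).shape[-1])
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std < 1e-8] = 1.0
        self.std = std
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValueError("standardizer is not fitted")
        return (np.asarray(X, dtype=float) - self.mean) / self.std


# --------------------------------------------------------------------------
# The fitted preprocessing state of a trained model
# --------------------------------------------------------------------------

@dataclass
class Preprocessor:
    """Maps raw cube pixels to network-ready inputs for one pipeline.

    ``mode`` selects the representation: ``"spectral"`` (pixel spectrum,
    also used by BSCNN via ``keep_bands``), ``"augmented"`` (spectrum +
    vectorized PCA patch) or ``"layers"`` (R×R×Q stack for the 2D-CNN).
    """

    mode: str
    band_removal: Optional[BandRemovalSpec] = None
    keep_bands: Optional[tuple[int, ...]] = None  # 1-based over retained bands
    standardize: bool = True
    geometry: Optional[PatchGeometry] = None
    pca_scope: str = "all"
    # fitted state
    spectrum_scaler: Optional[Standardizer] = None
    score_scaler: Optional[Standardizer] = None
    pca_basis: Optional[PCABasis] = None
    n_bands: Optional[int] = None

    def _reduced(self, cube: HSICube) -> HSICube:
        if self.band_removal is not None and len(self.band_removal) > 0:
            return remove_bands(cube, self.band_removal)
        return cube

    def fit(self, cube: HSICube, train_pixels: np.ndarray) -> "Preprocessor":
        if self.mode not in ("spectral", "augmented", "layers"):
            raise ValueError(f"unknown mode {self.mode!r}")
        reduced = self._reduced(cube)
        self.n_bands = reduced.n_bands
        tp = np.asarray(train_pixels, dtype=int)
        train_spectra = reduced.values[tp[:, 0], tp[:, 1], :].astype(float)
        if self.standardize:
            self.spectrum_scaler = Standardizer().fit(train_spectra)
        if self.mode in ("augmented", "layers"):
            if self.geometry is None:
                raise ValueError(f"mode {self.mode!r} requires a PatchGeometry")
            if self.geometry.N != reduced.n_bands:
                raise ValueError(
                    f"geometry expects N={self.geometry.N} bands, cube has {reduced.n_bands}"
                )
            self.pca_basis = pca_fit(
                reduced, self.geometry.Q, pixel_scope=self.pca_scope, train_pixels=tp
            )
            grid = pca_transform(reduced, self.pca_basis)
            if self.standardize:
                self.score_scaler = Standardizer().fit(grid[tp[:, 0], tp[:, 1], :])
        return self

    def transform(self, cube: HSICube, pixels: np.ndarray) -> np.ndarray:
        """Network-ready inputs for (row, col, ...) pixels of ``cube``.

        Returns (n, N) vectors for spectral mode, (n, N + R*R*Q) for
        augmented mode, and (n, R, R, Q) stacks for layers mode.
        """
        reduced = self._reduced(cube)
        if self.n_bands is not None and reduced.n_bands != self.n_bands:
            raise ValueError(
                f"cube has {reduced.n_bands} retained bands, model expects {self.n_bands}"
            )
        px = np.asarray(pixels, dtype=int)
        spectra = reduced.values[px[:, 0], px[:, 1], :].astype(float)
        if self.spectrum_scaler is not None:
            spectra = self.spectrum_scaler.transform(spectra)
        if self.mode == "spectral":
            if self.keep_bands is not None:
                spectra = mask_bands(spectra, self.keep_bands)
            return spectra
        grid = pca_transform(reduced, self.pca_basis)
        if self.score_scaler is not None:
            grid = self.score_scaler.transform(grid)
        patches = extract_patches(grid, px, self.geometry.R)
        if self.mode == "layers":
            return patches
        return np.concatenate([spectra, patches.reshape(len(px), -1)], axis=1)

    @property
    def input_size(self) -> int | tuple[int, int, int]:
        if self.n_bands is None:
            raise ValueError("preprocessor is not fitted")
        if self.mode == "spectral":
            return self.n_bands
        g = self.geometry
        if self.mode == "augmented":
            return g.augmented_length
        return (g.R, g.R, g.Q)

    # -- serialization ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        if self.spectrum_scaler is not None:
            arrays["pp_spec_mean"] = self.spectrum_scaler.mean
            arrays["pp_spec_std"] = self.spectrum_scaler.std
        if self.score_scaler is not None:
            arrays["pp_score_mean"] = self.score_scaler.mean
            arrays["pp_score_std"] = self.score_scaler.std
        if self.pca_basis is not None:
            arrays["pp_pca_mean"] = self.pca_basis.mean_spectrum
            arrays["pp_pca_components"] = self.pca_basis.components
            arrays["pp_pca_variance"] = self.pca_basis.explained_variance
        return arrays

    def meta(self) -> dict:
        return {
            "mode": self.mode,
            "band_removal": str(self.band_removal) if self.band_removal else "",
            "keep_bands": list(self.keep_bands) if self.keep_bands else None,
            "standardize": self.standardize,
            "geometry": (
                {"R": self.geometry.R, "Q": self.geometry.Q, "N": self.geometry.N}
                if self.geometry
                else None
            ),
            "pca_scope": self.pca_scope,
            "n_bands": self.n_bands,
        }

    @classmethod
    def from_state(cls, meta: dict, arrays: dict[str, np.ndarray]) -> "Preprocessor":
        from .hsi_io import parse_band_removal

        geometry = None
        if meta.get("geometry"):
            g = meta["geometry"]
            geometry = PatchGeometry(R=g["R"], Q=g["Q"], N=g["N"])
        pp = cls(
            mode=meta["mode"],
            band_removal=parse_band_removal(meta["band_removal"]) if meta.get("band_removal") else None,
            keep_bands=tuple(meta["keep_bands"]) if meta.get("keep_bands") else None,
            standardize=meta["standardize"],
            geometry=geometry,
            pca_scope=meta.get("pca_scope", "all"),
            n_bands=meta.get("n_bands"),
        )
        if "pp_spec_mean" in arrays:
            pp.spectrum_scaler = Standardizer(arrays["pp_spec_mean"], arrays["pp_spec_std"])
        if "pp_score_mean" in arrays:
            pp.score_scaler = Standardizer(arrays["pp_score_mean"], arrays["pp_score_std"])
        if "pp_pca_mean" in arrays:
            pp.pca_basis = PCABasis(
                arrays["pp_pca_mean"], arrays["pp_pca_components"], arrays["pp_pca_variance"]
            )
        return pp
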