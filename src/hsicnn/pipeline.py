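"""End-to-end pipeline runs: remove bands → split → build inputs → train
→ predict → evaluate → render map.

Four pipelines are wired, differing only in the input representation and
architecture:

* ``spectral-1d`` — pixel spectra into the 1D-CNN;
* ``bscnn``       — spectral-1d trained on all bands, band subsets scored
  by zero-masking on a validation split held out from the training
  pixels, best subset retrained;
* ``augmented-1d``— spectrum + vectorized PCA neighborhood (length
  N + R·R·Q) into the 1D-CNN;
* ``pca-2d``      — R×R×Q principal-component layers into the 2D-CNN.

One global seed fans out to named sub-seeds (split, training, band
selection) so each component can be reproduced independently.  Every run
writes a manifest of its effective settings sufficient to re-run it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .band_selection import BandSubset, retrain_with_subset, select_bands
from .cnn_core import (
    TrainConfig,
    TrainedModel,
    build_spec_1d,
    build_spec_2d,
    save_model,
    train,
)
from .evaluation import EvalReport
from .hsi_io import (
    GroundTruth,
    HSICube,
    default_palette,
    load_cube,
    load_ground_truth,
    parse_band_removal,
    save_classification_map,
)
from .preprocess import PatchGeometry, Preprocessor, split_train_test

__all__ = ["RunConfig", "PipelineResult", "PipelineStageError", "run_pipeline", "run_sweep"]

logger = logging.getLogger("hsicnn")

PIPELINES = ("spectral-1d", "bscnn", "augmented-1d", "pca-2d")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to run one pipeline end to end.

    ``cube_path``/``gt_path`` may be left None when arrays are passed to
    :func:`run_pipeline` directly (as the synthetic tests do).
    """

    pipeline: str = "spectral-1d"
    cube_path: Optional[str] = None
    gt_path: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0
    # splitting
    fraction: float = 0.5
    stratified: bool = False
    # band handling
    band_removal: str = ""
    n_prime: Optional[int] = None  # BSCNN subset size
    n_trials: int = 100  # BSCNN trials L
    selection_holdout: float = 0.2  # validation share of train pixels for scoring
    # spatial representation
    R: int = 21
    Q: int = 1
    pca_scope: str = "all"
    standardize: bool = True
    # training
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    depth: int = 4
    filters: int = 20

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(f"pipeline must be one of {PIPELINES}, got {self.pipeline!r}")
        if self.pipeline == "bscnn" and self.n_prime is None:
            raise ValueError("bscnn requires n_prime (the subset size N')")
        if self.pipeline in ("augmented-1d", "pca-2d"):
            if self.R < 1 or self.R % 2 == 0:
                raise ValueError(f"R must be an odd positive integer, got {self.R}")
            if self.Q < 1:
                raise ValueError(f"Q must be >= 1, got {self.Q}")
        if not 0 < self.selection_holdout < 1:
            raise ValueError("selection_holdout must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data["config"])


@dataclass
class PipelineResult:
    report: EvalReport
    model: TrainedModel
    map_labels: np.ndarray
    manifest: dict
    band_subset: Optional[BandSubset] = None
    out_dir: Optional[Path] = None


def _derive_seeds(seed: int) -> dict[str, int]:
    names = ("split", "train", "bands", "holdout")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


class _Stage:
    """Log the wall time of one pipeline stage and name it on failure."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
            return False
        logger.error("stage %s: failed after %.2fs (%s)", self.name, dt, exc)
        if not isinstance(exc, PipelineStageError):
            raise PipelineStageError(self.name, exc) from exc
        return False


def run_pipeline(
    config: RunConfig,
    cube: Optional[HSICube] = None,
    gt: Optional[GroundTruth] = None,
) -> PipelineResult:
    """Execute one pipeline and (if ``out_dir`` is set) write its artifacts.

    Artifacts: ``report.json``/``report.csv`` (per-class PA + OA),
    ``map.png``/``map.csv`` (predicted labels on labeled pixels, black
    elsewhere), ``model.npz`` and ``manifest.json``.  Partial outputs are
    removed when a stage fails.
    """
    seeds = _derive_seeds(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    created: list[Path] = []
    try:
        with _Stage("load"):
            if cube is None:
                if config.cube_path is None:
                    raise ValueError("no cube given: set cube_path or pass a cube")
                cube = load_cube(config.cube_path)
            if gt is None:
                if config.gt_path is None:
                    raise ValueError("no ground truth given: set gt_path or pass one")
                gt = load_ground_truth(config.gt_path)
            if gt.labels.shape != (cube.rows, cube.cols):
                raise ValueError("ground truth shape does not match the cube")

        with _Stage("split"):
            split = split_train_test(gt, config.fraction, seeds["split"], config.stratified)

        with _Stage("preprocess"):
            removal = parse_band_removal(config.band_removal)
            n_retained = cube.n_bands - len(removal)
            mode = {"spectral-1d": "spectral", "bscnn": "spectral",
                    "augmented-1d": "augmented", "pca-2d": "layers"}[config.pipeline]
            geometry = None
            if mode in ("augmented", "layers"):
                geometry = PatchGeometry(R=config.R, Q=config.Q, N=n_retained)
            pp = Preprocessor(
                mode=mode,
                band_removal=removal if len(removal) else None,
                standardize=config.standardize,
                geometry=geometry,
                pca_scope=config.pca_scope,
            ).fit(cube, split.train_pixels)
            X_train = pp.transform(cube, split.train_pixels)
            y_train = split.train_pixels[:, 2]
            if mode == "augmented":
                logger.info("augmented input length: %d", X_train.shape[1])

        with _Stage("build-spec"):
            M = gt.n_classes
            if config.pipeline == "pca-2d":
                spec = build_spec_2d(config.R, config.Q, M, config.depth, config.filters)
            else:
                spec = build_spec_1d(X_train.shape[1], M, config.depth, config.filters)

        train_cfg = TrainConfig(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=seeds["train"],
        )

        band_subset: Optional[BandSubset] = None
        selection_table: Optional[pd.DataFrame] = None
        if config.pipeline == "bscnn":
            with _Stage("train-full"):
                net, history = train(spec, X_train, y_train, train_cfg)
                full_model = TrainedModel(spec, net, pp, gt.class_names, history)
            with _Stage("band-select"):
                hold_rng = np.random.default_rng(seeds["holdout"])
                order = hold_rng.permutation(len(X_train))
                n_hold = max(int(round(config.selection_holdout * len(X_train))), 1)
                hold, keep = order[:n_hold], order[n_hold:]
                band_subset, selection_table = select_bands(
                    full_model, X_train[hold], y_train[hold],
                    config.n_prime, config.n_trials, seeds["bands"],
                )
                logger.info(
                    "selected %d bands with validation OA %.4f",
                    band_subset.n_kept, band_subset.score_oa,
                )
            with _Stage("retrain"):
                net, history = retrain_with_subset(
                    band_subset, spec, X_train, y_train, train_cfg
                )
                pp = replace_keep_bands(pp, band_subset.kept_band_indices)
        else:
            with _Stage("train"):
                net, history = train(spec, X_train, y_train, train_cfg)

        model = TrainedModel(spec, net, pp, gt.class_names, history)

        with _Stage("predict"):
            labeled = gt.labeled_pixels()
            pred_all, _ = model.predict_pixels(cube, labeled)
            map_labels = np.zeros_like(gt.labels)
            map_labels[labeled[:, 0], labeled[:, 1]] = pred_all

        with _Stage("evaluate"):
            test_mask = _membership(labeled[:, :2], split.test_pixels[:, :2])
            report = EvalReport.from_predictions(
                labeled[test_mask, 2], pred_all[test_mask], gt.class_names
            )
            logger.info("test OA %.4f over %d pixels", report.oa, report.n_test)

        manifest = {
            "config": asdict(config),
            "seeds": seeds,
            "n_train": split.n_train,
            "n_test": split.n_test,
            "n_retained_bands": n_retained,
            "input_size": spec.input_size if isinstance(spec.input_size, int) else list(spec.input_size),
            "overall_accuracy": report.oa,
            "selected_bands": list(band_subset.kept_band_indices) if band_subset else None,
        }

        if out_dir is not None:
            with _Stage("write"):
                out_dir.mkdir(parents=True, exist_ok=True)
                created.append(report.to_json(out_dir / "report.json"))
                created.append(report.to_csv(out_dir / "report.csv"))
                png, csv = save_classification_map(
                    map_labels, default_palette(gt.n_classes), out_dir / "map.png"
                )
                created += [png, csv]
                created.append(save_model(model, out_dir / "model.npz"))
                if selection_table is not None:
                    sel_path = out_dir / "band_selection.csv"
                    selection_table.to_csv(sel_path, index=False)
                    created.append(sel_path)
                manifest_path = out_dir / "manifest.json"
                manifest_path.write_text(json.dumps(manifest, indent=2))
                created.append(manifest_path)

        return PipelineResult(report, model, map_labels, manifest, band_subset, out_dir)
    except PipelineStageError:
        for path in created:
            path.unlink(missing_ok=True)
        raise


def replace_keep_bands(pp: Preprocessor, kept: Sequence[int]) -> Preprocessor:
    """A copy of a fitted spectral preprocessor with the BSCNN mask set."""
    import copy

    out = copy.deepcopy(pp)
    out.keep_bands = tuple(int(i) for i in kept)
    return out


def _membership(pixels: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Boolean mask of rows of ``pixels`` that appear in ``subset``."""
    ncols = pixels.shape[1]
    a = pixels.astype(np.int64)
    b = subset.astype(np.int64)
    scale = max(a[:, 1].max(initial=0), b[:, 1].max(initial=0)) + 1
    return np.isin(a[:, 0] * scale + a[:, 1], b[:, 0] * scale + b[:, 1])


def run_sweep(
    config: RunConfig,
    sweep: str,
    values: Sequence[int],
    cube: Optional[HSICube] = None,
    gt: Optional[GroundTruth] = None,
) -> pd.DataFrame:
    """One full pipeline run per sweep value; returns a (value, OA) table.

    ``sweep`` is ``"bands"`` (BSCNN subset size N′) or ``"components"``
    (principal components Q).  Invalid values are rejected before any
    training; a failed run flags its row and the sweep continues.
    """
    if sweep not in ("bands", "components"):
        raise ValueError("sweep must be 'bands' or 'components'")
    values = [int(v) for v in values]
    if sweep == "bands":
        if cube is None and config.cube_path:
            cube = load_cube(config.cube_path)
        if cube is None:
            raise ValueError("band sweep needs the cube to validate counts")
        n_retained = cube.n_bands - len(parse_band_removal(config.band_removal))
        bad = [v for v in values if not 1 <= v < n_retained]
        if bad:
            raise ValueError(f"band counts {bad} are not in 1..{n_retained - 1}")
    else:
        bad = [v for v in values if v < 1]
        if bad:
            raise ValueError(f"component counts must be >= 1, got {bad}")
    rows = []
    for v in values:
        run_cfg = replace(
            config,
            out_dir=None,
            **({"n_prime": v, "pipeline": "bscnn"} if sweep == "bands" else {"Q": v}),
        )
        try:
            result = run_pipeline(run_cfg, cube=cube, gt=gt)
            rows.append({"value": v, "oa": result.report.oa, "error": ""})
        except PipelineStageError as exc:
            logger.error("sweep value %d failed: %s", v, exc)
            rows.append({"value": v, "oa": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
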