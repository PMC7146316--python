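"""CNN-based band selection (BSCNN).

The wrapper procedure: train a 1D-CNN once on all N bands, then score L
random N′-band subsets by zero-masking the evaluation inputs outside each
subset and measuring overall accuracy with the *frozen* network; the
best-scoring subset is adopted and a fresh network is retrained on
inputs masked to it (the input vector keeps its full length N, with the
unselected bands reset to zero).

Scoring uses whatever evaluation samples the caller supplies; the
pipeline defaults to a validation split held out from the training
pixels so the test set never influences selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnn_core import TrainConfig, TrainedModel, predict_proba, train
from .evaluation import confusion_matrix, overall_accuracy
from .preprocess import mask_bands

__all__ = [
    "BandSubset",
    "sample_subsets",
    "evaluate_subset",
    "select_bands",
    "retrain_with_subset",
    "sweep_band_counts",
]


@dataclass(frozen=True)
class BandSubset:
    """One candidate subset: N′ kept band positions (1-based over the
    retained bands) with its overall-accuracy score."""

    kept_band_indices: tuple[int, ...]
    score_oa: float = float("nan")
    trial_id: int = -1

    def __post_init__(self) -> None:
        idx = tuple(sorted(set(int(i) for i in self.kept_band_indices)))
        if len(idx) != len(self.kept_band_indices):
            raise ValueError("kept_band_indices contains duplicates")
        object.__setattr__(self, "kept_band_indices", idx)

    @property
    def n_kept(self) -> int:
        return len(self.kept_band_indices)


def sample_subsets(
    N: int, N_prime: int, L: int, seed: int
) -> list[BandSubset]:
    """L uniform random N′-subsets of 1..N, independently per trial.

    N′ must be strictly smaller than N; trials may repeat a subset
    (sampling is independent, no deduplication).
    """
    if not 1 <= N_prime < N:
        raise ValueError(f"need 1 <= N' < N, got N'={N_prime}, N={N}")
    if L < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    subsets = []
    for t in range(L):
        kept = rng.choice(N, size=N_prime, replace=False) + 1
        subsets.append(BandSubset(tuple(int(i) for i in kept), trial_id=t))
    return subsets


def evaluate_subset(
    model: TrainedModel,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    subset: BandSubset,
) -> float:
    """Overall accuracy of the frozen model on zero-masked inputs.

    ``X_eval`` are network-ready spectral inputs (n, N); every entry
    outside the subset is reset to zero before the forward pass.  Model
    parameters are never touched.  Masking with the full band set
    reproduces the unmasked accuracy bit-exactly (the mask is then the
    identity).
    """
    if model.spec.dimensionality != "1d":
        raise ValueError("band selection applies to the pixelwise 1D-CNN")
    X_eval = np.asarray(X_eval, dtype=float)
    n_bands = X_eval.shape[1]
    if subset.kept_band_indices and max(subset.kept_band_indices) > n_bands:
        raise ValueError(
            f"subset index {max(subset.kept_band_indices)} exceeds the {n_bands} input bands"
        )
    masked = mask_bands(X_eval, subset.kept_band_indices)
    pred = np.argmax(predict_proba(model.network, masked), axis=1) + 1
    conf = confusion_matrix(y_eval, pred, model.spec.n_classes)
    return overall_accuracy(conf)


def select_bands(
    model: TrainedModel,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    N_prime: int,
    L: int,
    seed: int,
) -> tuple[BandSubset, pd.DataFrame]:
    """Score L random subsets and return the argmax-OA one plus the score table.

    Ties break toward the earliest trial.  The table has one row per
    trial (trial_id, n_kept, bands, oa), ready to dump as CSV.
    """
    N = int(np.asarray(X_eval).shape[1])
    candidates = sample_subsets(N, N_prime, L, seed)
    rows = []
    best: Optional[BandSubset] = None
    for cand in candidates:
        oa = evaluate_subset(model, X_eval, y_eval, cand)
        scored = BandSubset(cand.kept_band_indices, score_oa=oa, trial_id=cand.trial_id)
        rows.append(
            {
                "trial_id": scored.trial_id,
                "n_kept": scored.n_kept,
                "bands": " ".join(map(str, scored.kept_band_indices)),
                "oa": oa,
            }
        )
        if best is None or oa > best.score_oa:
            best = scored
    return best, pd.DataFrame(rows)


def retrain_with_subset(
    subset: BandSubset,
    spec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
):
    """Train a fresh network on inputs zero-masked to the subset.

    The input length stays N — unselected bands are zeros, exactly as
    they will be at prediction time.  Returns (network, loss_history).
    """
    X_train = np.asarray(X_train, dtype=float)
    if subset.kept_band_indices and max(subset.kept_band_indices) > X_train.shape[1]:
        raise ValueError("subset indices exceed the input band count")
    masked = mask_bands(X_train, subset.kept_band_indices)
    return train(spec, masked, y_train, config)


def sweep_band_counts(
    model: TrainedModel,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    counts: Sequence[int],
    L: int,
    seed: int,
) -> pd.DataFrame:
    """Best selection score per candidate band count N′.

    Runs one full :func:`select_bands` per count (each with its own
    derived seed) and returns a plottable table (n_bands, best_oa,
    best_bands) — the band-number sweep behind choosing N′.
    """
    N = int(np.asarray(X_eval).shape[1])
    bad = [c for c in counts if not 1 <= c < N]
    if bad:
        raise ValueError(f"band counts {bad} are not in 1..{N - 1}")
    child_seeds = np.random.SeedSequence(seed).spawn(len(counts))
    rows = []
    for count, child in zip(counts, child_seeds):
        best, _ = select_bands(
            model, X_eval, y_eval, count, L, int(child.generate_state(1)[0] % 2**31)
        )
        rows.append(
            {
                "n_bands": count,
                "best_oa": best.score_oa,
                "best_bands": " ".join(map(str, best.kept_band_indices)),
            }
        )
    return pd.DataFrame(rows)
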