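"""Leakage-free repeated evaluation protocol.

For each repetition seed the data are stratified-split 8:2 into a
training-pool and a test set, and the pool again 8:2 into training and
validation rows (64/16/20 overall, class ratios preserved within one
sample per part). The reducer is fitted on training rows only (the
validation rows additionally steer autoencoder early stopping; PCA and
random projection, which need no early stopping, are fitted on the
merged 80% pool), the trained reducer encodes all parts, classifier
hyper-parameters are chosen by 5-fold cross-validated accuracy on the
encoded pool, the selected model is refit on the whole encoded pool,
and AUC / AUPRC / accuracy are measured on the encoded test rows —
which never reach any parameter-fitting step. The procedure repeats
over n_repeats consecutive seeds and the per-seed AUCs are averaged.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from .classification import (
    Algorithm,
    ClassifierSpec,
    cross_validate_select,
    fit_and_score,
)
from .profiles import LabelVector, ProfileMatrix
from .representation import (
    AEArchitecture,
    AEKind,
    pca_reduce,
    rp_reduce,
    train_autoencoder,
)

__all__ = [
    "Reducer",
    "DataSplit",
    "RunConfig",
    "SeedResult",
    "EvaluationResult",
    "EvaluationError",
    "LeakageRecorder",
    "stratified_split",
    "run_once",
    "repeat_evaluation",
    "write_results",
]


class EvaluationError(RuntimeError):
    pass


class Reducer(str, enum.Enum):
    NONE = "none"
    PCA = "PCA"
    RP = "RP"
    SAE = "SAE"
    DAE = "DAE"
    VAE = "VAE"
    CAE = "CAE"

    @property
    def is_autoencoder(self) -> bool:
        return self in (Reducer.SAE, Reducer.DAE, Reducer.VAE, Reducer.CAE)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint stratified train/validation/test index sets for one seed."""

    train_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        for name in ("train_idx", "validation_idx", "test_idx"):
            object.__setattr__(self, name, np.sort(np.asarray(getattr(self, name), dtype=int)))
        all_idx = np.concatenate([self.train_idx, self.validation_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise EvaluationError("split parts overlap")

    @property
    def pool_idx(self) -> np.ndarray:
        """Training pool = train + validation (the outer 80%)."""
        return np.sort(np.concatenate([self.train_idx, self.validation_idx]))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels: LabelVector, seed: int) -> DataSplit:
    """64/16/20 stratified split: outer 8:2 (pool vs test), inner 8:2
    (train vs validation), per-class counts rounded half-up.

    Deterministic given ``seed``; requires >= 5 samples in each class.
    """
    y = np.asarray(labels.labels if isinstance(labels, LabelVector) else labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 5:
        raise EvaluationError(
            f"each class needs >= 5 samples to stratify, got counts {counts.tolist()}"
        )
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = _round_half_up(0.2 * len(idx))
        rest = idx[n_test:]
        n_val = _round_half_up(0.2 * len(rest))
        test.append(idx[:n_test])
        val.append(rest[:n_val])
        train.append(rest[n_val:])
    return DataSplit(
        train_idx=np.concatenate(train),
        validation_idx=np.concatenate(val),
        test_idx=np.concatenate(test),
        seed=seed,
    )


@dataclass(frozen=True)
class RunConfig:
    """What to run: a reducer (with architecture if an AE), a classifier,
    and the repetition plan."""

    reducer: Reducer = Reducer.NONE
    reducer_architecture: AEArchitecture | None = None
    classifier: Algorithm = Algorithm.RF
    n_repeats: int = 5
    base_seed: int = 0
    train_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "reducer", Reducer(self.reducer))
        object.__setattr__(self, "classifier", Algorithm(self.classifier))
        if self.reducer.is_autoencoder and self.reducer_architecture is None:
            raise EvaluationError(
                f"reducer {self.reducer.value} requires reducer_architecture"
            )
        if not self.reducer.is_autoencoder and self.reducer_architecture is not None:
            raise EvaluationError(
                "reducer_architecture is only meaningful for autoencoder reducers"
            )


@dataclass(frozen=True)
class SeedResult:
    seed: int
    best_spec: ClassifierSpec
    auc: float
    auprc: float
    accuracy: float


@dataclass(frozen=True)
class EvaluationResult:
    """Per-seed metrics plus cross-seed means."""

    config: RunConfig
    per_seed: tuple
    mean_auc: float
    mean_auprc: float
    mean_accuracy: float


class LeakageRecorder:
    """Instrumentation hook: records the sample indices visible to every
    parameter-fitting stage so tests can prove the test set never leaks."""

    def __init__(self):
        self.events: list[tuple[str, np.ndarray]] = []

    def record(self, stage: str, indices) -> None:
        self.events.append((stage, np.asarray(indices, dtype=int).copy()))

    def fitted_indices(self) -> np.ndarray:
        if not self.events:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([idx for _, idx in self.events]))


def _encode_parts(profile_values, split, config, seed, recorder):
    """Fit the reducer leakage-free; return encoded (pool, test) matrices."""
    reducer = config.reducer
    x = profile_values
    pool, test = split.pool_idx, split.test_idx
    if reducer is Reducer.NONE:
        return x[pool], x[test]
    if reducer is Reducer.PCA:
        if recorder:
            recorder.record("pca_fit", pool)
        return pca_reduce(x[pool], x[test])
    if reducer is Reducer.RP:
        if recorder:
            recorder.record("rp_fit", pool)
        return rp_reduce(x[pool], x[test], seed=seed)
    # autoencoder: gradient updates see train only, validation rows steer
    # early stopping; both are encoded and merged as the classifier pool
    if recorder:
        recorder.record("ae_fit", pool)
    encoder = train_autoencoder(
        config.reducer_architecture,
        x[split.train_idx],
        x[split.validation_idx],
        seed,
        **config.train_kwargs,
    )
    return encoder.transform(x[pool]), encoder.transform(x[test])


def run_once(
    profiles: ProfileMatrix,
    labels: LabelVector,
    config: RunConfig,
    seed: int,
    recorder: LeakageRecorder | None = None,
) -> SeedResult:
    """One repetition: split, fit reducer, select classifier, score test."""
    x = profiles.values if isinstance(profiles, ProfileMatrix) else np.asarray(profiles)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if isinstance(labels, LabelVector):
        labels.require_both_classes()

    stage = "split"
    try:
        split = stratified_split(labels, seed)
        stage = "reduce"
        pool_x, test_x = _encode_parts(x, split, config, seed, recorder)
        stage = "select"
        if recorder:
            recorder.record("cv_select", split.pool_idx)
        selection = cross_validate_select(pool_x, y[split.pool_idx], config.classifier, seed)
        stage = "score"
        auc, auprc, accuracy, _ = fit_and_score(
            pool_x, y[split.pool_idx], test_x, y[split.test_idx], selection.best_spec, seed
        )
    except Exception as exc:  # attach the failing stage for diagnosis
        raise EvaluationError(f"stage '{stage}' failed for seed {seed}: {exc}") from exc
    return SeedResult(seed, selection.best_spec, auc, auprc, accuracy)


def run_once_ae_grid(
    profiles: ProfileMatrix,
    labels: LabelVector,
    kind: AEKind,
    classifier: Algorithm,
    seed: int,
    train_kwargs: dict | None = None,
) -> tuple[SeedResult, AEArchitecture]:
    """One repetition searching the whole architecture grid of one AE family.

    Every architecture is trained on the training rows; the one with the
    lowest validation reconstruction loss is selected for encoding, so
    architecture choice — like hyper-parameter choice — never sees the
    test set. Returns the seed result and the winning architecture.
    """
    from .representation import enumerate_ae_grid

    x = profiles.values
    y = labels.labels
    split = stratified_split(labels, seed)
    best = None
    for arch in enumerate_ae_grid(kind, x.shape[1]):
        encoder = train_autoencoder(
            arch, x[split.train_idx], x[split.validation_idx], seed,
            **(train_kwargs or {}),
        )
        val = min(encoder.training_log.val_loss)
        if best is None or val < best[0]:
            best = (val, encoder)
    encoder = best[1]
    pool_x = encoder.transform(x[split.pool_idx])
    test_x = encoder.transform(x[split.test_idx])
    selection = cross_validate_select(pool_x, y[split.pool_idx], classifier, seed)
    auc, auprc, accuracy, _ = fit_and_score(
        pool_x, y[split.pool_idx], test_x, y[split.test_idx], selection.best_spec, seed
    )
    return SeedResult(seed, selection.best_spec, auc, auprc, accuracy), encoder.architecture


def repeat_evaluation(
    profiles: ProfileMatrix, labels: LabelVector, config: RunConfig
) -> EvaluationResult:
    """Run seeds base_seed … base_seed + n_repeats − 1 and average."""
    per_seed = tuple(
        run_once(profiles, labels, config, config.base_seed + i)
        for i in range(config.n_repeats)
    )
    return EvaluationResult(
        config=config,
        per_seed=per_seed,
        mean_auc=float(np.mean([r.auc for r in per_seed])),
        mean_auprc=float(np.mean([r.auprc for r in per_seed])),
        mean_accuracy=float(np.mean([r.accuracy for r in per_seed])),
    )


def write_results(result: EvaluationResult, path) -> None:
    """Write a per-seed TSV (with a summary row) and a JSON twin."""
    arch = result.config.reducer_architecture
    arch_text = arch.describe() if arch is not None else "-"
    header = "seed\treducer\tarchitecture\tclassifier\tbest_hyper_parameters\tauc\tauprc\taccuracy"
    lines = [header]
    for r in result.per_seed:
        lines.append(
            f"{r.seed}\t{result.config.reducer.value}\t{arch_text}\t"
            f"{result.config.classifier.value}\t{r.best_spec.to_text()}\t"
            f"{r.auc:.6f}\t{r.auprc:.6f}\t{r.accuracy:.6f}"
        )
    lines.append(
        f"mean\t{result.config.reducer.value}\t{arch_text}\t"
        f"{result.config.classifier.value}\t-\t"
        f"{result.mean_auc:.6f}\t{result.mean_auprc:.6f}\t{result.mean_accuracy:.6f}"
    )
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    twin = {
        "reducer": result.config.reducer.value,
        "architecture": arch.to_dict() if arch is not None else None,
        "classifier": result.config.classifier.value,
        "per_seed": [
            {
                "seed": r.seed,
                "best_hyper_parameters": r.best_spec.to_text(),
                "auc": r.auc,
                "auprc": r.auprc,
                "accuracy": r.accuracy,
            }
            for r in result.per_seed
        ],
        "mean_auc": result.mean_auc,
        "mean_auprc": result.mean_auprc,
        "mean_accuracy": result.mean_accuracy,
    }
    json_path = path[: path.rfind(".")] + ".json" if "." in path else path + ".json"
    with open(json_path, "w") as fh:
        json.dump(twin, fh, indent=2)
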