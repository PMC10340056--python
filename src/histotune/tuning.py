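"""Hyperparameter tuning harness.

The two metaheuristics search the unit box ``[0,1]^d``; a
:class:`~histotune.space.SearchSpace` decodes each point into physical
hyperparameters; the fitness is the percentage of misclassified
validation instances after a short training run (lower is better). The
full pipeline tunes the feature extractor with the Earth-radius optimizer
first, then the classifier head with the coati optimizer, retrains with
the winning settings and reports per-class metrics on the training and
held-out portions.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from .metrics import EvaluationReport, build_report
from .nn.models import CRNNConfig, ExtractorConfig, ImageClassifier
from .nn.training import TrainConfig, prepare_images, train_classifier
from .optimizers import BERConfig, Bounds, COAConfig, ber_optimize, coa_optimize
from .space import HyperparamSpec, SearchSpace
from .synth import LabeledImageSet, SyntheticSpec, generate_dataset, read_dataset, split_dataset

__all__ = [
    "extractor_search_space",
    "crnn_search_space",
    "TrialResult",
    "fitness_error_rate",
    "ModelBuilder",
    "run_ber_tuning",
    "run_coa_tuning",
    "PipelineConfig",
    "PipelineResult",
    "run_full_pipeline",
]


def extractor_search_space() -> SearchSpace:
    """Default extractor space: attention kernel, width, optimizer settings."""
    return SearchSpace([
        HyperparamSpec("eca_kernel", "categorical", choices=(3, 5, 7)),
        HyperparamSpec("width_multiplier", "continuous", 0.25, 1.0),
        HyperparamSpec("learning_rate", "continuous", 1e-4, 1e-1, scale="log"),
        HyperparamSpec("weight_decay", "continuous", 1e-6, 1e-3, scale="log"),
    ])


def crnn_search_space() -> SearchSpace:
    """Default classifier-head space: LSTM width, dropout, batch, smoothing."""
    return SearchSpace([
        HyperparamSpec("lstm_units", "integer", 16, 128),
        HyperparamSpec("dropout", "continuous", 0.0, 0.6),
        HyperparamSpec("batch_size", "categorical", choices=(8, 16, 32)),
        HyperparamSpec("label_smoothing", "continuous", 0.0, 0.2),
    ])


DEFAULT_HYPERPARAMS: dict[str, Any] = {
    "eca_kernel": 3,
    "width_multiplier": 1.0,
    "learning_rate": 3e-3,
    "weight_decay": 1e-5,
    "lstm_units": 32,
    "dropout": 0.1,
    "batch_size": 32,
    "label_smoothing": 0.1,
}


@dataclass
class TrialResult:
    """Outcome of one hyperparameter evaluation."""

    hyperparams: dict[str, Any]
    fitness: float  # validation error rate, percent
    vector: np.ndarray | None = None
    seed: int = 0


class ModelBuilder:
    """Builds and briefly trains a classifier from a hyperparameter record.

    Unspecified hyperparameters fall back to :data:`DEFAULT_HYPERPARAMS`;
    architecture constants (stage widths before the multiplier, input
    size, class count) are fixed at construction.
    """

    def __init__(
        self,
        input_size: int = 32,
        n_classes: int = 5,
        base_widths: tuple[int, ...] = (8, 16),
        groups: int = 2,
        epochs: int = 5,
        model_seed: int = 0,
    ):
        self.input_size = input_size
        self.n_classes = n_classes
        self.base_widths = base_widths
        self.groups = groups
        self.epochs = epochs
        self.model_seed = model_seed

    def configs(self, hp: dict[str, Any]) -> tuple[ExtractorConfig, CRNNConfig, TrainConfig]:
        hp = {**DEFAULT_HYPERPARAMS, **hp}
        mult = hp["width_multiplier"]
        widths = tuple(
            max(self.groups, self.groups * round(w * mult / self.groups))
            for w in self.base_widths
        )
        ext = ExtractorConfig(
            stage_widths=widths,
            groups=self.groups,
            eca_kernel=int(hp["eca_kernel"]),
            input_size=self.input_size,
        )
        crnn = CRNNConfig(
            conv_widths=(max(8, widths[-1]),),
            dropout=float(hp["dropout"]),
            lstm_units=int(hp["lstm_units"]),
            n_classes=self.n_classes,
            label_smoothing=float(hp["label_smoothing"]),
        )
        train = TrainConfig(
            epochs=self.epochs,
            batch_size=int(hp["batch_size"]),
            learning_rate=float(hp["learning_rate"]),
            weight_decay=float(hp["weight_decay"]),
            seed=self.model_seed,
        )
        return ext, crnn, train

    def build(self, hp: dict[str, Any]) -> tuple[ImageClassifier, TrainConfig]:
        ext, crnn, train = self.configs(hp)
        return ImageClassifier(ext, crnn, seed=self.model_seed), train


def fitness_error_rate(
    hyperparams: dict[str, Any],
    builder: ModelBuilder,
    train_xy: tuple[np.ndarray, np.ndarray],
    val_xy: tuple[np.ndarray, np.ndarray],
) -> float:
    """Validation error percent after a short training run.

    ``100 * misclassified / total`` on the validation set; a failed
    training run yields ``+inf`` with a warning.
    """
    if len(val_xy[0]) == 0:
        raise ValueError("validation set must be non-empty")
    try:
        model, train_cfg = builder.build(hyperparams)
        train_classifier(model, train_xy, None, train_cfg, track_metrics=False)
    except (RuntimeError, FloatingPointError) as exc:
        warnings.warn(f"training aborted ({exc}); fitness set to +inf", stacklevel=2)
        return float("inf")
    pred = model.predict(val_xy[0])
    return float(100.0 * np.mean(pred != np.asarray(val_xy[1])))


def _make_vector_fitness(space, builder, train_xy, val_xy, trial_log, which):
    def fn(vector: np.ndarray) -> float:
        hp = space.decode(vector)
        fit = fitness_error_rate(hp, builder, train_xy, val_xy)
        trial_log.append({"phase": which, "trial": len(trial_log), **hp, "fitness": fit})
        return fit

    return fn


def run_ber_tuning(
    space: SearchSpace,
    builder: ModelBuilder,
    train_xy,
    val_xy,
    config: BERConfig,
    trial_log: list | None = None,
) -> TrialResult:
    """Tune with the Earth-radius optimizer; returns the best trial."""
    trial_log = trial_log if trial_log is not None else []
    fn = _make_vector_fitness(space, builder, train_xy, val_xy, trial_log, "ber")
    best, _history = ber_optimize(fn, Bounds.unit(space.dimension), config)
    return TrialResult(space.decode(best.values), best.fitness, best.values, config.seed)


def run_coa_tuning(
    space: SearchSpace,
    builder: ModelBuilder,
    train_xy,
    val_xy,
    config: COAConfig,
    trial_log: list | None = None,
) -> TrialResult:
    """Tune with the coati optimizer; returns the best trial."""
    trial_log = trial_log if trial_log is not None else []
    fn = _make_vector_fitness(space, builder, train_xy, val_xy, trial_log, "coa")
    best, _history = coa_optimize(fn, Bounds.unit(space.dimension), config)
    return TrialResult(space.decode(best.values), best.fitness, best.values, config.seed)


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    ``data`` is a directory path or a :class:`SyntheticSpec`. Budgets are
    desk-scale by default: 5 agents x 5 iterations per optimizer and
    5-epoch tuning trials.
    """

    data: Any = None
    split_ratio: float = 0.8
    val_fraction: float = 0.2
    ber_population: int = 5
    ber_iterations: int = 5
    coa_population: int = 5
    coa_iterations: int = 5
    trial_epochs: int = 5
    final_epochs: int = 12
    base_widths: tuple[int, ...] = (8, 16)
    groups: int = 2
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.data is None:
            self.data = SyntheticSpec(images_per_class=64, image_size=32,
                                      difficulty=0.2, seed=self.seed)


@dataclass
class PipelineResult:
    best_extractor: TrialResult
    best_head: TrialResult
    default_fitness: float
    train_report: EvaluationReport
    test_report: EvaluationReport
    history: dict[str, list[float]]
    trial_log: list[dict]
    model: ImageClassifier


def _load_data(data, seed: int) -> LabeledImageSet:
    if isinstance(data, LabeledImageSet):
        return data
    if isinstance(data, SyntheticSpec):
        return generate_dataset(data)
    path = Path(data)
    if not path.exists():
        raise FileNotFoundError(
            f"dataset directory {path} not found; generate one with the "
            "synthetic generator (histotune simulate) or point at a "
            "class-per-folder image directory"
        )
    return read_dataset(path)


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load/generate data, tune extractor then head, retrain and evaluate.

    Stage order: split off the held-out portion; carve a validation set
    from the training portion for tuning fitness; BER-tune the extractor
    space; COA-tune the head space with the extractor settings frozen;
    retrain on the whole training portion with the tuned settings; report
    per-class metrics for both portions. A fitness evaluation of the
    default hyperparameters under the same budget is logged alongside, so
    tuned-versus-default comparisons are auditable.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(4) % (2**31)]
    dataset = _load_data(config.data, config.seed)

    train_set, test_set = split_dataset(dataset, config.split_ratio, seed=seeds[0])
    fit_train, fit_val = split_dataset(train_set, 1.0 - config.val_fraction, seed=seeds[1])

    x_fit = prepare_images(fit_train.images)
    y_fit = fit_train.labels
    x_val = prepare_images(fit_val.images)
    y_val = fit_val.labels

    builder = ModelBuilder(
        input_size=dataset.images.shape[1],
        n_classes=dataset.n_classes,
        base_widths=config.base_widths,
        groups=config.groups,
        epochs=config.trial_epochs,
        model_seed=seeds[2],
    )
    trial_log: list[dict] = []

    default_fitness = fitness_error_rate(
        dict(DEFAULT_HYPERPARAMS), builder, (x_fit, y_fit), (x_val, y_val)
    )
    trial_log.append({"phase": "default", "trial": -1,
                      **DEFAULT_HYPERPARAMS, "fitness": default_fitness})

    best_ext = run_ber_tuning(
        extractor_search_space(), builder, (x_fit, y_fit), (x_val, y_val),
        BERConfig(config.ber_population, config.ber_iterations, seed=seeds[0]),
        trial_log,
    )

    class _FrozenExtractorBuilder(ModelBuilder):
        def configs(inner, hp):
            return super().configs({**best_ext.hyperparams, **hp})

    head_builder = _FrozenExtractorBuilder(
        input_size=builder.input_size, n_classes=builder.n_classes,
        base_widths=builder.base_widths, groups=builder.groups,
        epochs=builder.epochs, model_seed=builder.model_seed,
    )
    best_head = run_coa_tuning(
        crnn_search_space(), head_builder, (x_fit, y_fit), (x_val, y_val),
        COAConfig(config.coa_population, config.coa_iterations, seed=seeds[1]),
        trial_log,
    )

    # final training on the full training portion with tuned settings
    final_hp = {**best_ext.hyperparams, **best_head.hyperparams}
    final_builder = ModelBuilder(
        input_size=builder.input_size, n_classes=builder.n_classes,
        base_widths=builder.base_widths, groups=builder.groups,
        epochs=config.final_epochs, model_seed=seeds[3],
    )
    model, train_cfg = final_builder.build(final_hp)
    x_train_all = prepare_images(train_set.images)
    x_test = prepare_images(test_set.images)
    history = train_classifier(
        model, (x_train_all, train_set.labels), (x_test, test_set.labels), train_cfg
    )

    ratio_tag = f"{int(round(config.split_ratio * 100))}:{int(round((1 - config.split_ratio) * 100))}"
    train_scores = model.predict_proba(x_train_all)
    test_scores = model.predict_proba(x_test)
    train_report = build_report(
        train_set.labels, train_scores.argmax(axis=1), train_scores,
        dataset.class_names, split=f"{ratio_tag} train",
    )
    test_report = build_report(
        test_set.labels, test_scores.argmax(axis=1), test_scores,
        dataset.class_names, split=f"{ratio_tag} test",
    )

    result = PipelineResult(
        best_extractor=best_ext, best_head=best_head,
        default_fitness=default_fitness,
        train_report=train_report, test_report=test_report,
        history=history, trial_log=trial_log, model=model,
    )
    if config.output_dir is not None:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.train_report.to_csv(out / "report_train.csv")
    result.test_report.to_csv(out / "report_test.csv")
    with open(out / "reports.json", "w") as fh:
        json.dump({
            "train": result.train_report.to_dict(),
            "test": result.test_report.to_dict(),
            "best_extractor": _jsonable(result.best_extractor.hyperparams),
            "best_head": _jsonable(result.best_head.hyperparams),
            "tuned_fitness": {
                "extractor": result.best_extractor.fitness,
                "head": result.best_head.fitness,
            },
            "default_fitness": result.default_fitness,
            "seed": config.seed,
        }, fh, indent=2)
    if result.trial_log:
        keys = sorted({k for row in result.trial_log for k in row})
        with open(out / "trials.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(result.trial_log)
    result.model.save(out / "model.npz")


def _jsonable(record: dict) -> dict:
    return {k: (v.item() if isinstance(v, np.generic) else v) for k, v in record.items()}
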