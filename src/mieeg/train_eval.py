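"""Experiment orchestration: splits, training loop, metrics, sweeps.

The central object is :class:`MotorImageryClassifier`, a statsmodels-style
model front end: construct it from a :class:`~mieeg.synth.TrialSet`, call
``fit()`` and obtain a :class:`MotorImageryResults` carrying the trained
network, the learning curve and the validation metric suite
(accuracy, precision/"discrimination", sensitivity, specificity, AUC).
The functional pieces (``split_dataset``, ``train``, ``evaluate``,
``kernel_size_sweep``, ``time_segment_analysis``) are exposed directly for
scripted use and for the command-line tool.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import cnn
from .cnn import CNNArchitecture, CNNParameters, TrainingConfig, one_hot
from .csp import DEFAULT_BANDS, CSPModel, csp_feature_matrix, fit_csp_model
from .synth import TrialSet

logger = logging.getLogger(__name__)

#: positive class for all confusion-based metrics: left-hand imagery (code 0)
POSITIVE_CLASS = 0


@dataclass(frozen=True)
class SplitSpec:
    """Stratified shuffled train/validation split (default 8:2)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index arrays.

    Per-class sizes are floored/ceiled (largest-remainder rounding) so the
    overall train size equals ``round(train_fraction * n)``; an 8,600-sample
    pool at 8:2 therefore yields exactly 6,880 / 1,720.
    """
    labels = np.asarray(labels)
    n = labels.size
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples to split")
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    n_train_total = int(round(spec.train_fraction * n))
    exact = spec.train_fraction * counts
    floors = np.floor(exact).astype(int)
    floors = np.minimum(np.maximum(floors, 1), counts - 1)
    deficit = n_train_total - floors.sum()
    order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    take = floors.copy()
    for idx in order:
        if deficit <= 0:
            break
        if take[idx] < counts[idx] - 1:
            take[idx] += 1
            deficit -= 1
    train_parts, val_parts = [], []
    for cls, n_take in zip(classes, take):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members.size)
        train_parts.append(members[perm[:n_take]])
        val_parts.append(members[perm[n_take:]])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(val_parts))


def split_dataset(samples, labels: np.ndarray,
                  spec: SplitSpec) -> tuple[tuple, tuple]:
    """Split (samples, labels) into ((train_x, train_y), (val_x, val_y))."""
    labels = np.asarray(labels)
    tr, va = split_indices(labels, spec)
    if isinstance(samples, np.ndarray):
        return (samples[tr], labels[tr]), (samples[va], labels[va])
    samples = list(samples)
    return (
        ([samples[i] for i in tr], labels[tr]),
        ([samples[i] for i in va], labels[va]),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-based metric suite plus rank-sum AUC.

    ``precision`` is also exposed as ``discrimination``, the name some BCI
    evaluation tables use for the same TP/(TP+FP) quantity.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    auc: float

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    discrimination = precision

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "discrimination": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


def auc_mann_whitney(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = is_positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum = ranks[is_positive].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_from_predictions(true_labels: np.ndarray, pred_labels: np.ndarray,
                             scores: np.ndarray) -> MetricsReport:
    true_labels = np.asarray(true_labels, dtype=int)
    pred_labels = np.asarray(pred_labels, dtype=int)
    pos = true_labels == POSITIVE_CLASS
    pred_pos = pred_labels == POSITIVE_CLASS
    return MetricsReport(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        auc=auc_mann_whitney(scores, pos),
    )


def evaluate(params: CNNParameters, arch: CNNArchitecture,
             features: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Metric suite on a labelled feature matrix.

    The positive class is left-hand imagery (label 0); the AUC score is the
    predicted probability of that class.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0 or np.unique(labels).size < 2:
        raise ValueError("evaluation needs a nonempty set with both classes (AUC)")
    pred, probs = cnn.predict(params, arch, features)
    return metrics_from_predictions(labels, pred, probs[:, POSITIVE_CLASS])


def _accuracy(params, arch, features, labels) -> float:
    pred, _ = cnn.predict(params, arch, features)
    return float(np.mean(pred == np.asarray(labels)))


def train(train_features: np.ndarray, train_labels: np.ndarray,
          val_features: np.ndarray | None, val_labels: np.ndarray | None,
          arch: CNNArchitecture, config: TrainingConfig,
          *, max_iterations: int | None = None, log_every: int = 100,
          stop_at_train_error: float | None = None,
          ) -> tuple[CNNParameters, pd.DataFrame]:
    """Mini-batch SGD training loop.

    Runs ``epochs`` passes over shuffled mini-batches (or exactly
    ``max_iterations`` batches if given), with the exponentially decaying
    learning rate evaluated at each global iteration.  Every ``log_every``
    iterations (and at the end) the learning curve records iteration, lr,
    train/validation misclassification error and accuracy.  Fully
    deterministic given ``config.seed``.  ``stop_at_train_error`` stops
    early once the logged training error falls below the threshold.
    """
    train_features = np.asarray(train_features, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    if train_features.shape[0] == 0:
        raise ValueError("training set is empty")
    n = train_features.shape[0]
    batches_per_epoch = int(np.ceil(n / config.batch_size))
    total = max_iterations if max_iterations is not None \
        else config.epochs * batches_per_epoch
    params = cnn.init_parameters(arch, config.seed)
    rng = np.random.default_rng(config.seed)
    targets = one_hot(train_labels, arch.n_classes)

    rows: list[dict] = []

    def log_row(iteration: int, eta: float) -> float:
        train_acc = _accuracy(params, arch, train_features, train_labels)
        row = {
            "iteration": iteration, "lr": eta,
            "train_error": 1.0 - train_acc, "train_acc": train_acc,
            "val_error": np.nan, "val_acc": np.nan,
        }
        if val_features is not None and len(val_features):
            val_acc = _accuracy(params, arch, val_features, val_labels)
            row["val_error"], row["val_acc"] = 1.0 - val_acc, val_acc
        rows.append(row)
        return row["train_error"]

    iteration = 0
    done = False
    while iteration < total and not done:
        order = rng.permutation(n)
        for b in range(batches_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            eta = cnn.lr_at(iteration, config)
            trace = cnn.forward(params, arch, train_features[idx],
                                training=True, dropout_rate=config.dropout_rate,
                                rng=rng)
            grads = cnn.backward(trace, params, arch, targets[idx])
            params = cnn.sgd_step(params, grads, eta)
            iteration += 1
            if iteration % log_every == 0 or iteration == total:
                err = log_row(iteration, eta)
                if stop_at_train_error is not None and err < stop_at_train_error:
                    done = True
            if iteration >= total or done:
                break
    if not rows or rows[-1]["iteration"] != iteration:
        log_row(iteration, cnn.lr_at(max(iteration - 1, 0), config))
    return params, pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    """Everything produced by one CSP+CNN run on a TrialSet."""

    params: CNNParameters
    arch: CNNArchitecture
    csp_model: CSPModel
    learning_curve: pd.DataFrame
    train_metrics: MetricsReport
    val_metrics: MetricsReport
    train_idx: np.ndarray
    val_idx: np.ndarray


def default_csp_arch(n_features: int) -> CNNArchitecture:
    """Default CSP-path network: two conv layers (8 and 16 kernels, length 2),
    a 32-unit tanh dense layer, 2-class softmax head."""
    return CNNArchitecture(input_length=n_features)


def run_csp_cnn_experiment(trials: TrialSet, *,
                           bands=DEFAULT_BANDS, m: int = 1,
                           arch: CNNArchitecture | None = None,
                           training: TrainingConfig | None = None,
                           split: SplitSpec | None = None,
                           window: str | tuple[float, float] | None = "imagery",
                           max_iterations: int | None = None,
                           log_every: int = 100,
                           stop_at_train_error: float | None = None,
                           ) -> ExperimentResult:
    """Full pipeline: crop to the imagery window, 8:2 stratified split, fit
    CSP on the training trials only, extract log-variance features, train
    the CNN and evaluate both partitions."""
    training = training or TrainingConfig()
    split = split or SplitSpec(seed=training.seed)
    if window == "imagery":
        window = trials.config.imagery_window
    segment = trials if window is None else trials.crop(*window)
    labels = segment.labels
    tr_idx, va_idx = split_indices(labels, split)
    train_trials = TrialSet(
        trials=tuple(segment.trials[i] for i in tr_idx), config=segment.config
    )
    csp_model = fit_csp_model(train_trials, bands=bands, m=m)
    features = csp_feature_matrix(segment, csp_model)
    arch = arch or default_csp_arch(features.shape[1])
    params, curve = train(
        features[tr_idx], labels[tr_idx], features[va_idx], labels[va_idx],
        arch, training, max_iterations=max_iterations, log_every=log_every,
        stop_at_train_error=stop_at_train_error,
    )
    return ExperimentResult(
        params=params, arch=arch, csp_model=csp_model, learning_curve=curve,
        train_metrics=evaluate(params, arch, features[tr_idx], labels[tr_idx]),
        val_metrics=evaluate(params, arch, features[va_idx], labels[va_idx]),
        train_idx=tr_idx, val_idx=va_idx,
    )


@dataclass(frozen=True)
class SweepResult:
    kernel_lengths: np.ndarray
    accuracy_per_length: np.ndarray  # NaN where the length was invalid

    @property
    def best_length(self) -> int:
        # ties -> smallest length (first occurrence)
        return int(self.kernel_lengths[np.nanargmax(self.accuracy_per_length)])


def kernel_size_sweep(train_features: np.ndarray, train_labels: np.ndarray,
                      val_features: np.ndarray, val_labels: np.ndarray,
                      base_arch: CNNArchitecture, lengths,
                      config: TrainingConfig, *,
                      max_iterations: int | None = None) -> SweepResult:
    """Train one model per first-layer kernel length (same seed for all)
    and record validation accuracy; invalid lengths are skipped with a
    warning and recorded as NaN."""
    lengths = np.asarray(list(lengths), dtype=int)
    accs = np.full(lengths.size, np.nan)
    for i, length in enumerate(lengths):
        convs = (dataclasses.replace(base_arch.conv_layers[0], kernel_length=int(length)),
                 *base_arch.conv_layers[1:])
        try:
            arch = dataclasses.replace(base_arch, conv_layers=convs)
        except ValueError as exc:
            warnings.warn(f"kernel length {length} skipped: {exc}", stacklevel=2)
            continue
        params, _ = train(train_features, train_labels, None, None, arch,
                          config, max_iterations=max_iterations,
                          log_every=10 ** 9)
        accs[i] = _accuracy(params, arch, val_features, val_labels)
    return SweepResult(kernel_lengths=lengths, accuracy_per_length=accs)


@dataclass(frozen=True)
class SegmentResult:
    segment_bounds_s: tuple[tuple[float, float], ...]
    mean_accuracy_per_segment: np.ndarray


DEFAULT_SEGMENTS = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0))


def time_segment_analysis(trials: TrialSet, *,
                          segments=DEFAULT_SEGMENTS,
                          bands=DEFAULT_BANDS, m: int = 1,
                          training: TrainingConfig | None = None,
                          split: SplitSpec | None = None,
                          max_iterations: int | None = 1500,
                          ) -> SegmentResult:
    """Run the full CSP+CNN pipeline on consecutive 2 s slices of each trial
    and report validation accuracy per slice."""
    if trials.config.trial_duration_s < max(end for _, end in segments):
        raise ValueError("trials too short for the requested segments")
    accs = []
    for start, end in segments:
        result = run_csp_cnn_experiment(
            trials.crop(start, end - start), bands=bands, m=m,
            training=training, split=split, window=None,
            max_iterations=max_iterations, log_every=10 ** 9,
        )
        accs.append(result.val_metrics.accuracy)
        logger.info("segment [%g, %g) s: validation accuracy %.3f",
                    start, end, accs[-1])
    return SegmentResult(
        segment_bounds_s=tuple((float(a), float(b)) for a, b in segments),
        mean_accuracy_per_segment=np.asarray(accs),
    )


class MotorImageryClassifier:
    """Model front end over the CSP+CNN pipeline.

    Parameters
    ----------
    trials
        Labelled two-channel TrialSet (the raw input).
    m
        CSP filter pairs per band; feature length is ``4 * m``.
    bands
        Analysis bands, default mu (8-12 Hz) and beta (12-25 Hz).
    arch, training, split
        Network architecture, optimizer hyperparameters and split spec;
        defaults follow the package's canonical configuration.

    Examples
    --------
    >>> trials = generate_dataset(GeneratorConfig(seed=7), n_per_class=200)
    >>> res = MotorImageryClassifier(trials).fit(max_iterations=3000)
    >>> print(res.summary())
    """

    def __init__(self, trials: TrialSet, *, m: int = 1, bands=DEFAULT_BANDS,
                 arch: CNNArchitecture | None = None,
                 training: TrainingConfig | None = None,
                 split: SplitSpec | None = None,
                 window: str | tuple[float, float] | None = "imagery"):
        self.trials = trials
        self.m = m
        self.bands = bands
        self.arch = arch
        self.training = training or TrainingConfig()
        self.split = split or SplitSpec(seed=self.training.seed)
        self.window = window

    def fit(self, *, max_iterations: int | None = None,
            log_every: int = 100) -> "MotorImageryResults":
        result = run_csp_cnn_experiment(
            self.trials, bands=self.bands, m=self.m, arch=self.arch,
            training=self.training, split=self.split, window=self.window,
            max_iterations=max_iterations, log_every=log_every,
        )
        return MotorImageryResults(self, result)


class MotorImageryResults:
    """Fitted-model container: trained parameters, learning curve, metrics."""

    def __init__(self, model: MotorImageryClassifier, result: ExperimentResult):
        self.model = model
        self._result = result
        self.params = result.params
        self.arch = result.arch
        self.csp_model = result.csp_model
        self.learning_curve = result.learning_curve
        self.train_metrics = result.train_metrics
        self.val_metrics = result.val_metrics

    def predict(self, trials: TrialSet) -> np.ndarray:
        """Predicted integer labels (0 = left, 1 = right) for new trials."""
        segment = trials
        if self.model.window is not None:
            window = (trials.config.imagery_window
                      if self.model.window == "imagery" else self.model.window)
            segment = trials.crop(*window)
        features = csp_feature_matrix(segment, self.csp_model)
        labels, _ = cnn.predict(self.params, self.arch, features)
        return labels

    def summary(self) -> str:
        """Plain-text summary table of the run and its validation metrics."""
        r = self._result
        last = r.learning_curve.iloc[-1]
        lines = [
            "Motor-imagery CSP + 1-D CNN classifier",
            "=" * 54,
            f"trials: {len(self.model.trials)}  "
            f"(train {r.train_idx.size} / val {r.val_idx.size})",
            f"CSP: m={self.csp_model.m}, bands={list(self.csp_model.bands)}, "
            f"N={self.csp_model.n_features}",
            f"CNN: conv={[(c.n_kernels, c.kernel_length) for c in self.arch.conv_layers]}, "
            f"dense={self.arch.dense_width}, classes={self.arch.n_classes}",
            f"iterations: {int(last['iteration'])}  (final lr {last['lr']:.6f})",
            "-" * 54,
            f"{'metric':<16}{'train':>10}{'validation':>14}",
        ]
        for name in ("accuracy", "precision", "sensitivity", "specificity", "auc"):
            tr = getattr(self.train_metrics, name)
            va = getattr(self.val_metrics, name)
            lines.append(f"{name:<16}{tr:>10.4f}{va:>14.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)
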