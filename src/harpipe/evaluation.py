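"""Subject-wise cross-validation, metrics, and condition comparison.

The experiment harness runs a grid of (sensor location x balancing arm x
classifier family) cells. Within each cell, subjects are partitioned into
folds (default 8, i.e. 28 train / 4 test subjects for a 32-subject cohort);
per fold the pipeline is: feature z-scoring fit on training rows only ->
class balancing on the training rows only (undersampling averaged over 10
random repeats) -> fit -> predict the held-out subjects -> metrics. No
test-subject epoch ever reaches the scaler, the resampler or the model.

Reported metrics follow the one-vs-rest definitions: per-class recall
(sensitivity), specificity, precision and F1, overall accuracy, and balanced
accuracy — the arithmetic mean of per-class recalls — which is the headline
metric because plain accuracy is dominated by the majority class under severe
imbalance. Conditions are compared with a Kruskal-Wallis test per metric and
a Tukey-Kramer-style rank-based post hoc (studentized-range critical values).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import LabeledFeatureMatrix
from .ingest import ACTIVITY_CLASSES, RawRecording, epoch_stream
from .modeling import ActivityClassifier, ClassifierSpec, Scaler
from .resampling import random_undersample, repeat_undersample, smote_oversample

logger = logging.getLogger(__name__)

BALANCING_ARMS = ("none", "undersample", "oversample")
MINORITY_CLASSES = ("ascending_stairs", "descending_stairs")


class EvaluationError(ValueError):
    """Raised for invalid evaluation configuration or inputs."""


def class_shares_from_durations(durations: dict[str, float]) -> dict[str, float]:
    """Per-class share of total duration (fractions summing to 1).

    Dataset bookkeeping for imbalance reporting: e.g. recorded minutes per
    activity class -> fraction of the corpus each class occupies.
    """
    total = float(sum(durations.values()))
    if total <= 0:
        raise EvaluationError("total duration must be positive")
    return {k: v / total for k, v in durations.items()}


# ---------------------------------------------------------------------------
# folds


@dataclass
class CVFold:
    fold_id: int
    train_subjects: tuple
    test_subjects: tuple

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise EvaluationError("train and test subjects overlap")


def make_subject_folds(
    subject_ids, n_folds: int = 8, seed: int = 0
) -> list[CVFold]:
    """Random subject-wise partition into ``n_folds`` disjoint test groups.

    Every subject appears in exactly one test group; any remainder when the
    subject count is not divisible is spread one-per-fold (logged).
    """
    subjects = list(dict.fromkeys(subject_ids))  # stable de-dup
    if n_folds > len(subjects):
        raise EvaluationError(
            f"n_folds={n_folds} exceeds the {len(subjects)} subjects"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    if len(subjects) % n_folds:
        logger.debug(
            "make_subject_folds: %d subjects not divisible by %d folds; "
            "remainder spread across folds", len(subjects), n_folds,
        )
    groups = np.array_split(order, n_folds)
    folds = []
    for i, g in enumerate(groups):
        test = tuple(subjects[j] for j in g)
        train = tuple(s for s in subjects if s not in set(test))
        folds.append(CVFold(fold_id=i, train_subjects=train, test_subjects=test))
    return folds


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """One-vs-rest classification metrics for a set of predictions."""

    class_order: tuple
    confusion: np.ndarray  # rows = true, cols = predicted
    recall: dict
    specificity: dict
    precision: dict
    f1: dict
    accuracy: float
    balanced_accuracy: float
    minority_avg_recall: float

    def as_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "minority_avg_recall": self.minority_avg_recall,
            **{f"recall_{c}": self.recall[c] for c in self.class_order},
        }


def compute_metrics(y_true, y_pred, class_order=None) -> MetricsReport:
    """Per-class one-vs-rest metrics plus accuracy and balanced accuracy.

    Classes absent from ``y_true`` get NaN recall and are excluded from the
    balanced-accuracy mean (logged). Balanced accuracy is the arithmetic mean
    of the per-class recalls.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise EvaluationError("empty input")
    if len(y_true) != len(y_pred):
        raise EvaluationError("y_true and y_pred lengths differ")
    if class_order is None:
        class_order = tuple(sorted(set(y_true) | set(y_pred)))
    class_order = tuple(class_order)
    known = set(class_order)
    stray = (set(y_true) | set(y_pred)) - known
    if stray:
        raise EvaluationError(f"labels outside class_order: {stray}")

    k = len(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1

    n = conf.sum()
    recall, spec, prec, f1 = {}, {}, {}, {}
    for i, c in enumerate(class_order):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            logger.debug("compute_metrics: class %s absent from y_true", c)
            recall[c] = float("nan")
        else:
            recall[c] = tp / (tp + fn)
        spec[c] = tn / (tn + fp) if (tn + fp) else float("nan")
        prec[c] = tp / (tp + fp) if (tp + fp) else 0.0
        pr, rc = prec[c], recall[c]
        f1[c] = (
            2 * pr * rc / (pr + rc)
            if not np.isnan(rc) and (pr + rc) > 0
            else 0.0
        )
    recalls = np.array([recall[c] for c in class_order], dtype=float)
    bal_acc = float(np.nanmean(recalls))
    minority = [recall[c] for c in MINORITY_CLASSES if c in recall]
    minority_avg = (
        float(np.nanmean(minority)) if minority and not np.all(np.isnan(minority))
        else float("nan")
    )
    return MetricsReport(
        class_order=class_order,
        confusion=conf,
        recall=recall,
        specificity=spec,
        precision=prec,
        f1=f1,
        accuracy=float(np.trace(conf) / n),
        balanced_accuracy=bal_acc,
        minority_avg_recall=minority_avg,
    )


def average_metric_rows(rows: list[dict]) -> dict:
    """Element-wise mean of metric dictionaries (NaN-aware)."""
    keys = rows[0].keys()
    return {k: float(np.nanmean([r[k] for r in rows])) for k in keys}


# ---------------------------------------------------------------------------
# experiment harness


@dataclass
class ExperimentConfig:
    """Grid + pipeline settings for a cross-validation experiment."""

    balancing_arms: tuple = ("none", "undersample")
    classifiers: tuple = (ClassifierSpec("random_forest"),)
    n_folds: int = 8
    undersample_repeats: int = 10
    smote_k: int = 5
    window_s: float = 5.0
    hop_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.balancing_arms) - set(BALANCING_ARMS)
        if bad:
            raise EvaluationError(f"unknown balancing arms: {bad}")


class CrossValidationExperiment:
    """Subject-wise cross-validation of classifiers over balancing arms.

    Built from per-sensor feature matrices (or raw recordings, which are
    epoched and featurized on construction); ``run()`` returns an
    :class:`ExperimentResults`.
    """

    def __init__(
        self,
        features_by_sensor: dict[str, LabeledFeatureMatrix],
        config: ExperimentConfig | None = None,
    ):
        if not features_by_sensor:
            raise EvaluationError("need at least one sensor's feature matrix")
        self.features_by_sensor = features_by_sensor
        self.config = config or ExperimentConfig()

    @classmethod
    def from_recordings(
        cls,
        recordings: list[RawRecording],
        config: ExperimentConfig | None = None,
    ) -> "CrossValidationExperiment":
        from .featurize import extract_features

        config = config or ExperimentConfig()
        by_sensor: dict[str, list] = {}
        for rec in recordings:
            epochs = epoch_stream(rec, window_s=config.window_s, hop_s=config.hop_s)
            by_sensor.setdefault(rec.sensor_location, []).extend(epochs)
        features = {
            loc: extract_features(eps, window_s=config.window_s)
            for loc, eps in by_sensor.items()
        }
        return cls(features, config)

    # -- single pipeline cell ----------------------------------------------

    def _fit_predict(self, train, test, spec, arm, seed_seq):
        """One (train matrix, test matrix, classifier, arm) evaluation.

        Returns the metric row (averaged over undersampling repeats for the
        undersample arm) and the wall-clock training time.
        """
        t0 = time.perf_counter()
        class_order = tuple(
            c for c in ACTIVITY_CLASSES if c in set(train.labels) | set(test.labels)
        ) or tuple(sorted(set(train.labels)))
        if arm == "undersample":
            repeats = repeat_undersample(
                train, n_repeats=self.config.undersample_repeats, seed=seed_seq
            )
            rows = []
            for rep in repeats:
                res = ActivityClassifier(rep, spec).fit()
                rows.append(
                    compute_metrics(test.labels, res.predict(test), class_order).as_row()
                )
            row = average_metric_rows(rows)
        else:
            if arm == "oversample":
                scaler = Scaler.fit(train.X)
                train = smote_oversample(
                    train,
                    k=self.config.smote_k,
                    seed=seed_seq,
                    scaler=(scaler.means, scaler.sds),
                )
            res = ActivityClassifier(train, spec).fit()
            row = compute_metrics(
                test.labels, res.predict(test), class_order
            ).as_row()
        return row, time.perf_counter() - t0

    def run(self) -> "ExperimentResults":
        cfg = self.config
        rows = []
        root = np.random.SeedSequence(cfg.seed)
        for sensor, matrix in sorted(self.features_by_sensor.items()):
            subjects = list(dict.fromkeys(matrix.subjects))
            folds = make_subject_folds(subjects, n_folds=cfg.n_folds, seed=cfg.seed)
            for fold in folds:
                train_all = matrix.subset_subjects(fold.train_subjects)
                test = matrix.subset_subjects(fold.test_subjects)
                if len(test) == 0 or len(train_all) == 0:
                    continue
                for arm in cfg.balancing_arms:
                    for spec in cfg.classifiers:
                        cell_seed = np.random.SeedSequence(
                            entropy=root.entropy,
                            spawn_key=(
                                hash((sensor, fold.fold_id, arm, spec.family))
                                & 0x7FFFFFFF,
                            ),
                        )
                        try:
                            row, elapsed = self._fit_predict(
                                train_all, test, spec, arm, cell_seed
                            )
                        except Exception:  # isolate cell failures
                            logger.exception(
                                "cell failed: sensor=%s fold=%d arm=%s family=%s",
                                sensor, fold.fold_id, arm, spec.family,
                            )
                            continue
                        rows.append(
                            {
                                "sensor": sensor,
                                "fold": fold.fold_id,
                                "arm": arm,
                                "classifier": spec.family,
                                "train_time_s": elapsed,
                                **row,
                            }
                        )
        return ExperimentResults(pd.DataFrame(rows), cfg)


class ExperimentResults:
    """Per-fold metric table plus aggregation and summary views."""

    def __init__(self, per_fold: pd.DataFrame, config: ExperimentConfig):
        self.per_fold = per_fold
        self.config = config

    def aggregate(self) -> pd.DataFrame:
        """Mean of per-fold metrics per (sensor, arm, classifier) cell."""
        metric_cols = [
            c
            for c in self.per_fold.columns
            if c not in ("sensor", "fold", "arm", "classifier")
        ]
        return (
            self.per_fold.groupby(["sensor", "arm", "classifier"])[metric_cols]
            .mean()
            .reset_index()
        )

    def metric_by_condition(
        self, metric: str, condition: str = "arm"
    ) -> dict[str, np.ndarray]:
        """Per-fold values of one metric grouped by a condition column."""
        out = {}
        for value, grp in self.per_fold.groupby(condition):
            out[str(value)] = grp[metric].to_numpy(dtype=float)
        return out

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Cross-validation experiment",
            "=" * 60,
            f"folds: {self.config.n_folds}   "
            f"undersample repeats: {self.config.undersample_repeats}",
            "",
            agg.to_string(
                index=False,
                columns=[
                    "sensor", "arm", "classifier",
                    "balanced_accuracy", "minority_avg_recall", "accuracy",
                ],
                float_format=lambda v: f"{v:.3f}",
            ),
        ]
        return "\n".join(lines)


def run_experiment(
    features_by_sensor: dict[str, LabeledFeatureMatrix],
    config: ExperimentConfig | None = None,
) -> ExperimentResults:
    """Functional wrapper around :class:`CrossValidationExperiment`."""
    return CrossValidationExperiment(features_by_sensor, config).run()


# ---------------------------------------------------------------------------
# condition comparison


@dataclass
class ComparisonReport:
    metric: str
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # condition_a, condition_b, mean_rank_diff, p, significant
    degenerate: bool = False


def compare_conditions(
    values_by_condition: dict[str, np.ndarray],
    metric: str = "balanced_accuracy",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Kruskal-Wallis across conditions plus Tukey-Kramer rank post hoc.

    The post hoc compares mean ranks pairwise, with the critical value taken
    from the studentized-range distribution (infinite degrees of freedom), the
    classic pairing for a Kruskal-Wallis omnibus. All-identical inputs return
    p = 1 with the degenerate flag set.
    """
    names = sorted(values_by_condition)
    if len(names) < 2:
        raise EvaluationError("need at least 2 conditions")
    groups = [np.asarray(values_by_condition[n], dtype=float) for n in names]
    for n, g in zip(names, groups):
        if len(g) < 3:
            raise EvaluationError(f"condition {n!r} has fewer than 3 values")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        pairs = pd.DataFrame(
            [
                {"condition_a": a, "condition_b": b, "mean_rank_diff": 0.0,
                 "p": 1.0, "significant": False}
                for i, a in enumerate(names)
                for b in names[i + 1:]
            ]
        )
        return ComparisonReport(metric, 0.0, 1.0, pairs, degenerate=True)

    h, p = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = {}
    start = 0
    for n, size in zip(names, sizes):
        mean_ranks[n] = ranks[start : start + size].mean()
        start += size
    big_n = len(pooled)
    # tie correction for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (big_n - 1))
    var = big_n * (big_n + 1) / 12.0 - tie_term
    k = len(names)
    records = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = mean_ranks[a] - mean_ranks[b]
            se = np.sqrt(var * (1 / sizes[names.index(a)] + 1 / sizes[names.index(b)]))
            q = abs(diff) / se * np.sqrt(2.0)
            p_pair = float(stats.studentized_range.sf(q, k, np.inf))
            records.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "mean_rank_diff": float(diff),
                    "p": p_pair,
                    "significant": bool(p_pair < alpha),
                }
            )
    return ComparisonReport(metric, float(h), float(p), pd.DataFrame(records))
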