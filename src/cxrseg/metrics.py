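"""Segmentation metrics, cross-validation and paired comparison.

Per-class quality is summarized by pixel accuracy, the Dice coefficient

    D(S, G) = 2|S ∩ G| / (|S| + |G|),

and the Jaccard index J(S, G) = |S ∩ G| / |S ∪ G|; the two are linked by
the identity J = D / (2 - D).  The training objective the pipeline aims to
maximize is the mean Dice plus mean Jaccard over the evaluation set, with
each image's D and J first averaged over the structure classes (background
excluded so the dominant trivial class cannot inflate the score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .datatypes import CLASS_NAMES, STRUCTURE_CLASSES, Dataset, MaskStack
from .model import TrainConfig, UNetSegmenter, UNetSpec, train_model

__all__ = [
    "MetricsReport",
    "FoldPlan",
    "DegenerateComparisonError",
    "dice",
    "jaccard",
    "pixel_accuracy",
    "combined_objective",
    "evaluate_model",
    "make_folds",
    "cross_validate",
    "paired_t_test",
]


def _check_pair(pred, truth, binary=True):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if binary:
        for name, arr in (("pred", pred), ("truth", truth)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} raster is not binary")
    return pred.astype(bool), truth.astype(bool)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient of two binary rasters; both-empty scores 1."""
    p, t = _check_pair(pred, truth)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index of two binary rasters; both-empty scores 1."""
    p, t = _check_pair(pred, truth)
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels on which the two rasters agree."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.mean(pred == truth))


def _image_dj(pred: MaskStack, truth: MaskStack) -> tuple[float, float]:
    """Per-image Dice and Jaccard, averaged over structure classes."""
    ds = [dice(pred[c], truth[c]) for c in STRUCTURE_CLASSES]
    js = [jaccard(pred[c], truth[c]) for c in STRUCTURE_CLASSES]
    return float(np.mean(ds)), float(np.mean(js))


def combined_objective(
    predictions: list[MaskStack], truths: list[MaskStack]
) -> float:
    """Mean Dice plus mean Jaccard over an image set; lies in [0, 2]."""
    if len(predictions) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    if not predictions:
        raise ValueError("empty evaluation set")
    pairs = [_image_dj(p, t) for p, t in zip(predictions, truths)]
    d_mean = float(np.mean([d for d, _ in pairs]))
    j_mean = float(np.mean([j for _, j in pairs]))
    return d_mean + j_mean


@dataclass
class MetricsReport:
    """Per-class metric means over an evaluation set.

    ``per_class`` is indexed by class name with columns accuracy / dice /
    jaccard; ``per_sample`` keeps the underlying per-image values (rows:
    sample id x class) so paired comparisons between methods are possible.
    ``overall_accuracy`` is the all-channel pixel accuracy.
    """

    per_class: pd.DataFrame
    combined_objective: float
    n_samples: int
    overall_accuracy: float
    per_sample: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.per_class.to_csv(path, index_label="class")

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "per_class": self.per_class.to_dict(orient="index"),
                    "combined_objective": self.combined_objective,
                    "overall_accuracy": self.overall_accuracy,
                    "n_samples": self.n_samples,
                },
                indent=2,
            )
        )


def evaluate_model(
    model: UNetSegmenter, test: Dataset, config: TrainConfig | None = None
) -> MetricsReport:
    """Per-class accuracy/Dice/Jaccard of a trained model on a test set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    threshold = config.threshold if config is not None else model.threshold
    rows = []
    pred_stacks, truth_stacks = [], []
    overall = []
    for sample in test:
        probs = model.predict_proba(sample.image)
        binary = (probs > threshold).astype(np.uint8)
        pred = MaskStack(binary, CLASS_NAMES[: binary.shape[0]])
        pred_stacks.append(pred)
        truth_stacks.append(sample.masks)
        overall.append(float(np.mean(binary == sample.masks.channels)))
        for c in sample.masks.class_names:
            rows.append(
                {
                    "id": sample.identifier,
                    "class": c,
                    "accuracy": pixel_accuracy(pred[c], sample.masks[c]),
                    "dice": dice(pred[c], sample.masks[c]),
                    "jaccard": jaccard(pred[c], sample.masks[c]),
                }
            )
    per_sample = pd.DataFrame(rows)
    per_class = (
        per_sample.groupby("class", sort=False)[["accuracy", "dice", "jaccard"]]
        .mean()
        .reindex(list(CLASS_NAMES))
    )
    return MetricsReport(
        per_class=per_class,
        combined_objective=combined_objective(pred_stacks, truth_stacks),
        n_samples=len(test),
        overall_accuracy=float(np.mean(overall)),
        per_sample=per_sample,
    )


@dataclass(frozen=True)
class FoldPlan:
    """A seeded k-fold partition: identifier -> fold index."""

    k: int
    assignments: dict
    seed: int
    strata: tuple | None = None

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]


def make_folds(
    dataset: Dataset, k: int, strata=None, seed: int = 0
) -> FoldPlan:
    """Balanced, seeded (optionally stratified) k-fold plan over a dataset."""
    n = len(dataset)
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, {n}]")
    ids = dataset.identifiers
    if strata is not None:
        if len(strata) != n:
            raise ValueError("strata length must match dataset size")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), np.asarray(strata))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    assignments = {}
    for fold, (_, test_idx) in enumerate(split_iter):
        for i in test_idx:
            assignments[ids[i]] = fold
    return FoldPlan(
        k=k,
        assignments=assignments,
        seed=seed,
        strata=tuple(strata) if strata is not None else None,
    )


@dataclass
class CVSummary:
    """Across-fold metric means."""

    per_class: pd.DataFrame
    combined_objective: float
    overall_accuracy: float


def cross_validate(
    dataset: Dataset,
    unet: UNetSpec,
    config: TrainConfig,
    folds: FoldPlan,
) -> tuple[list[MetricsReport], CVSummary]:
    """Train k models, each evaluated on its held-out fold.

    Returns the per-fold reports and the arithmetic across-fold mean of
    every metric.
    """
    missing = set(dataset.identifiers) - set(folds.assignments)
    if missing:
        raise ValueError(f"fold plan does not cover ids: {sorted(missing)[:5]}")
    reports = []
    for fold in range(folds.k):
        test_ids = folds.fold_ids(fold)
        train_ids = [i for i in dataset.identifiers if i not in set(test_ids)]
        try:
            model, _ = train_model(dataset.subset(train_ids), unet, config)
            reports.append(evaluate_model(model, dataset.subset(test_ids), config))
        except Exception as exc:  # annotate with fold index
            raise RuntimeError(f"cross-validation failed in fold {fold}") from exc
    per_class = sum(r.per_class for r in reports) / len(reports)
    summary = CVSummary(
        per_class=per_class,
        combined_objective=float(np.mean([r.combined_objective for r in reports])),
        overall_accuracy=float(np.mean([r.overall_accuracy for r in reports])),
    )
    return reports, summary


class DegenerateComparisonError(ValueError):
    """Raised when paired scores have zero-variance differences."""


def paired_t_test(scores_a, scores_b) -> tuple[float, float, int]:
    """Two-sided paired t-test on per-sample score differences.

    Returns ``(t, p, df)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` on the
    differences ``d = a - b`` (sample standard deviation, ``df = n - 1``)
    and the p-value from the exact t distribution.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired scores")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateComparisonError("all paired differences are identical")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p, n - 1
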