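"""Multi-miRNA subtype classifiers by sequential forward selection.

One-vs-rest subtype membership is scored by a ridge-penalized logistic
model on standardized log2 expression of a small miRNA panel.  Panels are
grown greedily: at each step the candidate that most improves the
repeat-averaged, stratified cross-validated AUC is added; growth stops
when the best candidate improves the criterion by less than
``min_improvement`` or the panel reaches ``max_features``.

Cross-validation pools the held-out scores of all folds of one stratified
partition and computes a single AUC on the pool (stable with minority
classes of 8-11 samples, where per-fold AUCs would rest on 1-3 positives).
The criterion averages this over several fold partitions.  The final
reported AUC is recomputed for the selected panel over ``n_repeats`` fold
partitions whose seeds are disjoint from those used during selection; both
numbers are exposed because a greedily selected panel's cross-validated
AUC on the same cohort retains selection (winner's-curse) bias that fresh
fold partitions alone cannot remove.

All randomness derives from ``SfsConfig.seed``; reruns are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import ContrastError, GroupContrast, MirnaExpressionMatrix, make_contrast

__all__ = [
    "SfsConfig",
    "ClassifierModel",
    "LinearScorer",
    "UndefinedAucError",
    "roc_auc",
    "roc_curve_points",
    "fit_linear_scorer",
    "cv_pooled_auc",
    "repeated_cv_auc",
    "sequential_forward_select",
    "build_subtype_models",
    "DEFAULT_MODEL_TARGETS",
]

logger = logging.getLogger(__name__)

#: the subtype models built by default: MMR-deficient, p53-abnormal, CTNNB1-mutated
DEFAULT_MODEL_TARGETS = (
    ("molecular", "MMRd"),
    ("molecular", "p53abn"),
    ("ctnnb1", "mutated"),
)


class UndefinedAucError(ValueError):
    """AUC requested for labels containing a single class."""


@dataclass(frozen=True)
class SfsConfig:
    """Cross-validation and stopping parameters for forward selection.

    ``n_repeats`` fold partitions back the final reported AUC; during
    selection each candidate is scored over ``n_selection_repeats``
    partitions (shared across candidates and steps, so comparisons are
    paired).  ``regularization`` is the L2 penalty weight of the logistic
    scorer (inverse of scikit-learn's C).
    """

    n_folds: int = 5
    n_repeats: int = 50
    n_selection_repeats: int = 5
    max_features: int = 10
    min_improvement: float = 0.005
    seed: int = 0
    regularization: float = 1.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1 or self.n_selection_repeats < 1:
            raise ValueError("repeat counts must be at least 1")
        if self.max_features < 1:
            raise ValueError("max_features must be at least 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")

    def selection_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed).spawn(2)[0]
        return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(self.n_selection_repeats)]

    def evaluation_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed).spawn(2)[1]
        return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(self.n_repeats)]


@dataclass(frozen=True)
class ClassifierModel:
    """An ordered selected panel with its cross-validated performance."""

    contrast_name: str
    selected_mirnas: tuple[str, ...]
    mean_auc: float
    repeat_aucs: tuple[float, ...]
    selection_trace: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected_mirnas", tuple(self.selected_mirnas))
        object.__setattr__(self, "repeat_aucs", tuple(float(a) for a in self.repeat_aucs))
        object.__setattr__(
            self,
            "selection_trace",
            tuple((m, float(c)) for m, c in self.selection_trace),
        )
        if not self.selected_mirnas:
            raise ValueError("a model must contain at least one miRNA")
        if len(set(self.selected_mirnas)) != len(self.selected_mirnas):
            raise ValueError("selected panel contains duplicates")

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast_name,
            "selected_mirnas": list(self.selected_mirnas),
            "mean_auc": self.mean_auc,
            "repeat_aucs": list(self.repeat_aucs),
            "selection_trace": [
                {"added": m, "criterion": c} for m, c in self.selection_trace
            ],
        }


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive scores above random negative).

    Ties between a positive and a negative score count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAucError("AUC needs at least one positive and one negative label")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve as (threshold, tpr, fpr) rows, one per distinct score."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float),
                              drop_intermediate=False)
    return pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})


# ---------------------------------------------------------------------------
# linear scorer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearScorer:
    """Deterministic log-odds scorer over standardized feature expression."""

    features: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    intercept: float

    def score_values(self, X: np.ndarray) -> np.ndarray:
        """Scores for raw feature values X (samples x features)."""
        X = np.asarray(X, dtype=float).reshape(-1, len(self.features))
        safe = np.where(self.scale > 0, self.scale, 1.0)
        Z = (X - self.center) / safe
        Z[:, self.scale == 0] = 0.0
        return Z @ self.weights + self.intercept

    def score(self, expr: MirnaExpressionMatrix, sample_ids: Sequence[str]) -> np.ndarray:
        cols = expr.sample_index(sample_ids)
        X = np.stack([expr.row(f)[cols] for f in self.features], axis=1)
        return self.score_values(X)


def _fit_scorer_arrays(
    X: np.ndarray, y: np.ndarray, features: Sequence[str], regularization: float
) -> LinearScorer:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0
    if constant.any():
        logger.warning(
            "constant feature(s) %s in training data; weight set to 0",
            [features[i] for i in np.flatnonzero(constant)],
        )
    safe = np.where(constant, 1.0, scale)
    Z = (X - center) / safe
    Z[:, constant] = 0.0
    clf = LogisticRegression(C=1.0 / regularization, solver="lbfgs", max_iter=1000)
    clf.fit(Z, y.astype(int))
    # orient so the score is the log-odds of the positive class
    weights = clf.coef_[0] * (1 if clf.classes_[1] == 1 else -1)
    intercept = float(clf.intercept_[0] * (1 if clf.classes_[1] == 1 else -1))
    return LinearScorer(tuple(features), center, scale, weights, intercept)


def fit_linear_scorer(
    expr: MirnaExpressionMatrix,
    contrast: GroupContrast,
    features: Sequence[str],
    regularization: float = 1.0,
) -> LinearScorer:
    """Fit the ridge-logistic scorer on all samples of the contrast.

    Standardization parameters are learned from the same samples the model
    is fit on; inside cross-validation both are learned on training folds
    only (see :func:`cv_pooled_auc`).
    """
    X, y = _design(expr, contrast, features)
    return _fit_scorer_arrays(X, y, features, regularization)


def _design(
    expr: MirnaExpressionMatrix, contrast: GroupContrast, features: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    features = list(features)
    if not features:
        raise ValueError("need at least one feature")
    pos_idx, neg_idx = contrast.indices(expr)
    cols = np.concatenate([pos_idx, neg_idx])
    X = expr.expr[[expr.mirna_ids.index(f) for f in features]][:, cols].T
    y = np.zeros(cols.size, dtype=bool)
    y[: pos_idx.size] = True
    return np.ascontiguousarray(X), y


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _cv_auc_arrays(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    config: SfsConfig,
    fold_seed: int,
) -> float:
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < config.n_folds:
        raise ContrastError(
            f"smallest class has {n_min} samples, fewer than n_folds="
            f"{config.n_folds}; use a smaller n_folds"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=fold_seed)
    scores = np.empty(y.size)
    for train, test in skf.split(X, y):
        scorer = _fit_scorer_arrays(X[train], y[train], features, config.regularization)
        scores[test] = scorer.score_values(X[test])
    return roc_auc(scores, y)


def cv_pooled_auc(
    expr: MirnaExpressionMatrix,
    contrast: GroupContrast,
    features: Sequence[str],
    config: SfsConfig,
    fold_seed: int,
) -> float:
    """AUC of one stratified k-fold pass: held-out scores pooled, one AUC."""
    X, y = _design(expr, contrast, features)
    return _cv_auc_arrays(X, y, features, config, fold_seed)


def repeated_cv_auc(
    expr: MirnaExpressionMatrix,
    contrast: GroupContrast,
    features: Sequence[str],
    config: SfsConfig,
    fold_seeds: Sequence[int],
) -> np.ndarray:
    """Cross-validated AUC for each fold-partition seed."""
    X, y = _design(expr, contrast, features)
    return np.array([_cv_auc_arrays(X, y, features, config, s) for s in fold_seeds])


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------

def sequential_forward_select(
    expr: MirnaExpressionMatrix,
    contrast: GroupContrast,
    candidates: Sequence[str],
    config: SfsConfig,
) -> ClassifierModel:
    """Grow a panel greedily by repeat-averaged cross-validated AUC.

    The first feature is always the best-scoring candidate (a model is
    never empty); later additions must improve the criterion by at least
    ``min_improvement``.  Ties break toward the earlier candidate index.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate miRNA")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate list contains duplicates")
    Xall, y = _design(expr, contrast, candidates)
    col = {m: j for j, m in enumerate(candidates)}
    sel_seeds = config.selection_seeds()

    def criterion(feats: list[str]) -> float:
        X = Xall[:, [col[f] for f in feats]]
        return float(
            np.mean([_cv_auc_arrays(X, y, feats, config, s) for s in sel_seeds])
        )

    selected: list[str] = []
    trace: list[tuple[str, float]] = []
    best_so_far = -np.inf
    remaining = list(candidates)
    while remaining and len(selected) < config.max_features:
        step_scores = [criterion(selected + [c]) for c in remaining]
        k = int(np.argmax(step_scores))  # argmax takes the first maximum: earlier index wins ties
        best_cand, best_score = remaining[k], step_scores[k]
        if selected and best_score < best_so_far + config.min_improvement:
            break
        if not selected and best_score <= 0.5:
            logger.warning(
                "no candidate beats AUC 0.5 for %s; keeping single best %r (%.3f)",
                contrast.name, best_cand, best_score,
            )
        selected.append(best_cand)
        remaining.pop(k)
        best_so_far = best_score
        trace.append((best_cand, best_score))

    eval_aucs = repeated_cv_auc(expr, contrast, selected, config, config.evaluation_seeds())
    return ClassifierModel(
        contrast_name=contrast.name,
        selected_mirnas=tuple(selected),
        mean_auc=float(eval_aucs.mean()),
        repeat_aucs=tuple(eval_aucs),
        selection_trace=tuple(trace),
    )


def _stage_seed(base_seed: int, tag: str) -> int:
    import hashlib

    digest = hashlib.sha256(f"{base_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def build_subtype_models(
    expr: MirnaExpressionMatrix,
    ann: pd.DataFrame,
    targets: Sequence[tuple[str, str]] | None = None,
    config: SfsConfig | None = None,
    candidates: Sequence[str] | None = None,
) -> list[ClassifierModel]:
    """Forward-select one panel per (variable, level) target.

    Targets default to the MMR-deficient, p53-abnormal and CTNNB1-mutated
    groups.  A target whose contrast is degenerate (too few labelled
    samples) is skipped with a warning; the remaining targets still run.
    Each target derives its own seed from ``config.seed`` so panels are
    independent but reproducible.
    """
    if targets is None:
        targets = DEFAULT_MODEL_TARGETS
    config = config or SfsConfig()
    candidates = list(candidates) if candidates is not None else list(expr.mirna_ids)
    models = []
    for variable, level in targets:
        try:
            contrast = make_contrast(ann, variable, level)
            target_config = replace(config, seed=_stage_seed(config.seed, f"{variable}={level}"))
            models.append(
                sequential_forward_select(expr, contrast, candidates, target_config)
            )
        except ContrastError as exc:
            logger.warning("skipping %s=%s: %s", variable, level, exc)
    return models
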