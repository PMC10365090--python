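"""Classifier grid, hold-out validation and the evaluation metric panel.

Classifiers: linear-kernel SVM with box constraint 1, a feed-forward MLP
(one hidden layer of 10 logistic units), and a bagged ensemble of depth-
limited decision trees ("random forests with a split of 10": each tree is
limited to 10 splits; ensemble size 1 recovers a single decision tree).
The positive class is disease control. Feature selection is always refit
inside the training partition of the hold-out split — the leakage-safe
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ctradiomics.errors import ConfigurationError
from ctradiomics.feature_selection import SelectionConfig, rank_features, select_top
from ctradiomics.feature_table import FeatureTable

CLASSIFIERS = ("svm_linear", "mlp", "tree_ensemble")

#: "a split of 10" read as 10 binary splits per tree
TREE_MAX_SPLITS = 10
TREE_ENSEMBLE_SIZE = 50


@dataclass(frozen=True)
class ModelConfig:
    classifier: str = "svm_linear"
    svm_box_constraint: float = 1.0
    mlp_hidden_layer_sizes: tuple[int, ...] = (10,)
    tree_max_splits: int = TREE_MAX_SPLITS
    tree_ensemble_size: int = TREE_ENSEMBLE_SIZE
    holdout_train_fraction: float = 0.75
    seed: int = 0
    cv_seed: int = 0

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ConfigurationError(f"unknown classifier {self.classifier!r}")
        if self.svm_box_constraint <= 0:
            raise ConfigurationError("box constraint must be positive")
        if not 0.0 < self.holdout_train_fraction < 1.0:
            raise ConfigurationError("train fraction must lie in (0, 1)")


@dataclass
class EvaluationReport:
    """Metric panel for one split; accuracy == 100 - misclassification rate."""

    split: str
    auroc: float
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    misclassification_rate_pct: float
    misclassified_count: int
    n: int

    def as_dict(self) -> dict:
        return {
            "split": self.split,
            "AUROC": self.auroc,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "misclassification_rate_pct": self.misclassification_rate_pct,
            "misclassified_count": self.misclassified_count,
            "n": self.n,
        }


def auroc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ConfigurationError("AUROC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def evaluate(scores, predictions, labels, split: str) -> EvaluationReport:
    """Metric panel with disease control (label 1) as the positive class."""
    y = np.asarray(labels).astype(int).ravel()
    yhat = np.asarray(predictions).astype(int).ravel()
    n = y.size
    tp = int(((yhat == 1) & (y == 1)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    mis = fp + fn
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    rate = 100.0 * mis / n
    return EvaluationReport(
        split=split,
        auroc=auroc(scores, y),
        accuracy_pct=100.0 - rate,
        sensitivity_pct=sens,
        specificity_pct=spec,
        misclassification_rate_pct=rate,
        misclassified_count=mis,
        n=n,
    )


class TrainedModel:
    """Fitted classifier exposing a continuous score and a binary decision."""

    def __init__(self, estimator, feature_names: list[str], cfg: ModelConfig):
        self.estimator = estimator
        self.feature_names = list(feature_names)
        self.config = cfg

    def _matrix(self, table: FeatureTable) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.data.columns]
        if missing:
            raise ConfigurationError(f"missing feature columns: {missing}")
        return table.data[self.feature_names].to_numpy(dtype=float)

    def scores(self, table: FeatureTable) -> np.ndarray:
        x = self._matrix(table)
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(x))
        return np.asarray(self.estimator.predict_proba(x)[:, 1])

    def predict(self, table: FeatureTable) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._matrix(table))).astype(int)


def _build_estimator(cfg: ModelConfig):
    if cfg.classifier == "svm_linear":
        return SVC(kernel="linear", C=cfg.svm_box_constraint)
    if cfg.classifier == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=cfg.mlp_hidden_layer_sizes,
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=cfg.seed,
        )
    tree = DecisionTreeClassifier(
        max_leaf_nodes=cfg.tree_max_splits + 1, random_state=cfg.seed
    )
    if cfg.tree_ensemble_size == 1:
        return tree
    return BaggingClassifier(
        estimator=tree, n_estimators=cfg.tree_ensemble_size, random_state=cfg.seed
    )


def train(table: FeatureTable, labels, cfg: ModelConfig) -> TrainedModel:
    """Fit a classifier on already-selected, already-normalized features."""
    x = table.data.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training labels contain a single class")
    est = _build_estimator(cfg)
    est.fit(x, y)
    return TrainedModel(est, table.feature_names, cfg)


def stratified_holdout_split(
    labels, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of a single stratified split. Resplits (with an
    incremented seed) if a partition ends up single-class."""
    y = np.asarray(labels).astype(int).ravel()
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        train_idx, val_idx = [], []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            n_train = int(round(train_fraction * len(idx)))
            train_idx.extend(idx[:n_train])
            val_idx.extend(idx[n_train:])
        train_idx = np.sort(train_idx)
        val_idx = np.sort(val_idx)
        if len(np.unique(y[train_idx])) == 2 and len(np.unique(y[val_idx])) == 2:
            return train_idx, val_idx
    raise ConfigurationError("could not produce a two-class stratified split")


@dataclass
class PipelineResult:
    train_report: EvaluationReport
    validation_report: EvaluationReport
    model: TrainedModel
    selected_features: list[str]
    selection_config: SelectionConfig = field(default_factory=SelectionConfig)


def holdout_cv(
    table: FeatureTable,
    labels,
    model_cfg: ModelConfig,
    selection_cfg: SelectionConfig | None = None,
    force_include: tuple[str, ...] = (),
) -> PipelineResult:
    """Single stratified 75/25 hold-out with selection inside the split.

    The table is normalized per partition (each side with its own
    statistics), selection is refit on the training partition only, and the
    metric panel is emitted for both partitions. Columns in
    ``force_include`` are guaranteed a slot in the selected set (displacing
    the lowest-ranked pick if necessary).
    """
    y = np.asarray(labels).astype(int).ravel()
    if y.size < 8:
        raise ConfigurationError("need at least 8 subjects for hold-out validation")
    tr_idx, va_idx = stratified_holdout_split(
        y, model_cfg.holdout_train_fraction, model_cfg.cv_seed
    )
    ids = np.asarray(table.subject_ids)
    train_tab = table.subset(ids[tr_idx]).zscore_normalize()
    val_tab = table.subset(ids[va_idx]).zscore_normalize()
    y_tr, y_va = y[tr_idx], y[va_idx]

    if selection_cfg is not None:
        n_sel = min(selection_cfg.n_select, train_tab.n_features)
        if n_sel < selection_cfg.n_select:
            selection_cfg = replace(selection_cfg, n_select=n_sel)
        ranking = rank_features(train_tab, y_tr, selection_cfg)
        selected = select_top(ranking, n_sel)
        for name in force_include:
            if name not in selected:
                if name not in train_tab.data.columns:
                    raise ConfigurationError(
                        f"forced feature {name!r} missing from table"
                    )
                selected = selected[:-1] + [name]
    else:
        selected = train_tab.feature_names
        selection_cfg = SelectionConfig()

    model = train(train_tab.select(selected), y_tr, model_cfg)
    val_sel = val_tab.select(selected)
    return PipelineResult(
        train_report=evaluate(
            model.scores(train_tab.select(selected)),
            model.predict(train_tab.select(selected)),
            y_tr,
            "train",
        ),
        validation_report=evaluate(
            model.scores(val_sel), model.predict(val_sel), y_va, "internal_cv"
        ),
        model=model,
        selected_features=selected,
        selection_config=selection_cfg,
    )


def external_validate(
    model: TrainedModel, external_table: FeatureTable, labels
) -> EvaluationReport:
    """Metric panel on an untouched external cohort.

    The external table is normalized independently with its own Z-scores
    before inference, mirroring the per-database normalization rule.
    """
    tab = external_table.zscore_normalize().select(model.feature_names)
    y = np.asarray(labels).astype(int).ravel()
    return evaluate(model.scores(tab), model.predict(tab), y, "external_validation")
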