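"""Dimension reduction: ReliefF and relevancy-redundancy statistical ranking.

The statistical method greedily ranks features with the composite score
``S = |Z| * (1 - alpha * rho)`` where ``Z`` is a two-class relevancy
statistic (t, rank-sum, or scaled |AUROC - 0.5|) and ``rho`` is the mean
absolute Pearson correlation with the already-selected features. The
source formula is printed as ``S = Z * [(1 - alpha) rho]``, which rewards
redundancy and contradicts its own stated purpose; the corrected form is
the default and the literal printed form stays available behind
``literal_score=True`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ctradiomics.errors import ConfigurationError
from ctradiomics.feature_table import FeatureTable

Z_STATISTICS = ("t_test", "wilcoxon", "auroc")
DEFAULT_ALPHA = 0.7
DEFAULT_K_NEIGHBORS = 10


@dataclass(frozen=True)
class SelectionConfig:
    method: str = "statistical"  # or "relieff"
    z_statistic: str = "t_test"
    alpha: float = DEFAULT_ALPHA
    k_neighbors: int = DEFAULT_K_NEIGHBORS
    n_select: int = 30
    literal_score: bool = False

    def __post_init__(self):
        if self.method not in ("statistical", "relieff"):
            raise ConfigurationError(f"unknown selection method {self.method!r}")
        if self.z_statistic not in Z_STATISTICS:
            raise ConfigurationError(f"unknown z statistic {self.z_statistic!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.n_select < 1:
            raise ConfigurationError("n_select must be >= 1")


@dataclass
class SelectionResult:
    """Ranked selection with per-feature Z, redundancy rho and score S."""

    selected: list[str]
    z: pd.Series  # relevancy statistic per feature (all features)
    rho: pd.Series  # redundancy at selection time (selected only)
    score: pd.Series  # composite S (selected) or ReliefF weight (all)
    config: SelectionConfig = field(default_factory=SelectionConfig)

    def write_tsv(self, path: str) -> None:
        rows = []
        for rank, name in enumerate(self.selected, start=1):
            rows.append(
                {
                    "feature": name,
                    "rank": rank,
                    "Z": self.z.get(name, np.nan),
                    "rho": self.rho.get(name, np.nan),
                    "score": self.score.get(name, np.nan),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _as_xy(table: FeatureTable, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    x = table.data.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if x.shape[0] != y.size:
        raise ConfigurationError("labels length does not match table")
    if set(np.unique(y)) - {0, 1}:
        raise ConfigurationError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("both classes must be present")
    return x, y, list(table.data.columns)


# ------------------------------------------------------------------- ReliefF
def relieff_weights(x: np.ndarray, y: np.ndarray, k: int = DEFAULT_K_NEIGHBORS) -> np.ndarray:
    """Standard ReliefF weights for binary labels.

    Every instance contributes margins from its k nearest hits and k
    nearest misses under Manhattan distance on range-scaled features. A
    class with fewer than k+1 members truncates k with a warning.
    """
    n, p = x.shape
    rng_span = x.max(axis=0) - x.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    xs = x / rng_span  # per-feature diffs are now |a-b| in [0, 1]

    class_counts = np.bincount(y, minlength=2)
    k_eff = min(k, class_counts.min() - 1)
    if k_eff < k:
        warnings.warn(f"class too small for k={k}; truncated to k={k_eff}")
    if k_eff < 1:
        raise ConfigurationError("need at least 2 subjects per class for ReliefF")

    # prior of the miss class, per instance, as in multi-class ReliefF
    priors = class_counts / n

    dist = np.abs(xs[:, None, :] - xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_eff]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_eff]]
        hit_diff = np.abs(xs[hits] - xs[i]).mean(axis=0)
        miss_diff = np.abs(xs[misses] - xs[i]).mean(axis=0)
        miss_w = priors[1 - y[i]] / (1.0 - priors[y[i]])  # = 1 for binary
        w += (miss_w * miss_diff - hit_diff) / n
    return w


def relieff_rank(
    table: FeatureTable, labels, k: int = DEFAULT_K_NEIGHBORS
) -> SelectionResult:
    """Rank all features by descending ReliefF weight."""
    x, y, names = _as_xy(table, labels)
    w = relieff_weights(x, y, k)
    order = np.argsort(-w, kind="stable")  # ties broken by column order
    weights = pd.Series(w, index=names)
    return SelectionResult(
        selected=[names[i] for i in order],
        z=weights,
        rho=pd.Series(dtype=float),
        score=weights,
        config=SelectionConfig(method="relieff", k_neighbors=k),
    )


# ------------------------------------------------------- statistical ranking
def relevancy_statistic(x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Per-feature two-class statistic Z; zero-variance features get Z=0."""
    x0, x1 = x[y == 0], x[y == 1]
    variable = x.std(axis=0) > 0
    z = np.zeros(x.shape[1])
    if kind == "t_test":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(x1, x0, axis=0)
        z[variable] = t[variable]
    elif kind == "wilcoxon":
        for j in np.flatnonzero(variable):
            z[j] = stats.ranksums(x1[:, j], x0[:, j]).statistic
    elif kind == "auroc":
        n0, n1 = len(x0), len(x1)
        for j in np.flatnonzero(variable):
            ranks = stats.rankdata(x[:, j])
            auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
            z[j] = 2.0 * abs(auc - 0.5)
    else:
        raise ConfigurationError(f"unknown z statistic {kind!r}")
    return np.nan_to_num(z)


def statistical_rank(table: FeatureTable, cfg: SelectionConfig, labels) -> SelectionResult:
    """Greedy forward relevancy-redundancy ranking.

    Step 1 picks the max-|Z| feature (rho of an empty set is 0). Each later
    step recomputes, for every remaining candidate, rho = mean |Pearson r|
    with the selected set and S = |Z| * (1 - alpha * rho), then picks the
    max-S candidate; column order breaks ties.
    """
    x, y, names = _as_xy(table, labels)
    n, p = x.shape
    n_select = min(cfg.n_select, p)

    z = relevancy_statistic(x, y, cfg.z_statistic)
    abs_z = np.abs(z)

    # z-scored columns so Pearson r is a dot product / n
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    xn = (x - x.mean(axis=0)) / sd_safe
    xn[:, sd == 0] = 0.0

    selected: list[int] = []
    rho_at_pick = np.zeros(p)
    score_at_pick = np.zeros(p)
    abs_corr_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)

    for step in range(n_select):
        if step == 0:
            rho = np.zeros(p)
        else:
            rho = abs_corr_sum / step
        if cfg.literal_score:
            score = abs_z * (1.0 - cfg.alpha) * rho
        else:
            score = abs_z * (1.0 - cfg.alpha * rho)
        score = np.where(available, score, -np.inf)
        pick = int(np.argmax(score))
        selected.append(pick)
        available[pick] = False
        rho_at_pick[pick] = rho[pick]
        score_at_pick[pick] = score[pick]
        abs_corr_sum += np.abs(xn.T @ xn[:, pick]) / n

    sel_names = [names[i] for i in selected]
    return SelectionResult(
        selected=sel_names,
        z=pd.Series(z, index=names),
        rho=pd.Series(rho_at_pick[selected], index=sel_names),
        score=pd.Series(score_at_pick[selected], index=sel_names),
        config=cfg,
    )


def rank_features(table: FeatureTable, labels, cfg: SelectionConfig) -> SelectionResult:
    """Dispatch on ``cfg.method``."""
    if cfg.method == "relieff":
        return relieff_rank(table, labels, cfg.k_neighbors)
    return statistical_rank(table, cfg, labels)


def select_top(result: SelectionResult, n: int) -> list[str]:
    """First ``n`` feature names in rank order."""
    if n > len(result.selected):
        raise ConfigurationError(
            f"cannot select {n} features from a ranking of {len(result.selected)}"
        )
    return result.selected[:n]
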