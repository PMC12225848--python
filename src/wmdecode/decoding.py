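"""Label decoding from region-metric feature vectors.

Each decoding run repeats a stratified random 80/20 subsampling: z-scoring
fitted on the training rows only, Relief-style feature weighting on the
training rows only, top-weighted features into a linear maximum-margin
classifier, accuracy scored on the held-out rows.  Selection frequencies
across repeats and label-permutation nulls quantify stability and chance
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.svm import SVC

from .defs import FEATURE_NAMES

__all__ = [
    "DecodingConfig",
    "FeatureTable",
    "DecodingRun",
    "SelectionFrequency",
    "PermutationNull",
    "zscore_fit_apply",
    "minmax_fit_apply",
    "relief_scores",
    "run_decoding",
    "pth_scan",
    "permutation_test",
    "rt_classes",
]


@dataclass(frozen=True)
class DecodingConfig:
    n_repeats: int = 100
    test_fraction: float = 0.2
    n_selected: int = 9
    k_neighbors: int = 10
    svm_c: float = 1.0
    scaling: str = "zscore"  # or "minmax"
    seed: int = 0


@dataclass
class FeatureTable:
    """Feature matrix with binary labels (and optional subject grouping)."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    band: str | None = None
    pth: float | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes disagree")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing/non-finite feature values")
        if np.unique(self.y).size != 2:
            raise ValueError("need exactly two classes")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        label_column: str,
        classes: tuple[str, str] | None = None,
        feature_names: tuple[str, ...] = FEATURE_NAMES,
    ) -> "FeatureTable":
        sub = frame
        if classes is not None:
            sub = frame[frame[label_column].isin(classes)]
        groups = (
            sub["subject_id"].to_numpy() if "subject_id" in sub.columns else None
        )
        return cls(
            X=sub[list(feature_names)].to_numpy(),
            y=sub[label_column].to_numpy(),
            groups=groups,
            feature_names=feature_names,
            band=sub["band"].iloc[0] if "band" in sub.columns else None,
            pth=float(sub["pth"].iloc[0]) if "pth" in sub.columns else None,
        )


@dataclass
class DecodingRun:
    accuracies: np.ndarray
    selection_matrix: np.ndarray  # n_repeats x n_features, 0/1
    config: DecodingConfig

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class SelectionFrequency:
    counts: np.ndarray  # per-feature integer, 0..n_repeats
    n_repeats: int
    n_selected: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    significant: np.ndarray | None = None


@dataclass
class PermutationNull:
    null_accuracies: np.ndarray
    p_value: float  # empirical permutation p (calibrated)
    p_ranksum: float  # rank-sum of true repeats vs null means (anti-conservative)
    n_shuffles: int
    true_run: DecodingRun | None = None


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets with the training mean and sample (n-1) SD;
    zero-variance features map to 0 everywhere."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    train_z = (train - mean) / safe
    test_z = (test - mean) / safe
    train_z[:, sd == 0] = 0.0
    test_z[:, sd == 0] = 0.0
    return train_z, test_z


def minmax_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scale to [0, 1] with the training min/max; constant features map to 0."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    lo, hi = train.min(axis=0), train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    train_s = (train - lo) / span
    test_s = (test - lo) / span
    const = hi == lo
    train_s[:, const] = 0.0
    test_s[:, const] = 0.0
    return train_s, test_s


_SCALERS = {"zscore": zscore_fit_apply, "minmax": minmax_fit_apply}


def relief_scores(
    features: np.ndarray, labels: np.ndarray, k_neighbors: int = 10
) -> np.ndarray:
    """ReliefF weights for binary labels.

    For every sample the k nearest same-class (hits) and k nearest
    other-class (misses) neighbors under Euclidean distance contribute
    +|feature diff| for misses and -|feature diff| for hits, with diffs
    scaled by the feature range; the total is averaged over samples.
    Deterministic: neighbor ties resolve by sample index.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("relief_scores requires exactly two classes")
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= "
            f"{k_neighbors + 1} for k_neighbors={k_neighbors}"
        )
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    weights = np.zeros(d)
    for i in range(n):
        same = (y == y[i]).nonzero()[0]
        same = same[same != i]
        other = (y != y[i]).nonzero()[0]
        hits = same[np.lexsort((same, dist[i, same]))][:k_neighbors]
        misses = other[np.lexsort((other, dist[i, other]))][:k_neighbors]
        hit_diff = np.abs(X[hits] - X[i]) / span
        miss_diff = np.abs(X[misses] - X[i]) / span
        weights += miss_diff.mean(axis=0) - hit_diff.mean(axis=0)
    return weights / n


def _stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        members = np.nonzero(y == cls)[0]
        perm = rng.permutation(members)
        n_test = max(1, int(round(test_fraction * members.size)))
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _top_features(weights: np.ndarray, n_selected: int) -> np.ndarray:
    # ties broken toward the lower feature index
    order = np.lexsort((np.arange(weights.size), -weights))
    return np.sort(order[:n_selected])


def run_decoding(
    table: FeatureTable, config: DecodingConfig = DecodingConfig()
) -> tuple[DecodingRun, SelectionFrequency]:
    """Repeated stratified 80/20 subsampling decoding.

    Per repeat: scale (train-fit), Relief on the scaled training rows, keep
    the ``n_selected`` top-weighted features, train a linear SVM, score on
    the held-out rows.  Reproducible from ``config.seed``.
    """
    X, y = table.X, table.y
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 trials per class, got class sizes {counts.tolist()}"
        )
    n_features = X.shape[1]
    n_selected = min(config.n_selected, n_features)
    scaler = _SCALERS[config.scaling]
    rng = np.random.default_rng(config.seed)
    accuracies = np.empty(config.n_repeats)
    selection = np.zeros((config.n_repeats, n_features), dtype=int)
    for rep in range(config.n_repeats):
        train_idx, test_idx = _stratified_split(y, config.test_fraction, rng)
        train_s, test_s = scaler(X[train_idx], X[test_idx])
        k_nb = min(config.k_neighbors, np.bincount(
            pd.factorize(y[train_idx])[0]).min() - 1)
        weights = relief_scores(train_s, y[train_idx], k_neighbors=max(1, k_nb))
        chosen = _top_features(weights, n_selected)
        selection[rep, chosen] = 1
        clf = SVC(kernel="linear", C=config.svm_c)
        clf.fit(train_s[:, chosen], y[train_idx])
        accuracies[rep] = clf.score(test_s[:, chosen], y[test_idx])
    run = DecodingRun(accuracies=accuracies, selection_matrix=selection, config=config)
    freq = SelectionFrequency(
        counts=selection.sum(axis=0),
        n_repeats=config.n_repeats,
        n_selected=n_selected,
        feature_names=table.feature_names,
    )
    return run, freq


def pth_scan(
    tables: dict[float, FeatureTable], config: DecodingConfig = DecodingConfig()
) -> tuple[float, DecodingRun, SelectionFrequency, dict[float, float]]:
    """Decode at every threshold and keep the one with the highest mean
    accuracy (ties go to the smallest pth)."""
    if not tables:
        raise ValueError("no thresholds supplied")
    results = {}
    for pth in sorted(tables):
        results[pth] = run_decoding(tables[pth], config)
    mean_by_pth = {pth: run.mean_accuracy for pth, (run, _) in results.items()}
    best_pth = max(sorted(mean_by_pth), key=lambda pth: mean_by_pth[pth])
    best_pth = min(
        pth for pth in mean_by_pth if mean_by_pth[pth] == mean_by_pth[best_pth]
    )
    run, freq = results[best_pth]
    return best_pth, run, freq, mean_by_pth


def permutation_test(
    table: FeatureTable,
    config: DecodingConfig = DecodingConfig(),
    n_shuffles: int = 1000,
    r_perm: int = 10,
    true_run: DecodingRun | None = None,
) -> PermutationNull:
    """Label-permutation null for a decoding run.

    Every shuffle permutes the labels (never the features) and reruns the
    full pipeline -- selection included -- with ``r_perm`` subsampling
    repeats; the per-shuffle mean accuracies form the null.

    Two p-values are reported.  ``p_value`` is the empirical permutation
    p, (1 + #{null >= true mean}) / (n_shuffles + 1): exact under label
    exchangeability, and exactly calibrated when ``r_perm`` equals the true
    run's repeat count.  ``p_ranksum`` is the two-sided rank-sum between
    the true run's per-repeat accuracies and the null accuracies; the true
    repeats all share one labeling, so under the null this comparison is
    pseudo-replicated and rejects far too often -- it is kept for
    comparability with common practice, not for inference.
    """
    if true_run is None:
        true_run, _ = run_decoding(table, config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    null_cfg = replace(config, n_repeats=r_perm)
    null_accs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        y_perm = rng.permutation(table.y)
        shuffled = FeatureTable(
            X=table.X, y=y_perm, feature_names=table.feature_names
        )
        run, _ = run_decoding(
            shuffled, replace(null_cfg, seed=int(rng.integers(2**31)))
        )
        null_accs[s] = run.mean_accuracy
    p_emp = float(
        (1 + np.sum(null_accs >= true_run.mean_accuracy)) / (n_shuffles + 1)
    )
    p_ranksum = float(ranksums(true_run.accuracies, null_accs).pvalue)
    return PermutationNull(
        null_accuracies=null_accs,
        p_value=p_emp,
        p_ranksum=p_ranksum,
        n_shuffles=n_shuffles,
        true_run=true_run,
    )


def rt_classes(
    rt_ms: np.ndarray, subject_ids: np.ndarray
) -> np.ndarray:
    """Fast/slow labels for one condition's pooled reaction times.

    RTs are z-scored within subject (controls baseline speed differences),
    pooled and sorted ascending; the floor(N/4) smallest are 'fast', the
    floor(N/4) largest 'slow', the rest 'excluded'.
    """
    rt_ms = np.asarray(rt_ms, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if np.any(rt_ms <= 0):
        raise ValueError("reaction times must be positive")
    n = rt_ms.size
    if n < 8:
        raise ValueError(f"need >= 8 pooled trials, got {n}")
    z = np.empty(n)
    for subject in np.unique(subject_ids):
        members = subject_ids == subject
        vals = rt_ms[members]
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        z[members] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    n_q = n // 4
    order = np.lexsort((np.arange(n), z))  # stable under ties
    labels = np.full(n, "excluded", dtype=object)
    labels[order[:n_q]] = "fast"
    labels[order[n - n_q :]] = "slow"
    return labels
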